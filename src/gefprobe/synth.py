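"""Seeded synthetic-data generators with known ground truth.

Every input class the analysis modules consume can be generated here
deterministically: conformational ensembles of an idealised multi-domain CA
chain with controllable per-residue flexibility, binding scenarios with a
known fraction of sterically intruding frames, multiple sequence alignments
with designed block-identity structure, and mant-GDP exchange traces drawn
from the mono-exponential model. All randomness flows through
``numpy.random.default_rng`` (PCG64), so a seed fully determines the output;
ground-truth labels/parameters are returned alongside the data, making every
downstream test self-validating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import KineticTrace
from .msa import Msa
from .structures import Atom, Ensemble, SelectionSpec, Structure
from .clash import ResidueMap

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Ideal alpha-helical CA geometry: 2.3 A radius, 1.5 A rise, 100 deg twist
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully seeded generator request: same spec, byte-identical output."""

    seed: int
    kind: str  # "ensemble" | "binding" | "msa" | "trace"
    parameters: dict = field(default_factory=dict)


def _helix_backbone(n_res: int, start_resnum: int = 1, chain_id: str = "A",
                    origin: np.ndarray | None = None) -> Structure:
    """Idealised CA-only helical chain, ~3.8 A CA-CA spacing."""
    atoms = []
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    for i in range(n_res):
        t = i * _HELIX_TWIST
        xyz = origin + np.array(
            [_HELIX_RADIUS * np.cos(t), _HELIX_RADIUS * np.sin(t), _HELIX_RISE * i]
        )
        atoms.append(
            Atom(serial=i + 1, name="CA", element="C", residue_name="ALA",
                 chain_id=chain_id, residue_number=start_resnum + i, coords=xyz)
        )
    return Structure(atoms=atoms, label=f"helix{n_res}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_toy_ensemble(
    n_res: int,
    sigma_profile: np.ndarray | float,
    n_frames: int,
    seed: int,
    species_label: str = "toy",
    rigid_transforms: bool = True,
) -> tuple[Ensemble, dict]:
    """Jittered idealised chain: per-residue isotropic Gaussian flexibility.

    Each frame is the helical base chain with residue i displaced by
    N(0, sigma_profile[i]^2) per axis, then (optionally) given a random rigid
    transform so that superposition is genuinely exercised downstream.
    Returns the ensemble and a ground-truth dict with the sigma profile.
    """
    if n_res < 4:
        raise ValueError("need n_res >= 4")
    if n_frames < 2:
        raise ValueError("need n_frames >= 2")
    sigma = np.broadcast_to(np.asarray(sigma_profile, float), (n_res,)).copy()
    if np.any(sigma < 0):
        raise ValueError("sigma_profile must be non-negative")
    rng = np.random.default_rng(seed)
    base = _helix_backbone(n_res)
    base_coords = base.coords
    frames = []
    for _ in range(n_frames):
        jitter = rng.normal(size=(n_res, 3)) * sigma[:, None]
        coords = base_coords + jitter
        if rigid_transforms:
            rot = _random_rotation(rng)
            trans = rng.uniform(-20.0, 20.0, size=3)
            coords = coords @ rot.T + trans
        frames.append(coords)
    ens = Ensemble(topology=base, frames=frames, species_label=species_label)
    truth = {"sigma_profile": sigma.tolist(), "seed": seed,
             "expected_rmsf": (sigma * np.sqrt(3.0)).tolist()}
    return ens, truth


def _rigid_mode_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3n) of rigid-body modes at a configuration."""
    n = coords.shape[0]
    centred = coords - coords.mean(axis=0)
    modes = []
    for k in range(3):
        t = np.zeros((n, 3)); t[:, k] = 1.0
        modes.append(t.ravel())
    for k in range(3):
        e = np.zeros(3); e[k] = 1.0
        modes.append(np.cross(np.broadcast_to(e, (n, 3)), centred).ravel())
    basis = np.array(modes)
    q, _ = np.linalg.qr(basis.T)
    return q.T[:6]


def make_mode_ensemble(
    n_res: int,
    mode_variances: list[float],
    n_frames: int,
    seed: int,
    species_label: str = "modes",
    rigid_transforms: bool = True,
) -> tuple[Ensemble, dict]:
    """Ensemble fluctuating along a few known internal collective modes.

    Displacement directions are random unit vectors orthogonalised against
    the six rigid-body modes (and each other), so rigid superposition leaves
    the internal amplitudes untouched and the generating covariance is known
    exactly: variance ``mode_variances[k]`` (A^2) along direction k. Ground
    truth includes the directions and the expected PCA variance fractions.
    """
    rng = np.random.default_rng(seed)
    base = _helix_backbone(n_res)
    y = base.coords
    dim = 3 * n_res
    rigid = _rigid_mode_basis(y)
    dirs = []
    for _ in mode_variances:
        v = rng.normal(size=dim)
        v -= rigid.T @ (rigid @ v)
        for d in dirs:
            v -= d * (d @ v)
        v /= np.linalg.norm(v)
        dirs.append(v)
    dirs = np.array(dirs)
    sds = np.sqrt(np.asarray(mode_variances, float))
    amps = rng.normal(size=(n_frames, len(sds))) * sds
    frames = []
    for a in amps:
        coords = (y.ravel() + dirs.T @ a).reshape(n_res, 3)
        if rigid_transforms:
            rot = _random_rotation(rng)
            trans = rng.uniform(-20.0, 20.0, size=3)
            coords = coords @ rot.T + trans
        frames.append(coords)
    ens = Ensemble(topology=base, frames=frames, species_label=species_label)
    v = np.asarray(mode_variances, float)
    truth = {
        "mode_variances": v.tolist(),
        "expected_variance_fractions": (v / v.sum()).tolist(),
        "directions": dirs,
        "amplitudes": amps,
        "seed": seed,
    }
    return ens, truth


def make_binding_scenario(
    p_intrude: float,
    n_frames: int,
    seed: int,
    n_intrude: int | None = None,
    species_label: str = "synthetic",
) -> tuple[Ensemble, Structure, ResidueMap, SelectionSpec, SelectionSpec, dict]:
    """Ground-truth scenario for the steric binding-compatibility statistic.

    The template holds an anchor chain A (residues 1-50) and a partner chain
    B (residues 120-133) at a fixed offset. Ensemble frames share the anchor
    geometry; a mobile loop (chain A, residues 62-78) is either kept clear of
    the partner (all inter-region distances > 6 A) or displaced into it
    (distances < 1 A, guaranteed vdW overlap > 1 A). Intrusion is Bernoulli
    with probability ``p_intrude`` unless ``n_intrude`` pins the exact count
    (first ``n_intrude`` frames after a seeded shuffle). Each frame then gets
    a random rigid transform. Returns (ensemble, template, residue map,
    mobile-region spec, template-region spec, ground truth).
    """
    if not (0.0 <= p_intrude <= 1.0):
        raise ValueError("p_intrude must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_anchor, n_loop, n_partner = 50, 17, 14
    anchor = _helix_backbone(n_anchor, start_resnum=1, chain_id="A")
    partner_origin = np.array([30.0, 0.0, 0.0])
    partner = _helix_backbone(n_partner, start_resnum=120, chain_id="B",
                              origin=partner_origin)
    template = Structure(atoms=anchor.atoms + partner.atoms, label="template")

    partner_coords = partner.coords
    # clear placement: far from the partner in -x
    clear_loop = _helix_backbone(n_loop, start_resnum=62, chain_id="A",
                                 origin=np.array([-30.0, 10.0, 0.0])).coords
    # intruding placement: first loop atoms sit 0.3 A off partner atoms
    intrude_loop = clear_loop.copy()
    k = min(n_loop, n_partner)
    intrude_loop[:k] = partner_coords[:k] + np.array([0.3, 0.0, 0.0])

    loop_atoms = [
        Atom(serial=n_anchor + i + 1, name="CA", element="C", residue_name="ALA",
             chain_id="A", residue_number=62 + i, coords=clear_loop[i])
        for i in range(n_loop)
    ]
    topology = Structure(atoms=anchor.atoms + loop_atoms, label="mobile")
    anchor_coords = anchor.coords

    if n_intrude is not None:
        labels = np.zeros(n_frames, dtype=bool)
        labels[:n_intrude] = True
        rng.shuffle(labels)
    else:
        labels = rng.random(n_frames) < p_intrude
    frames = []
    for intruded in labels:
        loop = intrude_loop if intruded else clear_loop
        coords = np.vstack([anchor_coords, loop])
        rot = _random_rotation(rng)
        trans = rng.uniform(-20.0, 20.0, size=3)
        frames.append(coords @ rot.T + trans)
    ens = Ensemble(topology=topology, frames=frames, species_label=species_label)
    rmap = ResidueMap(
        pairs=[(("A", r), ("A", r)) for r in range(1, n_anchor + 1)], source="user"
    )
    region_mobile = SelectionSpec(chain_id="A", residue_range=(62, 78))
    region_template = SelectionSpec(chain_id="B", residue_range=(120, 133))
    truth = {
        "intruded": labels.tolist(),
        "n_intruded": int(labels.sum()),
        "expected_percent_compatible": 100.0 * int(n_frames - labels.sum()) / n_frames,
        "p_intrude": p_intrude,
        "seed": seed,
    }
    return ens, template, rmap, region_mobile, region_template, truth


def make_synthetic_msa(
    block_sizes: list[int],
    within_identity: float,
    between_identity: float,
    length: int = 400,
    seed: int = 0,
) -> tuple[Msa, dict]:
    """Gapless MSA whose pairwise identities follow a block design.

    A root sequence is mutated into one ancestor per block, and each block
    member is the ancestor with further mutations; mutation counts are chosen
    so the expected within-block and between-block identities equal the
    targets (realised values scatter by a few points at the default length).
    The realised identity matrix is returned in the ground truth.
    """
    if not (0 <= between_identity < within_identity <= 100):
        raise ValueError("need 0 <= between < within <= 100")
    rng = np.random.default_rng(seed)
    L = length
    w = within_identity / 100.0
    b = between_identity / 100.0
    # member mutations m: expected within identity 1 - (2m - m^2/L)/L = w
    m = int(round(L - L * np.sqrt(w)))
    # ancestor mutations c: expected between identity ~ (1-c/L)^2 * w = b
    c = int(round(L * (1.0 - np.sqrt(b / w))))

    root = rng.choice(list(AMINO_ACIDS), size=L)
    names, rows = [], []
    for bi, size in enumerate(block_sizes):
        ancestor = root.copy()
        pos = rng.choice(L, size=c, replace=False)
        for p in pos:
            ancestor[p] = rng.choice([a for a in AMINO_ACIDS if a != ancestor[p]])
        for si in range(size):
            seq = ancestor.copy()
            pos = rng.choice(L, size=m, replace=False)
            for p in pos:
                seq[p] = rng.choice([a for a in AMINO_ACIDS if a != seq[p]])
            names.append(f"block{bi}_seq{si}")
            rows.append("".join(seq))
    msa = Msa(names=names, rows=rows)
    from .msa import pairwise_identity_matrix

    realized = pairwise_identity_matrix(msa)
    block_index = np.concatenate(
        [np.full(s, i) for i, s in enumerate(block_sizes)]
    )
    truth = {
        "block_sizes": list(block_sizes),
        "block_index": block_index.tolist(),
        "within_identity_target": within_identity,
        "between_identity_target": between_identity,
        "realized_identity": realized.values.tolist(),
        "seed": seed,
    }
    return msa, truth


def make_ortholog_pair(
    length: int = 190, substitution_rate: float = 0.05, seed: int = 0
) -> tuple[str, str, dict]:
    """Synthetic ortholog pair: one sequence plus a mutated copy.

    A stand-in for closely related cross-species orthologs (e.g. a small
    GTPase and its fish counterpart): the second sequence carries an exact
    number of substitutions, round(rate * length), so the true ungapped
    identity is known by construction.
    """
    rng = np.random.default_rng(seed)
    a = rng.choice(list(AMINO_ACIDS), size=length)
    n_sub = int(round(substitution_rate * length))
    pos = rng.choice(length, size=n_sub, replace=False)
    bsec = a.copy()
    for p in pos:
        bsec[p] = rng.choice([x for x in AMINO_ACIDS if x != bsec[p]])
    truth = {"true_identity": 100.0 * (length - n_sub) / length,
             "n_substitutions": n_sub, "seed": seed}
    return "".join(a), "".join(bsec), truth


def make_trace(
    a0: float,
    a_plateau: float,
    k_obs: float,
    noise_sd: float,
    duration_s: float,
    sampling_s: float,
    baseline_s: float = 300.0,
    seed: int = 0,
    metadata: dict | None = None,
) -> tuple[KineticTrace, dict]:
    """Exchange trace from the mono-exponential model with a flat baseline.

    Samples every ``sampling_s`` seconds: a flat baseline at ``a0`` for
    ``baseline_s``, then (a0 - a_plateau) exp(-k_obs t') + a_plateau for
    ``duration_s``, with i.i.d. Gaussian noise of sd ``noise_sd`` throughout.
    ``t_reaction_start_s`` equals ``baseline_s``.
    """
    if k_obs < 0:
        raise ValueError("k_obs must be >= 0")
    if a_plateau > a0:
        raise ValueError("decay model requires a_plateau <= a0")
    if not (1.0 <= sampling_s <= 60.0):
        raise ValueError("sampling_s must be within [1, 60] s")
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, baseline_s + duration_s, sampling_s)
    ideal = np.where(
        time < baseline_s,
        a0,
        (a0 - a_plateau) * np.exp(-k_obs * np.clip(time - baseline_s, 0, None))
        + a_plateau,
    )
    signal = ideal + rng.normal(scale=noise_sd, size=time.shape) if noise_sd > 0 else ideal
    trace = KineticTrace(
        time_s=time, signal=signal, t_reaction_start_s=baseline_s,
        metadata=metadata or {"condition": "synthetic"},
    )
    truth = {"a0": a0, "a_plateau": a_plateau, "k_obs": k_obs,
             "noise_sd": noise_sd, "seed": seed}
    return trace, truth


def write_scenario(spec: ScenarioSpec, out_dir: str | Path) -> dict:
    """Materialise a scenario to disk in the formats the pipeline reads.

    Writes PDB/FASTA/CSV files plus ``ground_truth.json``; returns the ground
    truth. Used by the ``gefprobe synth`` CLI subcommand.
    """
    from . import structures as st
    from .kinetics import write_trace_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = dict(spec.parameters)
    if spec.kind == "ensemble":
        ens, truth = make_toy_ensemble(
            n_res=p.get("n_res", 60), sigma_profile=p.get("sigma", 0.5),
            n_frames=p.get("n_frames", 50), seed=spec.seed,
        )
        st.write_ensemble(ens, out / "ensemble.pdb")
    elif spec.kind == "binding":
        ens, template, rmap, _, _, truth = make_binding_scenario(
            p_intrude=p.get("p_intrude", 0.3), n_frames=p.get("n_frames", 100),
            seed=spec.seed,
        )
        st.write_ensemble(ens, out / "ensemble.pdb")
        st.write_structure(template, out / "template.pdb")
    elif spec.kind == "msa":
        msa, truth = make_synthetic_msa(
            block_sizes=p.get("block_sizes", [3, 3]),
            within_identity=p.get("within", 60.0),
            between_identity=p.get("between", 10.0),
            length=p.get("length", 400), seed=spec.seed,
        )
        with open(out / "alignment.fasta", "w") as fh:
            for name, row in zip(msa.names, msa.rows):
                fh.write(f">{name}\n{row}\n")
    elif spec.kind == "trace":
        trace, truth = make_trace(
            a0=p.get("a0", 1.0), a_plateau=p.get("a_plateau", 0.4),
            k_obs=p.get("k_obs", 0.01), noise_sd=p.get("noise_sd", 0.01),
            duration_s=p.get("duration_s", 3600.0),
            sampling_s=p.get("sampling_s", 5.0), seed=spec.seed,
        )
        write_trace_csv(trace, out / "trace.csv")
    else:
        raise ValueError(f"unknown scenario kind {spec.kind!r}")
    serializable = {k: v for k, v in truth.items()
                    if not isinstance(v, np.ndarray)}
    (out / "ground_truth.json").write_text(json.dumps(serializable, indent=2,
                                                      sort_keys=True))
    return truth
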