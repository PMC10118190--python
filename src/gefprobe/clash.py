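"""Steric binding-compatibility of an ensemble against a template complex.

The statistic: each ensemble frame is superposed onto a template GEF:GTPase
complex via an anchor domain (CA atoms of a residue-to-residue map), and
atoms of a mobile "clashing region" are checked for van der Waals overlap
with a region of the template-bound GTPase. A frame is binding-compatible
when no atom pair clashes; the per-species result is the percentage of
compatible frames.

A clash between atoms i, j means  d(i, j) < r_vdw(i) + r_vdw(j) - overlap_threshold,
i.e. the spheres interpenetrate by at least ``overlap_threshold`` (0.4 A by
default, the MolProbity-style serious-overlap cutoff). Heavy atoms only by
default. A plain distance-cutoff mode is available via ``distance_cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import (
    CA_ONLY,
    Ensemble,
    SelectionSpec,
    Structure,
    select_atoms,
)
from .superpose import SelectionError, kabsch
from . import msa as _msa


@dataclass(frozen=True)
class ResidueMap:
    """One-to-one pairing of mobile residues to template residues.

    Each pair maps a (chain_id, residue_number) on the mobile structure to one
    on the template. At least 3 pairs are required (a rigid superposition
    needs three points).
    """

    pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    source: str = "user"  # "user" | "alignment-derived"

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise ValueError(f"residue map needs >= 3 pairs, got {len(self.pairs)}")
        mob = [p[0] for p in self.pairs]
        tem = [p[1] for p in self.pairs]
        if len(set(mob)) != len(mob) or len(set(tem)) != len(tem):
            raise ValueError("residue map must be one-to-one (duplicate residues)")


@dataclass
class ClashReport:
    """Clashing atom pairs of one frame against the template region.

    Each entry of ``clashing_pairs`` is (mobile atom index, template atom
    index, distance in A, overlap in A). ``min_distance`` is the smallest
    inter-region distance regardless of clashing.
    """

    frame_index: int
    clashing_pairs: list[tuple[int, int, float, float]]
    is_compatible: bool
    min_distance: float = float("inf")

    @property
    def n_clashes(self) -> int:
        return len(self.clashing_pairs)


@dataclass
class CompatibilityResult:
    """Fraction of ensemble frames sterically compatible with binding."""

    species_label: str
    n_frames: int
    n_compatible: int
    per_frame: list[ClashReport] = field(default_factory=list)

    @property
    def percent_compatible(self) -> float:
        return 100.0 * self.n_compatible / self.n_frames

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species_label,
                "frame": [r.frame_index for r in self.per_frame],
                "n_clashes": [r.n_clashes for r in self.per_frame],
                "min_distance_A": [r.min_distance for r in self.per_frame],
                "compatible": [r.is_compatible for r in self.per_frame],
            }
        )

    def summary(self) -> dict:
        return {
            "species": self.species_label,
            "n_frames": self.n_frames,
            "n_compatible": self.n_compatible,
            "percent_compatible": self.percent_compatible,
        }


def build_residue_map(
    mobile: Structure,
    mobile_anchor: SelectionSpec,
    template: Structure,
    template_anchor: SelectionSpec,
    mode: str = "user",
    pairs: list[tuple[tuple[str, int], tuple[str, int]]] | None = None,
) -> ResidueMap:
    """Pair anchor residues of a mobile structure with a template.

    ``mode="user"`` validates a supplied pairing against both structures.
    ``mode="auto"`` extracts the one-letter sequences of the anchor CA atoms,
    aligns them globally, and pairs residues at aligned non-gap columns.
    """
    if mode == "user":
        if not pairs:
            raise ValueError("user mode requires explicit pairs")
        mob_keys = set(mobile.residue_keys())
        tem_keys = set(template.residue_keys())
        for m, t in pairs:
            if m not in mob_keys:
                raise ValueError(f"mobile residue {m} not found")
            if t not in tem_keys:
                raise ValueError(f"template residue {t} not found")
        return ResidueMap(pairs=list(pairs), source="user")
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    mob_res = _anchor_residues(mobile, mobile_anchor)
    tem_res = _anchor_residues(template, template_anchor)
    seq_m = "".join(r[2] for r in mob_res)
    seq_t = "".join(r[2] for r in tem_res)
    aln = _msa.global_align(seq_m, seq_t)
    out: list[tuple[tuple[str, int], tuple[str, int]]] = []
    i = j = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            out.append((mob_res[i][:2], tem_res[j][:2]))
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
    if len(out) < 3:
        raise ValueError(
            f"alignment-derived map has only {len(out)} pairs; anchors too dissimilar"
        )
    return ResidueMap(pairs=out, source="alignment-derived")


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "SEP": "S", "TPO": "T", "MSE": "M",
}


def _anchor_residues(s: Structure, anchor: SelectionSpec) -> list[tuple[str, int, str]]:
    spec = SelectionSpec(chain_id=anchor.chain_id, residue_range=anchor.residue_range,
                         atom_names=CA_ONLY)
    idx = select_atoms(s, spec)
    out = []
    for i in idx:
        a = s.atoms[i]
        out.append((a.chain_id, a.residue_number, THREE_TO_ONE.get(a.residue_name, "X")))
    return out


def detect_clashes(
    atoms_a: list,
    coords_a: np.ndarray,
    atoms_b: list,
    coords_b: np.ndarray,
    overlap_threshold: float = 0.4,
    distance_cutoff: float | None = None,
    frame_index: int = 0,
    radii: dict[str, float] | None = None,
) -> ClashReport:
    """All clashing atom pairs between two atom sets.

    With the default vdW-overlap policy, pair (i, j) clashes iff
    d(i, j) < r_i + r_j - overlap_threshold. Passing ``distance_cutoff``
    switches to a plain cutoff: clash iff d(i, j) < distance_cutoff.
    """
    if len(atoms_a) == 0 or len(atoms_b) == 0:
        raise SelectionError("clash detection requires non-empty atom sets")
    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)
    d = cdist(coords_a, coords_b)
    if distance_cutoff is not None:
        limit = np.full_like(d, float(distance_cutoff))
        overlaps = distance_cutoff - d
    else:
        ra = np.array([a.vdw_radius(radii) for a in atoms_a])
        rb = np.array([b.vdw_radius(radii) for b in atoms_b])
        vdw_sum = ra[:, None] + rb[None, :]
        limit = vdw_sum - overlap_threshold
        overlaps = vdw_sum - d
    ii, jj = np.nonzero(d < limit)
    pairs = [(int(i), int(j), float(d[i, j]), float(overlaps[i, j]))
             for i, j in zip(ii, jj)]
    return ClashReport(
        frame_index=frame_index,
        clashing_pairs=pairs,
        is_compatible=len(pairs) == 0,
        min_distance=float(d.min()),
    )


def compatibility_fraction(
    e: Ensemble,
    template: Structure,
    residue_map: ResidueMap,
    region_mobile: SelectionSpec,
    region_template: SelectionSpec,
    overlap_threshold: float = 0.4,
    distance_cutoff: float | None = None,
    heavy_atoms_only: bool = True,
    max_clashes: int = 0,
    stride: int = 1,
    radii: dict[str, float] | None = None,
) -> CompatibilityResult:
    """Percentage of frames that can bind the template partner without clashes.

    For every ``stride``-th frame: superpose the frame onto the template using
    the CA atoms of the mapped anchor residues, transform the frame's region
    atoms, and detect clashes against the template region. A frame is
    compatible when it has at most ``max_clashes`` clashing pairs (default 0:
    "does not clash"). Inputs are never mutated.
    """
    topo = e.topology
    mob_ca = {(a.chain_id, a.residue_number): i for i, a in enumerate(topo.atoms)
              if a.name.upper() == "CA"}
    tem_ca = {(a.chain_id, a.residue_number): i for i, a in enumerate(template.atoms)
              if a.name.upper() == "CA"}
    anchor_mob_idx, anchor_tem_idx = [], []
    for m, t in residue_map.pairs:
        if m not in mob_ca:
            raise ValueError(f"anchor residue {m} has no CA atom in ensemble topology")
        if t not in tem_ca:
            raise ValueError(f"anchor residue {t} has no CA atom in template")
        anchor_mob_idx.append(mob_ca[m])
        anchor_tem_idx.append(tem_ca[t])
    tem_coords = template.coords
    anchor_ref = tem_coords[anchor_tem_idx]

    reg_mob = select_atoms(topo, region_mobile)
    reg_tem = select_atoms(template, region_template)
    if heavy_atoms_only:
        reg_mob = [i for i in reg_mob if topo.atoms[i].element.upper() != "H"]
        reg_tem = [j for j in reg_tem if template.atoms[j].element.upper() != "H"]
    if not reg_mob or not reg_tem:
        raise SelectionError("clash region selection resolved to zero atoms")
    atoms_mob = [topo.atoms[i] for i in reg_mob]
    atoms_tem = [template.atoms[j] for j in reg_tem]
    coords_tem_region = tem_coords[reg_tem]

    reports: list[ClashReport] = []
    n_compatible = 0
    for fi in range(0, e.n_frames, stride):
        frame = e.frames[fi]
        sp = kabsch(frame[anchor_mob_idx], anchor_ref)
        moved = sp.apply(frame[reg_mob])
        rep = detect_clashes(
            atoms_mob, moved, atoms_tem, coords_tem_region,
            overlap_threshold=overlap_threshold,
            distance_cutoff=distance_cutoff,
            frame_index=fi, radii=radii,
        )
        rep.is_compatible = rep.n_clashes <= max_clashes
        if rep.is_compatible:
            n_compatible += 1
        reports.append(rep)
    return CompatibilityResult(
        species_label=e.species_label,
        n_frames=len(reports),
        n_compatible=n_compatible,
        per_frame=reports,
    )
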