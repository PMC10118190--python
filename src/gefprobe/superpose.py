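"""Least-squares rigid superposition, RMSD/RMSF, and a one-way ANOVA helper.

Superposition is the Kabsch algorithm: the proper rotation (never a
reflection) and translation minimising the root-mean-square deviation between
two matched point sets. RMSD series superpose each ensemble frame on a
reference independently; RMSF profiles measure per-residue fluctuation about
an iteratively refined mean structure, the convention of standard trajectory
tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .structures import CA_ONLY, Ensemble, SelectionSpec, Structure, select_atoms


class IllPosedFitError(ValueError):
    """Superposition is underdetermined (too few or degenerate points)."""


class SelectionError(ValueError):
    """An atom selection resolved to nothing where atoms were required."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping mobile onto reference, plus the minimised RMSD.

    Apply as ``coords @ rotation.T + translation``.
    """

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,), Angstrom
    rmsd: float               # Angstrom, >= 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RmsfProfile:
    """Per-residue root-mean-square fluctuation about the mean structure."""

    residue_keys: list[tuple[str, int]]  # (chain_id, residue_number)
    rmsf: np.ndarray                     # Angstrom, aligned with residue_keys

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [c for c, _ in self.residue_keys],
                "resnum": [r for _, r in self.residue_keys],
                "rmsf_A": self.rmsf,
            }
        )


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Both arrays are (n, 3) with matched rows, n >= 3 and not collinear.
    Returns the proper rotation/translation minimising RMSD and the minimised
    RMSD itself.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise IllPosedFitError(
            f"matched (n,3) arrays required, got {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise IllPosedFitError(f"need >= 3 points, got {n}")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    # Collinear point sets leave a rotational degree of freedom unresolved.
    if np.linalg.matrix_rank(x, tol=1e-9 * max(1.0, np.abs(x).max())) < 2:
        raise IllPosedFitError("degenerate (collinear) geometry")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    trans = mu_r - rot @ mu_m
    fitted = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(
    e: Ensemble,
    reference: Structure | np.ndarray | None = None,
    sel: SelectionSpec | None = None,
) -> pd.DataFrame:
    """Per-frame minimised RMSD versus a reference over a selection.

    Each frame is superposed independently. ``reference`` defaults to frame 0;
    the selection defaults to CA atoms. Returns a DataFrame with columns
    ``frame`` and ``rmsd_A`` (mean available via ``df["rmsd_A"].mean()``).
    """
    if sel is None:
        sel = SelectionSpec(atom_names=CA_ONLY)
    idx = select_atoms(e.topology, sel)
    if not idx:
        raise SelectionError("RMSD selection matched no atoms")
    if reference is None:
        ref_coords = e.frames[0][idx]
    elif isinstance(reference, Structure):
        ridx = select_atoms(reference, sel)
        if not ridx:
            raise SelectionError("RMSD selection matched no atoms in reference")
        ref_coords = reference.coords[ridx]
    else:
        ref_coords = np.asarray(reference, float)[idx]
    rmsds = [kabsch(frame[idx], ref_coords).rmsd for frame in e.frames]
    return pd.DataFrame({"frame": np.arange(e.n_frames), "rmsd_A": rmsds})


def _iterative_mean_superpose(
    frames: list[np.ndarray], idx: list[int], n_iter: int = 2
) -> list[np.ndarray]:
    """Superpose all frames to their running mean over ``idx`` atoms."""
    fitted = [f.copy() for f in frames]
    for _ in range(n_iter):
        mean_sel = np.mean([f[idx] for f in fitted], axis=0)
        for i, f in enumerate(fitted):
            sp = kabsch(f[idx], mean_sel)
            fitted[i] = sp.apply(f)
    return fitted


def rmsf_profile(e: Ensemble, sel: SelectionSpec | None = None,
                 n_iter: int = 2) -> RmsfProfile:
    """Per-residue RMSF about the iteratively refined mean structure.

    Frames are superposed to the ensemble average over the selection
    (CA atoms by default), the average recomputed, and the superposition
    repeated ``n_iter`` times. RMSF_i = sqrt(mean over frames of
    |x_i - <x_i>|^2), averaged over the selected atoms of each residue.
    """
    if e.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if sel is None:
        sel = SelectionSpec(atom_names=CA_ONLY)
    idx = select_atoms(e.topology, sel)
    if not idx:
        raise SelectionError("RMSF selection matched no atoms")
    fitted = _iterative_mean_superpose(e.frames, idx, n_iter=n_iter)
    stack = np.stack([f[idx] for f in fitted])          # (n_frames, n_sel, 3)
    mean = stack.mean(axis=0)
    msf_atom = np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0)  # per atom

    keys: list[tuple[str, int]] = []
    per_res: dict[tuple[str, int], list[float]] = {}
    for j, ai in enumerate(idx):
        a = e.topology.atoms[ai]
        k = (a.chain_id, a.residue_number)
        if k not in per_res:
            per_res[k] = []
            keys.append(k)
        per_res[k].append(msf_atom[j])
    rmsf = np.array([np.sqrt(np.mean(per_res[k])) for k in keys])
    return RmsfProfile(residue_keys=keys, rmsf=rmsf)


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with an effect size.

    ``degenerate`` is set when all observations are identical, where
    F = 0/0 is undefined.
    """

    f_statistic: float
    p_value: float
    eta_squared: float
    df_between: int
    df_within: int
    degenerate: bool = False


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA across >= 2 groups.

    Each group needs >= 2 observations. Returns F = MS_between / MS_within
    with (k-1, N-k) degrees of freedom, the p-value from the F distribution,
    and eta-squared (SS_between / SS_total) as an effect size.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    ss_total = ss_between + ss_within
    if ss_total == 0.0:
        return AnovaResult(
            f_statistic=float("nan"), p_value=float("nan"), eta_squared=float("nan"),
            df_between=k - 1, df_within=n_total - k, degenerate=True,
        )
    f, p = stats.f_oneway(*groups)
    return AnovaResult(
        f_statistic=float(f), p_value=float(p),
        eta_squared=float(ss_between / ss_total),
        df_between=k - 1, df_within=n_total - k,
    )
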