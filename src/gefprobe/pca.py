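"""Cartesian-coordinate principal component analysis of conformational ensembles.

Frames are subsampled by a stride, rigid-body motion is removed by iterative
superposition onto the ensemble mean, and the covariance of the flattened
selected coordinates is eigendecomposed. Components are collective motions;
eigenvalues their variances (A^2). Covariance (not correlation) PCA on
mass-unweighted CA coordinates is the default, matching common trajectory
tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .structures import CA_ONLY, Ensemble, SelectionSpec, Structure, select_atoms
from .superpose import SelectionError, kabsch

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Fitted coordinate-PCA model.

    ``mean_coords`` is the 3N mean of the superposed, flattened selection;
    ``components`` is (n_components, 3N) with orthonormal rows, sign-fixed so
    each row's largest-magnitude coefficient is positive; ``eigenvalues`` are
    descending variances in A^2; ``variance_fraction[k]`` is
    eigenvalue_k / total variance (all eigenvalues, not only those retained).
    """

    mean_coords: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    stride_used: int
    n_frames_used: int
    atom_indices: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def eigenvalue_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "eigenvalue_A2": self.eigenvalues,
                "variance_fraction": self.variance_fraction,
                "cumulative": np.cumsum(self.variance_fraction),
            }
        )


@dataclass(frozen=True)
class PCProjection:
    """Scores of one frame on the retained components (Angstrom)."""

    frame_index: int
    scores: np.ndarray


def _converged_mean_superpose(
    frames: list[np.ndarray], idx: list[int],
    tol: float = 1e-12, max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Align selections onto their mean until the mean is a fixed point.

    Returns (aligned selections stacked (n_frames, n_sel, 3), mean (n_sel, 3)).
    Convergence to a fixed point matters: projections re-align frames onto the
    stored mean, and the two alignments must agree to numerical precision.
    """
    mean = frames[0][idx]
    aligned = None
    for _ in range(max_iter):
        aligned = np.stack([kabsch(f[idx], mean).apply(f[idx]) for f in frames])
        new_mean = aligned.mean(axis=0)
        shift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if shift < tol:
            break
    # Canonical orientation: centre the mean and rotate it into its
    # principal-axes frame with deterministic axis signs, so the fitted
    # components do not depend on the input ensemble's global pose.
    centroid = mean.mean(axis=0)
    mean_c = mean - centroid
    _, axes = np.linalg.eigh(mean_c.T @ mean_c)
    axes = axes[:, ::-1]  # descending spread
    for k in range(2):
        if np.sum((mean_c @ axes[:, k]) ** 3) < 0:
            axes[:, k] *= -1
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    aligned = (aligned - centroid) @ axes
    mean = mean_c @ axes
    return aligned, mean


def fit_pca(
    e: Ensemble,
    sel: SelectionSpec | None = None,
    stride: int = 5,
    n_components: int = 20,
) -> PCAModel:
    """Fit coordinate PCA on every ``stride``-th frame of an ensemble.

    The post-stride frame count must exceed ``n_components``;
    ``n_components`` larger than 3 * n_selected_atoms is clipped with a
    warning.
    """
    if sel is None:
        sel = SelectionSpec(atom_names=CA_ONLY)
    idx = select_atoms(e.topology, sel)
    if not idx:
        raise SelectionError("PCA selection matched no atoms")
    frames = e.frames[::stride]
    n_used = len(frames)
    if n_used <= n_components:
        raise ValueError(
            f"{n_used} frames after stride {stride} cannot support "
            f"{n_components} components"
        )
    dim = 3 * len(idx)
    if n_components > dim:
        logger.warning("n_components %d clipped to 3*n_atoms = %d", n_components, dim)
        n_components = dim
    aligned, mean_sel = _converged_mean_superpose(frames, idx)
    flat = aligned.reshape(n_used, -1)
    mean = mean_sel.ravel()
    centred = flat - mean
    cov = centred.T @ centred / (n_used - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T                     # rows are components
    # Reproducible sign: largest-magnitude coefficient positive.
    for row in evecs:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCAModel(
        mean_coords=mean,
        components=evecs[:n_components],
        eigenvalues=evals[:n_components],
        variance_fraction=frac[:n_components],
        stride_used=stride,
        n_frames_used=n_used,
        atom_indices=list(idx),
    )


def project(e: Ensemble, m: PCAModel, sel: SelectionSpec | None = None) -> list[PCProjection]:
    """Project ensemble frames into a fitted PCA model's component space.

    Each frame is superposed onto the model mean over the model's selection,
    centred, and dotted with the components.
    """
    if sel is None:
        sel = SelectionSpec(atom_names=CA_ONLY)
    idx = select_atoms(e.topology, sel)
    if 3 * len(idx) != m.mean_coords.size:
        raise ValueError(
            f"selection gives dimension {3 * len(idx)}, model expects {m.mean_coords.size}"
        )
    mean_ref = m.mean_coords.reshape(-1, 3)
    out = []
    for i, frame in enumerate(e.frames):
        fitted = kabsch(frame[idx], mean_ref).apply(frame[idx]).ravel()
        scores = m.components @ (fitted - m.mean_coords)
        out.append(PCProjection(frame_index=i, scores=scores))
    return out


def projection_table(projections: list[PCProjection], species: str = "") -> pd.DataFrame:
    rows = {
        "species": species,
        "frame": [p.frame_index for p in projections],
    }
    k = projections[0].scores.size if projections else 0
    for c in range(k):
        rows[f"pc{c + 1}"] = [p.scores[c] for p in projections]
    return pd.DataFrame(rows)


def extrema_structures(
    e: Ensemble, projections: list[PCProjection], pc_index: int
) -> tuple[Structure, Structure]:
    """Frames attaining the min and max score on one component.

    ``pc_index`` is 0-based. Ties break to the lowest frame index; an all-tied
    component is flagged in the log.
    """
    if not projections:
        raise ValueError("no projections supplied")
    k = projections[0].scores.size
    if not (0 <= pc_index < k):
        raise IndexError(f"pc_index {pc_index} out of range for {k} components")
    scores = np.array([p.scores[pc_index] for p in projections])
    frames = np.array([p.frame_index for p in projections])
    i_min = frames[int(np.argmin(scores))]
    i_max = frames[int(np.argmax(scores))]
    if np.allclose(scores, scores[0]):
        logger.warning("all scores equal on PC %d; returning frame %d twice",
                       pc_index + 1, frames[0])
    lo = e.frame_structure(int(i_min))
    hi = e.frame_structure(int(i_max))
    lo.label = f"{e.species_label}_pc{pc_index + 1}_min_frame{i_min}"
    hi.label = f"{e.species_label}_pc{pc_index + 1}_max_frame{i_max}"
    return lo, hi
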