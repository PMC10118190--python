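"""Mant-GDP exchange-kinetics: normalization, mono-exponential fits, activation calls.

A nucleotide-exchange experiment records fluorescence of mant-GDP-loaded
GTPase: a flat baseline (~300 s) before reagent addition, then a decay as
mant-GDP is released. Traces are normalised by the mean baseline signal, and
the decay phase is fitted to

    f(t) = (a0 - a_plateau) * exp(-k_obs * t) + a_plateau

with t measured from the reaction start, yielding the apparent first-order
rate constant k_obs (s^-1). A GEF is called active when it raises k_obs
relative to the intrinsic (GTPase-only) exchange by at least a fold
threshold, with a confidence interval that excludes no effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize


class NormalizationError(ValueError):
    """Baseline window empty or baseline mean unusable."""


@dataclass
class KineticTrace:
    """A fluorescence time course with reaction-start metadata.

    ``t_reaction_start_s`` is the moment of reagent (GDP/GEF/EDTA) addition;
    everything before it is baseline. ``metadata`` carries labels such as the
    GTPase, the GEF and its concentration, and the condition
    ("intrinsic" | "gef" | "edta").
    """

    time_s: np.ndarray
    signal: np.ndarray
    t_reaction_start_s: float
    metadata: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.signal = np.asarray(self.signal, float)
        if self.time_s.shape != self.signal.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and signal must be matching 1-D arrays")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (self.time_s[0] <= self.t_reaction_start_s <= self.time_s[-1]):
            raise ValueError("t_reaction_start_s outside the recorded time range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "signal": self.signal})


def read_trace_csv(csv_path: str | Path, sidecar_path: str | Path | None = None) -> KineticTrace:
    """Read a trace from a (time_s, signal) CSV plus a JSON metadata sidecar.

    The sidecar defaults to ``<csv stem>.json`` and must provide
    ``t_reaction_start_s``; remaining keys become metadata.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    t0 = float(meta.pop("t_reaction_start_s"))
    return KineticTrace(
        time_s=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        t_reaction_start_s=t0,
        metadata=meta,
    )


def write_trace_csv(t: KineticTrace, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    t.to_frame().to_csv(csv_path, index=False)
    meta = dict(t.metadata)
    meta["t_reaction_start_s"] = t.t_reaction_start_s
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def normalize_trace(t: KineticTrace, baseline_window_s: float = 300.0) -> KineticTrace:
    """Divide the whole trace by the mean signal of the pre-reaction baseline.

    The baseline is the window [t_start - baseline_window_s, t_start); it must
    contain at least 3 samples and its mean must be positive. The normalised
    baseline mean is 1 by construction.
    """
    mask = (t.time_s >= t.t_reaction_start_s - baseline_window_s) & (
        t.time_s < t.t_reaction_start_s
    )
    if mask.sum() < 3:
        raise NormalizationError(
            f"baseline window holds {int(mask.sum())} samples; need >= 3"
        )
    base = float(t.signal[mask].mean())
    if base <= 0:
        raise NormalizationError(f"baseline mean {base} is not positive")
    return replace(t, signal=t.signal / base, normalized=True)


@dataclass
class ExponentialFit:
    """Fitted mono-exponential decay parameters with uncertainties.

    ``k_obs`` is the apparent exchange rate (s^-1). ``converged=False`` with
    the ``no_decay`` flag marks a flat trace (no detectable exchange), which
    is a meaningful outcome for an inactive GEF, not a failure.
    """

    a0: float
    a_plateau: float
    k_obs: float
    residual_sse: float
    se_a0: float = float("nan")
    se_a_plateau: float = float("nan")
    se_k_obs: float = float("nan")
    converged: bool = True
    no_decay: bool = False


def _model(t: np.ndarray, a0: float, a_plateau: float, k: float) -> np.ndarray:
    return (a0 - a_plateau) * np.exp(-k * t) + a_plateau


def fit_monoexponential(
    t: KineticTrace,
    skip_s: float = 0.0,
    noise_floor: float | None = None,
) -> ExponentialFit:
    """Fit the decay phase to (a0 - a_plateau) exp(-k_obs t') + a_plateau.

    Only samples with t >= t_reaction_start_s + skip_s are used (``skip_s``
    masks the mixing artifact right after reagent addition). Initial guesses:
    a0 from the first post-start sample, a_plateau from the mean of the last
    10% of samples, k from a log-linear regression of signal - a_plateau
    guess. A trace whose early mean does not exceed its tail mean by more
    than the noise floor (3x the baseline standard deviation unless given) is
    flagged ``no_decay`` with k_obs = 0 and converged = False.
    """
    post = t.time_s >= t.t_reaction_start_s + skip_s
    tt = t.time_s[post] - t.t_reaction_start_s
    y = t.signal[post]
    if tt.size < 10:
        raise ValueError(f"need >= 10 post-start samples, got {tt.size}")

    if noise_floor is None:
        pre = t.time_s < t.t_reaction_start_s
        noise_floor = 3.0 * float(np.std(t.signal[pre])) if pre.sum() >= 3 else 0.0
    n_tail = max(3, tt.size // 10)
    # Short head window: a fast decay is over within a tiny fraction of the
    # record, so only the first few samples still carry the amplitude.
    head_mean = float(y[: max(3, min(10, tt.size // 10))].mean())
    tail_mean = float(y[-n_tail:].mean())
    if head_mean - tail_mean <= max(noise_floor, 1e-12):
        sse = float(np.sum((y - y.mean()) ** 2))
        return ExponentialFit(
            a0=float(y[0]), a_plateau=tail_mean, k_obs=0.0,
            residual_sse=sse, converged=False, no_decay=True,
        )

    a0_guess = float(y[0])
    plateau_guess = tail_mean
    amp = y - plateau_guess
    pos = amp > max(1e-3 * (a0_guess - plateau_guess), 1e-12)
    if pos.sum() >= 2:
        slope = np.polyfit(tt[pos], np.log(amp[pos]), 1)[0]
        k_guess = max(-slope, 1e-6)
    else:
        k_guess = 1.0 / max(tt[-1], 1.0)

    try:
        popt, pcov = optimize.curve_fit(
            _model, tt, y,
            p0=[a0_guess, plateau_guess, k_guess],
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            ftol=1e-10, xtol=1e-10, maxfev=500 * 4,
        )
    except RuntimeError:
        return ExponentialFit(
            a0=a0_guess, a_plateau=plateau_guess, k_obs=k_guess,
            residual_sse=float("nan"), converged=False,
        )
    resid = y - _model(tt, *popt)
    ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 3
    return ExponentialFit(
        a0=float(popt[0]), a_plateau=float(popt[1]), k_obs=float(popt[2]),
        residual_sse=float(np.sum(resid ** 2)),
        se_a0=float(ses[0]), se_a_plateau=float(ses[1]), se_k_obs=float(ses[2]),
        converged=True,
    )


@dataclass
class ActivationCall:
    """Decision on GEF activity versus intrinsic exchange.

    ``fold_activation`` is mean k_obs(GEF arm) / mean k_obs(intrinsic arm);
    ``ci_95`` its 95% confidence interval. The call is "active" when the fold
    reaches the threshold and the CI excludes 1, "inactive" when the CI upper
    bound stays below the threshold, otherwise "indeterminate".
    """

    fold_activation: float
    ci_95: tuple[float, float]
    call: str
    fold_threshold: float = 2.0


def classify_activation(
    gef_fits: list[ExponentialFit],
    intrinsic_fits: list[ExponentialFit],
    fold_threshold: float = 2.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> ActivationCall:
    """Call GEF activity from replicate k_obs fits of both arms.

    With >= 3 replicates per arm the 95% CI of the fold comes from a
    nonparametric bootstrap over replicates; with fewer, from propagating the
    per-fit standard errors of the means. An intrinsic arm with only no-decay
    fits makes the ratio meaningless and yields "indeterminate".
    """
    if not gef_fits or not intrinsic_fits:
        raise ValueError("both arms need at least one fit")
    kg = np.array([f.k_obs for f in gef_fits])
    ki = np.array([f.k_obs for f in intrinsic_fits])
    if np.all([f.no_decay for f in intrinsic_fits]) or ki.mean() <= 0:
        return ActivationCall(float("nan"), (float("nan"), float("nan")),
                              "indeterminate", fold_threshold)
    fold = float(kg.mean() / ki.mean())
    if len(kg) >= 3 and len(ki) >= 3:
        rng = np.random.default_rng(seed)
        bg = rng.choice(kg, size=(n_boot, len(kg)), replace=True).mean(axis=1)
        bi = rng.choice(ki, size=(n_boot, len(ki)), replace=True).mean(axis=1)
        ok = bi > 0
        folds = bg[ok] / bi[ok]
        lo, hi = np.percentile(folds, [2.5, 97.5])
    else:
        se_g = np.array([f.se_k_obs for f in gef_fits])
        se_i = np.array([f.se_k_obs for f in intrinsic_fits])
        se_g = np.where(np.isfinite(se_g), se_g, 0.0)
        se_i = np.where(np.isfinite(se_i), se_i, 0.0)
        sem_g = np.sqrt(np.sum(se_g ** 2)) / len(kg)
        sem_i = np.sqrt(np.sum(se_i ** 2)) / len(ki)
        rel = np.sqrt((sem_g / kg.mean()) ** 2 + (sem_i / ki.mean()) ** 2)
        lo, hi = fold * (1 - 1.96 * rel), fold * (1 + 1.96 * rel)
    if fold >= fold_threshold and not (lo <= 1.0 <= hi):
        call = "active"
    elif hi < fold_threshold:
        call = "inactive"
    else:
        call = "indeterminate"
    return ActivationCall(fold, (float(lo), float(hi)), call, fold_threshold)


def fit_table(fits: list[ExponentialFit], labels: list[str] | None = None) -> pd.DataFrame:
    labels = labels or [f"trace_{i}" for i in range(len(fits))]
    return pd.DataFrame(
        {
            "label": labels,
            "a0": [f.a0 for f in fits],
            "a_plateau": [f.a_plateau for f in fits],
            "k_obs_per_s": [f.k_obs for f in fits],
            "se_k_obs": [f.se_k_obs for f in fits],
            "converged": [f.converged for f in fits],
            "no_decay": [f.no_decay for f in fits],
        }
    )
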