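"""Slow-modality (500 ms) residence-time analysis.

At a long frame interval, diffusing molecules blur out and only
chromatin-bound molecules are tracked, so track durations measure binding
residence. The survival function of track durations is fitted with one- and
two-component exponential decays; in the two-component fit the long-lived
component is read as specific binding and the short-lived one as
non-specific sampling, and their time constants (tau = 1/k) and fraction
ratio summarise the binding kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .fastkinetics import per_track_diffusion
from .trajectories import Trajectory

__all__ = ["SurvivalFit", "residence_times", "survival_curve", "fit_exponentials"]

#: maximum expected diffusion coefficient of the immobile population, um^2/s
SLOW_D_MAX = 0.05


@dataclass
class SurvivalFit:
    model: str  # "1-exp" or "2-exp"
    k_long: float  # per-s
    k_short: float
    frac_long: float
    sse: float
    degenerate: bool = False
    converged: bool = True

    @property
    def tau_long(self) -> float:
        return 1.0 / self.k_long

    @property
    def tau_short(self) -> float:
        return 1.0 / self.k_short

    @property
    def ratio_long_short(self) -> float:
        if self.frac_long >= 1.0:
            return float("inf")
        return self.frac_long / (1.0 - self.frac_long)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "tau_long_s": self.tau_long,
            "tau_short_s": self.tau_short,
            "k_long_per_s": self.k_long,
            "k_short_per_s": self.k_short,
            "frac_long": self.frac_long,
            "ratio_long_short": self.ratio_long_short,
            "sse": self.sse,
            "degenerate": self.degenerate,
            "converged": self.converged,
        }


def residence_times(
    trajectories: Sequence[Trajectory], d_max: float = SLOW_D_MAX
) -> np.ndarray:
    """Track durations (s) of the immobile population.

    Duration = (last frame - first frame + 1) * frame interval. Tracks whose
    per-track diffusion coefficient exceeds ``d_max`` (default 0.05 um^2/s)
    are excluded as still-mobile. All tracks must share one frame interval.
    """
    if len(trajectories) == 0:
        return np.empty(0)
    dts = {t.frame_interval for t in trajectories}
    if len(dts) > 1:
        raise ValueError(f"mixed frame intervals: {sorted(dts)}")
    out = []
    for t in trajectories:
        if len(t) >= 5 and per_track_diffusion(t) > d_max:
            continue
        out.append(t.duration)
    return np.array(out)


def survival_curve(durations: Sequence[float]) -> np.ndarray:
    """Empirical survival function: rows (t, fraction of durations >= t).

    Evaluated at the observed (quantized) duration values; S is monotone
    non-increasing with S(min time) = 1.
    """
    d = np.sort(np.asarray(durations, dtype=float))
    if len(d) < 10:
        raise ValueError("need >= 10 durations for a survival curve")
    times = np.unique(d)
    n = len(d)
    s = 1.0 - np.searchsorted(d, times, side="left") / n
    return np.column_stack([times, s])


def _model_curve(t: np.ndarray, theta: np.ndarray, components: int) -> np.ndarray:
    if components == 1:
        return np.exp(-theta[0] * t)
    k_long, k_short, frac = theta
    return frac * np.exp(-k_long * t) + (1 - frac) * np.exp(-k_short * t)


def fit_exponentials(
    curve: np.ndarray,
    components: int = 2,
    n_init: int = 10,
    seed: int = 0,
) -> SurvivalFit:
    """Least-squares exponential decay fit of a survival curve.

    ``components=1`` fits S(t) = exp(-k t); ``components=2`` fits
    frac * exp(-k_long t) + (1 - frac) * exp(-k_short t) with k_long <
    k_short enforced by ordering the solution. Multi-start least squares
    with uniform weights over the observed time points. If the two fitted
    time constants come within one time-grid step of each other the fit is
    flagged degenerate and collapsed to the 1-exp solution.

    Times are referenced to the first observed point before fitting: a
    duration quantized up to k frame intervals means the underlying event
    outlived (k - 1) intervals, so the survival of frame-quantized data at
    time k*dt equals the continuous mixture survival at (k-1)*dt. Fitting
    against t - t_min removes that one-frame bias exactly; the reported
    rates are unchanged by the shift.
    """
    curve = np.asarray(curve, dtype=float)
    if components not in (1, 2):
        raise ValueError("components must be 1 or 2")
    t, s = curve[:, 0], curve[:, 1]
    if len(np.unique(t)) < 5:
        raise ValueError("need >= 5 distinct time points")
    t = t - t.min()
    t_scale = max(np.mean(t), 1e-9)
    rng = np.random.default_rng(seed)

    def run(n_comp: int) -> tuple[np.ndarray, float] | None:
        best = None
        for i in range(n_init):
            if n_comp == 1:
                x0 = np.array([1.0 / (t_scale * rng.uniform(0.3, 3.0))])
                lo, hi = [1e-6], [1e4]
            else:
                k0 = 1.0 / (t_scale * rng.uniform(1.0, 5.0))
                k1 = 1.0 / (t_scale * rng.uniform(0.05, 0.8))
                x0 = np.array([k0, k1, rng.uniform(0.2, 0.8)])
                lo, hi = [1e-6, 1e-6, 0.0], [1e4, 1e4, 1.0]
            try:
                res = least_squares(
                    lambda th: _model_curve(t, th, n_comp) - s,
                    x0, bounds=(lo, hi), max_nfev=5000,
                )
            except Exception:
                continue
            sse = float(np.sum(res.fun**2))
            if best is None or sse < best[1]:
                best = (res.x, sse)
        return best

    if components == 1:
        best = run(1)
        if best is None:
            return SurvivalFit("1-exp", np.nan, np.nan, np.nan, np.inf,
                               converged=False)
        return SurvivalFit("1-exp", float(best[0][0]), float(best[0][0]), 1.0,
                           best[1])

    best = run(2)
    if best is None:
        return SurvivalFit("2-exp", np.nan, np.nan, np.nan, np.inf, converged=False)
    theta, sse = best
    k_a, k_b, frac = theta
    if k_a <= k_b:
        k_long, k_short, frac_long = k_a, k_b, frac
    else:
        k_long, k_short, frac_long = k_b, k_a, 1.0 - frac
    grid_step = float(np.min(np.diff(np.unique(t))))
    if abs(1.0 / k_long - 1.0 / k_short) < grid_step:
        one = run(1)
        if one is not None:
            return SurvivalFit("1-exp", float(one[0][0]), float(one[0][0]), 1.0,
                               one[1], degenerate=True)
    return SurvivalFit("2-exp", float(k_long), float(k_short), float(frac_long),
                       sse)
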