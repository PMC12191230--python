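"""Fast-modality (20 ms) diffusion analyses.

A nuclear transcription factor explores chromatin in a mixture of states:
bound (chromatin-engaged), slow-diffusing and fast-diffusing. At a 20 ms
frame interval the jump-length distribution pooled over several lags is
informative about the state mixture: for a molecule diffusing with
coefficient D observed with localization error sigma, the jump length r
over n frames (lag time t = n*dt) is Rayleigh with

    p(r | D, t) = r / (2 (D t + sigma^2)) * exp(-r^2 / (4 (D t + sigma^2))),

and the 3-state model fits a mixture of three such components (fractions
F_B + F_S + F_F = 1) to the empirical jump-length cumulative distributions
over the first ``n_lags`` lags, with sigma fitted from the data and the
printed per-state diffusion bounds enforced. Complementary per-trajectory
statistics — MSD power-law exponents, per-track diffusion coefficients, the
jump-angle distribution folded to [0, 180] degrees (reversal excess =
anisotropy), and the confinement radius about the trajectory centroid —
characterise the search strategy; per-cell feature means feed a PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .trajectories import Trajectory

__all__ = [
    "JumpModelFit",
    "MsdFit",
    "CellSummary",
    "msd_curve",
    "fit_msd_powerlaw",
    "per_track_diffusion",
    "split_mobile_immobile",
    "pooled_jumps",
    "fit_three_state",
    "jump_angles",
    "anisotropy",
    "confinement_radius",
    "radius_of_gyration",
    "cell_features",
    "features_pca",
]

#: printed per-state diffusion bounds, um^2/s
D_BOUNDS = {"bound": (1e-5, 0.1), "slow": (1e-3, 0.5), "fast": (0.2, 5.0)}
SIGMA_BOUNDS = (0.005, 0.1)  # um


@dataclass
class JumpModelFit:
    f_bound: float
    f_slow: float
    f_fast: float
    d_bound: float
    d_slow: float
    d_fast: float
    sigma: float
    sse: float
    n_init: int
    seed: int
    n_jumps: int
    converged: bool = True

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.f_bound, self.f_slow, self.f_fast)

    @property
    def diffusion(self) -> tuple[float, float, float]:
        return (self.d_bound, self.d_slow, self.d_fast)

    def to_dict(self) -> dict:
        return {
            "fractions": {"bound": self.f_bound, "slow": self.f_slow,
                          "fast": self.f_fast},
            "diffusion_um2_s": {"bound": self.d_bound, "slow": self.d_slow,
                                "fast": self.d_fast},
            "sigma_um": self.sigma,
            "sse": self.sse,
            "n_init": self.n_init,
            "seed": self.seed,
            "n_jumps": self.n_jumps,
            "converged": self.converged,
            "bounds": D_BOUNDS,
        }


@dataclass
class MsdFit:
    d_app: float
    alpha: float
    offset: float
    fraction_used: float = 0.9
    converged: bool = True


@dataclass
class CellSummary:
    cell_id: str
    track_d: np.ndarray = field(repr=False, default=None)
    mobile_fraction: float = np.nan
    anisotropy_ratio: float = np.nan
    confinement_radii: np.ndarray = field(repr=False, default=None)
    mean_jump: float = np.nan
    fractions: tuple[float, float, float] | None = None

    def feature_vector(self) -> dict[str, float]:
        return {
            "median_track_d": float(np.median(self.track_d)),
            "mean_jump": self.mean_jump,
            "median_confinement_radius": float(np.median(self.confinement_radii)),
            "anisotropy_ratio": self.anisotropy_ratio,
            "mobile_fraction": self.mobile_fraction,
        }


# ---------------------------------------------------------------------------
# MSD


def msd_curve(traj: Trajectory, fraction_used: float = 0.9) -> np.ndarray:
    """Time-averaged MSD: rows (lag seconds, msd um^2), lags up to
    fraction_used of the track length."""
    n = len(traj)
    if n < 2:
        raise ValueError("track too short for an MSD curve")
    max_lag = max(1, int(np.floor(fraction_used * (n - 1))))
    rows = []
    for lag in range(1, max_lag + 1):
        dx = traj.x[lag:] - traj.x[:-lag]
        dy = traj.y[lag:] - traj.y[:-lag]
        rows.append((lag * traj.frame_interval, float(np.mean(dx**2 + dy**2))))
    return np.array(rows)


def fit_msd_powerlaw(curve: np.ndarray, offset_init: float = 0.5) -> MsdFit:
    """Least-squares fit of msd(t) = 4 D t^alpha + offset.

    The offset absorbs the 4 sigma^2 localization-noise plateau and is
    constrained non-negative, which keeps the offset/alpha trade-off from
    dragging single-track fits off scale. Three deterministic starts are
    tried (the configured offset_init, a log-log regression, and the
    first-lag slope) and the best SSE wins.
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) < 3:
        raise ValueError("need at least 3 lags to fit the power law")
    t, msd = curve[:, 0], curve[:, 1]

    def resid(theta):
        log_d, alpha, offset = theta
        return 4.0 * np.exp(log_d) * t**alpha + offset - msd

    slope, icept = np.polyfit(np.log(t), np.log(np.maximum(msd, 1e-12)), 1)
    d0 = max(np.median(msd / (4 * t)), 1e-8)
    starts = [
        [np.log(d0), 1.0, max(offset_init, 0.0)],
        [icept - np.log(4.0), float(np.clip(slope, -0.9, 2.9)), 0.0],
        [np.log(max(msd[0] / (4 * t[0]), 1e-8)), 1.0, 0.0],
    ]
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                resid, x0,
                bounds=([-30, -1.0, 0.0], [10, 3.0, np.inf]),
                max_nfev=2000,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        return MsdFit(np.nan, np.nan, np.nan, converged=False)
    log_d, alpha, offset = best[1]
    return MsdFit(float(np.exp(log_d)), float(alpha), float(offset))


# ---------------------------------------------------------------------------
# per-track diffusion


def per_track_diffusion(traj: Trajectory, sigma_est: float = 0.0) -> float:
    """Localization-error-corrected per-track D from 1-frame jumps.

    D = <r^2> / (4 dt) - sigma^2 / dt, floored at 1e-6 um^2/s.
    """
    if len(traj) < 5:
        raise ValueError("track too short (need >= 5 localizations)")
    r = traj.jumps(lag=1)
    if len(r) == 0:
        return 1e-6
    dt = traj.frame_interval
    d = float(np.mean(r**2)) / (4.0 * dt) - sigma_est**2 / dt
    return max(d, 1e-6)


def split_mobile_immobile(
    track_ds: Sequence[float], d_threshold: float = 0.1
) -> tuple[float, float]:
    """(mobile_fraction, immobile_fraction) of tracks by a D threshold."""
    ds = np.asarray(track_ds, dtype=float)
    if len(ds) == 0:
        raise ValueError("need at least one track")
    immobile = float(np.mean(ds < d_threshold))
    return 1.0 - immobile, immobile


# ---------------------------------------------------------------------------
# 3-state jump-distance model


def pooled_jumps(
    trajectories: Sequence[Trajectory], n_lags: int = 6
) -> dict[int, np.ndarray]:
    """Jump distances pooled over trajectories, per lag 1..n_lags.

    Jumps spanning gap-closed (missing) frames are excluded.
    """
    out: dict[int, list[np.ndarray]] = {lag: [] for lag in range(1, n_lags + 1)}
    for t in trajectories:
        for lag in range(1, n_lags + 1):
            r = t.jumps(lag=lag, contiguous=True)
            if len(r):
                out[lag].append(r)
    return {
        lag: (np.concatenate(v) if v else np.empty(0)) for lag, v in out.items()
    }


def _canonicalize_slots(best, unpack, resid, lohi, bounds):
    """Resolve label-switching between states with overlapping D bounds.

    A mixture component whose D lies inside a slower slot's bounds fits the
    data near-identically from either slot, so the slot labels of such
    solutions are not identified by the likelihood. Each slot permutation of
    the best solution that respects the per-slot D bounds is polished by a
    short refit; among solutions whose SSE is within 1% of the optimum the
    mass is reported in the slowest compatible slot (bound before slow
    before fast).
    """
    from itertools import permutations

    sse0, res0 = best
    fracs, ds_, sig = unpack(res0.x)
    comps = sorted(zip(fracs, ds_), key=lambda c: -c[0])
    slot_bounds = [bounds["bound"], bounds["slow"], bounds["fast"]]
    lo, hi = lohi
    chosen = best
    chosen_key = (fracs[0], fracs[1])
    for perm in permutations(range(3)):
        # perm[j] = slot receiving component j (components in F-desc order)
        slots = [None, None, None]
        ok = True
        for j, (f, d) in enumerate(comps):
            s = perm[j]
            blo, bhi = slot_bounds[s]
            if f > 0.05 and not (blo <= d <= bhi):
                ok = False
                break
            slots[s] = (f, float(np.clip(d, blo, bhi)))
        if not ok:
            continue
        fb, fs = slots[0][0], slots[1][0]
        a = fb
        b = fs / (1 - a) if a < 1 else 0.5
        x0 = np.clip(
            [a, b, slots[0][1], slots[1][1], slots[2][1], sig], lo, hi
        )
        res = least_squares(resid, x0, bounds=(lo, hi), max_nfev=500)
        sse = float(np.sum(res.fun**2))
        if sse <= sse0 * 1.01 + 1e-15:
            f_new = unpack(res.x)[0]
            key = (f_new[0], f_new[1])
            if key > chosen_key:
                chosen = (sse, res)
                chosen_key = key
    return chosen


def _mixture_cdf(r: np.ndarray, t_lag: float, fracs, ds, sigma: float) -> np.ndarray:
    out = np.zeros_like(r)
    for f, d in zip(fracs, ds):
        out += f * (1.0 - np.exp(-(r**2) / (4.0 * (d * t_lag + sigma**2))))
    return out


def fit_three_state(
    trajectories: Sequence[Trajectory],
    n_lags: int = 6,
    n_init: int = 10,
    bounds: dict[str, tuple[float, float]] = D_BOUNDS,
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
    seed: int = 0,
    n_grid: int = 99,
) -> JumpModelFit:
    """Fit the 3-state jump-distance mixture to pooled jump-length CDFs.

    The empirical jump-length CDF of each lag is evaluated on an equal-mass
    quantile grid and fit jointly (lags weighted equally) by constrained
    least squares; fractions are parameterized by stick-breaking so they
    always sum to 1, per-state D bounds are enforced, and the localization
    error sigma is fitted from the data. ``n_init`` random multi-starts are
    tried and the best SSE is returned.
    """
    jumps = pooled_jumps(trajectories, n_lags)
    dt = trajectories[0].frame_interval
    n_total = sum(len(v) for v in jumps.values())
    if n_total < 500:
        raise ValueError(f"need >= 500 pooled jumps, got {n_total}")

    grids = []  # (t_lag, r_grid, p_grid)
    probs = (np.arange(1, n_grid + 1) - 0.5) / n_grid
    for lag, r in jumps.items():
        if len(r) < 10:
            continue
        grids.append((lag * dt, np.quantile(r, probs), probs))

    lo = np.array([0.0, 0.0, bounds["bound"][0], bounds["slow"][0],
                   bounds["fast"][0], sigma_bounds[0]])
    hi = np.array([1.0, 1.0, bounds["bound"][1], bounds["slow"][1],
                   bounds["fast"][1], sigma_bounds[1]])

    def unpack(theta):
        a, b, db, ds_, df, sig = theta
        fracs = (a, (1 - a) * b, (1 - a) * (1 - b))
        return fracs, (db, ds_, df), sig

    def resid(theta):
        fracs, ds_, sig = unpack(theta)
        parts = []
        for t_lag, rq, p in grids:
            parts.append(_mixture_cdf(rq, t_lag, fracs, ds_, sig) - p)
        return np.concatenate(parts)

    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_init):
        if i == 0:
            x0 = np.array([1 / 3, 1 / 2, 0.005, 0.1, 1.0, 0.03])
        else:
            x0 = np.empty(6)
            x0[0] = rng.uniform(0.05, 0.95)
            x0[1] = rng.uniform(0.05, 0.95)
            for j, key in enumerate(("bound", "slow", "fast")):
                blo, bhi = bounds[key]
                x0[2 + j] = np.exp(rng.uniform(np.log(blo), np.log(bhi)))
            x0[5] = rng.uniform(*sigma_bounds)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), max_nfev=3000)
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        return JumpModelFit(*([np.nan] * 7), np.inf, n_init, seed, n_total,
                            converged=False)
    best = _canonicalize_slots(best, unpack, resid, (lo, hi), bounds)
    sse, res = best
    fracs, ds_, sig = unpack(res.x)
    return JumpModelFit(
        f_bound=float(fracs[0]),
        f_slow=float(fracs[1]),
        f_fast=float(fracs[2]),
        d_bound=float(ds_[0]),
        d_slow=float(ds_[1]),
        d_fast=float(ds_[2]),
        sigma=float(sig),
        sse=sse,
        n_init=n_init,
        seed=seed,
        n_jumps=n_total,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# jump angles, anisotropy, confinement


def jump_angles(traj: Trajectory, min_jump: float = 0.125) -> np.ndarray:
    """Angles (degrees, folded to [0, 180]) between consecutive displacements.

    Only pairs whose two displacements both exceed ``min_jump`` (um, default
    125 nm) contribute; 0 = forward continuation, 180 = reversal.
    """
    if len(traj) < 3:
        return np.empty(0)
    d = traj.displacements()
    if len(d) < 2:
        return np.empty(0)
    v1, v2 = d[:-1], d[1:]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > min_jump) & (n2 > min_jump)
    if not ok.any():
        return np.empty(0)
    cosang = np.sum(v1[ok] * v2[ok], axis=1) / (n1[ok] * n2[ok])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def anisotropy(angles: np.ndarray, window: float = 30.0) -> float:
    """Fold ratio: reversal (180 +/- window) over forward (0 + window) counts.

    An empty forward window gives +inf with a warning.
    """
    angles = np.asarray(angles, dtype=float)
    n_back = int(np.sum(angles >= 180.0 - window))
    n_fwd = int(np.sum(angles <= window))
    if n_fwd == 0:
        warnings.warn("no forward-window angles; anisotropy ratio is +inf")
        return float("inf")
    return n_back / n_fwd


def confinement_radius(traj: Trajectory) -> float:
    """Max distance of any localization from the trajectory centroid (um)."""
    if len(traj) < 5:
        raise ValueError("track too short (need >= 5 localizations)")
    cx, cy = traj.x.mean(), traj.y.mean()
    return float(np.max(np.hypot(traj.x - cx, traj.y - cy)))


def radius_of_gyration(traj: Trajectory) -> float:
    """RMS distance from the centroid; alternative confinement metric."""
    if len(traj) < 5:
        raise ValueError("track too short (need >= 5 localizations)")
    cx, cy = traj.x.mean(), traj.y.mean()
    return float(np.sqrt(np.mean((traj.x - cx) ** 2 + (traj.y - cy) ** 2)))


# ---------------------------------------------------------------------------
# per-cell features and PCA


def cell_features(
    trajectories: Sequence[Trajectory],
    cell_id: str = "cell",
    sigma_est: float = 0.0,
    d_threshold: float = 0.1,
    min_jump: float = 0.125,
) -> CellSummary:
    """Per-cell summary of track-level dynamics (tracks shorter than 5 skipped)."""
    usable = [t for t in trajectories if len(t) >= 5]
    if not usable:
        raise ValueError("no track with >= 5 localizations")
    ds = np.array([per_track_diffusion(t, sigma_est) for t in usable])
    mobile, _ = split_mobile_immobile(ds, d_threshold)
    radii = np.array([confinement_radius(t) for t in usable])
    jumps = np.concatenate([t.jumps(lag=1) for t in usable])
    angles = np.concatenate([jump_angles(t, min_jump) for t in usable])
    ratio = anisotropy(angles) if len(angles) else np.nan
    return CellSummary(
        cell_id=cell_id,
        track_d=ds,
        mobile_fraction=mobile,
        anisotropy_ratio=ratio,
        confinement_radii=radii,
        mean_jump=float(jumps.mean()),
    )


def features_pca(
    summaries: Sequence[CellSummary], n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Standardized PCA of per-cell features.

    Constant features are dropped with a warning. The sign of each component
    is fixed so its largest-magnitude loading is positive. Returns
    (coordinates, explained variance ratios, feature names used).
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 cells for PCA")
    names = list(summaries[0].feature_vector())
    X = np.array([[s.feature_vector()[k] for k in names] for s in summaries])
    keep = []
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0 or not np.all(np.isfinite(X[:, j])):
            warnings.warn(f"dropping constant/non-finite feature {name!r}")
        else:
            keep.append(j)
    if not keep:
        # all cells identical: every coordinate is at the origin
        return np.zeros((len(summaries), n_components)), np.zeros(n_components), []
    X = X[:, keep]
    names = [names[j] for j in keep]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    k = min(n_components, len(s))
    coords = np.zeros((len(summaries), n_components))
    for c in range(k):
        sign = np.sign(vt[c, np.argmax(np.abs(vt[c]))]) or 1.0
        coords[:, c] = u[:, c] * s[c] * sign
    var = s**2 / np.sum(s**2)
    explained = np.zeros(n_components)
    explained[:k] = var[:k]
    return coords, explained, names
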