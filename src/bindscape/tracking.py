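"""Spot detection and nearest-neighbour trajectory linking.

Detection follows the multiple-target-tracing recipe in simplified form: a
generalized-likelihood-ratio (matched-filter) test of a Gaussian spot
against locally flat background is applied at every pixel of a detection
box, thresholded at a false-alarm probability (default 10^-6.5 per pixel),
and each surviving local maximum is refined to sub-pixel position by
least-squares 2D Gaussian fitting (bounded iterations and termination
tolerance; candidates whose refinement wanders more than a maximum
refinement distance are rejected).

Linking is greedy mutual-nearest-neighbour within a tracking radius, with
track ends persisting across a bounded number of gap frames and a minimum
trajectory length filter (defaults: radius 9 px, 2 gap frames, 5
localizations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from scipy.stats import norm

from .trajectories import Trajectory

__all__ = [
    "Localization",
    "TrackingConfig",
    "detect_spots",
    "detect_stack",
    "link_trajectories",
    "read_stack",
    "write_stack",
]


@dataclass(frozen=True)
class Localization:
    frame: int
    x: float  # um
    y: float  # um
    intensity: float = 0.0
    precision_flag: bool = True


@dataclass
class TrackingConfig:
    radius: float = 9.0  # tracking radius, pixels
    max_gap: int = 2  # frames a track end survives unmatched
    min_length: int = 5  # localizations
    detection_threshold: float = 1.5  # peak factor over local background
    pfa: float = 10 ** -6.5  # per-pixel false-alarm probability
    box: int = 7  # detection box, pixels
    max_iter: int = 50
    tol: float = 1e-2
    max_refine: float = 1.5  # pixels
    pixel_size: float = 0.1  # um
    d_max: float | None = None  # um^2/s; caps the link radius per frame interval

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")
        if self.box % 2 == 0:
            raise ValueError("detection box must be odd")

    def link_radius_um(self, frame_interval: float) -> float:
        """Effective link radius: pixel radius capped by expected max displacement.

        With a maximum expected diffusion coefficient D_max, displacements
        beyond ~3 sigma of a 2D Gaussian step (sigma^2 = 2 D_max dt per axis)
        are implausible; the smaller of that and the pixel radius is used.
        """
        r = self.radius * self.pixel_size
        if self.d_max is not None:
            r = min(r, 3.0 * np.sqrt(4.0 * self.d_max * frame_interval))
        return r


def _gaussian_kernel(box: int, sd: float) -> np.ndarray:
    half = box // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(ax**2) / (2 * sd**2))
    return np.outer(g, g)


def detect_spots(
    frame_image: np.ndarray, cfg: TrackingConfig, psf_sd: float = 1.35
) -> list[Localization]:
    """Detect diffraction-limited spots in one frame.

    ``psf_sd`` is the PSF standard deviation in pixels. The GLRT statistic
    per pixel is the normalized zero-mean matched-filter response; under the
    flat-background null (variance estimated robustly from the frame) it is
    standard normal, so the threshold is the (1 - pfa) normal quantile.
    Returns localizations in micrometres with ``frame`` left at 0.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if min(img.shape) < cfg.box:
        raise ValueError("image smaller than the detection box")

    w = _gaussian_kernel(cfg.box, psf_sd)
    w_tilde = w - w.mean()
    response = ndimage.convolve(img, w_tilde, mode="reflect")
    background = ndimage.uniform_filter(img, size=cfg.box, mode="reflect")
    resid = img - background
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if sigma <= 0:
        sigma = max(np.sqrt(max(background.mean(), 1.0)), 1e-12)
    z = response / (sigma * np.linalg.norm(w_tilde))
    z_crit = norm.isf(cfg.pfa)

    maxima = ndimage.maximum_filter(z, size=3, mode="reflect") == z
    cand = (
        (z > z_crit)
        & maxima
        & (img > cfg.detection_threshold * np.maximum(background, 1e-12))
    )
    half = cfg.box // 2
    cand[:half, :] = cand[-half:, :] = False
    cand[:, :half] = cand[:, -half:] = False

    locs: list[Localization] = []
    for iy, ix in zip(*np.nonzero(cand)):
        fit = _refine_gaussian(img, int(ix), int(iy), psf_sd, cfg)
        if fit is None:
            continue
        x_px, y_px, amp, converged = fit
        locs.append(
            Localization(
                frame=0,
                x=x_px * cfg.pixel_size,
                y=y_px * cfg.pixel_size,
                intensity=amp,
                precision_flag=converged,
            )
        )
    return locs


def _refine_gaussian(
    img: np.ndarray, ix: int, iy: int, psf_sd: float, cfg: TrackingConfig
) -> tuple[float, float, float, bool] | None:
    """Least-squares sub-pixel Gaussian refinement around a candidate pixel.

    Fits amplitude, background and centre with fixed PSF width by
    Gauss-Newton on the box window; rejects candidates whose centre moves
    more than max_refine pixels from the seed.
    """
    half = cfg.box // 2
    y0, y1 = iy - half, iy + half + 1
    x0, x1 = ix - half, ix + half + 1
    if y0 < 0 or x0 < 0 or y1 > img.shape[0] or x1 > img.shape[1]:
        return None
    win = img[y0:y1, x0:x1]
    ys, xs = np.mgrid[y0:y1, x0:x1]
    xs = xs + 0.5  # pixel centres
    ys = ys + 0.5
    cx, cy = ix + 0.5, iy + 0.5
    b = float(win.min())
    a = float(win.max() - b)
    converged = False
    for _ in range(cfg.max_iter):
        g = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * psf_sd**2))
        model = a * g + b
        r = win - model
        # Jacobian columns: dA, db, dcx, dcy
        d_cx = a * g * (xs - cx) / psf_sd**2
        d_cy = a * g * (ys - cy) / psf_sd**2
        J = np.stack([g.ravel(), np.ones(g.size), d_cx.ravel(), d_cy.ravel()], axis=1)
        try:
            step, *_ = np.linalg.lstsq(J, r.ravel(), rcond=None)
        except np.linalg.LinAlgError:
            return None
        a += step[0]
        b += step[1]
        cx += np.clip(step[2], -1.0, 1.0)
        cy += np.clip(step[3], -1.0, 1.0)
        if np.hypot(step[2], step[3]) < cfg.tol:
            converged = True
            break
    if np.hypot(cx - (ix + 0.5), cy - (iy + 0.5)) > cfg.max_refine:
        return None
    if a <= 0:
        return None
    return float(cx), float(cy), float(a), converged


def detect_stack(
    stack: np.ndarray, cfg: TrackingConfig, psf_sd: float = 1.35
) -> list[list[Localization]]:
    """Run detection on every frame of a (T, H, W) stack."""
    out = []
    for f, frame in enumerate(stack):
        locs = detect_spots(frame, cfg, psf_sd)
        out.append(
            [
                Localization(f, l.x, l.y, l.intensity, l.precision_flag)
                for l in locs
            ]
        )
    return out


def link_trajectories(
    localizations_by_frame: Sequence[Sequence[Localization]],
    cfg: TrackingConfig,
    frame_interval: float,
) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbour linking with gap closing.

    At each frame, an open track end and a new localization are linked when
    each is the other's nearest candidate within the link radius; remaining
    conflicts drop the link (conservative). Unmatched ends persist for up to
    max_gap frames; tracks shorter than min_length are discarded.
    """
    seen: set[tuple[int, float, float]] = set()
    for frame_locs in localizations_by_frame:
        for l in frame_locs:
            key = (l.frame, l.x, l.y)
            if key in seen:
                raise ValueError(f"duplicate localization at {key}")
            seen.add(key)

    radius = cfg.link_radius_um(frame_interval)
    open_tracks: list[dict] = []  # {"locs": [...], "last_frame": int}
    closed: list[list[Localization]] = []

    for frame_locs in localizations_by_frame:
        if not frame_locs:
            continue
        frame = frame_locs[0].frame
        # retire stale ends
        still_open = []
        for tr in open_tracks:
            if frame - tr["last_frame"] > cfg.max_gap + 1:
                closed.append(tr["locs"])
            else:
                still_open.append(tr)
        open_tracks = still_open

        unmatched = list(range(len(frame_locs)))
        if open_tracks:
            ends = np.array(
                [[tr["locs"][-1].x, tr["locs"][-1].y] for tr in open_tracks]
            )
            pts = np.array([[l.x, l.y] for l in frame_locs])
            dist = np.linalg.norm(ends[:, None, :] - pts[None, :, :], axis=2)
            dist[dist > radius] = np.inf
            assigned_tracks: set[int] = set()
            assigned_pts: set[int] = set()
            # mutual nearest neighbours, smallest distance first
            order = np.argsort(dist, axis=None)
            for flat in order:
                ti, pi = np.unravel_index(flat, dist.shape)
                if not np.isfinite(dist[ti, pi]):
                    break
                if ti in assigned_tracks or pi in assigned_pts:
                    continue
                # smallest-distance-first over free ends/points = mutual
                # nearest neighbour among the unassigned
                open_tracks[ti]["locs"].append(frame_locs[pi])
                open_tracks[ti]["last_frame"] = frame
                assigned_tracks.add(ti)
                assigned_pts.add(pi)
            unmatched = [i for i in range(len(frame_locs)) if i not in assigned_pts]
        for i in unmatched:
            open_tracks.append({"locs": [frame_locs[i]], "last_frame": frame})

    closed.extend(tr["locs"] for tr in open_tracks)

    trajectories = []
    tid = 0
    for locs in closed:
        if len(locs) < cfg.min_length:
            continue
        trajectories.append(
            Trajectory(
                tid,
                np.array([l.frame for l in locs]),
                np.array([l.x for l in locs]),
                np.array([l.y for l in locs]),
                frame_interval=frame_interval,
                pixel_size=cfg.pixel_size,
            )
        )
        tid += 1
    return trajectories


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))
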