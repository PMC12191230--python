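"""Ground-truthed synthetic data for every pipeline stage.

Each generator emulates one of the study's data modalities and returns its
planted ground truth alongside the data, so downstream modules can be tested
as recovery problems:

* a peak universe with planted shared / lost / gained structure and planted
  motifs (stand-in for per-allele DamID peak lists plus peak sequences);
* PBM probe tables whose intensities are driven by a planted 8-mer affinity
  landscape plus Gaussian noise;
* 2D single-molecule trajectories from a 3-state (bound / slow / fast)
  diffusion process with localization error and photobleaching, at either
  the fast (20 ms) or slow (500 ms) acquisition lag;
* camera-like image stacks rendered from trajectories (Gaussian PSF,
  Poisson shot noise over Poisson background);
* bi-exponential residence times quantized to the frame interval;
* two-time-point yeast-two-hybrid fluorescence readings.

All generators draw from one ``numpy.random.default_rng(seed)`` per call;
the seed is a required config field and identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet
from .motifs import revcomp
from .trajectories import Trajectory

__all__ = [
    "PeakSimConfig",
    "PbmSimConfig",
    "SmtSimConfig",
    "DwellSimConfig",
    "PeakUniverse",
    "PbmResult",
    "PlacementError",
    "simulate_peak_universe",
    "simulate_pbm",
    "simulate_trajectories",
    "render_image_stack",
    "simulate_dwell_data",
    "simulate_y2h",
]

BASES = np.array(list("ACGT"))


class PlacementError(RuntimeError):
    """Planted peaks could not be placed without overlap."""


# ---------------------------------------------------------------------------
# peak universe


@dataclass
class PeakSimConfig:
    genome_length: int = 1_000_000
    n_chrom: int = 2
    n_shared: int = 50
    n_lost: int = 20
    n_gained: int = 10
    peak_width: int = 400
    planted_motifs: list[tuple[str, float, int]] = field(default_factory=list)
    gc_background: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_shared, self.n_lost, self.n_gained) < 0:
            raise ValueError("peak counts must be >= 0")
        if self.peak_width <= 0 or self.genome_length < self.peak_width:
            raise ValueError("peak_width must fit in genome_length")
        if not 0 <= self.gc_background <= 1:
            raise ValueError("gc_background must be in [0,1]")
        for kmer, frac, copies in self.planted_motifs:
            if set(kmer.upper()) - set("ACGT"):
                raise ValueError(f"planted motif {kmer!r} not over ACGT")
            if not 0 <= frac <= 1:
                raise ValueError("motif fraction must be in [0,1]")
            if copies < 1 or copies * len(kmer) > self.peak_width:
                raise ValueError("motif copies must fit in peak_width")


@dataclass
class PeakUniverse:
    wt: PeakSet
    variant: PeakSet
    sequences: dict[str, str]
    truth: dict[str, str]  # peak name -> shared | lost | gained


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _plant(seq: str, kmer: str, copies: int, rng: np.random.Generator) -> str:
    """Plant non-overlapping copies of a k-mer (random strand each) in a sequence."""
    chars = list(seq)
    k = len(kmer)
    taken: list[tuple[int, int]] = []
    placed = 0
    for _ in range(1000):
        if placed == copies:
            break
        off = int(rng.integers(0, len(seq) - k + 1))
        if any(off < e and off + k > s for s, e in taken):
            continue
        ins = kmer if rng.random() < 0.5 else revcomp(kmer)
        chars[off: off + k] = list(ins)
        taken.append((off, off + k))
        placed += 1
    if placed < copies:
        raise PlacementError(f"could not plant {copies} copies of {kmer}")
    return "".join(chars)


def simulate_peak_universe(cfg: PeakSimConfig) -> PeakUniverse:
    """Generate WT and variant peak sets with planted shared/lost/gained labels.

    WT = shared + lost peaks, variant = shared + gained peaks; all planted
    peaks are mutually non-overlapping. Planted motifs are inserted into the
    configured fraction of WT-bound (shared and lost) peak sequences, each
    copy on a random strand.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_shared + cfg.n_lost + cfg.n_gained
    placed: dict[str, list[tuple[int, int]]] = {}
    peaks: list[GenomicInterval] = []
    labels = (
        ["shared"] * cfg.n_shared + ["lost"] * cfg.n_lost + ["gained"] * cfg.n_gained
    )
    for i in range(n_total):
        for attempt in range(10000):
            chrom = f"chr{int(rng.integers(1, cfg.n_chrom + 1))}"
            start = int(rng.integers(0, cfg.genome_length - cfg.peak_width + 1))
            end = start + cfg.peak_width
            if all(
                end <= s or start >= e for s, e in placed.get(chrom, [])
            ):
                placed.setdefault(chrom, []).append((start, end))
                peaks.append(
                    GenomicInterval(chrom, start, end, name=f"peak_{i:05d}")
                )
                break
        else:
            raise PlacementError(
                f"could not place peak {i} of {n_total} without overlap"
            )

    truth = {iv.name: lab for iv, lab in zip(peaks, labels)}
    sequences = {
        iv.name: _random_sequence(rng, cfg.peak_width, cfg.gc_background)
        for iv in peaks
    }
    wt_names = [iv.name for iv, lab in zip(peaks, labels) if lab in ("shared", "lost")]
    for kmer, frac, copies in cfg.planted_motifs:
        n_carry = int(round(frac * len(wt_names)))
        carriers = rng.choice(len(wt_names), size=n_carry, replace=False)
        for ci in carriers:
            name = wt_names[ci]
            sequences[name] = _plant(sequences[name], kmer.upper(), copies, rng)

    wt = PeakSet(
        "WT",
        [iv for iv, lab in zip(peaks, labels) if lab in ("shared", "lost")],
        merge=False,
    )
    variant = PeakSet(
        "variant",
        [iv for iv, lab in zip(peaks, labels) if lab in ("shared", "gained")],
        merge=False,
    )
    wt.intervals.sort()
    variant.intervals.sort()
    return PeakUniverse(wt, variant, sequences, truth)


# ---------------------------------------------------------------------------
# PBM


@dataclass
class PbmSimConfig:
    n_probes: int = 60000
    probe_length: int = 36
    affinity_map: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    intensity_baseline: float = 500.0
    intensity_range: float = 10000.0
    coverage: int = 8  # probes guaranteed to carry each mapped 8-mer (0 = none)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_length < 8:
            raise ValueError("probe_length must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for k, a in self.affinity_map.items():
            if len(k) != 8 or set(k.upper()) - set("ACGT"):
                raise ValueError(f"affinity_map key {k!r} must be an 8-mer over ACGT")
            if not 0 <= a <= 1:
                raise ValueError("affinities must be in [0,1]")


@dataclass
class PbmResult:
    probes: pd.DataFrame  # probe_id, sequence, intensity
    affinity_map: dict[str, float]


def _probe_affinity(seq: str, amap: Mapping[str, float]) -> float:
    best = 0.0
    rc = revcomp(seq)
    for kmer, a in amap.items():
        if a > best and (kmer in seq or kmer in rc):
            best = a
    return best


def simulate_pbm(cfg: PbmSimConfig) -> PbmResult:
    """Generate a probe table from a planted 8-mer affinity landscape.

    Probe intensity = baseline + range * (max affinity over contained 8-mers,
    either strand) + Gaussian noise; the max-affinity rule keeps the planted
    landscape interpretable. To emulate the guaranteed k-mer coverage of
    universal array designs, each mapped 8-mer is implanted into ``coverage``
    randomly chosen probes (set coverage=0 for purely random probes).
    """
    if not cfg.affinity_map:
        raise ValueError("affinity_map must not be empty")
    rng = np.random.default_rng(cfg.seed)
    amap = {k.upper(): v for k, v in cfg.affinity_map.items()}
    seqs = [
        _random_sequence(rng, cfg.probe_length, 0.5) for _ in range(cfg.n_probes)
    ]
    if cfg.coverage > 0:
        for kmer in amap:
            rows = rng.choice(cfg.n_probes, size=min(cfg.coverage, cfg.n_probes),
                              replace=False)
            for r in rows:
                off = int(rng.integers(0, cfg.probe_length - 8 + 1))
                s = seqs[r]
                seqs[r] = s[:off] + kmer + s[off + 8:]
    affinity = np.array([_probe_affinity(s, amap) for s in seqs])
    intensity = (
        cfg.intensity_baseline
        + cfg.intensity_range * affinity
        + rng.normal(0.0, cfg.noise_sd, size=cfg.n_probes)
    )
    probes = pd.DataFrame(
        {
            "probe_id": [f"probe_{i:06d}" for i in range(cfg.n_probes)],
            "sequence": seqs,
            "intensity": intensity,
        }
    )
    return PbmResult(probes, amap)


# ---------------------------------------------------------------------------
# SMT trajectories


@dataclass
class SmtSimConfig:
    n_molecules: int = 1000
    frame_interval: float = 0.020
    n_frames: int = 50
    fractions: tuple[float, float, float] = (0.3, 0.3, 0.4)  # bound, slow, fast
    diffusion: tuple[float, float, float] = (0.01, 0.15, 1.0)  # um^2/s
    switch_rates: np.ndarray | None = None  # 3x3 per-s rates, 0 = static states
    loc_error_sd: float = 0.035  # um
    bleach_rate: float = 2.0  # per-s
    pixel_size: float = 0.1  # um
    fov: int = 256  # pixels (square field)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")
        d = self.diffusion
        if not (d[0] <= d[1] <= d[2]):
            raise ValueError("require D_bound <= D_slow <= D_fast")
        if self.loc_error_sd < 0 or self.bleach_rate < 0:
            raise ValueError("rates and noise must be >= 0")
        if self.switch_rates is not None:
            sw = np.asarray(self.switch_rates, dtype=float)
            if sw.shape != (3, 3) or (sw[~np.eye(3, dtype=bool)] < 0).any():
                raise ValueError("switch_rates must be a 3x3 non-negative matrix")
            self.switch_rates = sw


def _state_path(
    rng: np.random.Generator, state0: int, n_steps: int, dt: float, rates: np.ndarray
) -> np.ndarray:
    """State index per displacement step under exponential switching."""
    states = np.empty(n_steps, dtype=np.int64)
    s = state0
    t_next = np.inf
    out_rate = rates[s].sum() - rates[s, s]
    if out_rate > 0:
        t_next = rng.exponential(1.0 / out_rate)
    t = 0.0
    for i in range(n_steps):
        t += dt
        while t_next <= t:
            probs = rates[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(3, p=probs))
            out_rate = rates[s].sum() - rates[s, s]
            t_next += rng.exponential(1.0 / out_rate) if out_rate > 0 else np.inf
        states[i] = s
    return states


def simulate_trajectories(
    cfg: SmtSimConfig,
) -> tuple[list[Trajectory], list[np.ndarray]]:
    """Simulate 2D trajectories from the 3-state diffusion model.

    Each molecule draws one state from the configured (bound, slow, fast)
    fractions and keeps it unless switching rates are given. Per-frame
    displacements per axis are Normal(0, 2 D dt); the observed position adds
    Normal(0, sigma^2) localization error per axis. Track length is the
    minimum of the bleaching time (geometric with per-frame survival
    exp(-k_b dt)) and n_frames, further truncated when the molecule leaves
    the field of view.

    Returns the observed trajectories and, per molecule, the true state
    index at every retained localization.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval
    fov_um = cfg.fov * cfg.pixel_size
    p_survive = float(np.exp(-cfg.bleach_rate * dt))
    trajectories: list[Trajectory] = []
    truth: list[np.ndarray] = []
    for mol in range(cfg.n_molecules):
        state0 = int(rng.choice(3, p=np.asarray(cfg.fractions)))
        if p_survive >= 1.0:
            n_loc = cfg.n_frames
        else:
            n_loc = min(1 + int(rng.geometric(1.0 - p_survive)) - 1, cfg.n_frames)
            n_loc = max(n_loc, 1)
        if cfg.switch_rates is not None and n_loc > 1:
            states = np.concatenate(
                [[state0], _state_path(rng, state0, n_loc - 1, dt, cfg.switch_rates)]
            )
        else:
            states = np.full(n_loc, state0, dtype=np.int64)
        pos = np.empty((n_loc, 2))
        pos[0] = rng.uniform(0, fov_um, size=2)
        d_arr = np.asarray(cfg.diffusion)
        if n_loc > 1:
            sd = np.sqrt(2.0 * d_arr[states[1:]] * dt)
            steps = rng.normal(0.0, 1.0, size=(n_loc - 1, 2)) * sd[:, None]
            pos[1:] = pos[0] + np.cumsum(steps, axis=0)
        # truncate at field-of-view exit
        inside = np.all((pos >= 0) & (pos <= fov_um), axis=1)
        if not inside.all():
            n_loc = max(1, int(np.argmin(inside)))
            pos = pos[:n_loc]
            states = states[:n_loc]
        obs = pos + rng.normal(0.0, cfg.loc_error_sd, size=pos.shape)
        trajectories.append(
            Trajectory(
                mol,
                np.arange(n_loc),
                obs[:, 0],
                obs[:, 1],
                frame_interval=dt,
                pixel_size=cfg.pixel_size,
            )
        )
        truth.append(states)
    return trajectories, truth


def render_image_stack(
    trajectories: Sequence[Trajectory],
    psf_sd: float = 0.135,
    photons: int = 500,
    background: float = 10.0,
    seed: int = 0,
    fov: int = 64,
    pixel_size: float = 0.1,
) -> np.ndarray:
    """Render trajectories as a (T, H, W) photon-count image stack.

    Each localization becomes a 2D Gaussian of integrated intensity
    ``photons`` and width ``psf_sd`` (um), sampled with Poisson shot noise
    over a Poisson background of ``background`` counts per pixel. Pixel
    centres sit at integer + 0.5 in pixel units.
    """
    if photons < 0 or background < 0:
        raise ValueError("photons and background must be >= 0")
    rng = np.random.default_rng(seed)
    n_frames = 1 + max((int(t.frames[-1]) for t in trajectories), default=0)
    expected = np.full((n_frames, fov, fov), float(background))
    sd_px = psf_sd / pixel_size
    half = max(3, int(np.ceil(4 * sd_px)))
    for t in trajectories:
        for f, xu, yu in zip(t.frames, t.x, t.y):
            cx, cy = xu / pixel_size, yu / pixel_size
            ix, iy = int(np.floor(cx)), int(np.floor(cy))
            x0, x1 = max(0, ix - half), min(fov, ix + half + 1)
            y0, y1 = max(0, iy - half), min(fov, iy + half + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1) + 0.5
            ys = np.arange(y0, y1) + 0.5
            gx = np.exp(-((xs - cx) ** 2) / (2 * sd_px**2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * sd_px**2))
            spot = photons * np.outer(gy, gx) / (2 * np.pi * sd_px**2)
            expected[int(f), y0:y1, x0:x1] += spot
    return rng.poisson(expected).astype(np.uint16)


# ---------------------------------------------------------------------------
# residence times


@dataclass
class DwellSimConfig:
    tau_long: float = 5.0  # s, specific binding
    tau_short: float = 0.9  # s, non-specific binding
    frac_long: float = 0.5
    n_tracks: int = 2000
    frame_interval: float = 0.5  # s
    censor_at: float = 250.0  # s, acquisition limit
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau_long > self.tau_short > 0:
            raise ValueError("require tau_long > tau_short > 0")
        if not 0 <= self.frac_long <= 1:
            raise ValueError("frac_long must be in [0,1]")
        if self.censor_at < self.frame_interval:
            raise ValueError("censor_at must be >= frame_interval")


def simulate_dwell_data(cfg: DwellSimConfig) -> np.ndarray:
    """Residence times from a bi-exponential mixture, frame-quantized and censored.

    Each time is drawn from frac_long * Exp(tau_long) + (1 - frac_long) *
    Exp(tau_short), rounded up to a whole number of frame intervals (a
    binding event is observed for the frames it spans), and capped at the
    acquisition limit ``censor_at``.
    """
    rng = np.random.default_rng(cfg.seed)
    long_mask = rng.random(cfg.n_tracks) < cfg.frac_long
    t = np.where(
        long_mask,
        rng.exponential(cfg.tau_long, cfg.n_tracks),
        rng.exponential(cfg.tau_short, cfg.n_tracks),
    )
    quant = np.ceil(t / cfg.frame_interval) * cfg.frame_interval
    return np.minimum(quant, cfg.censor_at)


# ---------------------------------------------------------------------------
# yeast two-hybrid


def simulate_y2h(
    strengths: Mapping[tuple[str, str], float],
    n_replicates: int = 3,
    f0: float = 1000.0,
    growth: float = 3.0,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-time-point fluorescence readings for bait-prey pairs.

    ``strengths`` maps (bait, prey) to a relative interaction strength in
    [0, 1] (wild-type bait conventionally 1.0). T1 readings scatter around
    ``f0``; T2 = T1 * growth * strength, with multiplicative noise of
    coefficient of variation ``noise_cv`` on both.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (bait, prey), s in strengths.items():
        if not 0 <= s <= 1:
            raise ValueError("interaction strengths must be in [0,1]")
        for rep in range(n_replicates):
            f1 = f0 * (1 + rng.normal(0, noise_cv))
            f2 = max(0.0, f1 * growth * s * (1 + rng.normal(0, noise_cv)))
            rows.append((bait, prey, rep, max(f1, 0.0), f2))
    return pd.DataFrame(rows, columns=["bait", "prey", "replicate", "f_t1", "f_t2"])
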