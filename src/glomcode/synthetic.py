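"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the three kinds of raw data the analysis consumes:

* :func:`generate_movie` — single-trial calcium-imaging stacks: Gaussian
  glomerular activity spots riding on a textured baseline, multiplicative
  mono-exponential photobleaching, integer inter-trial shifts, and additive
  Gaussian noise.  Paper-mode geometry is 344 x 260 px at 4 um/px, 40 frames
  at 4 Hz with the odor pulse on frames 9-16 (1-based).
* :func:`generate_gcead_dataset` — per-antenna GC-EAD peak tables with
  Bernoulli detection dropout and retention-time jitter, plus FID peak
  tables for replicate headspace samples.
* :func:`generate_group_table` — grouped sample x feature abundance tables
  with a controllable between-group separation, for ordination/ANOSIM.

All generators are bit-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import Movie

__all__ = [
    "MovieGroundTruth",
    "EadGroundTruth",
    "GroupTableSpec",
    "generate_movie",
    "generate_gcead_dataset",
    "generate_group_table",
    "response_waveform",
    "make_baseline_map",
    "grid_spot_centers",
    "make_movie_truth",
]

# Paper-mode acquisition geometry: 344 x 260 px, 4 um/px, 40 frames at 4 Hz.
PAPER_SHAPE = (260, 344)  # (H, W)
PAPER_PX_SIZE = 4.0
PAPER_FRAME_RATE = 4.0
PAPER_N_FRAMES = 40
STIM_ONSET = 9  # 1-based frame of odor onset (2 s at 4 Hz)
STIM_OFFSET = 16  # 1-based last odor frame


def response_waveform(
    n_frames: int = PAPER_N_FRAMES,
    onset: int = STIM_ONSET,
    peak_frame: int = 12,
    decay_tau: float = 8.0,
) -> np.ndarray:
    """Unit-amplitude dF/F time course of a responding glomerulus.

    Zero before stimulus onset, linear rise to 1 at ``peak_frame``, then
    exponential return with time constant ``decay_tau`` frames.  Frames are
    1-based; the returned array is indexed 0-based (index = frame - 1).
    """
    frames = np.arange(1, n_frames + 1, dtype=float)
    s = np.zeros(n_frames)
    rise = (frames >= onset) & (frames <= peak_frame)
    s[rise] = (frames[rise] - onset + 1) / (peak_frame - onset + 1)
    after = frames > peak_frame
    s[after] = np.exp(-(frames[after] - peak_frame) / decay_tau)
    return s


def bleach_profile(n_frames: int, tau: float, frac: float) -> np.ndarray:
    """Multiplicative bleaching factor per frame: 1 at frame 1, 1-frac at the end.

    Offset-plus-exponential form ``a + b exp(-t/tau)`` — the same family the
    correction stage fits.
    """
    if not 0.0 <= frac < 1.0:
        raise ValueError(f"bleach_frac must be in [0, 1), got {frac}")
    if frac == 0.0:
        return np.ones(n_frames)
    t = np.arange(n_frames, dtype=float)
    b = frac / (1.0 - np.exp(-(n_frames - 1) / tau))
    a = 1.0 - b
    return a + b * np.exp(-t / tau)


@dataclass(frozen=True)
class MovieGroundTruth:
    """Generative parameters for one synthetic imaging experiment.

    ``amplitudes[stimulus, spot]`` is the true peak dF/F of each activity
    spot, defined as the ROI-mean over the standard 60 um x 60 um square ROI
    centered on the spot (so extracted responses are directly comparable).
    """

    baseline_map: np.ndarray
    spot_centers: tuple[tuple[int, int], ...]
    amplitudes: np.ndarray
    shifts: np.ndarray
    spot_sigma: float = 12.0
    bleach_tau: float = 40.0
    bleach_frac: float = 0.2
    noise_sd: float = 0.005
    seed: int = 0
    frame_rate: float = PAPER_FRAME_RATE
    px_size: float = PAPER_PX_SIZE
    n_frames: int = PAPER_N_FRAMES
    roi_side_um: float = 60.0

    def __post_init__(self):
        base = np.asarray(self.baseline_map, dtype=float)
        amps = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        shifts = np.atleast_2d(np.asarray(self.shifts, dtype=int))
        object.__setattr__(self, "baseline_map", base)
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "shifts", shifts)
        if base.ndim != 2 or np.any(base <= 0):
            raise ValueError("baseline_map must be 2-D and strictly positive")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.bleach_frac < 1.0:
            raise ValueError("bleach_frac must be in [0, 1)")
        H, W = base.shape
        for r, c in self.spot_centers:
            if not (0 <= r < H and 0 <= c < W):
                raise ValueError(f"spot center {(r, c)} outside {H}x{W} image")
        if amps.shape[1] != len(self.spot_centers):
            raise ValueError("amplitudes second axis must match spot count")
        if shifts.shape != (amps.shape[0], 2):
            raise ValueError("shifts must be (n_stimuli, 2)")

    @property
    def n_stimuli(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def roi_half_px(self) -> int:
        side_px = int(round(self.roi_side_um / self.px_size))
        return side_px // 2


def _spot_gain_maps(truth: MovieGroundTruth) -> np.ndarray:
    """Per-spot spatial gain, scaled so its ROI mean at the center is 1."""
    H, W = truth.baseline_map.shape
    rr = np.arange(H)[:, None]
    cc = np.arange(W)[None, :]
    h = truth.roi_half_px
    gains = np.empty((len(truth.spot_centers), H, W))
    for i, (r, c) in enumerate(truth.spot_centers):
        g = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * truth.spot_sigma**2))
        roi = g[max(r - h, 0) : r + h + 1, max(c - h, 0) : c + h + 1]
        gains[i] = g / roi.mean()
    return gains


def _apply_integer_shift(frame: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Translate by whole pixels, replicating edge values into vacated areas."""
    H, W = frame.shape
    pr, pc = abs(int(drow)), abs(int(dcol))
    padded = np.pad(frame, ((pr, pr), (pc, pc)), mode="edge")
    r0 = pr - int(drow)
    c0 = pc - int(dcol)
    return padded[r0 : r0 + H, c0 : c0 + W]


def generate_movie(
    truth: MovieGroundTruth, stimulus_id: int, *, gains: np.ndarray | None = None
) -> Movie:
    """Render the fluorescence stack for one odor-stimulation trial.

    F(x, t) = baseline(x) * (1 + sum_s A[stim, s] g_s(x) w(t)) * B(t),
    then the trial's integer shift, then additive Gaussian noise with
    per-pixel SD ``noise_sd * baseline(x)``.  Deterministic in
    ``(truth.seed, stimulus_id)``.

    ``gains`` may be passed to reuse precomputed spot gain maps across trials.
    """
    if not 0 <= stimulus_id < truth.n_stimuli:
        raise ValueError(f"stimulus_id {stimulus_id} out of range")
    if gains is None:
        gains = _spot_gain_maps(truth)
    w = response_waveform(truth.n_frames)
    bleach = bleach_profile(truth.n_frames, truth.bleach_tau, truth.bleach_frac)
    amps = truth.amplitudes[stimulus_id]
    spot_field = (amps[:, None, None] * gains).sum(axis=0)  # (H, W)
    signal = 1.0 + w[:, None, None] * spot_field[None]
    stack = truth.baseline_map[None] * signal * bleach[:, None, None]

    drow, dcol = truth.shifts[stimulus_id]
    if drow or dcol:
        stack = np.stack([_apply_integer_shift(f, drow, dcol) for f in stack])

    if truth.noise_sd > 0:
        rng = np.random.default_rng([truth.seed, stimulus_id])
        stack = stack + rng.normal(
            0.0, truth.noise_sd, stack.shape
        ) * truth.baseline_map[None]
    return Movie(data=stack, frame_rate=truth.frame_rate, px_size=truth.px_size)


def make_baseline_map(
    shape: tuple[int, int] = PAPER_SHAPE,
    *,
    base: float = 100.0,
    texture_amp: float = 20.0,
    texture_sigma: float = 4.0,
    seed: int = 0,
) -> np.ndarray:
    """Positive baseline fluorescence with smooth anatomical texture.

    The texture (smoothed white noise) mimics the antennal-lobe outline and
    tracheae that make raw frames registrable.
    """
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), texture_sigma)
    tex *= texture_amp / max(tex.std(), 1e-12)
    out = base + tex
    return np.clip(out, base * 0.1, None)


def grid_spot_centers(
    shape: tuple[int, int], n_spots: int, margin: int = 24
) -> tuple[tuple[int, int], ...]:
    """Deterministic near-square grid of spot centers away from the borders."""
    H, W = shape
    ncols = int(np.ceil(np.sqrt(n_spots * W / H)))
    nrows = int(np.ceil(n_spots / ncols))
    rows = np.linspace(margin, H - 1 - margin, nrows)
    cols = np.linspace(margin, W - 1 - margin, ncols)
    centers = [
        (int(round(r)), int(round(c))) for r in rows for c in cols
    ][:n_spots]
    return tuple(centers)


def make_movie_truth(
    amplitudes: np.ndarray,
    *,
    geometry: str = "paper",
    seed: int = 0,
    shifts: np.ndarray | None = None,
    max_shift: int = 6,
    noise_sd: float = 0.005,
    bleach_frac: float = 0.2,
    bleach_tau: float = 40.0,
) -> MovieGroundTruth:
    """Convenience constructor for a full experiment's ground truth.

    geometry "paper": 344 x 260 px, spot sigma 12 px.  geometry "desk":
    half-scale 172 x 130 px, spot sigma 6 px — same statistical structure at
    a quarter of the pixel count, for benchmarks and tests.
    """
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    n_stimuli, n_spots = amplitudes.shape
    if geometry == "paper":
        shape, sigma, margin = PAPER_SHAPE, 12.0, 28
    elif geometry == "desk":
        # spot sigma small enough that neighboring spots (>= ~22 px apart on
        # the 23-spot grid) contribute negligibly to each other's ROI
        shape, sigma, margin = (130, 172), 5.0, 20
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng([seed, 1])
    if shifts is None:
        shifts = rng.integers(-max_shift, max_shift + 1, size=(n_stimuli, 2))
        shifts[0] = 0  # first trial defines the reference frame
    return MovieGroundTruth(
        baseline_map=make_baseline_map(shape, seed=seed),
        spot_centers=grid_spot_centers(shape, n_spots, margin=margin),
        amplitudes=amplitudes,
        shifts=np.asarray(shifts, dtype=int),
        spot_sigma=sigma,
        bleach_tau=bleach_tau,
        bleach_frac=bleach_frac,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# GC-EAD synthetic data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EadGroundTruth:
    """True compound set and acquisition noise model for a GC-EAD study.

    ``compounds`` rows are (retention time in min, EAD amplitude in mV,
    headspace label).  Each antenna detects each compound of the headspace it
    is stimulated with independently with probability ``detect_prob``;
    detected peaks get Gaussian retention-time jitter and log-normal
    amplitude/area noise.  ``n_replicates`` independent FID-only headspace
    samples per headspace carry per-compound presence with probability
    ``replicate_presence_prob``.
    """

    compounds: tuple[tuple[float, float, str], ...]
    detect_prob: float = 0.9
    rt_jitter_sd: float = 0.02
    n_antennae: int = 5
    n_replicates: int = 3
    replicate_presence_prob: float = 0.9
    amp_noise_frac: float = 0.15
    area_scale: float = 1e6
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError("detect_prob must be in [0, 1]")
        if self.rt_jitter_sd < 0:
            raise ValueError("rt_jitter_sd must be nonnegative")
        rts = sorted(rt for rt, _, _ in self.compounds)
        if any(rt <= 0 for rt in rts):
            raise ValueError("retention times must be strictly positive")
        if any(amp < 0 for _, amp, _ in self.compounds):
            raise ValueError("amplitudes must be nonnegative")
        gaps = np.diff(rts)
        if len(gaps) and self.rt_jitter_sd > 0 and gaps.min() <= self.rt_jitter_sd:
            raise ValueError(
                "rt_jitter_sd must be smaller than the minimum inter-compound RT gap"
            )


@dataclass
class EadDataset:
    """Tidy outputs of :func:`generate_gcead_dataset`.

    ``ead_peaks``: one row per detected peak per antenna (antenna_id,
    headspace, rt, amplitude, area, compound_id).  ``fid_peaks``: FID peaks of
    replicate headspace samples (sample_id, headspace, replicate, rt, area,
    compound_id).  ``compounds``: the ground-truth compound table.
    """

    ead_peaks: pd.DataFrame
    fid_peaks: pd.DataFrame
    compounds: pd.DataFrame


def generate_gcead_dataset(truth: EadGroundTruth) -> EadDataset:
    """Simulate per-antenna EAD peak tables and replicate FID samples."""
    rng = np.random.default_rng(truth.seed)
    comp = pd.DataFrame(
        list(truth.compounds), columns=["rt", "amplitude", "headspace"]
    )
    comp.insert(0, "compound_id", np.arange(len(comp)))

    ead_rows = []
    for hs, sub in comp.groupby("headspace", sort=False):
        for ant in range(truth.n_antennae):
            antenna_id = f"{hs}_ant{ant}"
            for row in sub.itertuples(index=False):
                if rng.random() >= truth.detect_prob:
                    continue
                rt = row.rt + rng.normal(0.0, truth.rt_jitter_sd)
                amp = row.amplitude * np.exp(
                    rng.normal(0.0, truth.amp_noise_frac)
                )
                area = truth.area_scale * (0.1 + row.amplitude) * np.exp(
                    rng.normal(0.0, truth.amp_noise_frac)
                )
                ead_rows.append(
                    (antenna_id, hs, rt, amp, area, row.compound_id)
                )
    ead = pd.DataFrame(
        ead_rows,
        columns=["antenna_id", "headspace", "rt", "amplitude", "area", "compound_id"],
    )

    fid_rows = []
    for hs, sub in comp.groupby("headspace", sort=False):
        for rep in range(truth.n_replicates):
            sample_id = f"{hs}_rep{rep}"
            for row in sub.itertuples(index=False):
                if rng.random() >= truth.replicate_presence_prob:
                    continue
                rt = row.rt + rng.normal(0.0, truth.rt_jitter_sd)
                area = truth.area_scale * (0.1 + row.amplitude) * np.exp(
                    rng.normal(0.0, truth.amp_noise_frac)
                )
                fid_rows.append((sample_id, hs, rep, rt, area, row.compound_id))
    fid = pd.DataFrame(
        fid_rows,
        columns=["sample_id", "headspace", "replicate", "rt", "area", "compound_id"],
    )
    return EadDataset(ead_peaks=ead, fid_peaks=fid, compounds=comp)


# ---------------------------------------------------------------------------
# Grouped abundance tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupTableSpec:
    """Log-normal sample x feature abundance model with planted group structure.

    ``separation`` displaces each group's mean log-abundance along a random
    unit direction in feature space; 0 makes samples exchangeable.  An
    optional second crossed factor adds its own displacement
    (``second_separation``) so two-way designs can be simulated.
    """

    n_groups: int = 2
    n_per_group: int = 10
    n_features: int = 30
    separation: float = 1.0
    sigma_log: float = 0.5
    base_mean: float = 10.0
    second_factor_levels: int = 0
    second_separation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_groups, self.n_per_group, self.n_features) < 1:
            raise ValueError("dimensions must be positive")
        if self.sigma_log < 0 or self.separation < 0 or self.second_separation < 0:
            raise ValueError("dispersion/separation must be nonnegative")


def generate_group_table(spec: GroupTableSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (abundance table, labels).

    Labels have column ``group`` and, if ``second_factor_levels > 0``,
    column ``factor2``; the design is then fully crossed with
    ``n_per_group`` samples per (group, factor2) cell.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    dir_a = rng.standard_normal((spec.n_groups, p))
    dir_a /= np.linalg.norm(dir_a, axis=1, keepdims=True)
    levels_b = max(spec.second_factor_levels, 1)
    dir_b = rng.standard_normal((levels_b, p))
    dir_b /= np.linalg.norm(dir_b, axis=1, keepdims=True)

    rows, labels = [], []
    for g in range(spec.n_groups):
        for b in range(levels_b):
            for _ in range(spec.n_per_group):
                mu = np.log(spec.base_mean) + spec.separation * dir_a[g]
                if spec.second_factor_levels > 0:
                    mu = mu + spec.second_separation * dir_b[b]
                rows.append(np.exp(mu + rng.normal(0.0, spec.sigma_log, p)))
                labels.append((f"g{g}", f"b{b}"))

    table = pd.DataFrame(
        np.asarray(rows), columns=[f"feat{j}" for j in range(p)]
    )
    table.index = [f"s{i}" for i in range(len(rows))]
    lab = pd.DataFrame(labels, columns=["group", "factor2"], index=table.index)
    if spec.second_factor_levels == 0:
        lab = lab[["group"]]
    return table, lab
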