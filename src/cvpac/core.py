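"""Complex-valued phase-amplitude coupling (CV-PAC).

Each pixel of a CV-PAC comodulogram is a complex number whose modulus is the
KL-based modulation index (coupling strength, in [0, 1]) and whose argument
is the low-frequency phase at which the high-frequency amplitude peaks (the
coupled phase).  The comodulogram is computed on a 10 x 10 grid of
(low-frequency, high-frequency) interval pairs: 1-10 Hz and 30-160 Hz, each
split into 10 intervals equally spaced in log frequency.

Pipeline per analysis window: a complex Morlet CWT extracts the phase series
at every low-frequency interval centre and the amplitude envelope at every
high-frequency centre; the amplitude is averaged within N = 18 phase bins
tiling [-pi, pi); the normalised bin profile P(j) is compared with the
uniform distribution via the Kullback-Leibler divergence, giving the
modulation index S = D_KL(P, U) / log N; the arg-max bin centre gives the
coupled phase psi; the pixel is S * exp(i * psi).

A surrogate test screens out chance-level coupling: the phase series is
shuffled, the strength recomputed, and the pixel zeroed unless it reaches
the top alpha fraction of the shuffled strengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import Window
from .wavelet import DEFAULT_BANDWIDTH, cwt_band, cwt_complex

__all__ = [
    "N_PHASE_BINS",
    "FrequencyGrid",
    "PhaseAmplitudeDistribution",
    "CVPACImage",
    "BandMask",
    "BAND_RANGES",
    "phase_amplitude_distribution",
    "kl_to_uniform",
    "modulation_index",
    "coupling_phase",
    "cvpac_pixel",
    "compute_cvpac",
    "surrogate_test",
    "band_mask",
    "ablation_statistics",
    "ablate_band",
    "restrict_rows",
    "save_images",
    "load_images",
    "cwt_band",
]

N_PHASE_BINS = 18

#: Clinical band limits (Hz).  Low bands partition the 1-10 Hz axis,
#: gamma/hfo partition the 30-160 Hz axis.
BAND_RANGES: dict[str, tuple[str, float, float]] = {
    "slow_delta": ("low", 1.0, 2.0),
    "fast_delta": ("low", 2.0, 4.0),
    "theta": ("low", 4.0, 8.0),
    "alpha": ("low", 8.0, 10.0),
    "gamma": ("high", 30.0, 80.0),
    "hfo": ("high", 80.0, 160.0),
}


@dataclass(frozen=True)
class FrequencyGrid:
    """Log-spaced frequency grid of the comodulogram.

    ``low_edges`` and ``high_edges`` are the interval boundaries (11 values
    for 10 intervals each on the default grid); interval centres are the
    geometric means of consecutive edges.
    """

    low_edges: np.ndarray
    high_edges: np.ndarray
    n_bins: int = N_PHASE_BINS

    def __post_init__(self) -> None:
        object.__setattr__(self, "low_edges", np.asarray(self.low_edges, float))
        object.__setattr__(self, "high_edges", np.asarray(self.high_edges, float))
        for name, edges in (("low", self.low_edges), ("high", self.high_edges)):
            if edges.ndim != 1 or edges.size < 2:
                raise ValueError(f"{name}_edges needs at least two values")
            if np.any(np.diff(edges) <= 0):
                raise ValueError(f"{name}_edges must be strictly increasing")
        if self.n_bins < 2:
            raise ValueError("need at least 2 phase bins")

    @classmethod
    def default(cls) -> "FrequencyGrid":
        """1-10 Hz and 30-160 Hz, 10 intervals each, equal steps in log space."""
        return cls(
            low_edges=np.geomspace(1.0, 10.0, 11),
            high_edges=np.geomspace(30.0, 160.0, 11),
        )

    @property
    def low_centers(self) -> np.ndarray:
        return np.sqrt(self.low_edges[:-1] * self.low_edges[1:])

    @property
    def high_centers(self) -> np.ndarray:
        return np.sqrt(self.high_edges[:-1] * self.high_edges[1:])

    @property
    def n_low(self) -> int:
        return self.low_edges.size - 1

    @property
    def n_high(self) -> int:
        return self.high_edges.size - 1

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, columns) = (high intervals, low intervals)."""
        return (self.n_high, self.n_low)

    def bin_centers(self) -> np.ndarray:
        """Centres of the phase bins tiling [-pi, pi)."""
        width = 2 * np.pi / self.n_bins
        return -np.pi + (np.arange(self.n_bins) + 0.5) * width

    def cell_of(self, f_low: float, f_high: float) -> tuple[int, int]:
        """(row, col) of the grid cell containing a frequency pair."""
        col = int(np.searchsorted(self.low_edges, f_low, side="right")) - 1
        row = int(np.searchsorted(self.high_edges, f_high, side="right")) - 1
        if not (0 <= col < self.n_low and 0 <= row < self.n_high):
            raise ValueError(f"({f_low}, {f_high}) Hz outside the grid")
        return row, col


@dataclass
class PhaseAmplitudeDistribution:
    """Normalised mean-amplitude-per-phase-bin profile P(j), sum P = 1."""

    p: np.ndarray
    bin_centers: np.ndarray
    empty_bins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, float)
        self.bin_centers = np.asarray(self.bin_centers, float)
        if self.p.shape != self.bin_centers.shape:
            raise ValueError("p and bin_centers must have equal length")
        if np.any(self.p < 0):
            raise ValueError("P(j) must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.p.size


def _bin_centers(n_bins: int) -> np.ndarray:
    width = 2 * np.pi / n_bins
    return -np.pi + (np.arange(n_bins) + 0.5) * width


def _phase_bin_index(phase: np.ndarray, n_bins: int) -> np.ndarray:
    """Index of the [-pi, pi) phase bin of each sample."""
    idx = np.floor((phase + np.pi) / (2 * np.pi) * n_bins).astype(np.intp)
    # phase exactly +pi folds into the last bin
    return np.clip(idx, 0, n_bins - 1)


def _mean_amplitude_per_bin(
    idx: np.ndarray, amplitude: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean amplitude per phase bin; empty bins get 0 and are flagged."""
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    empty = counts == 0
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=~empty)
    return means, empty


def phase_amplitude_distribution(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_bins: int = N_PHASE_BINS,
    empty_bin: str = "zero",
) -> PhaseAmplitudeDistribution:
    """Bin amplitude by phase and normalise to a probability profile.

    P(j) = <A>_j / sum_k <A>_k where <A>_j is the mean amplitude over the
    samples whose phase falls in bin j of [-pi, pi).

    Parameters
    ----------
    empty_bin:
        ``"zero"`` treats an empty bin's mean as 0 and flags it;
        ``"error"`` rejects the window instead.
    """
    phase = np.asarray(phase, float)
    amplitude = np.asarray(amplitude, float)
    if phase.shape != amplitude.shape or phase.ndim != 1:
        raise ValueError("phase and amplitude must be equal-length 1-D series")
    if empty_bin not in ("zero", "error"):
        raise ValueError(f"unknown empty_bin mode {empty_bin!r}")
    idx = _phase_bin_index(phase, n_bins)
    means, empty = _mean_amplitude_per_bin(idx, amplitude, n_bins)
    if empty.any() and empty_bin == "error":
        raise ValueError(f"empty phase bins: {np.flatnonzero(empty).tolist()}")
    total = means.sum()
    if total <= 0:
        # zero amplitude everywhere: no preferred phase, uniform by convention
        p = np.full(n_bins, 1.0 / n_bins)
    else:
        p = means / total
    return PhaseAmplitudeDistribution(p, _bin_centers(n_bins), empty_bins=empty)


def _check_normalised(dist: PhaseAmplitudeDistribution) -> np.ndarray:
    p = dist.p
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"distribution not normalised (sum = {p.sum()!r})")
    return p


def kl_to_uniform(dist: PhaseAmplitudeDistribution) -> float:
    """Kullback-Leibler divergence D_KL(P, U) with U(j) = 1/N (natural log).

    Terms with P(j) = 0 contribute 0; the result lies in [0, log N].
    """
    p = _check_normalised(dist)
    n = dist.n_bins
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] * n)))


def modulation_index(dist: PhaseAmplitudeDistribution) -> float:
    """Coupling strength S = D_KL(P, U) / log N, in [0, 1].

    0 for a uniform profile (no coupling), 1 when all amplitude mass falls
    in a single phase bin.  Invariant to the base of the logarithm.
    """
    return kl_to_uniform(dist) / np.log(dist.n_bins)


def coupling_phase(dist: PhaseAmplitudeDistribution) -> float:
    """Centre angle of the arg-max bin of P(j), in [-pi, pi).

    Ties are broken toward the lowest bin index.
    """
    _check_normalised(dist)
    return float(dist.bin_centers[int(np.argmax(dist.p))])


def cvpac_pixel(strength: float, phase: float) -> complex:
    """Polar to complex: S * cos(psi) + i * S * sin(psi).

    A zero-strength pixel is exactly 0 (its argument is unconstrained).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"strength must be in [0, 1], got {strength!r}")
    if strength == 0.0:
        return 0j
    return complex(strength * np.cos(phase), strength * np.sin(phase))


@dataclass
class CVPACImage:
    """A CV-PAC comodulogram: rows = high-frequency intervals, columns = low.

    ``pixels[r, c]`` couples the phase at ``grid.low_centers[c]`` with the
    amplitude at ``grid.high_centers[r]``; modulus = strength, argument =
    coupled phase.
    """

    pixels: np.ndarray
    grid: FrequencyGrid
    label: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, complex)
        if self.pixels.shape != self.grid.shape:
            raise ValueError(
                f"pixels shape {self.pixels.shape} != grid shape {self.grid.shape}"
            )
        if np.any(np.abs(self.pixels) > 1.0 + 1e-9):
            raise ValueError("pixel modulus exceeds 1")

    @property
    def strength(self) -> np.ndarray:
        return np.abs(self.pixels)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.pixels)

    def to_frame(self):
        """Long-format table: one row per pixel."""
        import pandas as pd

        rows, cols = self.grid.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return pd.DataFrame(
            {
                "low_center_hz": self.grid.low_centers[cc.ravel()],
                "high_center_hz": self.grid.high_centers[rr.ravel()],
                "strength": self.strength.ravel(),
                "phase_rad": self.phase.ravel(),
            }
        )


def _window_analysis_series(window: Window, pad_s: float) -> tuple[np.ndarray, int, int]:
    """Window samples flanked by recorded context, zero-padded to pad_s."""
    n_pad = int(round(pad_s * window.rate))
    before = window.context_before if window.context_before is not None else np.empty(0)
    after = window.context_after if window.context_after is not None else np.empty(0)
    before = np.asarray(before, float)[-n_pad:] if n_pad else np.empty(0)
    after = np.asarray(after, float)[:n_pad] if n_pad else np.empty(0)
    left = np.concatenate([np.zeros(n_pad - before.size), before])
    right = np.concatenate([after, np.zeros(n_pad - after.size)])
    series = np.concatenate([left, np.asarray(window.samples, float), right])
    return series, n_pad, n_pad


def _phase_amp_stack(
    window: Window,
    grid: FrequencyGrid,
    bandwidth: float,
    pad_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """CWT phases at low centres and amplitudes at high centres, pads trimmed."""
    if window.rate <= 2 * grid.high_edges[-1]:
        raise ValueError(
            f"rate {window.rate:g} Hz too low for a {grid.high_edges[-1]:g} Hz grid"
        )
    series, left, right = _window_analysis_series(window, pad_s)
    sl = slice(left, series.size - right if right else None)
    low_coef = cwt_complex(series, window.rate, grid.low_centers, bandwidth)
    high_coef = cwt_complex(series, window.rate, grid.high_centers, bandwidth)
    phases = np.angle(low_coef[:, sl])
    amps = np.abs(high_coef[:, sl])
    return phases, amps


def compute_cvpac(
    window: Window,
    grid: FrequencyGrid | None = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
    pad_s: float = 2.0,
    empty_bin: str = "zero",
) -> CVPACImage:
    """Compute the CV-PAC comodulogram of one analysis window.

    Edge effects of the wavelet transform are controlled by analysing the
    window together with ``pad_s`` seconds of recorded context on each side
    (zero-padded where no context is available) and trimming the pads after
    the transform.
    """
    grid = grid or FrequencyGrid.default()
    phases, amps = _phase_amp_stack(window, grid, bandwidth, pad_s)
    pixels = np.zeros(grid.shape, complex)
    any_empty = False
    for c in range(grid.n_low):
        idx = _phase_bin_index(phases[c], grid.n_bins)
        for r in range(grid.n_high):
            means, empty = _mean_amplitude_per_bin(idx, amps[r], grid.n_bins)
            if empty.any():
                if empty_bin == "error":
                    raise ValueError(
                        f"empty phase bin at low centre {grid.low_centers[c]:.3g} Hz"
                    )
                any_empty = True
            dist = PhaseAmplitudeDistribution(
                means / means.sum() if means.sum() > 0 else np.full(grid.n_bins, 1 / grid.n_bins),
                _bin_centers(grid.n_bins),
            )
            pixels[r, c] = cvpac_pixel(modulation_index(dist), coupling_phase(dist))
    prov = dict(window.provenance())
    if any_empty:
        prov["empty_phase_bins"] = True
    return CVPACImage(pixels, grid, label=window.label, provenance=prov)


def surrogate_test(
    window: Window,
    grid: FrequencyGrid | None = None,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    method: str = "block",
    block_s: float = 1.0,
    bandwidth: float = DEFAULT_BANDWIDTH,
    pad_s: float = 2.0,
) -> CVPACImage:
    """Surrogate-tested CV-PAC (ST-CV-PAC).

    For each low-frequency column the phase series is shuffled ``n_shuffles``
    times and the coupling strength recomputed against every high-frequency
    amplitude envelope.  A pixel survives only if its strength reaches the
    top ``alpha`` fraction of its shuffled strengths (i.e. is at least the
    smallest of the ``floor(alpha * n_shuffles)`` largest surrogate values);
    otherwise it is set to 0.  Under a no-coupling null this retains a pixel
    with probability ~ alpha.

    Shuffle methods:

    ``"block"`` (default)
        Circularly roll the phase series by a random offset, cut it into
        blocks of ``block_s`` seconds and permute the blocks.  This keeps
        the series' short-range autocorrelation — so the surrogate strength
        distribution matches the null of band-limited (autocorrelated)
        signals and the retention rate on no-coupling data is ~ alpha —
        while scrambling the long-range phase-amplitude alignment that
        genuine coupling lives on.
    ``"roll"``
        A single random circular shift per surrogate.  Also calibrated
        under the null, but a pure shift leaves the coupling strength of a
        strictly stationary periodic modulation unchanged (it only rotates
        the coupled phase), so its power against sustained coupling is low.
    ``"permute"``
        Full random permutation of the phase samples.  Destroys all
        autocorrelation, so on band-limited signals the surrogate strengths
        underestimate the null and far more than alpha of no-coupling
        pixels survive; kept for comparison.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20 for a meaningful quantile")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if method not in ("permute", "roll", "block"):
        raise ValueError(f"unknown shuffle method {method!r}")
    rng = np.random.default_rng(seed)
    grid = grid or FrequencyGrid.default()
    image = compute_cvpac(window, grid, bandwidth=bandwidth, pad_s=pad_s)
    phases, amps = _phase_amp_stack(window, grid, bandwidth, pad_s)
    n = phases.shape[1]
    log_n = np.log(grid.n_bins)
    # k-th largest surrogate value is the retention threshold
    n_top = max(int(np.floor(alpha * n_shuffles)), 1)
    n_blocks = max(int(round(n / max(block_s * window.rate, 1.0))), 2)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    keep = np.zeros(grid.shape, bool)
    for c in range(grid.n_low):
        idx = _phase_bin_index(phases[c], grid.n_bins)
        null = np.empty((n_shuffles, grid.n_high))
        for s in range(n_shuffles):
            if method == "permute":
                idx_s = idx[rng.permutation(n)]
            elif method == "roll":
                idx_s = np.roll(idx, rng.integers(1, n))
            else:
                rolled = np.roll(idx, rng.integers(n))
                idx_s = np.concatenate(
                    [rolled[edges[b] : edges[b + 1]] for b in rng.permutation(n_blocks)]
                )
            for r in range(grid.n_high):
                means, _ = _mean_amplitude_per_bin(idx_s, amps[r], grid.n_bins)
                total = means.sum()
                if total <= 0:
                    null[s, r] = 0.0
                    continue
                p = means / total
                nz = p > 0
                null[s, r] = np.sum(p[nz] * np.log(p[nz] * grid.n_bins)) / log_n
        thresh = np.sort(null, axis=0)[n_shuffles - n_top]
        keep[:, c] = image.strength[:, c] >= thresh
    pixels = np.where(keep, image.pixels, 0j)
    prov = dict(image.provenance)
    prov.update(surrogate={"n_shuffles": n_shuffles, "alpha": alpha, "method": method})
    return CVPACImage(pixels, grid, label=image.label, provenance=prov)


@dataclass(frozen=True)
class BandMask:
    """Boolean pixel mask selecting one clinical band of the grid."""

    name: str
    selected: np.ndarray

    @property
    def rows(self) -> np.ndarray:
        """Indices of fully selected rows (for row bands)."""
        return np.flatnonzero(self.selected.all(axis=1))

    @property
    def columns(self) -> np.ndarray:
        return np.flatnonzero(self.selected.all(axis=0))


def band_mask(grid: FrequencyGrid, band_name: str) -> BandMask:
    """Mask of the grid cells whose interval centre lies in a clinical band.

    Low bands (slow_delta 1-2, fast_delta 2-4, theta 4-8, alpha 8-10 Hz)
    select whole columns; gamma (30-80) and hfo (80-160 Hz) select whole
    rows.  Assignment is by interval centre, since log-spaced edges do not
    align exactly with the clinical boundaries.
    """
    if band_name not in BAND_RANGES:
        raise ValueError(
            f"unknown band {band_name!r}; expected one of {sorted(BAND_RANGES)}"
        )
    axis, lo, hi = BAND_RANGES[band_name]
    selected = np.zeros(grid.shape, bool)
    if axis == "low":
        cols = (grid.low_centers >= lo) & (grid.low_centers < hi)
        selected[:, cols] = True
    else:
        rows = (grid.high_centers >= lo) & (grid.high_centers < hi)
        selected[rows, :] = True
    return BandMask(band_name, selected)


@dataclass(frozen=True)
class ReplacementStats:
    """Per-part moments of a masked region, used for band ablation."""

    mean_re: float
    std_re: float
    mean_im: float
    std_im: float


def ablation_statistics(
    images: Sequence[CVPACImage] | Iterable[CVPACImage], mask: BandMask
) -> ReplacementStats:
    """Sample mean/std of real and imaginary parts over the masked region.

    Computed across all images of the split being ablated so that the
    replacement noise matches the region's distribution without leaking
    information between training and test splits.
    """
    vals = np.concatenate([img.pixels[mask.selected] for img in images])
    return ReplacementStats(
        mean_re=float(vals.real.mean()),
        std_re=float(vals.real.std()),
        mean_im=float(vals.imag.mean()),
        std_im=float(vals.imag.std()),
    )


def ablate_band(
    image: CVPACImage,
    mask: BandMask,
    seed: int | np.random.Generator | None = None,
    stats: ReplacementStats | None = None,
    mode: str = "per_part",
) -> CVPACImage:
    """Replace the masked pixels with moment-matched random values.

    ``mode="per_part"`` draws real and imaginary parts independently from
    Gaussians with the region's per-part mean and variance;
    ``mode="circular"`` draws a circularly-symmetric complex Gaussian with
    the pooled variance around the complex mean.  Unmasked pixels are
    unchanged.  Moduli are clipped to 1 to keep the image valid.
    """
    if mask.selected.shape != image.pixels.shape:
        raise ValueError("mask shape does not match image")
    rng = np.random.default_rng(seed)
    k = int(mask.selected.sum())
    if k == 0:
        return CVPACImage(
            image.pixels.copy(), image.grid, image.label, dict(image.provenance)
        )
    if stats is None:
        stats = ablation_statistics([image], mask)
    if mode == "per_part":
        re = rng.normal(stats.mean_re, stats.std_re, k)
        im = rng.normal(stats.mean_im, stats.std_im, k)
    elif mode == "circular":
        pooled = np.sqrt((stats.std_re**2 + stats.std_im**2) / 2)
        re = rng.normal(stats.mean_re, pooled, k)
        im = rng.normal(stats.mean_im, pooled, k)
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    repl = re + 1j * im
    mod = np.abs(repl)
    over = mod > 1.0
    repl[over] /= mod[over]
    pixels = image.pixels.copy()
    pixels[mask.selected] = repl
    prov = dict(image.provenance)
    prov["ablated_band"] = mask.name
    return CVPACImage(pixels, image.grid, image.label, prov)


def restrict_rows(image: CVPACImage, mask: BandMask) -> CVPACImage:
    """Keep only the high-frequency rows of a row band (gamma or hfo)."""
    rows = mask.rows
    if rows.size == 0 or not mask.selected[rows].all():
        raise ValueError(f"mask {mask.name!r} does not select whole rows")
    if np.any(np.diff(rows) != 1):
        raise ValueError("row band must be contiguous")
    grid = FrequencyGrid(
        low_edges=image.grid.low_edges,
        high_edges=image.grid.high_edges[rows[0] : rows[-1] + 2],
        n_bins=image.grid.n_bins,
    )
    prov = dict(image.provenance)
    prov["restricted_rows"] = mask.name
    return CVPACImage(image.pixels[rows].copy(), grid, image.label, prov)


def save_images(path, images: Sequence[CVPACImage]) -> None:
    """Write a set of comodulograms to a self-describing NPZ container."""
    images = list(images)
    if not images:
        raise ValueError("nothing to save")
    grid = images[0].grid
    np.savez_compressed(
        path,
        real=np.stack([im.pixels.real for im in images]),
        imag=np.stack([im.pixels.imag for im in images]),
        low_edges=grid.low_edges,
        high_edges=grid.high_edges,
        n_bins=grid.n_bins,
        labels=np.array([im.label or "" for im in images]),
        provenance=np.array([json.dumps(im.provenance) for im in images]),
    )


def load_images(path) -> list[CVPACImage]:
    with np.load(path, allow_pickle=False) as z:
        grid = FrequencyGrid(z["low_edges"], z["high_edges"], int(z["n_bins"]))
        out = []
        for re, im, lab, prov in zip(
            z["real"], z["imag"], z["labels"], z["provenance"]
        ):
            out.append(
                CVPACImage(
                    re + 1j * im,
                    grid,
                    label=str(lab) or None,
                    provenance=json.loads(str(prov)),
                )
            )
    return out
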