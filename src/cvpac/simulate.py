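"""Synthetic coupled-signal and labeled-dataset generation.

Stands in for patient SEEG: a low-frequency oscillation (1-10 Hz) whose
phase modulates the amplitude envelope of a high-frequency oscillation
(30-160 Hz), plus additive noise.  The per-component model is Tort-style
sinusoidal amplitude modulation locked to the low-frequency phase:

    x(t) = sum_c [ cos(2 pi f_low t + phi0)
                   + (1 - d + d * (1 + cos(2 pi f_low t + phi0 - psi)) / 2)
                     * sin(2 pi f_high t) ]  + noise(t)

where d in [0, 1] is the modulation depth and psi the coupled phase: the
high-frequency envelope peaks when the low-frequency phase equals psi.
d = 0 gives no coupling; d = 1 silences the carrier at the anti-phase.
The slow carrier is a cosine so that its wavelet-extracted instantaneous
phase equals the phase argument of the envelope; the recovered coupled
phase then matches psi directly.

Two labelled classes ("pathological" / "normal") are defined by per-band
circular-Gaussian phase distributions and per-band depth distributions over
the four low bands, emulating coupling patterns whose phases are separable
in the slow-delta, fast-delta and alpha bands, overlap in theta, and whose
theta coupling is stronger in the pathological class.  Dataset images are
always produced by running the CV-PAC pipeline on simulated windows, never
by drawing pixels directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .io import NORMAL, PATHOLOGICAL, Recording, Window, window_from_samples

__all__ = [
    "CouplingComponent",
    "CouplingProfile",
    "ClassSpec",
    "default_class_specs",
    "phase_only_class_specs",
    "generate_coupled_signal",
    "generate_labeled_dataset",
    "generate_patient_recording",
    "synthetic_cohort",
    "EXAMPLE_COHORT_SEIZURES",
    "PAPER_IMBALANCE",
]

#: Seizure durations (s) of the nine-patient example cohort (23 seizures).
EXAMPLE_COHORT_SEIZURES: dict[str, list[float]] = {
    "P1": [66, 61, 48],
    "P2": [74, 76, 77],
    "P3": [75, 84],
    "P4": [42, 64, 120],
    "P5": [65, 97, 67],
    "P6": [71],
    "P7": [44, 54, 55],
    "P8": [59, 60, 82],
    "P9": [76, 80],
}

#: pathological : normal window-count ratio of the motivating clinical
#: dataset (10,289 : 28,462), offered as an optional class imbalance.
PAPER_IMBALANCE = 10289 / 28462


@dataclass(frozen=True)
class CouplingComponent:
    """One (f_low, f_high) coupled pair.

    ``strength`` is the modulation depth d in [0, 1] of the amplitude
    envelope (the measured modulation index grows monotonically with it but
    is not numerically equal; see the calibration helper).
    """

    f_low: float
    f_high: float
    strength: float
    phase: float

    def __post_init__(self) -> None:
        if not 1.0 <= self.f_low <= 10.0:
            raise ValueError(f"f_low {self.f_low} outside [1, 10] Hz")
        if not 30.0 <= self.f_high <= 160.0:
            raise ValueError(f"f_high {self.f_high} outside [30, 160] Hz")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength (modulation depth) must be in [0, 1]")


@dataclass(frozen=True)
class CouplingProfile:
    """Full description of one synthetic window."""

    components: tuple[CouplingComponent, ...]
    noise_sd: float = 0.3
    duration_s: float = 10.0
    rate: float = 1000.0
    context_s: float = 2.0
    noise_color: str = "white"  # or "pink"

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        for comp in self.components:
            if self.rate <= 2 * comp.f_high:
                raise ValueError(
                    f"rate {self.rate} Hz violates Nyquist for {comp.f_high} Hz"
                )
        if self.noise_color not in ("white", "pink"):
            raise ValueError(f"unknown noise colour {self.noise_color!r}")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def generate_coupled_signal(
    profile: CouplingProfile,
    seed: int | np.random.Generator | None = None,
    channel_label: str = "synthetic",
    label: str | None = None,
    source_patient: str = "",
) -> Window:
    """Synthesize one window of phase-amplitude-coupled signal.

    The window is generated with ``context_s`` extra seconds on each side
    (marked as context, so the CV-PAC transform trims them after the CWT).
    The low-frequency oscillation of each component starts at a random
    initial phase; the coupled phase offset is exact by construction.
    """
    rng = np.random.default_rng(seed)
    n = int(round((profile.duration_s + 2 * profile.context_s) * profile.rate))
    t = np.arange(n) / profile.rate
    x = np.zeros(n)
    for comp in profile.components:
        phi0 = rng.uniform(-np.pi, np.pi)
        lf_phase = 2 * np.pi * comp.f_low * t + phi0
        d = comp.strength
        envelope = 1 - d + d * (1 + np.cos(lf_phase - comp.phase)) / 2
        x += np.cos(lf_phase) + envelope * np.sin(
            2 * np.pi * comp.f_high * t + rng.uniform(-np.pi, np.pi)
        )
    if profile.noise_sd > 0:
        noise = (
            _pink_noise(rng, n)
            if profile.noise_color == "pink"
            else rng.standard_normal(n)
        )
        x += profile.noise_sd * noise
    return window_from_samples(
        x,
        profile.rate,
        channel_label=channel_label,
        label=label,
        source_patient=source_patient,
        context_s=profile.context_s,
    )


# ---------------------------------------------------------------------------
# labelled classes
# ---------------------------------------------------------------------------

LOW_BANDS = ("slow_delta", "fast_delta", "theta", "alpha")


@dataclass(frozen=True)
class ClassSpec:
    """Per-band coupling statistics of one class.

    ``band_phase`` maps each low band to (circular mean, concentration
    kappa) of the coupled phase; ``band_strength`` maps each low band to
    (mean, sd) of the modulation depth (samples truncated to [0, 1]).
    """

    name: str
    band_phase: dict[str, tuple[float, float]]
    band_strength: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for band in LOW_BANDS:
            if band not in self.band_phase or band not in self.band_strength:
                raise ValueError(f"class {self.name!r} missing band {band!r}")
        for mu, _ in self.band_phase.values():
            if not -np.pi <= mu < np.pi:
                raise ValueError("phase means must lie in [-pi, pi)")


def default_class_specs() -> tuple[ClassSpec, ClassSpec]:
    """Qualitative two-class defaults.

    Phases are separable between classes in slow delta, fast delta and
    alpha; theta phases overlap but the pathological theta coupling is
    deeper.  The numbers are package choices emulating that qualitative
    pattern, not measurements.
    """
    kappa = 8.0
    pathological = ClassSpec(
        name=PATHOLOGICAL,
        band_phase={
            "slow_delta": (-2.0, kappa),
            "fast_delta": (2.5, kappa),
            "theta": (0.5, kappa),
            "alpha": (-1.0, kappa),
        },
        band_strength={
            "slow_delta": (0.6, 0.1),
            "fast_delta": (0.6, 0.1),
            "theta": (0.7, 0.1),
            "alpha": (0.6, 0.1),
        },
    )
    normal = ClassSpec(
        name=NORMAL,
        band_phase={
            "slow_delta": (0.8, kappa),
            "fast_delta": (-0.6, kappa),
            "theta": (0.5, kappa),
            "alpha": (1.5, kappa),
        },
        band_strength={
            "slow_delta": (0.6, 0.1),
            "fast_delta": (0.6, 0.1),
            "theta": (0.4, 0.1),
            "alpha": (0.6, 0.1),
        },
    )
    return pathological, normal


def phase_only_class_specs(kappa: float = 8.0) -> tuple[ClassSpec, ClassSpec]:
    """Two classes with identical strength statistics that differ only in
    their per-band coupled phases.

    Any classifier restricted to coupling strength sees exchangeable
    inputs; only the phase (hence the complex image) separates the classes.
    """
    strength = {band: (0.6, 0.1) for band in LOW_BANDS}
    pathological = ClassSpec(
        name=PATHOLOGICAL,
        band_phase={
            "slow_delta": (-2.0, kappa),
            "fast_delta": (2.5, kappa),
            "theta": (-0.5, kappa),
            "alpha": (-1.0, kappa),
        },
        band_strength=dict(strength),
    )
    normal = ClassSpec(
        name=NORMAL,
        band_phase={
            "slow_delta": (0.8, kappa),
            "fast_delta": (-0.6, kappa),
            "theta": (2.0, kappa),
            "alpha": (1.5, kappa),
        },
        band_strength=dict(strength),
    )
    return pathological, normal


def _band_center_range(band: str) -> tuple[float, float]:
    _, lo, hi = core.BAND_RANGES[band]
    return lo, hi


def _draw_profile(
    spec: ClassSpec,
    rng: np.random.Generator,
    bands: tuple[str, ...] = LOW_BANDS,
    noise_sd: float = 0.3,
    rate: float = 1000.0,
    duration_s: float = 10.0,
) -> CouplingProfile:
    comps = []
    for band in bands:
        lo, hi = _band_center_range(band)
        f_low = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        f_high = float(np.exp(rng.uniform(np.log(30.0), np.log(160.0))))
        mu, kappa = spec.band_phase[band]
        phase = float(rng.vonmises(mu, kappa))
        mean_d, sd_d = spec.band_strength[band]
        depth = float(np.clip(rng.normal(mean_d, sd_d), 0.0, 1.0))
        comps.append(CouplingComponent(f_low, f_high, depth, phase))
    return CouplingProfile(
        components=tuple(comps),
        noise_sd=noise_sd,
        duration_s=duration_s,
        rate=rate,
    )


def generate_labeled_dataset(
    specs: tuple[ClassSpec, ClassSpec] | None = None,
    n_per_class: int = 100,
    channels_per_class: int = 5,
    seed: int | np.random.Generator | None = None,
    grid: core.FrequencyGrid | None = None,
    noise_sd: float = 0.3,
    rate: float = 1000.0,
    imbalance: float | None = None,
    patient: str = "S1",
    return_windows: bool = False,
):
    """Generate labelled CV-PAC images by simulating windows and running the
    CV-PAC pipeline on them.

    Windows are assigned round-robin to ``channels_per_class`` synthetic
    channels per class so channel-level evaluation is exercised.  With
    ``imbalance`` = r, the first class keeps ``round(r * n_per_class)``
    windows (e.g. r ~ 0.36 reproduces a ~1:2.77 pathological:normal ratio).

    Returns a list of CVPACImage (and the windows too when
    ``return_windows``); each image's provenance records its channel and
    patient.
    """
    specs = specs or default_class_specs()
    grid = grid or core.FrequencyGrid.default()
    rng = np.random.default_rng(seed)
    images, windows = [], []
    for ci, spec in enumerate(specs):
        n = n_per_class if imbalance is None or ci != 0 else int(
            round(imbalance * n_per_class)
        )
        for k in range(n):
            profile = _draw_profile(spec, rng, noise_sd=noise_sd, rate=rate)
            chan = f"{spec.name[:4]}{k % channels_per_class}"
            win = generate_coupled_signal(
                profile,
                rng,
                channel_label=chan,
                label=spec.name,
                source_patient=patient,
            )
            windows.append(win)
            images.append(core.compute_cvpac(win, grid))
    if return_windows:
        return images, windows
    return images


def generate_patient_recording(
    patient: str,
    seizure_durations_s: list[float],
    specs: tuple[ClassSpec, ClassSpec] | None = None,
    channels_per_class: int = 2,
    seed: int | np.random.Generator | None = None,
    rate: float = 1000.0,
    noise_sd: float = 0.3,
    gap_s: float = 5.0,
) -> Recording:
    """Build one synthetic patient: a continuous multichannel recording with
    one seizure annotation per requested duration.

    Channels labelled ``PATHn-R`` carry pathological-class coupling and are
    marked resected; ``NORMn-R`` channels carry normal-class coupling.
    Within each seizure a channel's coupling parameters are redrawn from its
    class spec every ~10 s so successive windows vary.
    """
    specs = specs or default_class_specs()
    rng = np.random.default_rng(seed)
    total = sum(seizure_durations_s) + gap_s * (len(seizure_durations_s) + 1)
    n_total = int(round(total * rate))
    labels, resected, chans = [], [], []
    for spec, prefix in zip(specs, ("PATH", "NORM")):
        for k in range(channels_per_class):
            labels.append(f"{prefix}{k}-R")
            resected.append(spec.name == PATHOLOGICAL)
            chans.append(spec)
    samples = noise_sd * rng.standard_normal((len(labels), n_total))
    annotations = []
    cursor = gap_s
    for dur in seizure_durations_s:
        onset, term = cursor, cursor + dur
        annotations.append((onset, term))
        for ch, spec in enumerate(chans):
            t0 = onset
            while t0 < term:
                seg = min(10.0, term - t0)
                profile = _draw_profile(
                    spec, rng, noise_sd=0.0, rate=rate, duration_s=seg
                )
                i0 = int(round(t0 * rate))
                n = int(round(seg * rate))
                t = (np.arange(n) + i0) / rate
                for comp in profile.components:
                    phi0 = rng.uniform(-np.pi, np.pi)
                    lf = 2 * np.pi * comp.f_low * t + phi0
                    env = 1 - comp.strength + comp.strength * (
                        1 + np.cos(lf - comp.phase)
                    ) / 2
                    samples[ch, i0 : i0 + n] += np.cos(lf) + env * np.sin(
                        2 * np.pi * comp.f_high * t + rng.uniform(-np.pi, np.pi)
                    )
                t0 += seg
        cursor = term + gap_s
    return Recording(
        samples=samples,
        rate=rate,
        channel_labels=labels,
        annotations=annotations,
        resected=np.array(resected, bool),
        patient=patient,
    )


def synthetic_cohort(
    seizures: dict[str, list[float]] | None = None,
    specs: tuple[ClassSpec, ClassSpec] | None = None,
    channels_per_class: int = 2,
    seed: int = 0,
    rate: float = 1000.0,
) -> list[Recording]:
    """A multi-patient cohort (defaults to the nine-patient example layout)."""
    seizures = seizures or EXAMPLE_COHORT_SEIZURES
    seeds = np.random.SeedSequence(seed).spawn(len(seizures))
    return [
        generate_patient_recording(
            patient,
            durations,
            specs=specs,
            channels_per_class=channels_per_class,
            seed=np.random.default_rng(ss),
            rate=rate,
        )
        for ss, (patient, durations) in zip(seeds, sorted(seizures.items()))
    ]
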