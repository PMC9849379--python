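"""Reading intracranial EEG recordings and cutting analysis windows.

Two on-disk formats are supported: EDF (European Data Format, read through
:mod:`mne`) and delimited numeric text (CSV/TSV, one column per channel,
header row = channel labels).  Metadata that neither format carries —
sampling rate for text files, seizure marks, the bipolar derivation scheme,
excluded (artifact) channels and the resected channels that provide the
ground-truth labels — lives in a YAML sidecar next to the recording.

The analysis operates on a bipolar montage (differences of adjacent
electrode contacts, removing the common reference) and on 10 s windows slid
over each annotated seizure with a 2 s step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Recording",
    "Window",
    "load_recording",
    "load_sidecar",
    "to_bipolar",
    "sliding_windows",
    "window_from_samples",
    "write_delimited",
    "write_edf",
    "write_sidecar",
]

PATHOLOGICAL = "pathological"
NORMAL = "normal"


@dataclass
class Recording:
    """A multichannel recording with labels and seizure annotations.

    ``samples`` has shape (n_channels, n_samples); ``annotations`` is a list
    of (onset_seconds, termination_seconds) seizure marks; ``resected`` and
    ``excluded`` are per-channel booleans (surgical ground truth and
    artifact-channel exclusions).
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str]
    annotations: list[tuple[float, float]] = field(default_factory=list)
    resected: np.ndarray | None = None
    excluded: np.ndarray | None = None
    patient: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        n_ch = self.samples.shape[0]
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != n_ch:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        if self.resected is None:
            self.resected = np.zeros(n_ch, bool)
        if self.excluded is None:
            self.excluded = np.zeros(n_ch, bool)
        self.resected = np.asarray(self.resected, bool)
        self.excluded = np.asarray(self.excluded, bool)
        if self.resected.shape != (n_ch,) or self.excluded.shape != (n_ch,):
            raise ValueError("resected/excluded must be per-channel booleans")
        dur = self.duration_seconds
        cleaned = []
        for onset, term in self.annotations:
            if not onset < term:
                raise ValueError(f"annotation onset {onset} !< termination {term}")
            if onset < 0 or term > dur + 1e-9:
                raise ValueError(f"annotation ({onset}, {term}) outside the record")
            cleaned.append((float(onset), float(term)))
        self.annotations = cleaned

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_seconds(self) -> float:
        return self.samples.shape[1] / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None


@dataclass
class Window:
    """One analysis segment of one channel.

    ``samples`` is the core segment (``duration_seconds * rate`` samples);
    ``context_before``/``context_after`` hold flanking recorded samples used
    only to control wavelet edge effects.
    """

    channel_label: str
    start_seconds: float
    duration_seconds: float
    rate: float
    samples: np.ndarray
    label: str | None = None
    source_patient: str = ""
    context_before: np.ndarray | None = None
    context_after: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        expect = int(round(self.duration_seconds * self.rate))
        if self.samples.size != expect:
            raise ValueError(
                f"window of {self.duration_seconds} s at {self.rate} Hz needs "
                f"{expect} samples, got {self.samples.size}"
            )
        if self.label is not None and self.label not in (PATHOLOGICAL, NORMAL):
            raise ValueError(f"label must be pathological/normal, got {self.label!r}")

    def provenance(self) -> dict:
        return {
            "channel": self.channel_label,
            "patient": self.source_patient,
            "start_s": self.start_seconds,
            "duration_s": self.duration_seconds,
        }


def window_from_samples(
    samples: np.ndarray,
    rate: float,
    channel_label: str = "synthetic",
    label: str | None = None,
    start_seconds: float = 0.0,
    source_patient: str = "",
    context_s: float = 0.0,
) -> Window:
    """Wrap a bare series as a Window; optionally treat its first/last
    ``context_s`` seconds as edge-effect context rather than core samples."""
    samples = np.asarray(samples, float)
    n_ctx = int(round(context_s * rate))
    before = samples[:n_ctx] if n_ctx else None
    after = samples[samples.size - n_ctx :] if n_ctx else None
    core = samples[n_ctx : samples.size - n_ctx] if n_ctx else samples
    return Window(
        channel_label=channel_label,
        start_seconds=start_seconds,
        duration_seconds=core.size / rate,
        rate=rate,
        samples=core,
        label=label,
        source_patient=source_patient,
        context_before=before,
        context_after=after,
    )


# ---------------------------------------------------------------------------
# sidecar configuration
# ---------------------------------------------------------------------------

def load_sidecar(path) -> dict:
    """Read the YAML sidecar (rate, seizures, resected, excluded, pairs)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"sidecar {path} must be a mapping")
    return cfg


def write_sidecar(path, **entries) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def _apply_sidecar(rec: Recording, cfg: dict) -> Recording:
    labels = rec.channel_labels
    def flags(names):
        out = np.zeros(len(labels), bool)
        for name in names or []:
            out[rec.channel_index(str(name))] = True
        return out

    if "resected" in cfg:
        rec.resected = flags(cfg["resected"])
    if "excluded" in cfg:
        rec.excluded = flags(cfg["excluded"])
    if "seizures" in cfg:
        rec.annotations = [(float(a), float(b)) for a, b in cfg["seizures"]]
        rec.__post_init__()
    if "patient" in cfg:
        rec.patient = str(cfg["patient"])
    return rec


def _sidecar_for(path: Path) -> Path | None:
    for suffix in (".yaml", ".yml"):
        cand = path.with_suffix(suffix)
        if cand.exists():
            return cand
    return None


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_recording(path, format: str | None = None, config=None) -> Recording:
    """Load a recording from EDF or delimited text.

    ``format`` is inferred from the extension when omitted.  ``config`` is a
    sidecar YAML path or an already-parsed mapping; when omitted, a sidecar
    file next to the recording (same stem, ``.yaml``/``.yml``) is used if
    present.  Delimited files require the sidecar to state the sampling
    rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if config is None:
        side = _sidecar_for(path)
        cfg = load_sidecar(side) if side else {}
    elif isinstance(config, dict):
        cfg = config
    else:
        cfg = load_sidecar(config)

    if format == "edf":
        rec = _read_edf(path)
    elif format == "delimited":
        rec = _read_delimited(path, cfg)
    else:
        raise ValueError(f"unknown format {format!r}")
    return _apply_sidecar(rec, cfg)


def _read_delimited(path: Path, cfg: dict) -> Recording:
    sep = {".tsv": "\t", ".txt": None}.get(path.suffix.lower(), ",")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.isna().any().any():
        raise ValueError(f"{path}: channels have inconsistent lengths")
    rate = cfg.get("rate")
    if rate is None:
        raise ValueError(f"{path}: sampling rate missing (set 'rate' in the sidecar)")
    return Recording(
        samples=df.to_numpy(float).T,
        rate=float(rate),
        channel_labels=[str(c) for c in df.columns],
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires the optional dependency mne "
            "(pip install cvpac[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return Recording(
        samples=data,
        rate=float(raw.info["sfreq"]),
        channel_labels=[str(ch) for ch in raw.ch_names],
    )


# ---------------------------------------------------------------------------
# writing (fixtures, simulator output)
# ---------------------------------------------------------------------------

def write_delimited(path, rec: Recording, sep: str = ",") -> None:
    pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(
        path, sep=sep, index=False
    )


def write_edf(path, rec: Recording) -> None:
    """Write a 16-bit EDF file (amplitudes interpreted as microvolts).

    A deliberately small writer covering the subset of EDF this package
    needs for fixtures and simulator output: one data record per second,
    integer sampling rate, continuous recording.
    """
    if rate_frac := (rec.rate % 1):
        raise ValueError(f"EDF writer needs an integer rate, got {rec.rate}")
    rate = int(rec.rate)
    n_ch = rec.n_channels
    n_samp = rec.samples.shape[1]
    if n_samp % rate:
        raise ValueError("EDF writer needs a whole number of 1 s records")
    n_rec = n_samp // rate

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"field {text!r} exceeds {width} bytes")
        return b.ljust(width)

    phys_min, phys_max = [], []
    digital = np.empty((n_ch, n_samp), "<i2")
    for i, ch in enumerate(rec.samples):
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        digital[i] = np.round(
            (ch - lo) / (hi - lo) * 65535 - 32768
        ).astype("<i2")

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (1 + n_ch)), 8),
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),
            f(str(n_ch), 4),
        ]
    )
    sig = b"".join(f(lbl[:16], 16) for lbl in rec.channel_labels)
    sig += b"".join(f("", 80) for _ in range(n_ch))
    sig += b"".join(f("uV", 8) for _ in range(n_ch))
    sig += b"".join(f(f"{v:.6g}"[:8], 8) for v in phys_min)
    sig += b"".join(f(f"{v:.6g}"[:8], 8) for v in phys_max)
    sig += b"".join(f("-32768", 8) for _ in range(n_ch))
    sig += b"".join(f("32767", 8) for _ in range(n_ch))
    sig += b"".join(f("", 80) for _ in range(n_ch))
    sig += b"".join(f(str(rate), 8) for _ in range(n_ch))
    sig += b"".join(f("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * rate : (r + 1) * rate].tobytes())


# ---------------------------------------------------------------------------
# montage and windowing
# ---------------------------------------------------------------------------

def to_bipolar(
    rec: Recording,
    pairs: Sequence[tuple[str, str]],
    resection_rule: str = "any",
) -> Recording:
    """Derive a bipolar montage: channel "anode-cathode" = anode - cathode.

    A bipolar channel is labelled resected when *either* contact lies in the
    resection (``resection_rule="any"``, the default) or only when *both* do
    (``"both"``).  Pairs referencing excluded channels are rejected.
    """
    if resection_rule not in ("any", "both"):
        raise ValueError(f"unknown resection_rule {resection_rule!r}")
    samples, labels, resected = [], [], []
    for anode, cathode in pairs:
        ia, ic = rec.channel_index(anode), rec.channel_index(cathode)
        for idx, name in ((ia, anode), (ic, cathode)):
            if rec.excluded[idx]:
                raise ValueError(f"pair references excluded channel {name!r}")
        samples.append(rec.samples[ia] - rec.samples[ic])
        labels.append(f"{anode}-{cathode}")
        if resection_rule == "any":
            resected.append(rec.resected[ia] or rec.resected[ic])
        else:
            resected.append(rec.resected[ia] and rec.resected[ic])
    return Recording(
        samples=np.array(samples) if samples else np.empty((0, rec.samples.shape[1])),
        rate=rec.rate,
        channel_labels=labels,
        annotations=list(rec.annotations),
        resected=np.array(resected, bool),
        excluded=np.zeros(len(labels), bool),
        patient=rec.patient,
    )


def sliding_windows(
    rec: Recording,
    window_s: float = 10.0,
    step_s: float = 2.0,
    within: str = "seizure_annotations",
    context_s: float = 2.0,
    on_short: str = "error",
) -> list[Window]:
    """Cut overlapping analysis windows from every non-excluded channel.

    Windows start at onset, onset + step, ... while start + window_s fits
    inside the annotated span (``within="seizure_annotations"``) or the
    whole record (``within="whole_record"``), yielding
    floor((span - window_s) / step_s) + 1 windows per span per channel.
    Each window carries up to ``context_s`` seconds of recorded context on
    either side for edge-effect control, and the pathological/normal label
    of its channel.  Spans shorter than one window raise an error
    (``on_short="error"``) or are skipped (``"skip"``).
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    if within == "seizure_annotations":
        spans = rec.annotations
        if not spans:
            raise ValueError("recording has no seizure annotations")
    elif within == "whole_record":
        spans = [(0.0, rec.duration_seconds)]
    else:
        raise ValueError(f"unknown 'within' mode {within!r}")

    n_win = int(round(window_s * rec.rate))
    n_ctx = int(round(context_s * rec.rate))
    n_total = rec.samples.shape[1]
    out: list[Window] = []
    for onset, term in spans:
        if term - onset < window_s - 1e-9:
            if on_short == "skip":
                continue
            raise ValueError(
                f"span ({onset}, {term}) shorter than one {window_s} s window"
            )
        n_steps = int(np.floor((term - onset - window_s) / step_s + 1e-9)) + 1
        for ch in range(rec.n_channels):
            if rec.excluded[ch]:
                continue
            label = PATHOLOGICAL if rec.resected[ch] else NORMAL
            for k in range(n_steps):
                start = onset + k * step_s
                i0 = int(round(start * rec.rate))
                i1 = i0 + n_win
                out.append(
                    Window(
                        channel_label=rec.channel_labels[ch],
                        start_seconds=start,
                        duration_seconds=window_s,
                        rate=rec.rate,
                        samples=rec.samples[ch, i0:i1],
                        label=label,
                        source_patient=rec.patient,
                        context_before=rec.samples[ch, max(i0 - n_ctx, 0) : i0],
                        context_after=rec.samples[ch, i1 : min(i1 + n_ctx, n_total)],
                    )
                )
    return out
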