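"""Recording I/O, seizure/control segment extraction, and fixed preprocessing.

The unit of analysis is a :class:`Segment`: the annotated seizure interval
plus a margin of 30% of the seizure length on each side, or a control
window of identical duration taken at least five minutes away from any
seizure.  Preprocessing is a fixed chain — resample to 256 Hz, 1 Hz
high-pass, artifact correction, average re-reference, 40 Hz low-pass —
applied identically to seizure and control segments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from ._edf import write_edf

VIGILANCE_LEVELS = ("Awake", "NREM1", "NREM2", "NREM3", "REM", "unknown")
CLASSIFICATION_LEVELS = ("FAS", "FIAS", "FBTCS", "UC")

TARGET_FS = 256.0
HP_CUTOFF_HZ = 1.0
LP_CUTOFF_HZ = 40.0


class InsufficientControlData(RuntimeError):
    """No control window of the required duration is admissible."""


@dataclass
class SeizureAnnotation:
    seizure_id: str
    patient_id: str
    onset_s: float
    offset_s: float
    vigilance: str = "unknown"
    classification: str = "UC"

    def __post_init__(self):
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"seizure {self.seizure_id}: offset {self.offset_s} <= onset {self.onset_s}"
            )
        if self.vigilance not in VIGILANCE_LEVELS:
            raise ValueError(f"unknown vigilance stage {self.vigilance!r}")
        if self.classification not in CLASSIFICATION_LEVELS:
            raise ValueError(f"unknown seizure classification {self.classification!r}")

    @property
    def length_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class Recording:
    """Multichannel EEG in µV with its sampling rate and seizure annotations."""

    data: np.ndarray  # channels x samples
    fs: float
    channel_names: list[str]
    annotations: list[SeizureAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channel_names)} channel names"
            )
        dur = self.duration_s
        for ann in self.annotations:
            if ann.onset_s < 0 or ann.offset_s > dur:
                raise ValueError(
                    f"annotation {ann.seizure_id} [{ann.onset_s}, {ann.offset_s}) "
                    f"outside recording of {dur:.1f} s"
                )

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class Segment:
    """A cut of a recording; ``core_interval`` marks the annotated event.

    Times are seconds, 0-based from recording start; intervals half-open.
    """

    data: np.ndarray
    fs: float
    t0_s: float
    core_interval: tuple[float, float]
    role: str  # "seizure" | "control"
    channel_names: list[str] = field(default_factory=list)
    annotation: SeizureAnnotation | None = None
    clipped: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        a, b = self.core_interval
        end = self.t0_s + self.data.shape[1] / self.fs
        if not (self.t0_s - 1e-9 <= a < b <= end + 1e-9):
            raise ValueError(f"core interval {self.core_interval} outside segment")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


def _read_annotation_csv(path) -> list[SeizureAnnotation]:
    df = pd.read_csv(path)
    required = {"patient_id", "seizure_id", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV {path} lacks columns {sorted(missing)}")
    anns = []
    for row in df.itertuples(index=False):
        anns.append(
            SeizureAnnotation(
                seizure_id=str(row.seizure_id),
                patient_id=str(row.patient_id),
                onset_s=float(row.onset_s),
                offset_s=float(row.offset_s),
                vigilance=str(getattr(row, "vigilance", "unknown")),
                classification=str(getattr(row, "classification", "UC")),
            )
        )
    return anns


def load_recording(path, format: str | None = None, annotations=None) -> Recording:
    """Read an EDF (via MNE) or ``.npz`` raw-array file into a :class:`Recording`.

    Parameters
    ----------
    path
        EDF file (16-bit, standard header) or the package raw format: an
        ``.npz`` with ``data`` (channels x samples, µV), ``fs`` and
        ``channel_names`` arrays.
    format
        "edf" or "npz"; inferred from the suffix when None.
    annotations
        Optional CSV sidecar (patient_id, seizure_id, onset_s, offset_s,
        vigilance, classification).  For EDF input, embedded EDF+
        annotations whose description parses as ``seizure <id>`` are also
        picked up.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    anns: list[SeizureAnnotation] = []
    if fmt == "edf":
        import mne

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        except Exception as exc:  # surface a descriptive failure
            raise IOError(f"could not parse {path} as EDF: {exc}") from exc
        data = raw.get_data() * 1e6  # MNE returns Volts
        fs = float(raw.info["sfreq"])
        names = list(raw.ch_names)
        for onset, dur, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        ):
            parts = str(desc).split()
            if parts and parts[0].lower() == "seizure":
                sid = parts[1] if len(parts) > 1 else f"sz{len(anns)}"
                anns.append(
                    SeizureAnnotation(sid, "unknown", float(onset), float(onset + dur))
                )
    elif fmt == "npz":
        with np.load(path, allow_pickle=False) as npz:
            for key in ("data", "fs", "channel_names"):
                if key not in npz:
                    raise IOError(f"{path} lacks required array {key!r}")
            data = np.asarray(npz["data"], dtype=float)
            fs = float(npz["fs"])
            names = [str(c) for c in npz["channel_names"]]
    else:
        raise ValueError(f"unsupported recording format {fmt!r}")
    if annotations is not None:
        anns = _read_annotation_csv(annotations)
    return Recording(data=data, fs=fs, channel_names=names, annotations=anns)


def save_recording(recording: Recording, path, annotations_csv=None) -> None:
    """Write a Recording as EDF (``.edf``) or the npz raw format."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_edf(path, recording.data, recording.fs, recording.channel_names)
    else:
        np.savez_compressed(
            path,
            data=recording.data,
            fs=recording.fs,
            channel_names=np.array(recording.channel_names),
        )
    if annotations_csv is not None and recording.annotations:
        pd.DataFrame(
            [
                {
                    "patient_id": a.patient_id,
                    "seizure_id": a.seizure_id,
                    "onset_s": a.onset_s,
                    "offset_s": a.offset_s,
                    "vigilance": a.vigilance,
                    "classification": a.classification,
                }
                for a in recording.annotations
            ]
        ).to_csv(annotations_csv, index=False)


def _cut(recording: Recording, start_s: float, end_s: float) -> tuple[np.ndarray, float, float]:
    i0 = int(round(start_s * recording.fs))
    i1 = int(round(end_s * recording.fs))
    return recording.data[:, i0:i1], i0 / recording.fs, i1 / recording.fs


def extract_segments(
    recording: Recording,
    annotation: SeizureAnnotation,
    margin_frac: float = 0.30,
    control_gap_s: float = 300.0,
) -> tuple[Segment, Segment]:
    """Cut the seizure segment (with margins) and an equal-length control.

    The seizure segment spans ``[onset - m*L, offset + m*L)`` with ``L`` the
    seizure length, clipped to the recording bounds (clipping flagged).  The
    control is the earliest window of identical duration whose every sample
    is at least ``control_gap_s`` away from any annotated seizure.

    Raises
    ------
    InsufficientControlData
        when no admissible control window exists; such seizures are
        excluded from analysis.
    """
    if margin_frac < 0:
        raise ValueError("margin_frac must be >= 0")
    L = annotation.length_s
    m = margin_frac * L
    want_start, want_end = annotation.onset_s - m, annotation.offset_s + m
    start = max(0.0, want_start)
    end = min(recording.duration_s, want_end)
    clipped = (start > want_start + 1e-9) or (end < want_end - 1e-9)
    data, t0, t1 = _cut(recording, start, end)
    seizure = Segment(
        data=data,
        fs=recording.fs,
        t0_s=t0,
        core_interval=(annotation.onset_s, annotation.offset_s),
        role="seizure",
        channel_names=list(recording.channel_names),
        annotation=annotation,
        clipped=clipped,
        provenance={"margin_frac": margin_frac, "requested": (want_start, want_end)},
    )

    dur = t1 - t0
    # forbidden zones: gap around every annotated seizure
    forbidden = sorted(
        (a.onset_s - control_gap_s, a.offset_s + control_gap_s)
        for a in recording.annotations
    ) or [(annotation.onset_s - control_gap_s, annotation.offset_s + control_gap_s)]
    merged: list[list[float]] = []
    for lo, hi in forbidden:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    # admissible gaps between forbidden zones, clipped to the recording
    candidates = []
    cursor = 0.0
    for lo, hi in merged:
        if lo > cursor:
            candidates.append((cursor, min(lo, recording.duration_s)))
        cursor = max(cursor, hi)
    if cursor < recording.duration_s:
        candidates.append((cursor, recording.duration_s))
    control_start = None
    for lo, hi in candidates:
        if hi - lo >= dur - 0.5 / recording.fs:
            control_start = lo
            break
    if control_start is None:
        raise InsufficientControlData(
            f"seizure {annotation.seizure_id}: no control window of {dur:.1f} s "
            f"at least {control_gap_s:.0f} s from seizure activity"
        )
    n = data.shape[1]
    c0 = int(round(control_start * recording.fs))
    cdata = recording.data[:, c0 : c0 + n]
    ct0 = c0 / recording.fs
    # control core mirrors the seizure's position inside its segment
    rel_on = annotation.onset_s - t0
    control = Segment(
        data=cdata,
        fs=recording.fs,
        t0_s=ct0,
        core_interval=(ct0 + rel_on, ct0 + rel_on + L),
        role="control",
        channel_names=list(recording.channel_names),
        annotation=annotation,
        provenance={"control_gap_s": control_gap_s},
    )
    return seizure, control


@dataclass
class PreprocessConfig:
    target_fs: float = TARGET_FS
    hp_hz: float = HP_CUTOFF_HZ
    lp_hz: float = LP_CUTOFF_HZ
    hp_transition_hz: float = 0.1
    lp_transition_hz: float = 0.5
    artifact_stage: str = "robust_clip"  # "robust_clip" | "none" | callable via `artifact_fn`
    clip_k: float = 20.0
    clip_window_s: float = 1.0
    artifact_fn: object | None = None


def _zero_phase_filter(data, fs, cutoff_hz, transition_hz, pass_zero):
    """Zero-phase filter by spectral multiplication with a raised-cosine
    transition straddling the cutoff.

    The near-rectangular response keeps passband content untouched, which
    makes the whole chain stable under repeated application (idempotent up
    to the transition bands and edge transients).
    """
    n = data.shape[-1]
    f = np.fft.rfftfreq(n, 1.0 / fs)
    lo = cutoff_hz - transition_hz / 2.0
    g = np.clip((f - lo) / transition_hz, 0.0, 1.0)
    g = 0.5 - 0.5 * np.cos(np.pi * g)  # 0 -> 1 across the transition
    if pass_zero:  # low-pass
        g = 1.0 - g
    return np.fft.irfft(np.fft.rfft(data, axis=-1) * g, n=n, axis=-1)


def robust_clip(data: np.ndarray, fs: float, k: float = 20.0, window_s: float = 1.0):
    """Shrink windows whose RMS exceeds ``k`` x the channel's median window RMS.

    A simple stand-in artifact-correction stage: gross transients (electrode
    pops, movement bursts) are attenuated to the threshold amplitude while
    ordinary data pass through untouched.  Returns (cleaned, n_clipped).
    """
    out = data.copy()
    w = max(int(round(window_s * fs)), 8)
    n = data.shape[1]
    n_win = max(n // w, 1)
    clipped = 0
    for ch in range(data.shape[0]):
        segs = out[ch, : n_win * w].reshape(n_win, w)
        rms = np.sqrt(np.mean(segs**2, axis=1))
        med = np.median(rms)
        if med <= 0:
            continue
        bad = rms > k * med
        if bad.any():
            segs[bad] *= (k * med / rms[bad])[:, None]
            clipped += int(bad.sum())
    return out, clipped


def preprocess(segment: Segment, cfg: PreprocessConfig | None = None) -> Segment:
    """Apply the fixed chain: resample -> 1 Hz HP -> artifact stage -> average
    re-reference -> 40 Hz LP.  Output sampling rate is 256 Hz.

    Refuses input below the target rate (no upsampling) or containing NaNs.
    """
    cfg = cfg or PreprocessConfig()
    if segment.fs < cfg.target_fs:
        raise ValueError(
            f"segment rate {segment.fs} Hz below target {cfg.target_fs} Hz; upsampling refused"
        )
    if not np.isfinite(segment.data).all():
        raise ValueError("segment contains non-finite samples")
    data = segment.data
    fs = segment.fs
    if fs != cfg.target_fs:
        frac = Fraction(cfg.target_fs / fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        fs = cfg.target_fs
    data = _zero_phase_filter(data, fs, cfg.hp_hz, cfg.hp_transition_hz, pass_zero=False)
    n_clipped = 0
    if cfg.artifact_fn is not None:
        data = cfg.artifact_fn(data, fs)
    elif cfg.artifact_stage == "robust_clip":
        data, n_clipped = robust_clip(data, fs, cfg.clip_k, cfg.clip_window_s)
    elif cfg.artifact_stage != "none":
        raise ValueError(f"unknown artifact stage {cfg.artifact_stage!r}")
    data = data - data.mean(axis=0, keepdims=True)
    data = _zero_phase_filter(data, fs, cfg.lp_hz, cfg.lp_transition_hz, pass_zero=True)
    prov = dict(segment.provenance)
    prov.update(
        {
            "preprocessed": True,
            "target_fs": fs,
            "hp_hz": cfg.hp_hz,
            "lp_hz": cfg.lp_hz,
            "artifact_stage": cfg.artifact_stage,
            "windows_clipped": n_clipped,
        }
    )
    return replace(segment, data=data, fs=fs, provenance=prov)


def save_segment(segment: Segment, path) -> None:
    """Serialize a Segment as compressed arrays + a JSON provenance sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        data=segment.data,
        fs=segment.fs,
        t0_s=segment.t0_s,
        core_interval=np.array(segment.core_interval),
        channel_names=np.array(segment.channel_names),
    )
    meta = {
        "role": segment.role,
        "clipped": segment.clipped,
        "provenance": segment.provenance,
    }
    if segment.annotation is not None:
        a = segment.annotation
        meta["annotation"] = {
            "seizure_id": a.seizure_id,
            "patient_id": a.patient_id,
            "onset_s": a.onset_s,
            "offset_s": a.offset_s,
            "vigilance": a.vigilance,
            "classification": a.classification,
        }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_segment(path) -> Segment:
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        data = np.asarray(npz["data"])
        fs = float(npz["fs"])
        t0 = float(npz["t0_s"])
        core = tuple(float(v) for v in npz["core_interval"])
        names = [str(c) for c in npz["channel_names"]]
    meta = json.loads(path.with_suffix(".json").read_text())
    ann = None
    if "annotation" in meta:
        ann = SeizureAnnotation(**meta["annotation"])
    return Segment(
        data=data,
        fs=fs,
        t0_s=t0,
        core_interval=core,
        role=meta["role"],
        channel_names=names,
        annotation=ann,
        clipped=meta.get("clipped", False),
        provenance=meta.get("provenance", {}),
    )
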