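"""Ground-truth seizure simulator: bifurcation-morphology sources, scalp
mixing with artifacts, and whole synthetic cohorts with injectable
clinical-factor effects.

The taxonomy of seizure dynamotypes ties each transition to a bifurcation
class with a characteristic amplitude or inter-spike-interval (ISI)
scaling law.  The simulator realizes these as square-root normal-form
laws:

* SupH onset — amplitude grows as ``peak * sqrt((t - t_on)/tau)`` from
  zero (mirrored shrinkage at a SupH offset);
* SNIC onset — ISI diverges toward onset, ``base * sqrt(tau/(t - t_on))``
  (mirrored for a SNIC/SH offset, frequency falling to zero);
* SN/SubH onset and FLC offset — no prescribed law: constant amplitude
  and ISI with small (<=2%) jitter.

Sources are spike trains (biphasic ~70 ms transients on a slow
oscillation) with the law-controlled envelope and spike times recorded as
ground truth.  Scalp mixing projects sources through focal topographies on
a 19-channel 10-20 montage and adds pink background noise, frontal eye
blinks and temporal muscle bursts.  Cohort generation samples per-patient
metadata and per-seizure covariates, with requested probability shifts
(e.g. "SupH more likely while awake") injected exactly and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_preprocess import Recording

ONSET_CATEGORIES = ("SN/SubH", "SNIC", "SupH")
OFFSET_CATEGORIES = ("FLC", "SNIC/SH", "SupH")

MONTAGE_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]
# schematic 2-D scalp coordinates (x: left-right, y: posterior-anterior)
_POS = {
    "Fp1": (-0.3, 1.0), "Fp2": (0.3, 1.0),
    "F7": (-0.8, 0.6), "F3": (-0.4, 0.55), "Fz": (0.0, 0.55),
    "F4": (0.4, 0.55), "F8": (0.8, 0.6),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.8, -0.6), "P3": (-0.4, -0.55), "Pz": (0.0, -0.55),
    "P4": (0.4, -0.55), "T6": (0.8, -0.6),
    "O1": (-0.3, -1.0), "O2": (0.3, -1.0),
}


@dataclass(frozen=True)
class BifurcationType:
    side: str  # "onset" | "offset"
    category: str

    def __post_init__(self):
        legal = ONSET_CATEGORIES if self.side == "onset" else OFFSET_CATEGORIES
        if self.side not in ("onset", "offset"):
            raise ValueError(f"side must be onset/offset, got {self.side!r}")
        if self.category not in legal:
            raise ValueError(f"{self.category!r} is not a legal {self.side} class")


@dataclass
class SeizureSimSpec:
    onset_type: BifurcationType
    offset_type: BifurcationType
    duration_s: float = 60.0
    base_isi_s: float = 0.25
    peak_amp: float = 1.0
    tau_s: float = 5.0  # scaling-law time constant, both sides
    snr_db: float = 10.0
    margin_frac: float = 0.30
    fs: float = 256.0
    seed: int = 0

    def __post_init__(self):
        if self.onset_type.side != "onset" or self.offset_type.side != "offset":
            raise ValueError("onset_type/offset_type sides are swapped")
        if not self.duration_s > 4 * self.tau_s:
            raise ValueError(
                f"duration {self.duration_s} s must exceed 4*tau = {4 * self.tau_s} s"
            )
        if self.base_isi_s <= 0 or not np.isfinite(self.snr_db):
            raise ValueError("base_isi_s must be positive and snr_db finite")


@dataclass
class SourceTrace:
    signal: np.ndarray  # 1-D
    fs: float
    true_onset_s: float
    true_offset_s: float
    spike_times_s: np.ndarray
    envelope: np.ndarray  # amplitude law sampled on the trace grid
    spec: SeizureSimSpec | None = None

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.fs


def amplitude_law(category: str, t_rel: np.ndarray, tau: float) -> np.ndarray:
    """Envelope factor at time ``t_rel`` from the transition (into the seizure)."""
    t = np.asarray(t_rel, dtype=float)
    if category == "SupH":
        return np.sqrt(np.clip(t, 0, tau) / tau)
    return np.ones_like(t)


def isi_law(category: str, t_rel: np.ndarray, base_isi: float, tau: float) -> np.ndarray:
    """ISI at time ``t_rel`` from the transition (into the seizure)."""
    t = np.asarray(t_rel, dtype=float)
    if category in ("SNIC", "SNIC/SH"):
        return base_isi * np.maximum(1.0, np.sqrt(tau / np.maximum(t, 1e-6)))
    return np.full_like(t, base_isi)


def _spike_waveform(fs: float) -> np.ndarray:
    """Biphasic sharp transient, ~70 ms support (difference of Gaussians)."""
    t = np.arange(-0.06, 0.09, 1 / fs)
    w = np.exp(-0.5 * (t / 0.010) ** 2) - 0.65 * np.exp(-0.5 * ((t - 0.028) / 0.020) ** 2)
    return w / np.abs(w).max()


def simulate_source(spec: SeizureSimSpec, seed: int | None = None) -> SourceTrace:
    """Simulate one seizure source following the spec's bifurcation classes.

    The trace spans the seizure plus ``margin_frac`` margins on each side;
    ground-truth onset/offset, spike times and envelope samples are
    returned alongside the signal.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fs = spec.fs
    margin = spec.margin_frac * spec.duration_s
    total = spec.duration_s + 2 * margin
    n = int(round(total * fs))
    t = np.arange(n) / fs
    t_on, t_off = margin, margin + spec.duration_s

    amp_jitter = spec.onset_type.category != "SupH" and spec.offset_type.category != "SupH"
    isi_jitter = (
        spec.onset_type.category != "SNIC" and spec.offset_type.category != "SNIC/SH"
    )

    def isi_at(time_s: float) -> float:
        on = isi_law(spec.onset_type.category, time_s - t_on, spec.base_isi_s, spec.tau_s)
        off = isi_law(spec.offset_type.category, t_off - time_s, spec.base_isi_s, spec.tau_s)
        return float(on * off / spec.base_isi_s)

    spike_times = []
    # first spike shortly after onset; for a diverging SNIC law this start
    # sets the largest initial ISI the trace exhibits
    cur = t_on + 0.02 * spec.tau_s
    while cur < t_off:
        spike_times.append(cur)
        step = isi_at(cur)
        if isi_jitter:
            step *= 1.0 + rng.uniform(-0.02, 0.02)
        cur += step
    spike_times = np.asarray(spike_times)

    def amp_at(times: np.ndarray) -> np.ndarray:
        on = amplitude_law(spec.onset_type.category, times - t_on, spec.tau_s)
        off = amplitude_law(spec.offset_type.category, t_off - times, spec.tau_s)
        return spec.peak_amp * on * off

    env = np.where((t >= t_on) & (t < t_off), amp_at(t), 0.0)

    sig = np.zeros(n)
    wave = _spike_waveform(fs)
    half = len(wave) // 2
    amps = amp_at(spike_times)
    if amp_jitter:
        amps = amps * (1.0 + rng.uniform(-0.02, 0.02, size=amps.size))
    for st, a in zip(spike_times, amps):
        i = int(round(st * fs)) - half
        j0, j1 = max(i, 0), min(i + len(wave), n)
        sig[j0:j1] += a * wave[j0 - i : j1 - i]
    # slow oscillation under the spikes, same envelope; random phase so
    # distinct sources are not mutually coherent
    phase = rng.uniform(0, 2 * np.pi)
    sig += 0.25 * env * np.sin(2 * np.pi * t / spec.base_isi_s + phase)

    return SourceTrace(
        signal=sig,
        fs=fs,
        true_onset_s=t_on,
        true_offset_s=t_off,
        spike_times_s=spike_times,
        envelope=env,
        spec=spec,
    )


@dataclass
class NoiseSpec:
    snr_db: float = 10.0
    blink_rate_hz: float = 0.2
    muscle_rate_hz: float = 0.1
    blink_amp: float = 3.0  # relative to projected source RMS
    muscle_amp: float = 1.5


def focal_topography(center: str, width: float = 0.6, channels=MONTAGE_1020) -> np.ndarray:
    """Smooth scalp weight map peaked at ``center``, unit maximum."""
    cx, cy = _POS[center]
    w = np.array(
        [np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2)) for x, y in
         (_POS[ch] for ch in channels)]
    )
    return w / np.abs(w).max()


def _pink_noise(rng, n_ch: int, n: int, exponent: float = 1.0) -> np.ndarray:
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n=n, axis=1)
    return out / out.std(axis=1, keepdims=True)


def _blink_topo(channels) -> np.ndarray:
    w = np.zeros(len(channels))
    gains = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.45, "F8": 0.45, "F3": 0.35, "F4": 0.35, "Fz": 0.3}
    for i, ch in enumerate(channels):
        w[i] = gains.get(ch, 0.02)
    return w


def _muscle_topo(channels, rng) -> np.ndarray:
    w = np.zeros(len(channels))
    side = (("T3", "T5", "F7"), ("T4", "T6", "F8"))[int(rng.integers(0, 2))]
    for i, ch in enumerate(channels):
        w[i] = 1.0 if ch in side else 0.05
    return w


def mix_to_scalp(
    sources: list[SourceTrace],
    topographies: np.ndarray,
    noise_spec: NoiseSpec | None = None,
    seed: int = 0,
    channels=MONTAGE_1020,
) -> tuple[Recording, dict]:
    """Project sources to the scalp and add pink noise, blinks and muscle.

    ``topographies`` is (n_sources x n_channels).  The background noise is
    scaled so the RMS ratio of the summed projected sources to the pink
    background matches ``snr_db``; the realized ratio is returned in the
    info dict together with artifact event times.
    """
    noise_spec = noise_spec or NoiseSpec()
    rng = np.random.default_rng(seed)
    topographies = np.atleast_2d(np.asarray(topographies, dtype=float))
    if topographies.shape[0] != len(sources):
        raise ValueError(
            f"{len(sources)} sources but {topographies.shape[0]} topographies"
        )
    if topographies.shape[1] != len(channels):
        raise ValueError(
            f"topography length {topographies.shape[1]} != {len(channels)} channels"
        )
    n = max(s.signal.size for s in sources)
    fs = sources[0].fs
    brain = np.zeros((len(channels), n))
    for src, topo in zip(sources, topographies):
        brain[:, : src.signal.size] += np.outer(topo, src.signal)

    sig_rms = np.sqrt(np.mean(brain**2))
    target_noise_rms = sig_rms / 10 ** (noise_spec.snr_db / 20.0)
    noise = _pink_noise(rng, len(channels), n) * target_noise_rms
    data = brain + noise

    t = np.arange(n) / fs
    blink_topo = _blink_topo(channels)
    n_blinks = rng.poisson(noise_spec.blink_rate_hz * n / fs)
    blink_times = np.sort(rng.uniform(0, n / fs - 0.5, size=n_blinks))
    for bt in blink_times:
        dur = rng.uniform(0.25, 0.4)
        i0 = int(bt * fs)
        i1 = min(i0 + int(dur * fs), n)
        shape = np.sin(np.pi * np.arange(i1 - i0) / (i1 - i0)) ** 2
        data[:, i0:i1] += np.outer(blink_topo, noise_spec.blink_amp * sig_rms * shape)

    n_bursts = rng.poisson(noise_spec.muscle_rate_hz * n / fs)
    muscle_times = np.sort(rng.uniform(0, n / fs - 1.5, size=n_bursts))
    for mt in muscle_times:
        mtopo = _muscle_topo(channels, rng)
        dur = rng.uniform(0.5, 1.5)
        i0 = int(mt * fs)
        i1 = min(i0 + int(dur * fs), n)
        burst = rng.standard_normal(i1 - i0)
        # emphasize 20-45 Hz content
        b, a = sps.butter(2, [20 / (fs / 2), min(45 / (fs / 2), 0.99)], btype="band")
        burst = sps.filtfilt(b, a, burst)
        taper = np.hanning(i1 - i0)
        data[:, i0:i1] += np.outer(
            mtopo, noise_spec.muscle_amp * sig_rms * burst * taper / max(burst.std(), 1e-12)
        )

    realized_snr_db = 20 * np.log10(sig_rms / max(noise.std(), 1e-300))
    rec = Recording(data=data, fs=fs, channel_names=list(channels))
    info = {
        "realized_snr_db": float(realized_snr_db),
        "blink_times_s": blink_times,
        "muscle_times_s": muscle_times,
    }
    return rec, info


def synthetic_brain_score(trace: np.ndarray, fs: float, rng=None) -> float:
    """Surrogate for an automated brain/artifact IC classifier score.

    A logistic function of the fraction of 1-40 Hz spectral power that
    falls in the 1-13 Hz band: brain-like ictal sources are low-frequency
    dominated, muscle artifacts are not.  Output in (0, 1).
    """
    f, p = sps.periodogram(trace, fs=fs)
    band = (f >= 1) & (f <= 40)
    low = (f >= 1) & (f <= 13)
    tot = p[band].sum()
    r = p[low].sum() / tot if tot > 0 else 0.5
    score = 1.0 / (1.0 + np.exp(-(r - 0.5) * 8.0))
    if rng is not None:
        score = float(np.clip(score + rng.normal(0, 0.02), 0.0, 1.0))
    return float(score)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortSpec:
    n_patients: int = 30
    seizures_per_patient: int = 5
    vigilance_probs: dict = field(
        default_factory=lambda: {
            "Awake": 0.40, "NREM1": 0.10, "NREM2": 0.20, "NREM3": 0.20, "REM": 0.10,
        }
    )
    classification_probs: dict = field(
        default_factory=lambda: {"FAS": 0.20, "FIAS": 0.50, "FBTCS": 0.20, "UC": 0.10}
    )
    # base class probabilities follow the prevalence ordering reported for
    # surface recordings: constant-law classes dominate both sides
    onset_probs: dict = field(
        default_factory=lambda: {"SN/SubH": 0.66, "SNIC": 0.17, "SupH": 0.17}
    )
    offset_probs: dict = field(
        default_factory=lambda: {"FLC": 0.60, "SNIC/SH": 0.37, "SupH": 0.03}
    )
    effects: list = field(default_factory=list)  # (factor, level, class, delta)
    duration_mean_s: float = 60.0
    duration_sd_s: float = 15.0
    snr_db: float = 10.0
    seed: int = 0


_LOBES = ("temporal", "frontal", "parietal", "occipital")
_LOBE_P = (0.74, 0.11, 0.08, 0.07)
_ETIOLOGIES = ("hippocampal sclerosis", "cryptogenic", "cortical dysplasia", "other")
_ETIO_P = (0.34, 0.29, 0.18, 0.19)


def _inject(base: dict, effects, row: dict, side_cats) -> np.ndarray:
    """Apply (factor, level, class, delta) shifts to one seizure's class
    probabilities and renormalize the remaining classes proportionally."""
    p = np.array([base[c] for c in side_cats], dtype=float)
    for factor, level, cls, delta in effects:
        if cls not in side_cats or row.get(factor) != level:
            continue
        i = side_cats.index(cls)
        new = p[i] + delta
        if not (0.0 <= new <= 1.0):
            raise ValueError(
                f"effect ({factor}={level}, {cls}, {delta:+}) drives probability "
                f"to {new:.3f}, outside [0, 1]"
            )
        rest = 1.0 - p[i]
        p *= (1.0 - new) / rest if rest > 0 else 0.0
        p[i] = new
    return p / p.sum()


def generate_cohort(
    cohort_spec: CohortSpec, seed: int | None = None
) -> tuple[list[SeizureSimSpec], pd.DataFrame, pd.DataFrame]:
    """Sample a labeled cohort: per-seizure simulator specs + metadata/truth.

    Returns ``(sim_specs, metadata, truth)``.  ``metadata`` has one row per
    seizure (patient covariates repeated); ``truth`` carries the generating
    onset/offset class per seizure.  Rendering EEG from a sim spec is done
    on demand with :func:`simulate_source` / :func:`mix_to_scalp` (see
    :func:`render_seizure`).
    """
    master = cohort_spec.seed if seed is None else seed
    rng = np.random.default_rng(master)
    onset_cats = list(cohort_spec.onset_probs)
    offset_cats = list(cohort_spec.offset_probs)
    rows, truths, specs = [], [], []
    for p in range(cohort_spec.n_patients):
        pid = f"P{p:03d}"
        patient = {
            "patient_id": pid,
            "age": int(rng.integers(13, 66)),
            "gender": rng.choice(["male", "female"], p=[0.52, 0.48]),
            "lobe": rng.choice(_LOBES, p=_LOBE_P),
            "etiology": rng.choice(_ETIOLOGIES, p=_ETIO_P),
        }
        for s in range(cohort_spec.seizures_per_patient):
            row = dict(patient)
            row["seizure_id"] = f"{pid}_s{s}"
            row["vigilance"] = rng.choice(
                list(cohort_spec.vigilance_probs), p=list(cohort_spec.vigilance_probs.values())
            )
            row["classification"] = rng.choice(
                list(cohort_spec.classification_probs),
                p=list(cohort_spec.classification_probs.values()),
            )
            row["length_s"] = float(
                np.clip(rng.normal(cohort_spec.duration_mean_s, cohort_spec.duration_sd_s),
                        25.0, 240.0)
            )
            p_on = _inject(cohort_spec.onset_probs, cohort_spec.effects, row, onset_cats)
            p_off = _inject(cohort_spec.offset_probs, cohort_spec.effects, row, offset_cats)
            onset = rng.choice(onset_cats, p=p_on)
            offset = rng.choice(offset_cats, p=p_off)
            sim = SeizureSimSpec(
                onset_type=BifurcationType("onset", onset),
                offset_type=BifurcationType("offset", offset),
                duration_s=row["length_s"],
                snr_db=cohort_spec.snr_db,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rows.append(row)
            truths.append(
                {
                    "patient_id": pid,
                    "seizure_id": row["seizure_id"],
                    "onset_bifm": onset,
                    "offset_bifm": offset,
                }
            )
            specs.append(sim)
    return specs, pd.DataFrame(rows), pd.DataFrame(truths)


def render_seizure(
    sim: SeizureSimSpec, seed: int | None = None, n_extra_sources: int = 1
) -> tuple[Recording, SourceTrace, dict]:
    """Render one seizure spec to a scalp Recording.

    The seizure source gets a focal topography; ``n_extra_sources``
    non-seizure brain sources (alpha-band oscillations) are mixed in
    alongside the artifact/noise model.
    """
    rng = np.random.default_rng(sim.seed if seed is None else seed)
    src = simulate_source(sim, seed=int(rng.integers(0, 2**31 - 1)))
    centers = rng.choice(MONTAGE_1020, size=1 + n_extra_sources, replace=False)
    topos = [focal_topography(c) for c in centers]
    sources = [src]
    n = src.signal.size
    t = np.arange(n) / src.fs
    for k in range(n_extra_sources):
        f0 = rng.uniform(8, 12)
        bg = 0.15 * sim.peak_amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        sources.append(
            SourceTrace(
                signal=bg, fs=src.fs, true_onset_s=0.0, true_offset_s=0.0,
                spike_times_s=np.array([]), envelope=np.zeros(n),
            )
        )
    rec, info = mix_to_scalp(
        sources, np.vstack(topos), NoiseSpec(snr_db=sim.snr_db),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return rec, src, info


def simulate_reviewer_labels(
    truth: pd.DataFrame,
    n_ic: int = 8,
    clear_ic_range: tuple[int, int] = (0, 4),
    miss_rate: float = 0.1,
    confusion_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate two reviewers labeling each seizure's ICs against the truth.

    Each seizure carries the true transition in a per-seizure number of
    ICs drawn uniformly from ``clear_ic_range`` (some seizures yield no
    clear component, matching the varying per-seizure detectability that
    makes within-seizure permutation nulls exceed overall ones).  Each
    reviewer independently misses a clear IC with ``miss_rate`` and, when
    catching it, mislabels the class with ``confusion_rate``.  Non-clear
    ICs are labeled clear at a small false-alarm rate (miss_rate / 2).
    Returns the reviewer-label table (one row per IC x side x reviewer).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in truth.itertuples(index=False):
        n_clear = int(rng.integers(clear_ic_range[0], clear_ic_range[1] + 1))
        for ic in range(n_ic):
            is_clear = ic < n_clear
            for side, true_cls in (("onset", t.onset_bifm), ("offset", t.offset_bifm)):
                cats = [c for c in (ONSET_CATEGORIES if side == "onset" else OFFSET_CATEGORIES)]
                for reviewer in ("R1", "R2"):
                    if is_clear:
                        clear = rng.random() >= miss_rate
                    else:
                        clear = rng.random() < miss_rate / 2
                    if clear:
                        if is_clear and rng.random() >= confusion_rate:
                            bifm = true_cls
                        else:
                            bifm = rng.choice(cats)
                    else:
                        bifm = None
                    rows.append(
                        {
                            "patient_id": t.patient_id,
                            "seizure_id": t.seizure_id,
                            "ic_index": ic,
                            "side": side,
                            "reviewer": reviewer,
                            "clear": bool(clear),
                            "bifm": bifm,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_ic_dataset(
    cohort: CohortSpec | None = None,
    seed: int = 0,
    n_ic: int = 8,
    n_clear_ic: int = 2,
) -> pd.DataFrame:
    """Generate per-IC traces for classifier development, bypassing scalp
    mixing: each seizure contributes ``n_clear_ic`` source-bearing ICs (the
    seizure waveform plus noise at the cohort SNR) and noise/artifact ICs.

    Returns a table with one row per (seizure, ic): trace (object column),
    fs, side labels come later at feature time.  Columns: patient_id,
    seizure_id, ic_index, clear, onset_bifm, offset_bifm, trace,
    true_onset_s, true_offset_s, brain_score.
    """
    cohort = cohort or CohortSpec()
    specs, meta, truth = generate_cohort(cohort, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    rows = []
    for sim, t in zip(specs, truth.itertuples(index=False)):
        src = simulate_source(sim)
        n = src.signal.size
        noise_scale = src.signal.std() / 10 ** (cohort.snr_db / 20.0)
        for ic in range(n_ic):
            if ic < n_clear_ic:
                trace = src.signal + noise_scale * _pink_noise(rng, 1, n)[0]
                clear = True
            else:
                # artifact / background ICs: pink noise, occasionally with
                # a muscle-band or blink-like flavor
                kind = rng.integers(0, 3)
                trace = _pink_noise(rng, 1, n)[0] * src.signal.std() * 0.7
                if kind == 1:  # high-frequency muscle-like
                    b, a = sps.butter(2, [20 / (src.fs / 2), 0.34], btype="band")
                    trace = sps.filtfilt(b, a, rng.standard_normal(n))
                    trace *= src.signal.std() / max(trace.std(), 1e-12)
                clear = False
            score = synthetic_brain_score(trace, src.fs, rng)
            rows.append(
                {
                    "patient_id": t.patient_id,
                    "seizure_id": t.seizure_id,
                    "ic_index": ic,
                    "clear": clear,
                    "onset_bifm": t.onset_bifm,
                    "offset_bifm": t.offset_bifm,
                    "trace": trace,
                    "fs": src.fs,
                    "true_onset_s": src.true_onset_s,
                    "true_offset_s": src.true_offset_s,
                    "brain_score": score,
                }
            )
    return pd.DataFrame(rows)
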