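"""Synthetic phonocardiogram generation and WAV / manifest I/O.

A phonocardiogram (PCG) is an audio recording of heart sounds.  Each
cardiac cycle contains two transient valve-closure sounds: S1 (mitral and
tricuspid closure, spectral energy roughly 30-100 Hz) marking the start of
systole, and S2 (aortic and pulmonary closure, >= 100 Hz) marking its end.
Valvular disease adds a *murmur* -- band-limited noise between the heart
sounds whose frequency band is characteristic of the lesion (aortic
stenosis murmurs reach 100-450 Hz, mitral stenosis rumbles sit at
40-95 Hz, and so on).

The simulator here emulates exactly that structure: periodic
Gaussian-windowed S1/S2 bursts at a configurable heart rate, plus a
disease-specific band-passed noise murmur placed in systole (AS, MR, MVP)
or diastole (MS), plus additive white Gaussian noise at a configurable
SNR.  It is deliberately simple -- the point is controlled, labelled data
whose murmur band is known exactly, not hemodynamic realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

#: Recognised class labels: normal heart frequency plus the four valvular
#: diseases the classifier distinguishes.
CLASS_LABELS = ("NHF", "AS", "MR", "MS", "MVP")


@dataclass
class PCGRecording:
    """One labelled mono heart-sound signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples (arbitrary units), finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        One of ``CLASS_LABELS`` or ``"UNKNOWN"``.
    record_id : str
        Free-form identifier.
    """

    samples: np.ndarray
    fs: float
    label: str = "UNKNOWN"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.label not in CLASS_LABELS + ("UNKNOWN",):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class BandSpec:
    """A murmur (or normal) frequency band with its tolerance half-width."""

    name: str
    f_lo: float
    f_hi: float
    tol: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")
        if self.tol < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset generator."""

    n_per_class: int = 10
    fs: float = 4000.0
    duration_s: float = 5.0
    heart_rate_bpm: float = 60.0
    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not (1.0 <= self.duration_s <= 30.0):
            raise ValueError("duration_s must lie in [1, 30] seconds")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


# Murmur/normal bands: (name, f_lo, f_hi, tol).  Tolerance is a symmetric
# Hz half-width on the band edges.
_BAND_TABLE = (
    ("AR", 65.0, 395.0, 10.5),
    ("TR", 90.0, 400.0, 16.5),
    ("PR", 90.0, 150.0, 15.7),
    ("PDA", 90.0, 140.0, 20.9),
    ("MVP", 45.0, 90.0, 7.5),
    ("MS", 40.0, 95.0, 6.7),
    ("MR", 45.0, 160.0, 9.0),
    ("ASD", 60.0, 200.0, 25.5),
    ("AS", 100.0, 450.0, 35.4),
    ("PS", 150.0, 380.0, 27.1),
    ("NHF", 100.0, 180.0, 20.5),
)


def default_band_table() -> list[BandSpec]:
    """The eleven standard heart-murmur frequency bands.

    Covers regurgitations, stenoses, septal defects and the normal range;
    the five-class simulator uses the AS/MR/MS/MVP/NHF rows.
    """
    return [BandSpec(*row) for row in _BAND_TABLE]


def band_for_label(label: str) -> BandSpec:
    for row in _BAND_TABLE:
        if row[0] == label:
            return BandSpec(*row)
    raise KeyError(f"no band defined for label {label!r}")


def _gauss_burst(n: int, fs: float, center_s: float, width_s: float,
                 freq: float, amp: float, phase: float = 0.0) -> np.ndarray:
    """Gaussian-windowed tone burst; the building block for S1 and S2."""
    t = np.arange(n) / fs
    env = np.exp(-0.5 * ((t - center_s) / width_s) ** 2)
    return amp * env * np.sin(2 * np.pi * freq * (t - center_s) + phase)


def _bandpass_noise(n: int, fs: float, f_lo: float, f_hi: float,
                    rng: np.random.Generator) -> np.ndarray:
    """White noise band-passed to [f_lo, f_hi] with a 4th-order Butterworth."""
    noise = rng.standard_normal(n + 400)
    nyq = fs / 2.0
    sos = butter(4, [f_lo / nyq, min(f_hi, 0.99 * nyq) / nyq], btype="band",
                 output="sos")
    return sosfiltfilt(sos, noise)[200:-200]


#: Fraction of each cardiac cycle occupied by systole (S1 -> S2).
SYSTOLE_FRACTION = 0.35

# Systolic murmurs accompany AS, MR and MVP; the MS rumble is diastolic.
_MURMUR_PHASE = {"AS": "systole", "MR": "systole", "MVP": "systole",
                 "MS": "diastole"}


def simulate_recording(label: str, cfg: SimConfig,
                       rng: np.random.Generator | None = None,
                       record_id: str = "") -> PCGRecording:
    """Synthesize one labelled PCG recording.

    The clean signal is a train of cardiac cycles at ``cfg.heart_rate_bpm``:
    an S1 burst (tone ~60 Hz, inside the 30-100 Hz systolic band) at the
    start of each cycle and an S2 burst (~150 Hz, above 100 Hz) at the end
    of systole.  For disease labels a band-limited noise murmur is placed
    in the systolic interval (AS/MR/MVP) or the diastolic interval (MS),
    band-passed to the label's murmur band.  White Gaussian noise is added
    so that the clean-signal-to-noise power ratio equals ``cfg.snr_db``.
    """
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASS_LABELS}")
    if cfg.fs <= 0:
        raise ValueError("sampling rate must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n = int(round(cfg.duration_s * cfg.fs))
    fs = cfg.fs
    cycle_s = 60.0 / cfg.heart_rate_bpm
    sys_s = SYSTOLE_FRACTION * cycle_s

    x = np.zeros(n)
    t_end = cfg.duration_s
    # mild beat-to-beat jitter on burst amplitude/frequency for realism
    c = 0.0
    murmur_mask = np.zeros(n, dtype=bool)
    while c < t_end:
        s1_c = c + 0.04
        s2_c = c + sys_s + 0.02
        f1 = 60.0 * (1 + 0.05 * rng.standard_normal())
        f2 = 150.0 * (1 + 0.05 * rng.standard_normal())
        a1 = 1.0 * (1 + 0.1 * rng.standard_normal())
        a2 = 0.8 * (1 + 0.1 * rng.standard_normal())
        x += _gauss_burst(n, fs, s1_c, 0.018, f1, a1)
        x += _gauss_burst(n, fs, s2_c, 0.012, f2, a2)
        # murmur interval for this cycle (clear of the S1/S2 bursts)
        if label in _MURMUR_PHASE:
            if _MURMUR_PHASE[label] == "systole":
                lo_t, hi_t = c + 0.09, c + sys_s - 0.02
            else:
                lo_t, hi_t = c + sys_s + 0.08, c + cycle_s - 0.03
            i0, i1 = int(lo_t * fs), int(min(hi_t, t_end) * fs)
            if i1 > i0:
                murmur_mask[i0:i1] = True
        c += cycle_s

    if label in _MURMUR_PHASE:
        band = band_for_label(label)
        murmur = _bandpass_noise(n, fs, band.f_lo, band.f_hi, rng)
        # smooth on/off ramps at segment edges
        w = np.convolve(murmur_mask.astype(float),
                        np.ones(int(0.01 * fs)) / int(0.01 * fs), mode="same")
        murmur *= w
        s_rms = np.sqrt(np.mean(x**2)) + 1e-12
        m_rms = np.sqrt(np.mean(murmur[murmur_mask] ** 2)) + 1e-12
        murmur *= 0.55 * s_rms / m_rms * np.sqrt(1.0 / SYSTOLE_FRACTION)
        x = x + murmur

    # additive white noise at the requested SNR w.r.t. the clean composite
    p_sig = np.mean(x**2)
    p_noise = p_sig / (10 ** (cfg.snr_db / 10.0))
    x_noisy = x + np.sqrt(p_noise) * rng.standard_normal(n)

    rec = PCGRecording(x_noisy, fs, label=label,
                       record_id=record_id or f"{label.lower()}-sim")
    rec.clean = x  # ground truth, used by denoising benchmarks
    rec.murmur_mask = murmur_mask
    return rec


def simulate_dataset(cfg: SimConfig,
                     class_counts: dict[str, int] | None = None,
                     out_dir: str | Path | None = None
                     ) -> tuple[list[PCGRecording], pd.DataFrame]:
    """Simulate a labelled dataset and (optionally) write WAVs + manifest.

    ``class_counts`` overrides the balanced ``cfg.n_per_class`` with an
    explicit per-class count map, which is how imbalanced fixtures for the
    oversampling stage are produced.  Returns the recordings and a manifest
    frame with columns ``record_id, path, label``.
    """
    counts = class_counts or {lab: cfg.n_per_class for lab in CLASS_LABELS}
    rng = np.random.default_rng(cfg.seed)
    recs: list[PCGRecording] = []
    rows = []
    for lab in CLASS_LABELS:
        for i in range(counts.get(lab, 0)):
            rid = f"{lab.lower()}-{i:04d}"
            rec = simulate_recording(lab, cfg, rng=rng, record_id=rid)
            recs.append(rec)
            path = ""
            if out_dir is not None:
                path = str(Path(out_dir) / f"{rid}.wav")
                write_wav(rec, path)
            rows.append({"record_id": rid, "path": path, "label": lab})
    manifest = pd.DataFrame(rows, columns=["record_id", "path", "label"])
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return recs, manifest


def write_wav(rec: PCGRecording, path: str | Path,
              encoding: str = "float32") -> None:
    """Write a recording as RIFF WAV (IEEE float-32 or PCM-16)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if encoding == "float32":
        wavfile.write(path, int(rec.fs), rec.samples.astype(np.float32))
    elif encoding == "pcm16":
        peak = np.max(np.abs(rec.samples)) or 1.0
        q = np.clip(rec.samples / peak, -1.0, 1.0)
        wavfile.write(path, int(rec.fs),
                      np.round(q * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")


def read_wav(path: str | Path, label: str = "UNKNOWN",
             record_id: str | None = None) -> PCGRecording:
    """Read a WAV file; multi-channel input keeps the first channel."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        logger.warning("%s has %d channels; keeping the first", path, data.shape[1])
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(float)
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483648.0
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return PCGRecording(samples, float(fs), label=label,
                        record_id=record_id or path.stem)


def read_manifest(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path)
    required = {"record_id", "path", "label"}
    if not required.issubset(m.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return m


def load_dataset(manifest_path: str | Path) -> list[PCGRecording]:
    """Load every recording referenced by a manifest CSV."""
    m = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    recs = []
    for _, row in m.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        recs.append(read_wav(p, label=row["label"], record_id=row["record_id"]))
    return recs
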