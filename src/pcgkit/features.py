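"""Feature extraction: envelope, cycle segmentation, band powers, timing.

The classifier consumes one fixed-order numeric row per recording:

* fractional Welch-PSD power in each of the eleven murmur bands,
* delta (0.5-4 Hz) and theta (4-8 Hz) *envelope-modulation* powers --
  the cardiac rhythm itself and its first harmonics live there, and
  murmur on/off gating modulates the envelope at those rates,
* systolic/diastolic timing statistics recovered from S1/S2
  segmentation of the Shannon-energy envelope,
* global statistics (RMS, zero-crossing rate, spectral centroid).

Everything here is deterministic -- no random number generator is
touched anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt, welch

from .synthio import BandSpec, PCGRecording, default_band_table

#: envelope-modulation bands, Hz
DELTA_BAND = (0.5, 4.0)
THETA_BAND = (4.0, 8.0)


@dataclass
class FeatureTable:
    """n x d feature matrix with names, labels and record ids."""

    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray
    record_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("X shape does not match feature_names")
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains NaN/Inf")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "record_id", self.record_ids)
        df["label"] = self.y
        if hasattr(self, "synthetic"):
            df["synthetic"] = self.synthetic
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        meta = [c for c in ("record_id", "label", "synthetic") if c in df.columns]
        names = [c for c in df.columns if c not in meta]
        table = cls(X=df[names].to_numpy(float), feature_names=names,
                    y=df["label"].to_numpy(), record_ids=list(df["record_id"]))
        if "synthetic" in df.columns:
            table.synthetic = df["synthetic"].to_numpy(bool)
        return table


def envelope(rec: PCGRecording, smooth_hz: float = 20.0) -> np.ndarray:
    """Normalized Shannon-energy envelope, low-pass smoothed.

    The signal is scaled to unit peak; the Shannon energy
    ``-x^2 log(x^2)`` emphasises medium-amplitude content (heart sounds)
    over both the noise floor and isolated spikes, and the result is
    smoothed with a zero-phase 20 Hz Butterworth low-pass and floored at
    zero.
    """
    x = rec.samples
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("all-zero signal has no envelope")
    u = x / peak
    se = -(u**2) * np.log(u**2 + 1e-12)
    nyq = rec.fs / 2.0
    sos = butter(2, min(smooth_hz, 0.99 * nyq) / nyq, output="sos")
    env = sosfiltfilt(sos, se)
    return np.maximum(env, 0.0)


def segment_cycles(rec: PCGRecording, min_gap_s: float = 0.2
                   ) -> list[dict]:
    """Locate S1/S2 pairs by envelope peak-picking.

    Peaks at least ``min_gap_s`` apart are detected on the Shannon
    envelope; consecutive peak gaps are classified by the physiological
    rule that systole (S1 to S2) is shorter than diastole (S2 to the
    next S1).  Returns one dict per complete cycle with ``s1``, ``s2``
    sample indices and the cycle bounds.
    """
    env = envelope(rec)
    dist = max(1, int(min_gap_s * rec.fs))
    peaks, props = find_peaks(env, distance=dist,
                              height=0.2 * np.max(env))
    if peaks.size < 3:
        raise ValueError("too few envelope peaks to segment cycles")
    # decide whether the even peaks are S1 by comparing alternate gaps
    gaps = np.diff(peaks)
    even_first = np.mean(gaps[0::2]) < np.mean(gaps[1::2])
    start = 0 if even_first else 1
    cycles = []
    for i in range(start, peaks.size - 2, 2):
        s1, s2, nxt = peaks[i], peaks[i + 1], peaks[i + 2]
        cycles.append({"s1": int(s1), "s2": int(s2),
                       "start": int(s1), "end": int(nxt),
                       "s1_height": float(env[s1]),
                       "s2_height": float(env[s2])})
    if not cycles:
        raise ValueError("no complete cardiac cycle detected")
    return cycles


def band_power_features(rec: PCGRecording,
                        bands: list[BandSpec] | None = None,
                        welch_window_s: float = 1.0) -> dict[str, float]:
    """Fractional Welch-PSD power per murmur band, plus delta/theta
    envelope-modulation powers.

    Band fractions are power inside ``[f_lo, f_hi]`` divided by total
    power, hence in [0, 1].  Delta/theta are the same fractions computed
    on the PSD of the Shannon envelope, capturing rhythm-rate modulation
    rather than audio-frequency content.
    """
    bands = bands if bands is not None else default_band_table()
    fs = rec.fs
    for b in bands:
        if b.f_hi > fs / 2:
            raise ValueError(f"band {b.name} edge {b.f_hi} Hz above Nyquist")
    nper = min(int(welch_window_s * fs), rec.samples.size)
    f, pxx = welch(rec.samples, fs=fs, nperseg=nper)
    total = np.trapezoid(pxx, f) + 1e-300
    out = {}
    for b in bands:
        sel = (f >= b.f_lo) & (f <= b.f_hi)
        out[f"band_{b.name}"] = float(np.trapezoid(pxx[sel], f[sel]) / total)
    env = envelope(rec)
    fe, pe = welch(env - np.mean(env), fs=fs,
                   nperseg=min(rec.samples.size, int(4 * fs)))
    etot = np.trapezoid(pe, fe) + 1e-300
    for name, (lo, hi) in (("delta", DELTA_BAND), ("theta", THETA_BAND)):
        sel = (fe >= lo) & (fe <= hi)
        out[f"env_{name}"] = float(np.trapezoid(pe[sel], fe[sel]) / etot)
    return out


def interval_features(cycles: list[dict], fs: float) -> dict[str, float]:
    """Timing and intensity statistics of the segmented cycles."""
    if not cycles:
        raise ValueError("empty cycle list")
    sys_d = np.array([(c["s2"] - c["s1"]) / fs for c in cycles])
    dia_d = np.array([(c["end"] - c["s2"]) / fs for c in cycles])
    cyc_d = sys_d + dia_d
    amp_ratio = np.array([c["s1_height"] / (c["s2_height"] + 1e-12)
                          for c in cycles])
    return {
        "systole_mean_s": float(np.mean(sys_d)),
        "systole_sd_s": float(np.std(sys_d)),
        "diastole_mean_s": float(np.mean(dia_d)),
        "diastole_sd_s": float(np.std(dia_d)),
        "systole_cycle_ratio": float(np.mean(sys_d / cyc_d)),
        "s1_s2_amp_ratio": float(np.mean(amp_ratio)),
    }


def _global_stats(rec: PCGRecording) -> dict[str, float]:
    x = rec.samples
    f, pxx = welch(x, fs=rec.fs, nperseg=min(x.size, int(rec.fs)))
    centroid = float(np.sum(f * pxx) / (np.sum(pxx) + 1e-300))
    s = np.sign(x)
    s = s[s != 0]
    zcr = float(np.sum(s[1:] != s[:-1]) / x.size) if s.size > 1 else 0.0
    return {"rms": float(np.sqrt(np.mean(x**2))),
            "zero_cross_rate": zcr,
            "spectral_centroid_hz": centroid}


def extract_features(recs: list[PCGRecording],
                     bands: list[BandSpec] | None = None) -> FeatureTable:
    """One feature row per recording; fixed, documented column order.

    Columns: the eleven band fractions (table order), env_delta,
    env_theta, six interval statistics, rms, zero_cross_rate,
    spectral_centroid_hz.  Recordings whose cycle segmentation fails
    get neutral timing features (all zeros) rather than being dropped.
    """
    if not recs:
        raise ValueError("empty recording list")
    rows, names = [], None
    for rec in recs:
        feats = band_power_features(rec, bands)
        try:
            feats.update(interval_features(segment_cycles(rec), rec.fs))
        except ValueError:
            feats.update({k: 0.0 for k in
                          ("systole_mean_s", "systole_sd_s", "diastole_mean_s",
                           "diastole_sd_s", "systole_cycle_ratio",
                           "s1_s2_amp_ratio")})
        feats.update(_global_stats(rec))
        if names is None:
            names = list(feats)
        rows.append([feats[k] for k in names])
    return FeatureTable(X=np.array(rows), feature_names=names,
                        y=np.array([r.label for r in recs]),
                        record_ids=[r.record_id for r in recs])
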