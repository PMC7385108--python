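"""Extraction of the six cardiovascular features from ECG and ICG streams.

The feature set is the standard ambulatory impedance-cardiography panel:

- IBI   interbeat interval (ms), from ECG R peaks
- RSA   respiratory sinus arrhythmia, log(ms^2) spectral power in 0.12-0.4 Hz
- PEP   pre-ejection period (ms), R peak to ICG B point
- LVET  left ventricular ejection time (ms), B point to X point
- SV    stroke volume (mL), Kubicek's equation
- CO    cardiac output (L/min), SV x heart rate

Quality control excludes artifactual data; it never corrects it.  Rejected
beats and ensembles carry a reason code and are excluded from every mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

if TYPE_CHECKING:  # pragma: no cover
    from .synthdata import RawRecording

#: canonical feature order used throughout the package
FEATURE_NAMES = ("ibi", "rsa", "pep", "lvet", "sv", "co")

#: acceptable physiological ranges (QC, not estimation)
IBI_RANGE_MS = (300.0, 2000.0)
PEP_RANGE_MS = (30.0, 200.0)
LVET_RANGE_MS = (100.0, 500.0)
MAX_INTERVAL_GRADIENT_MS = 30.0

#: RSA band (respiratory frequencies) in Hz
RSA_BAND_HZ = (0.12, 0.4)

#: ICG ensemble window relative to the R peak, in seconds
ENSEMBLE_PRE_S = 0.25
ENSEMBLE_POST_S = 0.50
ENSEMBLE_N_BEATS = 8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BeatSeries:
    """Detected R peaks with per-beat-pair IBI values and quality flags.

    ``ibi[j]`` is the interval (ms) between ``r_peak_times[j]`` and
    ``r_peak_times[j+1]`` and is attributed to the *second* beat of the pair.
    """

    r_peak_times: np.ndarray  # seconds, strictly increasing
    ibi: np.ndarray           # ms, len == len(r_peak_times) - 1
    quality: np.ndarray       # 'ok' | 'rejected', aligned with ibi
    reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        self.ibi = np.asarray(self.ibi, dtype=float)
        self.quality = np.asarray(self.quality, dtype=object)
        if self.r_peak_times.size and np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")
        if self.ibi.size != max(self.r_peak_times.size - 1, 0):
            raise ValueError("ibi must have one entry per beat pair")
        if not self.reasons:
            self.reasons = [""] * self.ibi.size

    @property
    def accepted(self) -> np.ndarray:
        """Boolean mask over IBI entries."""
        return self.quality == "ok"

    def accepted_beat_indices(self) -> np.ndarray:
        """Indices of beats whose trailing IBI passed QC (beat 0 excluded)."""
        return np.flatnonzero(self.accepted) + 1

    @classmethod
    def from_ibi(cls, ibi_ms: Sequence[float], start_s: float = 0.0) -> "BeatSeries":
        """Build a series from an IBI trajectory (first beat at ``start_s``)."""
        ibi = np.asarray(ibi_ms, dtype=float)
        times = start_s + np.concatenate(([0.0], np.cumsum(ibi) / 1000.0))
        return cls(times, ibi, np.array(["ok"] * ibi.size, dtype=object))


@dataclass
class EnsembleICG:
    """One overlapping 8-beat ensemble average of dZ/dt around the R peak."""

    anchor_time: float        # R-peak time (s) of the last contributing beat
    window: np.ndarray        # averaged dZ/dt, R-250 ms .. R+500 ms
    n_beats: int
    r_index: int              # sample index of the R peak inside window
    ibi_ms: float             # mean accepted IBI of contributing beats
    b_index: Optional[int] = None
    x_index: Optional[int] = None
    quality: str = "ok"

    @property
    def dzdt_peak_index(self) -> int:
        """Index of the dZ/dt maximum after the R peak."""
        seg = self.window[self.r_index + 1:]
        return self.r_index + 1 + int(np.argmax(seg))

    @property
    def dzdt_max(self) -> float:
        return float(self.window[self.dzdt_peak_index])


@dataclass
class FeatureVector:
    """Six cardiovascular features for one analysis window; NaN = missing."""

    ibi: float = np.nan
    rsa: float = np.nan
    pep: float = np.nan
    lvet: float = np.nan
    sv: float = np.nan
    co: float = np.nan
    reasons: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))


@dataclass
class KubicekParams:
    """Constants of Kubicek's stroke-volume equation.

    rho: blood resistivity (ohm cm); L: distance between the inner ICG
    recording electrodes (cm), measured per participant-day; z0: mean basal
    thoracic impedance (ohm).
    """

    rho: float = 135.0
    L: float = 30.0
    z0: float = 30.0

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.L <= 0 or self.z0 <= 0:
            raise ValueError("Kubicek parameters must be strictly positive")


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def filter_ecg(ecg: np.ndarray, fs: float,
               band: tuple = (0.5, 45.0), order: int = 6) -> np.ndarray:
    """Zero-phase elliptic band-pass (0.5-45 Hz) of the raw ECG.

    Forward-backward filtering preserves fiducial timing (no group delay);
    the two passes double the 0.1 dB ripple and 80 dB stopband, leaving
    mains noise at 60 Hz below 0.3% and DC below 1e-6 of input amplitude.
    """
    if fs <= 2 * band[1]:
        raise ValueError(f"fs={fs} too low for band {band}")
    sos = sps.ellip(order, 0.1, 80.0, band, btype="bandpass", fs=fs,
                    output="sos")
    return sps.sosfiltfilt(sos, np.asarray(ecg, dtype=float))


def detect_r_peaks(ecg: np.ndarray, fs: float,
                   min_rr_s: float = 0.25) -> BeatSeries:
    """Detect R peaks on a (filtered) ECG with an adaptive amplitude threshold.

    Hamilton/Pan-Tompkins-class approach: candidate peaks must exceed a
    fraction of the typical QRS amplitude, estimated from 2-s block maxima,
    and be separated by a physiological refractory interval.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of signal")
    block = max(int(2 * fs), 1)
    nblk = max(x.size // block, 1)
    bmax = np.abs(x[: nblk * block]).reshape(nblk, block).max(axis=1)
    height = 0.4 * float(np.median(bmax))
    if height <= 0:
        warnings.warn("flat ECG: no R peaks detected")
        return BeatSeries(np.array([]), np.array([]), np.array([], dtype=object))
    peaks, _ = sps.find_peaks(x, height=height, distance=int(min_rr_s * fs))
    if peaks.size == 0:
        warnings.warn("no R peaks detected")
        return BeatSeries(np.array([]), np.array([]), np.array([], dtype=object))
    times = peaks / fs
    ibi = np.diff(times) * 1000.0
    return BeatSeries(times, ibi, np.array(["ok"] * ibi.size, dtype=object))


def qc_ibi(beats: BeatSeries,
           ibi_range: tuple = IBI_RANGE_MS,
           max_beat_delta_ms: float = 300.0) -> BeatSeries:
    """Flag artifactual IBIs: out of range, or ectopic beat-to-beat jumps.

    Rejected values are excluded from all downstream computation, never
    corrected.
    """
    quality = np.array(["ok"] * beats.ibi.size, dtype=object)
    reasons = [""] * beats.ibi.size
    last_ok = None
    for j, v in enumerate(beats.ibi):
        if not (ibi_range[0] <= v <= ibi_range[1]):
            quality[j] = "rejected"
            reasons[j] = "ibi-out-of-range"
            continue
        if last_ok is not None and abs(v - last_ok) > max_beat_delta_ms:
            quality[j] = "rejected"
            reasons[j] = "ectopic-delta"
            continue
        last_ok = v
    return BeatSeries(beats.r_peak_times.copy(), beats.ibi.copy(),
                      quality, reasons)


# ---------------------------------------------------------------------------
# RSA
# ---------------------------------------------------------------------------

def compute_rsa(beats: BeatSeries, window: tuple,
                fs_interp: float = 4.0, band: tuple = RSA_BAND_HZ,
                eps: float = 1e-12, min_beats: int = 8) -> float:
    """Respiratory sinus arrhythmia over ``window`` = [t0, t1).

    Mirrors standard HRV processing: cubic interpolation of the accepted
    beat-to-beat IBI series to a uniform grid, linear detrending, Hamming
    taper, FFT periodogram, then the natural log of the integrated power
    density between 0.12 and 0.4 Hz.  Zero band power is floored at ``eps``
    (ms^2) before the log.  Returns NaN when too few accepted beats.
    """
    t0, t1 = window
    idx = beats.accepted_beat_indices()
    t = beats.r_peak_times[idx]
    sel = (t >= t0) & (t < t1)
    t = t[sel]
    v = beats.ibi[idx[sel] - 1]
    if t.size < min_beats or (t.size and (t[-1] - t[0]) < 1.0 / band[0]):
        return float("nan")
    grid = np.arange(t[0], t[-1], 1.0 / fs_interp)
    series = CubicSpline(t, v)(grid)
    f, pxx = sps.periodogram(series, fs=fs_interp, window="hamming",
                             detrend="linear")
    m = (f >= band[0]) & (f <= band[1])
    power = float(np.trapezoid(pxx[m], f[m])) if m.sum() > 1 else 0.0
    return float(np.log(max(power, eps)))


# ---------------------------------------------------------------------------
# ICG ensembles and fiducial points
# ---------------------------------------------------------------------------

def build_ensembles(dzdt: np.ndarray, beats: BeatSeries, fs: float,
                    n_beats: int = ENSEMBLE_N_BEATS) -> list:
    """Overlapping ensemble averages of dZ/dt around accepted R peaks.

    Each ensemble averages ``n_beats`` consecutive accepted beats over
    R-250 ms .. R+500 ms, advancing one beat per ensemble.  Beats rejected
    by IBI QC never contribute.
    """
    dzdt = np.asarray(dzdt, dtype=float)
    pre = int(round(ENSEMBLE_PRE_S * fs))
    post = int(round(ENSEMBLE_POST_S * fs))
    idx = beats.accepted_beat_indices()
    samples = np.round(beats.r_peak_times * fs).astype(int)
    usable = [i for i in idx
              if samples[i] - pre >= 0 and samples[i] + post < dzdt.size]
    if len(usable) < n_beats:
        warnings.warn(f"only {len(usable)} usable beats; no ensembles")
        return []
    out = []
    for j in range(len(usable) - n_beats + 1):
        grp = usable[j: j + n_beats]
        wins = np.stack([dzdt[samples[i] - pre: samples[i] + post + 1]
                         for i in grp])
        ibi_vals = beats.ibi[np.array(grp) - 1]
        out.append(EnsembleICG(
            anchor_time=float(beats.r_peak_times[grp[-1]]),
            window=wins.mean(axis=0),
            n_beats=n_beats,
            r_index=pre,
            ibi_ms=float(ibi_vals.mean()),
        ))
    return out


def _second_difference(w: np.ndarray) -> np.ndarray:
    """Centered second difference (narrow stencil keeps fiducials sharp)."""
    d2 = np.zeros_like(w)
    d2[1:-1] = np.diff(w, 2)
    return d2


def detect_b_point(ens: EnsembleICG, fs: float,
                   search_start_ms: float = 10.0,
                   curvature_frac: float = 1e-4) -> Optional[int]:
    """B point: maximal second derivative of dZ/dt between R and dZ/dt max.

    The aortic-valve-opening inflection produces a curvature maximum at the
    foot of the dZ/dt upstroke.  The candidate must show curvature above a
    small fraction of the ensemble amplitude, so featureless (monotone)
    windows yield no B point; absence is a value, not an error.
    """
    w = ens.window
    p = ens.dzdt_peak_index
    lo = ens.r_index + int(round(search_start_ms / 1000.0 * fs))
    if lo >= p:
        return None
    d2 = _second_difference(w)
    b = lo + int(np.argmax(d2[lo:p]))
    amp = float(w.max() - w.min())
    if amp <= 0 or d2[b] < curvature_frac * amp:
        return None
    return b


def detect_x_point(ens: EnsembleICG, fs: float,
                   curvature_frac: float = 1e-4) -> Optional[int]:
    """X point: curvature-maximal local minimum of dZ/dt after dZ/dt max.

    The aortic-valve-closing notch is the prominent trough following the
    ejection peak.  Candidates are local minima with sufficient second
    derivative; the deepest qualifying trough is returned, or None when the
    notch is absent or truncated by the window.
    """
    w = ens.window
    p = ens.dzdt_peak_index
    if p >= w.size - 2:
        return None
    d2 = _second_difference(w)
    amp = float(w.max() - w.min())
    best = None
    for i in range(p + 1, w.size - 1):
        if w[i] <= w[i - 1] and w[i] <= w[i + 1] and d2[i] >= curvature_frac * amp:
            if best is None or w[i] < w[best]:
                best = i
    return best


def correct_b_points(b_series: np.ndarray, order: int = 3,
                     nsigma: float = 3.0, max_iter: int = 3) -> np.ndarray:
    """Outlier correction of a B-point series via forward/reverse AR models.

    An AR(``order``) model with intercept is fit by least squares to the
    series in both time directions.  A point is an outlier when its residual
    exceeds ``nsigma`` robust SDs under *both* predictions (one suffices at
    the edges where only one direction exists); outliers are replaced by the
    mean of the available predictions.  Passes repeat so adjacent outliers
    are caught.  Series shorter than ``order + 2`` are returned unchanged.
    """
    y = np.asarray(b_series, dtype=float).copy()
    n = y.size
    if n < order + 2:
        warnings.warn("B-point series too short for AR correction")
        return y

    def _ar_predict(z: np.ndarray) -> np.ndarray:
        rows = np.column_stack([z[order - k - 1: len(z) - k - 1]
                                for k in range(order)])
        X = np.column_stack([np.ones(rows.shape[0]), rows])
        coef, *_ = np.linalg.lstsq(X, z[order:], rcond=None)
        pred = np.full(len(z), np.nan)
        pred[order:] = X @ coef
        return pred

    def _dir_flags(pred: np.ndarray) -> np.ndarray:
        res = y - pred
        ok = np.isfinite(res)
        sd = 1.4826 * np.median(np.abs(res[ok] - np.median(res[ok])))
        sd = max(sd, 1e-9)
        out = np.abs(res) > nsigma * sd
        out[~ok] = True  # an undefined direction does not veto the other
        return out

    for _ in range(max_iter):
        fwd = _ar_predict(y)
        rev = _ar_predict(y[::-1])[::-1]
        defined = np.isfinite(fwd) | np.isfinite(rev)
        flagged = _dir_flags(fwd) & _dir_flags(rev) & defined
        if not flagged.any():
            break
        repl = np.nanmean(np.vstack([fwd, rev]), axis=0)
        y[flagged] = repl[flagged]
    return y


# ---------------------------------------------------------------------------
# systolic intervals and volumetric features
# ---------------------------------------------------------------------------

@dataclass
class SystolicIntervals:
    pep: float
    lvet: float
    quality: str = "ok"
    reason: str = ""


def compute_systolic_intervals(ens_list: Sequence[EnsembleICG], fs: float,
                               pep_range: tuple = PEP_RANGE_MS,
                               lvet_range: tuple = LVET_RANGE_MS,
                               max_gradient_ms: float = MAX_INTERVAL_GRADIENT_MS,
                               ) -> list:
    """PEP and LVET per ensemble with range and gradient quality checks.

    PEP = (B - R) and LVET = (X - B), both in ms.  Values outside the
    physiological ranges, or jumping more than ``max_gradient_ms`` from the
    previous accepted ensemble, are flagged rejected (and excluded, not
    corrected).
    """
    out = []
    prev_pep = prev_lvet = None
    for ens in ens_list:
        if ens.b_index is None or ens.x_index is None:
            out.append(SystolicIntervals(np.nan, np.nan, "rejected",
                                         "fiducial-missing"))
            continue
        pep = (ens.b_index - ens.r_index) * 1000.0 / fs
        lvet = (ens.x_index - ens.b_index) * 1000.0 / fs
        quality, reason = "ok", ""
        if not (pep_range[0] <= pep <= pep_range[1]):
            quality, reason = "rejected", "pep-out-of-range"
        elif not (lvet_range[0] <= lvet <= lvet_range[1]):
            quality, reason = "rejected", "lvet-out-of-range"
        elif prev_pep is not None and (abs(pep - prev_pep) > max_gradient_ms or
                                       abs(lvet - prev_lvet) > max_gradient_ms):
            quality, reason = "rejected", "gradient"
        if quality == "ok":
            prev_pep, prev_lvet = pep, lvet
        out.append(SystolicIntervals(pep, lvet, quality, reason))
    return out


def compute_sv_co(ens: EnsembleICG, intervals: SystolicIntervals,
                  params: KubicekParams, ibi_ms: Optional[float] = None) -> tuple:
    """Stroke volume (Kubicek) and cardiac output for one accepted ensemble.

    SV = rho (L/Z0)^2 LVET_s (dZ/dt)_max in mL; CO = SV x HR / 1000 in L/min.
    """
    if params.z0 <= 0:
        raise ValueError("Z0 must be positive")
    ibi = ens.ibi_ms if ibi_ms is None else ibi_ms
    sv = params.rho * (params.L / params.z0) ** 2 * (intervals.lvet / 1000.0) \
        * ens.dzdt_max
    co = sv * (60000.0 / ibi) / 1000.0
    return float(sv), float(co)


# ---------------------------------------------------------------------------
# windowed feature extraction
# ---------------------------------------------------------------------------

def extract_features(recording: "RawRecording", window: tuple,
                     params: Optional[KubicekParams] = None,
                     prefiltered: bool = False) -> FeatureVector:
    """Extract the six-feature vector from one [t0, t1) window of a recording.

    IBI and RSA come from the QC'd beat series; PEP/LVET/SV/CO are means over
    accepted ICG ensembles anchored inside the window.  A feature with no
    accepted data is NaN with a reason code.
    """
    t0, t1 = window
    duration = recording.ecg.size / recording.fs
    if t0 < 0 or t1 > duration or t1 <= t0:
        raise ValueError(f"window {window} outside recording [0, {duration:.2f})")
    params = params or KubicekParams(z0=float(np.mean(recording.z0)))

    ecg = recording.ecg if prefiltered else filter_ecg(recording.ecg, recording.fs)
    beats = qc_ibi(detect_r_peaks(ecg, recording.fs))
    fv = FeatureVector()

    idx = beats.accepted_beat_indices()
    t = beats.r_peak_times[idx] if idx.size else np.array([])
    in_win = idx[(t >= t0) & (t < t1)] if idx.size else np.array([], dtype=int)
    if in_win.size:
        fv.ibi = float(beats.ibi[in_win - 1].mean())
    else:
        fv.reasons["ibi"] = "no-accepted-beats"

    fv.rsa = compute_rsa(beats, (t0, t1))
    if not np.isfinite(fv.rsa):
        fv.reasons["rsa"] = "too-few-beats"

    ens_all = build_ensembles(recording.dzdt, beats, recording.fs)
    ens = [e for e in ens_all if t0 <= e.anchor_time < t1]
    for e in ens:
        e.b_index = detect_b_point(e, recording.fs)
        if e.b_index is not None:
            e.x_index = detect_x_point(e, recording.fs)
    intervals = compute_systolic_intervals(ens, recording.fs)
    acc = [(e, iv) for e, iv in zip(ens, intervals) if iv.quality == "ok"]
    if acc:
        fv.pep = float(np.mean([iv.pep for _, iv in acc]))
        fv.lvet = float(np.mean([iv.lvet for _, iv in acc]))
        svco = [compute_sv_co(e, iv, params) for e, iv in acc]
        fv.sv = float(np.mean([s for s, _ in svco]))
        fv.co = float(np.mean([c for _, c in svco]))
    else:
        for f in ("pep", "lvet", "sv", "co"):
            fv.reasons[f] = "no-accepted-ensembles"
    return fv
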