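"""Context-aware experience-sampling trigger engine.

A prompt fires when the interbeat interval changes by more than a threshold
(default +/-167 ms) over a trailing 8-s window while the participant is
still (accelerometry <= 10 cm/s^2 over 30 s) and has not changed posture
(torso-thigh relative orientation stable over 30 s), with a 5-min
refractory interval between prompts.  Two additional random prompts per
day are scheduled uniformly, one per 4-hour half-day, subject to the same
stillness/posture gates and refractory rule.

The IBI-change rule compares the current beat's IBI against every accepted
beat in the trailing window and fires on the maximum absolute difference —
the most sensitive reading of a "substantial, sustained change"; it is a
configuration point.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .signals import BeatSeries


@dataclass
class TriggerConfig:
    ibi_delta_threshold_ms: float = 167.0
    change_window_s: float = 8.0
    stillness_window_s: float = 30.0
    accel_threshold: float = 10.0        # cm/s^2
    posture_tolerance_deg: float = 15.0
    refractory_s: float = 300.0
    random_prompts_per_day: int = 2
    half_day_s: float = 4 * 3600.0
    target_prompts_per_day: int = 20
    threshold_clamp_ms: tuple = (65.0, 266.0)
    adapt_exponent: float = 0.21
    #: 'max_diff' compares the current IBI against every accepted beat in
    #: the trailing window; 'endpoint' against the earliest one only
    comparison: str = "max_diff"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.refractory_s < self.change_window_s:
            raise ValueError("refractory must be >= change window")
        for v in (self.ibi_delta_threshold_ms, self.change_window_s,
                  self.stillness_window_s, self.accel_threshold,
                  self.refractory_s):
            if v <= 0:
                raise ValueError("trigger parameters must be positive")


@dataclass
class PromptLog:
    """Fired prompts: (time s, 'triggered' | 'random', ibi_delta ms or None)."""

    prompts: list = field(default_factory=list)
    threshold_history: list = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.prompts])


def detect_ibi_change(beats: BeatSeries, t: float,
                      cfg: TriggerConfig) -> Optional[float]:
    """Signed IBI change at time ``t`` vs the trailing 8-s window, if any.

    Returns ``ibi(t) - ibi(t_ref)`` for the accepted reference beat in
    [t - window, t] with the largest absolute difference, when that
    difference exceeds the threshold; otherwise None.
    """
    idx = beats.accepted_beat_indices()
    times = beats.r_peak_times[idx]
    in_win = idx[(times >= t - cfg.change_window_s) & (times <= t)]
    if in_win.size < 2:
        return None
    vals = beats.ibi[in_win - 1]
    cur = vals[-1]
    if cfg.comparison == "endpoint":
        best = cur - vals[0]
    else:
        diffs = cur - vals[:-1]
        best = diffs[np.argmax(np.abs(diffs))]
    return float(best) if abs(best) > cfg.ibi_delta_threshold_ms else None


def stillness_gate(accel_t: np.ndarray, accel: np.ndarray, t: float,
                   cfg: TriggerConfig) -> bool:
    """True iff all accelerometer channels and their vector magnitude stay
    at or below the threshold over [t - 30 s, t].  Missing coverage fails."""
    accel_t = np.asarray(accel_t)
    if accel_t.size == 0 or accel_t[0] > t - cfg.stillness_window_s or accel_t[-1] < t:
        return False
    m = (accel_t >= t - cfg.stillness_window_s) & (accel_t <= t)
    seg = np.asarray(accel)[:, m]
    if seg.size == 0:
        return False
    mag = np.sqrt((seg ** 2).sum(axis=0))
    return bool((np.abs(seg) <= cfg.accel_threshold).all()
                and (mag <= cfg.accel_threshold).all())


def classify_posture(torso_deg: float, thigh_deg: float) -> str:
    """Posture from IMU inclinations (degrees from vertical)."""
    if torso_deg > 60:
        return "reclining"
    if thigh_deg > 45:
        return "sitting"
    return "standing"


def posture_gate(imu_t: np.ndarray, torso: np.ndarray, thigh: np.ndarray,
                 t: float, cfg: TriggerConfig) -> tuple:
    """(stable, posture): stable iff the torso-thigh relative angle varied
    less than the tolerance over [t - 30 s, t].  Missing coverage fails."""
    imu_t = np.asarray(imu_t)
    if imu_t.size == 0 or imu_t[0] > t - cfg.stillness_window_s or imu_t[-1] < t:
        return False, "unknown"
    m = (imu_t >= t - cfg.stillness_window_s) & (imu_t <= t)
    rel = np.asarray(thigh)[m] - np.asarray(torso)[m]
    if rel.size == 0:
        return False, "unknown"
    stable = bool(rel.max() - rel.min() < cfg.posture_tolerance_deg)
    i = np.flatnonzero(m)[-1]
    return stable, classify_posture(float(np.asarray(torso)[i]),
                                    float(np.asarray(thigh)[i]))


def run_trigger_engine(beats: BeatSeries, accel_t: np.ndarray,
                       accel: np.ndarray, imu_t: np.ndarray,
                       torso: np.ndarray, thigh: np.ndarray,
                       cfg: TriggerConfig,
                       span: Optional[tuple] = None,
                       random_prompts: bool = True) -> PromptLog:
    """Run the full prompt engine over one recording day.

    Triggered prompts are evaluated at accepted beat times in chronological
    order.  Each scheduled random time fires at the first whole second at or
    after it (within its half-day) where both gates pass and the refractory
    interval has elapsed.  All candidates are processed on one merged
    timeline so refractory interactions are well defined.
    """
    log = PromptLog()
    if beats.r_peak_times.size == 0:
        return log
    if span is None:
        span = (float(beats.r_peak_times[0]), float(beats.r_peak_times[-1]))
    t0, t1 = span

    # precomputed accepted-beat arrays: the per-beat IBI-change rule then
    # needs only a binary search over the trailing window
    acc_idx = beats.accepted_beat_indices()
    acc_t = beats.r_peak_times[acc_idx]
    acc_v = beats.ibi[acc_idx - 1]

    def _delta(pos: int) -> Optional[float]:
        t = acc_t[pos]
        lo = int(np.searchsorted(acc_t, t - cfg.change_window_s, side="left"))
        if pos - lo < 1:
            return None
        if cfg.comparison == "endpoint":
            best = float(acc_v[pos] - acc_v[lo])
        else:
            diffs = acc_v[pos] - acc_v[lo:pos]
            best = float(diffs[np.argmax(np.abs(diffs))])
        return best if abs(best) > cfg.ibi_delta_threshold_ms else None

    queue: list = []
    seqno = 0
    for pos, bt in enumerate(acc_t):
        if t0 <= bt <= t1:
            heapq.heappush(queue, (float(bt), seqno, "beat", pos))
            seqno += 1
    if random_prompts:
        rng = np.random.default_rng(cfg.seed)
        n_half = cfg.random_prompts_per_day
        for h in range(n_half):
            h0 = t0 + h * cfg.half_day_s
            h1 = min(t0 + (h + 1) * cfg.half_day_s, t1)
            if h0 >= t1:
                break
            tau = float(rng.uniform(h0, h1))
            heapq.heappush(queue, (math.ceil(tau), seqno, "random", h1))
            seqno += 1

    last = -math.inf
    while queue:
        t, _, kind, payload = heapq.heappop(queue)
        if kind == "beat":
            if t - last < cfg.refractory_s:
                continue
            delta = _delta(payload)
            if delta is None:
                continue
            if not stillness_gate(accel_t, accel, t, cfg):
                continue
            stable, _ = posture_gate(imu_t, torso, thigh, t, cfg)
            if not stable:
                continue
            log.prompts.append((t, "triggered", delta))
            last = t
        else:  # random
            h1 = payload
            ok = (t - last >= cfg.refractory_s
                  and stillness_gate(accel_t, accel, t, cfg)
                  and posture_gate(imu_t, torso, thigh, t, cfg)[0])
            if ok:
                log.prompts.append((float(t), "random", None))
                last = t
            elif t + 1.0 <= h1:
                heapq.heappush(queue, (t + 1.0, seqno, "random", h1))
                seqno += 1
    log.prompts.sort(key=lambda p: p[0])
    return log


def ibi_delta_to_bpm(baseline_ibi_ms: float, delta_ms: float) -> float:
    """Heart-rate change (bpm) equivalent to an IBI change at a baseline.

    At 1000 ms baseline, +167 ms is a decrease of about 9 bpm and -167 ms an
    increase of about 12 bpm.
    """
    if baseline_ibi_ms + delta_ms <= 0 or baseline_ibi_ms <= 0:
        raise ValueError("resulting IBI must be positive")
    return 60000.0 / (baseline_ibi_ms + delta_ms) - 60000.0 / baseline_ibi_ms


def adapt_threshold(day_prompt_count: int, cfg: TriggerConfig,
                    threshold_ms: Optional[float] = None) -> float:
    """Per-day multiplicative threshold update toward the target prompt rate.

    Raises the threshold when the day produced too many prompts and lowers
    it when too few, clamped to the configured range (default 65-266 ms).
    The default exponent makes one day at twice the target adjust a 167 ms
    threshold by about +26 ms.
    """
    thr = cfg.ibi_delta_threshold_ms if threshold_ms is None else threshold_ms
    lo, hi = cfg.threshold_clamp_ms
    ratio = day_prompt_count / cfg.target_prompts_per_day
    new = thr * ratio ** cfg.adapt_exponent if ratio > 0 else lo
    return float(np.clip(new, lo, hi))
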