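"""Synthetic ambulatory data with known ground truth.

Two levels of simulation feed the pipeline:

1. *Feature level*: per-participant Gaussian mixtures in 6-D change-score
   space (IBI ms, RSA log-units, PEP ms, LVET ms, SV mL, CO L/min), with a
   Zipf word vocabulary, per-cluster valence/arousal models on -50..+50, and
   sitting-dominant posture.  Every event retains its true component so
   cluster-recovery and calibration suites can score against truth.

2. *Signal level*: raw 500 Hz ECG / dZ/dt / Z0 / accelerometer / IMU
   streams built beat by beat from a scripted IBI trajectory, with the ICG B
   inflection at R + PEP and the X trough at B + LVET, and ground-truth
   fiducial annotations alongside.

All generation is reproducible: identical seeds give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .events import Event
from .signals import FEATURE_NAMES

#: typical within-person SD of raw change scores per feature, used as the
#: base scale of mixture components (ms, log-units, ms, ms, mL, L/min)
FEATURE_SCALES = np.array([40.0, 0.5, 8.0, 15.0, 6.0, 0.6])

#: posture frequencies emulating sitting-dominant ambulatory sampling
DEFAULT_POSTURE_PROBS = {
    "sitting": 0.7388, "standing": 0.1247, "reclining": 0.0827, "other": 0.0538,
}

#: grand means / between-cluster spread of the affect-rating models
VALENCE_MEAN, VALENCE_SD = 10.16, 16.0
AROUSAL_MEAN, AROUSAL_SD = 6.40, 18.0

_BASE_LEXICON = [
    "calm", "tired", "happy", "relaxed", "bored", "content", "excited",
    "anxious", "annoyed", "stressed", "sad", "focused", "uncomfortable",
    "curious", "amused", "frustrated", "hopeful", "lonely", "grateful",
    "nervous", "angry", "peaceful", "surprised", "distracted", "confident",
    "worried", "cheerful", "restless", "proud", "embarrassed", "afraid",
    "interested", "disappointed", "energetic", "sleepy", "irritated",
]


# ---------------------------------------------------------------------------
# participant truth
# ---------------------------------------------------------------------------

@dataclass
class ParticipantTruth:
    """Ground-truth generative model for one simulated participant."""

    participant_id: str
    K: int
    mixture_weights: np.ndarray          # (K,), sums to 1
    component_means: np.ndarray          # (K, 6), raw change-score units
    component_covariances: np.ndarray    # (K, 6, 6), positive definite
    vocabulary: list
    word_affinity: np.ndarray            # (|vocab|, K), nonnegative
    rating_model: dict                   # per-cluster valence/arousal (mean, sd)
    posture_probs: dict
    seed: int

    def __post_init__(self) -> None:
        self.mixture_weights = np.asarray(self.mixture_weights, dtype=float)
        if abs(self.mixture_weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if self.component_means.shape != (self.K, len(FEATURE_NAMES)):
            raise ValueError("component_means must be K x 6")
        for k in range(self.K):
            np.linalg.cholesky(self.component_covariances[k])  # PD check
        for means in (self.rating_model["valence_mean"],
                      self.rating_model["arousal_mean"]):
            if np.any(np.abs(np.asarray(means)) > 50):
                raise ValueError("rating means must lie within [-50, 50]")


def generate_participant_truth(seed: int, separation: float = 5.0,
                               k_range: tuple = (3, 8),
                               specificity: float = 0.0,
                               vocab_size: Optional[int] = None,
                               posture_probs: Optional[dict] = None,
                               participant_id: Optional[str] = None,
                               equal_weights: bool = False,
                               ) -> ParticipantTruth:
    """Draw a ground-truth mixture for one participant.

    ``separation`` is the minimum pairwise Mahalanobis distance between
    component means in pooled-SD units; means are placed at random directions
    and rescaled so the minimum pairwise distance equals it exactly (K >= 2).
    ``specificity`` in [0, 1] interpolates the word-cluster affinity from
    near-uniform (the same words span all clusters, a many-to-many mapping)
    to fully disjoint blocks, and likewise scales between-cluster shifts of
    the rating model (0 = identical affect across clusters; 1 = means spread
    1.5 rating-SDs apart).
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    if not (1 <= k_range[0] <= k_range[1] <= 20):
        raise ValueError("k_range must lie within [1, 20]")
    rng = np.random.default_rng(seed)
    K = int(rng.integers(k_range[0], k_range[1] + 1))

    if equal_weights:
        weights = np.full(K, 1.0 / K)
    else:
        weights = rng.dirichlet(np.full(K, 5.0))
    weights = weights / weights.sum()

    # component means: random directions scaled to the requested separation
    u = rng.normal(size=(K, len(FEATURE_NAMES)))
    if K >= 2:
        d = np.sqrt(((u[:, None, :] - u[None, :, :]) ** 2).sum(-1))
        mind = d[np.triu_indices(K, 1)].min()
        u = u * (separation / max(mind, 1e-12))
    else:
        u = np.zeros_like(u)
    means = u * FEATURE_SCALES

    jitter = rng.uniform(0.7, 1.0, size=(K, len(FEATURE_NAMES)))
    covs = np.stack([np.diag((FEATURE_SCALES * jitter[k]) ** 2)
                     for k in range(K)])

    if vocab_size is None:
        vocab_size = int(np.clip(rng.lognormal(np.log(29.0), 0.6), 9, 147))
    vocab = list(_BASE_LEXICON[:vocab_size])
    vocab += [f"feeling{i:03d}" for i in range(len(vocab), vocab_size)]
    zipf = 1.0 / np.arange(1, vocab_size + 1)
    uniform_aff = np.tile(zipf[:, None], (1, K))
    blocks = np.zeros((vocab_size, K))
    blocks[np.arange(vocab_size), np.arange(vocab_size) % K] = 1.0
    affinity = (1 - specificity) * uniform_aff \
        + specificity * (zipf[:, None] * blocks * K)

    shift = specificity * 1.5
    offsets = (np.arange(K) - (K - 1) / 2.0)
    rating_model = {
        "valence_mean": np.clip(VALENCE_MEAN + shift * VALENCE_SD * offsets,
                                -50, 50),
        "valence_sd": np.full(K, VALENCE_SD),
        "arousal_mean": np.clip(AROUSAL_MEAN + shift * AROUSAL_SD * offsets,
                                -50, 50),
        "arousal_sd": np.full(K, AROUSAL_SD),
    }
    return ParticipantTruth(
        participant_id=participant_id or f"sim{seed}",
        K=K, mixture_weights=weights, component_means=means,
        component_covariances=covs, vocabulary=vocab, word_affinity=affinity,
        rating_model=rating_model,
        posture_probs=dict(posture_probs or DEFAULT_POSTURE_PROBS),
        seed=int(seed),
    )


def generate_events(truth: ParticipantTruth, n_events: int) -> list:
    """Sample feature-level events from a participant's truth mixture.

    Each event draws a true component, a 6-D raw change score, at least one
    word (propensity = word_affinity column of its component, intensities
    uniform 1-5), ratings from the component's affect model truncated to
    [-50, 50], and a posture.  Deterministic given the truth's seed.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng([truth.seed, 0x5EED])
    comps = rng.choice(truth.K, size=n_events, p=truth.mixture_weights)
    postures = list(truth.posture_probs)
    pp = np.array([truth.posture_probs[p] for p in postures])
    pp = pp / pp.sum()
    events = []
    for i, k in enumerate(comps):
        change = rng.multivariate_normal(truth.component_means[k],
                                         truth.component_covariances[k])
        n_words = 1 + rng.poisson(0.7)
        prob = truth.word_affinity[:, k]
        prob = prob / prob.sum()
        n_words = min(n_words, np.count_nonzero(prob))
        widx = rng.choice(len(truth.vocabulary), size=n_words, replace=False,
                          p=prob)
        words = [(truth.vocabulary[w], int(rng.integers(1, 6))) for w in widx]
        val = float(np.clip(rng.normal(truth.rating_model["valence_mean"][k],
                                       truth.rating_model["valence_sd"][k]),
                            -50, 50))
        aro = float(np.clip(rng.normal(truth.rating_model["arousal_mean"][k],
                                       truth.rating_model["arousal_sd"][k]),
                            -50, 50))
        events.append(Event(
            participant_id=truth.participant_id, event_id=i,
            prompt_time=float(300.0 * (i + 1)), change=change,
            valence=val, arousal=aro, words=words,
            posture=postures[int(rng.choice(len(postures), p=pp))],
            true_component=int(k),
        ))
    return events


def generate_zspace_mixture(seed: int, K: int, separation: float,
                            n: int, dim: int = 6) -> tuple:
    """Unit-covariance Gaussian mixture directly on the standardized scale.

    Component means are placed so the minimum pairwise distance equals
    ``separation`` within-component SDs; weights are equal.  This is the
    cluster-recovery harness: the returned matrix is what the DP-GMM fitter
    consumes, with true labels for scoring.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(K, dim))
    if K >= 2:
        d = np.sqrt(((u[:, None, :] - u[None, :, :]) ** 2).sum(-1))
        u = u * (separation / max(d[np.triu_indices(K, 1)].min(), 1e-12))
    else:
        u = np.zeros_like(u)
    labels = rng.integers(0, K, size=n)
    Z = rng.normal(size=(n, dim)) + u[labels]
    return Z, labels


# ---------------------------------------------------------------------------
# raw signal generation
# ---------------------------------------------------------------------------

@dataclass
class IcgParams:
    """Scripted ICG morphology: fiducial offsets and amplitudes."""

    pep_ms: float = 100.0       # R to B
    lvet_ms: float = 300.0      # B to X
    dzdt_max: float = 1.0       # ohm/s at the ejection peak
    z0: float = 30.0            # basal impedance, ohm
    x_depth_frac: float = 0.3   # X trough depth relative to dzdt_max
    recovery_ms: float = 80.0   # X back to baseline


@dataclass
class RawRecording:
    """Synchronized 500 Hz streams with optional ground-truth annotations."""

    fs: float
    ecg: np.ndarray                    # microvolt
    dzdt: np.ndarray                   # ohm/s
    z0: np.ndarray                     # ohm
    accel: np.ndarray                  # (3, N), cm/s^2
    torso_angle: np.ndarray            # degrees from vertical
    thigh_angle: np.ndarray            # degrees from vertical
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.ecg.size
        for name in ("dzdt", "z0", "torso_angle", "thigh_angle"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length differs from ecg")
        if self.accel.shape != (3, n):
            raise ValueError("accel must be 3 x N")
        for key in ("r_peak_times", "b_point_times", "x_point_times"):
            t = np.asarray(self.truth.get(key, []))
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"truth {key} must be strictly increasing")

    @property
    def duration(self) -> float:
        return self.ecg.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.ecg.size) / self.fs


def make_ibi_trajectory(duration_s: float, base_ms: float = 1000.0,
                        rsa_amplitude_ms: float = 0.0,
                        rsa_freq_hz: float = 0.25,
                        ramps: Sequence[tuple] = ()) -> np.ndarray:
    """Beat-wise IBI series: a base level, sinusoidal respiratory modulation
    within the 0.12-0.4 Hz band, and optional scripted linear ramps
    ``(t_start_s, t_end_s, delta_ms)`` added over their span."""
    ibi, t = [], 0.0
    while t < duration_s:
        v = base_ms + rsa_amplitude_ms * np.sin(2 * np.pi * rsa_freq_hz * t)
        for (a, b, delta) in ramps:
            if t >= b:
                v += delta
            elif t > a:
                v += delta * (t - a) / (b - a)
        ibi.append(v)
        t += v / 1000.0
    return np.asarray(ibi)


def _half_cos(n: int) -> np.ndarray:
    """Rise from 0 to 1 with curvature maximal at the first sample."""
    return (1.0 - np.cos(np.pi * np.arange(n) / max(n - 1, 1))) / 2.0


def generate_raw_recording(ibi_trajectory: Sequence[float],
                           icg_params: Optional[IcgParams] = None,
                           duration: Optional[float] = None,
                           seed: int = 0, fs: float = 500.0,
                           ecg_noise_sd: float = 0.0,
                           motion_epochs: Sequence[tuple] = (),
                           posture_script: Sequence[tuple] = (),
                           start_s: float = 0.5) -> RawRecording:
    """Build raw streams from a beat-level script.

    ECG is a train of Mexican-hat (Ricker) QRS pulses at cumulative IBI
    times — only R-peak timing needs to be recoverable.  Each dZ/dt beat is
    a half-cosine upstroke whose foot (curvature maximum) sits exactly at
    R + PEP, an ejection peak, and a trough exactly at B + LVET, so the
    generated annotations place B/X extrema at the requested offsets.
    ``motion_epochs`` are ``(t0, t1, amplitude)`` bursts on the
    accelerometer; ``posture_script`` are ``(t, torso_deg, thigh_deg)`` step
    changes (default: sitting, torso 0 deg / thigh 90 deg).
    """
    ibi = np.asarray(ibi_trajectory, dtype=float)
    if np.any((ibi < 300) | (ibi > 2000)):
        raise ValueError("IBI values must lie within [300, 2000] ms")
    p = icg_params or IcgParams()
    rng = np.random.default_rng(seed)

    r_times = start_s + np.concatenate(([0.0], np.cumsum(ibi[:-1]) / 1000.0))
    if duration is None:
        duration = float(r_times[-1] + 1.5)
    n = int(round(duration * fs))
    tgrid = np.arange(n) / fs
    r_times = r_times[r_times < duration - (p.pep_ms + p.lvet_ms
                                            + p.recovery_ms) / 1000.0 - 0.05]

    # ECG: Ricker pulses, ~20 ms wide, 800 uV
    ecg = np.zeros(n)
    width = int(0.01 * fs)
    qrs = sps_ricker(8 * width + 1, width)
    qrs = 800.0 * qrs / qrs.max()
    half = qrs.size // 2
    for rt in r_times:
        c = int(round(rt * fs))
        lo, hi = c - half, c + half + 1
        s0, s1 = max(lo, 0), min(hi, n)
        ecg[s0:s1] += qrs[s0 - lo: qrs.size - (hi - s1)]
    if ecg_noise_sd > 0:
        ecg = ecg + rng.normal(0.0, ecg_noise_sd, size=n)

    # dZ/dt beat morphology
    dzdt = np.zeros(n)
    rise = int(round(0.4 * p.lvet_ms / 1000.0 * fs))
    fall = int(round(0.6 * p.lvet_ms / 1000.0 * fs))
    rec = int(round(p.recovery_ms / 1000.0 * fs))
    up = p.dzdt_max * _half_cos(rise + 1)
    down = p.dzdt_max - (p.dzdt_max * (1 + p.x_depth_frac)) * _half_cos(fall + 1)
    back = -p.x_depth_frac * p.dzdt_max * (1.0 - _half_cos(rec + 1))
    beat = np.concatenate([up, down[1:], back[1:]])
    for rt in r_times:
        b0 = int(round((rt + p.pep_ms / 1000.0) * fs))
        s1 = min(b0 + beat.size, n)
        if b0 >= 0 and s1 > b0:
            dzdt[b0:s1] += beat[: s1 - b0]

    z0 = np.full(n, p.z0)
    accel = np.zeros((3, n))
    for (a, b, amp) in motion_epochs:
        accel[0, (tgrid >= a) & (tgrid < b)] += amp
    torso = np.zeros(n)
    thigh = np.full(n, 90.0)
    for (t, to, th) in posture_script:
        m = tgrid >= t
        torso[m] = to
        thigh[m] = th

    b_times = r_times + p.pep_ms / 1000.0
    x_times = b_times + p.lvet_ms / 1000.0
    return RawRecording(
        fs=fs, ecg=ecg, dzdt=dzdt, z0=z0, accel=accel,
        torso_angle=torso, thigh_angle=thigh,
        truth={
            "r_peak_times": np.round(r_times * fs) / fs,
            "b_point_times": b_times, "x_point_times": x_times,
            "ibi_trajectory": ibi,
        },
    )


def sps_ricker(points: int, a: float) -> np.ndarray:
    """Ricker (Mexican-hat) wavelet."""
    t = np.arange(points) - (points - 1) / 2.0
    amp = 2.0 / (np.sqrt(3 * a) * np.pi ** 0.25)
    return amp * (1 - (t / a) ** 2) * np.exp(-0.5 * (t / a) ** 2)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_recording_csv(rec: RawRecording, path) -> None:
    """Columnar CSV (one row per sample) plus a JSON annotation sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "t": rec.times, "ecg": rec.ecg, "dzdt": rec.dzdt, "z0": rec.z0,
        "ax": rec.accel[0], "ay": rec.accel[1], "az": rec.accel[2],
        "torso_angle": rec.torso_angle, "thigh_angle": rec.thigh_angle,
    })
    df.to_csv(path, index=False, float_format="%.6g")
    sidecar = {k: np.asarray(v).tolist() for k, v in rec.truth.items()}
    sidecar["fs"] = rec.fs
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_recording_csv(path) -> RawRecording:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(".json")
    truth, fs = {}, None
    if sidecar_path.exists():
        truth = json.loads(sidecar_path.read_text())
        fs = truth.pop("fs", None)
        truth = {k: np.asarray(v) for k, v in truth.items()}
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(df["t"].to_numpy())))
    return RawRecording(
        fs=float(fs), ecg=df["ecg"].to_numpy(), dzdt=df["dzdt"].to_numpy(),
        z0=df["z0"].to_numpy(),
        accel=np.vstack([df["ax"], df["ay"], df["az"]]),
        torso_angle=df["torso_angle"].to_numpy(),
        thigh_angle=df["thigh_angle"].to_numpy(), truth=truth,
    )


def events_to_frames(events: list) -> tuple:
    """(header, word) DataFrames: one row per event, one per (event, word)."""
    head = pd.DataFrame([{
        "participant": e.participant_id, "event_id": e.event_id,
        "prompt_time": e.prompt_time, "valence": e.valence,
        "arousal": e.arousal, "posture": e.posture, "quality": e.quality,
        "true_component": e.true_component,
        **{f"change_{f}": (e.change[j] if e.change is not None else np.nan)
           for j, f in enumerate(FEATURE_NAMES)},
    } for e in events])
    rows = [{"participant": e.participant_id, "event_id": e.event_id,
             "word": w, "intensity": i}
            for e in events for (w, i) in e.words]
    return head, pd.DataFrame(rows, columns=["participant", "event_id",
                                             "word", "intensity"])


def events_from_frames(head: pd.DataFrame, words: pd.DataFrame) -> list:
    by_event = {}
    for _, r in words.iterrows():
        by_event.setdefault((r["participant"], r["event_id"]), []).append(
            (str(r["word"]), int(r["intensity"])))
    out = []
    for _, r in head.iterrows():
        change = np.array([r[f"change_{f}"] for f in FEATURE_NAMES])
        tc = r.get("true_component")
        out.append(Event(
            participant_id=str(r["participant"]), event_id=int(r["event_id"]),
            prompt_time=float(r["prompt_time"]), change=change,
            valence=float(r["valence"]), arousal=float(r["arousal"]),
            posture=str(r["posture"]), quality=str(r["quality"]),
            words=by_event.get((r["participant"], r["event_id"]), []),
            true_component=None if pd.isna(tc) else int(tc),
        ))
    return out
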