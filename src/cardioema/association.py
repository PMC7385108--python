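"""Word, affect, and context associations with physiological clusters.

Because cluster membership is probabilistic, each event's emotion words and
ratings are spread over clusters with its membership weights; soft mass that
falls outside retained clusters accumulates in an unclustered ("UC")
column, so per-word mass always sums to the number of events containing the
word.  Hypothesis tests (Kruskal-Wallis for ratings, chi-square for
categorical context) use hard max-probability assignments and are
deliberately uncorrected for multiple comparisons.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import UNCLUSTERED, ClusterSolution

_PUNCT = str.maketrans("", "", string.punctuation)


def normalize_word(word: str) -> str:
    """Lowercase and strip punctuation; no stemming."""
    return word.strip().lower().translate(_PUNCT)


@dataclass
class WordStats:
    n_unique_words: int
    mean_clusters_per_word: float
    mean_pct_clusters_per_word: float
    mean_pct_unique_words_per_cluster: float
    per_word: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_cluster: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class AffectByCluster:
    cluster_summary: pd.DataFrame   # weighted means and ranges per cluster
    valence_H: float = np.nan
    valence_p: float = np.nan
    arousal_H: float = np.nan
    arousal_p: float = np.nan
    reason: str = ""


def weighted_word_counts(events: list, sol: ClusterSolution) -> pd.DataFrame:
    """Word x cluster soft-weight matrix (retained clusters + a UC column).

    weight(w, k) = sum over events containing w of that event's membership
    in k; the event's mass outside retained clusters goes to UC.
    """
    usable = [e for e in events if e.quality == "usable"]
    if len(usable) != sol.n_events:
        raise ValueError("events not aligned with membership rows")
    cols = list(sol.retained_ids) + [UNCLUSTERED]
    rows: dict = {}
    for i, e in enumerate(usable):
        p = sol.membership[i]
        uc = 1.0 - p[sol.retained_ids].sum()
        for w in {normalize_word(w) for w, _ in e.words}:
            acc = rows.setdefault(w, np.zeros(len(cols)))
            acc[:-1] += p[sol.retained_ids]
            acc[-1] += uc
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "word"
    return df.sort_index()


def word_stats(weights: pd.DataFrame, threshold: float = 1.0) -> WordStats:
    """Consistency/specificity summary of word usage across clusters.

    A word "labels" a cluster when its soft weight there reaches
    ``threshold`` (one event-equivalent by default).  The UC column never
    counts as a cluster.  Per-word means are unweighted over unique words.
    """
    clusters = [c for c in weights.columns if c != UNCLUSTERED]
    if not clusters:
        raise ValueError("need at least one retained cluster")
    K = len(clusters)
    used = weights[clusters] >= threshold
    n_per_word = used.sum(axis=1)
    words_per_cluster = used.sum(axis=0)
    n_words = len(weights)
    per_word = pd.DataFrame({"n_clusters": n_per_word,
                             "pct_clusters": 100.0 * n_per_word / K})
    per_cluster = pd.DataFrame({
        "n_words": words_per_cluster,
        "pct_unique_words": 100.0 * words_per_cluster / max(n_words, 1)})
    return WordStats(
        n_unique_words=n_words,
        mean_clusters_per_word=float(n_per_word.mean()) if n_words else np.nan,
        mean_pct_clusters_per_word=(float(per_word["pct_clusters"].mean())
                                    if n_words else np.nan),
        mean_pct_unique_words_per_cluster=float(
            per_cluster["pct_unique_words"].mean()),
        per_word=per_word, per_cluster=per_cluster,
    )


def affect_by_cluster(events: list, sol: ClusterSolution,
                      alpha: float = 0.05) -> AffectByCluster:
    """Weighted affect summaries per cluster plus Kruskal-Wallis tests.

    The tests group valence (and separately arousal) by hard max-probability
    retained cluster, excluding UC events, and require at least two groups
    with two events each; otherwise the test is reported missing with a
    reason.  Within-cluster ranges use the hard-assigned events.
    """
    usable = [e for e in events if e.quality == "usable"]
    labels = sol.hard_labels()
    rows = []
    for k in sol.retained_ids:
        w = sol.membership[:, k]
        v = np.array([e.valence for e in usable])
        a = np.array([e.arousal for e in usable])
        hard = np.array([lab == k for lab in labels])
        rows.append({
            "cluster": k,
            "weighted_valence": float((w * v).sum() / w.sum()),
            "weighted_arousal": float((w * a).sum() / w.sum()),
            "valence_range": float(v[hard].max() - v[hard].min())
            if hard.any() else np.nan,
            "arousal_range": float(a[hard].max() - a[hard].min())
            if hard.any() else np.nan,
            "n_hard": int(hard.sum()),
        })
    out = AffectByCluster(cluster_summary=pd.DataFrame(rows))

    groups_v, groups_a = [], []
    for k in sol.retained_ids:
        sel = [i for i, lab in enumerate(labels) if lab == k]
        if len(sel) >= 2:
            groups_v.append([usable[i].valence for i in sel])
            groups_a.append([usable[i].arousal for i in sel])
    if len(groups_v) < 2:
        out.reason = "fewer-than-2-groups"
        return out
    for name, groups in (("valence", groups_v), ("arousal", groups_a)):
        flat = np.concatenate(groups)
        if np.all(flat == flat[0]):  # identical ratings: no variation at all
            H, p = 0.0, 1.0
        else:
            H, p = stats.kruskal(*groups)
        setattr(out, f"{name}_H", float(H))
        setattr(out, f"{name}_p", float(p))
    return out


def context_by_cluster(events: list, sol: ClusterSolution,
                       feature: str = "posture") -> Optional[dict]:
    """Chi-square test and Cramér's V for a categorical context feature.

    Builds the hard-cluster x category contingency table (UC excluded).
    Degenerate tables (a single cluster or a single category) have V = 0
    and no test; an empty table returns None.
    """
    usable = [e for e in events if e.quality == "usable"]
    labels = sol.hard_labels()
    pairs = [(lab, getattr(e, feature)) for lab, e in zip(labels, usable)
             if lab != UNCLUSTERED]
    if not pairs:
        return None
    tab = pd.crosstab(pd.Series([p[0] for p in pairs], name="cluster"),
                      pd.Series([p[1] for p in pairs], name=feature))
    n = tab.to_numpy().sum()
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return {"table": tab, "chi2": np.nan, "p": np.nan, "dof": 0,
                "cramers_v": 0.0}
    chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    v = float(np.sqrt(chi2 / (n * (min(tab.shape) - 1))))
    return {"table": tab, "chi2": float(chi2), "p": float(p), "dof": int(dof),
            "cramers_v": v}


def significant_fraction(p_values, alpha: float = 0.05) -> float:
    """Percentage of finite p-values below alpha (uncorrected)."""
    p = np.asarray([x for x in p_values if np.isfinite(x)], dtype=float)
    if p.size == 0:
        return float("nan")
    return float(100.0 * (p < alpha).sum() / p.size)
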