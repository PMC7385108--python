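"""Effect sizes, change classification, pattern mining, and autonomic modes.

Each retained cluster is summarized by six effect sizes d = m / sigma,
where m is the cluster's weighted mean raw change for a feature and sigma
the participant's SD of that feature's change scores over all analyzed
events (a one-sample Cohen's d against "no change").  Rounded to one
decimal (half away from zero), each d maps to a symbol: 'nc' inside
(-0.2, 0.2), '+' at or above 0.2, '-' at or below -0.2, giving a 6-symbol
pattern code in the fixed order IBI RSA PEP LVET SV CO.  Identical codes
across participants are the "common patterns"; RSA and PEP effect sizes
further classify parasympathetic (PNS) and sympathetic (SNS) change — PEP
is an *inverse* SNS indicator — and their combination places each cluster
in an autonomic-space mode (reciprocal, coactivation, coinhibition,
uncoupled, negligible).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signals import FEATURE_NAMES

SYMBOLS = ("-", "nc", "+")
MAGNITUDES = ("negligible", "small", "medium", "large")

#: change / magnitude cuts on |rounded d|
CHANGE_CUT = 0.2
MAGNITUDE_CUTS = (0.2, 0.5, 0.8)


@dataclass(frozen=True)
class PatternCode:
    """Six {-, nc, +} symbols in feature order, with magnitude labels."""

    symbols: tuple
    magnitudes: tuple

    def __post_init__(self) -> None:
        if len(self.symbols) != len(FEATURE_NAMES):
            raise ValueError("pattern code must have 6 symbols")

    def __str__(self) -> str:
        return " ".join(self.symbols)


@dataclass(frozen=True)
class AutonomicClass:
    pns: str   # 'activation' | 'withdrawal' | 'negligible'
    sns: str
    mode: str  # 'reciprocal' | 'coactivation' | 'coinhibition'
    #            | 'uncoupled' | 'negligible'


def effect_size(m: float, sigma: float) -> float:
    """One-sample standardized change: d = (m - 0) / sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return m / sigma


def round_half_away(d: float, decimals: int = 1) -> float:
    """Round half away from zero (0.15 -> 0.2, -0.15 -> -0.2)."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(d) * scale + 0.5), d) / scale


def classify_change(d: float) -> tuple:
    """(symbol, magnitude) of an effect size, after rounding to one decimal.

    'nc' covers the open interval (-0.2, 0.2); |rounded d| >= 0.2 is a
    change ('+' or '-').  Magnitudes follow the conventional 0.2/0.5/0.8
    cuts on |rounded d|.
    """
    if not np.isfinite(d):
        raise ValueError("effect size must be finite")
    r = round_half_away(d)
    if abs(r) < CHANGE_CUT:
        symbol = "nc"
    else:
        symbol = "+" if r > 0 else "-"
    a = abs(r)
    if a < MAGNITUDE_CUTS[0]:
        mag = "negligible"
    elif a < MAGNITUDE_CUTS[1]:
        mag = "small"
    elif a < MAGNITUDE_CUTS[2]:
        mag = "medium"
    else:
        mag = "large"
    return symbol, mag


def pattern_code(d_values: Sequence[float]) -> PatternCode:
    """Classify all six effect sizes in the fixed feature order."""
    if len(d_values) != len(FEATURE_NAMES):
        raise ValueError("need one effect size per feature")
    pairs = [classify_change(d) for d in d_values]
    return PatternCode(tuple(s for s, _ in pairs), tuple(m for _, m in pairs))


def find_common_patterns(codes: Sequence[PatternCode],
                         min_freq: int = 2) -> pd.DataFrame:
    """Exact-string duplicate mining of pattern codes across all clusters.

    Relative frequency is expressed against the *total* number of clusters
    (not only those above the cut), rounded to two decimals.
    """
    if not codes:
        raise ValueError("need at least one pattern code")
    total = len(codes)
    counts = Counter(str(c) for c in codes)
    rows = [{"pattern": patt, "freq": freq,
             "rel_freq_pct": round(100.0 * freq / total, 2)}
            for patt, freq in counts.items() if freq >= min_freq]
    df = pd.DataFrame(rows, columns=["pattern", "freq", "rel_freq_pct"])
    return df.sort_values(["freq", "pattern"],
                          ascending=[False, True]).reset_index(drop=True)


def classify_ans_branch(rsa_d: float, pep_d: float) -> tuple:
    """(PNS class, SNS class) from RSA and PEP effect sizes.

    RSA is a direct PNS indicator: d >= 0.2 activation, d <= -0.2
    withdrawal.  PEP is inverse for the SNS: d >= 0.2 (longer PEP) is SNS
    withdrawal, d <= -0.2 activation.  Both use the rounded-d rule.
    """
    rsa_sym, _ = classify_change(rsa_d)
    pep_sym, _ = classify_change(pep_d)
    pns = {"+": "activation", "-": "withdrawal", "nc": "negligible"}[rsa_sym]
    sns = {"+": "withdrawal", "-": "activation", "nc": "negligible"}[pep_sym]
    return pns, sns


def classify_autonomic_mode(pns: str, sns: str) -> str:
    """Autonomic-space mode from the two branch classes."""
    if pns == "negligible" and sns == "negligible":
        return "negligible"
    if pns == "negligible" or sns == "negligible":
        return "uncoupled"
    if pns == sns:
        return "coactivation" if pns == "activation" else "coinhibition"
    return "reciprocal"


def autonomic_class(rsa_d: float, pep_d: float) -> AutonomicClass:
    pns, sns = classify_ans_branch(rsa_d, pep_d)
    return AutonomicClass(pns, sns, classify_autonomic_mode(pns, sns))


def branch_proportion_test(branch_classes: Sequence[tuple]) -> Optional[dict]:
    """Chi-square test of independence on the 2 x 3 branch-by-class table.

    Rows are the PNS and SNS branches; columns count clusters classified as
    withdrawal, activation, or negligible in that branch (df = 2).  Returns
    None for degenerate tables with an all-zero margin.
    """
    if len(branch_classes) < 2:
        raise ValueError("need at least 2 clusters")
    cats = ("withdrawal", "activation", "negligible")
    tab = np.array([[sum(p == c for p, _ in branch_classes) for c in cats],
                    [sum(s == c for _, s in branch_classes) for c in cats]],
                   dtype=float)
    keep = tab.sum(axis=0) > 0
    tab = tab[:, keep]
    if tab.shape[1] < 2 or np.any(tab.sum(axis=1) == 0):
        return None
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p),
            "table": pd.DataFrame(tab, index=["pns", "sns"],
                                  columns=np.array(cats)[keep])}


def pattern_word_join(pattern_table: pd.DataFrame, cluster_codes: dict,
                      cluster_word_weights: dict, top_n: int = 5) -> dict:
    """Most frequent words per common pattern.

    For each pattern, the top-``top_n`` words (by soft weight, ties broken
    lexicographically) of every matching cluster are pooled; the result maps
    pattern string -> DataFrame of words with the number of matching
    clusters whose top list contains each word.
    """
    out = {}
    for patt in pattern_table["pattern"]:
        counts: Counter = Counter()
        for cid, code in cluster_codes.items():
            if str(code) != patt:
                continue
            weights = cluster_word_weights.get(cid)
            if weights is None or len(weights) == 0:
                continue
            top = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
            counts.update(w for w, _ in top)
        df = pd.DataFrame(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
                          columns=["word", "n_clusters"])
        out[patt] = df
    return out
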