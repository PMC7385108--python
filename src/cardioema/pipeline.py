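"""End-to-end orchestration with deterministic seeding.

The default path is feature-level: simulate per-participant event sets with
known mixture structure, standardize within person, fit the DP-GMM, then
run the word/affect association and cross-participant pattern analyses,
writing every table as CSV and every solution as JSON.  Raw-signal stages
(waveform simulation, triggering, feature extraction) are available through
their modules and the CLI for recording-level work.

Seeding rule: every stochastic stage receives a child of the master seed
via ``numpy.random.SeedSequence(master).spawn``; participant i's generator
seed is ``spawn[i].generate_state(1)[0] % 2**31``.  Identical configs give
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import association, clustering, patterns, synthdata
from .events import change_matrix, filter_participants, standardize_within_person
from .signals import FEATURE_NAMES

REQUIRED_KEYS = ("seed", "n_participants", "n_events")


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 5
    n_events: int = 100
    separation: float = 5.0
    k_range: tuple = (3, 8)
    specificity: float = 0.0
    min_cluster_frac: float = clustering.MIN_CLUSTER_FRACTION
    min_usable_events: int = 70
    dpgmm: clustering.DPGMMConfig = field(
        default_factory=clustering.DPGMMConfig)
    outdir: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        for key in REQUIRED_KEYS:
            if key not in d:
                raise ValueError(f"missing config key: '{key}'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        if isinstance(d.get("dpgmm"), dict):
            d["dpgmm"] = clustering.DPGMMConfig(**d["dpgmm"])
        return cls(**d)


@dataclass
class RunReport:
    paths: dict
    summary: dict


def participant_seed(master_seed: int, index: int) -> int:
    children = np.random.SeedSequence(master_seed).spawn(index + 1)
    return int(children[index].generate_state(1)[0] % (2 ** 31))


def analyze_participant(events: list, dpgmm_cfg: clustering.DPGMMConfig,
                        min_frac: float = clustering.MIN_CLUSTER_FRACTION,
                        ) -> dict:
    """Cluster one participant's events and derive all per-cluster summaries."""
    standardize_within_person(events)
    Z = change_matrix(events, standardized=True)
    C = change_matrix(events, standardized=False)
    sol = clustering.fit_dpgmm(Z, dpgmm_cfg)
    clustering.retain_clusters(sol, min_frac)
    means = clustering.weighted_cluster_means(sol, C)
    sigma = C.std(axis=0, ddof=1)

    per_cluster = []
    for k, m in means.items():
        d = np.array([patterns.effect_size(m[j], sigma[j])
                      for j in range(len(FEATURE_NAMES))])
        code = patterns.pattern_code(d)
        ac = patterns.autonomic_class(d[1], d[2])  # rsa, pep
        per_cluster.append({
            "cluster": k,
            "size_fraction": float(sol.size_fractions[k]),
            **{f"mean_{f}": float(m[j]) for j, f in enumerate(FEATURE_NAMES)},
            **{f"d_{f}": float(d[j]) for j, f in enumerate(FEATURE_NAMES)},
            "code": str(code), "pns": ac.pns, "sns": ac.sns, "mode": ac.mode,
        })

    weights = association.weighted_word_counts(events, sol)
    wstats = association.word_stats(weights)
    affect = association.affect_by_cluster(events, sol)
    context = association.context_by_cluster(events, sol, "posture")
    return {"solution": sol, "clusters": per_cluster, "word_weights": weights,
            "word_stats": wstats, "affect": affect, "context": context,
            "quality": clustering.membership_quality(sol)}


def describe_pattern(pns: str, sns: str) -> str:
    """Templated branch summary used in the common-pattern table."""
    mode = patterns.classify_autonomic_mode(pns, sns)
    if mode == "negligible":
        return "Negligible change in PNS/SNS activity"
    parts = [f"PNS {pns}" if pns != "negligible" else "",
             f"SNS {sns}" if sns != "negligible" else ""]
    body = ", ".join(p for p in parts if p)
    return f"{body} ({mode})"


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Simulate, cluster, associate, and mine patterns for a whole cohort."""
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    all_events, results = {}, {}
    for i in range(cfg.n_participants):
        seed = participant_seed(cfg.seed, i)
        truth = synthdata.generate_participant_truth(
            seed, separation=cfg.separation, k_range=cfg.k_range,
            specificity=cfg.specificity, participant_id=f"p{i:03d}")
        all_events[truth.participant_id] = synthdata.generate_events(
            truth, cfg.n_events)

    included = filter_participants(
        [e for evs in all_events.values() for e in evs],
        min_events=cfg.min_usable_events)

    paths: dict = {}
    pooled_codes, pooled_branches, cluster_rows = [], [], []
    kw_valence_p, kw_arousal_p = [], []
    for pid in sorted(included):
        events = all_events[pid]
        res = analyze_participant(events, cfg.dpgmm, cfg.min_cluster_frac)
        results[pid] = res
        for row in res["clusters"]:
            row = {"participant": pid, **row}
            cluster_rows.append(row)
            pooled_codes.append(row["code"])
            pooled_branches.append((row["pns"], row["sns"]))
        kw_valence_p.append(res["affect"].valence_p)
        kw_arousal_p.append(res["affect"].arousal_p)
        if outdir:
            head, words = synthdata.events_to_frames(events)
            head.to_csv(outdir / f"events_{pid}.csv", index=False)
            words.to_csv(outdir / f"words_{pid}.csv", index=False)
            res["solution"].to_json(outdir / f"solution_{pid}.json")
            pd.DataFrame(res["solution"].membership).to_csv(
                outdir / f"membership_{pid}.csv", index=False)
            res["word_weights"].to_csv(outdir / f"word_weights_{pid}.csv")

    clusters_df = pd.DataFrame(cluster_rows)
    common = patterns.find_common_patterns(
        [_code_from_str(c) for c in pooled_codes], min_freq=2)
    if len(common):
        sym_map = {"+": "activation", "-": "withdrawal", "nc": "negligible"}
        inv_map = {"+": "withdrawal", "-": "activation", "nc": "negligible"}
        common["description"] = [
            describe_pattern(sym_map[c.split()[1]], inv_map[c.split()[2]])
            for c in common["pattern"]]
    branch = patterns.branch_proportion_test(pooled_branches) \
        if len(pooled_branches) >= 2 else None

    mode_counts = clusters_df["mode"].value_counts() if len(clusters_df) else {}
    summary = {
        "n_participants": cfg.n_participants,
        "n_included": len(included),
        "total_clusters": int(len(clusters_df)),
        "mean_clusters_per_person": float(
            clusters_df.groupby("participant").size().mean())
        if len(clusters_df) else np.nan,
        "mean_membership_quality": float(np.mean(
            [results[p]["quality"] for p in results])) if results else np.nan,
        "n_common_patterns": int(len(common)),
        "pct_valence_significant": association.significant_fraction(
            kw_valence_p),
        "pct_arousal_significant": association.significant_fraction(
            kw_arousal_p),
        "mode_fractions": {m: float(c / len(clusters_df))
                           for m, c in dict(mode_counts).items()},
        "branch_chi2": None if branch is None else branch["chi2"],
    }
    if outdir:
        clusters_df.to_csv(outdir / "clusters.csv", index=False)
        common.to_csv(outdir / "common_patterns.csv", index=False)
        if len(clusters_df):
            modes = clusters_df[["participant", "cluster", "d_rsa", "d_pep",
                                 "mode"]].copy()
            modes["pns_d"] = modes.pop("d_rsa")
            modes["sns_d"] = -modes.pop("d_pep")  # PEP is inverse for SNS
            modes.to_csv(outdir / "modes.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                        sort_keys=True))
        paths = {p.name: str(p) for p in sorted(outdir.iterdir())}
    return RunReport(paths=paths, summary=summary)


def _code_from_str(code_str: str) -> patterns.PatternCode:
    symbols = tuple(code_str.split())
    return patterns.PatternCode(symbols, tuple("negligible" for _ in symbols))


def load_flat_config(path) -> dict:
    """Flat ``key = value`` config file (ints/floats/tuples auto-coerced)."""
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if "," in value:
            out[key] = tuple(_coerce(v) for v in value.split(","))
        else:
            out[key] = _coerce(value)
    return out


def _coerce(v: str):
    v = v.strip()
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v
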