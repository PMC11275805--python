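"""Resistance / sensitivity classification and cross-inhibitor analysis.

Three classification strategies:

* **Resistance mutation** (per inhibitor): grows significantly faster
  than wild type under the inhibitor — one-sided test of beta_inh
  against the effect threshold 0.5 with tail-probability cutoff 0.1 —
  while growing no faster than wild type in the control
  (beta_DMSO <= 0).
* **Resistance position**: a position carrying at least one resistance
  mutation for that inhibitor.
* **GOF / LOF in the growth-rate-differential sense**: on the
  recentered score gamma = beta_inh - beta_DMSO, gain-of-function is
  gamma > 0.75 and loss-of-function gamma < 0.

Hotspot aggregation counts resistance (mutation, inhibitor) pairs per
position across all inhibitors of a type, and partitions resistance
variants into type-shared/exclusive sets (Venn over major types).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import RecenteredScores, ScoreTable, tail_probability
from .types import VARIANT_COLUMNS, ConditionMeta, VariantKey

__all__ = [
    "call_resistance", "resistance_positions", "classify_gof_lof",
    "classify_within_condition", "hotspot_counts", "HotspotSummary",
    "differential_pairs", "type_exclusive_resistance",
]


def call_resistance(scores_inh: ScoreTable, scores_dmso: ScoreTable,
                    tail_cutoff: float = 0.1,
                    effect_cutoff_beta: float = 0.5,
                    dmso_cutoff: float = 0.0,
                    gof_threshold: float = 0.75) -> pd.DataFrame:
    """Call inhibitor-specific resistance mutations.

    is_resistance(v) = [P(beta_inh < effect_cutoff) <= tail_cutoff]
    AND [beta_DMSO <= dmso_cutoff].  Synonymous variants are never
    resistant (they are the wild-type reference, beta == 0 by
    normalization).  Variants missing a DMSO score get an NA call.

    Returns a call table with ``is_resistance`` (nullable boolean),
    ``gamma`` and the differential GOF/LOF flags, one row per variant.
    """
    a = scores_inh.data[VARIANT_COLUMNS + ["beta", "se", "df"]]
    b = scores_dmso.data[VARIANT_COLUMNS + ["beta"]]
    m = a.merge(b, on=VARIANT_COLUMNS, how="left", suffixes=("_inh", "_dmso"))
    if m["beta_dmso"].isna().all():
        raise ValueError("no shared variants between inhibitor and DMSO scores")

    tail = tail_probability(m["beta_inh"].to_numpy(), m["se"].to_numpy(),
                            m["df"].to_numpy(), effect_cutoff_beta)
    m["tail_prob_resist"] = tail
    m["gamma"] = m["beta_inh"] - m["beta_dmso"]

    passes = (pd.Series(tail <= tail_cutoff, index=m.index)
              & (m["beta_dmso"] <= dmso_cutoff)
              & (m["var_class"] != "synonymous"))
    na = m["beta_dmso"].isna() | m["beta_inh"].isna()
    m["is_resistance"] = passes.astype("boolean").mask(na)

    gl = classify_gof_lof(m["gamma"], gof_threshold)
    m["gof"] = gl["gof"]
    m["lof"] = gl["lof"]
    m["inhibitor"] = scores_inh.condition.name
    return m


def classify_gof_lof(gamma: pd.Series, gof_threshold: float = 0.75) -> pd.DataFrame:
    """Differential-sensitivity flags on the recentered score: GOF iff
    gamma > threshold, LOF iff gamma < 0, neutral otherwise (mutually
    exclusive); NA gamma gives NA flags."""
    gamma = pd.Series(gamma).astype(float)
    na = gamma.isna()
    gof = (gamma > gof_threshold).astype("boolean").mask(na)
    lof = (gamma < 0).astype("boolean").mask(na)
    category = pd.Series(np.where(na, pd.NA,
                         np.where(gamma > gof_threshold, "GOF",
                                  np.where(gamma < 0, "LOF", "neutral"))),
                         index=gamma.index, dtype="object")
    return pd.DataFrame({"gof": gof, "lof": lof, "category": category})


def classify_within_condition(scores: ScoreTable, alpha: float = 0.05) -> pd.Series:
    """Single-condition GOF/LOF vs wild type: two-sided test of beta
    against 0, Benjamini-Hochberg corrected across variants at
    ``alpha``; significant positives are GOF, negatives LOF."""
    d = scores.data
    p_two = 2.0 * np.minimum(d["p_lt_wt"], d["p_gt_wt"]).clip(upper=0.5)
    ok = p_two.notna()
    q = np.full(len(d), np.nan)
    if ok.any():
        q[ok.to_numpy()] = stats.false_discovery_control(p_two[ok], method="bh")
    sig = q <= alpha
    lab = np.where(sig & (d["beta"] > 0), "GOF",
                   np.where(sig & (d["beta"] < 0), "LOF", "neutral"))
    return pd.Series(np.where(ok, lab, pd.NA), index=d.index, name="within_condition_class")


def resistance_positions(calls: pd.DataFrame) -> set[int]:
    """Positions carrying at least one resistance mutation."""
    res = calls[calls["is_resistance"] == True]  # noqa: E712 (nullable boolean)
    return set(res["position"].astype(int))


def _variant_keys(df: pd.DataFrame) -> set[VariantKey]:
    return {VariantKey(int(p), w, m, c) for p, w, m, c in
            zip(df["position"], df["wt_aa"], df["mut_aa"], df["var_class"])}


@dataclass
class HotspotSummary:
    """Per-(position, inhibitor-type) resistance-mutation counts plus
    the Venn partition of resistance variants over major types."""

    counts: pd.DataFrame                       # position, inhibitor_type, count
    shared_sets: dict[tuple[str, ...], set[VariantKey]]

    def count(self, position: int, inhibitor_type: str) -> int:
        c = self.counts
        sel = c[(c["position"] == position) & (c["inhibitor_type"] == inhibitor_type)]
        return int(sel["count"].sum())


def hotspot_counts(calls_by_inhibitor: Mapping[str, pd.DataFrame],
                   conditions: list[ConditionMeta]) -> HotspotSummary:
    """Aggregate resistance calls into per-type positional hotspots.

    Each resistant (mutation, inhibitor) pair contributes 1 to its
    position under the inhibitor's major type, summed over all
    inhibitors of that type.  The shared-set partition assigns a
    variant to a type combination iff it is resistant to >= 1 inhibitor
    of each type in the combination and none outside it.
    """
    meta = {c.name: c for c in conditions}
    for name in calls_by_inhibitor:
        if name not in meta:
            raise ValueError(f"no condition metadata for inhibitor {name!r}")
    types_present = sorted({meta[n].major_type for n in calls_by_inhibitor})

    positions = sorted(set().union(*(set(c["position"].astype(int))
                                     for c in calls_by_inhibitor.values())))
    tally: dict[tuple[int, str], int] = {(p, t): 0 for p in positions for t in types_present}
    per_type_sets: dict[str, set[VariantKey]] = {t: set() for t in types_present}
    for name, calls in calls_by_inhibitor.items():
        t = meta[name].major_type
        res = calls[calls["is_resistance"] == True]  # noqa: E712
        for p in res["position"].astype(int):
            tally[(p, t)] += 1
        per_type_sets[t] |= _variant_keys(res)

    counts = pd.DataFrame([(p, t, n) for (p, t), n in sorted(tally.items(),
                                                             key=lambda kv: (kv[0][1], kv[0][0]))],
                          columns=["position", "inhibitor_type", "count"])

    shared: dict[tuple[str, ...], set[VariantKey]] = {}
    for r in range(1, len(types_present) + 1):
        for combo in combinations(types_present, r):
            inside = set.intersection(*(per_type_sets[t] for t in combo))
            outside = set().union(*(per_type_sets[t] for t in types_present
                                    if t not in combo)) if len(combo) < len(types_present) else set()
            shared[combo] = inside - outside
    return HotspotSummary(counts, shared)


def differential_pairs(recentered_a: RecenteredScores, recentered_b: RecenteredScores,
                       calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                       gof_threshold: float = 0.75,
                       require_resistance: bool = True,
                       ) -> tuple[set[VariantKey], set[VariantKey]]:
    """Divergent-sensitivity variants for an inhibitor pair.

    First set: GOF under inhibitor a (gamma_a > threshold and, by
    default, a statistically filtered resistance call under a) and LOF
    under b (gamma_b < 0).  Second set is the mirror image.  Rows with
    NA on either side are excluded.
    """
    def side(rec_g, rec_l, calls_g):
        m = (rec_g.data[VARIANT_COLUMNS + ["gamma"]]
             .merge(rec_l.data[VARIANT_COLUMNS + ["gamma"]],
                    on=VARIANT_COLUMNS, suffixes=("_g", "_l"))
             .merge(calls_g[VARIANT_COLUMNS + ["is_resistance"]], on=VARIANT_COLUMNS))
        ok = m["gamma_g"].notna() & m["gamma_l"].notna()
        sel = ok & (m["gamma_g"] > gof_threshold) & (m["gamma_l"] < 0)
        if require_resistance:
            sel &= (m["is_resistance"] == True)  # noqa: E712
        return _variant_keys(m[sel])

    return (side(recentered_a, recentered_b, calls_a),
            side(recentered_b, recentered_a, calls_b))


def type_exclusive_resistance(calls_by_inhibitor: Mapping[str, pd.DataFrame],
                              conditions: list[ConditionMeta],
                              ) -> dict[str, set[VariantKey]]:
    """Variants resistant only to inhibitors of a single major type.

    A variant lands in type X's exclusive set iff it is a resistance
    mutation for >= 1 inhibitor of type X and for 0 inhibitors of any
    other type.
    """
    meta = {c.name: c for c in conditions}
    types_present = sorted({meta[n].major_type for n in calls_by_inhibitor})
    if len(types_present) < 2:
        raise ValueError("need >= 2 inhibitor types for exclusivity analysis")
    per_type: dict[str, set[VariantKey]] = {t: set() for t in types_present}
    for name, calls in calls_by_inhibitor.items():
        res = calls[calls["is_resistance"] == True]  # noqa: E712
        per_type[meta[name].major_type] |= _variant_keys(res)
    return {t: per_type[t] - set().union(*(per_type[u] for u in types_present if u != t))
            for t in types_present}
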