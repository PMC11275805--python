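"""Synthetic pooled-selection screen generator.

Emulates a saturation-mutagenesis library of a contiguous protein
region carried through a growth-based selection: every variant grows
exponentially at the wild-type rate plus its own fitness offset (log2
doublings per sampling interval), samples are sequenced to a fixed
depth at each of T timepoints in R replicates, and read counts are
drawn multinomially from the expected variant frequencies.  The
generator also fabricates per-(variant, inhibitor) feature tables with
the qualitative structure the downstream predictor assumes: a
language-model log-likelihood ratio correlated positively with control
fitness, a stability change correlated negatively, and position-level
structural features that are constant across mutations at a position.

The stated world (defaults) is: a bimodal control-fitness mixture
(neutral N(0, 0.15^2) with weight 0.6, deleterious N(-2, 0.4^2) with
weight 0.4), nonsense variants forced below the deleterious mean,
wild type doubling exactly twice per interval in every condition, a
uniform negative sensitivity shift (-1.5) for neutral variants under
inhibitors, and planted resistance (position, mutation) pairs that gain
+0.75..+1.5 doublings under inhibitors of the matching type only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTable
from .mlmodel import ALL_FEATURES
from .types import (AMINO_ACIDS, STOP, VARIANT_COLUMNS, ConditionMeta,
                    SimDesign, major_type)

__all__ = [
    "EffectParams", "build_library", "assign_true_scores",
    "simulate_counts", "simulate_feature_table", "random_wt_sequence",
]

# Residue van der Waals volumes (A^3), used for the delta-volume feature.
AA_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
    STOP: 0.0,
}


def random_wt_sequence(length: int, seed: int = 0) -> str:
    """Deterministic pseudo-random wild-type sequence (for demos/tests)."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def build_library(region_start: int, region_end: int, wt_sequence: str,
                  stop_spacing: int = 11) -> pd.DataFrame:
    """Enumerate the variant library over a contiguous region.

    Per position: 19 missense variants plus one synonymous
    (wild-type-identical) control; additionally one nonsense (stop)
    control at every ``stop_spacing``-th position, phase-anchored at
    ``region_start``.  Rows are ordered by position, then mutant
    residue alphabetically with ``*`` last.

    Returns a DataFrame with columns position, wt_aa, mut_aa, var_class.
    """
    if stop_spacing < 1:
        raise ValueError("stop_spacing must be >= 1")
    n_pos = region_end - region_start + 1
    if n_pos < 1:
        raise ValueError("region_end must be >= region_start")
    if len(wt_sequence) != n_pos:
        raise ValueError(
            f"wt_sequence length {len(wt_sequence)} does not match region "
            f"{region_start}-{region_end} ({n_pos} positions)")
    bad = set(wt_sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residue letters in wt_sequence: {sorted(bad)}")

    rows = []
    for i, wt in enumerate(wt_sequence):
        pos = region_start + i
        for mut in AMINO_ACIDS:
            cls = "synonymous" if mut == wt else "missense"
            rows.append((pos, wt, mut, cls))
        if i % stop_spacing == 0:
            rows.append((pos, wt, STOP, "nonsense"))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


@dataclass(frozen=True)
class EffectParams:
    """Distribution parameters for ground-truth fitness effects.

    Scores are log2 growth-rate offsets from wild type per sampling
    interval (0 = wild-type-like; -2 = not growing when wild type
    doubles twice per interval).
    """

    neutral_mean: float = 0.0
    neutral_sd: float = 0.15
    neutral_weight: float = 0.6
    deleterious_mean: float = -2.0
    deleterious_sd: float = 0.4
    #: nonsense variants sit this far below the deleterious mean (minus
    #: a half-normal jitter), guaranteeing "strongly negative".
    nonsense_offset: float = 0.3
    nonsense_jitter_sd: float = 0.2
    #: growth-rate penalty applied to neutral-component variants under
    #: inhibitors (wild-type rate minus inhibition).
    sensitivity_shift: float = -1.5
    #: planted resistance effects are drawn uniformly from this range.
    resistance_low: float = 0.75
    resistance_high: float = 1.5


def _resistant_mask(library: pd.DataFrame, pairs: set[tuple[int, str]]) -> np.ndarray:
    keys = list(zip(library["position"].to_numpy(), library["mut_aa"].to_numpy()))
    return np.array([k in pairs for k in keys], dtype=bool)


def assign_true_scores(library: pd.DataFrame, conditions: list[ConditionMeta],
                       resistance_spec: dict[str, set[tuple[int, str]]] | None = None,
                       effect_params: EffectParams = EffectParams(),
                       seed: int = 0) -> pd.DataFrame:
    """Draw ground-truth fitness effects per (variant, condition).

    Control (DMSO) scores come from the bimodal mixture; synonymous
    variants are exactly 0 everywhere, nonsense variants strictly below
    the deleterious-component mean.  Under an inhibitor, neutral
    variants receive the sensitivity shift, planted resistance pairs of
    the matching inhibitor type receive a positive effect (> 0.5) while
    their control score is forced <= 0, and deleterious variants keep
    their control score.

    Returns a long DataFrame: variant columns + ``condition`` +
    ``true_score``.
    """
    p = effect_params
    resistance_spec = resistance_spec or {}
    known = {c.inhibitor_type for c in conditions} | {c.major_type for c in conditions}
    for itype, pairs in resistance_spec.items():
        if itype not in known:
            raise ValueError(f"resistance_spec references unknown inhibitor type {itype!r}")
        region = (library["position"].min(), library["position"].max())
        for pos, _aa in pairs:
            if not region[0] <= pos <= region[1]:
                raise ValueError(f"resistance position {pos} outside library region {region}")

    rng = np.random.default_rng(seed)
    n = len(library)
    is_syn = (library["var_class"] == "synonymous").to_numpy()
    is_non = (library["var_class"] == "nonsense").to_numpy()

    all_res_pairs: set[tuple[int, str]] = set().union(*resistance_spec.values()) if resistance_spec else set()
    res_any = _resistant_mask(library, all_res_pairs)
    if (res_any & is_syn).any():
        import warnings
        warnings.warn("resistance_spec pairs matching the wild-type residue are "
                      "synonymous and stay at score 0 (never resistant)")
    res_any &= ~is_syn

    neutral = rng.random(n) < p.neutral_weight
    dmso = np.where(neutral,
                    rng.normal(p.neutral_mean, p.neutral_sd, n),
                    rng.normal(p.deleterious_mean, p.deleterious_sd, n))
    dmso[is_non] = (p.deleterious_mean - p.nonsense_offset
                    - np.abs(rng.normal(0.0, p.nonsense_jitter_sd, n)))[is_non]
    # planted resistance pairs: wild-type-like but never advantaged in
    # control; the 0.05 margin keeps the control score detectably <= 0
    dmso[res_any] = -(0.05 + np.abs(rng.normal(0.0, 0.1, n)))[res_any]
    neutral = neutral | res_any
    dmso[is_syn] = 0.0

    frames = []
    for cond in conditions:
        if cond.is_dmso:
            score = dmso.copy()
        else:
            score = dmso.copy()
            shift = neutral & ~is_syn & ~is_non
            score[shift] = dmso[shift] + p.sensitivity_shift
            pairs = set()
            for itype, pp in resistance_spec.items():
                if itype in (cond.inhibitor_type, cond.major_type):
                    pairs |= set(pp)
            res = _resistant_mask(library, pairs) & ~is_syn
            score[res] = rng.uniform(p.resistance_low, p.resistance_high, n)[res]
            score[is_syn] = 0.0
        out = library.copy()
        out["condition"] = cond.name
        out["true_score"] = score
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def _condition_seed(seed: int, name: str) -> np.random.SeedSequence:
    # crc32 keeps the derivation independent of PYTHONHASHSEED
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])


def simulate_counts(effects: pd.DataFrame, condition: ConditionMeta,
                    design: SimDesign,
                    initial_freqs: np.ndarray | None = None) -> CountTable:
    """Simulate a pooled-selection count table for one condition.

    Expected relative abundance of variant v at time index t (0..T-1)
    is proportional to ``freq0(v) * 2**((g_wt + true_score(v)) * t)``
    with g_wt the wild-type doublings per interval.  With
    ``noise_mode='none'`` the table holds depth-scaled expected
    abundances (real-valued, identical across replicates); with
    ``'multinomial'`` each (replicate, timepoint) sample is an
    independent multinomial draw of size ``depth``.
    """
    sub = effects[effects["condition"] == condition.name]
    if sub.empty:
        raise ValueError(f"no effects for condition {condition.name!r}")
    variants = sub[VARIANT_COLUMNS].reset_index(drop=True)
    s = sub["true_score"].to_numpy(float)
    n = len(s)
    if initial_freqs is None:
        f0 = np.full(n, 1.0 / n)
    else:
        f0 = np.asarray(initial_freqs, float)
        if f0.shape != (n,) or np.any(f0 < 0):
            raise ValueError("initial_freqs must be nonnegative, one per variant")
        f0 = f0 / f0.sum()

    g = condition.wt_doublings_per_interval
    T, R, depth = design.n_timepoints, design.n_replicates, design.depth
    t = np.arange(T)
    # growth in log2 space, normalized per timepoint to frequencies
    log2_ab = np.log2(f0)[:, None] + (g + s)[:, None] * t[None, :]
    log2_ab -= log2_ab.max(axis=0, keepdims=True)
    ab = np.exp2(log2_ab)
    probs = ab / ab.sum(axis=0, keepdims=True)          # (V, T)

    counts = np.empty((n, R, T), dtype=float)
    if design.noise_mode == "none":
        counts[:] = (depth * probs)[:, None, :]
    else:
        rng = np.random.default_rng(_condition_seed(design.seed, condition.name))
        for r in range(R):
            for ti in range(T):
                counts[:, r, ti] = rng.multinomial(depth, probs[:, ti])
    return CountTable(variants=variants, counts=counts, condition=condition)


def simulate_feature_table(library: pd.DataFrame,
                           inhibitors: list[ConditionMeta],
                           effects: pd.DataFrame,
                           seed: int = 0,
                           llr_noise_sd: float = 0.5,
                           ddg_noise_sd: float = 0.4) -> pd.DataFrame:
    """Fabricate the 14-feature table consumed by the predictor.

    Stands in for the structure-derived feature pipelines (language
    model, stability prediction, docking, pocket analysis).  The
    statistical structure emulated: ``llr`` is the control true score
    plus noise (positively related to fitness), ``ddG`` is negatively
    related to fitness, ``delta_volume`` is the physical residue-volume
    change, position-level features (``residue_atp_distance``,
    ``crystal_rmsf``) are identical across mutations at a position, and
    ``inhibitor_mw`` depends only on the inhibitor.
    """
    if any(c.is_dmso for c in inhibitors):
        raise ValueError("feature tables are per-inhibitor; DMSO not allowed")
    rng = np.random.default_rng(seed)
    n = len(library)
    positions = np.sort(library["position"].unique())
    npos = len(positions)

    all_names = set(effects["condition"].unique())
    if "DMSO" in all_names:
        control = "DMSO"
    else:
        rest = all_names - {c.name for c in inhibitors}
        if len(rest) != 1:
            raise ValueError("cannot identify a unique control condition in effects")
        control = rest.pop()
    dmso = effects[effects["condition"] == control]
    dmso_score = library.merge(dmso, on=VARIANT_COLUMNS, how="left")["true_score"].to_numpy()
    if np.isnan(dmso_score).any():
        raise ValueError("effects missing control scores for some library variants")

    # position-level structural features
    pos_atp = dict(zip(positions, rng.uniform(4.0, 30.0, npos)))
    pos_rmsf = dict(zip(positions, 0.1 + np.abs(rng.normal(0.6, 0.25, npos))))

    # variant-level (inhibitor-independent) features
    llr = dmso_score + rng.normal(0.0, llr_noise_sd, n)
    ddg = -0.8 * dmso_score + rng.normal(0.0, ddg_noise_sd, n)
    dddg = rng.normal(0.0, 0.8, n)
    dvol = np.array([AA_VOLUME[m] - AA_VOLUME[w]
                     for w, m in zip(library["wt_aa"], library["mut_aa"])])

    frames = []
    for cond in inhibitors:
        crng = np.random.default_rng(_condition_seed(seed, "features:" + cond.name))
        out = library.copy()
        out["inhibitor"] = cond.name
        out["llr"] = llr
        out["inhibitor_mw"] = round(float(crng.uniform(350.0, 650.0)), 1)
        out["ligand_rmsd"] = np.abs(crng.normal(1.0, 0.6, n))
        out["dddG"] = dddg
        out["ddG"] = ddg
        out["residue_atp_distance"] = out["position"].map(pos_atp)
        pos_inh = dict(zip(positions, crng.uniform(2.0, 15.0, npos)))
        out["inhibitor_distance"] = out["position"].map(pos_inh)
        out["crystal_rmsf"] = out["position"].map(pos_rmsf)
        out["residue_rmsd"] = np.abs(crng.normal(0.5, 0.3, n))
        out["rf_score"] = crng.normal(6.0, 0.8, n)
        out["pocket_volume"] = np.abs(crng.normal(450.0, 60.0, n))
        out["hydrophobicity_score"] = crng.normal(30.0, 8.0, n)
        out["polarity_score"] = crng.normal(10.0, 3.0, n)
        out["delta_volume"] = dvol
        frames.append(out)
    table = pd.concat(frames, ignore_index=True)
    assert list(table.columns[-14:]) == ALL_FEATURES or set(ALL_FEATURES) <= set(table.columns)
    return table
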