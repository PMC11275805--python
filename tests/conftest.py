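"""Shared fixtures: a small saturation library, a condition panel with
planted resistance pairs, and noise-free / multinomial count tables."""

import numpy as np
import pandas as pd
import pytest

import dms_tki as dt

# planted resistance pairs (position, mut_aa) per major inhibitor type
RES_I = {(1062, "R"), (1065, "C")}
RES_II = {(1068, "M")}


@pytest.fixture(scope="session")
def wt_seq():
    return dt.random_wt_sequence(12, seed=11)


@pytest.fixture(scope="session")
def library(wt_seq):
    return dt.build_library(1059, 1070, wt_seq, stop_spacing=11)


@pytest.fixture(scope="session")
def conditions():
    return [
        dt.ConditionMeta("DMSO", "DMSO"),
        dt.ConditionMeta("inhA1", "I_a"),
        dt.ConditionMeta("inhA2", "I_a"),
        dt.ConditionMeta("inhB1", "II"),
        dt.ConditionMeta("inhB2", "II"),
    ]


@pytest.fixture(scope="session")
def effects(library, conditions):
    return dt.assign_true_scores(
        library, conditions, {"I": RES_I, "II": RES_II}, seed=5)


@pytest.fixture(scope="session")
def noise_free_tables(effects, conditions):
    design = dt.SimDesign(3, 4, 10 ** 6, "none", seed=5)
    return {c.name: dt.simulate_counts(effects, c, design) for c in conditions}


@pytest.fixture(scope="session")
def noisy_tables(effects, conditions):
    design = dt.SimDesign(3, 4, 10 ** 6, "multinomial", seed=5)
    return {c.name: dt.simulate_counts(effects, c, design) for c in conditions}


@pytest.fixture(scope="session")
def noise_free_scores(noise_free_tables):
    return {name: dt.score_condition(tab, pseudocount=0.0)
            for name, tab in noise_free_tables.items()}


@pytest.fixture(scope="session")
def noisy_scores(noisy_tables):
    return {name: dt.score_condition(tab)
            for name, tab in noisy_tables.items()}


def true_scores_for(effects, table, condition_name):
    """Ground-truth scores aligned to a count table's variant order."""
    sub = effects[effects["condition"] == condition_name]
    return table.variants.merge(
        sub, on=["position", "wt_aa", "mut_aa", "var_class"],
        how="left")["true_score"].to_numpy()


def make_count_table(counts, var_classes=None, condition=None):
    """Tiny hand-built CountTable; counts is (V, R, T)."""
    counts = np.asarray(counts, float)
    V = counts.shape[0]
    if var_classes is None:
        var_classes = ["missense"] * (V - 1) + ["synonymous"]
    variants = pd.DataFrame({
        "position": np.arange(1, V + 1),
        "wt_aa": ["A"] * V,
        "mut_aa": [("A" if c == "synonymous" else ("*" if c == "nonsense" else "V"))
                   for c in var_classes],
        "var_class": var_classes,
    })
    cond = condition or dt.ConditionMeta("DMSO", "DMSO")
    return dt.CountTable(variants, counts, cond)
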