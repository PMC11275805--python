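"""Feature-augmented fitness predictor.

A gradient-boosted decision-tree regressor predicts per-(variant,
inhibitor) fitness from a protein-language-model log-likelihood ratio
(always included) plus up to 13 optional biophysical/chemical features.
Overfitting on the small feature space is controlled three ways:

* monotonicity constraints — predictions are forced non-decreasing in
  the language-model score (``llr``) and non-increasing in the
  stability change (``ddG``);
* feature binning — the remaining (non-monotone) features are coarsened
  into 4-5 bins, each value replaced by the median of the training
  values falling in its bin;
* a leakage-aware split — whole inhibitors (one type I, one type II),
  20% of positions, and two mutant amino acids are held out for
  testing, and cross-validation folds partition positions and amino
  acids rather than rows.

Model selection enumerates feature subsets (all 2^13 = 8192 with llr
fixed, or a deterministic prefix under a cap), tunes hyperparameters
per subset on a 20% tuning holdout, ranks subsets by grouped 10-fold
cross-validated Pearson r, and evaluates the winner per inhibitor on
the untouched test partition.

The regressor is scikit-learn's HistGradientBoostingRegressor (the
installed gradient-boosting family with per-feature ``monotonic_cst``);
hyperparameters are drawn by seeded random search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingRegressor

from .types import VARIANT_COLUMNS

__all__ = [
    "LLR", "OPTIONAL_FEATURES", "ALL_FEATURES", "MONOTONE_CONSTRAINTS",
    "NEVER_BINNED", "SplitSpec", "Splits", "ModelResult",
    "enumerate_feature_subsets", "bin_features", "make_splits",
    "make_cv_folds", "crossvalidate", "fit_model", "model_search",
    "validate_feature_table",
]

LLR = "llr"

#: The 13 optional features of the catalog (llr is always present).
OPTIONAL_FEATURES = [
    "inhibitor_mw",          # inhibitor molecular weight
    "ligand_rmsd",           # redocked vs reference ligand pose RMSD
    "dddG",                  # ddG(type-I-bound) - ddG(type-II-bound)
    "ddG",                   # stability change of the bound-state structure
    "residue_atp_distance",  # C-alpha to ATP-centroid distance (per position)
    "inhibitor_distance",    # shortest residue-inhibitor distance
    "crystal_rmsf",          # positional fluctuation across crystal structures
    "residue_rmsd",          # mutant vs wild-type residue RMSD
    "rf_score",              # random-forest binding-affinity score
    "pocket_volume",
    "hydrophobicity_score",
    "polarity_score",
    "delta_volume",          # residue volume change upon mutation
]

ALL_FEATURES = [LLR] + OPTIONAL_FEATURES          # 14 features total

MONOTONE_CONSTRAINTS = {LLR: 1, "ddG": -1}

#: Monotone-constrained features keep their raw values (never binned).
NEVER_BINNED = (LLR, "ddG")

KEY_COLUMNS = VARIANT_COLUMNS + ["inhibitor"]


def validate_feature_table(table: pd.DataFrame, target: str | None = None) -> None:
    """Enforce the feature-table contract: key columns + llr present,
    no unrecognized columns, exactly the 14-name catalog admitted."""
    allowed = set(KEY_COLUMNS) | set(ALL_FEATURES) | ({target} if target else set())
    unknown = set(table.columns) - allowed
    if unknown:
        raise ValueError(f"unrecognized feature columns: {sorted(unknown)}")
    missing = [c for c in KEY_COLUMNS + [LLR] if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing required columns: {missing}")
    if table[LLR].isna().any():
        raise ValueError("llr must be present for every row")


def enumerate_feature_subsets(optional_features: Sequence[str] = OPTIONAL_FEATURES,
                              ) -> list[tuple[str, ...]]:
    """All subsets of the optional features, in deterministic binary-
    counting order (subset i contains feature j iff bit j of i is set);
    llr is implicitly part of every model.  13 optional features give
    2^13 = 8192 subsets."""
    if len(set(optional_features)) != len(optional_features):
        raise ValueError("duplicate optional feature names")
    k = len(optional_features)
    return [tuple(f for j, f in enumerate(optional_features) if (i >> j) & 1)
            for i in range(2 ** k)]


def bin_features(table: pd.DataFrame, train_mask: np.ndarray,
                 n_bins: int = 4,
                 breakpoints: Mapping[str, Sequence[float]] | None = None,
                 features: Sequence[str] | None = None) -> pd.DataFrame:
    """Coarsen non-monotone features into bins, median-coded.

    Breakpoints default to training-partition quantiles (``n_bins``
    equal-probability bins); a manual ``breakpoints`` mapping overrides
    per feature (the study chose bins by eye so that one or two bins
    hold most values).  Each value is replaced by the median of the
    *training* values in its bin; values beyond the outermost
    breakpoints fall into the edge bins.  ``llr`` and ``ddG`` pass
    through unchanged.  An empty training bin is merged with its
    neighbor with a warning.
    """
    if features is None:
        features = [f for f in OPTIONAL_FEATURES
                    if f in table.columns and f not in NEVER_BINNED]
    out = table.copy()
    train_mask = np.asarray(train_mask, bool)
    for f in features:
        if f in NEVER_BINNED:
            continue
        vals = table[f].to_numpy(float)
        tr = vals[train_mask]
        tr = tr[np.isfinite(tr)]
        if len(tr) == 0:
            warnings.warn(f"no finite training values for {f!r}; left unbinned")
            continue
        manual = bool(breakpoints and f in breakpoints)
        if manual:
            edges = np.asarray(sorted(breakpoints[f]), float)
            if np.any(np.diff(edges) <= 0):
                raise ValueError(f"breakpoints for {f!r} must be strictly increasing")
        else:
            qs = np.linspace(0, 1, n_bins + 1)[1:-1]
            edges = np.unique(np.quantile(tr, qs))
        # interior edges only; outer bins are open-ended
        idx = np.digitize(vals, edges)
        idx_tr = np.digitize(tr, edges)
        medians = {}
        for b in range(len(edges) + 1):
            members = tr[idx_tr == b]
            if len(members) == 0:
                if manual:   # quantile ties merge silently (routine for discrete features)
                    warnings.warn(f"empty training bin {b} for {f!r}; merged with neighbor")
                continue
            medians[b] = float(np.median(members))
        filled = sorted(medians)
        if not filled:
            continue
        # empty bins inherit the nearest filled bin's median (merge)
        lookup = {b: medians[min(filled, key=lambda fb: abs(fb - b))]
                  for b in range(len(edges) + 1)}
        out[f] = np.where(np.isfinite(vals),
                          np.vectorize(lookup.get)(idx), vals)
    return out


@dataclass(frozen=True)
class SplitSpec:
    """Design of the train/tune/test split.

    ``heldout_inhibitors`` names exactly one type I and one type II
    inhibitor whose rows all go to test; additionally a random 20% of
    positions and all mutations to two random amino acids are held
    out.  ``excluded_conditions`` (the control and any sole
    representative of a type, e.g. the single type I 1/2 inhibitor) are
    dropped entirely, so the model cannot memorize them.
    """

    heldout_inhibitors: tuple[str, str]
    heldout_position_fraction: float = 0.20
    heldout_amino_acids: tuple[str, str] | None = None
    excluded_conditions: frozenset[str] = frozenset()
    seed: int = 0


@dataclass
class Splits:
    train: pd.Index
    tune: pd.Index
    test: pd.Index
    heldout_positions: set[int] = field(default_factory=set)
    heldout_amino_acids: tuple[str, ...] = ()
    heldout_inhibitors: tuple[str, ...] = ()


def make_splits(table: pd.DataFrame, spec: SplitSpec) -> Splits:
    """Partition feature-table rows into train / tune / test.

    test = rows of the held-out inhibitors UNION rows at the held-out
    positions UNION rows with the held-out mutant amino acids;
    tune = 20% random rows of the remainder; train = the rest.
    Partitions are disjoint and exhaustive over non-excluded rows,
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    df = table[~table["inhibitor"].isin(spec.excluded_conditions)]
    present = set(df["inhibitor"].unique())
    for inh in spec.heldout_inhibitors:
        if inh not in present:
            raise ValueError(f"held-out inhibitor {inh!r} absent from table")

    positions = np.sort(df["position"].unique())
    n_hold = max(1, int(round(spec.heldout_position_fraction * len(positions))))
    held_pos = set(rng.choice(positions, size=n_hold, replace=False).tolist())

    if spec.heldout_amino_acids is None:
        aas = np.sort(df.loc[df["mut_aa"] != "*", "mut_aa"].unique())
        held_aa = tuple(rng.choice(aas, size=2, replace=False).tolist())
    else:
        held_aa = tuple(spec.heldout_amino_acids)

    in_test = (df["inhibitor"].isin(spec.heldout_inhibitors)
               | df["position"].isin(held_pos)
               | df["mut_aa"].isin(held_aa))
    test_idx = df.index[in_test]
    rest = df.index[~in_test].to_numpy()
    rng.shuffle(rest)
    n_tune = int(round(0.20 * len(rest)))
    tune_idx = pd.Index(np.sort(rest[:n_tune]))
    train_idx = pd.Index(np.sort(rest[n_tune:]))
    return Splits(train_idx, tune_idx, test_idx, held_pos, held_aa,
                  tuple(spec.heldout_inhibitors))


def make_cv_folds(positions: Sequence[int], amino_acids: Sequence[str],
                  k: int = 10, seed: int = 0,
                  ) -> list[tuple[set[int], set[str]]]:
    """Grouped fold design: positions partitioned into k equal groups
    (disjoint, exhaustive); amino acids into k groups of
    ceil(n_aa / k), re-sampling a few residues when n_aa is not an
    exact multiple (e.g. 18 residues -> 10 groups of 2 with 2 reused).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    pos = np.array(sorted(set(positions)))
    rng.shuffle(pos)
    pos_groups = [set(g.tolist()) for g in np.array_split(pos, k)]

    aas = np.array(sorted(set(amino_acids)))
    rng.shuffle(aas)
    g = max(1, int(np.ceil(len(aas) / k)))
    need = g * k
    if need > len(aas):
        pad = rng.choice(aas, size=need - len(aas), replace=False)
        aas = np.concatenate([aas, pad])
    aa_groups = [set(aas[i * g:(i + 1) * g].tolist()) for i in range(k)]
    return list(zip(pos_groups, aa_groups))


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    mse = float(np.mean((y_true - y_pred) ** 2))
    if len(y_true) < 3 or np.std(y_true) == 0 or np.std(y_pred) == 0:
        return np.nan, mse
    return float(stats.pearsonr(y_true, y_pred)[0]), mse


def _make_regressor(features: Sequence[str], params: Mapping, seed: int,
                    ) -> HistGradientBoostingRegressor:
    cst = [MONOTONE_CONSTRAINTS.get(f, 0) for f in features]
    return HistGradientBoostingRegressor(monotonic_cst=cst, random_state=seed,
                                         early_stopping=False, **params)


def _sample_params(rng: np.random.Generator) -> dict:
    """One draw from the hyperparameter space (tree depth, ensemble
    size, learning rate, leaf regularization, column subsampling, tree
    growth limits — mirroring the usual gradient-boosting knobs).
    Ranges are sized for desk-scale tables (hundreds to a few thousand
    rows, <= 14 features): shallow trees, modest ensembles."""
    return {
        "max_depth": int(rng.choice([2, 3, 4])),
        "max_iter": int(rng.integers(20, 151)),
        "learning_rate": float(10 ** rng.uniform(-1.7, -0.4)),
        "min_samples_leaf": int(rng.integers(5, 51)),
        "l2_regularization": float(10 ** rng.uniform(-3, 1)),
        "max_features": float(rng.uniform(0.6, 1.0)),
        "max_leaf_nodes": int(rng.choice([7, 15, 31])),
    }


def fit_model(train: pd.DataFrame, features: Sequence[str],
              target: str = "target", tune: pd.DataFrame | None = None,
              hp_budget: int = 30, seed: int = 0,
              params: Mapping | None = None,
              ) -> tuple[HistGradientBoostingRegressor, dict, float]:
    """Fit the constrained regressor, optionally tuning hyperparameters.

    With ``tune`` supplied and no fixed ``params``, runs ``hp_budget``
    seeded random-search trials minimizing tuning-holdout MSE.  Returns
    (fitted model, chosen params, tuning MSE — nan if untuned).
    ``llr`` must be among the features.
    """
    features = list(features)
    if LLR not in features:
        raise ValueError("llr must be included in every model")
    X, y = train[features].to_numpy(float), train[target].to_numpy(float)
    rng = np.random.default_rng(seed)

    if params is not None:
        model = _make_regressor(features, params, seed).fit(X, y)
        return model, dict(params), np.nan
    if tune is None or hp_budget < 1:
        model = _make_regressor(features, {}, seed).fit(X, y)
        return model, {}, np.nan

    Xt, yt = tune[features].to_numpy(float), tune[target].to_numpy(float)
    best = (np.inf, None, None)
    for _ in range(hp_budget):
        p = _sample_params(rng)
        m = _make_regressor(features, p, seed).fit(X, y)
        mse = float(np.mean((yt - m.predict(Xt)) ** 2))
        if mse < best[0]:
            best = (mse, p, m)
    return best[2], best[1], best[0]


def crossvalidate(data: pd.DataFrame, features: Sequence[str],
                  target: str = "target", k: int = 10, seed: int = 0,
                  params: Mapping | None = None) -> dict:
    """Grouped k-fold cross-validation on the training set.

    Fold i validates on rows at fold-i positions OR with fold-i amino
    acids and trains on rows touching neither group, so performance is
    always measured on unseen positions and unseen substitutions.
    Returns averaged Pearson r and MSE plus per-fold values.
    """
    folds = make_cv_folds(data["position"].unique(),
                          data.loc[data["mut_aa"] != "*", "mut_aa"].unique(),
                          k=k, seed=seed)
    rs, mses = [], []
    for i, (pos_g, aa_g) in enumerate(folds):
        in_pos = data["position"].isin(pos_g)
        in_aa = data["mut_aa"].isin(aa_g)
        val = data[in_pos | in_aa]
        tr = data[~in_pos & ~in_aa]
        if len(val) == 0 or len(tr) < 10:
            continue
        m, _, _ = fit_model(tr, features, target, params=params or {}, seed=seed + i)
        r, mse = _metrics(val[target].to_numpy(float),
                          m.predict(val[list(features)].to_numpy(float)))
        rs.append(r)
        mses.append(mse)
    return {"cv_pearson": float(np.nanmean(rs)) if rs else np.nan,
            "cv_mse": float(np.nanmean(mses)) if mses else np.nan,
            "fold_pearson": rs, "fold_mse": mses, "folds": folds}


@dataclass
class ModelResult:
    """Outcome of one feature subset in the model search."""

    features: tuple[str, ...]            # includes llr
    cv_pearson: float
    cv_mse: float
    params: dict
    tune_mse: float = np.nan
    test_pearson_per_inhibitor: dict | None = None
    test_mse_per_inhibitor: dict | None = None
    test_pearson: float = np.nan
    model: HistGradientBoostingRegressor | None = field(default=None, repr=False)


def model_search(table: pd.DataFrame, split: Splits,
                 subsets: Sequence[tuple[str, ...]] | None = None,
                 target: str = "target", k: int = 10, hp_budget: int = 10,
                 seed: int = 0, subset_cap: int | None = None,
                 bin_kwargs: Mapping | None = None) -> list[ModelResult]:
    """Enumerate feature subsets, rank by cross-validated Pearson r,
    and evaluate the winner per inhibitor on the test partition.

    Non-monotone features are binned first (breakpoints and medians
    computed on the training partition only).  Per subset: seeded
    random hyperparameter search on the train/tune split, then grouped
    k-fold cross-validation on the full training set (train + tune)
    with the chosen hyperparameters.  The winner is refit on the full
    training set and scored per inhibitor on test.  Returns results
    sorted by cv_pearson descending (winner first, with test metrics).
    """
    validate_feature_table(table, target=target)
    if subsets is None:
        subsets = enumerate_feature_subsets(
            [f for f in OPTIONAL_FEATURES if f in table.columns])
    if subset_cap is not None:
        subsets = list(subsets)[:subset_cap]
    if not subsets:
        raise ValueError("no feature subsets to search")

    train_mask = table.index.isin(split.train) | table.index.isin(split.tune)
    binned = bin_features(table, train_mask, **(bin_kwargs or {}))
    tr, tu, te = (binned.loc[split.train], binned.loc[split.tune],
                  binned.loc[split.test])
    full_train = pd.concat([tr, tu])

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(len(subsets))]

    results = []
    for sub, cseed in zip(subsets, child_seeds):
        feats = (LLR,) + tuple(sub)
        _, params, tune_mse = fit_model(tr, feats, target, tune=tu,
                                        hp_budget=hp_budget, seed=cseed)
        cv = crossvalidate(full_train, feats, target, k=k, seed=cseed,
                           params=params)
        results.append(ModelResult(feats, cv["cv_pearson"], cv["cv_mse"],
                                   params, tune_mse))
    results.sort(key=lambda r: (-(r.cv_pearson if np.isfinite(r.cv_pearson)
                                  else -np.inf), r.features))

    win = results[0]
    model, _, _ = fit_model(full_train, win.features, target,
                            params=win.params, seed=seed)
    win.model = model
    per_r, per_mse = {}, {}
    for inh, sub in te.groupby("inhibitor"):
        r, mse = _metrics(sub[target].to_numpy(float),
                          model.predict(sub[list(win.features)].to_numpy(float)))
        per_r[inh], per_mse[inh] = r, mse
    win.test_pearson_per_inhibitor = per_r
    win.test_mse_per_inhibitor = per_mse
    win.test_pearson, _ = _metrics(te[target].to_numpy(float),
                                   model.predict(te[list(win.features)].to_numpy(float)))
    return results
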