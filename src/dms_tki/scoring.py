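"""Fitness scoring on the cell-doubling-rate scale.

Counts are wild-type normalized — per sample, log2 counts are centered
on the mean log2 count of the synonymous (wild-type-equivalent)
variants — and the normalized trajectory of each variant is regressed
on the integer time index, per replicate.  Because wild type doubles a
fixed number of times between consecutive timepoints in every
condition, the slope beta is the variant's log2 growth-rate offset from
wild type per sampling interval: 0 means wild-type-like growth, -2
means no net growth when wild type doubles twice per interval (2^(2-2)
= 1x per interval), +1 means one extra doubling (2^(2+1) = 8x).

Uncertainty.  beta is always the mean of the per-replicate OLS slopes.
Two standard-error methods are offered:

``poisson`` (default)
    count-level error propagation: the sampling variance of each
    normalized log2 count is estimated from the count itself (delta
    method; sequencing counts are Poisson-like), propagated through the
    OLS slope and averaged over replicates.  Degrees of freedom are
    effectively large, so tails are normal.  This is the calibrated
    choice for multinomial sequencing noise (as in count-based
    enrichment scorers) and the one used for interval coverage.

``replicate``
    the empirical standard deviation of the R replicate slopes divided
    by sqrt(R), with Student-t(R-1) tails.  Honest about between-
    replicate variability but with R=3 a +/-1.96*se interval only
    covers ~81% (t with 2 df), so it is not the default.

``tail_prob_resist`` is P(beta < 0.5) under the estimate's sampling
distribution — the one-sided test against the resistance effect
threshold; resistance calls require it <= 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountTable
from .types import VARIANT_COLUMNS, ConditionMeta

__all__ = [
    "ScoreTable", "RecenteredScores", "normalize_counts",
    "score_condition", "recenter", "correlation_matrix", "tail_probability",
]

_LOG2 = np.log(2.0)

SCORE_COLUMNS = VARIANT_COLUMNS + ["beta", "se", "df", "p_gt_wt", "p_lt_wt",
                                   "tail_prob_resist"]


@dataclass
class ScoreTable:
    """Per-variant fitness scores for one condition."""

    data: pd.DataFrame            # SCORE_COLUMNS
    condition: ConditionMeta

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(4, "condition", self.condition.name)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class RecenteredScores:
    """DMSO-subtracted (recentered) scores gamma for one inhibitor."""

    data: pd.DataFrame            # variant cols + beta_inh, beta_dmso, gamma, ...
    inhibitor: str

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(4, "inhibitor", self.inhibitor)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def normalize_counts(table: CountTable, pseudocount: float = 0.5) -> np.ndarray:
    """Wild-type log2 normalization.

    m(v,r,t) = log2(count + pseudocount) minus the mean over synonymous
    variants of the same quantity at that (replicate, timepoint).  The
    synonymous mean of m is exactly 0 per sample, anchoring wild type
    at slope 0.
    """
    syn = table.synonymous_mask()
    if not syn.any():
        raise ValueError("no synonymous variants: wild-type normalization undefined")
    logc = np.log2(table.counts + pseudocount)
    return logc - logc[syn].mean(axis=0, keepdims=True)


def tail_probability(beta: np.ndarray, se: np.ndarray, df: np.ndarray,
                     threshold: float) -> np.ndarray:
    """P(beta < threshold) under the estimate's sampling distribution
    (Student-t with ``df`` degrees of freedom; normal when df is inf).
    Degenerate se == 0 collapses to an indicator."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    df = np.broadcast_to(np.asarray(df, float), beta.shape)
    out = np.full(beta.shape, np.nan)
    zero = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (threshold - beta) / se
    finite = np.isfinite(beta) & np.isfinite(se) & ~zero
    use_t = finite & np.isfinite(df)
    out[use_t] = stats.t.cdf(z[use_t], df[use_t])
    use_n = finite & ~np.isfinite(df)
    out[use_n] = stats.norm.cdf(z[use_n])
    deg = np.isfinite(beta) & zero
    out[deg] = np.where(beta[deg] < threshold, 1.0,
                        np.where(beta[deg] > threshold, 0.0, 0.5))
    return out


def _poisson_se(table: CountTable, pseudocount: float,
                xc: np.ndarray, sxx: float) -> np.ndarray:
    """Delta-method slope standard error from count-level Poisson noise.

    var(log2 c) ~= 1 / ((c + pseudocount) * ln(2)^2); the synonymous-
    mean normalizer contributes its own (shared) variance, and for
    synonymous variants the covariance with the normalizer is removed.
    """
    c = table.counts + max(pseudocount, 0.5)   # variance floor for zero counts
    var_log = 1.0 / (c * _LOG2 ** 2)                      # (V, R, T)
    syn = table.synonymous_mask()
    n_syn = int(syn.sum())
    var_norm = var_log[syn].sum(axis=0, keepdims=True) / n_syn ** 2
    var_m = var_log + var_norm
    var_m[syn] -= 2.0 * var_log[syn] / n_syn
    var_slope = (xc[None, None, :] ** 2 * var_m).sum(axis=2) / sxx ** 2  # (V, R)
    R = table.n_replicates
    return np.sqrt(var_slope.sum(axis=1)) / R


def score_condition(table: CountTable, pseudocount: float = 0.5,
                    se_method: str = "poisson",
                    resist_threshold: float = 0.5) -> ScoreTable:
    """Score one condition: per-replicate OLS slope of the normalized
    log2 trajectory against time index, averaged over replicates.

    See the module docstring for the se methods.  Variants with fewer
    than 2 finite timepoints get NA scores with a warning.
    """
    if table.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints to regress")
    if se_method not in ("poisson", "replicate"):
        raise ValueError("se_method must be 'poisson' or 'replicate'")
    m = normalize_counts(table, pseudocount)
    V, R, T = m.shape
    x = np.arange(T, dtype=float)
    xc = x - x.mean()
    sxx = float((xc ** 2).sum())

    finite = np.isfinite(m)
    bad = (~finite).sum(axis=(1, 2)) > 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} variants have non-finite normalized "
                      "counts; scores set to NA")
    slopes = np.einsum("vrt,t->vr", np.where(finite, m, 0.0), xc) / sxx
    beta = slopes.mean(axis=1)
    beta[bad] = np.nan

    if se_method == "replicate":
        if R >= 2:
            se = slopes.std(axis=1, ddof=1) / np.sqrt(R)
            df = np.full(V, float(R - 1))
        else:
            # single replicate: residual-based slope se, df = T - 2
            fit = slopes[:, 0:1] * xc[None, :]
            resid = m[:, 0, :] - m[:, 0, :].mean(axis=1, keepdims=True) - fit
            s2 = (resid ** 2).sum(axis=1) / max(T - 2, 1)
            se = np.sqrt(s2 / sxx)
            df = np.full(V, float(max(T - 2, 1)))
    else:
        se = _poisson_se(table, pseudocount, xc, sxx)
        df = np.full(V, np.inf)
    se = np.where(bad, np.nan, se)

    p_lt = tail_probability(beta, se, df, 0.0)
    data = table.variants.copy()
    data["beta"] = beta
    data["se"] = se
    data["df"] = df
    data["p_gt_wt"] = 1.0 - p_lt
    data["p_lt_wt"] = p_lt
    data["tail_prob_resist"] = tail_probability(beta, se, df, resist_threshold)
    return ScoreTable(data, table.condition)


def recenter(scores_inh: ScoreTable, scores_dmso: ScoreTable) -> RecenteredScores:
    """Recentered score gamma = beta_inhibitor - beta_DMSO per variant.

    Subtracting the control score cancels folding/expression/stability
    effects, isolating inhibitor sensitivity.  NA-propagating; variants
    present in only one table get NA for the missing side.
    """
    if not scores_dmso.condition.is_dmso:
        warnings.warn(f"recentering against non-DMSO condition "
                      f"{scores_dmso.condition.name!r}")
    a = scores_inh.data[VARIANT_COLUMNS + ["beta", "se", "df", "tail_prob_resist"]]
    b = scores_dmso.data[VARIANT_COLUMNS + ["beta", "se"]]
    merged = a.merge(b, on=VARIANT_COLUMNS, how="outer",
                     suffixes=("_inh", "_dmso"))
    if len(merged) == len(a) + len(b):
        raise ValueError("disjoint variant sets: nothing to recenter")
    merged = merged.rename(columns={"beta_inh": "beta_inh",
                                    "beta_dmso": "beta_dmso"})
    merged["gamma"] = merged["beta_inh"] - merged["beta_dmso"]
    return RecenteredScores(merged, scores_inh.condition.name)


def correlation_matrix(tables: list, value: str | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between conditions.

    Accepts ScoreTable (uses ``beta``) or RecenteredScores (uses
    ``gamma``); ``value`` overrides the column.  Pairs sharing fewer
    than 3 variants get NA with a warning.  Symmetric, unit diagonal.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables to correlate")
    cols = {}
    for t in tables:
        if isinstance(t, ScoreTable):
            name, col = t.condition.name, value or "beta"
        elif isinstance(t, RecenteredScores):
            name, col = t.inhibitor, value or "gamma"
        else:
            raise TypeError(f"cannot correlate {type(t).__name__}")
        cols[name] = t.data.set_index(VARIANT_COLUMNS)[col]
    wide = pd.DataFrame(cols)
    mat = wide.corr(method="pearson", min_periods=3)
    np.fill_diagonal(mat.values, 1.0)
    n_shared = wide.notna().astype(int).T @ wide.notna().astype(int)
    if (n_shared.values[np.triu_indices(len(mat), 1)] < 3).any():
        warnings.warn("some condition pairs share < 3 variants; entries set to NA")
    return mat
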