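"""Variant count tables: container, TSV I/O, and inclusion filtering.

The on-disk contract is a long-format TSV with columns ``position``,
``wt_aa``, ``mut_aa``, ``var_class``, ``condition``, ``replicate``
(1-based), ``timepoint`` (0-based) and ``count``.  Every (variant,
replicate, timepoint) cell must be present exactly once per condition;
a missing cell is an error, not an implicit zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import VARIANT_COLUMNS, ConditionMeta

__all__ = [
    "CountTable", "read_counts", "write_counts",
    "read_conditions", "write_conditions", "filter_variants",
]

COUNTS_COLUMNS = VARIANT_COLUMNS + ["condition", "replicate", "timepoint", "count"]


@dataclass
class CountTable:
    """Counts for one condition, dense over variants x replicates x timepoints."""

    variants: pd.DataFrame          # columns: position, wt_aa, mut_aa, var_class
    counts: np.ndarray              # (V, R, T), nonnegative
    condition: ConditionMeta

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[0] != len(self.variants):
            raise ValueError("counts must be (n_variants, R, T)")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_variants(self) -> int:
        return self.counts.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.counts.shape[2]

    def synonymous_mask(self) -> np.ndarray:
        return (self.variants["var_class"] == "synonymous").to_numpy()

    def to_long(self) -> pd.DataFrame:
        """Long-format frame matching the counts TSV contract."""
        V, R, T = self.counts.shape
        var = self.variants.loc[self.variants.index.repeat(R * T)].reset_index(drop=True)
        var["condition"] = self.condition.name
        var["replicate"] = np.tile(np.repeat(np.arange(1, R + 1), T), V)
        var["timepoint"] = np.tile(np.arange(T), V * R)
        var["count"] = self.counts.reshape(-1)
        return var

    def subset(self, mask: np.ndarray) -> "CountTable":
        return CountTable(self.variants.loc[mask].reset_index(drop=True),
                          self.counts[np.asarray(mask, bool)], self.condition)


def write_counts(tables: Iterable[CountTable] | CountTable, path: str | Path) -> None:
    if isinstance(tables, CountTable):
        tables = [tables]
    long = pd.concat([t.to_long() for t in tables], ignore_index=True)
    long.to_csv(path, sep="\t", index=False)


def write_conditions(conditions: Iterable[ConditionMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(c.name, c.inhibitor_type, c.wt_doublings_per_interval) for c in conditions],
        columns=["condition", "inhibitor_type", "wt_doublings_per_interval"],
    ).to_csv(path, sep="\t", index=False)


def read_conditions(path: str | Path) -> list[ConditionMeta]:
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "inhibitor_type", "wt_doublings_per_interval"}
    if not required <= set(df.columns):
        raise ValueError(f"condition metadata must have columns {sorted(required)}")
    return [ConditionMeta(r.condition, r.inhibitor_type,
                          float(r.wt_doublings_per_interval))
            for r in df.itertuples()]


def read_counts(path: str | Path,
                conditions: Mapping[str, ConditionMeta] | Iterable[ConditionMeta] | None = None,
                ) -> dict[str, CountTable]:
    """Read a counts TSV into one dense :class:`CountTable` per condition.

    ``conditions`` supplies metadata (inhibitor type, wild-type
    doublings); without it, a placeholder is attached (DMSO type for a
    condition named ``DMSO``, type ``I_a`` otherwise) — fine for
    filtering, but supply real metadata before scoring mixed designs.

    Raises on malformed headers, negative counts, duplicate cells (with
    the offending 1-based file row) and incomplete replicate/timepoint
    grids.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts TSV missing columns {missing}")

    meta: dict[str, ConditionMeta] = {}
    if conditions is not None:
        if isinstance(conditions, Mapping):
            meta = dict(conditions)
        else:
            meta = {c.name: c for c in conditions}

    if df.empty:
        return {}
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise ValueError(f"negative count at file row {neg[0] + 2}")
    key_cols = VARIANT_COLUMNS + ["condition", "replicate", "timepoint"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        row = int(df.index[dup][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"duplicate (variant, replicate, timepoint) cell at file row {row}")

    out: dict[str, CountTable] = {}
    for name, sub in df.groupby("condition", sort=False):
        reps = np.sort(sub["replicate"].unique())
        tps = np.sort(sub["timepoint"].unique())
        if not np.array_equal(tps, np.arange(len(tps))):
            raise ValueError(f"condition {name!r}: timepoints must be 0..T-1, got {tps}")
        variants = (sub[VARIANT_COLUMNS].drop_duplicates()
                    .reset_index(drop=True))
        expected = len(variants) * len(reps) * len(tps)
        if len(sub) != expected:
            raise ValueError(
                f"condition {name!r}: incomplete grid — {len(sub)} rows, "
                f"expected {expected} (missing cells are errors, not zeros)")
        wide = sub.pivot_table(index=VARIANT_COLUMNS,
                               columns=["replicate", "timepoint"],
                               values="count", sort=False)
        wide = wide.reindex(pd.MultiIndex.from_frame(variants))
        if wide.isna().any().any():
            raise ValueError(f"condition {name!r}: missing (variant, replicate, timepoint) cells")
        counts = wide.to_numpy().reshape(len(variants), len(reps), len(tps))
        cond = meta.get(name) or ConditionMeta(
            str(name), "DMSO" if str(name).upper() == "DMSO" else "I_a")
        out[str(name)] = CountTable(variants, counts, cond)
    return out


def filter_variants(table: CountTable, mean_min: float = 4.0,
                    zero_frac_max: float = 10 / 12,
                    zero_frac_t0_max: float = 2 / 3,
                    ) -> tuple[CountTable, pd.DataFrame]:
    """Apply the inclusion thresholds to a count table.

    A variant is kept iff its mean count over all R*T cells is
    >= ``mean_min``, its fraction of zero cells over all R*T cells is
    <= ``zero_frac_max``, and its fraction of zero cells among the R
    timepoint-0 cells (pre-selection) is <= ``zero_frac_t0_max``.
    Thresholds are inclusive: boundary values pass.

    Returns the filtered table and a per-variant report with the three
    statistics, the keep flag, and the first failing reason.
    """
    if table.n_variants == 0:
        raise ValueError("empty count table")
    c = table.counts
    mean_count = c.mean(axis=(1, 2))
    zero_all = (c == 0).mean(axis=(1, 2))
    zero_t0 = (c[:, :, 0] == 0).mean(axis=1)

    ok_mean = mean_count >= mean_min
    ok_zero = zero_all <= zero_frac_max
    ok_t0 = zero_t0 <= zero_frac_t0_max
    kept = ok_mean & ok_zero & ok_t0

    reason = np.where(~ok_mean, "low_mean_count",
                      np.where(~ok_zero, "too_many_zeros",
                               np.where(~ok_t0, "too_many_zeros_t0", "pass")))
    report = table.variants.copy()
    report["mean_count"] = mean_count
    report["zero_fraction_all"] = zero_all
    report["zero_fraction_t0"] = zero_t0
    report["kept"] = kept
    report["reason"] = reason
    return table.subset(kept), report
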