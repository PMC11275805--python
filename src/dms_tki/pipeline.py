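"""End-to-end orchestration: simulate (or ingest) -> filter -> score ->
recenter -> correlate -> classify -> hotspots -> pairwise comparison ->
optional predictor fit, with every intermediate written as TSV plus a
JSON manifest of parameters, per-stage seeds and file checksums.

A single global seed expands deterministically into per-stage seeds
(stage-name hashed), so any stage can be rerun in isolation and two
runs of the same config produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import counts as ct
from . import mlmodel as ml
from . import scoring as sc
from . import simulate as sim
from .types import AMINO_ACIDS, STOP, VARIANT_COLUMNS, ConditionMeta, SimDesign, check_one_dmso

__all__ = ["RunConfig", "run_pipeline", "make_heatmap_table", "stage_seed"]

log = logging.getLogger("dms_tki")

MUTATION_ORDER = list(AMINO_ACIDS) + [STOP]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2 ** 31


def _default_conditions() -> list[dict]:
    return [
        {"name": "DMSO", "inhibitor_type": "DMSO"},
        {"name": "inhibA1", "inhibitor_type": "I_a"},
        {"name": "inhibA2", "inhibitor_type": "I_a"},
        {"name": "inhibB1", "inhibitor_type": "II"},
        {"name": "inhibB2", "inhibitor_type": "II"},
    ]


@dataclass
class RunConfig:
    """Configuration of a full run; defaults give a small demo screen.

    Stage parameters default to the study's stated values: inclusion
    thresholds mean >= 4, zero fraction <= 10/12 overall and <= 2/3 at
    T0; resistance test threshold 0.5 with tail cutoff 0.1 and DMSO
    effect cutoff 0; differential GOF threshold 0.75; 20% held-out
    positions and 10 cross-validation folds for the predictor.
    """

    region_start: int = 1059
    region_end: int = 1108
    wt_sequence: str | None = None          # None -> seeded random sequence
    stop_spacing: int = 11
    conditions: list = field(default_factory=_default_conditions)
    resistance_spec: dict = field(default_factory=dict)   # type -> [[pos, aa], ...]
    n_replicates: int = 3
    n_timepoints: int = 4
    depth: int = 100_000
    noise_mode: str = "multinomial"
    pseudocount: float = 0.5
    mean_min: float = 4.0
    zero_frac_max: float = 10 / 12
    zero_frac_t0_max: float = 2 / 3
    tail_cutoff: float = 0.1
    effect_cutoff_beta: float = 0.5
    dmso_cutoff: float = 0.0
    gof_threshold: float = 0.75
    run_ml: bool = False
    subset_cap: int = 64
    hp_budget: int = 10
    cv_folds: int = 10
    out_dir: str = "run_output"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def condition_meta(self) -> list[ConditionMeta]:
        out = [ConditionMeta(c["name"], c["inhibitor_type"],
                             float(c.get("wt_doublings_per_interval", 2.0)))
               for c in self.conditions]
        check_one_dmso(out)
        return out

    def resistance_pairs(self) -> dict[str, set[tuple[int, str]]]:
        return {t: {(int(p), a) for p, a in pairs}
                for t, pairs in self.resistance_spec.items()}


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_heatmap_table(scores: pd.DataFrame, value: str = "beta") -> pd.DataFrame:
    """Heatmap-ready long table: one row per (position, mutation) over
    the full 21-row substitution grid (alphabetical, stop last), with
    the score value and synonymous / missing flags."""
    wt_by_pos = (scores[["position", "wt_aa"]].drop_duplicates()
                 .set_index("position")["wt_aa"])
    grid = pd.MultiIndex.from_product([wt_by_pos.index, MUTATION_ORDER],
                                      names=["position", "mut_aa"]).to_frame(index=False)
    grid["wt_aa"] = grid["position"].map(wt_by_pos)
    merged = grid.merge(scores[["position", "mut_aa", value]],
                        on=["position", "mut_aa"], how="left")
    merged = merged.rename(columns={value: "value"})
    merged["is_synonymous"] = merged["mut_aa"] == merged["wt_aa"]
    merged["is_missing"] = merged["value"].isna()
    return merged[["position", "wt_aa", "mut_aa", "value",
                   "is_synonymous", "is_missing"]]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write a complete run directory.

    Writes counts, filter reports, score/recentered/call/hotspot
    tables, condition correlation matrices, per-inhibitor heatmap
    tables, the first type I vs type II differential comparison, the
    predictor leaderboard when ``run_ml`` is set, and ``manifest.json``
    with parameters, stage seeds and sha256 checksums of every output.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict = {"config": asdict(config), "stage_seeds": {}, "outputs": {}}

    try:
        conditions = config.condition_meta()
        dmso = next(c for c in conditions if c.is_dmso)
        inhibitors = [c for c in conditions if not c.is_dmso]

        # --- simulate ---------------------------------------------------
        s_seed = stage_seed(config.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = s_seed
        wt = config.wt_sequence or sim.random_wt_sequence(
            config.region_end - config.region_start + 1, seed=s_seed)
        library = sim.build_library(config.region_start, config.region_end,
                                    wt, config.stop_spacing)
        effects = sim.assign_true_scores(library, conditions,
                                         config.resistance_pairs(), seed=s_seed)
        design = SimDesign(config.n_replicates, config.n_timepoints,
                           config.depth, config.noise_mode, seed=s_seed)
        tables = {c.name: sim.simulate_counts(effects, c, design) for c in conditions}
        ct.write_counts(list(tables.values()), out / "counts.tsv")
        ct.write_conditions(conditions, out / "conditions.tsv")
        _write(effects, out / "true_effects.tsv")
        log.info("simulated %d variants x %d conditions", len(library), len(conditions))

        # --- filter -> score -------------------------------------------
        reports, scores = [], {}
        for name, tab in tables.items():
            kept, rep = ct.filter_variants(tab, config.mean_min,
                                           config.zero_frac_max,
                                           config.zero_frac_t0_max)
            rep.insert(4, "condition", name)
            reports.append(rep)
            scores[name] = sc.score_condition(kept, config.pseudocount)
            log.info("%s: kept %d/%d variants", name, kept.n_variants, tab.n_variants)
        _write(pd.concat(reports, ignore_index=True), out / "filter_report.tsv")
        all_scores = pd.concat(
            [s.data.assign(condition=n) for n, s in scores.items()],
            ignore_index=True)
        _write(all_scores, out / "scores.tsv")

        # --- recenter, correlate ----------------------------------------
        recentered = {c.name: sc.recenter(scores[c.name], scores[dmso.name])
                      for c in inhibitors}
        _write(pd.concat([r.data.assign(inhibitor=n) for n, r in recentered.items()],
                         ignore_index=True), out / "recentered.tsv")
        corr_beta = sc.correlation_matrix(list(scores.values()))
        corr_beta.to_csv(out / "correlations_beta.tsv", sep="\t", float_format="%.6g")
        if len(recentered) >= 2:
            corr_gamma = sc.correlation_matrix(list(recentered.values()))
            corr_gamma.to_csv(out / "correlations_gamma.tsv", sep="\t",
                              float_format="%.6g")

        # --- classify, hotspots, compare --------------------------------
        calls = {c.name: cl.call_resistance(scores[c.name], scores[dmso.name],
                                            config.tail_cutoff,
                                            config.effect_cutoff_beta,
                                            config.dmso_cutoff,
                                            config.gof_threshold)
                 for c in inhibitors}
        _write(pd.concat(calls.values(), ignore_index=True), out / "calls.tsv")
        hs = cl.hotspot_counts(calls, conditions)
        _write(hs.counts, out / "hotspots.tsv")
        shared = pd.DataFrame(
            [("+".join(combo), len(vs)) for combo, vs in sorted(hs.shared_sets.items())],
            columns=["type_combination", "n_variants"])
        _write(shared, out / "shared_sets.tsv")

        pair = None
        t1 = [c for c in inhibitors if c.major_type == "I"]
        t2 = [c for c in inhibitors if c.major_type == "II"]
        if t1 and t2:
            pair = (t1[0].name, t2[0].name)
            gof_a, gof_b = cl.differential_pairs(
                recentered[pair[0]], recentered[pair[1]],
                calls[pair[0]], calls[pair[1]], config.gof_threshold)
            rows = ([(p, w, m, c, f"GOF_{pair[0]}_LOF_{pair[1]}")
                     for p, w, m, c in sorted(gof_a)]
                    + [(p, w, m, c, f"GOF_{pair[1]}_LOF_{pair[0]}")
                       for p, w, m, c in sorted(gof_b)])
            _write(pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["profile"]),
                   out / f"differential_{pair[0]}_vs_{pair[1]}.tsv")

        for name, r in recentered.items():
            _write(make_heatmap_table(r.data, "gamma"), out / f"heatmap_{name}.tsv")

        # --- predictor ---------------------------------------------------
        if config.run_ml:
            m_seed = stage_seed(config.seed, "mlfit")
            manifest["stage_seeds"]["mlfit"] = m_seed
            features = sim.simulate_feature_table(library, inhibitors, effects,
                                                  seed=m_seed)
            gamma_long = pd.concat(
                [r.data[VARIANT_COLUMNS + ["gamma"]].assign(inhibitor=n)
                 for n, r in recentered.items()], ignore_index=True)
            ftab = features.merge(gamma_long, on=VARIANT_COLUMNS + ["inhibitor"])
            ftab = ftab.dropna(subset=["gamma"]).reset_index(drop=True)
            held = (t1[0].name, t2[0].name)
            split = ml.make_splits(ftab, ml.SplitSpec(
                heldout_inhibitors=held, excluded_conditions=frozenset({dmso.name}),
                seed=m_seed))
            results = ml.model_search(ftab, split, target="gamma",
                                      k=config.cv_folds, hp_budget=config.hp_budget,
                                      seed=m_seed, subset_cap=config.subset_cap)
            board = pd.DataFrame(
                [{"rank": i + 1, "features": "+".join(r.features),
                  "cv_pearson": r.cv_pearson, "cv_mse": r.cv_mse,
                  "test_pearson": r.test_pearson}
                 for i, r in enumerate(results)])
            _write(board, out / "ml_results.tsv")
            per_inh = pd.DataFrame(
                [(inh, results[0].test_pearson_per_inhibitor[inh],
                  results[0].test_mse_per_inhibitor[inh])
                 for inh in sorted(results[0].test_pearson_per_inhibitor)],
                columns=["inhibitor", "test_pearson", "test_mse"])
            _write(per_inh, out / "ml_test_per_inhibitor.tsv")

        for p in sorted(out.glob("*.tsv")):
            manifest["outputs"][p.name] = _checksum(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True, default=str))
    except Exception as exc:          # abort with stage context
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    return out
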