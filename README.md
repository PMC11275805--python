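# dms-tki

Analysis pipeline for deep mutational scanning (DMS) of a kinase domain
under a panel of ATP-competitive inhibitors: pooled-selection fitness
scoring on a cell-doubling-rate scale, resistance/sensitivity
classification, cross-inhibitor differential analysis, hotspot
aggregation by inhibitor type, and a feature-augmented machine-learning
fitness predictor. A synthetic-data generator with known ground truth
stands in for raw sequencing data, so every stage is testable end to
end on a laptop.

## Who this is for

Groups running pooled growth-selection screens of kinase variants
against small-molecule inhibitors (e.g. Ba/F3-style selections where a
variant library competes under drug at IC50, sampled by sequencing at
several timepoints), who need reproducible scoring and a principled
definition of "resistance mutation" across a drug panel.

## The model

Counts per variant ν, replicate r and timepoint t are wild-type
normalized:

    m(ν,r,t) = log2(c(ν,r,t) + δ) − mean over synonymous w of log2(c(w,r,t) + δ)

and regressed on the integer time index per replicate. Because the
experiment holds wild-type growth at exactly two doublings per sampling
interval in every condition, the averaged slope β_ν is the variant's
log2 growth-rate offset from wild type per interval: β = 0 is wild-type
growth, β = −2 means cells are not growing (2^(2−2) = 1× per interval),
β = +1 means an extra doubling (2^(2+1) = 8×). Standard errors come
from count-level (Poisson) error propagation by default; see
`docs/methods.md`.

Derived quantities and calls:

* recentered score γ_ν = β_ν,inhibitor − β_ν,DMSO (cancels
  expression/stability effects, isolating drug sensitivity);
* **resistance mutation**: P(β_inh < 0.5) ≤ 0.1 (one-sided test against
  the effect threshold) AND β_DMSO ≤ 0;
* **resistance position**: ≥ 1 resistance mutation at the position;
* differential **GOF** (γ > 0.75) / **LOF** (γ < 0), hotspot counts per
  (position, inhibitor type), type-shared/exclusive resistance sets,
  and divergent-pair analysis (GOF under one inhibitor, LOF under the
  other).

The predictor is a gradient-boosted tree regressor over 14
interpretable features — a protein-language-model log-likelihood ratio
(always included, constrained positive) plus 13 optional
structural/chemical features (stability change constrained negative,
the rest median-binned) — selected by exhaustive feature-subset
enumeration (2^13 = 8192 models, or a capped prefix) under grouped
10-fold cross-validation that holds out whole positions and amino
acids, with whole inhibitors held out for the final test.

## Worked example

```bash
python examples/01_simulate_and_score.py
```

prints (abridged):

```
DMSO: kept 302/302 variants after the mean>=4 / zero-fraction filters
  median score -0.12 (negative = slower than wild type under this condition)
  synonymous scores center at +0.0000 (wild-type anchor; 0 by construction)
  planted resistance 1062R: beta = -0.12 +/- 0.009
crizo-like: kept 302/302 variants after the mean>=4 / zero-fraction filters
  median score -1.58 (negative = slower than wild type under this condition)
  planted resistance 1062R: beta = +1.11 +/- 0.006
```

The planted resistance mutation is indistinguishable from its mild
control phenotype in DMSO (β ≈ −0.1) but gains about one extra
doubling per interval under the inhibitor — exactly the signature the
resistance caller looks for. `examples/02`–`05` walk through
classification, hotspot/differential analysis, the predictor, and the
one-call pipeline (`dt.run_pipeline(dt.RunConfig(...))`), which writes
every intermediate TSV plus a checksum manifest for byte-identical
reruns.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the doubling-rate worked example from scratch — a noise-free
simulated screen with a frozen variant, an eightfold-per-interval
variant and synonymous controls, wild type doubling twice per interval
— scores it with the production scorer, and writes the three scores as
JSON. The initial pool composition is randomized by `--seed`; the
scores are invariant to it.

## Layout

```
src/dms_tki/      library (types, simulate, counts, scoring, classify,
                  mlmodel, pipeline)
examples/         one narrative script per capability
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance.py
docs/methods.md   model, assumptions, parameter choices, limitations
```
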