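"""Call resistance mutations and positions for one inhibitor.

A resistance mutation must (a) grow significantly faster than wild
type under the inhibitor — one-sided test of beta against 0.5 with
tail-probability cutoff 0.1 — and (b) show no growth advantage in the
DMSO control (beta_DMSO <= 0).  The recentered score
gamma = beta_inhibitor - beta_DMSO isolates drug sensitivity from
expression/stability effects; gamma > 0.75 is gain-of-function,
gamma < 0 loss-of-function in the differential sense.
"""

import dms_tki as dt

library = dt.build_library(1059, 1073, dt.random_wt_sequence(15, seed=2), 11)
conditions = [dt.ConditionMeta("DMSO", "DMSO"), dt.ConditionMeta("inhibitor-A", "I_a")]
planted = {(1060, "K"), (1065, "Y"), (1070, "W")}
effects = dt.assign_true_scores(library, conditions, {"I": planted}, seed=2)
design = dt.SimDesign(3, 4, 500_000, "multinomial", seed=2)

scores = {}
for cond in conditions:
    kept, _ = dt.filter_variants(dt.simulate_counts(effects, cond, design))
    scores[cond.name] = dt.score_condition(kept)

calls = dt.call_resistance(scores["inhibitor-A"], scores["DMSO"])
res = calls[calls["is_resistance"] == True]  # noqa: E712
print(f"resistance mutations called: {len(res)} "
      f"(planted: {len(planted)})")
for _, r in res.iterrows():
    mark = "planted" if (r["position"], r["mut_aa"]) in planted else "extra"
    print(f"  {r['wt_aa']}{r['position']}{r['mut_aa']}: beta_inh={r['beta_inh']:+.2f} "
          f"beta_dmso={r['beta_dmso']:+.2f} gamma={r['gamma']:+.2f}  [{mark}]")

positions = dt.resistance_positions(calls)
print(f"resistance positions (>=1 resistance mutation): {sorted(positions)}")

gl = calls["gof"].sum(), calls["lof"].sum()
print(f"differential classes: {gl[0]} GOF (gamma>0.75), {gl[1]} LOF (gamma<0) "
      f"of {len(calls)} variants — LOF dominates because most variants lose "
      "growth under drug")
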