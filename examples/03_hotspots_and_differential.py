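"""Aggregate resistance across an inhibitor panel: hotspots, shared and
type-exclusive variants, and a divergent type I vs type II pair.

Positions where resistance mutations recur across inhibitors of one
type are candidate hotspots; variants resistant to one type but
sensitized to the other support sequential or combination dosing.
"""

import dms_tki as dt

library = dt.build_library(1059, 1078, dt.random_wt_sequence(20, seed=3), 11)
conditions = [
    dt.ConditionMeta("DMSO", "DMSO"),
    dt.ConditionMeta("typeI-1", "I_a"), dt.ConditionMeta("typeI-2", "I_b"),
    dt.ConditionMeta("typeII-1", "II"), dt.ConditionMeta("typeII-2", "II"),
]
# position 1063 resists both types; 1060/1071 are type-specific
effects = dt.assign_true_scores(
    library, conditions,
    {"I": {(1060, "R"), (1063, "H")}, "II": {(1071, "M"), (1063, "H")}}, seed=3)
design = dt.SimDesign(3, 4, 500_000, "multinomial", seed=3)

scores = {c.name: dt.score_condition(dt.filter_variants(
    dt.simulate_counts(effects, c, design))[0]) for c in conditions}
inhibitors = [c for c in conditions if not c.is_dmso]
calls = {c.name: dt.call_resistance(scores[c.name], scores["DMSO"])
         for c in inhibitors}

hs = dt.hotspot_counts(calls, conditions)
top = hs.counts[hs.counts["count"] > 0]
print("hotspot counts (resistance mutation-inhibitor pairs per position/type):")
print(top.to_string(index=False))

print("\nshared resistance variants by type combination:")
for combo, vs in sorted(hs.shared_sets.items()):
    if vs:
        names = ", ".join(f"{v.wt_aa}{v.position}{v.mut_aa}" for v in sorted(vs))
        print(f"  {'+'.join(combo)}: {names}")

excl = dt.type_exclusive_resistance(calls, conditions)
for t, vs in excl.items():
    print(f"type {t} exclusive: {len(vs)} variants "
          "(resistant to this type only — candidates for switching therapy)")

rec_a = dt.recenter(scores["typeI-1"], scores["DMSO"])
rec_b = dt.recenter(scores["typeII-1"], scores["DMSO"])
gof_a, gof_b = dt.differential_pairs(rec_a, rec_b,
                                     calls["typeI-1"], calls["typeII-1"])
print(f"\ntypeI-1 vs typeII-1 divergent mutations: "
      f"{len(gof_a)} GOF-in-I/LOF-in-II, {len(gof_b)} GOF-in-II/LOF-in-I")
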