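"""Conformational statistics of a covalent inhibitor's warhead.

Generates two-state trajectories for a reactive-competent system (both
states about equally populated) and for one where an extra side-chain
H-bond stabilizes the unreactive state, then pools 4 x 30 000 snapshots
each, builds Boltzmann-inversion surfaces and reports reactive fractions,
basin gaps and the distance-dihedral coupling.
"""

from covfes import (
    basin_delta,
    boltzmann_fes,
    coupling_report,
    hbond_occupancy,
    l718q_like_model,
    make_two_state_ensemble,
    pool_features,
    reactive_fraction,
    t790m_like_model,
)

for name, model in (
    ("reactive-competent (gatekeeper-mutant-like)", t790m_like_model()),
    ("H-bond-stabilized unreactive (P-loop-mutant-like)", l718q_like_model()),
):
    pooled = pool_features(make_two_state_ensemble(model, seed=11))
    fes = boltzmann_fes(pooled)
    stats = reactive_fraction(pooled, cutoff=3.9)
    p_a = (pooled["state"] == "a").mean()
    gap = basin_delta(p_a, 1 - p_a)
    hb = hbond_occupancy(pooled, cutoff=3.5)
    print(f"\n{name}:")
    print(f"  pooled snapshots: {len(pooled)} "
          f"(out of histogram range: {fes.meta['out_of_range']:.0f})")
    print(f"  reactive fraction (S-Cbeta < 3.9 A): {100 * stats.pooled_fraction:.1f}% "
          f"pooled; per replica "
          f"{[round(100 * f, 1) for f in stats.per_replica['fraction']]}")
    print(f"  basin gap dA(a->b) = {gap:+.2f} kcal/mol "
          f"(negative = unreactive state b more stable)")
    print(f"  H-bond occupancy (<= 3.5 A): {100 * hb['pooled']:.1f}%")

coup = coupling_report(pool_features(make_two_state_ensemble(t790m_like_model(), seed=11)))
print(f"\ndistance-dihedral coupling: point-biserial r = "
      f"{coup['point_biserial_r']:.2f} (permutation p = {coup['permutation_p']:.3f}); "
      f"{100 * coup['switch_crossing_fraction']:.0f}% of state switches cross "
      f"the 4.5 A midline within {coup['lag']} snapshots")
print("strong r means the warhead's approach distance and the acrylamide "
      "dihedral flip together, i.e. one conformational gate controls "
      "reactivity.")
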