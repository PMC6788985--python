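"""Power of a 19-locus panel to detect FST = 0.005 (drift simulation)."""
from escapetrace.power import (PowerScenario, default_panel_frequencies,
                               drift_for_target_fst, simulate_power)

base = default_panel_frequencies(seed=0)       # 19 loci, He ~ 0.8
sizes = [50] * 10                               # ten samples of 50
t = drift_for_target_fst(0.005, ne=1000)
scen = PowerScenario(base, sizes, ne=1000, t=t, replicates=100)
res = simulate_power(scen, seed=1)
print(f"target FST {res['expected_fst']:.4f} "
      f"(Ne = 1000 drifting {t} generations)")
print(f"power = {100 * res['power']:.0f}% at alpha = 0.05 over "
      f"{res['replicates']} replicates; realized mean FST "
      f"{res['realized_mean_fst']:.4f}")
print("a highly polymorphic microsatellite panel detects even this weak "
      "differentiation essentially always")
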