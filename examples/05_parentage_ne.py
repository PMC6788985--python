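"""Parent-offspring LOD assignment and LD effective population size."""
from escapetrace.dataset import allele_frequencies
from escapetrace.ne import ne_ld
from escapetrace.parentage import ParentageSettings, find_parent_offspring
from escapetrace.simulate import (PopulationSpec, ScenarioSpec,
                                  generate_scenario, wright_fisher_sample)

pops = [PopulationSpec("adults", 120, "farm-associated", "res"),
        PopulationSpec("juv", 100, "YoY", "res")]
spec = ScenarioSpec(pops, {"res": 0.01}, pop_fst=0.003, missing_rate=0.003,
                    trios=[("adults", "juv", 6)], seed=3)
ds, truth = generate_scenario(spec)
pairs = find_parent_offspring(ds.subset_populations(["adults"]),
                              ds.subset_populations(["juv"]),
                              allele_frequencies(ds),
                              ParentageSettings(reps=1000), seed=5)
print(f"accepted pairs (critical LOD {pairs.attrs['critical_lod']:.2f}):")
print(pairs[["adult", "juvenile", "lod", "mismatches"]].round(2).to_string())
n_true = 2 * len(truth["individuals"].query("origin == 'trio_offspring'"))
print(f"{n_true} true parent-offspring links were planted\n")

wf = wright_fisher_sample(ne=100, n_sample=60, n_loci=19, seed=0)
est = ne_ld(wf, 0, freq_cutoff=0.02)
print(f"LD-Ne from a sample of 60 out of a true Ne = 100 population: "
      f"{est.ne:.0f} (95% CI {est.ci95[0]:.0f}, {est.ci95[1]:.0f})")
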