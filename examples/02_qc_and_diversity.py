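"""Locus QC (null-allele EM) and per-population diversity summaries."""
from escapetrace import missing_summary
from escapetrace.diversity import diversity_summary
from escapetrace.nullalleles import apply_locus_qc, locus_qc, null_allele_table
from escapetrace.simulate import default_survey_scenario, generate_scenario

ds, _ = generate_scenario(default_survey_scenario(seed=1))
print("missing data per locus (tail):")
print(missing_summary(ds).tail(3).round(4).to_string())

nulls = null_allele_table(ds)
qc = locus_qc(nulls, drop_threshold=0.1)
print("\nloci flagged for removal (mean null frequency >= 0.1):")
print(qc[qc["drop"]].round(3).to_string())
apply_locus_qc(ds, qc)

table = diversity_summary(ds.active_view())
print(f"\ndiversity on the {len(ds.active_loci)}-locus active panel "
      "(A alleles, Ae effective, Ar rarefied, Ho/He heterozygosity, FIS):")
print(table.groupby("group")[["A", "Ae", "Ar", "Ho", "He", "FIS"]]
      .mean().round(3).to_string())
print("farmed strains show the bottleneck signature: fewer (effective) "
      "alleles and lower heterozygosity than the wild groups")
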