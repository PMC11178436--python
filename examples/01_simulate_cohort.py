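"""Simulate a clonal duckweed cohort and write VCF + metadata + truth.

Eight diploid L. minor ponds and four triploid (M/M/T) L. japonica ponds
are placed in a 200 km box; each pond holds clone-mates of one founder.
"""

from lemnapop import CohortSpec, simulate_cohort, write_cohort

spec = CohortSpec(n_pops_sp1=8, n_pops_sp2=4, samples_per_pop=4,
                  n_sites=4000, seed=1)
table, truth = simulate_cohort(spec)
paths = write_cohort(table, truth, "cohort")

print(f"sites x samples: {table.n_sites} x {table.n_samples}")
print(truth.samples.groupby(["species", "ploidy"]).size())
print(f"wrote: {', '.join(paths.values())}")
# Each sample is a clone of its pond founder; the truth table records the
# hidden species, ploidy and population used by the recovery tests.
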