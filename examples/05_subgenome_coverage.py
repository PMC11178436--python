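"""Sub-genome coverage on a combined parental reference.

An M/M/T hybrid maps two haplotypes to the M sub-genome and one to T, so
its mean coverage ratio M:T is ~2:1; a pure diploid leaves the T sub-genome
essentially uncovered.
"""

from lemnapop import single_sample_subgenome_table, subgenome_coverage

for comp in ("MMT", "MM", "MT", "MTT"):
    table = single_sample_subgenome_table(comp, n_sites_per_subgenome=10_000, seed=1)
    cov = subgenome_coverage(table, "S1")
    ratio = f"{cov.ratio:.2f}" if cov.ratio == cov.ratio else "undefined"
    print(f"true {comp:4s}: depth M {cov.mean_depth['M']:5.1f}, "
          f"T {cov.mean_depth['T']:5.1f}, ratio {ratio:>9s}, "
          f"T covered {100 * cov.t_nonzero_fraction:5.1f}% -> call {cov.species_call}")
# Coverage ratios near 2, 1 and 0.5 recover the hybrid dosage configuration;
# < 5% covered T sites identifies the pure species.
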