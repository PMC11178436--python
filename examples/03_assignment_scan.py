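"""Per-SNP assignment-marker scan between the two species.

Each SNP is tested with a quasibinomial logistic model under three genotype
codings; markers with FDR < 0.05 and >= 80% deviance explained are the
species-diagnostic "assignment markers".
"""

from lemnapop import CohortSpec, filter_variants, scan_assignment_markers, simulate_cohort

table, truth = simulate_cohort(CohortSpec(seed=1))
filtered, _ = filter_variants(table)
species = dict(zip(truth.samples["sample"], truth.samples["species"]))

results, summary = scan_assignment_markers(filtered, species)
print(f"scanned {summary.n_scanned} sites ({summary.n_skipped} skipped)")
print(f"significant assignment markers: {summary.n_significant} "
      f"({100 * summary.fraction_significant:.2f}%)")
print(f"difference classes among markers: {summary.diff_class_counts}")
# Sites fixed between the parental genomes appear as 0/0 in the diploid
# species and 0/1 in the triploid hybrid (the diploid caller folds the 1/3
# dosage into a het call), so most markers are hom-vs-het differences.
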