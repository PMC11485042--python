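"""Gene-level aggregation of per-variant GWAS evidence.

Demonstrates the sum-of-chi-squares gene score: per-variant p-values in a
50 kb window are combined against a chi-square-mixture null whose weights
are the eigenvalues of the local LD matrix, so correlated variants are not
double-counted.
"""

import numpy as np

from omicsmeta import SimConfig, PlantedGene, simulate_cohort
from omicsmeta.gwas import run_gwas_aggregation, single_variant_gwas
from omicsmeta.pipeline import prepare_cohort_trait

cohort = simulate_cohort(
    SimConfig(seed=3, n_samples=500, n_genes=60,
              planted=[PlantedGene("G0004", gwas_h2=0.08)])
)
trait_resid, info = prepare_cohort_trait(cohort, seed=3)
print("retained genotype PCs:", info["retained_pcs"])

variants = cohort.variants
summary = single_variant_gwas(
    np.vstack([v.dosages for v in variants]),
    [v.variant_id for v in variants],
    [v.chrom for v in variants],
    [v.pos for v in variants],
    trait_resid.to_numpy(),
)
print(f"scanned {len(summary)} variants; "
      f"min per-variant p = {summary['p'].min():.2e}")

scores = run_gwas_aggregation(
    summary, cohort.genes, cohort.dosage_map, "trait"
)
top = scores.nsmallest(3, "p")[["gene_id", "p", "n_units"]]
print(top.to_string(index=False))
# G0004 carries the planted common-variant signal: its gene score should
# be orders of magnitude below the null genes, using ~5 variants each.
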