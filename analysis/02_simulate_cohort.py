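#!/usr/bin/env python
"""Generate the synthetic study cohort and write it in standard formats.

120 diploid samples, 8 LD blocks, planted SV and small-variant cis-QTL, two
small-variant/SV pairs in perfect LD, a grouped (splicing-style) feature,
class-specific missingness (higher for SVs) and 2% het->hom errors on SV
genotypes.  Writes VCF, QTLtools-dialect phenotype BED, covariate TSV and a
ground-truth JSON under results/cohort/.
"""

from pathlib import Path

import numpy as np

from svmolqtl import SimConfig, simulate_qtl_cohort
from svmolqtl.io import (write_covariates_tsv, write_phenotype_bed,
                         write_truth_json, write_vcf)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 3


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_samples=120, n_blocks=8, variants_per_block=25,
                    n_perfect_ld_pairs=2, seed=SEED)
    cohort = simulate_qtl_cohort(cfg, n_sv_features=3, n_small_features=3,
                                 n_null_features=4, beta=1.0,
                                 plant_on_ld_pairs=2,
                                 group_sizes={"gene0": 3})
    write_vcf(cohort.genotypes, OUT / "genotypes.vcf")
    write_phenotype_bed(cohort.phenotypes, OUT / "phenotypes.bed")
    write_covariates_tsv(cohort.covariates, OUT / "covariates.tsv")
    write_truth_json(cohort.truth, OUT / "truth.json")
    g = cohort.genotypes
    print(f"cohort: {g.n_samples} samples, {g.n_variants} variants "
          f"({int(g.variants['is_sv'].sum())} SVs), "
          f"{cohort.phenotypes.n_features} phenotypes")
    print(f"mean missingness: small "
          f"{np.isnan(g.dosages[:, ~g.variants['is_sv']]).mean():.3%}, "
          f"SV {np.isnan(g.dosages[:, g.variants['is_sv'].to_numpy()]).mean():.3%}")
    print(f"planted effects: {len(cohort.truth.causal_map)}; "
          f"perfect-LD pairs: {cohort.truth.perfect_ld_pairs}")


if __name__ == "__main__":
    main()
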