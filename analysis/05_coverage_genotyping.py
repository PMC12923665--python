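#!/usr/bin/env python
"""Coverage-based duplication genotyping and genotype-correction retest.

Simulates 500-bp depth tracks for 120 samples around two duplications at a
13.5x background, genotypes them from the region fold change (>=1.3x het,
>=1.8x hom), measures concordance against a deliberately corrupted caller-
style genotype set (het carriers dropped to hom-ref), and shows that
correcting the misgenotyped samples strengthens a planted association.
Writes results/dup_calls.tsv and results/dup_concordance.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from svmolqtl import (SimConfig, concordance, correct_and_retest,
                      genotype_duplications, simulate_coverage,
                      simulate_genotypes, simulate_phenotypes)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 5


def main() -> None:
    ROOT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    samples = [f"sample{str(i).zfill(3)}" for i in range(120)]
    regions = [("1", 100_000, 130_000), ("1", 300_000, 330_000)]
    truth_geno = [{s: int(g) for s, g in
                   zip(samples, rng.choice([0, 1, 2], size=120, p=[0.5, 0.35, 0.15]))}
                  for _ in regions]
    tracks = simulate_coverage(list(zip(regions, truth_geno)), depth_mean=13.5,
                               window_bp=500, seed=SEED + 1)
    calls = genotype_duplications(tracks, regions)
    calls.to_csv(ROOT / "dup_calls.tsv", sep="\t", index=False)

    code = {"0/0": 0.0, "0/1": 1.0, "1/1": 2.0}
    cov_based = pd.DataFrame(
        {s: [code[calls[(calls["start"] == r[1]) & (calls["sample"] == s)]
                  ["genotype"].iloc[0]] for r in regions] for s in samples},
        index=[f"dup{i}" for i in range(len(regions))])
    truth_df = pd.DataFrame({s: [float(tg[s]) for tg in truth_geno]
                             for s in samples},
                            index=[f"dup{i}" for i in range(len(regions))])
    # caller-style query: 4 het carriers of dup0 miscalled as hom-ref
    query = truth_df.copy()
    hets = [s for s in samples if truth_df.loc["dup0", s] == 1.0][:4]
    query.loc["dup0", hets] = 0.0
    res = concordance(cov_based, query)
    res.confusion.to_csv(ROOT / "dup_concordance.tsv", sep="\t")
    print("coverage-based vs caller-style genotypes:")
    print(res.confusion.to_string())
    print(f"aggregate error rate {res.error_rate:.3%}; "
          f"het F1 = {res.per_class_f1[1]:.3f}")

    # correcting the misgenotyped carriers strengthens a planted association
    cfg = SimConfig(n_samples=120, n_blocks=1, variants_per_block=5,
                    maf_range=(0.3, 0.5), sv_fraction=1.0,
                    missingness_rate_sv=0.0, seed=SEED + 2)
    g, truth = simulate_genotypes(cfg)
    vid = str(g.variants["id"].iloc[0])
    truth.causal_map["dupgene"] = (vid, 0.9)
    phenos, cov = simulate_phenotypes(g, truth, cfg)
    dose = g.dosage_of(vid)
    het_idx = np.flatnonzero(dose == 1)[:4]
    corrections = [(g.samples[i], vid, 1.0) for i in het_idx]
    g.dosages[het_idx, 0] = 0.0  # miscall the carriers
    before, after = correct_and_retest(g, corrections, phenos, cov,
                                       "dupgene", vid)
    print(f"association before correction: p = {before.p:.3g}; "
          f"after: p = {after.p:.3g}")


if __name__ == "__main__":
    main()
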