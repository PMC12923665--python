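"""Formats, filters, LD and covariate construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svmolqtl import (FilterConfig, GenotypeMatrix, PhenotypeTable,
                      SimConfig, classify_variant, compute_ld, filter_variants,
                      grm_pca, inject_missingness, inverse_normal_transform,
                      ld_prune, prepare_expression, read_genotypes,
                      select_rna_pcs, simulate_genotypes, summarize_counts)
from svmolqtl.datamodel import VARIANT_COLUMNS, r2_pairwise, scree_elbow
from svmolqtl.io import (read_phenotype_bed, write_phenotype_bed, write_vcf,
                         read_covariates_tsv, write_covariates_tsv)


def _toy_matrix(dosages, positions=None, chrom="1", is_sv=None):
    dosages = np.asarray(dosages, dtype=float)
    n, v = dosages.shape
    positions = positions if positions is not None else (np.arange(v) + 1) * 100
    is_sv = is_sv if is_sv is not None else [False] * v
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(v)], "chrom": chrom,
        "pos": positions, "ref_len": 1, "alt_len": 1,
        "var_class": ["DEL" if s else "SNP" for s in is_sv],
        "is_sv": is_sv, "sv_len": [60 if s else 0 for s in is_sv],
    })
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosages)


class TestVariantClassification:
    @pytest.mark.parametrize("ref_len,alt_len,svtype,svlen,expected", [
        (1, 1, None, None, ("SNP", False)),
        (61, 1, None, None, ("DEL", True)),     # 60-bp deletion allele
        (1, 61, None, None, ("INS", True)),
        (47, 1, None, None, ("INDEL", False)),  # 46-bp indel stays small
        (1, 1, "DUP", 5000, ("DUP", True)),
        (1, 1, "INV", 300, ("INV", True)),
    ])
    def test_fifty_bp_rule(self, ref_len, alt_len, svtype, svlen, expected):
        var_class, is_sv, _ = classify_variant(ref_len, alt_len, svtype, svlen)
        assert (var_class, is_sv) == expected

    def test_invariant_sv_iff_sv_class(self):
        cfg = SimConfig(n_samples=30, n_blocks=3, variants_per_block=20,
                        sv_fraction=0.3, seed=2)
        g, _ = simulate_genotypes(cfg)
        sv_class = g.variants["var_class"].isin(["DEL", "INS", "DUP", "INV"])
        assert (g.variants["is_sv"] == sv_class).all()
        assert (g.variants.loc[g.variants["is_sv"], "sv_len"] >= 50).all()


class TestVcfRoundTrip:
    def test_write_read_preserves_dosages_and_classes(self, tmp_path, cohort):
        g = cohort.genotypes  # includes missingness and SVs
        path = tmp_path / "cohort.vcf"
        write_vcf(g, path)
        g2 = read_genotypes(str(path))
        assert sorted(g2.variants["id"]) == sorted(g.variants["id"])
        order = [g2.variant_index(v) for v in g.variants["id"]]
        got = g2.dosages[:, order]
        assert got.shape == g.dosages.shape
        assert np.array_equal(np.isnan(got), np.isnan(g.dosages))
        assert np.array_equal(got[~np.isnan(got)], g.dosages[~np.isnan(g.dosages)])
        meta = g2.variants.iloc[order]
        assert np.array_equal(meta["is_sv"].to_numpy(),
                              g.variants["is_sv"].to_numpy())
        assert np.array_equal(meta["var_class"].to_numpy(),
                              g.variants["var_class"].to_numpy())

    def test_small_caller_length_cap(self, tmp_path):
        # a 46-bp indel without SV annotation is dropped under a 45-bp cap
        path = tmp_path / "indel.vcf"
        ref46 = "A" * 47
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\n"
            f"1\t100\tindel46\t{ref46}\tA\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "1\t200\tsnp\tA\tG\t.\tPASS\t.\tGT\t1/1\t./.\n")
        full = read_genotypes(str(path))
        assert set(full.variants["id"]) == {"indel46", "snp"}
        capped = read_genotypes(str(path), small_caller_cap=45)
        assert set(capped.variants["id"]) == {"snp"}
        assert np.isnan(capped.dosage_of("snp")[1])

    def test_multiallelic_split_and_het_dosage(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\n"
            "1\t100\tm\tA\tG,T\t.\tPASS\t.\tGT\t1/2\t0/1\n")
        g = read_genotypes(str(path))
        assert g.n_variants == 2
        assert list(g.dosages[:, 0]) == [1.0, 1.0]  # G allele
        assert list(g.dosages[:, 1]) == [1.0, 0.0]  # T allele


class TestFilters:
    def test_maf_missingness_and_window_boundaries(self):
        n = 117
        d = np.zeros((n, 4))
        d[0, 0] = 2.0                     # AC=2 -> MAF 0.85% : excluded
        d[: n // 2, 1] = 1.0              # common, clean : included
        d[: n // 2, 2] = 1.0
        d[:12, 2] = np.nan                # 12/117 = 10.3% missing : excluded
        d[: n // 2, 3] = 1.0              # common, clean but out of window
        g = _toy_matrix(d, positions=[500, 600, 700, 500_000 + 1_000_001])
        feats = PhenotypeTable(
            pd.DataFrame([{"chrom": "1", "start": 500_000, "end": 500_100,
                           "pid": "f", "gid": "f", "strand": "+"}]),
            np.zeros((1, n)), [f"s{i}" for i in range(n)])
        cis = filter_variants(g, feats)
        assert list(cis["f"]) == [1]
        # boundary: exactly 1 Mb from the anchor is included
        g2 = _toy_matrix(d[:, [1, 1]], positions=[500_000, 1_500_000])
        cis2 = filter_variants(g2, feats)
        assert list(cis2["f"]) == [0, 1]

    def test_filter_is_idempotent(self, cohort):
        cis = filter_variants(cohort.genotypes, cohort.phenotypes)
        for pid, idx in cis.items():
            sub = cohort.genotypes.subset_variants(idx)
            cis_again = filter_variants(sub, cohort.phenotypes)
            assert len(cis_again[pid]) == len(idx)


class TestLd:
    def test_identical_and_mirrored_vectors_give_r2_one(self):
        x = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        g = _toy_matrix(np.column_stack([x, x, 2 - x]))
        pairs = {p.variant_b: p.r2 for p in compute_ld(g, "v0")}
        assert pairs["v1"] == pytest.approx(1.0)
        assert pairs["v2"] == pytest.approx(1.0)

    def test_six_sample_toy_matches_direct_formula(self):
        x = [0.0, 1.0, 2.0, 0.0, 1.0, 2.0]
        y = [0.0, 1.0, 1.0, 0.0, 2.0, 2.0]
        n = 6
        sx, sy = sum(x), sum(y)
        sxx = sum(v * v for v in x)
        syy = sum(v * v for v in y)
        sxy = sum(a * b for a, b in zip(x, y))
        num = n * sxy - sx * sy
        expected = num * num / ((n * sxx - sx * sx) * (n * syy - sy * sy))
        r2, used = r2_pairwise(np.array(x), np.array(y))
        assert used == 6
        assert r2 == pytest.approx(expected, abs=1e-12)

    def test_r2_uses_pairwise_complete_samples_only(self):
        x = np.array([0, 1, 2, 0, np.nan, 2.0])
        y = np.array([0, 1, 2, np.nan, 1, 2.0])
        r2, n = r2_pairwise(x, y)
        assert n == 4
        assert r2 == pytest.approx(1.0)

    def test_affine_recoding_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 40).astype(float)
        y = rng.integers(0, 3, 40).astype(float)
        r2a, _ = r2_pairwise(x, y)
        r2b, _ = r2_pairwise(2 - x, 3 * y + 1)
        assert r2a == pytest.approx(r2b)


class TestLdPrune:
    def test_independent_variants_survive(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(300, 10)).astype(float)
        g = _toy_matrix(d)
        pruned = ld_prune(g)
        assert pruned.n_variants == 10

    def test_duplicated_column_loses_exactly_one_copy(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, 100).astype(float)
        d = np.column_stack([col, col, rng.integers(0, 3, 100)])
        pruned = ld_prune(_toy_matrix(d))
        assert pruned.n_variants == 2
        assert len({tuple(pruned.dosages[:, j]) for j in range(2)}) == 2

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=(50, 3)).astype(float)
        noisy = np.clip(base + rng.integers(-1, 2, size=(50, 3)), 0, 2)
        d = np.column_stack([base, noisy])
        g = _toy_matrix(d)
        maf = g.maf()
        # independent oracle: same greedy rule, straight double loop
        keep = list(range(6))
        changed = True
        while changed:
            changed = False
            for a in range(len(keep)):
                for b in range(a + 1, len(keep)):
                    i, j = keep[a], keep[b]
                    r = np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2
                    if r > 0.2:
                        keep.remove(i if maf[i] <= maf[j] else j)
                        changed = True
                        break
                if changed:
                    break
        pruned = ld_prune(g)
        assert sorted(pruned.variants["id"]) == sorted(f"v{k}" for k in keep)

    def test_no_surviving_pair_exceeds_threshold(self, cohort):
        pruned = ld_prune(cohort.genotypes_clean.subset_variants(range(40)),
                          r2=0.5)
        for a in range(pruned.n_variants):
            for b in range(a + 1, pruned.n_variants):
                if pruned.variants["chrom"].iloc[a] != pruned.variants["chrom"].iloc[b]:
                    continue
                r2, _ = r2_pairwise(pruned.dosages[:, a], pruned.dosages[:, b])
                assert np.isnan(r2) or r2 <= 0.5


class TestGrmPca:
    def test_cluster_structure_separates_on_pc1(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, size=40).astype(float)
        b = rng.integers(0, 3, size=40).astype(float)
        d = np.vstack([np.tile(a, (10, 1)), np.tile(b, (10, 1))])
        d += rng.normal(0, 0.01, d.shape)
        g = _toy_matrix(d)
        pcs, _ = grm_pca(g, pc_range=(1, 3))
        pc1 = pcs.iloc[:, 0].to_numpy()
        assert (pc1[:10] > 0).all() != (pc1[10:] > 0).all()

    def test_pc_directions_are_orthogonal(self, cohort):
        pcs, evals = grm_pca(cohort.genotypes_clean, pc_range=(1, 6))
        V = pcs.to_numpy() / np.sqrt(np.clip(evals[:6], 1e-12, None))
        gram = V.T @ V
        assert np.allclose(gram, np.eye(6), atol=1e-8)

    def test_eigenvalues_match_dense_eigensolver_on_toy(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(5, 12)).astype(float)
        g = _toy_matrix(d)
        _, evals = grm_pca(g, pc_range=(1, 5))
        # oracle: rebuild the standardized GRM by hand and use eigvalsh
        p = d.mean(axis=0) / 2
        ok = (p > 0) & (p < 1)
        Z = (d[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        expected = np.sort(np.linalg.eigvalsh(Z @ Z.T / ok.sum()))[::-1]
        assert np.allclose(evals, expected, atol=1e-10)


class TestRnaPcSelection:
    def test_single_dominant_eigenvalue_elbows_at_one(self):
        lam = np.array([50.0, 1.0, 0.9, 0.8, 0.7, 0.6])
        assert scree_elbow(lam) == 1

    def test_planted_factors_recovered_within_one(self):
        rng = np.random.default_rng(6)
        k = 4
        n, m = 80, 300
        F = rng.normal(size=(n, k)) * np.array([9, 8, 7, 6.0])
        W = rng.normal(size=(k, m))
        X = F @ W + rng.normal(0, 1.0, size=(n, m))
        feats = pd.DataFrame({"chrom": "1", "start": np.arange(m), "end": np.arange(m) + 1,
                              "pid": [f"g{i}" for i in range(m)],
                              "gid": [f"g{i}" for i in range(m)], "strand": "+"})
        phenos = PhenotypeTable(feats, X.T, [f"s{i}" for i in range(n)])
        _, _, n_pcs, _ = select_rna_pcs(phenos)
        assert abs(n_pcs - k) <= 1

    def test_known_covariate_captured_by_pc_is_removed(self):
        rng = np.random.default_rng(7)
        n, m = 60, 100
        f1 = rng.normal(size=n) * 10
        X = np.outer(f1, rng.normal(size=m)) + rng.normal(0, 0.5, size=(n, m))
        feats = pd.DataFrame({"chrom": "1", "start": np.arange(m), "end": np.arange(m) + 1,
                              "pid": [f"g{i}" for i in range(m)],
                              "gid": [f"g{i}" for i in range(m)], "strand": "+"})
        phenos = PhenotypeTable(feats, X.T, [f"s{i}" for i in range(n)])
        known = pd.DataFrame({"batch": f1, "age": rng.normal(size=n)},
                             index=[f"s{i}" for i in range(n)])
        _, kept, _, _ = select_rna_pcs(phenos, known)
        assert "batch" not in kept.columns and "age" in kept.columns


class TestExpressionPreparation:
    def _mats(self):
        samples = [f"s{i}" for i in range(20)]
        tpm = pd.DataFrame(1.0, index=["lowtpm", "boundary", "good"], columns=samples)
        counts = pd.DataFrame(100, index=tpm.index, columns=samples)
        tpm.loc["lowtpm"] = 0.05                      # fails TPM everywhere
        counts.loc["boundary"] = 0                    # passes in exactly 10%
        counts.loc["boundary", samples[:2]] = 10
        return tpm, counts

    def test_threshold_and_boundary_rules(self):
        tpm, counts = self._mats()
        out = prepare_expression(tpm, counts)
        assert set(out.features["pid"]) == {"boundary", "good"}

    def test_each_feature_is_permutation_of_int_quantiles(self):
        tpm, counts = self._mats()
        rng = np.random.default_rng(8)
        # continuous values: the rank-based transform then yields the same
        # sorted quantile vector for every feature
        for fid in tpm.index:
            tpm.loc[fid] = rng.lognormal(1, 1, tpm.shape[1]) + 0.2
        out = prepare_expression(tpm, counts)
        sorted_rows = np.sort(out.values, axis=1)
        for row in sorted_rows[1:]:
            assert np.allclose(row, sorted_rows[0])

    def test_int_values_are_the_offset_normal_quantiles(self):
        x = np.random.default_rng(9).normal(size=31)
        out = inverse_normal_transform(x)
        expected = stats.norm.ppf((np.arange(1, 32) - 0.5) / 31)
        assert np.allclose(np.sort(out), expected)


class TestCallsetAccounting:
    def test_reported_increases(self):
        base = {"Autosomes": 22_636_961, "MSY": 20_177, "equal": 5, "zero": 0}
        comp = {"Autosomes": 23_163_376, "MSY": 69_402, "equal": 5, "zero": 9}
        out = summarize_counts(base, comp).set_index("region")
        assert out.loc["MSY", "increase_pct"] == 244.0
        assert out.loc["Autosomes", "increase_pct"] == 2.3
        assert out.loc["equal", "increase_pct"] == 0.0
        assert np.isnan(out.loc["zero", "increase_pct"])

    def test_mismatched_regions_rejected(self):
        with pytest.raises(ValueError):
            summarize_counts({"a": 1}, {"b": 2})


class TestTextRoundTrips:
    def test_phenotype_bed_and_covariates(self, tmp_path, cohort):
        bed = tmp_path / "phenos.bed"
        write_phenotype_bed(cohort.phenotypes, bed)
        back = read_phenotype_bed(bed)
        assert back.samples == cohort.phenotypes.samples
        assert np.allclose(back.values, cohort.phenotypes.values, atol=1e-5)
        tsv = tmp_path / "cov.tsv"
        write_covariates_tsv(cohort.covariates, tsv)
        cov = read_covariates_tsv(tsv)
        assert np.allclose(cov.to_numpy(), cohort.covariates.to_numpy())
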