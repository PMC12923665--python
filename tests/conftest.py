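import pytest

from svmolqtl import SimConfig, simulate_qtl_cohort


@pytest.fixture(scope="session")
def cohort():
    """Small mixed cohort: planted SV and small-variant QTL, null features,
    perfect-LD pairs, class-specific missingness and 2% SV het->hom errors."""
    cfg = SimConfig(n_samples=120, n_blocks=8, variants_per_block=25,
                    n_perfect_ld_pairs=2, seed=3)
    return simulate_qtl_cohort(cfg, n_sv_features=3, n_small_features=3,
                               n_null_features=4, beta=1.0)


@pytest.fixture(scope="session")
def mapped(cohort):
    from svmolqtl import classify_leads, map_molqtl
    perm, signals = map_molqtl(cohort.genotypes, cohort.phenotypes,
                               cohort.covariates, n_perm=200, seed=1)
    classes = classify_leads(signals, cohort.genotypes.variants)
    return perm, signals, classes
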