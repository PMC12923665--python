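"""Sensitivity experiments and cohort-level genotype summaries.

These experiments quantify how het->hom genotyping errors and unequal
genotype missingness distort molQTL detection on synthetic cohorts with
planted effects, alongside descriptive summaries (SV discovery saturation,
singleton accounting, per-sample heterozygosity) of the genotype matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cisqtl import association_single, map_molqtl
from .datamodel import GenotypeMatrix
from .simdata import SimConfig, simulate_genotypes, simulate_phenotypes, simulate_qtl_cohort
from .svenrich import classify_leads


@dataclass
class ExperimentResult:
    grid: np.ndarray
    detection_rate: np.ndarray
    details: pd.DataFrame
    replicates: int
    seed: int


def _detected_sv_features(cohort, n_perm: int, seed: int, fdr: float) -> dict[str, bool]:
    """Planted-SV features detected as SV molQTL (significant AND SV lead)."""
    perm, signals = map_molqtl(cohort.genotypes, cohort.phenotypes,
                               cohort.covariates, n_perm=n_perm, seed=seed,
                               fdr=fdr, conditional=False)
    classes = classify_leads(signals, cohort.genotypes.variants)
    by_feature = {cl.signal.feature: cl for cl in classes if cl.signal.rank == 0}
    out = {}
    for fid, (vid, _) in cohort.truth.causal_map.items():
        if not fid.startswith("svgene"):
            continue
        cl = by_feature.get(fid)
        out[fid] = bool(cl is not None and cl.lead_class == "SV")
    return out


def error_sensitivity_experiment(config: SimConfig, epsilon_grid: list[float],
                                 replicates: int = 20, seed: int = 0,
                                 n_sv_features: int = 8, n_null_features: int = 4,
                                 beta: float = 1.0, n_perm: int = 200,
                                 fdr: float = 0.05) -> ExperimentResult:
    """Detection of planted SV molQTL as het->hom errors accumulate.

    For each epsilon the same per-replicate cohort is corrupted with
    het->homref errors injected into SV genotypes only (the error draws are
    coupled across epsilons, so the flipped set grows monotonically with the
    rate), the full mapping plus lead classification is run, and the
    fraction of planted SV molQTL still detected as SV-led is recorded.
    """
    grid = np.asarray(sorted(epsilon_grid), dtype=float)
    rates = np.zeros(len(grid))
    rows = []
    for gi, eps in enumerate(grid):
        hits = []
        for rep in range(replicates):
            cfg = replace(config, seed=seed + 1000 * rep)
            cohort = simulate_qtl_cohort(cfg, n_sv_features=n_sv_features,
                                         n_null_features=n_null_features,
                                         beta=beta, error_rate=float(eps))
            det = _detected_sv_features(cohort, n_perm=n_perm,
                                        seed=seed + 1000 * rep, fdr=fdr)
            hits.extend(det.values())
            rows.append(dict(epsilon=float(eps), replicate=rep,
                             n_planted=len(det), n_detected=int(sum(det.values()))))
        rates[gi] = float(np.mean(hits)) if hits else np.nan
    return ExperimentResult(grid=grid, detection_rate=rates,
                            details=pd.DataFrame(rows), replicates=replicates,
                            seed=seed)


def missingness_bias_experiment(config: SimConfig, missing_grid: list[int],
                                seed: int = 0, beta: float = 1.0
                                ) -> ExperimentResult:
    """Signed p-value gap between perfect-LD pair members vs missingness.

    Effects are planted on the SV member of each perfect-LD pair; per grid
    point m, m genotypes of the small member are masked (the SV stays
    complete) and both members are re-tested.  The masked sample sets are
    nested across m, so the p-value gap can only reflect the growing
    casewise-deletion mismatch.  Delta = (-log10 p_small) - (-log10 p_sv);
    at m = 0 the two regressions are identical and Delta is exactly zero.
    """
    if config.n_perfect_ld_pairs < 1:
        raise ValueError("missingness_bias_experiment needs planted perfect-LD pairs")
    cfg = replace(config, missingness_rate_small=0.0, missingness_rate_sv=0.0,
                  het_to_hom_error_rate=0.0, seed=seed)
    g, truth = simulate_genotypes(cfg)
    for i, (small_id, sv_id) in enumerate(truth.perfect_ld_pairs):
        truth.causal_map[f"pair{i}"] = (sv_id, beta)
    phenos, cov = simulate_phenotypes(g, truth, cfg)
    rng = np.random.default_rng(seed + 7)
    mask_order = {small_id: rng.permutation(g.n_samples)
                  for small_id, _ in truth.perfect_ld_pairs}
    grid = np.asarray(sorted(missing_grid), dtype=int)
    rows = []
    for m in grid:
        for i, (small_id, sv_id) in enumerate(truth.perfect_ld_pairs):
            fid = f"pair{i}"
            y = phenos.values[phenos.row(fid)]
            small = g.dosage_of(small_id).copy()
            if m > 0:
                small[mask_order[small_id][:m]] = np.nan
            st_small = association_single(small, y, cov)
            st_sv = association_single(g.dosage_of(sv_id), y, cov)
            delta = -np.log10(st_small.p) + np.log10(st_sv.p)
            rows.append(dict(m=int(m), pair=i, p_small=st_small.p, p_sv=st_sv.p,
                             delta_log10p=float(delta),
                             sv_loses=bool(st_small.p < st_sv.p)))
    details = pd.DataFrame(rows)
    med = details.groupby("m")["delta_log10p"].apply(lambda d: float(np.median(np.abs(d))))
    return ExperimentResult(grid=grid, detection_rate=med.to_numpy(),
                            details=details, replicates=len(truth.perfect_ld_pairs),
                            seed=seed)


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def sv_saturation(g: GenotypeMatrix, n_orders: int = 10, seed: int = 0
                  ) -> pd.DataFrame:
    """Cumulative distinct SVs carried by >= 1 sample, over random orderings.

    Returns one row per cohort size with the mean and min/max envelope
    across orderings.  Missing genotypes never count as carrying.
    """
    if g.n_samples < 1:
        raise ValueError("sv_saturation requires at least one sample")
    sv_cols = np.flatnonzero(g.variants["is_sv"].to_numpy())
    carried = np.nan_to_num(g.dosages[:, sv_cols], nan=0.0) >= 1
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_orders, g.n_samples), dtype=int)
    for o in range(n_orders):
        order = rng.permutation(g.n_samples)
        seen = np.zeros(len(sv_cols), dtype=bool)
        for i, s in enumerate(order):
            seen |= carried[s]
            curves[o, i] = int(seen.sum())
    return pd.DataFrame({
        "n_samples": np.arange(1, g.n_samples + 1),
        "mean": curves.mean(axis=0),
        "min": curves.min(axis=0),
        "max": curves.max(axis=0),
    })


def singleton_summary(g: GenotypeMatrix) -> dict[str, int]:
    """Single-sample SV accounting: singletons (AC = 1 in one sample) and
    doubletons (AC = 2 confined to one sample).  Missing genotypes are
    excluded from carrier counting."""
    sv_cols = np.flatnonzero(g.variants["is_sv"].to_numpy())
    dos = np.nan_to_num(g.dosages[:, sv_cols], nan=0.0)
    carriers = (dos >= 1).sum(axis=0)
    single = carriers == 1
    ac_in_single = dos[:, single].max(axis=0) if single.any() else np.empty(0)
    singletons = int(np.sum(ac_in_single == 1))
    doubletons = int(np.sum(ac_in_single == 2))
    return dict(n_sv=len(sv_cols), segregating=int((carriers > 0).sum()),
                single_sample=int(single.sum()), singletons=singletons,
                doubletons=doubletons)


def heterozygosity_compare(g_small: GenotypeMatrix, g_sv: GenotypeMatrix
                           ) -> tuple[pd.DataFrame, float, float]:
    """Per-sample heterozygosity (% het of non-missing calls) for two
    genotype sets, compared with a two-sided Welch t-test.

    Samples with zero non-missing genotypes in either set are excluded with
    a warning.  Returns (per-sample table, t, p).
    """
    if list(g_small.samples) != list(g_sv.samples):
        raise ValueError("genotype sets must share samples")

    def _het_pct(g: GenotypeMatrix) -> np.ndarray:
        het = (g.dosages == 1).sum(axis=1)
        nonmiss = (~np.isnan(g.dosages)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nonmiss > 0, 100.0 * het / nonmiss, np.nan)

    a = _het_pct(g_small)
    b = _het_pct(g_sv)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if (~ok).any():
        warnings.warn(f"excluded {int((~ok).sum())} samples with no non-missing "
                      "genotypes", stacklevel=2)
    t, p = stats.ttest_ind(a[ok], b[ok], equal_var=False)
    table = pd.DataFrame({"sample": np.asarray(g_small.samples)[ok],
                          "het_small_pct": a[ok], "het_sv_pct": b[ok]})
    return table, float(t), float(p)
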