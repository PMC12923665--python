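"""Synthetic cohort generator with known ground truth.

Emulates the structure of a moderate-coverage long-read cohort used for
cis-molQTL mapping: ~120 diploid samples, LD-block genotypes mixing small
variants and SVs (including small-variant/SV pairs in perfect LD), an MAF
spectrum down to 1%, class-specific genotype missingness (higher for SVs),
het->hom genotyping errors, planted cis effects on inverse-normal-transformed
phenotypes, grouped splicing-style phenotypes, and 500-bp depth tracks with
duplication fold-changes (1.5x het / 2.0x hom around a 13.5x background).

Genotypes are generated from a latent-Gaussian haplotype model: each sample
carries two haplotype latents per LD block, and each variant thresholds a
correlated Gaussian at the quantile of its drawn allele frequency.  Marginal
allele frequencies are therefore exact, diploid dosages are Hardy-Weinberg,
and within-block LD is controlled by a single correlation parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (GenotypeMatrix, PhenotypeTable, SV_MIN_LEN,
                        VARIANT_COLUMNS, inverse_normal_transform)

_SV_TYPES = ("DEL", "INS", "DUP", "INV")
_SV_TYPE_P = (0.35, 0.45, 0.10, 0.10)  # long-read catalogues skew to insertions

ERROR_MODES = ("het_to_homref", "het_to_homalt", "symmetric")


@dataclass(frozen=True)
class PlantedEffect:
    feature: str
    variant: str
    beta: float


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 120
    n_blocks: int = 10
    variants_per_block: int = 30
    sv_fraction: float = 0.10
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_perfect_ld_pairs: int = 0
    planted_effects: tuple[PlantedEffect, ...] = ()
    missingness_rate_small: float = 0.012
    missingness_rate_sv: float = 0.053
    het_to_hom_error_rate: float = 0.02
    depth_mean: float = 13.5
    window_bp: int = 500
    seed: int = 0
    ld_rho: float = 0.9
    block_span_bp: int = 1_000_000
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("sv_fraction", "missingness_rate_small", "missingness_rate_sv",
                     "het_to_hom_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth carried alongside a simulated cohort.

    ``missing_log`` entries are (sample, variant, original dosage) and
    ``error_log`` entries (sample, variant, original, reported), so the
    pre-injection matrix can be reconstructed exactly.
    """

    causal_map: dict[str, tuple[str, float]] = field(default_factory=dict)
    error_log: list[tuple[str, str, float, float]] = field(default_factory=list)
    missing_log: list[tuple[str, str, float]] = field(default_factory=list)
    perfect_ld_pairs: list[tuple[str, str]] = field(default_factory=list)


def _int_scale_slope(b: float, weights: np.ndarray, sigma_rest: float) -> float:
    """Asymptotic INT-scale regression slope for a raw dosage slope ``b``.

    The phenotype is a mixture of normals y | d=k ~ N(b k, sigma_rest^2)
    with dosage weights w_k.  After the rank-based transform, z = Phi^-1(F(y))
    is exactly standard normal, so the slope of z on d is
    sum_k w_k k E[z | d=k] / var(d).
    """
    from scipy.stats import norm

    k_vals = np.arange(len(weights), dtype=float)
    mean_d = float(weights @ k_vals)
    var_d = float(weights @ k_vals ** 2 - mean_d ** 2)
    if var_d <= 0:
        raise ValueError("dosage has zero variance")
    u = np.linspace(-8.0, 8.0, 2001)
    phi = norm.pdf(u)
    phi /= phi.sum()
    cov = 0.0
    for k, w in zip(k_vals, weights):
        if w == 0:
            continue
        y = b * k + sigma_rest * u
        F = sum(wj * norm.cdf((y - b * kj) / sigma_rest)
                for kj, wj in zip(k_vals, weights))
        z = norm.ppf(np.clip(F, 1e-14, 1 - 1e-14))
        cov += w * (k - mean_d) * float(z @ phi)
    return cov / var_d


def _calibrate_raw_slope(beta: float, dose: np.ndarray, sigma_rest: float) -> float:
    """Raw slope whose asymptotic INT-scale coefficient equals ``beta``."""
    from scipy.optimize import brentq

    if beta == 0.0:
        return 0.0
    sign = np.sign(beta)
    target = abs(beta)
    weights = np.array([(dose == k).mean() for k in (0.0, 1.0, 2.0)])
    var_d = float(np.var(dose))
    sup = _int_scale_slope(50.0 * sigma_rest, weights, sigma_rest)
    if target >= sup:
        raise ValueError(
            f"INT-scale beta {beta} unattainable for this dosage distribution "
            f"(maximum ~{sup:.3f}); a rank-normal phenotype has unit variance")
    b0 = target * sigma_rest / np.sqrt(max(1.0 - target ** 2 * var_d, 1e-6))
    lo, hi = 0.0, max(4.0 * b0, sigma_rest)
    while _int_scale_slope(hi, weights, sigma_rest) < target:
        hi *= 2.0
    b = brentq(lambda x: _int_scale_slope(x, weights, sigma_rest) - target,
               lo, hi, xtol=1e-10)
    return float(sign * b)


def _sv_metadata(rng: np.random.Generator) -> tuple[str, int, int, int]:
    svtype = str(rng.choice(_SV_TYPES, p=_SV_TYPE_P))
    sv_len = int(np.clip(rng.lognormal(mean=5.6, sigma=1.0), SV_MIN_LEN, 50_000))
    if svtype == "DEL":
        return svtype, sv_len + 1, 1, sv_len
    if svtype == "INS":
        return svtype, 1, sv_len + 1, sv_len
    return svtype, 1, 1, sv_len  # symbolic DUP/INV


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw an LD-block dosage matrix with SV metadata and perfect-LD pairs."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"sample{str(i).zfill(3)}" for i in range(n)]
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    truth = SimTruth(causal_map={pe.feature: (pe.variant, pe.beta)
                                 for pe in config.planted_effects})
    sqrt_rho = np.sqrt(config.ld_rho)
    sqrt_tail = np.sqrt(1.0 - config.ld_rho)
    for b in range(config.n_blocks):
        chrom = str(b + 1)
        vpb = config.variants_per_block
        if vpb == 0:
            continue
        pos = np.sort(rng.choice(config.block_span_bp, size=vpb, replace=False)) + 1
        maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=vpb)
        tau = stats.norm.ppf(maf)
        z = rng.standard_normal((n, 2))  # per-haplotype block latent
        eps = rng.standard_normal((n, 2, vpb))
        alleles = (sqrt_rho * z[:, :, None] + sqrt_tail * eps) < tau[None, None, :]
        dosages = alleles.sum(axis=1).astype(float)
        n_sv = int(round(config.sv_fraction * vpb))
        sv_idx = set(rng.choice(vpb, size=n_sv, replace=False).tolist()) if n_sv else set()
        block_rows = []
        for j in range(vpb):
            if j in sv_idx:
                var_class, ref_len, alt_len, sv_len = _sv_metadata(rng)
                is_sv = True
            else:
                sv_len = 0
                if rng.random() < 0.9:
                    var_class, ref_len, alt_len = "SNP", 1, 1
                else:
                    ilen = int(rng.integers(1, 21))
                    var_class = "INDEL"
                    sv_len = ilen
                    if rng.random() < 0.5:
                        ref_len, alt_len = ilen + 1, 1
                    else:
                        ref_len, alt_len = 1, ilen + 1
                is_sv = False
            vid = f"{chrom}:{pos[j]}:{var_class}"
            block_rows.append(dict(id=vid, chrom=chrom, pos=int(pos[j]),
                                   ref_len=ref_len, alt_len=alt_len,
                                   var_class=var_class, is_sv=is_sv, sv_len=sv_len,
                                   target_maf=float(maf[j])))
            cols.append(dosages[:, j])
        rows.extend(block_rows)
    # perfect-LD pairs: one small variant mirrored by an SV with identical
    # pre-error dosages, planted round-robin across blocks
    for k in range(config.n_perfect_ld_pairs):
        b = k % max(config.n_blocks, 1)
        chrom = str(b + 1)
        block_small = [i for i, r in enumerate(rows)
                       if r["chrom"] == chrom and not r["is_sv"]]
        if not block_small:
            raise ValueError("perfect-LD pair requested but block has no small variant")
        common = [i for i in block_small if rows[i]["target_maf"] >= 0.1]
        block_small = common or block_small  # prefer common pairs
        src = block_small[int(rng.integers(len(block_small)))]
        sv_len = int(np.clip(rng.lognormal(mean=5.6, sigma=1.0), SV_MIN_LEN, 50_000))
        pos_sv = min(rows[src]["pos"] + int(rng.integers(1, 50_000)),
                     config.block_span_bp)
        svtype = "DEL" if rng.random() < 0.5 else "INS"
        ref_len, alt_len = (sv_len + 1, 1) if svtype == "DEL" else (1, sv_len + 1)
        vid = f"{chrom}:{pos_sv}:{svtype}:ld{k}"
        rows.append(dict(id=vid, chrom=chrom, pos=pos_sv, ref_len=ref_len,
                         alt_len=alt_len, var_class=svtype, is_sv=True,
                         sv_len=sv_len, target_maf=rows[src]["target_maf"]))
        cols.append(cols[src].copy())
        truth.perfect_ld_pairs.append((rows[src]["id"], vid))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["target_maf"])
    dosages = np.column_stack(cols) if cols else np.empty((n, 0))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages), truth


def simulate_phenotypes(genotypes: GenotypeMatrix, truth: SimTruth,
                        config: SimConfig, n_null_features: int = 0,
                        group_sizes: Mapping[str, int] | None = None,
                        covariate_betas: tuple[float, float] = (0.3, 0.2),
                        beta_scale: str = "int",
                        ) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Planted-effect phenotypes on the inverse-normal scale.

    y = covariate effects + dosage * beta_raw + Gaussian noise, inverse-normal
    transformed per feature.  The planted beta is interpreted on the INT
    scale: because the transform standardises the total phenotype variance,
    the raw slope is pre-scaled (beta_raw = beta * sigma_rest /
    sqrt(1 - beta^2 var(dosage)), with sigma_rest the non-genetic SD) so the
    regression coefficient recovered from the transformed phenotype equals
    the requested beta.  This requires beta^2 var(dosage) < 1 — an INT-scale
    effect cannot exceed the reciprocal dosage SD.

    With ``beta_scale="raw"`` the planted beta is instead applied directly to
    the pre-transform phenotype (so in the zero-noise limit the dosage
    explains the raw phenotype completely).

    Grouped features (intron-cluster stand-ins) share a group id and the
    planted effect, with independent noise per member.  Feature anchors are
    placed within 100 kb of the planted variant.  Run this on the
    pre-missingness matrix; genotype corruption is injected afterwards so
    the phenotypes reflect the true dosages.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = genotypes.n_samples
    group_sizes = dict(group_sizes or {})
    cov = pd.DataFrame({"age": rng.normal(size=n), "rin": rng.normal(size=n)},
                       index=list(genotypes.samples))
    cov_effect = cov.to_numpy() @ np.asarray(covariate_betas)
    feats: list[dict] = []
    values: list[np.ndarray] = []

    def _add(pid: str, gid: str, chrom: str, anchor: int, signal: np.ndarray) -> None:
        y = cov_effect + signal + rng.normal(0.0, config.noise_sd, size=n)
        feats.append(dict(chrom=chrom, start=int(anchor), end=int(anchor) + 1000,
                          pid=pid, gid=gid, strand="+"))
        values.append(y)

    for fid, (vid, beta) in truth.causal_map.items():
        try:
            j = genotypes.variant_index(vid)
        except KeyError:
            raise ValueError(f"planted variant {vid!r} for feature {fid!r} "
                             "is absent from the genotype matrix") from None
        dose = genotypes.dosages[:, j]
        if np.isnan(dose).any():
            raise ValueError(f"planted variant {vid!r} has missing dosages; "
                             "simulate phenotypes before injecting missingness")
        chrom = str(genotypes.variants["chrom"].iloc[j])
        anchor = max(1, int(genotypes.variants["pos"].iloc[j])
                     + int(rng.integers(-100_000, 100_001)))
        if beta_scale == "raw":
            beta_raw = beta
        elif beta_scale == "int":
            sigma_rest = np.sqrt(config.noise_sd ** 2
                                 + float(np.sum(np.square(covariate_betas))))
            beta_raw = _calibrate_raw_slope(beta, dose, sigma_rest)
        else:
            raise ValueError(f"beta_scale must be 'int' or 'raw', got {beta_scale!r}")
        k = group_sizes.get(fid, 1)
        if k == 1:
            _add(fid, fid, chrom, anchor, dose * beta_raw)
        else:
            for m in range(k):
                _add(f"{fid}:c{m + 1}", fid, chrom, anchor, dose * beta_raw)

    chroms = pd.unique(genotypes.variants["chrom"]) if genotypes.n_variants else ["1"]
    for i in range(n_null_features):
        chrom = str(chroms[int(rng.integers(len(chroms)))])
        anchor = int(rng.integers(1, config.block_span_bp))
        _add(f"null{i}", f"null{i}", chrom, anchor, np.zeros(n))

    if not feats:
        return (PhenotypeTable(pd.DataFrame(columns=["chrom", "start", "end", "pid",
                                                     "gid", "strand"]),
                               np.empty((0, n)), list(genotypes.samples)), cov)
    V = inverse_normal_transform(np.vstack(values), axis=1)
    return PhenotypeTable(pd.DataFrame(feats), V, list(genotypes.samples)), cov


def inject_missingness(genotypes: GenotypeMatrix, rate_small: float, rate_sv: float,
                       seed: int, sample_weight: np.ndarray | None = None,
                       truth: SimTruth | None = None
                       ) -> tuple[GenotypeMatrix, SimTruth]:
    """Set entries missing independently at the class rate.

    ``sample_weight`` optionally scales the per-sample rate (e.g. inverse
    coverage) to mimic coverage-linked missingness; default independent.
    """
    for r in (rate_small, rate_sv):
        if not (0.0 <= r <= 1.0):
            raise ValueError("missingness rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = genotypes.copy()
    truth = truth if truth is not None else SimTruth()
    is_sv = g.variants["is_sv"].to_numpy()
    rate = np.where(is_sv, rate_sv, rate_small)[None, :]
    if sample_weight is not None:
        w = np.asarray(sample_weight, dtype=float)[:, None]
        rate = np.clip(rate * w, 0.0, 1.0)
    else:
        rate = np.broadcast_to(rate, g.dosages.shape)
    hit = (rng.random(g.dosages.shape) < rate) & ~np.isnan(g.dosages)
    for i, j in zip(*np.nonzero(hit)):
        truth.missing_log.append((g.samples[i], str(g.variants["id"].iloc[j]),
                                  float(g.dosages[i, j])))
    g.dosages[hit] = np.nan
    return g, truth


def inject_genotype_errors(genotypes: GenotypeMatrix, epsilon: float, mode: str,
                           seed: int, variant_mask: np.ndarray | None = None,
                           truth: SimTruth | None = None
                           ) -> tuple[GenotypeMatrix, SimTruth]:
    """Flip heterozygous genotypes to homozygous with probability epsilon.

    Modes: ``het_to_homref`` (1 -> 0), ``het_to_homalt`` (1 -> 2), or
    ``symmetric`` (either direction, equal probability).  Missing entries are
    never eligible, keeping error and missingness logs disjoint.
    """
    if mode not in ERROR_MODES:
        raise ValueError(f"unknown error mode {mode!r}; expected one of {ERROR_MODES}")
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = genotypes.copy()
    truth = truth if truth is not None else SimTruth()
    eligible = g.dosages == 1.0
    if variant_mask is not None:
        eligible &= np.asarray(variant_mask, dtype=bool)[None, :]
    hit = eligible & (rng.random(g.dosages.shape) < epsilon)
    ii, jj = np.nonzero(hit)
    if mode == "het_to_homref":
        new = np.zeros(len(ii))
    elif mode == "het_to_homalt":
        new = np.full(len(ii), 2.0)
    else:
        new = rng.choice([0.0, 2.0], size=len(ii))
    for k in range(len(ii)):
        truth.error_log.append((g.samples[ii[k]], str(g.variants["id"].iloc[jj[k]]),
                                1.0, float(new[k])))
        g.dosages[ii[k], jj[k]] = new[k]
    return g, truth


def simulate_coverage(duplications: Sequence[tuple[tuple[str, int, int], Mapping[str, int]]],
                      depth_mean: float = 13.5, window_bp: int = 500, seed: int = 0,
                      chrom_length: int | None = None,
                      sample_depth_cv: float = 0.05) -> list:
    """Per-sample windowed depth tracks around duplication regions.

    Each duplication is ((chrom, start, end), {sample: true dosage}); inside
    the region a sample's expected depth is multiplied by (2 + dosage) / 2
    (1.5x het, 2.0x hom).  Window noise is Gaussian with SD sqrt(mean depth),
    truncated at zero (Poisson-like).  Samples get a mild lognormal depth
    scale so chromosome backgrounds differ slightly between individuals.
    """
    from .covgeno import CoverageTrack

    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    regions = sorted((r for r, _ in duplications), key=lambda r: (r[0], r[1]))
    for a, b in zip(regions, regions[1:]):
        if a[0] == b[0] and b[1] < a[2]:
            raise ValueError("duplication regions must be non-overlapping")
    samples: list[str] = []
    for _, geno in duplications:
        for s in geno:
            if s not in samples:
                samples.append(s)
    rng = np.random.default_rng(seed)
    chroms = sorted({r[0] for r, _ in duplications}) or ["1"]
    tracks = []
    length = chrom_length or (max((r[2] for r, _ in duplications), default=0) + 100 * window_bp)
    starts = np.arange(0, length, window_bp)
    scale = np.exp(rng.normal(0.0, sample_depth_cv, size=len(samples)))
    for si, sample in enumerate(samples):
        frames = []
        for chrom in chroms:
            mu = np.full(len(starts), depth_mean * scale[si])
            mids = starts + window_bp / 2
            for (rchrom, rstart, rend), geno in duplications:
                if rchrom != chrom:
                    continue
                dose = geno.get(sample, 0)
                inside = (mids >= rstart) & (mids < rend)
                mu[inside] *= (2.0 + dose) / 2.0
            depth = np.maximum(0.0, rng.normal(mu, np.sqrt(mu)))
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                        "end": starts + window_bp, "depth": depth}))
        df = pd.concat(frames, ignore_index=True)
        tracks.append(CoverageTrack(sample=sample,
                                    windows=df[["chrom", "start", "end"]],
                                    depth=df["depth"].to_numpy()))
    return tracks


# ---------------------------------------------------------------------------
# Cohort convenience wrapper
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    genotypes_clean: GenotypeMatrix
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    covariates: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def choose_causal_variants(g: GenotypeMatrix, n: int, seed: int, sv: bool | None = None,
                           maf_min: float = 0.1, exclude: set[str] | None = None
                           ) -> list[str]:
    """Pick causal candidates round-robin across blocks (chromosomes).

    ``sv`` restricts to SVs (True), small variants (False) or any (None).
    """
    rng = np.random.default_rng(seed)
    maf = g.maf()
    ok = maf >= maf_min
    if sv is not None:
        ok &= g.variants["is_sv"].to_numpy() == sv
    if exclude:
        ok &= ~g.variants["id"].isin(exclude).to_numpy()
    chrom = g.variants["chrom"].to_numpy()
    by_block: dict[str, list[int]] = {}
    for j in np.flatnonzero(ok):
        by_block.setdefault(chrom[j], []).append(int(j))
    blocks = sorted(by_block, key=lambda c: int(c) if c.isdigit() else c)
    chosen: list[str] = []
    bi = 0
    while len(chosen) < n and blocks:
        block = blocks[bi % len(blocks)]
        cands = by_block[block]
        if cands:
            j = cands.pop(int(rng.integers(len(cands))))
            chosen.append(str(g.variants["id"].iloc[j]))
        else:
            blocks.remove(block)
            continue
        bi += 1
    if len(chosen) < n:
        raise ValueError(f"only {len(chosen)} of {n} requested causal variants "
                         f"available at MAF >= {maf_min}")
    return chosen


def simulate_qtl_cohort(config: SimConfig, n_sv_features: int = 0,
                        n_small_features: int = 0, n_null_features: int = 0,
                        beta: float = 1.0, causal_maf_min: float = 0.1,
                        group_sizes: Mapping[str, int] | None = None,
                        plant_on_ld_pairs: int = 0,
                        apply_missingness: bool = True,
                        error_rate: float | None = None,
                        error_mode: str = "het_to_homref",
                        errors_sv_only: bool = True) -> Cohort:
    """End-to-end synthetic cohort: genotypes, planted QTL, corruption.

    Missingness and (optionally) het->hom errors are injected after the
    phenotypes are generated from the clean dosages, so association tests see
    the corrupted genotypes while the ground truth is preserved in ``truth``.
    """
    g_clean, truth = simulate_genotypes(config)
    exclude = {v for pair in truth.perfect_ld_pairs for v in pair}
    sv_ids = choose_causal_variants(g_clean, n_sv_features, seed=config.seed + 101,
                                    sv=True, maf_min=causal_maf_min, exclude=exclude)
    small_ids = choose_causal_variants(g_clean, n_small_features,
                                       seed=config.seed + 102, sv=False,
                                       maf_min=causal_maf_min, exclude=exclude)
    for i, vid in enumerate(sv_ids):
        truth.causal_map[f"svgene{i}"] = (vid, beta)
    for i, vid in enumerate(small_ids):
        truth.causal_map[f"gene{i}"] = (vid, beta)
    for i, (_, sv_id) in enumerate(truth.perfect_ld_pairs[:plant_on_ld_pairs]):
        truth.causal_map[f"pairgene{i}"] = (sv_id, beta)
    phenos, cov = simulate_phenotypes(g_clean, truth, config,
                                      n_null_features=n_null_features,
                                      group_sizes=group_sizes)
    g = g_clean
    if apply_missingness:
        g, truth = inject_missingness(g, config.missingness_rate_small,
                                      config.missingness_rate_sv,
                                      seed=config.seed + 201, truth=truth)
    eps = config.het_to_hom_error_rate if error_rate is None else error_rate
    if eps and eps > 0:
        mask = g.variants["is_sv"].to_numpy() if errors_sv_only else None
        g, truth = inject_genotype_errors(g, eps, error_mode,
                                          seed=config.seed + 202,
                                          variant_mask=mask, truth=truth)
    return Cohort(genotypes_clean=g_clean, genotypes=g, phenotypes=phenos,
                  covariates=cov, truth=truth, config=config)
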