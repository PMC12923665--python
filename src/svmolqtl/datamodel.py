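"""Core containers, standard-format I/O, variant/phenotype filters and LD.

Genotypes are unphased alternate-allele dosages in {0, 1, 2}; missing calls
are stored as NaN so that every downstream statistic can apply casewise
deletion explicitly rather than silently imputing.  Structural variants (SVs)
are deletions, insertions, duplications and inversions of at least 50 bp;
everything shorter is a "small" variant (SNP or indel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SV_CLASSES = ("DEL", "INS", "DUP", "INV")
SV_MIN_LEN = 50

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref_len", "alt_len", "var_class", "is_sv", "sv_len"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds used to define the testable variant and feature sets."""

    maf_min: float = 0.01
    max_missing: float = 0.10
    cis_window: int = 1_000_000
    small_variant_max_len: int = 45
    tpm_min: float = 0.1
    min_reads: int = 6
    min_sample_frac: float = 0.10

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_missing", "cis_window", "small_variant_max_len",
                     "tpm_min", "min_reads", "min_sample_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def classify_variant(ref_len: int, alt_len: int, svtype: str | None = None,
                     svlen: int | None = None) -> tuple[str, bool, int]:
    """Return (var_class, is_sv, sv_len) for one allele.

    The 50-bp rule is decisive: an allele is an SV iff its length difference
    (or declared SVLEN) reaches 50 bp, regardless of which caller emitted it.
    """
    if svlen is not None:
        length = abs(int(svlen))
    else:
        length = abs(int(alt_len) - int(ref_len))
    if length >= SV_MIN_LEN:
        if svtype in SV_CLASSES:
            return svtype, True, length
        return ("DEL" if ref_len > alt_len else "INS"), True, length
    if ref_len == 1 and alt_len == 1:
        return "SNP", False, 0
    return "INDEL", False, length


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with missingness as NaN."""

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant over non-missing alleles."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            af = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not present")
        return int(idx[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]

    def subset_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.variants.copy(), self.dosages.copy())


@dataclass
class PhenotypeTable:
    """Molecular phenotypes (genes or grouped intron clusters).

    ``features`` carries BED-style columns (chrom, start, end, pid, gid,
    strand); ``values`` is features x samples on the normalised scale.
    """

    features: pd.DataFrame
    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError("phenotype value shape inconsistent with features/samples")
        self.features = self.features.reset_index(drop=True)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def anchors(self, strand_aware: bool = True) -> np.ndarray:
        """Feature "start site" used to centre the cis window.

        Strand-aware by default: BED start for + features, BED end for -.
        """
        start = self.features["start"].to_numpy()
        if not strand_aware or "strand" not in self.features:
            return start
        end = self.features["end"].to_numpy()
        neg = self.features["strand"].to_numpy() == "-"
        return np.where(neg, end, start)

    def row(self, pid: str) -> int:
        idx = np.flatnonzero(self.features["pid"].to_numpy() == pid)
        if idx.size == 0:
            raise KeyError(f"phenotype {pid!r} not present")
        return int(idx[0])


@dataclass(frozen=True)
class LdPair:
    variant_a: str
    variant_b: str
    r2: float
    n_complete: int


def inverse_normal_transform(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Rank-based inverse normal transform with (rank - 0.5) / n offset.

    Ties receive average ranks, so tied observations map to the same normal
    quantile.  NaNs are preserved in place and ignored for ranking.
    """
    x = np.asarray(x, dtype=float)

    def _one(v: np.ndarray) -> np.ndarray:
        out = np.full_like(v, np.nan)
        ok = ~np.isnan(v)
        n = ok.sum()
        if n == 0:
            return out
        ranks = stats.rankdata(v[ok], method="average")
        out[ok] = stats.norm.ppf((ranks - 0.5) / n)
        return out

    return np.apply_along_axis(_one, axis, x)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_genotypes(vcf_path: str, hemizygous_dosage: int = 2,
                   small_caller_cap: int | None = None) -> GenotypeMatrix:
    """Load a VCF (GT required) into a dosage matrix.

    Multi-allelic records are split into one biallelic row per ALT allele,
    with the dosage counting that allele only.  ``./.`` becomes NaN.
    Hemizygous single-allele calls are coded 0/``hemizygous_dosage`` (default
    2, i.e. one alternate allele on a haploid contig counts as a homozygous
    dosage).  When ``small_caller_cap`` is set, non-SV indel alleles longer
    than the cap (and without SV annotation) are dropped — mirroring a
    small-variant caller length cutoff that leaves such alleles to the
    dedicated SV caller.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    rows: list[dict] = []
    dosage_cols: list[np.ndarray] = []
    for rec in vcf:
        gts = rec.genotypes  # list of [allele1, allele2?, phased]
        svtype = rec.INFO.get("SVTYPE")
        svlen = rec.INFO.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen_list = list(svlen)
        else:
            svlen_list = [svlen] * len(rec.ALT)
        for ai, alt in enumerate(rec.ALT):
            allele = ai + 1
            ref_len = len(rec.REF)
            alt_len = ref_len if alt.startswith("<") else len(alt)
            var_class, is_sv, sv_len = classify_variant(
                ref_len, alt_len, svtype=svtype, svlen=svlen_list[ai])
            if (small_caller_cap is not None and not is_sv
                    and var_class == "INDEL" and sv_len > small_caller_cap
                    and svtype is None):
                continue
            dos = np.full(len(samples), np.nan)
            for si, gt in enumerate(gts):
                alleles = [a for a in gt[:-1] if a != -2]  # -2 pads mixed ploidy
                if not alleles or any(a == -1 for a in alleles):
                    continue
                count = sum(1 for a in alleles if a == allele)
                if len(alleles) == 1:  # hemizygous call
                    dos[si] = float(hemizygous_dosage if count else 0)
                else:
                    dos[si] = float(count)
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if len(rec.ALT) > 1:
                vid = f"{vid}:{allele}"
            rows.append(dict(id=vid, chrom=rec.CHROM, pos=rec.POS, ref_len=ref_len,
                             alt_len=alt_len, var_class=var_class, is_sv=is_sv,
                             sv_len=sv_len))
            dosage_cols.append(dos)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (np.column_stack(dosage_cols) if dosage_cols
               else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------

def filter_variants(g: GenotypeMatrix, features: PhenotypeTable,
                    cfg: FilterConfig | None = None,
                    strand_aware: bool = True) -> dict[str, np.ndarray]:
    """Per-feature testable variant sets.

    A variant is testable for a feature iff |pos - anchor| <= cis_window
    (inclusive boundary), MAF >= maf_min, and missing fraction < max_missing.
    Returns a mapping pid -> array of variant column indices into ``g``.
    """
    cfg = cfg or FilterConfig()
    maf = g.maf()
    miss = g.missing_fraction()
    global_ok = (maf >= cfg.maf_min) & (miss < cfg.max_missing)
    pos = g.variants["pos"].to_numpy()
    chrom = g.variants["chrom"].astype(str).to_numpy()
    anchors = features.anchors(strand_aware=strand_aware)
    out: dict[str, np.ndarray] = {}
    for i, pid in enumerate(features.features["pid"]):
        fchrom = str(features.features["chrom"].iloc[i])
        in_cis = (chrom == fchrom) & (np.abs(pos - anchors[i]) <= cfg.cis_window)
        out[str(pid)] = np.flatnonzero(in_cis & global_ok)
    return out


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def r2_pairwise(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Squared Pearson correlation over pairwise-complete samples."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, n
    xs, ys = x[ok], y[ok]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = np.sqrt((xs ** 2).sum() * (ys ** 2).sum())
    if denom == 0:
        return np.nan, n
    r = float((xs * ys).sum() / denom)
    return r * r, n


def compute_ld(g: GenotypeMatrix, focal: str, window_bp: int = 1_000_000,
               r2_min: float = 0.0) -> list[LdPair]:
    """r^2 between the focal variant and every variant within the window."""
    fi = g.variant_index(focal)
    fpos = g.variants["pos"].iloc[fi]
    fchrom = g.variants["chrom"].iloc[fi]
    fx = g.dosages[:, fi]
    pairs: list[LdPair] = []
    sel = np.flatnonzero((g.variants["chrom"] == fchrom).to_numpy()
                         & (np.abs(g.variants["pos"].to_numpy() - fpos) <= window_bp))
    for j in sel:
        if j == fi:
            continue
        r2, n = r2_pairwise(fx, g.dosages[:, j])
        if np.isnan(r2):
            if n < 3:
                warnings.warn(
                    f"LD pair ({focal}, {g.variants['id'].iloc[j]}) skipped: "
                    f"only {n} complete pairs", stacklevel=2)
            continue  # zero-variance pairs are silently undefined
        if r2 >= r2_min:
            pairs.append(LdPair(focal, str(g.variants["id"].iloc[j]), r2, n))
    return pairs


def ld_prune(g: GenotypeMatrix, window_variants: int = 1000, step: int = 5,
             r2: float = 0.2) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning (plink --indep-pairwise style).

    Within each window, while any kept pair exceeds the r^2 threshold the
    member with the lower MAF is removed; windows advance by ``step``
    variants per chromosome.
    """
    maf = g.maf()
    keep = np.ones(g.n_variants, dtype=bool)
    order = g.variants.sort_values(["chrom", "pos"]).index.to_numpy()
    chroms = g.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = order[chroms[order] == chrom]
        start = 0
        while start < len(cidx):
            widx = cidx[start:start + window_variants]
            changed = True
            while changed:
                changed = False
                active = [i for i in widx if keep[i]]
                for a in range(len(active)):
                    for b in range(a + 1, len(active)):
                        i, j = active[a], active[b]
                        rij, _ = r2_pairwise(g.dosages[:, i], g.dosages[:, j])
                        if not np.isnan(rij) and rij > r2:
                            drop = i if maf[i] <= maf[j] else j
                            keep[drop] = False
                            changed = True
                            break
                    if changed:
                        break
            if start + window_variants >= len(cidx):
                break
            start += step
    return g.subset_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Covariate construction
# ---------------------------------------------------------------------------

def grm_pca(g: GenotypeMatrix, pc_range: tuple[int, int] = (2, 10)
            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the genomic relationship matrix.

    GRM = Z Z^T / m with Z the dosages standardised by allele frequency
    ((x - 2p) / sqrt(2 p (1-p))); missing dosages are mean-imputed here and
    only here.  Returns (PCs as a samples x k frame, all eigenvalues).  PC 1
    is excluded by default (``pc_range`` is 1-based inclusive).
    """
    if g.n_samples < 2 or g.n_variants < 2:
        raise ValueError("grm_pca requires at least 2 samples and 2 variants")
    X = g.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(X, axis=0) / 2.0
    col_mean = 2.0 * p
    nan_mask = np.isnan(X)
    X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
    var = 2.0 * p * (1.0 - p)
    ok = var > 0
    Z = (X[:, ok] - col_mean[ok]) / np.sqrt(var[ok])
    grm = Z @ Z.T / ok.sum()
    evals, evecs = np.linalg.eigh(grm)
    ordr = np.argsort(evals)[::-1]
    evals, evecs = evals[ordr], evecs[:, ordr]
    lo, hi = pc_range
    idx = np.arange(lo - 1, min(hi, len(evals)))
    pcs = evecs[:, idx] * np.sqrt(np.clip(evals[idx], 0, None))
    cols = [f"grm_pc{i + 1}" for i in idx]
    return pd.DataFrame(pcs, index=list(g.samples), columns=cols), evals


def scree_elbow(eigenvalues: np.ndarray) -> int:
    """Number of components retained by the scree elbow test.

    The elbow is the point with maximum perpendicular distance to the chord
    joining the first and last eigenvalue; that point is the first one on
    the noise floor, so the retained count is its index minus one (at least
    1).  A scree with one dominant eigenvalue followed by flat noise
    therefore retains a single component.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    m = len(lam)
    if m < 3:
        return 1
    x = np.arange(m, dtype=float)
    p0 = np.array([x[0], lam[0]])
    p1 = np.array([x[-1], lam[-1]])
    d = p1 - p0
    norm = np.hypot(*d)
    if norm == 0:
        return 1
    # distance from each point to the chord
    dist = np.abs(d[1] * (x - p0[0]) - d[0] * (lam - p0[1])) / norm
    return max(int(np.argmax(dist)), 1)


def select_rna_pcs(phenos: PhenotypeTable, known_covariates: pd.DataFrame | None = None,
                   r2_threshold: float = 0.5, max_pcs: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, int, np.ndarray]:
    """Hidden-confounder PCs from the phenotype matrix, elbow-selected.

    PCA is run on samples x features; the number of retained PCs is the
    scree elbow.  Known covariates whose squared correlation with any
    retained PC reaches ``r2_threshold`` are dropped from the known set
    (they are already captured by the hidden confounders).

    Returns (rna_pcs, kept_known, n_pcs, eigenvalues).
    """
    if len(phenos.samples) < 3:
        raise ValueError("select_rna_pcs requires at least 3 samples")
    X = phenos.values.T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    evals = s ** 2 / max(X.shape[0] - 1, 1)
    n_pcs = scree_elbow(evals)
    if max_pcs is not None:
        n_pcs = min(n_pcs, max_pcs)
    pcs = U[:, :n_pcs] * s[:n_pcs]
    rna_pcs = pd.DataFrame(pcs, index=list(phenos.samples),
                           columns=[f"rna_pc{i + 1}" for i in range(n_pcs)])
    if known_covariates is None or known_covariates.shape[1] == 0:
        kept = pd.DataFrame(index=list(phenos.samples))
        return rna_pcs, kept, n_pcs, evals
    known = known_covariates.loc[list(phenos.samples)]
    drop_cols = []
    for col in known.columns:
        v = known[col].to_numpy(dtype=float)
        for k in range(n_pcs):
            r2, _ = r2_pairwise(v, pcs[:, k])
            if not np.isnan(r2) and r2 >= r2_threshold:
                drop_cols.append(col)
                break
    kept = known.drop(columns=drop_cols)
    return rna_pcs, kept, n_pcs, evals


# ---------------------------------------------------------------------------
# Phenotype preparation
# ---------------------------------------------------------------------------

def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Cross-sample quantile normalisation of a features x samples matrix."""
    V = np.asarray(values, dtype=float)
    order = np.argsort(V, axis=0)
    ranks = np.empty_like(order)
    for j in range(V.shape[1]):
        ranks[order[:, j], j] = np.arange(V.shape[0])
    reference = np.sort(V, axis=0).mean(axis=1)
    return reference[ranks]


def prepare_expression(tpm: pd.DataFrame, counts: pd.DataFrame,
                       cfg: FilterConfig | None = None,
                       feature_info: pd.DataFrame | None = None) -> PhenotypeTable:
    """Expression filtering and normalisation.

    Keeps features where TPM >= tpm_min AND counts >= min_reads in at least
    ``min_sample_frac`` of samples (boundary inclusive), then quantile
    normalises across samples and inverse-normal transforms each feature.
    """
    cfg = cfg or FilterConfig()
    if list(tpm.columns) != list(counts.columns) or list(tpm.index) != list(counts.index):
        raise ValueError("TPM and count matrices must share features and samples")
    n = tpm.shape[1]
    passing = ((tpm.to_numpy() >= cfg.tpm_min) & (counts.to_numpy() >= cfg.min_reads))
    keep = passing.sum(axis=1) >= cfg.min_sample_frac * n
    kept_ids = tpm.index[keep]
    raw = tpm.loc[kept_ids].to_numpy(dtype=float)
    qn = quantile_normalize(raw)
    # rank on the quantile-normalised values, breaking QN-induced ties by the
    # raw values so each feature maps to the exact INT quantile vector;
    # genuine ties (equal raw and QN value) remain averaged
    V = np.empty_like(qn)
    for i in range(qn.shape[0]):
        comp = (stats.rankdata(qn[i], method="average")
                + 1e-9 * stats.rankdata(raw[i], method="average"))
        ranks = stats.rankdata(comp, method="average")
        V[i] = stats.norm.ppf((ranks - 0.5) / n)
    if feature_info is not None:
        feats = feature_info.loc[kept_ids].reset_index(drop=True).copy()
        feats["pid"] = list(kept_ids)
    else:
        feats = pd.DataFrame({
            "chrom": "1", "start": np.arange(len(kept_ids)) * 10_000 + 1,
            "end": np.arange(len(kept_ids)) * 10_000 + 1_001,
            "pid": list(kept_ids), "gid": list(kept_ids), "strand": "+",
        })
    return PhenotypeTable(features=feats[["chrom", "start", "end", "pid", "gid", "strand"]],
                          values=V, samples=list(tpm.columns))


# ---------------------------------------------------------------------------
# Callset accounting
# ---------------------------------------------------------------------------

def summarize_counts(baseline: Mapping[str, int], comparison: Mapping[str, int]
                     ) -> pd.DataFrame:
    """Percent increase in variant counts per region between two callsets.

    increase = (b/a - 1) * 100, rounded to one decimal; undefined (NaN) when
    the baseline count is zero.
    """
    regions = list(baseline)
    if set(regions) != set(comparison):
        raise ValueError("callsets must cover the same regions")
    rows = []
    for region in regions:
        a, b = baseline[region], comparison[region]
        inc = np.nan if a == 0 else round((b / a - 1.0) * 100.0, 1)
        rows.append(dict(region=region, baseline=a, comparison=b, increase_pct=inc))
    return pd.DataFrame(rows)
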