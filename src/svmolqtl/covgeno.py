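"""Coverage-based duplication genotyping and genotype-correction retests.

Duplication carriers raise read depth over the duplicated sequence: relative
to the chromosomal background, a heterozygous carrier averages ~1.5x and a
homozygous carrier ~2.0x.  Genotypes are assigned from the region fold
change with inclusive thresholds: >= 1.3 calls a het, >= 1.8 a hom
(the copy-number genotype is monotone in fold change by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cisqtl import AssocStat, association_single
from .datamodel import GenotypeMatrix, PhenotypeTable

GENOTYPES = ("0/0", "0/1", "1/1")
HET_FOLD = 1.3
HOM_FOLD = 1.8


@dataclass
class CoverageTrack:
    """Per-sample mean depth in fixed-width windows (0-based half-open)."""

    sample: str
    windows: pd.DataFrame  # chrom, start, end
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.depth) != len(self.windows):
            raise ValueError("depth length inconsistent with windows")
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")
        for _, grp in self.windows.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            if (ends[order][:-1] > starts[order][1:]).any():
                raise ValueError("windows must be non-overlapping")


@dataclass(frozen=True)
class DupCall:
    region: tuple[str, int, int]
    sample: str
    fold_change: float
    genotype: str


def _fold_to_genotype(fold: float) -> str:
    if fold >= HOM_FOLD:
        return "1/1"
    if fold >= HET_FOLD:
        return "0/1"
    return "0/0"


def background_coverage(track: CoverageTrack, chrom: str,
                        exclude_region: tuple[str, int, int] | None = None) -> float:
    """Mean window depth on the chromosome, excluding the duplication."""
    w = track.windows
    on = (w["chrom"].astype(str) == str(chrom)).to_numpy()
    if exclude_region is not None and str(exclude_region[0]) == str(chrom):
        _, rs, re = exclude_region
        overlaps = (w["start"].to_numpy() < re) & (w["end"].to_numpy() > rs)
        on &= ~overlaps
    if not on.any():
        raise ValueError(f"no eligible background windows on chromosome {chrom}")
    return float(track.depth[on].mean())


def region_fold_change(track: CoverageTrack, region: tuple[str, int, int],
                       background: float) -> float:
    """Length-weighted mean depth over the region divided by background.

    Partial windows are weighted by their overlap with the region.
    """
    if background <= 0:
        raise ValueError("background coverage must be positive")
    chrom, rs, re = region
    w = track.windows
    on = (w["chrom"].astype(str) == str(chrom)).to_numpy()
    starts = w["start"].to_numpy()
    ends = w["end"].to_numpy()
    overlap = np.minimum(ends, re) - np.maximum(starts, rs)
    sel = on & (overlap > 0)
    if not sel.any():
        raise ValueError(f"region {region} covered by no window")
    weights = overlap[sel].astype(float)
    mean_depth = float(np.average(track.depth[sel], weights=weights))
    return mean_depth / background


def genotype_duplication(track: CoverageTrack, region: tuple[str, int, int],
                         background: float | None = None) -> DupCall:
    """Assign 0/0, 0/1 or 1/1 from the region fold change."""
    if background is None:
        background = background_coverage(track, region[0], exclude_region=region)
    fold = region_fold_change(track, region, background)
    return DupCall(region=region, sample=track.sample, fold_change=fold,
                   genotype=_fold_to_genotype(fold))


def genotype_duplications(tracks: list[CoverageTrack],
                          regions: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Genotype every (region, sample), with per-sample chromosome background."""
    rows = []
    for region in regions:
        for track in tracks:
            call = genotype_duplication(track, region)
            rows.append(dict(chrom=region[0], start=region[1], end=region[2],
                             sample=call.sample, fold_change=call.fold_change,
                             genotype=call.genotype))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    confusion: pd.DataFrame  # truth rows x query columns, dosage coded 0/1/2
    per_variant_error: pd.Series
    per_class_f1: dict[int, float]
    error_rate: float
    n_missing_truth: int
    n_missing_query: int


def concordance(truth: pd.DataFrame, query: pd.DataFrame) -> ConcordanceResult:
    """Confusion counts, per-variant error rates and per-genotype F1.

    Both frames are variants x samples with dosages {0, 1, 2, NaN}; pairs
    with a missing value in either set are counted separately and excluded
    from the confusion matrix.
    """
    common_v = truth.index.intersection(query.index)
    common_s = truth.columns.intersection(query.columns)
    T = truth.loc[common_v, common_s].to_numpy(dtype=float)
    Q = query.loc[common_v, common_s].to_numpy(dtype=float)
    miss_t = np.isnan(T)
    miss_q = np.isnan(Q)
    ok = ~miss_t & ~miss_q
    conf = np.zeros((3, 3), dtype=int)
    for t in range(3):
        for q in range(3):
            conf[t, q] = int(np.sum(ok & (T == t) & (Q == q)))
    f1 = {}
    for c in range(3):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        denom = 2 * tp + fp + fn
        f1[c] = float(2 * tp / denom) if denom > 0 else np.nan
    err = np.where(ok, T != Q, False)
    with np.errstate(invalid="ignore"):
        per_var = err.sum(axis=1) / np.maximum(ok.sum(axis=1), 1)
    total_ok = int(ok.sum())
    return ConcordanceResult(
        confusion=pd.DataFrame(conf, index=[f"truth_{g}" for g in GENOTYPES],
                               columns=[f"query_{g}" for g in GENOTYPES]),
        per_variant_error=pd.Series(per_var, index=common_v),
        per_class_f1=f1,
        error_rate=float(err.sum() / total_ok) if total_ok else np.nan,
        n_missing_truth=int(miss_t.sum()),
        n_missing_query=int(miss_q.sum()),
    )


# ---------------------------------------------------------------------------
# Correction and re-test
# ---------------------------------------------------------------------------

def correct_and_retest(g: GenotypeMatrix, corrections: list[tuple[str, str, float]],
                       phenos: PhenotypeTable,
                       covariates: pd.DataFrame | np.ndarray | None,
                       feature: str, variant: str) -> tuple[AssocStat, AssocStat]:
    """Association before and after applying genotype corrections.

    ``corrections`` holds (sample, variant, corrected dosage) triples; every
    referenced sample/variant must exist.
    """
    y = phenos.values[phenos.row(feature)]
    before = association_single(g.dosage_of(variant), y, covariates,
                                feature=feature, variant=variant)
    g2 = g.copy()
    sample_pos = {s: i for i, s in enumerate(g2.samples)}
    for sample, vid, dose in corrections:
        if sample not in sample_pos:
            raise KeyError(f"unknown sample {sample!r} in corrections")
        g2.dosages[sample_pos[sample], g2.variant_index(vid)] = dose
    after = association_single(g2.dosage_of(variant), y, covariates,
                               feature=feature, variant=variant)
    return before, after
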