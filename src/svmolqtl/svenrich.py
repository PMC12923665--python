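"""SV molQTL definition, enrichment and perfect-LD rescue.

A signal is an "SV molQTL" when an SV attains the signal's minimum nominal
p-value — either strictly smallest or exactly tied with the lead small
variant.  Enrichment of SVs among lead (top) variants is assessed with a
Fisher exact test on unique top variants against the tested variant sets.
The perfect-LD rescue re-attributes small-led signals to SVs in complete LD
(r^2 = 1) with the lead whose p-value is larger only because of differing
missing-genotype subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .cisqtl import QtlSignal, association_single
from .datamodel import GenotypeMatrix, PhenotypeTable, r2_pairwise

_TIE_RTOL = 1e-12


@dataclass
class LeadClassification:
    signal: QtlSignal
    lead_class: str  # "SV" or "small"
    lead: str  # reported lead after tie-breaking
    tied_sv: bool  # an SV ties the minimum p with a small variant
    tied_variants: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class EnrichmentResult:
    a: int  # group-of-interest successes (e.g. SV top variants)
    b: int  # group-of-interest non-successes (non-top tested SVs)
    c: int  # comparison successes (small top variants)
    d: int  # comparison non-successes
    odds_ratio: float
    fold: float
    p: float


def classify_leads(signals: list[QtlSignal], variants: pd.DataFrame
                   ) -> list[LeadClassification]:
    """Classify each signal's lead as SV or small under the exact-tie rule."""
    meta = variants.set_index("id")
    out = []
    for sig in signals:
        if not sig.variant_ps:
            raise ValueError(f"signal for {sig.feature} has no significant variants")
        ids = np.array(list(sig.variant_ps))
        ps = np.array([sig.variant_ps[v] for v in ids])
        pmin = ps.min()
        tied = ids[np.abs(ps - pmin) <= _TIE_RTOL * max(pmin, 1e-300)]
        is_sv = meta.loc[tied, "is_sv"].to_numpy(dtype=bool)
        if is_sv.any():
            svs = tied[is_sv]
            pos = meta.loc[svs, "pos"].to_numpy()
            lead = str(svs[np.argmin(pos)])
            out.append(LeadClassification(sig, "SV", lead,
                                          tied_sv=bool((~is_sv).any()),
                                          tied_variants=tied.tolist()))
        else:
            pos = meta.loc[tied, "pos"].to_numpy()
            lead = str(tied[np.argmin(pos)])
            out.append(LeadClassification(sig, "small", lead, tied_sv=False,
                                          tied_variants=tied.tolist()))
    return out


def enrichment_test(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """2x2 Fisher exact test with sample odds ratio and proportion-ratio fold.

    odds_ratio = (a d) / (b c), undefined (NaN) when b c = 0; fold is the
    ratio of success proportions (a/(a+b)) / (c/(c+d)).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("contingency counts must be non-negative")
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return EnrichmentResult(a, b, c, d, np.nan, np.nan, 1.0)
    odds = (a * d) / (b * c) if b * c > 0 else np.nan
    fold = (a / (a + b)) / (c / (c + d)) if (a + b) > 0 and c > 0 else np.nan
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(a, b, c, d, float(odds), float(fold), float(max(p, 1e-300)))


# ---------------------------------------------------------------------------
# Functional-element overlap
# ---------------------------------------------------------------------------

def sv_intervals(variants: pd.DataFrame) -> pd.DataFrame:
    """Genomic footprint of each SV: [pos, pos + sv_len) for DEL/DUP/INV,
    a 1-bp anchor for insertions (0-based half-open)."""
    sv = variants[variants["is_sv"]].copy()
    start = sv["pos"].to_numpy() - 1
    length = np.where(sv["var_class"].to_numpy() == "INS", 1,
                      np.maximum(sv["sv_len"].to_numpy(), 1))
    sv["start"] = start
    sv["end"] = start + length
    return sv[["id", "chrom", "start", "end"]]


def _annotation_trees(annot: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in annot.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            if e > s:
                tree[int(s):int(e)] = True
        trees[str(chrom)] = tree
    return trees


def overlap_mask(intervals: pd.DataFrame, annot: pd.DataFrame,
                 min_frac: float | None = None) -> np.ndarray:
    """Which intervals overlap the annotation set.

    ``min_frac=None`` means any (>= 1 bp) intersection; otherwise at least
    that fraction of the interval must be covered by the (merged) annotation.
    """
    trees = _annotation_trees(annot)
    out = np.zeros(len(intervals), dtype=bool)
    for i, (chrom, s, e) in enumerate(zip(intervals["chrom"], intervals["start"],
                                          intervals["end"])):
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        hits = tree.overlap(int(s), int(e))
        if not hits:
            continue
        if min_frac is None:
            out[i] = True
            continue
        segs = sorted((max(int(s), h.begin), min(int(e), h.end)) for h in hits)
        covered, cur_s, cur_e = 0, None, None
        for hs, he in segs:
            if cur_e is None or hs > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = hs, he
            else:
                cur_e = max(cur_e, he)
        if cur_e is not None:
            covered += cur_e - cur_s
        out[i] = covered >= min_frac * max(int(e) - int(s), 1)
    return out


def functional_overlap_enrichment(molqtl_sv_ids: set[str], variants: pd.DataFrame,
                                  annotations: dict[str, pd.DataFrame],
                                  min_frac: float | None = None
                                  ) -> dict[str, EnrichmentResult]:
    """Per-annotation Fisher enrichment of SV molQTL vs other tested SVs."""
    iv = sv_intervals(variants)
    is_mol = iv["id"].isin(molqtl_sv_ids).to_numpy()
    out: dict[str, EnrichmentResult] = {}
    for name, annot in annotations.items():
        if annot.empty:
            out[name] = EnrichmentResult(0, int(is_mol.sum()), 0,
                                         int((~is_mol).sum()), np.nan, np.nan, 1.0)
            continue
        hit = overlap_mask(iv, annot, min_frac=min_frac)
        a = int((hit & is_mol).sum())
        b = int((~hit & is_mol).sum())
        c = int((hit & ~is_mol).sum())
        d = int((~hit & ~is_mol).sum())
        out[name] = enrichment_test(a, b, c, d)
    return out


# ---------------------------------------------------------------------------
# Perfect-LD rescue
# ---------------------------------------------------------------------------

def perfect_ld_rescue(classifications: list[LeadClassification],
                      g: GenotypeMatrix, phenos: PhenotypeTable,
                      covariates: pd.DataFrame | np.ndarray | None = None,
                      window_bp: int = 1_000_000,
                      r2_tol: float = 1e-9) -> pd.DataFrame:
    """SVs in perfect LD with small lead variants but with larger p-values.

    For every small-led signal, SVs within the window in complete LD
    (r^2 >= 1 - r2_tol over pairwise-complete samples) with the lead are
    re-tested against the signal's phenotype; those with a strictly larger
    nominal p become rescue candidates.  Per-variant missing-genotype counts
    attribute the p-value gap to unequal casewise-deletion subsets.
    """
    pos_all = g.variants["pos"].to_numpy()
    chrom_all = g.variants["chrom"].to_numpy()
    is_sv = g.variants["is_sv"].to_numpy()
    vids = g.variants["id"].to_numpy()
    rows = []
    for cl in classifications:
        if cl.lead_class != "small":
            continue
        sig = cl.signal
        li = g.variant_index(cl.lead)
        lead_dose = g.dosages[:, li]
        fi = phenos.row(sig.feature)
        y = phenos.values[fi]
        lead_stat = association_single(lead_dose, y, covariates,
                                       feature=sig.feature, variant=cl.lead)
        near = np.flatnonzero(is_sv & (chrom_all == chrom_all[li])
                              & (np.abs(pos_all - pos_all[li]) <= window_bp))
        for j in near:
            r2, n = r2_pairwise(lead_dose, g.dosages[:, j])
            if np.isnan(r2) or r2 < 1.0 - r2_tol:
                continue
            sv_stat = association_single(g.dosages[:, j], y, covariates,
                                         feature=sig.feature, variant=vids[j])
            miss_lead = int(np.isnan(lead_dose).sum())
            miss_sv = int(np.isnan(g.dosages[:, j]).sum())
            if miss_lead > miss_sv:
                attribution = "lead missing > SV missing"
            elif miss_lead < miss_sv:
                attribution = "SV missing > lead missing"
            else:
                attribution = "equal missingness"
            rows.append(dict(feature=sig.feature, rank=sig.rank, lead=cl.lead,
                             sv=str(vids[j]), r2=r2, n_complete=n,
                             p_lead=lead_stat.p, p_sv=sv_stat.p,
                             missing_lead=miss_lead, missing_sv=miss_sv,
                             rescued=bool(sv_stat.p > lead_stat.p),
                             attribution=attribution))
    return pd.DataFrame(rows, columns=["feature", "rank", "lead", "sv", "r2",
                                       "n_complete", "p_lead", "p_sv",
                                       "missing_lead", "missing_sv", "rescued",
                                       "attribution"])


def lead_enrichment(classifications: list[LeadClassification],
                    n_tested_sv: int, n_tested_small: int,
                    rescue: pd.DataFrame | None = None) -> EnrichmentResult:
    """Unique-top-variant SV enrichment; optionally augmented with rescues.

    With a rescue table, every small-led signal having at least one rescued
    SV in perfect LD is counted as SV-associated: its rescued SVs join the
    unique SV-top set and its small lead leaves the small-top set.  Rescue
    can only move signals towards the SV column, so the augmented enrichment
    is at least the baseline.
    """
    sv_tops: set[str] = set()
    small_tops: set[str] = set()
    rescued_features: set[tuple[str, int]] = set()
    if rescue is not None and len(rescue):
        res = rescue[rescue["rescued"]]
        rescued_features = set(zip(res["feature"], res["rank"]))
    for cl in classifications:
        key = (cl.signal.feature, cl.signal.rank)
        if cl.lead_class == "SV":
            sv_tops.add(cl.lead)
        elif rescue is not None and key in rescued_features:
            svs = rescue[(rescue["feature"] == key[0]) & (rescue["rank"] == key[1])
                         & rescue["rescued"]]["sv"]
            sv_tops.add(str(svs.iloc[0]))
        else:
            small_tops.add(cl.lead)
    a = len(sv_tops)
    c = len(small_tops)
    return enrichment_test(a, max(n_tested_sv - a, 0), c, max(n_tested_small - c, 0))


# ---------------------------------------------------------------------------
# Effect-size and MAF summaries
# ---------------------------------------------------------------------------

def maf_effect_summary(classifications: list[LeadClassification],
                       nominal: pd.DataFrame, g: GenotypeMatrix
                       ) -> tuple[pd.DataFrame, float]:
    """Lead-variant |beta| and MAF per class, with a Wilcoxon rank-sum test
    between SV and small-variant leads (two-sided).  Returns (table, p);
    p is NaN (and a warning is emitted) when a class has < 2 leads.
    """
    maf = g.maf()
    meta = g.variants.set_index("id")
    key = nominal.set_index(["feature", "variant"])["beta"]
    rows = []
    for cl in classifications:
        sig = cl.signal
        try:
            beta = float(key.loc[(sig.feature, cl.lead)])
        except KeyError:
            beta = np.nan
        j = g.variant_index(cl.lead)
        rows.append(dict(feature=sig.feature, rank=sig.rank, lead=cl.lead,
                         lead_class=cl.lead_class,
                         var_class=meta.loc[cl.lead, "var_class"],
                         maf=float(maf[j]), abs_beta=abs(beta)))
    df = pd.DataFrame(rows, columns=["feature", "rank", "lead", "lead_class",
                                     "var_class", "maf", "abs_beta"])
    sv = df.loc[df["lead_class"] == "SV", "abs_beta"].dropna()
    small = df.loc[df["lead_class"] == "small", "abs_beta"].dropna()
    if len(sv) < 2 or len(small) < 2:
        warnings.warn("rank-sum test skipped: fewer than 2 leads in a class",
                      stacklevel=2)
        return df, np.nan
    _, p = stats.ranksums(sv, small)
    return df, float(p)
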