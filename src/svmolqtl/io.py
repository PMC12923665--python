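"""Plain-text writers/readers for the cohort formats.

Genotypes go to VCF 4.2 (GT only, missing as ``./.``), molecular phenotypes
to QTLtools-dialect BED (#chr start end pid gid strand sample...), covariates
to a covariates x samples TSV, and per-window depth to 4-column BED
(0-based half-open windows).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, PhenotypeTable


def _gt_string(d: float) -> str:
    if np.isnan(d):
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(round(d))]


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        order = g.variants.sort_values(["chrom", "pos"]).index
        for i in order:
            v = g.variants.iloc[i]
            ref = "N" * int(v["ref_len"])
            if v["var_class"] in ("DUP", "INV"):
                alt = f"<{v['var_class']}>"
            else:
                alt = "N" * int(v["alt_len"])
            info = "."
            if v["is_sv"]:
                info = f"SVTYPE={v['var_class']};SVLEN={int(v['sv_len'])}"
            gts = "\t".join(_gt_string(d) for d in g.dosages[:, i])
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{ref}\t{alt}"
                     f"\t.\tPASS\t{info}\tGT\t{gts}\n")


def write_phenotype_bed(p: PhenotypeTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#chr\tstart\tend\tpid\tgid\tstrand\t" + "\t".join(p.samples) + "\n")
        for i in range(p.n_features):
            f = p.features.iloc[i]
            vals = "\t".join(f"{v:.6g}" for v in p.values[i])
            fh.write(f"{f['chrom']}\t{int(f['start'])}\t{int(f['end'])}\t{f['pid']}"
                     f"\t{f['gid']}\t{f['strand']}\t{vals}\n")


def read_phenotype_bed(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "chrom"})
    df["chrom"] = df["chrom"].astype(str)
    feat_cols = ["chrom", "start", "end", "pid", "gid", "strand"]
    samples = [c for c in df.columns if c not in feat_cols]
    return PhenotypeTable(features=df[feat_cols],
                          values=df[samples].to_numpy(dtype=float),
                          samples=samples)


def write_covariates_tsv(cov: pd.DataFrame, path: str | Path) -> None:
    """Covariates x samples TSV (covariate ids in the first column)."""
    cov.T.rename_axis("id").to_csv(path, sep="\t")


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    """Returns samples x covariates."""
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_coverage_bed(windows: pd.DataFrame, depth: np.ndarray, path: str | Path) -> None:
    out = windows[["chrom", "start", "end"]].copy()
    out["depth"] = depth
    out.to_csv(path, sep="\t", header=False, index=False)


def read_coverage_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "depth"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_truth_json(truth, path: str | Path) -> None:
    payload = {
        "causal_map": {k: [v[0], float(v[1])] for k, v in truth.causal_map.items()},
        "error_log": [[s, v, float(a), float(b)] for s, v, a, b in truth.error_log],
        "missing_log": [[s, v, float(orig)] for s, v, orig in truth.missing_log],
        "perfect_ld_pairs": [list(p) for p in truth.perfect_ld_pairs],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
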