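"""Permutation-based cis-molQTL mapping.

The nominal pass regresses each phenotype on each testable cis variant plus
covariates by OLS, fitted on exactly the samples with a non-missing dosage
for that variant (casewise deletion).  Per-variant regressions within one
missingness pattern are computed jointly through a QR projection of the
covariates on that pattern's sample subset — algebraically identical to
refitting the covariates in every regression, so unequal missingness between
variants propagates into the test statistics exactly.

The permutation pass permutes phenotype values against fixed genotypes and
covariates (one shared permutation sequence per feature across variants),
records the minimum nominal p per permutation, and fits a two-parameter Beta
distribution to the permuted minima by maximum likelihood (moment-based
initialisation).  The adjusted p-value is the fitted Beta CDF at the
observed minimum.  Gene-level significance is controlled at 5% FDR with
Storey q-values (Benjamini-Hochberg fallback), and each feature receives a
nominal significance threshold by inverting its Beta fit at the FDR
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datamodel import FilterConfig, GenotypeMatrix, PhenotypeTable, filter_variants

_P_FLOOR = 1e-300
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class AssocStat:
    feature: str
    variant: str
    n_used: int
    beta: float
    se: float
    p: float


@dataclass(frozen=True)
class BetaFit:
    alpha: float
    beta: float
    n_perm: int
    empirical_p: float
    converged: bool


@dataclass
class QtlSignal:
    feature: str
    gid: str
    rank: int
    lead: str
    p_nominal: float
    p_adjusted: float
    q: float
    threshold: float
    variant_ids: list[str] = field(default_factory=list)
    variant_ps: dict[str, float] = field(default_factory=dict)


def covariate_matrix(covariates: pd.DataFrame | np.ndarray | None,
                     n_samples: int) -> np.ndarray:
    """Design matrix with leading intercept column."""
    if covariates is None:
        return np.ones((n_samples, 1))
    C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) \
        else np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n_samples:
        raise ValueError("covariates not aligned with samples")
    return np.column_stack([np.ones(n_samples), C])


def _pattern_groups(G: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group variant columns by missingness pattern: [(sample_mask, cols)]."""
    masks = ~np.isnan(G)
    seen: dict[bytes, list[int]] = {}
    for j in range(G.shape[1]):
        seen.setdefault(masks[:, j].tobytes(), []).append(j)
    n = G.shape[0]
    return [(np.frombuffer(key, dtype=bool).copy(), np.asarray(cols))
            for key, cols in seen.items()]


def scan_feature(G: np.ndarray, y: np.ndarray, C1: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Casewise-deletion OLS of y on each column of G plus covariates.

    Returns (beta, se, p, n_used); entries are NaN where a variant is
    untestable (degenerate dosage or too few complete samples).
    """
    v = G.shape[1]
    k = C1.shape[1]
    beta = np.full(v, np.nan)
    se = np.full(v, np.nan)
    p = np.full(v, np.nan)
    n_used = np.zeros(v, dtype=int)
    for S, cols in _pattern_groups(G):
        ns = int(S.sum())
        n_used[cols] = ns
        if ns <= k + 1:  # n_used <= n_covariates + 2 (intercept included in k)
            continue
        Q, _ = np.linalg.qr(C1[S])
        Gt = G[np.ix_(S, cols)]
        Gt = Gt - Q @ (Q.T @ Gt)
        gnorm = np.linalg.norm(Gt, axis=0)
        ys = y[S]
        yt = ys - Q @ (Q.T @ ys)
        ynorm = np.linalg.norm(yt)
        ok = (gnorm > 1e-12) & (ynorm > 1e-12)
        if not ok.any():
            continue
        df = ns - k - 1
        num = Gt.T @ yt
        r = np.zeros(len(cols))
        r[ok] = np.clip(num[ok] / (gnorm[ok] * ynorm), -1.0, 1.0)
        one_minus = np.maximum(1.0 - r ** 2, 1e-16)
        t = r * np.sqrt(df / one_minus)
        pj = 2.0 * stats.t.sf(np.abs(t), df)
        bj = np.where(ok, num / np.maximum(gnorm ** 2, 1e-300), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            sj = np.abs(bj) / np.maximum(np.abs(t), 1e-300)
        beta[cols[ok]] = bj[ok]
        se[cols[ok]] = sj[ok]
        p[cols[ok]] = np.maximum(pj[ok], _P_FLOOR)
    return beta, se, p, n_used


def _min_p_perms(G: np.ndarray, Y: np.ndarray, C1: np.ndarray) -> np.ndarray:
    """Minimum nominal p across variants for each phenotype column of Y."""
    k = C1.shape[1]
    minp = np.full(Y.shape[1], np.nan)
    for S, cols in _pattern_groups(G):
        ns = int(S.sum())
        if ns <= k + 1:
            continue
        Q, _ = np.linalg.qr(C1[S])
        Gt = G[np.ix_(S, cols)]
        Gt = Gt - Q @ (Q.T @ Gt)
        gnorm = np.linalg.norm(Gt, axis=0)
        ok = gnorm > 1e-12
        if not ok.any():
            continue
        Ys = Y[S]
        Yt = Ys - Q @ (Q.T @ Ys)
        ynorm = np.linalg.norm(Yt, axis=0)
        ynorm = np.maximum(ynorm, 1e-300)
        R = (Gt[:, ok].T @ Yt) / (gnorm[ok, None] * ynorm[None, :])
        np.clip(R, -1.0, 1.0, out=R)
        df = ns - k - 1
        one_minus = np.maximum(1.0 - R ** 2, 1e-16)
        T = np.abs(R) * np.sqrt(df / one_minus)
        P = 2.0 * stats.t.sf(T, df)
        pat_min = P.min(axis=0)
        minp = np.fmin(minp, pat_min)
    return np.maximum(minp, _P_FLOOR)


def association_single(dosage: np.ndarray, y: np.ndarray,
                       covariates: pd.DataFrame | np.ndarray | None,
                       feature: str = "feature", variant: str = "variant"
                       ) -> AssocStat:
    """One casewise-deletion OLS association, returned as an AssocStat."""
    C1 = covariate_matrix(covariates, len(y))
    b, s, p, n = scan_feature(np.asarray(dosage, float)[:, None],
                              np.asarray(y, float), C1)
    return AssocStat(feature=feature, variant=variant, n_used=int(n[0]),
                     beta=float(b[0]), se=float(s[0]), p=float(p[0]))


def nominal_scan(g: GenotypeMatrix, phenos: PhenotypeTable,
                 covariates: pd.DataFrame | np.ndarray | None = None,
                 cis: dict[str, np.ndarray] | None = None,
                 cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Nominal pass: one row per (feature, testable cis variant)."""
    cis = cis if cis is not None else filter_variants(g, phenos, cfg)
    C1 = covariate_matrix(covariates, g.n_samples)
    vids = g.variants["id"].to_numpy()
    rows = []
    for i, pid in enumerate(phenos.features["pid"]):
        idx = cis.get(str(pid), np.empty(0, int))
        if len(idx) == 0:
            continue
        beta, se, p, n_used = scan_feature(g.dosages[:, idx], phenos.values[i], C1)
        for r, j in enumerate(idx):
            rows.append((str(pid), vids[j], int(n_used[r]), beta[r], se[r], p[r]))
    return pd.DataFrame(rows, columns=["feature", "variant", "n_used", "beta",
                                       "se", "p"])


# ---------------------------------------------------------------------------
# Beta approximation of permutation minima
# ---------------------------------------------------------------------------

def fit_beta_minp(minp: np.ndarray) -> tuple[float, float, bool]:
    """Two-parameter Beta MLE with method-of-moments initialisation.

    Returns (alpha, beta, converged); on optimisation failure the moment
    estimates are returned with converged=False.
    """
    x = np.clip(np.asarray(minp, float), 1e-12, 1.0 - 1e-12)
    m = x.mean()
    v = x.var()
    if v <= 0:
        return 1.0, 1.0, False
    c = m * (1.0 - m) / v - 1.0
    a0 = max(m * c, 1e-3)
    b0 = max((1.0 - m) * c, 1e-3)
    slog = np.log(x).sum()
    slog1m = np.log1p(-x).sum()
    n = len(x)

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        return float(n * special.betaln(a, b) - (a - 1) * slog - (b - 1) * slog1m)

    try:
        res = optimize.minimize(nll, np.log([a0, b0]), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 500})
        if res.success and np.all(np.isfinite(res.x)):
            a, b = np.exp(res.x)
            return float(a), float(b), True
    except (ValueError, FloatingPointError):
        pass
    return float(a0), float(b0), False


def _feature_rng(seed: int, feature_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(feature_index,)))


def _perm_columns(y: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    n = len(y)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)  # independent permutations
    return y[idx].T  # (n, n_perm)


_PERM_COLUMNS = ["feature", "gid", "n_variants", "best_variant", "p_nominal",
                 "slope", "empirical_p", "beta_alpha", "beta_beta",
                 "beta_converged", "p_adjusted", "n_perm"]


def permutation_pass(g: GenotypeMatrix, phenos: PhenotypeTable,
                     covariates: pd.DataFrame | np.ndarray | None = None,
                     cis: dict[str, np.ndarray] | None = None,
                     n_perm: int = 1000, seed: int = 0,
                     cfg: FilterConfig | None = None,
                     keep_perm_minima: bool = False,
                     perm_chunk: int = 20_000
                     ) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-feature beta-approximated empirical p-values.

    The empirical p uses the (1 + k) / (1 + n_perm) estimator; the adjusted p
    is the Beta CDF of the observed minimum nominal p.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    cis = cis if cis is not None else filter_variants(g, phenos, cfg)
    C1 = covariate_matrix(covariates, g.n_samples)
    vids = g.variants["id"].to_numpy()
    rows = []
    minima: dict[str, np.ndarray] = {}
    for i, pid in enumerate(phenos.features["pid"]):
        idx = cis.get(str(pid), np.empty(0, int))
        if len(idx) == 0:
            continue
        G = g.dosages[:, idx]
        y = phenos.values[i]
        beta, _, p, _ = scan_feature(G, y, C1)
        if np.all(np.isnan(p)):
            continue
        jbest = int(np.nanargmin(p))
        p0 = float(p[jbest])
        rng = _feature_rng(seed, i)
        chunks = []
        remaining = n_perm
        while remaining > 0:
            b = min(perm_chunk, remaining)
            Y = _perm_columns(y, b, rng)
            chunks.append(_min_p_perms(G, Y, C1))
            remaining -= b
        perm_min = np.concatenate(chunks)
        perm_min = perm_min[~np.isnan(perm_min)]
        emp = (1.0 + np.sum(perm_min <= p0)) / (1.0 + len(perm_min))
        a, bshape, conv = fit_beta_minp(perm_min)
        p_adj = float(stats.beta.cdf(p0, a, bshape)) if conv else float(emp)
        rows.append((str(pid), str(phenos.features["gid"].iloc[i]), len(idx),
                     vids[idx[jbest]], p0, float(beta[jbest]), float(emp),
                     a, bshape, conv, max(p_adj, _P_FLOOR), len(perm_min)))
        if keep_perm_minima:
            minima[str(pid)] = perm_min
    df = pd.DataFrame(rows, columns=_PERM_COLUMNS)
    return (df, minima) if keep_perm_minima else df


def grouped_permutation(g: GenotypeMatrix, phenos: PhenotypeTable,
                        covariates: pd.DataFrame | np.ndarray | None = None,
                        cis: dict[str, np.ndarray] | None = None,
                        n_perm: int = 1000, seed: int = 0,
                        cfg: FilterConfig | None = None,
                        perm_chunk: int = 20_000) -> pd.DataFrame:
    """Group-best permutation pass (intron-cluster style grouping).

    Per permutation one sample-label permutation is drawn per group and the
    minimum nominal p is taken across all (member phenotype x variant) pairs;
    the Beta fit and adjustment then proceed as in the ungrouped pass.  The
    reported feature is the member attaining the observed group minimum.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    cis = cis if cis is not None else filter_variants(g, phenos, cfg)
    C1 = covariate_matrix(covariates, g.n_samples)
    vids = g.variants["id"].to_numpy()
    gids = phenos.features["gid"].astype(str).to_numpy()
    rows = []
    for gi, gid in enumerate(pd.unique(gids)):
        members = np.flatnonzero(gids == gid)
        members = [m for m in members
                   if len(cis.get(str(phenos.features["pid"].iloc[m]), ())) > 0]
        if not members:
            continue
        rng = _feature_rng(seed, gi)
        perm_idx = np.argsort(rng.random((n_perm, g.n_samples)), axis=1)
        best = (np.inf, None, None)  # (p, pid, variant)
        n_var_total = 0
        group_min = np.full(n_perm, np.nan)
        for m in members:
            pid = str(phenos.features["pid"].iloc[m])
            idx = cis[pid]
            n_var_total += len(idx)
            G = g.dosages[:, idx]
            y = phenos.values[m]
            _, _, p, _ = scan_feature(G, y, C1)
            if not np.all(np.isnan(p)):
                jbest = int(np.nanargmin(p))
                if p[jbest] < best[0]:
                    best = (float(p[jbest]), pid, vids[idx[jbest]])
            start = 0
            while start < n_perm:
                stop = min(start + perm_chunk, n_perm)
                Y = y[perm_idx[start:stop]].T
                mp = _min_p_perms(G, Y, C1)
                group_min[start:stop] = np.fmin(group_min[start:stop], mp)
                start = stop
        if best[1] is None:
            continue
        group_min = group_min[~np.isnan(group_min)]
        p0 = best[0]
        emp = (1.0 + np.sum(group_min <= p0)) / (1.0 + len(group_min))
        a, bshape, conv = fit_beta_minp(group_min)
        p_adj = float(stats.beta.cdf(p0, a, bshape)) if conv else float(emp)
        rows.append((best[1], gid, n_var_total, best[2], p0, np.nan, float(emp),
                     a, bshape, conv, max(p_adj, _P_FLOOR), len(group_min)))
    return pd.DataFrame(rows, columns=_PERM_COLUMNS)


# ---------------------------------------------------------------------------
# FDR and per-feature thresholds
# ---------------------------------------------------------------------------

def storey_pi0(p: np.ndarray) -> float:
    """Storey's pi0 by the smoother method; NaN when the estimate fails."""
    p = np.asarray(p, float)
    m = len(p)
    if m < 20:
        return np.nan
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    try:
        coef = np.polyfit(lambdas, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
    except np.linalg.LinAlgError:
        return np.nan
    if not np.isfinite(pi0) or pi0 <= 0:
        return np.nan
    return min(pi0, 1.0)


def qvalues(p: np.ndarray) -> tuple[np.ndarray, float]:
    """Storey q-values; falls back to Benjamini-Hochberg (pi0 = 1)."""
    p = np.asarray(p, float)
    m = len(p)
    if m == 0:
        return p.copy(), 1.0
    pi0 = storey_pi0(p)
    if np.isnan(pi0):
        pi0 = 1.0
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out, pi0


def fdr_and_thresholds(perm_df: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Q-values, significance calls and per-feature nominal thresholds.

    The nominal threshold is the inverse Beta CDF — at the feature's fitted
    (alpha, beta) — of the adjusted-p cutoff at the FDR boundary (midpoint
    between the largest significant and smallest non-significant adjusted p).
    """
    df = perm_df.copy()
    if df.empty:
        df["q"] = df["significant"] = df["threshold"] = pd.Series(dtype=float)
        return df
    q, _ = qvalues(df["p_adjusted"].to_numpy())
    df["q"] = q
    df["significant"] = df["q"] <= fdr
    sig = df.loc[df["significant"], "p_adjusted"]
    nonsig = df.loc[~df["significant"], "p_adjusted"]
    if len(sig) == 0:
        df["threshold"] = np.nan
        return df
    if len(nonsig) == 0:
        cutoff = float(sig.max())
    else:
        cutoff = float((sig.max() + nonsig.min()) / 2.0)
    thr = stats.beta.ppf(cutoff, df["beta_alpha"].to_numpy(),
                         df["beta_beta"].to_numpy())
    df["threshold"] = np.where(df["significant"], thr, np.nan)
    return df


# ---------------------------------------------------------------------------
# Conditional analysis
# ---------------------------------------------------------------------------

def _impute_cols(X: np.ndarray) -> np.ndarray:
    X = X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = np.isnan(col)
        if bad.any():
            col[bad] = np.nanmean(col)
    return X


def pick_lead(p: np.ndarray, idx: np.ndarray, variants: pd.DataFrame,
              rtol: float = _TIE_RTOL) -> tuple[int, list[int]]:
    """Minimum-p variant with the SV-preferring, then leftmost, tie rule.

    Returns (chosen local index into ``idx``, all tied local indices).
    """
    pmin = np.nanmin(p)
    tied = np.flatnonzero(np.abs(p - pmin) <= rtol * max(pmin, _P_FLOOR))
    sub = variants.iloc[idx[tied]]
    is_sv = sub["is_sv"].to_numpy()
    pool = tied[is_sv] if is_sv.any() else tied
    pos = variants["pos"].to_numpy()[idx[pool]]
    return int(pool[np.argmin(pos)]), tied.tolist()


def conditional_scan(g: GenotypeMatrix, phenos: PhenotypeTable,
                     covariates: pd.DataFrame | np.ndarray | None,
                     fdr_df: pd.DataFrame,
                     cis: dict[str, np.ndarray] | None = None,
                     cfg: FilterConfig | None = None,
                     max_rank: int = 10) -> list[QtlSignal]:
    """Forward-backward stepwise decomposition into independent signals.

    Forward: iteratively add the current best variant (below the feature's
    nominal threshold) to the covariates and re-scan.  Backward: re-test each
    candidate conditioning on all other retained leads; variants passing the
    threshold conditionally are assigned to the signal and the lead is the
    minimum conditional p (SV-preferring tie rule).  Conditioning dosages are
    mean-imputed so the conditioned regression keeps each variant's own
    casewise-deletion subset.
    """
    cis = cis if cis is not None else filter_variants(g, phenos, cfg)
    C1 = covariate_matrix(covariates, g.n_samples)
    vids = g.variants["id"].to_numpy()
    signals: list[QtlSignal] = []
    sig_rows = fdr_df[fdr_df["significant"]] if "significant" in fdr_df else fdr_df
    for _, row in sig_rows.iterrows():
        pid = str(row["feature"])
        thr = float(row["threshold"])
        if not np.isfinite(thr):
            continue
        idx = cis.get(pid, np.empty(0, int))
        if len(idx) == 0:
            continue
        fi = phenos.row(pid)
        G = g.dosages[:, idx]
        y = phenos.values[fi]
        # forward pass
        leads: list[int] = []
        while len(leads) < max_rank:
            cond = _impute_cols(G[:, leads]) if leads else np.empty((len(y), 0))
            Cc = np.column_stack([C1, cond])
            if leads and np.linalg.matrix_rank(Cc) < Cc.shape[1]:
                warnings.warn(f"{pid}: collinear lead set, dropping newest lead",
                              stacklevel=2)
                leads.pop()
                break
            _, _, p, _ = scan_feature(G, y, Cc)
            p_masked = p.copy()
            p_masked[leads] = np.nan
            if np.all(np.isnan(p_masked)) or np.nanmin(p_masked) > thr:
                break
            leads.append(int(np.nanargmin(p_masked)))
        # backward pass
        for rank, lead_j in enumerate(leads):
            others = [l for l in leads if l != lead_j]
            cond = _impute_cols(G[:, others]) if others else np.empty((len(y), 0))
            Cc = np.column_stack([C1, cond])
            _, _, p, _ = scan_feature(G, y, Cc)
            passing = np.flatnonzero(~np.isnan(p) & (p <= thr))
            if len(passing) == 0:
                continue
            chosen, _ = pick_lead(p[passing], idx[passing], g.variants)
            lead_local = int(passing[chosen])
            signals.append(QtlSignal(
                feature=pid, gid=str(row["gid"]), rank=rank,
                lead=str(vids[idx[lead_local]]), p_nominal=float(p[lead_local]),
                p_adjusted=float(row["p_adjusted"]), q=float(row["q"]),
                threshold=thr,
                variant_ids=[str(vids[idx[j]]) for j in passing],
                variant_ps={str(vids[idx[j]]): float(p[j]) for j in passing}))
    return signals


def map_molqtl(g: GenotypeMatrix, phenos: PhenotypeTable,
               covariates: pd.DataFrame | np.ndarray | None = None,
               cfg: FilterConfig | None = None, n_perm: int = 1000,
               seed: int = 0, fdr: float = 0.05, grouped: bool = False,
               conditional: bool = True
               ) -> tuple[pd.DataFrame, list[QtlSignal]]:
    """Full mapping pipeline: permutation pass, FDR, conditional signals.

    With ``conditional=False`` each significant feature yields one rank-0
    signal whose significant set comes from the unconditioned nominal scan.
    """
    cis = filter_variants(g, phenos, cfg)
    if grouped:
        perm = grouped_permutation(g, phenos, covariates, cis, n_perm=n_perm,
                                   seed=seed)
    else:
        perm = permutation_pass(g, phenos, covariates, cis, n_perm=n_perm,
                                seed=seed)
    perm = fdr_and_thresholds(perm, fdr=fdr)
    if conditional:
        signals = conditional_scan(g, phenos, covariates, perm, cis)
        return perm, signals
    C1 = covariate_matrix(covariates, g.n_samples)
    vids = g.variants["id"].to_numpy()
    signals = []
    for _, row in perm[perm["significant"]].iterrows():
        pid = str(row["feature"])
        thr = float(row["threshold"])
        idx = cis.get(pid, np.empty(0, int))
        if len(idx) == 0 or not np.isfinite(thr):
            continue
        _, _, p, _ = scan_feature(g.dosages[:, idx], phenos.values[phenos.row(pid)], C1)
        passing = np.flatnonzero(~np.isnan(p) & (p <= thr))
        if len(passing) == 0:
            continue
        chosen, _ = pick_lead(p[passing], idx[passing], g.variants)
        lead_local = int(passing[chosen])
        signals.append(QtlSignal(
            feature=pid, gid=str(row["gid"]), rank=0,
            lead=str(vids[idx[lead_local]]), p_nominal=float(p[lead_local]),
            p_adjusted=float(row["p_adjusted"]), q=float(row["q"]), threshold=thr,
            variant_ids=[str(vids[idx[j]]) for j in passing],
            variant_ps={str(vids[idx[j]]): float(p[j]) for j in passing}))
    return perm, signals
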