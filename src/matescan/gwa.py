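"""Mixed-model genome-wide association on inbred-line means.

The association model is the standard single-variance-component LMM

    y = X b + Z u + e,   u ~ N(0, su2 K),  e ~ N(0, se2 I)

fit to covariate-adjusted line means: phenotypes are first regressed on
Wolbachia infection status and the karyotypes of the five major
polymorphic inversions, and the residuals (re-centred at the grand mean)
carried forward.  K is the genomic relationship matrix from
centred-and-scaled dosages.  The LMM is solved spectrally: K is
eigendecomposed once, the variance ratio delta = se2/su2 estimated by
REML under the no-variant model, and each variant tested by generalized
least squares in the rotated space with a two-sided Wald t test
(optionally re-estimating delta per variant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import optimize, stats

from .datatypes import INVERSIONS, GenotypeMatrix


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def maf_filter(g: GenotypeMatrix, threshold: float = 0.02) -> GenotypeMatrix:
    """Keep variants with folded minor-allele frequency strictly greater
    than ``threshold`` (computed over non-missing lines)."""
    if not 0.0 <= threshold < 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    return g.subset_variants(g.maf() > threshold)


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def _covariate_design(cov: pd.DataFrame, include_inversions: bool) -> np.ndarray:
    cols = [np.ones(len(cov))]
    if "wolbachia" in cov.columns:
        w = cov["wolbachia"]
        if w.dtype == object:
            w = w.map({"y": 1, "n": 0, "yes": 1, "no": 0, True: 1, False: 0})
        cols.append(w.to_numpy(dtype=float))
    if include_inversions:
        for inv in INVERSIONS:
            if inv not in cov.columns:
                continue
            for level in ("ST/INV", "INV/INV"):  # ST/ST is the reference
                cols.append((cov[inv] == level).to_numpy(dtype=float))
    X = np.column_stack(cols)
    # drop constant non-intercept columns so the fit is full rank
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    return X[:, keep]


def adjust_phenotype(
    means: pd.DataFrame | pd.Series,
    covariates: pd.DataFrame,
    include_inversions: bool = True,
) -> pd.Series:
    """Adjust line means for Wolbachia and inversion karyotypes by OLS;
    returns residual + grand mean, indexed by line.

    ``include_inversions=False`` reproduces the companion scan that leaves
    inversion effects in the phenotype.
    """
    s = means["mean"] if isinstance(means, pd.DataFrame) else means
    missing = s.index.difference(covariates.index)
    if len(missing):
        raise ValueError(f"missing covariate rows for lines: {list(missing)[:5]}")
    cov = covariates.loc[s.index]
    y = s.to_numpy(dtype=float)
    X = _covariate_design(cov, include_inversions)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid + y.mean(), index=s.index, name="adjusted")


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

def compute_grm(g: GenotypeMatrix) -> np.ndarray:
    """K = W W' / L with W the dosage matrix, each variant centred by 2p
    and scaled by sqrt(2p(1-p)); missing dosages mean-imputed per variant.
    Monomorphic variants carry no information and are dropped from W and L.
    """
    if g.n_variants == 0:
        raise ValueError("no variants")
    D = g.dosage.copy()
    mean = np.nanmean(D, axis=0)
    nanmask = np.isnan(D)
    D[nanmask] = np.broadcast_to(mean, D.shape)[nanmask]
    p = mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = scale > 0
    if not poly.any():
        raise ValueError("all variants monomorphic")
    W = (D[:, poly] - 2.0 * p[poly]) / scale[poly]
    return W @ W.T / int(poly.sum())


# ---------------------------------------------------------------------------
# LMM association
# ---------------------------------------------------------------------------

def _reml_delta_neg2ll(log_delta: float, s: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
    """-2 REML log-likelihood of the null (intercept-only) model as a
    function of log delta, with su2 profiled out."""
    delta = np.exp(log_delta)
    lam = s + delta
    w = 1.0 / lam
    xtx = np.sum(w * xr * xr)
    beta = np.sum(w * xr * yr) / xtx
    r = yr - beta * xr
    q = np.sum(w * r * r)
    n = len(yr)
    q = max(q, 1e-300)
    return (n - 1) * np.log(q / (n - 1)) + np.sum(np.log(lam)) + np.log(xtx)


def estimate_delta(y: np.ndarray, K: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """REML estimate of delta = se2/su2 under the no-variant model.

    Returns (delta, eigenvalues, eigenvectors) so callers reuse the
    spectral decomposition.
    """
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yr = U.T @ y
    xr = U.T @ np.ones_like(y)
    obj = lambda ld: _reml_delta_neg2ll(ld, s, yr, xr)
    grid = np.linspace(-10, 10, 21)
    vals = [obj(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded")
    return float(np.exp(res.x)), s, U


def lmm_association(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    K: np.ndarray,
    per_variant_reml: bool = False,
    delta: float | None = None,
) -> pd.DataFrame:
    """Per-variant mixed-model association with Wald t tests.

    By default delta is estimated once under the null and reused for every
    variant (two-step spectral approximation); ``per_variant_reml=True``
    re-estimates delta for each variant, and an explicit ``delta`` fixes
    the variance ratio (delta -> infinity recovers plain OLS).  Lines with
    a missing dosage at the tested variant are excluded from that
    variant's test (handled by a direct GLS solve on the reduced line
    set).
    """
    if isinstance(y, pd.Series):
        if list(y.index) != list(g.line_ids):
            y = y.reindex(g.line_ids)
            if y.isna().any():
                raise ValueError("phenotype missing for some genotyped lines")
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != g.n_lines or K.shape != (n, n):
        raise ValueError("y, genotypes and K must cover identical line sets")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    if np.any(np.linalg.eigvalsh(K) < -1e-6):
        raise ValueError("K is not positive semi-definite")

    if delta is None:
        delta, s, U = estimate_delta(y, K)
    else:
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0.0, None)
    lam = s + delta
    w = 1.0 / lam
    yr = U.T @ y
    xr0 = U.T @ np.ones(n)

    D = g.dosage
    complete = ~np.isnan(D).any(axis=0)
    maf = g.maf()

    beta = np.full(g.n_variants, np.nan)
    se = np.full(g.n_variants, np.nan)
    tstat = np.full(g.n_variants, np.nan)
    pval = np.full(g.n_variants, np.nan)
    nused = np.full(g.n_variants, n)

    def _gls_rotated(wv, x0, xv, yv):
        a11 = np.sum(wv * x0 * x0)
        a12 = np.sum(wv * x0 * xv)
        a22 = np.sum(wv * xv * xv)
        b1 = np.sum(wv * x0 * yv)
        b2 = np.sum(wv * xv * yv)
        det = a11 * a22 - a12 * a12
        if det <= 0:
            return np.nan, np.nan, np.nan, np.nan
        bet2 = (a11 * b2 - a12 * b1) / det
        bet1 = (b1 - a12 * bet2) / a11
        rss = np.sum(wv * yv * yv) - (b1 * bet1 + b2 * bet2)
        m = len(yv)
        sigma2 = max(rss, 0.0) / (m - 2)
        se2 = sigma2 * a11 / det
        if se2 <= 0:
            return bet2, np.nan, np.nan, np.nan
        t = bet2 / np.sqrt(se2)
        p = 2.0 * stats.t.sf(abs(t), df=m - 2)
        return bet2, np.sqrt(se2), t, p

    # fast path: complete variants, shared rotation, vectorized GLS
    idx = np.flatnonzero(complete)
    if idx.size:
        Xr = U.T @ D[:, idx]                      # (n, m)
        if per_variant_reml:
            for jj, j in enumerate(idx):
                dj, sj, Uj = estimate_delta_with_variant(y, K, D[:, j])
                wv = 1.0 / (sj + dj)
                beta[j], se[j], tstat[j], pval[j] = _gls_rotated(
                    wv, Uj.T @ np.ones(n), Uj.T @ D[:, j], Uj.T @ y
                )
        else:
            Wv = w[:, None]
            a11 = np.sum(w * xr0 * xr0)
            a12 = (xr0 * w) @ Xr
            a22 = np.einsum("ij,ij->j", Xr * Wv, Xr)
            b1 = np.sum(w * xr0 * yr)
            b2 = (yr * w) @ Xr
            det = a11 * a22 - a12**2
            ok = det > 0
            bet2 = np.where(ok, (a11 * b2 - a12 * b1) / np.where(ok, det, 1.0), np.nan)
            bet1 = (b1 - a12 * bet2) / a11
            rss = np.sum(w * yr * yr) - (b1 * bet1 + b2 * bet2)
            sigma2 = np.clip(rss, 0.0, None) / (n - 2)
            se2 = sigma2 * a11 / np.where(ok, det, np.nan)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = bet2 / np.sqrt(se2)
            p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
            beta[idx], se[idx] = bet2, np.sqrt(se2)
            tstat[idx], pval[idx] = t, p

    # slow path: variants with missing calls, reduced-line GLS
    for j in np.flatnonzero(~complete):
        use = ~np.isnan(D[:, j])
        m = int(use.sum())
        nused[j] = m
        if m < 3 or np.ptp(D[use, j]) == 0:
            continue
        Ks = K[np.ix_(use, use)]
        ss, Us = np.linalg.eigh(Ks)
        ss = np.clip(ss, 0.0, None)
        wv = 1.0 / (ss + delta)
        beta[j], se[j], tstat[j], pval[j] = _gls_rotated(
            wv, Us.T @ np.ones(m), Us.T @ D[use, j], Us.T @ y[use]
        )

    out = g.variants.copy()
    out["maf"] = maf
    out["n"] = nused
    out["beta"] = beta
    out["se"] = se
    out["stat"] = tstat
    out["p"] = np.clip(pval, np.nextafter(0, 1), 1.0)
    return out


def estimate_delta_with_variant(
    y: np.ndarray, K: np.ndarray, x: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact per-variant REML of delta with the tested variant as a fixed
    effect (the slow path behind ``per_variant_reml=True``)."""
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yr = U.T @ y
    X = np.column_stack([np.ones_like(y), x])
    Xr = U.T @ X

    def obj(ld):
        lam = s + np.exp(ld)
        w = 1.0 / lam
        XtWX = Xr.T @ (Xr * w[:, None])
        XtWy = Xr.T @ (w * yr)
        try:
            bet = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ bet
        q = max(np.sum(w * r * r), 1e-300)
        n = len(yr)
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return (n - 2) * np.log(q / (n - 2)) + np.sum(np.log(lam)) + logdet

    res = optimize.minimize_scalar(obj, bounds=(-10, 10), method="bounded")
    return float(np.exp(res.x)), s, U


# ---------------------------------------------------------------------------
# thresholds, annotation, overlap, inflation
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("test count must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def annotate_variants(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 1000,
) -> pd.DataFrame:
    """Assign each variant to every gene whose interval, widened by
    ``window`` bp on both sides, contains its position (1-based inclusive
    coordinates).  Unassigned variants are labelled ``intergenic``.

    Returns one row per (variant, gene) pair.
    """
    if (genes["start"] > genes["end"]).any():
        raise ValueError("malformed gene interval: start > end")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        t = IntervalTree()
        for _, row in sub.iterrows():
            # IntervalTree is half-open; +1 makes [start-w, end+w] inclusive
            t.addi(row["start"] - window, row["end"] + window + 1, row["gene_id"])
        trees[chrom] = t
    rows = []
    for i, row in records.iterrows():
        hits = trees.get(row["chrom"], IntervalTree())[row["pos"]]
        if hits:
            for h in sorted(hits, key=lambda h: str(h.data)):
                rows.append({**row.to_dict(), "gene_id": h.data})
        else:
            rows.append({**row.to_dict(), "gene_id": "intergenic"})
    return pd.DataFrame(rows)


def gene_overlap(lists: dict[str, set] | list) -> dict[str, int]:
    """Partition cardinalities for 2 or 3 gene sets.

    For two sets: ``shared``, ``unique_<name>``.  For three sets all seven
    Venn cells, keyed by the sorted membership combination.
    """
    if isinstance(lists, dict):
        names = list(lists)
        sets = [set(lists[n]) for n in names]
    else:
        names = [f"set{i+1}" for i in range(len(lists))]
        sets = [set(s) for s in lists]
    if len(sets) == 2:
        a, b = sets
        return {
            "shared": len(a & b),
            f"unique_{names[0]}": len(a - b),
            f"unique_{names[1]}": len(b - a),
        }
    if len(sets) == 3:
        a, b, c = sets
        return {
            f"only_{names[0]}": len(a - b - c),
            f"only_{names[1]}": len(b - a - c),
            f"only_{names[2]}": len(c - a - b),
            f"{names[0]}&{names[1]}": len((a & b) - c),
            f"{names[0]}&{names[2]}": len((a & c) - b),
            f"{names[1]}&{names[2]}": len((b & c) - a),
            "all_three": len(a & b & c),
        }
    raise ValueError("gene_overlap takes 2 or 3 sets")


def genomic_lambda(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square over its
    null median (0.4549)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))
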