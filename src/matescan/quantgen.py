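"""Line-level quantitative genetics of mating success.

Variance components and broad-sense heritability come from a one-way
random-effects model fit by REML on replicate-level mating proportions:

    y_ij = mu + g_i + e_ij,   g_i ~ N(0, sg2),  e_ij ~ N(0, se2)

with H2 = sg2 / (sg2 + se2).  The REML objective is profiled down to a
single variance ratio, so the fit is a bounded 1-D optimization; on
balanced designs it coincides with the closed-form ANOVA estimator.
Significance of the genetic variance uses a likelihood-ratio test against
the boundary null sg2 = 0 with the 50:50 mixture of a point mass at zero
and chi-square(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logit as _logit

from .datatypes import KARYOTYPE_LEVELS, validate_phenotypes


# ---------------------------------------------------------------------------
# line means
# ---------------------------------------------------------------------------

def replicate_proportions(pheno: pd.DataFrame, window: int | None = None) -> pd.DataFrame:
    """Per-replicate mating proportion (n_mated / n_females)."""
    validate_phenotypes(pheno)
    if window is not None:
        if window not in set(pheno["window_min"]):
            raise ValueError(f"no records for observation window {window} min")
        pheno = pheno[pheno["window_min"] == window]
    out = pheno.copy()
    out["proportion"] = out["n_mated"] / out["n_females"]
    return out


def line_means(pheno: pd.DataFrame, window: int | None = None) -> pd.DataFrame:
    """Unweighted line means of replicate proportions.

    Returns a DataFrame indexed by line with columns ``mean`` and
    ``n_replicates``.
    """
    props = replicate_proportions(pheno, window)
    g = props.groupby("line")["proportion"]
    out = pd.DataFrame({"mean": g.mean(), "n_replicates": g.size()})
    if (out["n_replicates"] == 0).any():
        raise ValueError("line with zero replicates")
    return out


# ---------------------------------------------------------------------------
# REML variance components / H2
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik_full: float
    loglik_null: float
    lrt: float
    p_value: float


def _reml_neg2ll(gamma: float, n_i: np.ndarray, ybar_i: np.ndarray, ssw: float, N: int) -> float:
    """-2 x REML log-likelihood (up to a constant), profiled over both
    variances, as a function of the ratio gamma = sg2/se2."""
    d = 1.0 + n_i * gamma
    w = n_i / d
    mu = np.sum(w * ybar_i) / np.sum(w)
    q = ssw + np.sum(w * (ybar_i - mu) ** 2)
    q = max(q, 1e-300)
    return (
        (N - 1) * np.log(q / (N - 1))
        + np.sum(np.log(d))
        + np.log(np.sum(w))
    )


def estimate_h2(
    pheno: pd.DataFrame,
    window: int | None = None,
    scale: str = "proportion",
) -> VarianceComponents:
    """REML fit of the one-way random-effects model; broad-sense H2.

    ``scale='logit'`` analyses logit-transformed proportions (clamped away
    from 0/1); the default analyses untransformed proportions.
    """
    props = replicate_proportions(pheno, window)
    y = props["proportion"].to_numpy(dtype=float)
    if scale == "logit":
        y = _logit(np.clip(y, 1e-3, 1 - 1e-3))
    elif scale != "proportion":
        raise ValueError(f"unknown scale {scale!r}")
    labels, inv = np.unique(props["line"].to_numpy(), return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("variance decomposition needs at least 2 lines")
    N = len(y)
    if N <= k:
        raise ValueError("need replicate measurements within lines")
    n_i = np.bincount(inv).astype(float)
    sums = np.bincount(inv, weights=y)
    ybar_i = sums / n_i
    ssw = float(np.sum((y - ybar_i[inv]) ** 2))

    obj = lambda g: _reml_neg2ll(g, n_i, ybar_i, ssw, N)
    # coarse log-grid then local refinement; gamma = 0 is a valid boundary
    grid = np.concatenate([[0.0], np.logspace(-6, 4, 41)])
    vals = [obj(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        hi = lo + 1e-6
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    gamma = float(res.x) if res.fun <= vals[i] else float(grid[i])
    neg2_full = min(float(res.fun), vals[i])
    neg2_null = obj(0.0)

    d = 1.0 + n_i * gamma
    w = n_i / d
    mu = np.sum(w * ybar_i) / np.sum(w)
    q = ssw + np.sum(w * (ybar_i - mu) ** 2)
    se2 = q / (N - 1)
    sg2 = gamma * se2
    h2 = sg2 / (sg2 + se2) if (sg2 + se2) > 0 else 0.0

    lrt = max(0.0, neg2_null - neg2_full)
    # boundary null: 0.5 chi2(0) + 0.5 chi2(1)
    p = 1.0 if lrt == 0.0 else 0.5 * stats.chi2.sf(lrt, df=1)
    return VarianceComponents(
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        h2=float(h2),
        loglik_full=-0.5 * neg2_full,
        loglik_null=-0.5 * neg2_null,
        lrt=float(lrt),
        p_value=float(max(p, np.nextafter(0, 1))),
    )


def anova_h2_balanced(pheno: pd.DataFrame, window: int | None = None) -> VarianceComponents:
    """Closed-form ANOVA (method-of-moments) estimator for balanced designs.

    sg2 = max(0, (MSB - MSW) / r), se2 = MSW.  Used as an independent
    cross-check of the REML fit; errors on unbalanced input.
    """
    props = replicate_proportions(pheno, window)
    y = props["proportion"].to_numpy(dtype=float)
    labels, inv = np.unique(props["line"].to_numpy(), return_inverse=True)
    n_i = np.bincount(inv)
    if len(set(n_i)) != 1:
        raise ValueError("ANOVA closed form requires a balanced design")
    r = int(n_i[0])
    k = len(labels)
    ybar_i = np.bincount(inv, weights=y) / r
    msb = r * np.sum((ybar_i - y.mean()) ** 2) / (k - 1)
    msw = np.sum((y - ybar_i[inv]) ** 2) / (k * (r - 1))
    sg2 = max(0.0, (msb - msw) / r)
    se2 = msw
    h2 = sg2 / (sg2 + se2) if sg2 + se2 > 0 else 0.0
    return VarianceComponents(sg2, se2, h2, np.nan, np.nan, np.nan, np.nan)


# ---------------------------------------------------------------------------
# trait correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    n: int
    t: float
    p_value: float


def trait_correlation(a: pd.DataFrame | pd.Series, b: pd.DataFrame | pd.Series) -> CorrelationResult:
    """Pearson correlation of line means between two traits.

    Inputs are line-mean tables (as from :func:`line_means`) or Series
    indexed by line; lines are inner-joined on id.
    """
    sa = a["mean"] if isinstance(a, pd.DataFrame) else a
    sb = b["mean"] if isinstance(b, pd.DataFrame) else b
    joined = pd.concat([sa.rename("a"), sb.rename("b")], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 shared lines, got {n}")
    x = joined["a"].to_numpy(dtype=float)
    y = joined["b"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the traits")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = np.nextafter(0, 1)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r=r, n=n, t=float(t), p_value=float(max(p, np.nextafter(0, 1))))


# ---------------------------------------------------------------------------
# inversion karyotype effects
# ---------------------------------------------------------------------------

@dataclass
class KaryotypeEffectResult:
    inversion: str
    classes: pd.DataFrame          # index: class; n, lsmean, ci_low, ci_high
    f_statistic: float
    p_value: float                 # overall F-test
    contrasts: pd.DataFrame        # index: class; estimate, t, p vs ST/ST


def karyotype_effect(
    means: pd.DataFrame | pd.Series,
    karyo: pd.DataFrame,
    inversion: str,
) -> KaryotypeEffectResult:
    """One-way fixed-effect model of line means on inversion karyotype.

    Least-squares means per class with t-based 95% confidence intervals,
    overall F-test, and pairwise contrasts of each non-standard class
    against ST/ST using the pooled residual variance.
    """
    s = means["mean"] if isinstance(means, pd.DataFrame) else means
    if inversion not in karyo.columns:
        raise ValueError(f"no karyotype column for {inversion!r}")
    df = pd.concat([s.rename("y"), karyo[inversion].rename("class")], axis=1, join="inner").dropna()
    present = [c for c in KARYOTYPE_LEVELS if c in set(df["class"])]
    extra = set(df["class"]) - set(KARYOTYPE_LEVELS)
    if extra:
        raise ValueError(f"unknown karyotype labels {sorted(extra)}")
    if len(present) < 2:
        raise ValueError("karyotype effect needs at least 2 classes present")

    y = df["y"].to_numpy(dtype=float)
    groups = [df.loc[df["class"] == c, "y"].to_numpy(dtype=float) for c in present]
    n = np.array([len(g) for g in groups])
    gm = np.array([g.mean() for g in groups])
    N = len(y)
    k = len(present)
    df_resid = N - k
    sse = sum(((g - m) ** 2).sum() for g, m in zip(groups, gm))
    ssb = float(np.sum(n * (gm - y.mean()) ** 2))
    if df_resid <= 0 or sse <= 0:
        mse = 0.0
        fstat = np.inf if ssb > 0 else 0.0
        p = np.nextafter(0, 1) if ssb > 0 else 1.0
    else:
        mse = sse / df_resid
        fstat = (ssb / (k - 1)) / mse
        p = float(stats.f.sf(fstat, k - 1, df_resid))
    tcrit = stats.t.ppf(0.975, df_resid) if df_resid > 0 else np.nan
    half = tcrit * np.sqrt(mse / n) if df_resid > 0 else np.full(k, np.nan)
    classes = pd.DataFrame(
        {"n": n, "lsmean": gm, "ci_low": gm - half, "ci_high": gm + half},
        index=pd.Index(present, name="class"),
    )

    rows = []
    if "ST/ST" in present:
        ref = classes.loc["ST/ST"]
        for c in present:
            if c == "ST/ST":
                continue
            est = classes.loc[c, "lsmean"] - ref["lsmean"]
            if mse > 0:
                se_c = np.sqrt(mse * (1.0 / classes.loc[c, "n"] + 1.0 / ref["n"]))
                t = est / se_c
                pc = 2.0 * stats.t.sf(abs(t), df_resid)
            else:
                t = np.inf * np.sign(est) if est != 0 else 0.0
                pc = np.nextafter(0, 1) if est != 0 else 1.0
            rows.append({"class": c, "estimate": est, "t": t, "p_value": pc})
    contrasts = pd.DataFrame(rows).set_index("class") if rows else pd.DataFrame(
        columns=["estimate", "t", "p_value"]
    )
    return KaryotypeEffectResult(
        inversion=inversion,
        classes=classes,
        f_statistic=float(fstat),
        p_value=float(max(p, np.nextafter(0, 1))),
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# Fisher exact mating contrasts
# ---------------------------------------------------------------------------

def fisher_mating_test(
    mated_a: int, unmated_a: int, mated_b: int, unmated_b: int
) -> float:
    """Two-sided Fisher exact test on a 2x2 mated/unmated table."""
    table = np.array([[mated_a, unmated_a], [mated_b, unmated_b]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum(axis=1).min() == 0 and table.sum() == 0:
        raise ValueError("empty table")
    if (table.sum(axis=0) == 0).all() or (table.sum(axis=1) == 0).all():
        raise ValueError("all-zero margin")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)
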