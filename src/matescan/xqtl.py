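"""Pooled-sequencing allele-frequency divergence (extreme-QTL) tests.

For each variant, the allele frequency of a pool of n flies sequenced to
coverage c estimates the group frequency with sampling variance

    v = p (1 - p) (1/(2n) + 1/c)

— the 1/(2n) term from drawing 2n chromosomes out of the source
population, the 1/c term from drawing c reads off the pool.  The
divergence statistic between a selected ("high") and a control group,
each with replicate pools, is

    Z = (pbar2 - pbar1) / sqrt(sum_r w2r v2r + sum_r w1r v1r)

with pbar the across-replicate mean frequency and within-group weights
w_r proportional to sequencing depth.  Two modes are provided:
``literal`` uses unweighted replicate means with single-power depth
weights in the denominator (the printed form); ``delta`` uses
depth-weighted means with the matching delta-method variance
(sum w_r^2 v_r).  The two coincide when depths within a group are equal.
Two-sided p-values come from the standard normal.

The multi-generation selection comparison has unpaired selected and
control pools: every selected x control pair is tested separately and a
variant passes only if its weakest pair (largest p) still clears the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PoolCounts

#: |Z| clamp applied when the variance term degenerates to zero at a
#: fixed/monomorphic site with a non-zero frequency difference.
DEFAULT_ZMAX = 37.0


@dataclass
class ZScanResult:
    """Per-variant scan table plus bookkeeping of skipped variants."""

    table: pd.DataFrame
    skipped: pd.DataFrame  # variant index + reason


def _group_stats(pools: list[PoolCounts], mode: str):
    """Stack replicate frequencies/variances; returns (pbar, var_term,
    usable) arrays over variants.  Replicates with zero coverage at a
    variant are dropped from that variant's mean and (renormalized)
    weights."""
    freqs = np.stack([p.frequencies() for p in pools])          # (R, L)
    cov = np.stack([p.coverage.astype(float) for p in pools])   # (R, L)
    nfly = np.array([p.n_flies for p in pools], dtype=float)[:, None]
    used = cov > 0
    v = freqs * (1.0 - freqs) * (1.0 / (2.0 * nfly) + 1.0 / np.where(used, cov, np.nan))
    wsum = np.where(used, cov, 0.0).sum(axis=0)
    usable = wsum > 0
    w = np.where(used, cov, 0.0) / np.where(usable, wsum, np.nan)
    if mode == "literal":
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            pbar = np.nanmean(np.where(used, freqs, np.nan), axis=0)
        var_term = np.nansum(np.where(used, w * v, 0.0), axis=0)
    elif mode == "delta":
        pbar = np.nansum(np.where(used, w * freqs, 0.0), axis=0)
        pbar = np.where(usable, pbar, np.nan)
        var_term = np.nansum(np.where(used, w * w * v, 0.0), axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    var_term = np.where(usable, var_term, np.nan)
    return pbar, var_term, usable


def z_scores(
    high: list[PoolCounts],
    control: list[PoolCounts],
    mode: str = "literal",
    zmax: float = DEFAULT_ZMAX,
) -> ZScanResult:
    """Z statistic and two-sided normal p-value for every variant.

    ``high`` plays group 2 and ``control`` group 1, so positive Z means
    the alt allele is more frequent in the selected group.
    """
    if not high or not control:
        raise ValueError("each group needs at least one pool")
    L = len(high[0].ref_count)
    for p in high + control:
        if len(p.ref_count) != L:
            raise ValueError("pools cover different variant sets")
    p1, v1, ok1 = _group_stats(control, mode)
    p2, v2, ok2 = _group_stats(high, mode)
    usable = ok1 & ok2
    denom = np.sqrt(v1 + v2)
    diff = p2 - p1
    with np.errstate(invalid="ignore", divide="ignore"):
        z = diff / denom
    # zero-variance sites: identical frequencies -> Z = 0; otherwise clamp
    degenerate = usable & (denom == 0)
    z = np.where(degenerate & (diff == 0), 0.0, z)
    z = np.where(degenerate & (diff != 0), np.sign(diff) * zmax, z)
    z = np.clip(z, -zmax, zmax)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    variants = high[0].variants.reset_index(drop=True)
    table = variants.copy()
    table["p1_bar"] = p1
    table["p2_bar"] = p2
    table["Z"] = z
    table["p"] = pval
    table.loc[~usable, ["Z", "p"]] = np.nan
    skipped = pd.DataFrame(
        {
            "variant_index": np.flatnonzero(~usable),
            "reason": "zero coverage in all replicates of a group",
        }
    )
    return ZScanResult(table=table, skipped=skipped)


def z_statistic(
    high: list[PoolCounts],
    control: list[PoolCounts],
    variant: int,
    mode: str = "literal",
) -> pd.Series:
    """Single-variant convenience wrapper around :func:`z_scores`."""
    res = z_scores(high, control, mode=mode)
    return res.table.iloc[variant]


def xqtl_scan(
    high: list[PoolCounts],
    control: list[PoolCounts],
    report_threshold: float = 1e-5,
    mode: str = "literal",
) -> pd.DataFrame:
    """Genome scan over replicated high vs control pools.

    Adds a ``significant`` flag for variants with p below
    ``report_threshold``; variants unusable in either group are dropped.
    """
    res = z_scores(high, control, mode=mode)
    table = res.table.dropna(subset=["Z"]).reset_index(drop=True)
    table["significant"] = table["p"] < report_threshold
    return table


def allpairs_divergence(
    selected: list[PoolCounts],
    control: list[PoolCounts],
    threshold: float = 1e-5,
    mode: str = "literal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unpaired all-pairs divergence with the minimal-difference rule.

    Every selected x control pool pair is tested as a single-replicate
    comparison; a variant passes only if the largest p-value over all
    pairs is below ``threshold``.  Returns ``(summary, pair_stats)``:
    ``summary`` has the worst-pair p and Z and a ``pass`` flag per
    variant, ``pair_stats`` the full per-pair statistics.
    """
    if not selected or not control:
        raise ValueError("each group needs at least one pool")
    pair_frames = []
    for s, c in product(selected, control):
        res = z_scores([s], [c], mode=mode)
        t = res.table.copy()
        t["selected_pool"] = s.pool_id
        t["control_pool"] = c.pool_id
        pair_frames.append(t)
    pairs = pd.concat(pair_frames, ignore_index=True)
    variants = selected[0].variants.reset_index(drop=True)
    pairs["_vidx"] = np.tile(np.arange(len(variants)), len(pair_frames))
    # a pair with no usable coverage yields NaN and blocks the variant
    worst = pairs.groupby("_vidx").agg(
        worst_p=("p", lambda p: p.max(skipna=False)),
        min_abs_Z=("Z", lambda z: np.nanmin(np.abs(z))),
        n_pairs=("p", "size"),
        n_pairs_passing=("p", lambda p: int((p < threshold).sum())),
    )
    summary = variants.copy()
    summary[["worst_p", "min_abs_Z", "n_pairs", "n_pairs_passing"]] = worst[
        ["worst_p", "min_abs_Z", "n_pairs", "n_pairs_passing"]
    ].to_numpy()
    summary["pass"] = summary["worst_p"] < threshold
    return summary, pairs.drop(columns="_vidx")
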