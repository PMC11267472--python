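"""Study-condition benchmark simulations.

Each function reproduces one of the package's headline checks at the
design sizes of the underlying study — 205 inbred lines with 10 assay
replicates, a 40-founder advanced intercross at census 800, 4 replicate
pools of 50 flies, truncation selection of the first 40 of 300 assayed
males over 18 generations — scaled in the number of variants so a full
run completes in minutes on one core.  All are deterministic given the
seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gwa, quantgen, selection_response, synthetic_data as sd, xqtl
from .config import stage_seed
from .datatypes import GenotypeMatrix, TraitModel


def h2_recovery(
    h2_values: tuple[float, ...] = (0.1, 0.27, 0.5, 0.9),
    n_sims: int = 100,
    n_lines: int = 205,
    replicates: int = 10,
    seed: int = 0,
) -> dict[float, float]:
    """Mean REML H2 estimate per generating value over ``n_sims``
    phenotype simulations at the panel's size."""
    out = {}
    for h2 in h2_values:
        ests = []
        for s in range(n_sims):
            ph = sd.simulate_line_phenotypes(
                n_lines, replicates, h2_target=h2,
                seed=stage_seed(seed, f"h2_{h2}_{s}"),
            )
            ests.append(quantgen.estimate_h2(ph).h2)
        out[h2] = float(np.mean(ests))
    return out


def response_slope_recovery(
    true_slope: float = 0.0088,
    noise_sd: float = 0.05,
    n_generations: int = 19,
    n_sims: int = 200,
    seed: int = 0,
) -> float:
    """Mean OLS slope estimate for noisy linear deviation series."""
    rng = np.random.default_rng(stage_seed(seed, "slope_recovery"))
    slopes = []
    gens = np.arange(n_generations)
    for _ in range(n_sims):
        dev = true_slope * gens + rng.normal(0, noise_sd, n_generations)
        sel = pd.DataFrame({"generation": gens, "population_id": "S1",
                            "proportion": dev})
        ctl = pd.DataFrame({"generation": gens, "population_id": "C1",
                            "proportion": 0.0})
        traj = selection_response.deviation_trajectory(sel, ctl)
        reg = selection_response.response_regression(traj)
        slopes.append(float(reg.loc[reg["series"] == "S1", "b"].iloc[0]))
    return float(np.mean(slopes))


def pool_frequency_bias(
    freq: float = 0.3,
    depth: int = 100,
    n_sites: int = 10_000,
    seed: int = 0,
) -> float:
    """Mean pooled-frequency estimate at a known true pool frequency."""
    rng = np.random.default_rng(stage_seed(seed, "pool_bias"))
    alt = rng.binomial(depth, freq, size=n_sites)
    return float((alt / depth).mean())


def xqtl_null_calibration(
    seed: int = 0,
    n_variants: int = 2500,
    aip_generations: int = 20,
    coverage: int = 60,
    pool_size: int = 50,
    n_replicates: int = 4,
) -> dict[str, float]:
    """Empirical type-I error of the pooled Z test under a no-selection
    null: disjoint pools of males drawn from one advanced intercross.

    Returns fractions of variants with p below 0.05 and 0.01 for the
    delta-method mode, plus the same for the printed (literal) form,
    which is conservative for replicated groups.
    """
    panel = sd.simulate_founders(40, n_variants, seed=stage_seed(seed, "null_panel"))
    aip = sd.build_aip(panel, aip_generations, seed=stage_seed(seed, "null_aip"))
    rng = np.random.default_rng(stage_seed(seed, "null_pools"))
    males = rng.permutation(np.flatnonzero(aip.is_male))
    high, control = [], []
    for r in range(n_replicates):
        lo = 2 * r * pool_size
        high.append(sd.simulate_pool_seq(
            aip, coverage, seed=stage_seed(seed, f"null_h{r}"),
            pool_id=f"h{r}", group="high", replicate=r + 1,
            member_idx=males[lo:lo + pool_size],
        ))
        control.append(sd.simulate_pool_seq(
            aip, coverage, seed=stage_seed(seed, f"null_c{r}"),
            pool_id=f"c{r}", group="control", replicate=r + 1,
            member_idx=males[lo + pool_size:lo + 2 * pool_size],
        ))
    out = {}
    for mode in ("delta", "literal"):
        p = xqtl.z_scores(high, control, mode=mode).table["p"].to_numpy()
        p = p[np.isfinite(p)]
        out[f"{mode}_frac_p05"] = float((p < 0.05).mean())
        out[f"{mode}_frac_p01"] = float((p < 0.01).mean())
    out["n_variants"] = int(len(p))
    return out


def lmm_permutation_type1(
    seed: int = 0,
    n_sims: int = 200,
    n_lines: int = 205,
    n_variants: int = 500,
    alpha: float = 0.05,
) -> float:
    """Fraction of mixed-model association p-values below ``alpha`` when
    the phenotype is permuted (independent of genotype)."""
    rng = np.random.default_rng(stage_seed(seed, "lmm_null"))
    freqs = rng.uniform(0.1, 0.5, n_variants)
    dosage = np.where(rng.random((n_lines, n_variants)) < freqs, 2.0, 0.0)
    variants = pd.DataFrame({"chrom": "2L", "pos": np.arange(1, n_variants + 1),
                             "ref": "A", "alt": "T"})
    g = GenotypeMatrix([f"L{i}" for i in range(n_lines)], variants, dosage)
    K = gwa.compute_grm(g)
    y0 = rng.normal(size=n_lines)
    hits = 0
    total = 0
    for _ in range(n_sims):
        y = rng.permutation(y0)
        assoc = gwa.lmm_association(y, g, K)
        p = assoc["p"].to_numpy()
        hits += int((p < alpha).sum())
        total += len(p)
    return hits / total


def xqtl_power_run(seed: int) -> int:
    """One extreme-QTL power replicate at the study design: 500 males
    assayed, 50 fastest vs 50 random, 4 biological replicates, pools of
    50.  The trait has 5 equal-magnitude causal variants segregating at
    intermediate frequency that jointly explain 90% of liability
    variance.  Returns how many of the 5 causal variants rank in the top
    20 of the scan.
    """
    rng = np.random.default_rng(seed)
    panel = sd.simulate_founders(40, 1000, seed=int(rng.integers(2**31)))
    aip = sd.build_aip(panel, 8, seed=int(rng.integers(2**31)))
    model = TraitModel.from_h2(
        aip, 5, 0.9, rng, causal_freq_range=(0.3, 0.7),
        effect_dist="equal", hazard_slope=2.0,
    )
    high, ctl = [], []
    for r in range(4):
        cohort = sd.random_mating_offspring(aip, 1100, seed=int(rng.integers(2**31)))
        males = np.flatnonzero(cohort.is_male)
        chosen = rng.choice(males, size=500, replace=False)
        model.assign_liabilities(cohort, rng)
        assay = sd.simulate_mating_assay(
            cohort, model, male_idx=chosen, window=60, seed=int(rng.integers(2**31))
        )
        fast = sd.truncation_select(assay, "k-fastest", 50, seed=int(rng.integers(2**31)))
        rand = sd.truncation_select(assay, "k-random", 50, seed=int(rng.integers(2**31)))
        for grp, ids, pools in (("high", fast, high), ("control", rand, ctl)):
            pools.append(sd.simulate_pool_seq(
                cohort, 200, seed=int(rng.integers(2**31)),
                pool_id=f"{grp}{r}", group=grp, replicate=r + 1, member_idx=ids,
            ))
    scan = xqtl.xqtl_scan(high, ctl, mode="delta")
    cv = panel.genotypes.variants.loc[model.causal_idx]
    top = scan.nsmallest(20, "p")
    return int(sum(
        ((top["chrom"] == c) & (top["pos"] == p)).any()
        for c, p in zip(cv["chrom"], cv["pos"])
    ))


def xqtl_power_benchmark(n_runs: int = 25, seed: int = 0) -> list[int]:
    return [xqtl_power_run(stage_seed(seed, f"xqtl_power_{i}")) for i in range(n_runs)]


def selection_response_run(seed: int, generations: int = 18) -> dict[str, float]:
    """One multi-generation selection replicate: first 40 of 300 assayed
    males bred each generation, liability heritability 0.27, two selected
    replicates against the 1-then-2 control design.  Returns the
    replicate-average regression slope and the final-generation
    selected/control proportions.
    """
    rng = np.random.default_rng(seed)
    panel = sd.simulate_founders(40, 400, seed=int(rng.integers(2**31)))
    aip = sd.build_aip(panel, 6, seed=int(rng.integers(2**31)))
    model = TraitModel.from_h2(aip, 20, 0.27, rng)
    traj_df, _ = sd.simulate_selection_experiment(
        panel, model, aip, generations=generations, seed=int(rng.integers(2**31))
    )
    sel = traj_df[traj_df["role"] == "selected"]
    ctl = traj_df[traj_df["role"] == "control"]
    traj = selection_response.deviation_trajectory(sel, ctl)
    reg = selection_response.response_regression(traj)
    final = traj_df[traj_df["generation"] == generations]
    return {
        "avg_slope": float(reg.loc[reg["series"] == "average", "b"].iloc[0]),
        "final_selected": float(final[final["role"] == "selected"]["proportion"].mean()),
        "final_control": float(final[final["role"] == "control"]["proportion"].mean()),
    }


def selection_response_benchmark(n_runs: int = 25, seed: int = 0,
                                 generations: int = 18) -> list[dict[str, float]]:
    return [
        selection_response_run(stage_seed(seed, f"selection_{i}"), generations)
        for i in range(n_runs)
    ]
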