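"""Forward simulation of the breeding, assay and sequencing designs.

This module generates every input the analysis modules consume, with the
statistical structure those analyses assume:

* an inbred founder panel (dosages in {0, 2}, inversion karyotypes,
  Wolbachia infection status);
* an advanced intercross population (AIP) built by two round-robin cross
  generations followed by bottle maintenance at census 800;
* no-choice mating assays (vials of 5 females x 10 males, per-minute
  liability-mapped mating hazards, copulating pairs removed);
* truncation selection (first-k-to-mate, k-fastest, k-random);
* pooled sequencing (binomial read sampling at a given depth);
* replicate-level line phenotypes under a one-way random-effects model.

Recombination is female-only (Drosophila males are achiasmatic) and is
suppressed inside inversion blocks when the mother is heterokaryotypic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    KARYOTYPE_LEVELS,
    FounderPanel,
    GenotypeMatrix,
    InversionBlock,
    MatingTrialTable,
    PoolCounts,
    Population,
    TraitModel,
)

DEFAULT_CHROMS = ("2L", "2R", "3L", "3R")
#: bp length per simulated chromosome arm (roughly a Drosophila arm).
DEFAULT_CHROM_LEN = 23_000_000
#: Recombination rate, Morgans per bp (~2 cM/Mb genome average in females).
DEFAULT_RECOMB_RATE = 2e-8


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------

def simulate_founders(
    n_lines: int,
    n_variants: int,
    maf_law: tuple = ("uniform", 0.05, 0.5),
    inversion_spec: dict[str, InversionBlock] | None = None,
    wolbachia_rate: float = 0.5,
    seed: int | None = None,
    chroms: tuple[str, ...] = DEFAULT_CHROMS,
    chrom_len: int = DEFAULT_CHROM_LEN,
    inv_shift: float = 0.5,
) -> FounderPanel:
    """Simulate a panel of fully inbred, sequenced founder lines.

    Each line is homozygous everywhere: at a variant with alt frequency
    ``p`` the line is alt/alt (dosage 2) with probability ``p`` and ref/ref
    otherwise.  Variants inside an inversion block are differentiated
    between arrangements: alt probability is shifted by ``inv_shift`` on
    inverted haplotypes, producing the island-of-divergence LD structure
    between block variants and karyotype class.

    Parameters
    ----------
    maf_law
        ``("uniform", lo, hi)`` or ``("fixed", p)`` — distribution of the
        generating alt-allele frequency, bounded in (0, 0.5].
    inversion_spec
        Mapping of inversion name to :class:`InversionBlock`.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 founder lines")
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    if not 0.0 <= wolbachia_rate <= 1.0:
        raise ValueError("wolbachia_rate must be a probability")
    rng = np.random.default_rng(seed)

    kind = maf_law[0]
    if kind == "uniform":
        lo, hi = float(maf_law[1]), float(maf_law[2])
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("uniform maf_law must be bounded in (0, 0.5]")
        freqs = rng.uniform(lo, hi, size=n_variants)
    elif kind == "fixed":
        p = float(maf_law[1])
        if not 0.0 <= p <= 1.0:
            raise ValueError("frequency outside [0,1]")
        freqs = np.full(n_variants, p)
    else:
        raise ValueError(f"unknown maf_law kind {kind!r}")

    # evenly many variants per arm, uniform sorted positions
    chrom_of = np.repeat(np.arange(len(chroms)), -(-n_variants // len(chroms)))[:n_variants]
    pos = np.empty(n_variants, dtype=np.int64)
    for c in range(len(chroms)):
        m = chrom_of == c
        pos[m] = np.sort(rng.choice(np.arange(1, chrom_len + 1), size=m.sum(), replace=False))
    variants = pd.DataFrame(
        {
            "chrom": np.asarray(chroms)[chrom_of],
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "af": freqs,
        }
    )

    inversion_spec = dict(inversion_spec or {})
    # per-line inverted-arrangement indicators: two latent haplotypes per line
    inv_hapcount = {}   # name -> (n_lines,) in {0,1,2}
    inv_contrib = {}    # name -> (n_lines,) in {0,1}: arrangement of the contributed haplotype
    for name, block in inversion_spec.items():
        f = block.inv_frequency
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"inversion frequency outside [0,1] for {name}")
        latent = rng.random((n_lines, 2)) < f
        inv_hapcount[name] = latent.sum(axis=1)
        # an inbred line transmits one haplotype; residually heterokaryotypic
        # lines transmit one of the two arrangements, fixed at panel creation
        inv_contrib[name] = np.where(
            inv_hapcount[name] == 1, rng.integers(0, 2, size=n_lines), inv_hapcount[name] // 2
        )

    # alt probability per line x variant, shifted inside inversion blocks
    p_line = np.broadcast_to(freqs, (n_lines, n_variants)).copy()
    for name, block in inversion_spec.items():
        in_block = (
            (variants["chrom"] == block.chrom)
            & (variants["pos"] >= block.start)
            & (variants["pos"] <= block.end)
        ).to_numpy()
        if not in_block.any():
            continue
        p_inv = np.clip(freqs[in_block] + inv_shift, 0.0, 1.0)
        h = inv_hapcount[name][:, None].astype(float)  # 0,1,2 inverted haplotypes
        p_line[:, in_block] = ((2.0 - h) * freqs[in_block] + h * p_inv) / 2.0

    dosage = np.where(rng.random((n_lines, n_variants)) < p_line, 2.0, 0.0)

    line_ids = [f"L{i:03d}" for i in range(1, n_lines + 1)]
    karyo = pd.DataFrame(index=pd.Index(line_ids, name="line"))
    inv_hap_df = pd.DataFrame(index=pd.Index(line_ids, name="line"))
    for name in inversion_spec:
        karyo[name] = np.asarray(KARYOTYPE_LEVELS)[inv_hapcount[name]]
        inv_hap_df[name] = inv_contrib[name].astype(np.int8)
    wolb = pd.Series(
        rng.random(n_lines) < wolbachia_rate, index=pd.Index(line_ids, name="line"), name="wolbachia"
    )

    genotypes = GenotypeMatrix(line_ids=line_ids, variants=variants, dosage=dosage)
    return FounderPanel(
        genotypes=genotypes,
        karyotypes=karyo,
        wolbachia=wolb,
        inversion_blocks=inversion_spec,
        inv_haplotype=inv_hap_df,
    )


# ---------------------------------------------------------------------------
# meiosis and breeding
# ---------------------------------------------------------------------------

@dataclass
class BreedingScheme:
    """Bottle-maintenance configuration for the advanced intercross.

    With the defaults, each generation consists of ``n_bottles`` bottles
    each founded by ``females_per_source + males_per_source`` flies from
    every bottle of the previous generation: 10 x (4 + 4) x 10 = 800.
    """

    n_bottles: int = 10
    females_per_source: int = 4
    males_per_source: int = 4

    @property
    def census(self) -> int:
        per_bottle = (self.females_per_source + self.males_per_source) * self.n_bottles
        return self.n_bottles * per_bottle


def _chrom_bounds(variants: pd.DataFrame) -> list[tuple[int, int]]:
    """[start, end) variant-index ranges per chromosome, in table order."""
    bounds = []
    chroms = variants["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            bounds.append((start, i))
            start = i
    return bounds


def _meiose(
    panel: FounderPanel,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    recomb_rate: float,
    rng: np.random.Generator,
    recombine: bool = True,
) -> np.ndarray:
    """Produce one gamete per row of (hap_a, hap_b) founder-origin pairs.

    Crossover counts per chromosome are Poisson at ``recomb_rate`` Morgans
    per bp; crossovers landing inside an inversion block of a
    heterokaryotypic parent are discarded (recombination suppression).
    With ``recombine=False`` (male meiosis) each gamete is an intact
    parental haplotype per chromosome.
    """
    n, L = hap_a.shape
    variants = panel.genotypes.variants
    pos = variants["pos"].to_numpy()
    bounds = _chrom_bounds(variants)
    # crossover parity per variant: start from per-chromosome random phase
    flips = np.zeros((n, L), dtype=np.int64)
    for (s, e) in bounds:
        flips[:, s] += rng.integers(0, 2, size=n)
        if not recombine:
            continue
        span_bp = pos[e - 1] - pos[s] + 1
        lam = recomb_rate * span_bp
        k = rng.poisson(lam, size=n)
        total = int(k.sum())
        if total == 0:
            continue
        which = np.repeat(np.arange(n), k)
        xpos = rng.integers(pos[s], pos[e - 1] + 1, size=total)
        # suppression: drop crossovers inside blocks where parent is heterokaryotypic
        keep = np.ones(total, dtype=bool)
        for name, block in panel.inversion_blocks.items():
            if block.chrom != variants["chrom"].iloc[s]:
                continue
            inv_state = panel.inv_haplotype[name].to_numpy()
            # arrangement carried at the block is the founder origin's arrangement
            bstart = np.searchsorted(pos[s:e], block.start) + s
            if bstart >= e:
                continue
            het = inv_state[hap_a[:, bstart]] != inv_state[hap_b[:, bstart]]
            inside = (xpos >= block.start) & (xpos <= block.end) & het[which]
            keep &= ~inside
        which, xpos = which[keep], xpos[keep]
        vidx = s + np.searchsorted(pos[s:e], xpos, side="left")
        vidx = np.minimum(vidx, e - 1)
        np.add.at(flips, (which, vidx), 1)
    use_b = (np.cumsum(flips, axis=1) % 2).astype(bool)
    return np.where(use_b, hap_b, hap_a)


def _offspring(
    panel: FounderPanel,
    mothers: Population,
    mother_idx: np.ndarray,
    fathers: Population,
    father_idx: np.ndarray,
    generation: int,
    recomb_rate: float,
    rng: np.random.Generator,
    male_recombination: bool = False,
) -> Population:
    """Breed one offspring per (mother, father) pair."""
    egg = _meiose(
        panel,
        mothers.founder_origin[mother_idx, 0],
        mothers.founder_origin[mother_idx, 1],
        recomb_rate,
        rng,
        recombine=True,
    )
    sperm = _meiose(
        panel,
        fathers.founder_origin[father_idx, 0],
        fathers.founder_origin[father_idx, 1],
        recomb_rate,
        rng,
        recombine=male_recombination,
    )
    origin = np.stack([egg, sperm], axis=1)
    is_male = rng.random(len(mother_idx)) < 0.5
    return Population(panel=panel, founder_origin=origin, is_male=is_male, generation=generation)


def build_aip(
    panel: FounderPanel,
    generations: int,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
    scheme: BreedingScheme | None = None,
    seed: int | None = None,
) -> Population:
    """Build the advanced intercross population.

    Generation 1 is a round-robin of the founders (line i females x line
    i+1 males, wrapping), giving exactly ``n_lines`` F1 genotypes.
    Generation 2 is a round-robin of consecutive F1 pairs.  Generation 3
    seeds the bottles with one female and one male from each generation-2
    cross per bottle; from generation 4 each bottle receives
    ``females_per_source + males_per_source`` flies from every bottle of
    the previous generation (census 800 with the default scheme).
    """
    scheme = scheme or BreedingScheme()
    if panel.n_lines < 3:
        raise ValueError("round-robin breeding needs at least 3 founder lines")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    n = panel.n_lines
    L = panel.genotypes.n_variants

    # generation 1: F1 genotype i = (line i, line i+1 mod n); founders are
    # inbred so each parent transmits its single haplotype unchanged
    f1_origin = np.empty((n, 2, L), dtype=np.int16)
    for i in range(n):
        f1_origin[i, 0] = i
        f1_origin[i, 1] = (i + 1) % n
    pop = Population(
        panel=panel,
        founder_origin=f1_origin,
        is_male=np.zeros(n, dtype=bool),  # F1 genotypes, sex assigned at use
        generation=1,
    )
    if generations == 1:
        return pop

    # generation 2: round-robin of F1 pairs — cross i uses F1 genotype i
    # females x F1 genotype (i+2 mod n) males (pairs of consecutive F1s)
    mother_idx = np.arange(n)
    father_idx = (np.arange(n) + 2) % n
    pop2_crosses = np.arange(n)
    pop = _offspring(panel, pop, mother_idx, pop, father_idx, 2, recomb_rate, rng)
    if generations == 2:
        return pop

    for gen in range(3, generations + 1):
        if gen == 3:
            # one female and one male from each gen-2 cross per bottle
            reps = scheme.n_bottles
            midx = np.tile(pop2_crosses, reps * 2)
            # mate within bottle: random pairing among the 40 crosses
            fidx = np.concatenate(
                [rng.permutation(pop2_crosses) for _ in range(reps * 2)]
            )
            child = _offspring(panel, pop, midx, pop, fidx, 3, recomb_rate, rng)
            per_bottle = 2 * len(pop2_crosses)
            child.bottle = np.repeat(np.arange(reps), per_bottle)
            # force balanced sex within bottles for downstream sampling
            child.is_male = np.tile(
                np.r_[np.zeros(per_bottle // 2, bool), np.ones(per_bottle - per_bottle // 2, bool)],
                reps,
            )
            pop = child
        else:
            pop = _maintain(panel, pop, scheme, gen, recomb_rate, rng)
    return pop


def _maintain(
    panel: FounderPanel,
    pop: Population,
    scheme: BreedingScheme,
    generation: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> Population:
    """One bottle-maintenance generation of the AIP."""
    per_bottle = (scheme.females_per_source + scheme.males_per_source) * scheme.n_bottles
    all_midx, all_fidx, bottles = [], [], []
    for b in range(scheme.n_bottles):
        fem_parents, male_parents = [], []
        for src in range(scheme.n_bottles):
            in_src = np.flatnonzero(pop.bottle == src)
            fem = in_src[~pop.is_male[in_src]]
            mal = in_src[pop.is_male[in_src]]
            fem_parents.append(rng.choice(fem, size=scheme.females_per_source, replace=False))
            male_parents.append(rng.choice(mal, size=scheme.males_per_source, replace=False))
        fem_parents = np.concatenate(fem_parents)
        male_parents = np.concatenate(male_parents)
        all_midx.append(rng.choice(fem_parents, size=per_bottle, replace=True))
        all_fidx.append(rng.choice(male_parents, size=per_bottle, replace=True))
        bottles.append(np.full(per_bottle, b))
    child = _offspring(
        panel,
        pop,
        np.concatenate(all_midx),
        pop,
        np.concatenate(all_fidx),
        generation,
        recomb_rate,
        rng,
    )
    child.bottle = np.concatenate(bottles)
    half = per_bottle // 2
    child.is_male = np.tile(
        np.r_[np.zeros(half, bool), np.ones(per_bottle - half, bool)], scheme.n_bottles
    )
    return child


def random_mating_offspring(
    pop: Population,
    n: int,
    seed: int | None = None,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
) -> Population:
    """Breed ``n`` offspring by random mating within ``pop``.

    Used to raise assay cohorts (e.g. the 500-male batches of the
    single-generation extreme-QTL design) from a maintained population
    without advancing its own census bookkeeping.
    """
    rng = np.random.default_rng(seed)
    fem = np.flatnonzero(~pop.is_male)
    mal = np.flatnonzero(pop.is_male)
    if len(fem) == 0 or len(mal) == 0:
        raise ValueError("population must contain both sexes")
    midx = rng.choice(fem, size=n, replace=True)
    fidx = rng.choice(mal, size=n, replace=True)
    child = _offspring(pop.panel, pop, midx, pop, fidx, pop.generation + 1, recomb_rate, rng)
    half = n // 2
    child.is_male = np.r_[np.zeros(half, bool), np.ones(n - half, bool)][rng.permutation(n)]
    return child


# ---------------------------------------------------------------------------
# mating assay
# ---------------------------------------------------------------------------

def simulate_mating_assay(
    males: Population,
    model: TraitModel,
    male_idx: np.ndarray | None = None,
    n_females: int = 5,
    n_males_per_vial: int = 10,
    window: int = 60,
    seed: int | None = None,
    liabilities: np.ndarray | None = None,
) -> MatingTrialTable:
    """No-choice mating assay in vials of ``n_females`` x ``n_males_per_vial``.

    Each minute, every not-yet-mated male in a vial attempts to copulate
    with probability given by the logistic hazard of his liability; as many
    attempts succeed as there are unmated females, the successful males
    drawn uniformly among that minute's attempters.  Copulating pairs are
    removed (a female never mates twice), latency is the minute index.
    """
    if window <= 0:
        raise ValueError("observation window must be positive")
    rng = np.random.default_rng(seed)
    if male_idx is None:
        male_idx = np.flatnonzero(males.is_male)
        if male_idx.size == 0:
            male_idx = np.arange(males.n_individuals)
    male_idx = np.asarray(male_idx)
    if liabilities is None:
        if males.liabilities is None:
            model.assign_liabilities(males, rng)
        liabilities = males.liabilities
    liab = liabilities[male_idx]
    hazards = model.minute_hazards(liab)

    n = len(male_idx)
    n_vials = -(-n // n_males_per_vial)
    vial_of = np.repeat(np.arange(n_vials), n_males_per_vial)[:n]
    females_left = np.full(n_vials, n_females)
    unmated = np.ones(n, dtype=bool)
    rec_vial, rec_male, rec_latency, rec_tie = [], [], [], []
    for minute in range(1, window + 1):
        if not females_left.any():
            break
        attempt = unmated & (rng.random(n) < hazards)
        if not attempt.any():
            continue
        order = rng.permutation(np.flatnonzero(attempt))
        for j in order:
            v = vial_of[j]
            if females_left[v] > 0:
                females_left[v] -= 1
                unmated[j] = False
                rec_vial.append(v)
                rec_male.append(male_idx[j])
                rec_latency.append(minute)
                rec_tie.append(rng.random())
    matings = pd.DataFrame(
        {
            "vial": np.array(rec_vial, dtype=int),
            "male_id": np.array(rec_male, dtype=int),
            "latency_min": np.array(rec_latency, dtype=float),
            "tiebreak": np.array(rec_tie, dtype=float),
        }
    )
    n_mated = np.zeros(n_vials, dtype=int)
    if len(matings):
        counts = matings.groupby("vial").size()
        n_mated[counts.index.to_numpy()] = counts.to_numpy()
    vial_sizes = np.bincount(vial_of, minlength=n_vials)
    vials = pd.DataFrame(
        {
            "vial": np.arange(n_vials),
            "n_females": n_females,
            "n_males": vial_sizes,
            "window_min": window,
            "n_mated": n_mated,
        }
    )
    return MatingTrialTable(vials=vials, matings=matings, assayed_male_ids=male_idx)


def truncation_select(
    assay: MatingTrialTable,
    rule: str,
    k: int,
    seed: int | None = None,
) -> np.ndarray:
    """Select male ids from an assay.

    ``first-k`` and ``k-fastest`` both rank maters by copulation latency
    (same-minute ties broken by the assay's seeded uniform draw) and take
    the ``k`` earliest — operationally identical when latencies are
    recorded on a common clock.  ``k-random`` samples uniformly among all
    assayed males.
    """
    rng = np.random.default_rng(seed)
    if rule in ("first-k", "k-fastest"):
        maters = assay.matings.sort_values(["latency_min", "tiebreak"], kind="mergesort")
        if len(maters) < k:
            raise ValueError(
                f"cannot select {k} maters: only {len(maters)} males mated "
                f"(shortfall {k - len(maters)})"
            )
        return maters["male_id"].to_numpy()[:k]
    if rule == "k-random":
        if len(assay.assayed_male_ids) < k:
            raise ValueError(f"cannot select {k} of {len(assay.assayed_male_ids)} assayed males")
        return rng.choice(assay.assayed_male_ids, size=k, replace=False)
    raise ValueError(f"unknown selection rule {rule!r}")


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------

def simulate_pool_seq(
    pool: Population,
    coverage_law: int | tuple = 60,
    seed: int | None = None,
    pool_id: str = "pool",
    group: str = "pool",
    replicate: int = 1,
    member_idx: np.ndarray | None = None,
) -> PoolCounts:
    """Sequence a pool of flies: binomial read sampling at the true pool
    frequency.

    ``coverage_law`` is either a fixed integer depth or
    ``("poisson", mean)`` for Poisson-distributed per-site depth.
    """
    rng = np.random.default_rng(seed)
    members = pool if member_idx is None else pool.take(np.asarray(member_idx))
    if members.n_individuals == 0:
        raise ValueError("pool is empty")
    freq = members.alt_frequencies()
    L = members.n_variants
    if isinstance(coverage_law, tuple):
        kind = coverage_law[0]
        if kind != "poisson":
            raise ValueError(f"unknown coverage law {kind!r}")
        depth = rng.poisson(float(coverage_law[1]), size=L)
    else:
        if int(coverage_law) < 0:
            raise ValueError("depth must be >= 0")
        depth = np.full(L, int(coverage_law))
    alt = rng.binomial(depth, freq)
    return PoolCounts(
        pool_id=pool_id,
        group=group,
        replicate=replicate,
        n_flies=members.n_individuals,
        variants=members.panel.genotypes.variants,
        ref_count=depth - alt,
        alt_count=alt,
    )


# ---------------------------------------------------------------------------
# line phenotypes
# ---------------------------------------------------------------------------

def simulate_line_phenotypes(
    n_lines: int,
    replicates: int,
    trials_per_replicate: int = 5,
    h2_target: float = 0.27,
    grand_mean: float = 0.05,
    total_sd: float = 0.02,
    window_min: int = 120,
    seed: int | None = None,
    line_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Replicate-level mating proportions under a one-way random-effects
    model on the proportion scale.

    Line effects are N(0, h2 * total_sd^2), replicate residuals
    N(0, (1-h2) * total_sd^2); the replicate proportion is
    ``grand_mean + line + residual`` clamped to [0, 1].  ``n_mated`` is
    stored on the modelled (continuous) scale as proportion x n_females so
    that downstream proportions reproduce the Gaussian model exactly.
    """
    if not 0.0 <= h2_target < 1.0:
        raise ValueError("h2_target must be in [0, 1)")
    if not 0.0 < grand_mean < 1.0:
        raise ValueError("grand_mean must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sg = np.sqrt(h2_target) * total_sd
    se = np.sqrt(1.0 - h2_target) * total_sd
    line_eff = rng.normal(0.0, sg, size=n_lines)
    resid = rng.normal(0.0, se, size=(n_lines, replicates))
    prop = np.clip(grand_mean + line_eff[:, None] + resid, 0.0, 1.0)
    if line_ids is None:
        line_ids = [f"L{i:03d}" for i in range(1, n_lines + 1)]
    return pd.DataFrame(
        {
            "line": np.repeat(line_ids, replicates),
            "replicate": np.tile(np.arange(1, replicates + 1), n_lines),
            "n_females": trials_per_replicate,
            "n_mated": (prop * trials_per_replicate).ravel(),
            "window_min": window_min,
        }
    )


# ---------------------------------------------------------------------------
# multi-generation selection experiment
# ---------------------------------------------------------------------------

def simulate_selection_experiment(
    panel: FounderPanel,
    model: TraitModel,
    base_pop: Population,
    generations: int = 18,
    n_selected_reps: int = 2,
    assay_males: int = 300,
    control_assay_males: int = 150,
    k: int = 40,
    second_control_generation: int = 5,
    window: int = 60,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
    seed: int | None = None,
    offspring_per_line: int = 700,
) -> tuple[pd.DataFrame, dict[str, Population]]:
    """Run the multi-generation selection design.

    Per selected replicate and generation, ``assay_males`` males are scored
    in vials (10 males x 5 females, ``window`` minutes); the first ``k`` to
    mate sire the next generation with ``k`` random sisters.  One control
    line breeds ``k`` random assayed males; a second control is split from
    the first at ``second_control_generation``.  Returns the trajectory
    table (generation, population_id, role, n_assayed_females, n_mated,
    proportion) and the final populations.
    """
    rng = np.random.default_rng(seed)

    def spawn(pop: Population, n: int) -> Population:
        # next generation bred from k sires x k dams sampled below
        midx = rng.choice(np.flatnonzero(~pop.is_male), size=n, replace=True)
        fidx = rng.choice(np.flatnonzero(pop.is_male), size=n, replace=True)
        child = _offspring(panel, pop, midx, pop, fidx, pop.generation + 1, recomb_rate, rng)
        half = n // 2
        child.is_male = np.r_[np.zeros(half, bool), np.ones(n - half, bool)][rng.permutation(n)]
        return child

    def seed_line(source: Population, n_parents: int = 80) -> Population:
        fem = rng.choice(np.flatnonzero(~source.is_male), size=n_parents // 2, replace=False)
        mal = rng.choice(np.flatnonzero(source.is_male), size=n_parents // 2, replace=False)
        line = source.take(np.r_[fem, mal])
        line.is_male = np.r_[np.zeros(n_parents // 2, bool), np.ones(n_parents // 2, bool)]
        return line

    lines: dict[str, Population] = {}
    roles: dict[str, str] = {}
    for r in range(1, n_selected_reps + 1):
        lines[f"S{r}"] = spawn(seed_line(base_pop), offspring_per_line)
        roles[f"S{r}"] = "selected"
    lines["C1"] = spawn(seed_line(base_pop), offspring_per_line)
    roles["C1"] = "control"

    records = []
    for gen in range(0, generations + 1):
        if gen == second_control_generation:
            lines["C2"] = spawn(lines["C1"], offspring_per_line)
            roles["C2"] = "control"
        for name in list(lines):
            pop = lines[name]
            n_assay = assay_males if roles[name] == "selected" or gen == 0 else control_assay_males
            males = np.flatnonzero(pop.is_male)
            if len(males) < n_assay:  # early generations: assay what exists
                n_assay_eff = len(males)
            else:
                n_assay_eff = n_assay
            chosen = rng.choice(males, size=n_assay_eff, replace=False)
            model.assign_liabilities(pop, rng)
            assay = simulate_mating_assay(
                pop,
                model,
                male_idx=chosen,
                window=window,
                seed=int(rng.integers(2**31)),
            )
            records.append(
                {
                    "generation": gen,
                    "population_id": name,
                    "role": roles[name],
                    "n_assayed": int(assay.vials["n_females"].sum()),
                    "n_mated": int(assay.vials["n_mated"].sum()),
                    "proportion": assay.proportion_mated(),
                }
            )
            if gen == generations:
                continue
            rule = "first-k" if roles[name] == "selected" else "k-random"
            try:
                sires = truncation_select(assay, rule, k, seed=int(rng.integers(2**31)))
            except ValueError:
                # fewer than k maters: breed from all maters plus random fill
                maters = assay.matings["male_id"].to_numpy()
                fill = rng.choice(
                    np.setdiff1d(chosen, maters), size=k - len(maters), replace=False
                )
                sires = np.r_[maters, fill]
            dams = rng.choice(np.flatnonzero(~pop.is_male), size=k, replace=False)
            parents = pop.take(np.r_[dams, sires])
            parents.is_male = np.r_[np.zeros(k, bool), np.ones(len(sires), bool)]
            lines[name] = spawn(parents, offspring_per_line)
    return pd.DataFrame(records), lines
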