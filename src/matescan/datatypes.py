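"""Shared containers for the mating-success analysis pipeline.

The pipeline moves between four kinds of data: line-level genotypes
(inbred panels coded 0/2), replicate-level mating-assay phenotypes,
pooled-sequencing allele counts, and simulated outbred populations whose
haplotypes are mosaics of founder haplotypes.  Everything tabular is a
pandas DataFrame with a documented schema; the numeric payloads are numpy
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five common polymorphic inversions used as GWA covariates.
INVERSIONS = ("In(2L)t", "In(2R)NS", "In(3R)P", "In(3R)K", "In(3R)Mo")

#: Karyotype class labels for a polymorphic inversion.
KARYOTYPE_LEVELS = ("ST/ST", "ST/INV", "INV/INV")

#: Required columns of a replicate-level phenotype table.
PHENOTYPE_COLUMNS = ("line", "replicate", "n_females", "n_mated", "window_min")


@dataclass
class GenotypeMatrix:
    """Line x variant dosage matrix with variant metadata.

    Parameters
    ----------
    line_ids
        Unique line identifiers, one per row of ``dosage``.
    variants
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``
        and optionally ``af`` (generating alt-allele frequency).
    dosage
        ``(n_lines, n_variants)`` float array.  Inbred lines use the
        alphabet {0, 2}; ``nan`` marks a missing call.
    """

    line_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.variants)} variants"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line ids must be unique")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_frequency(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing lines."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Folded minor-allele frequency in [0, 0.5]."""
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, np.asarray(mask)],
        )


@dataclass
class InversionBlock:
    """A recombination-suppressed chromosomal segment.

    Karyotype class of a genotype is determined by how many of its two
    haplotypes carry the inverted arrangement of the block.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    inv_frequency: float = 0.1


@dataclass
class FounderPanel:
    """Inbred founder panel: genotypes, inversion karyotypes, Wolbachia.

    ``inv_haplotype`` records, per founder line and inversion, whether the
    single haplotype the (inbred) line contributes to crosses carries the
    inverted arrangement; it drives recombination suppression downstream.
    """

    genotypes: GenotypeMatrix
    karyotypes: pd.DataFrame           # index: line id, one column per inversion
    wolbachia: pd.Series               # index: line id, bool
    inversion_blocks: dict[str, InversionBlock] = field(default_factory=dict)
    inv_haplotype: pd.DataFrame | None = None  # index: line, col per inversion, {0,1}

    @property
    def n_lines(self) -> int:
        return self.genotypes.n_lines

    @property
    def line_ids(self) -> list[str]:
        return self.genotypes.line_ids

    def founder_haplotypes(self) -> np.ndarray:
        """(n_lines, n_variants) 0/1 alt-allele haplotypes (dosage / 2)."""
        hap = self.genotypes.dosage / 2.0
        return np.nan_to_num(hap, nan=0.0).astype(np.int8)


@dataclass
class Population:
    """Simulated diploid population with founder-mosaic haplotypes.

    Haplotypes are stored as founder-origin labels on the variant grid:
    ``founder_origin[i, h, v]`` is the founder line index from which
    individual ``i`` inherited haplotype ``h`` at variant ``v``.  Origins
    therefore partition each haplotype exactly, and allele content is read
    through the founder haplotype table.
    """

    panel: FounderPanel
    founder_origin: np.ndarray  # (n, 2, n_variants) int16
    is_male: np.ndarray         # (n,) bool
    generation: int
    bottle: np.ndarray | None = None       # (n,) int, maintenance bottle id
    liabilities: np.ndarray | None = None  # (n,) float

    def __post_init__(self) -> None:
        self.founder_origin = np.asarray(self.founder_origin, dtype=np.int16)
        self.is_male = np.asarray(self.is_male, dtype=bool)
        if self.founder_origin.ndim != 3 or self.founder_origin.shape[1] != 2:
            raise ValueError("founder_origin must have shape (n, 2, n_variants)")
        if self.founder_origin.shape[0] != self.is_male.shape[0]:
            raise ValueError("sex vector length must match individual count")

    @property
    def n_individuals(self) -> int:
        return self.founder_origin.shape[0]

    @property
    def n_variants(self) -> int:
        return self.founder_origin.shape[2]

    def dosages(self, variant_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-individual alt-allele dosage in {0, 1, 2} at the given variants."""
        fh = self.panel.founder_haplotypes()
        if variant_idx is None:
            variant_idx = np.arange(self.n_variants)
        variant_idx = np.asarray(variant_idx)
        origin = self.founder_origin[:, :, variant_idx]  # (n, 2, k)
        alleles = fh[origin, variant_idx[None, None, :]]
        return alleles.sum(axis=1)

    def alt_frequencies(self) -> np.ndarray:
        """Population alt-allele frequency per variant (over 2n chromosomes)."""
        fh = self.panel.founder_haplotypes()
        idx = np.arange(self.n_variants)
        alleles = fh[self.founder_origin, idx[None, None, :]]
        return alleles.reshape(-1, self.n_variants).mean(axis=0)

    def take(self, idx: np.ndarray) -> "Population":
        idx = np.asarray(idx)
        return Population(
            panel=self.panel,
            founder_origin=self.founder_origin[idx],
            is_male=self.is_male[idx],
            generation=self.generation,
            bottle=None if self.bottle is None else self.bottle[idx],
            liabilities=None if self.liabilities is None else self.liabilities[idx],
        )


@dataclass
class TraitModel:
    """Additive liability model for male mating success.

    The liability of an individual is the sum of per-alt-allele effects at
    the causal variants plus a Gaussian environmental deviate.  Liability is
    mapped to a per-minute mating probability through a logistic link:
    ``p_minute = expit(hazard_intercept + hazard_slope * liability)``.
    """

    causal_idx: np.ndarray
    effects: np.ndarray
    env_sd: float = 1.0
    #: default gives ~1/3 of females mated per hour in an outbred base
    #: population at liability 0 (the observed starting point of the
    #: selection design)
    hazard_intercept: float = -6.2
    hazard_slope: float = 1.0
    #: fixed centring constant (reference-population mean genetic value);
    #: frozen at calibration so selection response shifts liabilities
    g_offset: float = 0.0

    def genetic_values(self, pop: Population) -> np.ndarray:
        if len(self.causal_idx) == 0:
            return np.zeros(pop.n_individuals)
        dos = pop.dosages(self.causal_idx)
        return dos @ self.effects

    def assign_liabilities(self, pop: Population, rng: np.random.Generator) -> np.ndarray:
        g = self.genetic_values(pop) - self.g_offset
        liab = g + rng.normal(0.0, self.env_sd, size=pop.n_individuals)
        pop.liabilities = liab
        return liab

    def minute_hazards(self, liabilities: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.hazard_intercept + self.hazard_slope * liabilities)

    @classmethod
    def from_h2(
        cls,
        pop: Population,
        n_causal: int,
        h2: float,
        rng: np.random.Generator,
        total_sd: float = 1.0,
        causal_freq_range: tuple[float, float] | None = None,
        effect_dist: str = "normal",
        **kwargs,
    ) -> "TraitModel":
        """Build a model whose realized liability-scale heritability in
        ``pop`` matches ``h2`` (effects rescaled to the population's actual
        genetic variance).

        ``causal_freq_range`` restricts causal variants to those whose alt
        frequency in ``pop`` lies in the given interval (segregating at
        intermediate frequency), the regime where extreme-QTL designs have
        power.
        """
        if not 0.0 <= h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        candidates = np.arange(pop.n_variants)
        if causal_freq_range is not None:
            freq = pop.alt_frequencies()
            lo, hi = causal_freq_range
            candidates = np.flatnonzero((freq >= lo) & (freq <= hi))
            if len(candidates) < n_causal:
                raise ValueError("not enough variants in the causal frequency range")
        causal = np.sort(rng.choice(candidates, size=n_causal, replace=False))
        if effect_dist == "normal":
            eff = rng.normal(0.0, 1.0, size=n_causal)
        elif effect_dist == "equal":
            # equal-magnitude effects, random sign: every causal variant is
            # genuinely large-effect rather than a lottery of draws
            eff = rng.choice([-1.0, 1.0], size=n_causal)
        else:
            raise ValueError(f"unknown effect_dist {effect_dist!r}")
        model = cls(causal_idx=causal, effects=eff, env_sd=1.0, **kwargs)
        g = model.genetic_values(pop)
        gvar = g.var()
        target_gvar = h2 * total_sd**2
        if gvar > 0 and target_gvar > 0:
            model.effects = eff * np.sqrt(target_gvar / gvar)
        elif target_gvar == 0:
            model.effects = np.zeros(n_causal)
        model.env_sd = float(np.sqrt((1.0 - h2) * total_sd**2))
        model.g_offset = float(model.genetic_values(pop).mean())
        return model


@dataclass
class MatingTrialTable:
    """Outcome of a no-choice mating assay.

    ``vials`` has one row per vial (vial, unit_id, n_females, n_males,
    window_min, n_mated); ``matings`` one row per copulation (vial,
    male_id, latency_min, tiebreak) where ``tiebreak`` is a seeded uniform
    draw used to order same-minute copulations.
    """

    vials: pd.DataFrame
    matings: pd.DataFrame
    assayed_male_ids: np.ndarray

    def proportion_mated(self) -> float:
        return float(self.vials["n_mated"].sum() / self.vials["n_females"].sum())


@dataclass
class PoolCounts:
    """Read counts for one sequenced pool of flies.

    ``n_flies`` is the number of (diploid) individuals in the pool, so the
    pool carries ``2 * n_flies`` chromosomes per autosomal site.
    """

    pool_id: str
    group: str
    replicate: int
    n_flies: int
    variants: pd.DataFrame
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count)
        self.alt_count = np.asarray(self.alt_count)
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise ValueError("read counts must be non-negative")
        if self.n_flies <= 0:
            raise ValueError("pool size must be positive")

    @property
    def coverage(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    def frequencies(self) -> np.ndarray:
        """Alt-allele frequency estimate; nan where coverage is zero."""
        cov = self.coverage.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(cov > 0, self.alt_count / cov, np.nan)


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check the replicate-level phenotype schema and value ranges."""
    missing = set(PHENOTYPE_COLUMNS) - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if (pheno["n_females"] <= 0).any():
        raise ValueError("n_females must be positive in every record")
    if ((pheno["n_mated"] < 0) | (pheno["n_mated"] > pheno["n_females"])).any():
        raise ValueError("n_mated must lie in [0, n_females]")
    return pheno
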