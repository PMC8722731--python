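"""Configuration objects for the diallel-population simulator.

A :class:`SimulationConfig` fully determines a simulated study population:
founder genomes, the selfed/outcrossed mating design, the genetic
architecture of the trait (major loci, polygenic background, inbreeding-
by-inbreeding epistasis, recessive juvenile lethals), per-site conservation
scores, and the field layout generating non-genetic nuisance variation.
Together with a seed it makes every downstream analysis reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass
class QTLSpec:
    """A single major locus with additive effect ``a`` and dominance ``d``.

    Genotypic value contributed is ``a * g + d * [g == 1]`` where ``g`` is the
    derived-allele dosage.  ``freq`` is the derived-allele frequency among
    founder haplotypes.  If ``carrier`` is given as ``(parent_index,
    haplotype_index)`` the derived allele is placed on exactly that founder
    haplotype (a private allele, ``freq`` ignored).
    """

    chrom: int
    cM: float
    freq: float
    a: float
    d: float
    carrier: Optional[tuple[int, int]] = None


@dataclass
class PolygenicSpec:
    """Background of partially recessive deleterious variants.

    Each locus gets a deleterious (negative) additive effect with magnitude
    drawn from an exponential distribution of scale ``effect_scale``, a
    dominance deviation ``d = -dom * a`` with per-locus ``dom`` equal to
    ``mean_dominance`` (``dom = 1`` makes the derived allele fully recessive),
    and a derived-allele frequency drawn from Beta(``freq_beta_a``,
    ``freq_beta_b``).
    """

    n_loci: int = 0
    effect_scale: float = 0.3
    mean_dominance: float = 0.6
    freq_beta_a: float = 1.0
    freq_beta_b: float = 5.0


@dataclass
class LethalSpec:
    """A recessive juvenile lethal carried on haplotype 0 of one parent."""

    chrom: int
    cM: float
    carrier_parent: int


@dataclass
class GerpSpec:
    """Per-site conservation-score model: which sites are scored and how."""

    fraction_scored: float = 0.8
    scale: float = 1.0  # exponential scale of positive scores


@dataclass
class FieldSpec:
    """Non-genetic field structure: year effects and spatial trends."""

    year_effects: Sequence[float] = (0.0, 0.0)
    row_poly: Sequence[float] = (0.0, 0.0, 0.0, 0.0)
    col_poly: Sequence[float] = (0.0, 0.0, 0.0, 0.0)
    shading_sd: float = 0.0
    shading_beta: float = 0.0
    border_effect: float = 0.0
    border_fraction: float = 0.0


@dataclass
class RateSegment:
    """Recombination-rate (cM/Mb) override for a cM window of a chromosome."""

    chrom: int
    cM_start: float
    cM_end: float
    cM_per_Mb: float


@dataclass
class SimulationConfig:
    n_parents: int = 20
    n_chromosomes: int = 2
    chrom_length_cM: float = 100.0
    marker_spacing_cM: float = 1.0
    trait_mean: float = 100.0
    selfed_family_sizes: Optional[Sequence[int]] = None
    outcross_design: Optional[Sequence[tuple[int, int, int]]] = None
    qtl_spec: Sequence[QTLSpec] = field(default_factory=list)
    polygenic_spec: PolygenicSpec = field(default_factory=PolygenicSpec)
    epistasis_b: float = 0.0
    lethal_spec: Sequence[LethalSpec] = field(default_factory=list)
    gerp_spec: GerpSpec = field(default_factory=GerpSpec)
    residual_sd_by_type_year: Optional[dict] = None
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    years: Sequence[str] = ("Y1", "Y2")
    # default cM -> bp rate, plus optional low/high recombination windows
    base_cM_per_Mb: float = 1.0
    rate_segments: Sequence[RateSegment] = field(default_factory=list)
    # optional observation models applied to the phased haplotype calls:
    # symmetric mis-assignment of the inherited haplotype, and independent
    # missingness (e.g. dormant-but-alive seed never sampled)
    call_error_rate: float = 0.0
    missing_call_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_parents < 2:
            raise ValueError("need at least 2 parents")
        if self.chrom_length_cM <= 0:
            raise ValueError("chromosome length must be positive")
        for q in self.qtl_spec:
            if q.carrier is None and not (0.0 < q.freq < 1.0):
                raise ValueError(f"QTL allele frequency {q.freq} outside (0,1)")
        if self.selfed_family_sizes is not None:
            if any(n < 1 for n in self.selfed_family_sizes):
                raise ValueError("family sizes must be >= 1")

    def residual_sd(self, progeny_type: str, year: str) -> float:
        table = self.residual_sd_by_type_year
        if table is None:
            return 1.0
        key = (progeny_type, year)
        if key not in table:
            raise ValueError(f"no residual SD configured for {key}")
        return float(table[key])


def maize_like_config(seed: int = 0) -> SimulationConfig:
    """Landrace-style preset: many common, small-effect, partially recessive
    deleterious variants and a single juvenile lethal.  Frequencies shifted
    upward emulate a post-bottleneck population where drift has raised the
    frequency of weakly deleterious alleles."""
    return SimulationConfig(
        n_parents=20,
        n_chromosomes=2,
        chrom_length_cM=100.0,
        marker_spacing_cM=1.0,
        polygenic_spec=PolygenicSpec(
            n_loci=150, effect_scale=0.25, mean_dominance=0.7,
            freq_beta_a=1.5, freq_beta_b=4.0,
        ),
        lethal_spec=[LethalSpec(chrom=0, cM=30.0, carrier_parent=0)],
        residual_sd_by_type_year={
            ("outcrossed", "Y1"): 3.0, ("outcrossed", "Y2"): 3.0,
            ("selfed", "Y1"): 3.5, ("selfed", "Y2"): 3.5,
        },
        seed=seed,
    )


def teosinte_like_config(seed: int = 0) -> SimulationConfig:
    """Wild-relative-style preset: fewer, rarer, larger-effect deleterious
    variants plus more recessive lethals, emulating a larger-Ne population
    where selection keeps strongly deleterious alleles rare."""
    return SimulationConfig(
        n_parents=20,
        n_chromosomes=2,
        chrom_length_cM=100.0,
        marker_spacing_cM=1.0,
        polygenic_spec=PolygenicSpec(
            n_loci=40, effect_scale=0.5, mean_dominance=0.7,
            freq_beta_a=0.6, freq_beta_b=10.0,
        ),
        lethal_spec=[
            LethalSpec(chrom=0, cM=60.0, carrier_parent=1),
            LethalSpec(chrom=1, cM=20.0, carrier_parent=2),
            LethalSpec(chrom=1, cM=75.0, carrier_parent=3),
        ],
        residual_sd_by_type_year={
            ("outcrossed", "Y1"): 3.0, ("outcrossed", "Y2"): 3.0,
            ("selfed", "Y1"): 3.0, ("selfed", "Y2"): 3.0,
        },
        seed=seed,
    )
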