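"""Diallel-population simulator with known genetic truth.

Simulates outbred founder genomes, meiosis onto selfed and outcrossed
full-sib families, and trait values built from additive + partially
recessive dominance effects, an optional inbreeding-by-inbreeding
(F-squared) epistasis term, recessive juvenile lethals, and field nuisance
effects.  Every stage is a deterministic function of the configuration and
seed, and the generator records the exact decomposition of each phenotype
so downstream estimators can be tested against closed-form truth.

Crossovers follow a no-interference (Haldane) model: the number of
crossovers per chromosome per meiosis is Poisson with mean equal to the map
length in Morgans, with breakpoint positions uniform on the cM map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "FounderGenome",
    "PopulationSim",
    "TraitTruth",
    "simulate_founders",
    "random_pedigree",
    "simulate_progeny",
    "simulate_phenotypes",
    "simulate_population",
    "simulate_diallel_gaussian",
    "hap_code",
]


def hap_code(parent_index: int, hap: int) -> int:
    """Global integer identity of founder haplotype ``hap`` of a parent."""
    return 2 * parent_index + hap


@dataclass
class FounderGenome:
    """Phased founder haplotypes with per-site annotation.

    ``haplotypes`` is a (n_parents, 2, n_sites) binary array of derived-allele
    carriage.  ``sites`` carries chrom, cM, bp, ref/alt, the ancestral allele
    and a conservation (GERP-like) score where present.  ``a`` and ``d`` are
    the per-site additive and dominance effects of the derived allele on the
    simulated trait (zero for neutral sites); ``lethal`` marks recessive
    juvenile lethal sites.  ``site_freqs`` are the generating derived-allele
    frequencies.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    parent_ids: list[str]
    site_freqs: np.ndarray
    a: np.ndarray
    d: np.ndarray
    lethal: np.ndarray

    @property
    def n_parents(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1 + 1]

    def realized_freqs(self) -> np.ndarray:
        """Derived-allele frequency among the 2*n_parents founder haplotypes."""
        return self.haplotypes.reshape(-1, self.haplotypes.shape[2]).mean(axis=0)

    def hap_matrix(self) -> np.ndarray:
        """(2*n_parents, n_sites) view, row index = global haplotype code."""
        return self.haplotypes.reshape(-1, self.haplotypes.shape[2])


@dataclass
class TraitTruth:
    """Exact decomposition of simulated phenotypes plus closed-form targets."""

    components: pd.DataFrame  # per individual: additive, dominance, epistatic, fixed, residual
    expected_delta: float
    expected_outcross_mean: float
    sigma2_A: float
    sigma2_D: float


@dataclass
class PopulationSim:
    """Bundle of everything one simulated population produces."""

    config: SimulationConfig
    founders: FounderGenome
    pedigree: pd.DataFrame
    mat_code: np.ndarray  # (n_progeny, n_sites) global haplotype codes, maternal
    pat_code: np.ndarray
    genotypes: np.ndarray  # derived-allele dosage, all progeny
    survived: np.ndarray
    phenotypes: pd.DataFrame  # survivors only
    truth: TraitTruth

    def surviving_index(self) -> np.ndarray:
        return np.flatnonzero(self.survived)


def _cM_to_bp(config: SimulationConfig, chrom: int, cM: np.ndarray) -> np.ndarray:
    """Map cM positions to bp through the configured piecewise rate map."""
    segs = [s for s in config.rate_segments if s.chrom == chrom]
    base = config.base_cM_per_Mb
    if not segs:
        return np.round(cM / base * 1e6).astype(np.int64) + 1
    # integrate 1/rate over [0, x] for each x
    edges = [0.0]
    rates = []
    pos = 0.0
    for s in sorted(segs, key=lambda s: s.cM_start):
        if s.cM_start > pos:
            edges.append(s.cM_start)
            rates.append(base)
        edges.append(s.cM_end)
        rates.append(s.cM_per_Mb)
        pos = s.cM_end
    edges.append(np.inf)
    rates.append(base)
    edges_arr = np.array(edges)
    bp = np.empty_like(cM, dtype=float)
    for i, x in enumerate(cM):
        acc = 0.0
        for lo, hi, r in zip(edges_arr[:-1], edges_arr[1:], rates):
            if x <= lo:
                break
            acc += (min(x, hi) - lo) / r
        bp[i] = acc * 1e6
    return np.round(bp).astype(np.int64) + 1


def simulate_founders(config: SimulationConfig, seed: Optional[int] = None) -> FounderGenome:
    """Draw phased founder genomes.

    Neutral background sites get derived-allele counts from a 1/k
    (standard-neutral) frequency spectrum over the 2N founder haplotypes;
    configured trait loci get binomial carriage at their target frequency,
    or exact placement when a carrier haplotype is specified.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    P = config.n_parents
    H = 2 * P

    chroms, cMs = [], []
    for c in range(config.n_chromosomes):
        pos = np.arange(0.0, config.chrom_length_cM, config.marker_spacing_cM)
        chroms.append(np.full(pos.size, c))
        cMs.append(pos)
    chrom = np.concatenate(chroms)
    cM = np.concatenate(cMs)
    S = chrom.size

    haps = np.zeros((H, S), dtype=np.uint8)
    freqs = np.zeros(S)
    a_eff = np.zeros(S)
    d_eff = np.zeros(S)
    lethal = np.zeros(S, dtype=bool)
    functional = np.zeros(S, dtype=bool)

    def site_at(c: int, pos: float) -> int:
        idx = np.flatnonzero(chrom == c)
        if idx.size == 0:
            raise ValueError(f"no sites on chromosome {c}")
        return idx[np.argmin(np.abs(cM[idx] - pos))]

    # major loci
    for q in config.qtl_spec:
        s = site_at(q.chrom, q.cM)
        functional[s] = True
        a_eff[s], d_eff[s] = q.a, q.d
        if q.carrier is not None:
            p_idx, h_idx = q.carrier
            haps[hap_code(p_idx, h_idx), s] = 1
            freqs[s] = 1.0 / H
        else:
            haps[:, s] = rng.random(H) < q.freq
            freqs[s] = q.freq

    # recessive juvenile lethals: one copy on haplotype 0 of the carrier
    for lth in config.lethal_spec:
        s = site_at(lth.chrom, lth.cM)
        if functional[s]:
            raise ValueError("lethal site collides with a QTL site")
        functional[s] = True
        lethal[s] = True
        haps[hap_code(lth.carrier_parent, 0), s] = 1
        freqs[s] = 1.0 / H

    # polygenic background on randomly chosen free sites
    pg = config.polygenic_spec
    if pg.n_loci > 0:
        free = np.flatnonzero(~functional)
        if free.size < pg.n_loci:
            raise ValueError("not enough sites for the polygenic background")
        loci = rng.choice(free, size=pg.n_loci, replace=False)
        functional[loci] = True
        mag = rng.exponential(pg.effect_scale, size=pg.n_loci)
        a_l = -mag
        d_l = -pg.mean_dominance * a_l  # masking in heterozygotes
        f_l = rng.beta(pg.freq_beta_a, pg.freq_beta_b, size=pg.n_loci)
        f_l = np.clip(f_l, 1.0 / H, 1 - 1.0 / H)
        a_eff[loci], d_eff[loci], freqs[loci] = a_l, d_l, f_l
        haps[:, loci] = rng.random((H, pg.n_loci)) < f_l[None, :]

    # neutral background: generating frequency from a 1/k (standard-neutral)
    # spectrum, haplotype carriage Bernoulli at that frequency so the stored
    # frequency is a true base-population value rather than an in-sample one
    neutral = np.flatnonzero(~functional)
    if neutral.size:
        k_support = np.arange(1, H)
        w = 1.0 / k_support
        p_true = rng.choice(k_support, size=neutral.size, p=w / w.sum()) / H
        haps[:, neutral] = rng.random((H, neutral.size)) < p_true[None, :]
        freqs[neutral] = p_true

    gs = config.gerp_spec
    gerp = np.full(S, np.nan)
    scored = rng.random(S) < gs.fraction_scored
    gerp[scored] = rng.exponential(gs.scale, size=int(scored.sum()))

    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=S)
    alt_shift = rng.integers(1, 4, size=S)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]

    bp = np.concatenate([
        _cM_to_bp(config, c, cM[chrom == c]) for c in range(config.n_chromosomes)
    ])
    sites = pd.DataFrame({
        "chrom": chrom.astype(int), "cM": cM, "bp": bp,
        "ref": ref, "alt": alt, "anc": ref, "gerp": gerp,
    })
    parent_ids = [f"P{i:03d}" for i in range(P)]
    return FounderGenome(
        sites=sites,
        haplotypes=haps.reshape(P, 2, S),
        parent_ids=parent_ids,
        site_freqs=freqs,
        a=a_eff,
        d=d_eff,
        lethal=lethal,
    )


def random_pedigree(config: SimulationConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Build a selfed + outcrossed full-sib family design.

    Defaults: every parent contributes a selfed family of 20 and each parent
    is crossed to two distinct random partners with 10 progeny per cross,
    emulating a sparse diallel.  Years are assigned at random per individual.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    P = config.n_parents
    parents = [f"P{i:03d}" for i in range(P)]
    sizes = config.selfed_family_sizes
    if sizes is None:
        sizes = [20] * P
    rows = []
    for i, n in enumerate(sizes):
        if i >= P:
            break
        for _ in range(int(n)):
            rows.append((parents[i], parents[i], "selfed"))
    design = config.outcross_design
    if design is None:
        design = []
        for i in range(P):
            for j in rng.choice([k for k in range(P) if k != i], size=2, replace=False):
                design.append((i, int(j), 10))
    for (m, f, n) in design:
        if not (0 <= m < P and 0 <= f < P):
            raise ValueError(f"pedigree references unknown parent ({m},{f})")
        if m == f:
            raise ValueError("outcross design entry with mother == father")
        for _ in range(int(n)):
            rows.append((parents[m], parents[f], "outcrossed"))
    ped = pd.DataFrame(rows, columns=["mother", "father", "progeny_type"])
    ped.insert(0, "id", [f"I{i:05d}" for i in range(len(ped))])
    ped["year"] = rng.choice(list(config.years), size=len(ped))
    return ped


def _gametes(founders: FounderGenome, config: SimulationConfig,
             parent_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Simulate one recombinant gamete per entry of ``parent_idx``.

    Returns global haplotype codes, shape (len(parent_idx), n_sites).
    """
    sites = founders.sites
    chrom = sites["chrom"].to_numpy()
    cM = sites["cM"].to_numpy()
    S = cM.size
    out = np.empty((parent_idx.size, S), dtype=np.int32)
    chrom_slices = [np.flatnonzero(chrom == c) for c in range(config.n_chromosomes)]
    morgans = config.chrom_length_cM / 100.0
    for g, p in enumerate(parent_idx):
        for c, idx in enumerate(chrom_slices):
            k = rng.poisson(morgans)
            start = rng.integers(0, 2)
            if k == 0:
                bits = np.full(idx.size, start)
            else:
                breaks = np.sort(rng.uniform(0.0, config.chrom_length_cM, size=k))
                bits = (start + np.searchsorted(breaks, cM[idx], side="right")) % 2
            out[g, idx] = 2 * p + bits
    return out


def simulate_progeny(founders: FounderGenome, pedigree: pd.DataFrame,
                     config: SimulationConfig, seed: Optional[int] = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Drop pedigree progeny through meiosis.

    Returns ``(mat_code, pat_code, genotypes, survived)``: phased inherited
    founder-haplotype identities per progeny per site (global codes), the
    derived-allele dosage matrix, and survival flags (False for individuals
    homozygous for any lethal allele; these are censored before phenotyping).
    """
    name_to_idx = {p: i for i, p in enumerate(founders.parent_ids)}
    try:
        mothers = np.array([name_to_idx[m] for m in pedigree["mother"]])
        fathers = np.array([name_to_idx[f] for f in pedigree["father"]])
    except KeyError as e:  # pragma: no cover - input error path
        raise ValueError(f"pedigree references unknown parent {e}") from None
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    mat_code = _gametes(founders, config, mothers, rng)
    pat_code = _gametes(founders, config, fathers, rng)
    H = founders.hap_matrix()
    cols = np.arange(H.shape[1])[None, :]
    genotypes = (H[mat_code, cols] + H[pat_code, cols]).astype(np.int8)
    # observation model on the haplotype calls (genotypes stay truth: the
    # error model represents phasing/imputation noise, not new alleles)
    if config.call_error_rate > 0:
        for codes, parent in ((mat_code, mothers), (pat_code, fathers)):
            flip = rng.random(codes.shape) < config.call_error_rate
            # symmetric mis-assignment: swap to the parent's other haplotype
            codes[flip] = np.where(codes[flip] % 2 == 0,
                                   codes[flip] + 1, codes[flip] - 1)
    if config.missing_call_rate > 0:
        miss = rng.random(mat_code.shape) < config.missing_call_rate
        mat_code[miss] = -1
        pat_code[miss] = -1
    survived = np.ones(len(pedigree), dtype=bool)
    for s in np.flatnonzero(founders.lethal):
        survived &= genotypes[:, s] < 2
    return mat_code, pat_code, genotypes, survived


def simulate_phenotypes(pedigree: pd.DataFrame, genotypes: np.ndarray,
                        founders: FounderGenome, config: SimulationConfig,
                        seed: Optional[int] = None,
                        survived: Optional[np.ndarray] = None
                        ) -> tuple[pd.DataFrame, TraitTruth]:
    """Generate trait values for surviving progeny.

    phenotype = trait_mean + year + spatial polynomials + shading*beta_S
              + border + sum_l (a_l g_l + d_l [g_l == 1]) + b * F_ped^2
              + eps(type, year)

    The pedigree inbreeding coefficient F_ped is 0.5 for selfed progeny of
    non-inbred parents and 0 for outcrossed progeny.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 3)
    n = len(pedigree)
    if survived is None:
        survived = np.ones(n, dtype=bool)
    fs = config.field_spec
    years = list(config.years)
    year_eff = dict(zip(years, fs.year_effects))
    yr = pedigree["year"].to_numpy()
    row = rng.uniform(-1, 1, size=n)
    col = rng.uniform(-1, 1, size=n)
    shading = rng.normal(0.0, fs.shading_sd, size=n) if fs.shading_sd > 0 else np.zeros(n)
    border = (rng.random(n) < fs.border_fraction).astype(float)

    fixed = np.array([year_eff.get(y, 0.0) for y in yr]) + config.trait_mean
    for p, beta in enumerate(fs.row_poly, start=1):
        fixed = fixed + beta * row ** p
    for p, beta in enumerate(fs.col_poly, start=1):
        fixed = fixed + beta * col ** p
    fixed = fixed + fs.shading_beta * shading + fs.border_effect * border

    func = np.flatnonzero((founders.a != 0) | (founders.d != 0))
    g = genotypes[:, func].astype(float)
    additive = g @ founders.a[func]
    dominance = (g == 1.0) @ founders.d[func]

    # epistasis acts on realized genomic homozygosity: with a single
    # generation of selfing the pedigree F is a two-level factor confounded
    # with progeny type, so a quadratic response is only identifiable (and
    # only biologically meaningful) through realized F
    q_all = founders.realized_freqs()
    poly = (q_all > 0) & (q_all < 1)
    exp_het = float(np.sum(2 * q_all[poly] * (1 - q_all[poly])))
    het_counts = (genotypes[:, poly] == 1).sum(axis=1)
    f_real = 1.0 - het_counts / exp_het if exp_het > 0 else np.zeros(n)
    epistatic = config.epistasis_b * np.clip(f_real, 0.0, None) ** 2

    types = pedigree["progeny_type"].to_numpy()
    sd = np.array([config.residual_sd(t, y) for t, y in zip(types, yr)])
    resid = rng.normal(0.0, 1.0, size=n) * sd

    y = fixed + additive + dominance + epistatic + resid

    pheno = pd.DataFrame({
        "id": pedigree["id"], "mother": pedigree["mother"],
        "father": pedigree["father"], "progeny_type": types,
        "year": yr, "row": row, "col": col, "shading": shading,
        "border": border, "trait": y,
    })
    comp = pd.DataFrame({
        "id": pedigree["id"], "fixed": fixed, "additive": additive,
        "dominance": dominance, "epistatic": epistatic, "residual": resid,
        "censored": ~survived,
    })

    # closed-form expectations at realized founder allele frequencies
    q = founders.realized_freqs()[func]
    p_ = 1.0 - q
    a_f, d_f = founders.a[func], founders.d[func]
    mean_year = float(np.mean([year_eff.get(y, 0.0) for y in years]))
    sel_mask = pedigree["progeny_type"].to_numpy() == "selfed"
    f2_out = float(np.mean(np.clip(f_real[~sel_mask], 0, None) ** 2)) if (~sel_mask).any() else 0.0
    f2_self = float(np.mean(np.clip(f_real[sel_mask], 0, None) ** 2)) if sel_mask.any() else 0.0
    exp_out = (config.trait_mean + mean_year
               + float(np.sum(2 * a_f * q + 2 * p_ * q * d_f))
               + config.epistasis_b * f2_out)
    # outcross mean minus selfed mean: directional dominance plus epistasis
    depression = (float(np.sum(2 * 0.5 * p_ * q * d_f))
                  + config.epistasis_b * (f2_out - f2_self))
    exp_delta = depression / exp_out if exp_out != 0 else np.nan
    alpha = a_f + d_f * (p_ - q)
    sigma2_A = float(np.sum(2 * p_ * q * alpha ** 2))
    sigma2_D = float(np.sum((2 * p_ * q * d_f) ** 2))
    truth = TraitTruth(
        components=comp, expected_delta=exp_delta,
        expected_outcross_mean=exp_out, sigma2_A=sigma2_A, sigma2_D=sigma2_D,
    )
    return pheno[survived].reset_index(drop=True), truth


def simulate_population(config: SimulationConfig, seed: Optional[int] = None) -> PopulationSim:
    """Run the full pipeline: founders -> pedigree -> meiosis -> phenotypes."""
    base = config.seed if seed is None else seed
    founders = simulate_founders(config, seed=base)
    pedigree = random_pedigree(config, seed=base)
    mat, pat, geno, survived = simulate_progeny(founders, pedigree, config, seed=base)
    pheno, truth = simulate_phenotypes(pedigree, geno, founders, config,
                                       seed=base, survived=survived)
    return PopulationSim(config, founders, pedigree, mat, pat, geno,
                         survived, pheno, truth)


def simulate_diallel_gaussian(pedigree: pd.DataFrame,
                              sigma2_gca: float = 1.0,
                              sigma2_s1: float = 1.0,
                              sigma2_sca: float = 0.5,
                              cov_gca_s1: float = 0.0,
                              sigma2_gca_e: float = 0.0,
                              sigma2_s1_e: float = 0.0,
                              sigma2_sca_e: float = 0.0,
                              resid_sd_by_type_year: Optional[dict] = None,
                              outcross_mean: float = 100.0,
                              selfed_mean: float = 90.0,
                              year_effects: Optional[dict] = None,
                              seed: int = 0) -> pd.DataFrame:
    """Draw phenotypes directly from the diallel mixed model.

    This is the distributional oracle for the REML fitter: parent effects on
    outcrossed progeny (GCA) and on selfed families are bivariate normal with
    the given components, cross-specific (SCA) deviations and year
    interactions are independent normals, and residual scatter may differ by
    progeny type and year.  Father effects equal the same parent's mother
    effect, as in the estimation model.
    """
    rng = np.random.default_rng(seed)
    parents = sorted(set(pedigree["mother"]) | set(pedigree["father"]))
    years = sorted(set(pedigree["year"]))
    P = len(parents)
    cov = np.array([[sigma2_gca, cov_gca_s1], [cov_gca_s1, sigma2_s1]])
    w = np.linalg.cholesky(cov + 1e-12 * np.eye(2)) @ rng.standard_normal((2, P))
    gca = dict(zip(parents, w[0]))
    s1 = dict(zip(parents, w[1]))
    sca: dict = {}
    gxe = {(p, y): rng.normal(0, np.sqrt(sigma2_gca_e)) for p in parents for y in years}
    s1xe = {(p, y): rng.normal(0, np.sqrt(sigma2_s1_e)) for p in parents for y in years}
    scaxe: dict = {}
    y_out = np.empty(len(pedigree))
    for i, r in enumerate(pedigree.itertuples(index=False)):
        yr = r.year
        if r.progeny_type == "selfed":
            g = selfed_mean + s1[r.mother] + s1xe[(r.mother, yr)]
            sd = 1.0 if resid_sd_by_type_year is None else resid_sd_by_type_year[("selfed", yr)]
        else:
            pair = tuple(sorted((r.mother, r.father)))
            if pair not in sca:
                sca[pair] = rng.normal(0, np.sqrt(sigma2_sca))
            if (pair, yr) not in scaxe:
                scaxe[(pair, yr)] = rng.normal(0, np.sqrt(sigma2_sca_e))
            g = (outcross_mean + gca[r.mother] + gca[r.father] + sca[pair]
                 + gxe[(r.mother, yr)] + gxe[(r.father, yr)] + scaxe[(pair, yr)])
            sd = 1.0 if resid_sd_by_type_year is None else resid_sd_by_type_year[("outcrossed", yr)]
        if year_effects:
            g += year_effects.get(yr, 0.0)
        y_out[i] = g + rng.normal(0, sd)
    out = pedigree.copy()
    out["trait"] = y_out
    for c in ("row", "col", "shading", "border"):
        if c not in out.columns:
            out[c] = 0.0
    return out
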