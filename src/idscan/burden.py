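"""Mutational burden, rare-allele load, and interval-overlap statistics.

Burden follows a partial-recessivity model on conservation (GERP-like)
scores: a site contributes its full score when an individual is homozygous
for the derived allele, a quarter of the score when heterozygous, and
nothing when homozygous ancestral.  Only sites segregating in the
population, polarized by a known ancestral allele, and with a positive
score are counted.  The rare-allele load of a parent is the mean carriage
frequency of minor alleles (MAF < 0.05 by default) across rare sites, with
homozygous calls double-weighted.  Interval-overlap permutation tests
re-place QTL support-interval windows uniformly on the genetic map
(preserving each window's cM length, never straddling chromosomes) to
build the null distribution of mean overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BurdenSummary", "OverlapTestResult",
    "site_burden", "parent_burden_summary", "daf_spectrum",
    "rare_allele_load", "load_depression_correlation",
    "interval_overlap_permutation",
]


@dataclass
class BurdenSummary:
    """Per parent x genotype class burden table plus per-parent totals."""

    by_class: pd.DataFrame   # individual, anc_geno (0/1/2), del_sites, mean_load, total_load
    per_parent: pd.DataFrame  # individual, total_burden, mean_burden, n_sites
    n_excluded_unpolarized: int = 0


@dataclass
class OverlapTestResult:
    observed_mean: float
    observed_zero: int
    n_permutations: int
    p_mean: float
    p_zero: float
    clustered: bool
    perm_mean: float


def site_burden(genotype_class: int, gerp: float) -> float:
    """Per-site burden: 0 (ancestral hom), 0.25*GERP (het), GERP (derived hom)."""
    if genotype_class == 0:
        return 0.0
    if genotype_class == 1:
        return 0.25 * gerp
    if genotype_class == 2:
        return float(gerp)
    raise ValueError(f"genotype class {genotype_class} not in {{0,1,2}}")


def parent_burden_summary(genotypes: np.ndarray, gerp: np.ndarray,
                          ancestral_known: np.ndarray,
                          parent_ids: Optional[Sequence[str]] = None
                          ) -> BurdenSummary:
    """Burden per parent from derived-allele dosages and site scores.

    ``genotypes``: (parents x sites) derived-allele dosage (negative =
    missing call, excluded per parent).  Sites kept: segregating among the
    parents, polarized (``ancestral_known``), positive GERP score.
    """
    G = np.asarray(genotypes)
    gerp = np.asarray(gerp, dtype=float)
    known = np.asarray(ancestral_known, dtype=bool)
    n_excl = int((~known).sum())
    called = G >= 0
    with np.errstate(invalid="ignore"):
        freq = np.where(called.sum(axis=0) > 0,
                        np.where(called, G, 0).sum(axis=0) / (2.0 * np.maximum(called.sum(axis=0), 1)),
                        np.nan)
    seg = (freq > 0) & (freq < 1)
    keep = known & seg & np.isfinite(gerp) & (gerp > 0)
    Gk = G[:, keep]
    gk = gerp[keep]
    if parent_ids is None:
        parent_ids = [f"P{i:03d}" for i in range(G.shape[0])]
    rows = []
    totals = []
    weights = {0: 0.0, 1: 0.25, 2: 1.0}
    for i, pid in enumerate(parent_ids):
        gi = Gk[i]
        ok = gi >= 0
        total_all = 0.0
        n_all = 0
        for cls in (0, 1, 2):
            m = ok & (gi == cls)
            cnt = int(m.sum())
            tot = float(weights[cls] * gk[m].sum())
            mean = tot / cnt if cnt else 0.0
            rows.append((pid, cls, cnt, mean, tot))
            total_all += tot
            n_all += cnt
        totals.append((pid, total_all, total_all / n_all if n_all else np.nan, n_all))
    by_class = pd.DataFrame(rows, columns=["individual", "anc_geno", "del_sites",
                                           "mean_load", "total_load"])
    per_parent = pd.DataFrame(totals, columns=["individual", "total_burden",
                                               "mean_burden", "n_sites"])
    return BurdenSummary(by_class=by_class, per_parent=per_parent,
                         n_excluded_unpolarized=n_excl)


def daf_spectrum(genotypes: np.ndarray, bins: int = 10,
                 ancestral_known: Optional[np.ndarray] = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Derived-allele frequency spectrum over the 2*n_parents haplotypes.

    Returns (bin edges, counts); monomorphic sites are excluded.
    """
    G = np.asarray(genotypes, dtype=float)
    n_hap = 2 * G.shape[0]
    freq = G.sum(axis=0) / n_hap
    if ancestral_known is not None:
        freq = freq[np.asarray(ancestral_known, dtype=bool)]
    freq = freq[(freq > 0) & (freq < 1)]
    counts, edges = np.histogram(freq, bins=bins, range=(0.0, 1.0))
    return edges, counts


def rare_allele_load(genotypes: np.ndarray, allele_freqs: np.ndarray,
                     maf_max: float = 0.05) -> np.ndarray:
    """Mean rare-allele carriage per parent, homozygotes double-weighted.

    At each site with minor-allele frequency below ``maf_max`` a parent
    contributes 0, 0.5 or 1 (het / minor-allele homozygote); the load is
    the mean over retained sites.  ``allele_freqs`` are the frequencies of
    the allele counted by the dosage coding, from the full parent panel.
    """
    G = np.asarray(genotypes, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    maf = np.minimum(p, 1.0 - p)
    rare = (maf < maf_max) & (maf > 0)
    if not rare.any():
        raise ValueError("no sites pass the rare-allele frequency filter")
    Gr = G[:, rare]
    pr = p[rare]
    # count copies of the *minor* allele at each site
    minor_dosage = np.where(pr <= 0.5, Gr, 2.0 - Gr)
    return minor_dosage.mean(axis=1) / 2.0


def load_depression_correlation(loads: pd.Series, family_delta: pd.Series
                                ) -> tuple[float, float]:
    """Pearson correlation between parental load and family-specific
    inbreeding depression; requires >= 3 parents with both values."""
    common = loads.index.intersection(family_delta.index)
    x = loads.loc[common].to_numpy(dtype=float)
    y = family_delta.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 parents with load and depression values")
    x, y = x[ok], y[ok]
    tol_x = 1e-12 * max(1.0, float(np.max(np.abs(x))))
    tol_y = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    if np.std(x) <= tol_x or np.std(y) <= tol_y:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _place_windows(lengths: np.ndarray, chrom_sizes: np.ndarray,
                   rng: np.random.Generator) -> list[tuple[int, float, float]]:
    """Place each window uniformly on the concatenated map.

    The chromosome is chosen with probability proportional to its count of
    valid start positions (size - window length, floored at 0); the start
    is uniform within the valid range.  Windows never straddle chromosome
    ends.
    """
    out = []
    for L in lengths:
        valid = np.maximum(chrom_sizes - L, 0.0)
        if valid.sum() <= 0:
            raise ValueError(f"window of {L} cM longer than every chromosome")
        pchrom = valid / valid.sum()
        c = rng.choice(len(chrom_sizes), p=pchrom)
        start = rng.uniform(0.0, valid[c])
        out.append((int(c), start, start + L))
    return out


def _count_overlaps(windows, targets) -> np.ndarray:
    """Overlapping targets per query window.  Targets are (chrom, lo, hi)
    intervals (points have lo == hi)."""
    counts = np.zeros(len(windows))
    for i, (c, lo, hi) in enumerate(windows):
        for (tc, tlo, thi) in targets:
            if tc == c and tlo <= hi and thi >= lo:
                counts[i] += 1
    return counts


def interval_overlap_permutation(query: Sequence[tuple[int, float, float]],
                                 targets: Sequence[tuple[int, float, float]],
                                 chrom_sizes: Sequence[float],
                                 B: int = 5000, seed: int = 0,
                                 permute_targets: bool = False
                                 ) -> OverlapTestResult:
    """Permutation test for non-random clustering of map intervals.

    ``query`` are observed windows (chrom, cM start, cM end); ``targets``
    are points or intervals in the same coordinates.  Each permutation
    re-places every query window uniformly at random on the genetic map,
    preserving its cM length; with ``permute_targets`` (the between-
    population comparison) the target windows are re-placed too.  The
    statistics are the mean number of overlaps per query and the number of
    queries with zero overlaps; two-sided empirical p-values use the
    doubled-tail (x+1)/(B+1) rule capped at 1.
    """
    rng = np.random.default_rng(seed)
    sizes = np.asarray(chrom_sizes, dtype=float)
    q_len = np.array([hi - lo for (_, lo, hi) in query], dtype=float)
    t_len = np.array([hi - lo for (_, lo, hi) in targets], dtype=float)
    obs_counts = _count_overlaps(list(query), list(targets))
    obs_mean = float(obs_counts.mean())
    obs_zero = int((obs_counts == 0).sum())
    perm_means = np.empty(B)
    perm_zeros = np.empty(B)
    for b in range(B):
        qw = _place_windows(q_len, sizes, rng)
        tw = (_place_windows(t_len, sizes, rng) if permute_targets
              else list(targets))
        cnt = _count_overlaps(qw, tw)
        perm_means[b] = cnt.mean()
        perm_zeros[b] = (cnt == 0).sum()

    def two_sided(perm, obs):
        hi = (np.sum(perm >= obs) + 1) / (B + 1)
        lo = (np.sum(perm <= obs) + 1) / (B + 1)
        return min(1.0, 2.0 * min(hi, lo))

    return OverlapTestResult(
        observed_mean=obs_mean, observed_zero=obs_zero, n_permutations=B,
        p_mean=two_sided(perm_means, obs_mean),
        p_zero=two_sided(perm_zeros, obs_zero),
        clustered=obs_mean > perm_means.mean(),
        perm_mean=float(perm_means.mean()),
    )
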