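"""Segregation-distortion scan in selfed families.

In the selfed progeny of a heterozygous parent, Mendelian segregation of
the two parental haplotypes predicts 1:2:1 genotype proportions at every
map position.  Recessive juvenile lethals (and other pre-sampling
selection) distort these ratios in the surviving progeny.  The scan runs
a 2-df chi-square goodness-of-fit test per family per map marker, controls
the genome-wide error rate through the effective number of independent
tests (ENT, from eigenvalues of the per-chromosome marker correlation
matrices), requires runs of at least three consecutive significant markers
to declare a segregation distortion region (SDR), confirms regions against
raw (unimputed) marker genotypes, and reports the local recombination-rate
context (distorted regions tend to sit in low-recombination sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .maps import LinkageMap

__all__ = [
    "FamilyScan", "ENTResult", "SDRegion",
    "family_segregation_scan", "effective_number_of_tests", "call_sdr",
    "confirm_sdr", "sdr_recombination_context",
]


@dataclass
class FamilyScan:
    family: str
    table: pd.DataFrame  # per marker: counts (aa, ab, bb), chi2, p


@dataclass
class ENTResult:
    per_chrom: dict
    ent_total: float
    alpha: float  # 0.05 / ENT_total


@dataclass
class SDRegion:
    family: str
    chrom: int
    marker_start: str
    marker_end: str
    cM_start: float
    cM_end: float
    bp_start: int
    bp_end: int
    row_lo: int
    row_hi: int
    pvalues: np.ndarray
    deficient_classes: list
    het_deficient: bool
    confirmed: Optional[bool] = None
    confirm_detail: Optional[pd.DataFrame] = None
    sdr_rate: float = np.nan
    chrom_rate: float = np.nan

    @property
    def length_cM(self) -> float:
        return self.cM_end - self.cM_start

    @property
    def length_Mb(self) -> float:
        return (self.bp_end - self.bp_start) / 1e6


def sdr_table(regions: Sequence[SDRegion]) -> pd.DataFrame:
    """SDR list as a flat summary table (one row per region)."""
    rows = []
    for r in regions:
        rows.append({
            "Family": r.family, "Chr": r.chrom,
            "marker_start": r.marker_start, "marker_end": r.marker_end,
            "cM_start": r.cM_start, "cM_end": r.cM_end,
            "pos_start": r.bp_start, "pos_end": r.bp_end,
            "Length(Mb)": r.length_Mb, "Length(cM)": r.length_cM,
            "SDR-RR": r.sdr_rate, "CRR": r.chrom_rate,
            "deficient": "/".join(r.deficient_classes),
            "confirmed": r.confirmed,
        })
    return pd.DataFrame(rows)


def _exact_multinomial_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact goodness-of-fit p for 1:2:1: total probability of outcomes no
    more likely than the observed one under Multinomial(n; 1/4, 1/2, 1/4)."""
    n = n_aa + n_ab + n_bb
    a = np.arange(n + 1)
    A, B = np.meshgrid(a, a, indexing="ij")
    C = n - A - B
    ok = C >= 0
    from scipy.special import gammaln
    with np.errstate(invalid="ignore"):
        logp = (gammaln(n + 1) - gammaln(A + 1) - gammaln(B + 1)
                - gammaln(np.where(ok, C, 0) + 1)
                + A * np.log(0.25) + B * np.log(0.5)
                + np.where(ok, C, 0) * np.log(0.25))
    logp = np.where(ok, logp, -np.inf)
    obs = logp[n_aa, n_ab]
    mask = logp <= obs + 1e-12
    return float(np.exp(logp[ok & mask]).sum())


def family_segregation_scan(mat_code: np.ndarray, pat_code: np.ndarray,
                            family_rows: np.ndarray, parent: int,
                            lmap: LinkageMap, family_id: str | None = None,
                            min_n: int = 20, exact: bool = False) -> FamilyScan:
    """Chi-square 1:2:1 scan of one selfed family along the map.

    ``family_rows`` indexes the selfed progeny of ``parent``.  At each map
    marker, progeny are classified by parental-haplotype genotype
    (h1h1 / h1h2 / h2h2); the 2-df chi-square tests the observed counts
    against (n/4, n/2, n/4).  Progeny with missing calls at a marker are
    dropped there.
    """
    if family_rows.size < min_n:
        raise ValueError(
            f"family {family_id or parent}: n={family_rows.size} below minimum {min_n}")
    sites = lmap.site_index()
    m = mat_code[np.ix_(family_rows, sites)]
    p = pat_code[np.ix_(family_rows, sites)]
    h1 = 2 * parent  # code of parent haplotype 1
    ok = (m >= 0) & (p >= 0)
    g = (m == h1).astype(np.int8) + (p == h1).astype(np.int8)  # copies of h1
    n_aa = ((g == 2) & ok).sum(axis=0)
    n_ab = ((g == 1) & ok).sum(axis=0)
    n_bb = ((g == 0) & ok).sum(axis=0)
    n = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        e_hom = n / 4.0
        e_het = n / 2.0
        chi2 = ((n_aa - e_hom) ** 2 / e_hom + (n_ab - e_het) ** 2 / e_het
                + (n_bb - e_hom) ** 2 / e_hom)
    if exact:
        pval = np.array([_exact_multinomial_p(int(a), int(b), int(c))
                         for a, b, c in zip(n_aa, n_ab, n_bb)])
    else:
        pval = stats.chi2.sf(chi2, df=2)
    tab = lmap.markers.reset_index(drop=True).copy()
    tab["n_aa"], tab["n_ab"], tab["n_bb"] = n_aa, n_ab, n_bb
    tab["n"] = n
    tab["chi2"] = chi2
    tab["p"] = pval
    return FamilyScan(family=family_id or f"P{parent:03d}", table=tab)


def _li_ji(eigenvalues: np.ndarray) -> float:
    """Li & Ji (2005) effective number of tests from correlation eigenvalues.

    f(lambda) = I(lambda >= 1) + fractional part; eigenvalues are rounded to
    10 decimals first because f is discontinuous at integers and numerical
    eigensolvers return e.g. 2 - 1e-16 for structurally integer eigenvalues.
    """
    lam = np.round(np.abs(eigenvalues), 10)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def _cheverud_nyholt(eigenvalues: np.ndarray) -> float:
    m = eigenvalues.size
    v = np.var(eigenvalues, ddof=1) if m > 1 else 0.0
    return float(1 + (m - 1) * (1 - v / m))


def _galwey(eigenvalues: np.ndarray) -> float:
    lam = np.maximum(eigenvalues, 0.0)
    return float(np.sum(np.sqrt(lam)) ** 2 / np.sum(lam))


_ENT_ESTIMATORS = {"li-ji": _li_ji, "cheverud-nyholt": _cheverud_nyholt,
                   "galwey": _galwey}


def effective_number_of_tests(genotypes: np.ndarray, lmap: LinkageMap,
                              method: str = "li-ji",
                              alpha: float = 0.05) -> ENTResult:
    """ENT from per-chromosome marker correlation eigenvalues.

    ``genotypes`` is the (progeny x map marker) additive dosage matrix of
    all scanned progeny.  Constant marker columns are removed before the
    correlation.  Per-chromosome ENTs are summed and the genome-wide
    threshold is alpha / ENT_total.
    """
    est = _ENT_ESTIMATORS[method]
    mk = lmap.markers.reset_index(drop=True)
    per = {}
    for c in mk["chrom"].unique():
        cols = np.flatnonzero((mk["chrom"] == c).to_numpy())
        G = np.asarray(genotypes, dtype=float)[:, cols]
        keep = G.std(axis=0) > 0
        G = G[:, keep]
        if G.shape[1] < 2:
            per[int(c)] = float(G.shape[1])
            continue
        R = np.corrcoef(G, rowvar=False)
        lam = np.linalg.eigvalsh(R)
        per[int(c)] = min(est(lam), G.shape[1])
    total = float(sum(per.values()))
    return ENTResult(per_chrom=per, ent_total=total, alpha=alpha / total)


def call_sdr(scan: FamilyScan, ent: ENTResult, min_run: int = 3) -> list[SDRegion]:
    """Maximal runs of >= min_run consecutive markers with p < alpha'."""
    tab = scan.table
    regions: list[SDRegion] = []
    for c in tab["chrom"].unique():
        sub = tab[tab["chrom"] == c].reset_index()
        sig = (sub["p"].to_numpy() < ent.alpha) & np.isfinite(sub["p"].to_numpy())
        i = 0
        while i < len(sub):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                block = sub.iloc[i:j + 1]
                pooled = block[["n_aa", "n_ab", "n_bb"]].sum()
                n_tot = pooled.sum()
                expected = np.array([0.25, 0.5, 0.25]) * n_tot
                deficit = pooled.to_numpy() < expected
                classes = [nm for nm, d in zip(("aa", "ab", "bb"), deficit) if d]
                regions.append(SDRegion(
                    family=scan.family, chrom=int(c),
                    marker_start=str(block.iloc[0]["marker"]),
                    marker_end=str(block.iloc[-1]["marker"]),
                    cM_start=float(block.iloc[0]["cM"]),
                    cM_end=float(block.iloc[-1]["cM"]),
                    bp_start=int(block.iloc[0]["bp"]),
                    bp_end=int(block.iloc[-1]["bp"]),
                    row_lo=int(block.iloc[0]["index"]),
                    row_hi=int(block.iloc[-1]["index"]),
                    pvalues=block["p"].to_numpy(),
                    deficient_classes=classes,
                    het_deficient="ab" in classes,
                ))
            i = j + 1
    return regions


def confirm_sdr(sdr: SDRegion, raw_genotypes: np.ndarray,
                parent_genotypes: np.ndarray, sites: pd.DataFrame,
                family_rows: np.ndarray, alpha: float = 0.05) -> SDRegion:
    """Confirm an SDR against raw marker genotypes inside its window.

    ``raw_genotypes`` are dosages for all progeny at all sites;
    ``parent_genotypes`` the focal parent's dosages.  Informative raw
    markers are those inside the SDR window where the parent is
    heterozygous.  The region is confirmed when more than half of the
    informative markers reject 1:2:1 at ``alpha``; with zero informative
    markers the status is left None (unverifiable).
    """
    chrom = sites["chrom"].to_numpy()
    bp = sites["bp"].to_numpy()
    window = np.flatnonzero((chrom == sdr.chrom) & (bp >= sdr.bp_start)
                            & (bp <= sdr.bp_end))
    informative = window[parent_genotypes[window] == 1]
    rows = []
    n_sig = 0
    for s in informative:
        g = raw_genotypes[family_rows, s]
        g = g[g >= 0]
        counts = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()])
        n = counts.sum()
        if n == 0:
            continue
        exp = np.array([0.25, 0.5, 0.25]) * n
        chi2 = float(np.sum((counts - exp) ** 2 / exp))
        p = float(stats.chi2.sf(chi2, df=2))
        n_sig += p < alpha
        rows.append((int(s), *counts, chi2, p))
    detail = pd.DataFrame(rows, columns=["site", "n0", "n1", "n2", "chi2", "p"])
    if len(detail) == 0:
        sdr.confirmed = None
    else:
        sdr.confirmed = bool(n_sig / len(detail) > 0.5)
    sdr.confirm_detail = detail
    return sdr


def sdr_recombination_context(sdr: SDRegion, lmap: LinkageMap
                              ) -> tuple[float, float, float]:
    """Recombination rates: (region cM/Mb, chromosome mean, genome mean)."""
    if sdr.bp_end <= sdr.bp_start:
        raise ValueError("SDR has zero physical length")
    region = sdr.length_cM / sdr.length_Mb
    mk = lmap.markers
    def _rate(sub):
        span_bp = sub["bp"].max() - sub["bp"].min()
        span_cM = sub["cM"].max() - sub["cM"].min()
        return span_cM / (span_bp / 1e6) if span_bp > 0 else np.nan
    chrom_rate = _rate(mk[mk["chrom"] == sdr.chrom])
    genome_rate = float(np.nanmean([
        _rate(mk[mk["chrom"] == c]) for c in mk["chrom"].unique()]))
    sdr.sdr_rate = region
    sdr.chrom_rate = chrom_rate
    return region, chrom_rate, genome_rate
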