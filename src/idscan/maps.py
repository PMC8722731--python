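"""Linkage maps, genomic relationship matrices, inbreeding, and marker PCs.

The linkage map is built directly from recombinations of parental
haplotypes observed in the progeny: within 1 cM, one percent of progeny
haplotypes are expected to recombine, so scanning each chromosome we emit a
map marker whenever the cumulative count of progeny haplotypes whose
founder-haplotype identity has changed since the last emitted marker
reaches 0.01 * (2N).  Consecutive emitted markers are assigned 1 cM
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LinkageMap", "GRMPair",
    "build_linkage_map", "compute_grms", "genomic_inbreeding", "marker_pcs",
]


@dataclass
class LinkageMap:
    """Map markers: per row chrom, site index into the source site table,
    marker id, cM and bp position."""

    markers: pd.DataFrame

    def __len__(self) -> int:
        return len(self.markers)

    def site_index(self) -> np.ndarray:
        return self.markers["site"].to_numpy()

    def chrom_lengths_cM(self) -> pd.Series:
        g = self.markers.groupby("chrom")["cM"]
        return g.max() - g.min()

    def total_cM(self) -> float:
        return float(self.chrom_lengths_cM().sum())


@dataclass
class GRMPair:
    ids: list[str]
    A: np.ndarray
    D: np.ndarray


def build_linkage_map(mat_code: np.ndarray, pat_code: np.ndarray,
                      sites: pd.DataFrame, n_progeny: int | None = None,
                      max_missing: float = 0.2) -> LinkageMap:
    """Select map markers at ~1 cM intervals from phased haplotype calls.

    ``mat_code``/``pat_code`` are (progeny x site) founder-haplotype
    identities (negative values = missing).  A site becomes the next map
    marker when the number of progeny haplotypes whose identity differs from
    the last emitted marker first reaches ``0.01 * 2N``; the first site of
    each chromosome is always emitted.  The k-th marker of a chromosome sits
    at k-1 cM.
    """
    if n_progeny is None:
        n_progeny = mat_code.shape[0]
    threshold = 0.01 * 2 * n_progeny
    haps = np.vstack([mat_code, pat_code])  # (2N, S)
    miss_frac = (haps < 0).mean(axis=0)
    chrom = sites["chrom"].to_numpy()
    rows = []
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        usable = idx[miss_frac[idx] <= max_missing]
        if usable.size == 0:
            raise ValueError(f"chromosome {c}: all sites exceed missingness limit")
        anchor = usable[0]
        rows.append((int(c), int(anchor), 0.0))
        k = 1
        ref = haps[:, anchor]
        for s in usable[1:]:
            cur = haps[:, s]
            ok = (ref >= 0) & (cur >= 0)
            changed = int(np.sum((ref != cur) & ok))
            if changed >= threshold:
                rows.append((int(c), int(s), float(k)))
                k += 1
                ref = cur
                anchor = s
    markers = pd.DataFrame(rows, columns=["chrom", "site", "cM"])
    markers["marker"] = [f"m{c}_{i}" for c, i in zip(markers["chrom"], markers["site"])]
    markers["bp"] = sites["bp"].to_numpy()[markers["site"].to_numpy()]
    return LinkageMap(markers[["chrom", "marker", "site", "cM", "bp"]])


def compute_grms(genotypes: np.ndarray, allele_freqs: np.ndarray | None = None,
                 ids: list[str] | None = None,
                 method: str = "vanraden1") -> GRMPair:
    """Additive and dominance genomic relationship matrices.

    ``method='vanraden1'`` (default): centered-and-scaled cross-product,
    A = W W' / (2 * sum p q) with W = M - 2p.  ``method='yang'``: the
    per-site-standardized estimator of Yang et al. (2010), whose diagonal
    uses (g^2 - (1 + 2p) g + 2p^2) / 2pq.  D uses centered heterozygosity
    indicators, D = H H' / sum 2pq(1 - 2pq) with H = het - 2pq.
    Monomorphic sites carry no information and are dropped; if every site
    is monomorphic the scaling is degenerate and an error is raised.
    """
    M = np.asarray(genotypes, dtype=float)
    if allele_freqs is None:
        p = M.mean(axis=0) / 2.0
    else:
        p = np.asarray(allele_freqs, dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic: GRM scaling degenerate")
    M = M[:, poly]
    p = p[poly]
    q = 1.0 - p
    W = M - 2.0 * p
    if method == "vanraden1":
        A = (W @ W.T) / (2.0 * np.sum(p * q))
    elif method == "yang":
        m = p.size
        Ws = W / np.sqrt(2.0 * p * q)
        A = (Ws @ Ws.T) / m
        diag = (M ** 2 - (1.0 + 2.0 * p) * M + 2.0 * p ** 2) / (2.0 * p * q)
        np.fill_diagonal(A, 1.0 + diag.mean(axis=1))
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    het = (M == 1.0).astype(float)
    Hc = het - 2.0 * p * q
    denomD = np.sum(2.0 * p * q * (1.0 - 2.0 * p * q))
    D = (Hc @ Hc.T) / denomD
    if ids is None:
        ids = [str(i) for i in range(M.shape[0])]
    return GRMPair(ids=list(ids), A=A, D=D)


def genomic_inbreeding(grm: GRMPair) -> np.ndarray:
    """Realized inbreeding coefficient per individual, F = diag(A) - 1.

    Under the cross-product convention the expected diagonal of A is 1 + F
    relative to the base population whose allele frequencies scaled the
    matrix; subtracting 1 recovers F (0 for non-inbred, 0.5 in expectation
    after one generation of selfing)."""
    return np.diag(grm.A) - 1.0


def marker_pcs(genotypes: np.ndarray, k: int) -> tuple[pd.DataFrame, bool]:
    """First k principal-component scores of the column-centered genotypes.

    Returns (scores, padded): scores are orthogonal and ordered by variance
    explained; if k exceeds the matrix rank the extra columns are zero and
    ``padded`` is True.
    """
    M = np.asarray(genotypes, dtype=float)
    n = M.shape[0]
    if k > min(M.shape):
        raise ValueError("k exceeds matrix dimensions")
    X = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    scores = U[:, :k] * s[:k]
    padded = k > rank
    if padded:
        scores = scores.copy()
        scores[:, rank:] = 0.0
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, columns=cols), padded
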