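"""Rare allele scan (RAS): per-parent-haplotype linkage mapping.

At every linkage-map position, the scan tests the additive and dominance
effect of one founder haplotype against all other parental alleles by
ordinary least squares on top of a nuisance design (year, genomic
inbreeding with year interactions, shading, border, spatial polynomials,
and marker principal components).  Support is measured as

    LOD = (n/2) * log10(RSS0 / RSSmark)

where RSS0 comes from the covariates-only fit on the same rows.  Peaks
with LOD >= 4 become candidate QTL with 2-LOD support intervals; a forward
stepwise search over candidates, scored by BIC on a fixed set of
complete-case rows, yields the final multi-QTL model, from which per-QTL
effects, drop-one variance partitions, and the predicted contribution of
each QTL to inbreeding depression (2 F p q d with F = 0.5 and q = 1/2N)
are reported.

The scan design makes it a generalization of a standard association test:
when exactly one founder haplotype carries a biallelic site's minor
allele, the haplotype dosage equals the minor-allele dosage and the two
tests coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maps import LinkageMap

__all__ = [
    "HaplotypeDosage", "LODProfile", "QTL",
    "haplotype_dosage", "ras_scan", "declare_initial_qtl", "stepwise_select",
    "predict_qtl_inbreeding_depression", "cross_validate",
]


@dataclass
class HaplotypeDosage:
    x_ha: np.ndarray  # copies of the focal founder haplotype, 0/1/2
    x_hd: np.ndarray  # heterozygote indicator for the focal haplotype
    used: np.ndarray  # rows with a non-missing call


@dataclass
class LODProfile:
    """Scan results: one row per (parent haplotype, map marker)."""

    table: pd.DataFrame

    def for_hap(self, code: int) -> pd.DataFrame:
        return self.table[self.table["hap_code"] == code]


@dataclass
class QTL:
    parent: int
    hap: int
    chrom: int
    marker: str
    cM: float
    bp: int
    lod: float
    a: float = np.nan
    d: float = np.nan
    a_se: float = np.nan
    d_se: float = np.nan
    a_pval: float = np.nan
    d_pval: float = np.nan
    n_het: int = 0
    n_hom: int = 0
    cM_start: float = np.nan
    cM_end: float = np.nan
    bp_start: int = 0
    bp_end: int = 0
    marker_lo: int = 0   # map-row index of interval start
    marker_hi: int = 0
    r2_A: float = np.nan
    r2_D: float = np.nan
    r2_AD: float = np.nan
    a_std: float = np.nan
    d_std: float = np.nan
    delta_pred: float = np.nan

    @property
    def hap_code(self) -> int:
        return 2 * self.parent + self.hap


def qtl_table(qtls: Sequence[QTL]) -> pd.DataFrame:
    """QTL set as a flat summary table, one row per QTL."""
    rows = []
    for q in qtls:
        rows.append({
            "Marker": f"{q.marker}_P{q.parent:03d}_h{q.hap + 1}",
            "parent": q.parent, "hap": q.hap + 1, "chrom": q.chrom,
            "cM": q.cM, "pos_bp": q.bp, "LOD": q.lod,
            "r2_A": q.r2_A, "r2_D": q.r2_D, "r2_AD": q.r2_AD,
            "a_effect": q.a, "a_pval": q.a_pval,
            "d_effect": q.d, "d_pval": q.d_pval,
            "N_het": q.n_het, "N_hom": q.n_hom,
            "cM_start": q.cM_start, "cM_end": q.cM_end,
            "Pos_start": q.bp_start, "Pos_end": q.bp_end,
            "a_std": q.a_std, "d_std": q.d_std, "delta_pred": q.delta_pred,
        })
    return pd.DataFrame(rows)


def haplotype_dosage(mat_code: np.ndarray, pat_code: np.ndarray,
                     parent: int, hap: int, site: int) -> HaplotypeDosage:
    """Dosage of founder haplotype (parent, hap) at one site, per progeny."""
    code = 2 * parent + hap
    m = mat_code[:, site]
    p = pat_code[:, site]
    used = (m >= 0) & (p >= 0)
    x = (m == code).astype(np.int8) + (p == code).astype(np.int8)
    x_hd = (x == 1).astype(np.int8)
    return HaplotypeDosage(x_ha=x, x_hd=x_hd, used=used)


def _hap_codes_present(mat_code: np.ndarray, pat_code: np.ndarray) -> np.ndarray:
    codes = np.union1d(np.unique(mat_code), np.unique(pat_code))
    return codes[codes >= 0]


def _fit_marker(e_y: np.ndarray, rss0: float, Q: np.ndarray,
                x_ha: np.ndarray, x_hd: np.ndarray):
    """Add (a, d) columns to an already-QR-reduced design (Frisch-Waugh).

    Returns (rss_mark, a, d, se_a, se_d, dropped_d flag).
    """
    u1 = x_ha - Q @ (Q.T @ x_ha)
    u2 = x_hd - Q @ (Q.T @ x_hd)
    g11 = float(u1 @ u1)
    g22 = float(u2 @ u2)
    g12 = float(u1 @ u2)
    b1 = float(u1 @ e_y)
    b2 = float(u2 @ e_y)
    det = g11 * g22 - g12 * g12
    n = e_y.size
    p0 = Q.shape[1]
    if g11 <= 1e-10 * n:
        return rss0, np.nan, np.nan, np.nan, np.nan, True
    if det <= 1e-10 * max(g11 * g22, 1e-300) or g22 <= 1e-10 * n:
        # dominance column aliased with additive: drop d
        a = b1 / g11
        rss = rss0 - b1 * a
        dof = n - p0 - 1
        s2 = rss / max(dof, 1)
        return rss, a, np.nan, np.sqrt(s2 / g11), np.nan, True
    a = (g22 * b1 - g12 * b2) / det
    d = (g11 * b2 - g12 * b1) / det
    rss = rss0 - (b1 * a + b2 * d)
    dof = n - p0 - 2
    s2 = max(rss, 0.0) / max(dof, 1)
    se_a = np.sqrt(s2 * g22 / det)
    se_d = np.sqrt(s2 * g11 / det)
    return rss, a, d, se_a, se_d, False


def ras_scan(trait: np.ndarray, mat_code: np.ndarray, pat_code: np.ndarray,
             lmap: LinkageMap, covariates: np.ndarray,
             hap_codes: Optional[Sequence[int]] = None,
             min_carriers: int = 5) -> LODProfile:
    """Scan every (founder haplotype, map marker) combination.

    ``covariates`` is the full nuisance design including the intercept and
    marker principal components.  Markers where fewer than ``min_carriers``
    progeny carry the focal haplotype are skipped (LOD = NaN, reason
    recorded).  Missing haplotype calls drop the affected progeny for that
    marker only, with RSS0 recomputed on the same rows.
    """
    y = np.asarray(trait, dtype=float)
    if not np.isfinite(y).any():
        raise ValueError("trait is all-missing")
    X0 = np.asarray(covariates, dtype=float)
    n_all = y.size
    sites = lmap.site_index()
    mat = mat_code[:, sites]
    pat = pat_code[:, sites]
    if hap_codes is None:
        hap_codes = _hap_codes_present(mat, pat)

    base_rows = np.isfinite(y)
    Qb, _ = np.linalg.qr(X0[base_rows])
    yb = y[base_rows]
    e_y = yb - Qb @ (Qb.T @ yb)
    rss0_base = float(e_y @ e_y)

    records = []
    markers = lmap.markers
    for code in hap_codes:
        dos_all = (mat == code).astype(np.int8) + (pat == code).astype(np.int8)
        miss = (mat < 0) | (pat < 0)
        for j in range(len(markers)):
            dos = dos_all[:, j]
            rows = base_rows & ~miss[:, j]
            if rows.sum() < X0.shape[1] + 3:
                continue
            if rows.all() == base_rows.all() and not miss[:, j].any():
                Q, ey, rss0, yr = Qb, e_y, rss0_base, yb
                d_j = dos[base_rows]
            else:
                Q, _ = np.linalg.qr(X0[rows])
                yr = y[rows]
                ey = yr - Q @ (Q.T @ yr)
                rss0 = float(ey @ ey)
                d_j = dos[rows]
            carriers = int((d_j > 0).sum())
            n_used = d_j.size
            if carriers < min_carriers:
                records.append((int(code), j, np.nan, n_used, rss0, np.nan,
                                np.nan, np.nan, np.nan, np.nan,
                                int((d_j == 1).sum()), int((d_j == 2).sum()),
                                "too_few_carriers"))
                continue
            het = (d_j == 1).astype(float)
            rss, a, d, se_a, se_d, dropped = _fit_marker(
                ey, rss0, Q, d_j.astype(float), het)
            rss = min(rss, rss0)
            lod = (n_used / 2.0) * np.log10(rss0 / rss) if rss > 0 else np.inf
            records.append((int(code), j, lod, n_used, rss0, rss, a, d,
                            se_a, se_d, int((d_j == 1).sum()),
                            int((d_j == 2).sum()),
                            "d_dropped" if dropped else ""))
    tab = pd.DataFrame(records, columns=[
        "hap_code", "marker_row", "lod", "n", "rss0", "rss_mark",
        "a", "d", "se_a", "se_d", "n_het", "n_hom", "note"])
    tab["parent"] = tab["hap_code"] // 2
    tab["hap"] = tab["hap_code"] % 2
    mk = markers.reset_index(drop=True)
    tab = tab.join(mk[["chrom", "marker", "cM", "bp"]], on="marker_row")
    return LODProfile(tab)


def declare_initial_qtl(profile: LODProfile, lmap: LinkageMap,
                        lod_min: float = 4.0) -> list[QTL]:
    """Candidate QTL: local maxima with LOD >= lod_min and 2-LOD intervals.

    For each parent haplotype and chromosome, the highest remaining marker
    above threshold becomes a peak; its support interval is the maximal
    contiguous marker run with LOD >= peak - 2.  Other above-threshold
    markers of the same haplotype inside that interval collapse onto the
    peak; peaks outside it are declared separately.
    """
    out: list[QTL] = []
    tab = profile.table
    mk = lmap.markers.reset_index(drop=True)
    for (code, chrom), sub in tab.groupby(["hap_code", "chrom"]):
        sub = sub.sort_values("marker_row")
        lod = sub["lod"].to_numpy()
        rows = sub["marker_row"].to_numpy()
        valid = np.isfinite(lod)
        claimed = np.zeros(lod.size, dtype=bool)
        while True:
            cand = np.flatnonzero(valid & ~claimed & (lod >= lod_min))
            if cand.size == 0:
                break
            peak = cand[np.argmax(lod[cand])]
            thr = lod[peak] - 2.0
            lo = peak
            while lo > 0 and valid[lo - 1] and lod[lo - 1] >= thr:
                lo -= 1
            hi = peak
            while hi < lod.size - 1 and valid[hi + 1] and lod[hi + 1] >= thr:
                hi += 1
            claimed[lo:hi + 1] = True
            r = sub.iloc[peak]
            out.append(QTL(
                parent=int(code) // 2, hap=int(code) % 2, chrom=int(chrom),
                marker=str(r["marker"]), cM=float(r["cM"]), bp=int(r["bp"]),
                lod=float(r["lod"]), a=float(r["a"]), d=float(r["d"]),
                a_se=float(r["se_a"]), d_se=float(r["se_d"]),
                n_het=int(r["n_het"]), n_hom=int(r["n_hom"]),
                cM_start=float(mk.loc[rows[lo], "cM"]),
                cM_end=float(mk.loc[rows[hi], "cM"]),
                bp_start=int(mk.loc[rows[lo], "bp"]),
                bp_end=int(mk.loc[rows[hi], "bp"]),
                marker_lo=int(rows[lo]), marker_hi=int(rows[hi]),
            ))
    out.sort(key=lambda q: (-q.lod, q.chrom, q.cM, q.parent))
    return out


def _bic(rss: float, n: int, k: int) -> float:
    return n * np.log(rss / n) + k * np.log(n)


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss, rank


def stepwise_select(candidates: Sequence[QTL], trait: np.ndarray,
                    mat_code: np.ndarray, pat_code: np.ndarray,
                    lmap: LinkageMap, X_env: np.ndarray,
                    X_pc: Optional[np.ndarray] = None,
                    outcross_sd: Optional[float] = None,
                    n_parents: Optional[int] = None,
                    outcross_mean: Optional[float] = None) -> tuple[list[QTL], dict]:
    """Forward BIC selection over candidate QTL.

    The search starts from the most significant candidate (highest LOD;
    ties broken by chromosome, cM, parent), adds at each round the
    candidate whose (a, d) pair most decreases BIC, and stops when no
    addition improves it.  BIC is evaluated on a fixed set of complete-case
    rows so that all comparisons share the same sample.  The final joint
    model yields per-QTL effects and drop-one variance partitions against
    the PC polygenic background.
    """
    y = np.asarray(trait, dtype=float)
    if X_pc is None:
        X_pc = np.empty((y.size, 0))
    cols = {}
    rows_ok = np.isfinite(y)
    site_of = dict(zip(range(len(lmap.markers)),
                       lmap.site_index()))
    for i, q in enumerate(candidates):
        # dosage at the candidate's peak map marker
        mrow = lmap.markers.index[lmap.markers["marker"] == q.marker][0]
        s = site_of[int(mrow)]
        dd = haplotype_dosage(mat_code, pat_code, q.parent, q.hap, s)
        cols[i] = (dd.x_ha.astype(float), dd.x_hd.astype(float))
        rows_ok &= dd.used
    rows = np.flatnonzero(rows_ok)
    n = rows.size
    X_base = np.hstack([X_env[rows], X_pc[rows]])
    yb = y[rows]

    order = sorted(range(len(candidates)),
                   key=lambda i: (-candidates[i].lod, candidates[i].chrom,
                                  candidates[i].cM, candidates[i].parent))
    selected: list[int] = []
    skipped: dict[int, str] = {}
    if not order:
        return [], {"n": n, "selected": [], "skipped": skipped}

    def design(sel):
        parts = [X_base]
        for i in sel:
            parts.append(cols[i][0][rows][:, None])
            parts.append(cols[i][1][rows][:, None])
        return np.hstack(parts)

    selected = [order[0]]
    X_cur = design(selected)
    _, rss_cur, rank = _ols(X_cur, yb)
    bic_cur = _bic(rss_cur, n, X_cur.shape[1])
    remaining = [i for i in order[1:]]
    while remaining:
        best_i, best_bic, best_rss = None, bic_cur, rss_cur
        for i in remaining:
            X_try = design(selected + [i])
            _, rss, rank = _ols(X_try, yb)
            if rank < X_try.shape[1]:
                skipped[i] = "collinear"
                continue
            b = _bic(rss, n, X_try.shape[1])
            if b < best_bic - 1e-9:
                best_i, best_bic, best_rss = i, b, rss
        if best_i is None:
            break
        selected.append(best_i)
        remaining = [i for i in remaining if i != best_i and i not in skipped]
        bic_cur, rss_cur = best_bic, best_rss

    # final joint model: effects, SEs, p-values, partitions
    X_fin = design(selected)
    beta, rss_fin, _ = _ols(X_fin, yb)
    dof = n - X_fin.shape[1]
    s2 = rss_fin / max(dof, 1)
    XtX_inv = np.linalg.pinv(X_fin.T @ X_fin)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 0))
    from scipy import stats as _st
    tss = float(np.sum((yb - yb.mean()) ** 2))
    r2_full = 1.0 - rss_fin / tss

    def r2_without(drop_cols):
        keep = [j for j in range(X_fin.shape[1]) if j not in drop_cols]
        _, rss_d, _ = _ols(X_fin[:, keep], yb)
        return 1.0 - rss_d / tss

    p_base = X_base.shape[1]
    final: list[QTL] = []
    for k_i, i in enumerate(selected):
        q = candidates[i]
        ja = p_base + 2 * k_i
        jd = ja + 1
        q.a, q.d = float(beta[ja]), float(beta[jd])
        q.a_se, q.d_se = float(se[ja]), float(se[jd])
        q.a_pval = float(2 * _st.t.sf(abs(q.a / q.a_se), dof)) if q.a_se > 0 else np.nan
        q.d_pval = float(2 * _st.t.sf(abs(q.d / q.d_se), dof)) if q.d_se > 0 else np.nan
        q.r2_A = r2_full - r2_without({ja})
        q.r2_D = r2_full - r2_without({jd})
        q.r2_AD = r2_full - r2_without({ja, jd})
        if outcross_sd:
            q.a_std = q.a / outcross_sd
            q.d_std = q.d / outcross_sd
        final.append(q)
    if n_parents and outcross_mean:
        predict_qtl_inbreeding_depression(final, n_parents, outcross_mean)

    pc_cols = set(range(X_env.shape[1], p_base))
    r2_pc = r2_full - r2_without(pc_cols) if pc_cols else 0.0
    qtl_cols = set(range(p_base, X_fin.shape[1]))
    r2_qtl = r2_full - r2_without(qtl_cols) if qtl_cols else 0.0
    summary = {
        "n": n, "bic": bic_cur, "rss": rss_fin, "r2_full": r2_full,
        "r2_pc": r2_pc, "r2_qtl": r2_qtl,
        "selected": [candidates[i].marker for i in selected],
        "skipped": {candidates[i].marker: why for i, why in skipped.items()},
    }
    return final, summary


def predict_qtl_inbreeding_depression(qtls: Sequence[QTL], n_parents: int,
                                      outcross_mean: float) -> float:
    """Predicted inbreeding depression from the QTL set.

    Each QTL contributes 2 F p q d_scaled with F = 0.5 (one selfing
    generation), q = 1/(2N) for N parents (the rare allele sits on a single
    founder haplotype), p = 1 - q, and d scaled to the outcross progeny
    mean.  Contributions are stored on the QTL objects and summed.
    """
    if outcross_mean == 0:
        raise ValueError("outcross mean is zero")
    q_freq = 1.0 / (2 * n_parents)
    p_freq = 1.0 - q_freq
    total = 0.0
    for q in qtls:
        d_scaled = q.d / outcross_mean
        q.delta_pred = 2.0 * 0.5 * p_freq * q_freq * d_scaled
        total += q.delta_pred
    return total


def cross_validate(trait: np.ndarray, mat_code: np.ndarray,
                   pat_code: np.ndarray, lmap: LinkageMap,
                   X_env: np.ndarray, X_pc: np.ndarray,
                   folds: int = 10, seed: int = 0, lod_min: float = 4.0,
                   min_carriers: int = 5) -> pd.DataFrame:
    """Out-of-sample validation of the scan + stepwise pipeline.

    Individuals are split into ``folds`` folds; in each fold the whole
    pipeline (scan, declaration, stepwise) is refit on the training split
    and four models are used to predict the held-out split: covariates
    only (null), + principal components (pc), + selected QTL (qtl), and
    + both (full).  Returns one row per fold with the correlation between
    predicted and observed trait values under each model.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(trait, dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    assign[perm] = np.arange(n) % folds
    rows_out = []
    for f in range(folds):
        test = assign == f
        train = ~test
        prof = ras_scan(y[train], mat_code[train], pat_code[train], lmap,
                        np.hstack([X_env[train], X_pc[train]]),
                        min_carriers=min_carriers)
        cands = declare_initial_qtl(prof, lmap, lod_min=lod_min)
        sel, _ = stepwise_select(cands, y[train], mat_code[train],
                                 pat_code[train], lmap, X_env[train],
                                 X_pc[train])
        qtl_cols_tr, qtl_cols_te = [], []
        for q in sel:
            mrow = lmap.markers.index[lmap.markers["marker"] == q.marker][0]
            s = lmap.site_index()[int(mrow)]
            dtr = haplotype_dosage(mat_code[train], pat_code[train],
                                   q.parent, q.hap, s)
            dte = haplotype_dosage(mat_code[test], pat_code[test],
                                   q.parent, q.hap, s)
            qtl_cols_tr += [dtr.x_ha.astype(float), dtr.x_hd.astype(float)]
            qtl_cols_te += [dte.x_ha.astype(float), dte.x_hd.astype(float)]
        Qtr = np.column_stack(qtl_cols_tr) if qtl_cols_tr else np.empty((train.sum(), 0))
        Qte = np.column_stack(qtl_cols_te) if qtl_cols_te else np.empty((test.sum(), 0))
        designs = {
            "null": (X_env[train], X_env[test]),
            "pc": (np.hstack([X_env[train], X_pc[train]]),
                   np.hstack([X_env[test], X_pc[test]])),
            "qtl": (np.hstack([X_env[train], Qtr]),
                    np.hstack([X_env[test], Qte])),
            "full": (np.hstack([X_env[train], X_pc[train], Qtr]),
                     np.hstack([X_env[test], X_pc[test], Qte])),
        }
        row = {"fold": f, "n_qtl": len(sel)}
        for name, (Xtr, Xte) in designs.items():
            beta, _, _ = _ols(Xtr, y[train])
            pred = Xte @ beta
            obs = y[test]
            if np.std(pred) > 0 and np.std(obs) > 0:
                row[f"r_{name}"] = float(np.corrcoef(pred, obs)[0, 1])
            else:
                row[f"r_{name}"] = np.nan
        row["r_qtl_vs_null"] = row["r_qtl"] - row["r_null"]
        row["r_full_vs_pc"] = row["r_full"] - row["r_pc"]
        rows_out.append(row)
    return pd.DataFrame(rows_out)
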