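"""Diallel mixed models for inbreeding depression, fitted by REML.

Four nested models of a partial-diallel mating design with selfed and
outcrossed full-sib families are supported:

* model 1: GCA, S1-family, SCA effects and their year interactions, with a
  common residual variance per year;
* model 2: model 1 with residual variances separated by progeny type x year
  (inbreds may be more or less environmentally buffered than outbreds);
* model 3: model 2 plus an unconstrained covariance between a parent's
  effects on its outcrossed (GCA) and selfed (S1) progenies;
* model 4: model 3 plus reciprocal general and specific combining-ability
  effects (maternal / parent-of-origin variation).

A father's outcross effect is constrained to equal the same parent's mother
(GCA) effect.  Restricted likelihoods are computed through Henderson's
mixed-model equations, variances are log-parameterized, and the GCA-S1
covariance is free on the real line subject to positive-definiteness of
the 2x2 parent covariance block (a barrier rejects non-PD proposals, so
boundary solutions surface as near-singular fits rather than failures).
Model choice uses BIC = -2 l_R + k ln(n) with k the number of
(co)variance parameters.

From a fit, `derive_parameters` computes the additive and dominance
variances (4 sigma2_GCA, 4 sigma2_SCA), narrow-sense heritability, the
coefficient of inbreeding depression delta = 1 - selfed mean / outcross
mean, and the inbreeding covariance components sigma_ADI and sigma2_DI.
`regress_on_F` fits the companion genomic-inbreeding regression with
polygenic GRM random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .design import fixed_design

__all__ = [
    "DiallelFit", "DerivedParams", "FRegressionFit",
    "fit_diallel", "fit_all_models", "select_model",
    "derive_parameters", "regress_on_F",
]

_LARGE = 1e10


# ---------------------------------------------------------------------------
# random-term bookkeeping


@dataclass
class _Term:
    name: str
    Z: np.ndarray              # n x q incidence
    kind: str                  # "variance" | "bivariate" | "kron_year"
    n_params: int
    q: int
    Ainv: Optional[np.ndarray] = None   # parent relationship inverse (variance/bivariate)
    logdetA: float = 0.0
    n_blocks: int = 1          # kron_year: number of year copies


def _parent_Ainv(A: Optional[np.ndarray], P: int) -> tuple[np.ndarray, float]:
    if A is None:
        return np.eye(P), 0.0
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("parent relationship matrix not positive definite")
    return np.linalg.inv(A), logdet


def _build_terms(ped: pd.DataFrame, model: int, parents: list[str],
                 years: list, parent_A: Optional[np.ndarray],
                 include_gxe: bool) -> list[_Term]:
    n = len(ped)
    P = len(parents)
    pidx = {p: i for i, p in enumerate(parents)}
    yidx = {y: i for i, y in enumerate(years)}
    mother = ped["mother"].map(pidx).to_numpy()
    father = ped["father"].map(pidx).to_numpy()
    yr = ped["year"].map(yidx).to_numpy()
    selfed = ped["progeny_type"].to_numpy() == "selfed"
    out = ~selfed
    Ainv, logdetA = _parent_Ainv(parent_A, P)

    Z_gca = np.zeros((n, P))
    rows = np.flatnonzero(out)
    np.add.at(Z_gca, (rows, mother[rows]), 1.0)
    np.add.at(Z_gca, (rows, father[rows]), 1.0)
    Z_s1 = np.zeros((n, P))
    rows_s = np.flatnonzero(selfed)
    Z_s1[rows_s, mother[rows_s]] = 1.0

    pairs = sorted({tuple(sorted((m, f))) for m, f in zip(mother[out], father[out])})
    pair_idx = {pr: i for i, pr in enumerate(pairs)}
    nq = len(pairs)
    Z_sca = np.zeros((n, nq))
    for i in rows:
        Z_sca[i, pair_idx[tuple(sorted((mother[i], father[i])))]] = 1.0

    terms: list[_Term] = []
    if model >= 3:
        Zj = np.hstack([Z_gca, Z_s1])
        terms.append(_Term("parent_joint", Zj, "bivariate", 3, 2 * P,
                           Ainv=Ainv, logdetA=logdetA))
    else:
        terms.append(_Term("gca", Z_gca, "variance", 1, P, Ainv=Ainv, logdetA=logdetA))
        terms.append(_Term("s1", Z_s1, "variance", 1, P, Ainv=Ainv, logdetA=logdetA))
    if nq:
        terms.append(_Term("sca", Z_sca, "variance", 1, nq))

    ny = len(years)
    if include_gxe and ny > 1:
        Z_gxe = np.zeros((n, P * ny))
        np.add.at(Z_gxe, (rows, mother[rows] * ny + yr[rows]), 1.0)
        np.add.at(Z_gxe, (rows, father[rows] * ny + yr[rows]), 1.0)
        terms.append(_Term("gca_x_year", Z_gxe, "kron_year", 1, P * ny,
                           Ainv=Ainv, logdetA=logdetA, n_blocks=ny))
        Z_s1e = np.zeros((n, P * ny))
        Z_s1e[rows_s, mother[rows_s] * ny + yr[rows_s]] = 1.0
        terms.append(_Term("s1_x_year", Z_s1e, "kron_year", 1, P * ny,
                           Ainv=Ainv, logdetA=logdetA, n_blocks=ny))
        if nq:
            Z_se = np.zeros((n, nq * ny))
            for i in rows:
                Z_se[i, pair_idx[tuple(sorted((mother[i], father[i])))] * ny + yr[i]] = 1.0
            terms.append(_Term("sca_x_year", Z_se, "variance", 1, nq * ny))

    if model >= 4:
        Z_rg = np.zeros((n, P))
        np.add.at(Z_rg, (rows, mother[rows]), 1.0)
        np.add.at(Z_rg, (rows, father[rows]), -1.0)
        terms.append(_Term("rgca", Z_rg, "variance", 1, P))
        if nq:
            Z_rs = np.zeros((n, nq))
            for i in rows:
                pr = tuple(sorted((mother[i], father[i])))
                Z_rs[i, pair_idx[pr]] = 1.0 if mother[i] == pr[0] else -1.0
            terms.append(_Term("rsca", Z_rs, "variance", 1, nq))
            if include_gxe and ny > 1:
                Z_rse = np.zeros((n, nq * ny))
                for i in rows:
                    pr = tuple(sorted((mother[i], father[i])))
                    Z_rse[i, pair_idx[pr] * ny + yr[i]] = (
                        1.0 if mother[i] == pr[0] else -1.0)
                terms.append(_Term("rsca_x_year", Z_rse, "variance", 1, nq * ny))

    # drop terms with no loaded rows (e.g. no outcross progeny)
    terms = [t for t in terms if np.any(t.Z)]
    return terms


def _term_Ginv(t: _Term, pars: np.ndarray) -> tuple[np.ndarray, float]:
    """(G^{-1}, log|G|) for one random term given its parameter slice."""
    if t.kind == "variance":
        v = pars[0]
        if t.Ainv is not None and t.Ainv.shape[0] == t.q:
            return t.Ainv / v, t.q * np.log(v) + t.logdetA
        return np.eye(t.q) / v, t.q * np.log(v) + t.logdetA
    if t.kind == "kron_year":
        v = pars[0]
        P = t.q // t.n_blocks
        Ainv = t.Ainv if t.Ainv is not None else np.eye(P)
        Ginv = np.kron(Ainv, np.eye(t.n_blocks)) / v
        return Ginv, t.q * np.log(v) + t.n_blocks * t.logdetA
    if t.kind == "bivariate":
        v1, v2, c = pars
        S = np.array([[v1, c], [c, v2]])
        det = v1 * v2 - c * c
        if det <= 1e-12 * max(v1 * v2, 1e-300) or v1 <= 0 or v2 <= 0:
            raise FloatingPointError("parent covariance block not PD")
        Sinv = np.array([[v2, -c], [-c, v1]]) / det
        P = t.q // 2
        Ainv = t.Ainv if t.Ainv is not None else np.eye(P)
        Ginv = np.kron(Sinv, Ainv)
        logG = P * np.log(det) + 2 * t.logdetA
        return Ginv, logG
    raise ValueError(t.kind)


# ---------------------------------------------------------------------------
# REML core via mixed-model equations


class _MME:
    """Precomputed Gram blocks for fast restricted-likelihood evaluation."""

    def __init__(self, X: np.ndarray, terms: list[_Term], y: np.ndarray,
                 resid_groups: list[np.ndarray]):
        self.p = X.shape[1]
        self.terms = terms
        self.q = sum(t.q for t in terms)
        W = np.hstack([X] + [t.Z for t in terms])
        self.W = W
        self.y = y
        self.groups = resid_groups
        self.M = [W[g].T @ W[g] for g in resid_groups]
        self.v = [W[g].T @ y[g] for g in resid_groups]
        self.s = [float(y[g] @ y[g]) for g in resid_groups]
        self.ng = [len(g) for g in resid_groups]
        self.n = len(y)

    def neg2_reml(self, resid_vars: np.ndarray, term_pars: list[np.ndarray],
                  want_solution: bool = False):
        p, q = self.p, self.q
        C = np.zeros((p + q, p + q))
        rhs = np.zeros(p + q)
        val = 0.0
        for Mg, vg, sg, ng, rv in zip(self.M, self.v, self.s, self.ng, resid_vars):
            w = 1.0 / rv
            C += w * Mg
            rhs += w * vg
            val += ng * np.log(rv)
        ypy0 = sum(sg / rv for sg, rv in zip(self.s, resid_vars))
        off = p
        for t, pars in zip(self.terms, term_pars):
            Ginv, logG = _term_Ginv(t, pars)
            C[off:off + t.q, off:off + t.q] += Ginv
            val += logG
            off += t.q
        cf = linalg.cho_factor(C, lower=True, check_finite=False)
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        ypy = ypy0 - float(rhs @ sol)
        val += logdetC + ypy
        if want_solution:
            Cinv = linalg.cho_solve(cf, np.eye(p + q), check_finite=False)
            return val, sol, Cinv
        return val


def _pack(terms: list[_Term]) -> list[tuple[int, str]]:
    """Layout of the term-parameter vector: (n_params, kind) per term."""
    return [(t.n_params, t.kind) for t in terms]


def _unpack_params(x: np.ndarray, n_resid: int, layout) -> tuple[np.ndarray, list[np.ndarray]]:
    resid = np.exp(x[:n_resid])
    pars = []
    off = n_resid
    for npar, kind in layout:
        if kind == "bivariate":
            v1, v2 = np.exp(x[off]), np.exp(x[off + 1])
            c = x[off + 2]
            pars.append(np.array([v1, v2, c]))
        else:
            pars.append(np.exp(x[off:off + npar]))
        off += npar
    return resid, pars


@dataclass
class DiallelFit:
    model: int
    varcomps: dict
    varcomp_se: dict
    loglik: float            # restricted log-likelihood (up to a constant)
    bic: float
    n: int
    k: int
    converged: bool
    beta: pd.Series
    gca_blup: pd.Series
    s1_blup: pd.Series
    sca_blup: pd.Series
    outcross_mean: float
    selfed_mean: float
    parents: list[str] = field(default_factory=list)
    theta_internal: Optional[np.ndarray] = None

    def summary(self) -> pd.DataFrame:
        rows = [(k, v, self.varcomp_se.get(k, np.nan)) for k, v in self.varcomps.items()]
        return pd.DataFrame(rows, columns=["component", "estimate", "se"])


def _resid_groups(ped: pd.DataFrame, model: int, years: list) -> tuple[list[np.ndarray], list[str]]:
    yr = ped["year"].to_numpy()
    if model == 1:
        labels = [f"resid[{y}]" for y in years]
        groups = [np.flatnonzero(yr == y) for y in years]
    else:
        t = np.where(ped["progeny_type"].to_numpy() == "selfed", "S", "O")
        labels, groups = [], []
        for y in years:
            for tt in ("O", "S"):
                g = np.flatnonzero((yr == y) & (t == tt))
                if g.size:
                    labels.append(f"resid[{tt},{y}]")
                    groups.append(g)
    keep = [i for i, g in enumerate(groups) if g.size]
    return [groups[i] for i in keep], [labels[i] for i in keep]


_VC_NAMES = {
    "gca": ["sigma2_GCA"], "s1": ["sigma2_S1"], "sca": ["sigma2_SCA"],
    "parent_joint": ["sigma2_GCA", "sigma2_S1", "cov_GCA_S1"],
    "gca_x_year": ["sigma2_GCAxE"], "s1_x_year": ["sigma2_S1xE"],
    "sca_x_year": ["sigma2_SCAxE"], "rgca": ["sigma2_RGCA"],
    "rsca": ["sigma2_RSCA"], "rsca_x_year": ["sigma2_RSCAxE"],
}


def fit_diallel(phenotypes: pd.DataFrame, model: int = 2,
                parent_A: Optional[np.ndarray] = None,
                parents: Optional[list[str]] = None,
                include_gxe: bool = True,
                trait: str = "trait",
                start: Optional[np.ndarray] = None,
                compute_se: bool = True,
                n_starts: int = 2) -> DiallelFit:
    """REML fit of one diallel model (1-4).

    ``phenotypes`` must carry id, mother, father, progeny_type, year, the
    trait column, and any field covariates (shading, border, row, col).
    """
    if model not in (1, 2, 3, 4):
        raise ValueError("model must be 1..4")
    ped = phenotypes
    n_self_fam = ped.loc[ped.progeny_type == "selfed", "mother"].nunique()
    n_out_fam = ped.loc[ped.progeny_type == "outcrossed", ["mother", "father"]]
    if n_self_fam < 2 or (len(n_out_fam) and
                          n_out_fam.apply(tuple, axis=1).nunique() < 2):
        raise ValueError("need at least 2 selfed and 2 outcross families")
    if parents is None:
        parents = sorted(set(ped["mother"]) | set(ped["father"]))
    years = sorted(pd.unique(ped["year"]))
    y = ped[trait].to_numpy(dtype=float)
    X, xnames = fixed_design(ped, include_type=True)
    terms = _build_terms(ped, model, parents, years, parent_A, include_gxe)
    groups, glabels = _resid_groups(ped, model, years)
    mme = _MME(X, terms, y, groups)
    layout = _pack(terms)
    n_resid = len(groups)
    n_par = n_resid + sum(t.n_params for t in terms)

    def objective(x):
        try:
            with np.errstate(invalid="ignore", over="ignore"):
                resid, pars = _unpack_params(x, n_resid, layout)
                if np.any(~np.isfinite(resid)):
                    return _LARGE
                return mme.neg2_reml(resid, pars)
        except (FloatingPointError, np.linalg.LinAlgError, linalg.LinAlgError):
            return _LARGE

    # starting values
    beta0, res0, *_ = np.linalg.lstsq(X, y, rcond=None)
    vtot = float(np.var(y - X @ beta0)) or 1.0
    starts = []
    if start is not None:
        starts.append(np.asarray(start, dtype=float))
        n_starts = max(n_starts, 1)
    base = np.full(n_par, np.log(vtot / (2 + len(terms))))
    off = n_resid
    for npar, kind in layout:
        if kind == "bivariate":
            base[off + 2] = 0.0
        off += npar
    starts.append(base)
    alt = base.copy()
    alt[:n_resid] = np.log(0.9 * vtot)
    alt[n_resid:] = np.log(0.05 * vtot)
    off = n_resid
    for npar, kind in layout:
        if kind == "bivariate":
            alt[off + 2] = 0.0
        off += npar
    starts.append(alt)

    best = None
    for x0 in starts[:max(n_starts, 1 if start is not None else 0) + (1 if start is not None else 0)]:
        r = optimize.minimize(objective, x0, method="L-BFGS-B")
        if best is None or r.fun < best.fun:
            best = r
    if best.fun >= _LARGE / 2:  # barrier region: fall back to a direct search
        for x0 in starts:
            r = optimize.minimize(objective, x0, method="Nelder-Mead",
                                  options={"maxiter": 400 * n_par,
                                           "xatol": 1e-6, "fatol": 1e-8})
            if r.fun < best.fun:
                best = r
    r2 = optimize.minimize(objective, best.x, method="Nelder-Mead",
                           options={"maxiter": 60 * n_par, "xatol": 1e-7,
                                    "fatol": 1e-9})
    if r2.fun <= best.fun:
        best = r2
    converged = bool(best.fun < _LARGE / 2)
    xhat = best.x
    resid, pars = _unpack_params(xhat, n_resid, layout)
    neg2, sol, Cinv = mme.neg2_reml(resid, pars, want_solution=True)

    # collect named components
    varcomps: dict = {}
    for lab, v in zip(glabels, resid):
        varcomps[lab] = float(v)
    for t, pv in zip(terms, pars):
        for nm, v in zip(_VC_NAMES[t.name], pv):
            varcomps[nm] = float(v)

    # delta-method SEs from a numeric Hessian on the natural scale
    varcomp_se = {k: np.nan for k in varcomps}
    if compute_se and converged:
        theta = np.concatenate([resid] + list(pars))
        names_nat = list(glabels) + [nm for t in terms for nm in _VC_NAMES[t.name]]

        def obj_nat(th):
            rv = th[:n_resid]
            if np.any(rv <= 0):
                return _LARGE
            off = n_resid
            pv = []
            for npar, kind in layout:
                chunk = th[off:off + npar]
                # variance entries must stay positive (covariance is free)
                n_var = 2 if kind == "bivariate" else npar
                if np.any(chunk[:n_var] <= 0):
                    return _LARGE
                pv.append(chunk)
                off += npar
            try:
                return mme.neg2_reml(rv, pv)
            except (FloatingPointError, np.linalg.LinAlgError, linalg.LinAlgError):
                return _LARGE

        H = _numeric_hessian(obj_nat, theta)
        try:
            cov = 2.0 * np.linalg.inv(H)  # inverse observed information of l_R
            d = np.diag(cov)
            for nm, vv in zip(names_nat, d):
                varcomp_se[nm] = float(np.sqrt(vv)) if vv > 0 else np.nan
        except np.linalg.LinAlgError:
            pass

    p = X.shape[1]
    beta = pd.Series(sol[:p], index=xnames)
    off = p
    blups = {}
    for t in terms:
        blups[t.name] = sol[off:off + t.q]
        off += t.q
    P = len(parents)
    if model >= 3 and "parent_joint" in blups:
        gca = blups["parent_joint"][:P]
        s1 = blups["parent_joint"][P:2 * P]
    else:
        gca = blups.get("gca", np.zeros(P))
        s1 = blups.get("s1", np.zeros(P))
    sca = blups.get("sca", np.zeros(0))

    # marginal progeny-type means at common fixed-effect values
    mean_row = _mean_design_row(ped, xnames, selfed=False)
    mean_row_s = _mean_design_row(ped, xnames, selfed=True)
    out_mean = float(mean_row @ beta.to_numpy())
    self_mean = float(mean_row_s @ beta.to_numpy())

    k = n_par
    bic = neg2 + k * np.log(len(y))
    return DiallelFit(
        model=model, varcomps=varcomps, varcomp_se=varcomp_se,
        loglik=-0.5 * neg2, bic=bic, n=len(y), k=k, converged=converged,
        beta=beta,
        gca_blup=pd.Series(gca, index=parents),
        s1_blup=pd.Series(s1, index=parents),
        sca_blup=pd.Series(sca),
        outcross_mean=out_mean, selfed_mean=self_mean,
        parents=list(parents), theta_internal=xhat,
    )


def _mean_design_row(ped: pd.DataFrame, xnames: list[str], selfed: bool) -> np.ndarray:
    """Prediction row: covariates at observed means, years equally weighted."""
    years = sorted(pd.unique(ped["year"]))
    ny = len(years)
    row = np.zeros(len(xnames))
    for j, nm in enumerate(xnames):
        if nm == "intercept":
            row[j] = 1.0
        elif nm.startswith("year["):
            row[j] = 1.0 / ny
        elif nm.startswith("type[selfed]:year["):
            row[j] = (1.0 / ny) if selfed else 0.0
        elif nm == "type[selfed]":
            row[j] = 1.0 if selfed else 0.0
        elif nm == "shading":
            row[j] = float(ped["shading"].mean())
        elif nm.startswith("border:"):
            row[j] = float(ped["border"].mean()) / ny
        elif ":" in nm and ("row^" in nm or "col^" in nm):
            base, _ = nm.split(":")
            axis, pw = base.split("^")
            row[j] = float((ped[axis] ** int(pw)).mean()) / ny
    return row


def _numeric_hessian(f, x0: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    n = x0.size
    h = np.maximum(np.abs(x0) * rel, 1e-6)
    H = np.zeros((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            xi, xj = np.zeros(n), np.zeros(n)
            xi[i] = h[i]
            xj[j] = h[j]
            fpp = f(x0 + xi + xj)
            fpm = f(x0 + xi - xj)
            fmp = f(x0 - xi + xj)
            fmm = f(x0 - xi - xj)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return 0.5 * H  # hessian of l_R-scale: f is -2 l_R


def fit_all_models(phenotypes: pd.DataFrame, models: Sequence[int] = (1, 2, 3, 4),
                   **kwargs) -> list[DiallelFit]:
    """Fit a nested sequence, warm-starting each model from the previous fit."""
    fits = []
    prev: Optional[DiallelFit] = None
    for m in sorted(models):
        start = None
        if prev is not None:
            start = _promote_start(prev, m, phenotypes, **kwargs)
        fits.append(fit_diallel(phenotypes, model=m, start=start, **kwargs))
        prev = fits[-1]
    return fits


def _promote_start(prev: DiallelFit, model: int, ped: pd.DataFrame, **kwargs):
    """Map a simpler model's estimates onto the next model's parameter vector."""
    vc = prev.varcomps
    years = sorted(pd.unique(ped["year"]))
    groups, glabels = _resid_groups(ped, model, years)
    resid = []
    for lab in glabels:
        if lab in vc:
            resid.append(vc[lab])
        else:
            # split model-1 per-year residual into type x year cells
            y = lab.split(",")[-1].rstrip("]")
            resid.append(vc.get(f"resid[{y}]", np.mean(list(vc.values()))))
    parents = kwargs.get("parents") or sorted(set(ped["mother"]) | set(ped["father"]))
    include_gxe = kwargs.get("include_gxe", True)
    terms = _build_terms(ped, model, parents, years, kwargs.get("parent_A"), include_gxe)
    x = list(np.log(np.maximum(resid, 1e-8)))
    for t in terms:
        if t.kind == "bivariate":
            x += [np.log(max(vc.get("sigma2_GCA", 0.1), 1e-8)),
                  np.log(max(vc.get("sigma2_S1", 0.1), 1e-8)),
                  vc.get("cov_GCA_S1", 0.0)]
        else:
            nm = _VC_NAMES[t.name][0]
            x.append(np.log(max(vc.get(nm, 0.05), 1e-8)))
    return np.array(x)


def select_model(fits: Sequence[DiallelFit]) -> DiallelFit:
    """Minimum-BIC fit; ties (and near-ties within 1e-6) go to the simpler model."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to select from")
    ok = sorted(ok, key=lambda f: f.model)
    best = ok[0]
    for f in ok[1:]:
        if f.bic < best.bic - 1e-6:
            best = f
    return best


@dataclass
class DerivedParams:
    sigma2_A: float
    sigma2_D: float
    h2: float
    delta: float
    sigma_ADI: float
    sigma2_DI: float
    s1_var_ratio: float
    r_s0s1: float
    significant: dict

    def as_series(self) -> pd.Series:
        return pd.Series({
            "Additive": self.sigma2_A, "Dominance": self.sigma2_D,
            "h2": self.h2, "ID_perc": 100.0 * self.delta,
            "sigma_ADI": self.sigma_ADI, "sigma2_DI": self.sigma2_DI,
            "S1_var_ratio": self.s1_var_ratio, "rS0S1": self.r_s0s1,
        })


def derive_parameters(fit: DiallelFit) -> DerivedParams:
    """Quantitative-genetic quantities from a converged diallel fit.

    sigma2_A = 4 sigma2_GCA, sigma2_D = 4 sigma2_SCA;
    h2 = sigma2_A / (0.5 sigma2_A + 0.25 sigma2_D + 2 sigma2_GCAxE
                     + sigma2_SCAxE + mean outcross residual);
    delta = 1 - selfed mean / outcross mean;
    sigma_ADI = 4 (Cov(GCA,S1) - 0.5 sigma2_A);
    sigma2_DI = 8 (sigma2_S1 - 4 Cov(GCA,S1) + sigma2_A - 0.25 sigma2_D).
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    vc = fit.varcomps
    s2A = 4.0 * vc.get("sigma2_GCA", 0.0)
    s2D = 4.0 * vc.get("sigma2_SCA", 0.0)
    out_resid = [v for k, v in vc.items()
                 if k.startswith("resid[O") or
                 (k.startswith("resid[") and "," not in k)]
    mean_resid = float(np.mean(out_resid)) if out_resid else np.nan
    denom = (0.5 * s2A + 0.25 * s2D + 2.0 * vc.get("sigma2_GCAxE", 0.0)
             + vc.get("sigma2_SCAxE", 0.0) + mean_resid)
    h2 = s2A / denom if denom else np.nan
    if fit.outcross_mean == 0:
        raise ValueError("outcross marginal mean is zero: delta undefined")
    delta = 1.0 - fit.selfed_mean / fit.outcross_mean
    cov = vc.get("cov_GCA_S1", np.nan)
    s2S1 = vc.get("sigma2_S1", np.nan)
    sigma_ADI = 4.0 * (cov - 0.5 * s2A) if np.isfinite(cov) else np.nan
    sigma2_DI = (8.0 * (s2S1 - 4.0 * cov + s2A - 0.25 * s2D)
                 if np.isfinite(cov) else np.nan)
    expected_s1 = s2A + 0.25 * s2D
    ratio = s2S1 / expected_s1 if expected_s1 > 0 else np.nan
    g, s = fit.gca_blup.to_numpy(), fit.s1_blup.to_numpy()
    if np.std(g) > 0 and np.std(s) > 0:
        r = float(np.corrcoef(g, s)[0, 1])
    else:
        r = np.nan
    sig = {}
    for nm in ("sigma2_GCA", "sigma2_S1", "sigma2_SCA", "cov_GCA_S1"):
        est, se = vc.get(nm), fit.varcomp_se.get(nm)
        if est is not None and se is not None and np.isfinite(se):
            sig[nm] = bool(abs(est) > 2 * se)
    return DerivedParams(s2A, s2D, h2, delta, sigma_ADI, sigma2_DI, ratio, r, sig)


# ---------------------------------------------------------------------------
# regression on the genomic inbreeding coefficient


@dataclass
class FRegressionFit:
    beta_F: float                 # main effect + mean year interaction
    beta_F_terms: pd.Series
    p_F: float
    beta_F2: Optional[float]
    p_F2: Optional[float]
    varcomps: dict
    loglik: float
    n: int
    beta: pd.Series


def _v_based_reml(y, X, Vparts, resid_groups):
    """Restricted likelihood with dense covariance V = sum v_i Vparts_i + R."""
    n = len(y)
    n_resid = len(resid_groups)
    kv = len(Vparts)
    masks = [np.zeros(n) for _ in resid_groups]
    for m, g in zip(masks, resid_groups):
        m[g] = 1.0

    def neg2(x):
        rv = np.exp(x[:n_resid])
        vs = np.exp(x[n_resid:])
        V = np.zeros((n, n))
        for v, Vp in zip(vs, Vparts):
            V += v * Vp
        d = np.zeros(n)
        for m, r in zip(masks, rv):
            d += m * r
        V[np.diag_indices(n)] += d
        try:
            cf = linalg.cho_factor(V, lower=True, check_finite=False)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return _LARGE
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi_y = linalg.cho_solve(cf, y, check_finite=False)
        Vi_X = linalg.cho_solve(cf, X, check_finite=False)
        XtViX = X.T @ Vi_X
        try:
            cfx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return _LARGE
        logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        beta = linalg.cho_solve(cfx, X.T @ Vi_y, check_finite=False)
        ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
        return logdetV + logdetX + ypy

    return neg2, kv + n_resid


def regress_on_F(phenotypes: pd.DataFrame, F: np.ndarray, grms,
                 quadratic: bool = False, trait: str = "trait") -> FRegressionFit:
    """Mixed-model regression of trait values on genomic inbreeding.

    Fixed effects: the field covariates of diallel model 1 minus the
    progeny-type terms, plus F and its year interactions (and the squared
    coefficient, negatives floored at zero before squaring, if
    ``quadratic``).  Random effects: polygenic additive (GRM A), dominance
    (GRM D), and a year-block-diagonal additive G x E term.  Residual
    variance is separate per year.  Returns the reported slope (main effect
    plus the average of its year interactions) and conditional Wald F-test
    p-values.
    """
    ped = phenotypes
    n = len(ped)
    F = np.asarray(F, dtype=float)
    if F.shape[0] != n:
        raise ValueError("F not aligned with phenotypes")
    years = sorted(pd.unique(ped["year"]))
    yr = ped["year"].to_numpy()
    extra = {"F": F}
    for y in years[1:]:
        extra[f"F:year[{y}]"] = F * (yr == y)
    if quadratic:
        F2 = np.where(F > 0, F, 0.0) ** 2
        if np.ptp(F2) == 0 or np.linalg.matrix_rank(np.column_stack([F, F2])) < 2:
            raise ValueError("F and F^2 collinear: no inbreeding variation")
        extra["F2"] = F2
        for y in years[1:]:
            extra[f"F2:year[{y}]"] = F2 * (yr == y)
    X, xnames = fixed_design(ped, include_type=False, extra=extra)
    y_vec = ped[trait].to_numpy(dtype=float)

    A, D = grms.A, grms.D
    Ablock = np.zeros_like(A)
    for yv in years:
        g = np.flatnonzero(yr == yv)
        Ablock[np.ix_(g, g)] = A[np.ix_(g, g)]
    groups = [np.flatnonzero(yr == yv) for yv in years]
    neg2, n_par = _v_based_reml(y_vec, X, [A, D, Ablock], groups)
    vtot = float(np.var(y_vec - X @ np.linalg.lstsq(X, y_vec, rcond=None)[0])) or 1.0
    x0 = np.log(np.full(n_par, vtot / n_par))
    best = optimize.minimize(neg2, x0, method="L-BFGS-B")
    if best.fun >= _LARGE / 2:
        best = optimize.minimize(neg2, x0, method="Nelder-Mead",
                                 options={"maxiter": 300 * n_par, "xatol": 1e-6,
                                          "fatol": 1e-8})
    x = best.x
    rv = np.exp(x[:len(groups)])
    vs = np.exp(x[len(groups):])
    V = vs[0] * A + vs[1] * D + vs[2] * Ablock
    d = np.zeros(n)
    for g, r in zip(groups, rv):
        d[g] = r
    V[np.diag_indices(n)] += d
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    Vi_X = linalg.cho_solve(cf, X, check_finite=False)
    XtViX = X.T @ Vi_X
    covb = np.linalg.inv(XtViX)
    beta = covb @ (Vi_X.T @ y_vec)
    beta_s = pd.Series(beta, index=xnames)

    def wald(prefix_exact: str, prefix_int: str):
        idx = [i for i, nm in enumerate(xnames)
               if nm == prefix_exact or nm.startswith(prefix_int)]
        if not idx:
            return np.nan, np.nan
        L = np.zeros((len(idx), len(xnames)))
        for r_, i in enumerate(idx):
            L[r_, i] = 1.0
        Lb = L @ beta
        M = L @ covb @ L.T
        stat = float(Lb @ np.linalg.solve(M, Lb)) / len(idx)
        df2 = n - len(xnames)
        return stat, float(stats.f.sf(stat, len(idx), df2))

    _, p_F = wald("F", "F:year[")
    f_terms = {nm: beta_s[nm] for nm in xnames if nm == "F" or nm.startswith("F:year[")}
    ints = [beta_s.get(f"F:year[{y}]", 0.0) for y in years]
    ints[0] = 0.0  # reference year
    slope = float(beta_s["F"] + np.mean(ints))
    beta_F2 = p_F2 = None
    if quadratic:
        _, p_F2 = wald("F2", "F2:year[")
        ints2 = [beta_s.get(f"F2:year[{y}]", 0.0) for y in years]
        ints2[0] = 0.0
        beta_F2 = float(beta_s["F2"] + np.mean(ints2))
    varcomps = {"sigma2_A": float(vs[0]), "sigma2_D": float(vs[1]),
                "sigma2_AxE": float(vs[2])}
    for yv, r in zip(years, rv):
        varcomps[f"resid[{yv}]"] = float(r)
    return FRegressionFit(
        beta_F=slope, beta_F_terms=pd.Series(f_terms), p_F=p_F,
        beta_F2=beta_F2, p_F2=p_F2, varcomps=varcomps,
        loglik=-0.5 * best.fun, n=n, beta=beta_s,
    )
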