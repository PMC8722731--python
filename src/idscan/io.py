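"""Readers and writers for the package's on-disk interchange formats.

Founder genomes travel as VCF (phased GT, ancestral allele and
conservation score as INFO keys AA and GERP), progeny haplotype calls as
long-format TSV, linkage maps / phenotypes / pedigrees as TSV/CSV, and
simulation truth as JSON.  VCF handling goes through pysam.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .maps import GRMPair, LinkageMap
from .simulate import FounderGenome

__all__ = [
    "write_founders_vcf", "read_founders_vcf",
    "write_haplotype_calls", "read_haplotype_calls",
    "write_map", "read_map", "write_grm", "read_grm",
    "write_truth_json",
]


def write_founders_vcf(founders: FounderGenome, path: str | Path) -> None:
    """Founder haplotypes as a phased VCF with AA and GERP INFO fields."""
    header = pysam.VariantHeader()
    header.add_meta("source", "idscan-simulated")
    sites = founders.sites
    for c in sorted(sites["chrom"].unique()):
        length = int(sites.loc[sites["chrom"] == c, "bp"].max()) + 1000
        header.contigs.add(str(c), length=length)
    header.info.add("AA", 1, "String", "Ancestral allele")
    header.info.add("GERP", 1, "Float", "Conservation score")
    header.info.add("CM", 1, "Float", "Genetic map position (cM)")
    header.formats.add("GT", 1, "String", "Genotype")
    for p in founders.parent_ids:
        header.add_sample(p)
    haps = founders.haplotypes
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in range(len(sites)):
            row = sites.iloc[s]
            rec = vcf.new_record(
                contig=str(int(row["chrom"])), start=int(row["bp"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            rec.info["AA"] = str(row["anc"])
            if np.isfinite(row["gerp"]):
                rec.info["GERP"] = float(row["gerp"])
            rec.info["CM"] = float(row["cM"])
            for i in range(founders.n_parents):
                rec.samples[i]["GT"] = (int(haps[i, 0, s]), int(haps[i, 1, s]))
                rec.samples[i].phased = True
            vcf.write(rec)


def read_founders_vcf(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a phased founder VCF back into (sites, haplotypes, parent ids)."""
    rows, gts = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            gerp = rec.info.get("GERP")
            rows.append({
                "chrom": int(rec.contig), "bp": rec.pos,
                "cM": float(rec.info.get("CM", np.nan)),
                "ref": rec.ref, "alt": rec.alts[0],
                "anc": rec.info.get("AA", rec.ref),
                "gerp": float(gerp) if gerp is not None else np.nan,
            })
            gts.append([rec.samples[s]["GT"] for s in samples])
    sites = pd.DataFrame(rows)
    haps = np.array(gts, dtype=np.uint8)          # sites x parents x 2
    haps = np.transpose(haps, (1, 2, 0))          # parents x 2 x sites
    return sites, haps, samples


def write_haplotype_calls(mat_code: np.ndarray, pat_code: np.ndarray,
                          sites: pd.DataFrame, ids, path: str | Path) -> None:
    """Long-format TSV: individual, chrom, marker index, inherited haplotype
    codes (2*parent + hap; -1 = missing)."""
    n, S = mat_code.shape
    df = pd.DataFrame({
        "individual": np.repeat(list(ids), S),
        "chrom": np.tile(sites["chrom"].to_numpy(), n),
        "marker": np.tile(np.arange(S), n),
        "maternal_founder_hap": mat_code.ravel(),
        "paternal_founder_hap": pat_code.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def read_haplotype_calls(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    ids = list(pd.unique(df["individual"]))
    S = df["marker"].max() + 1
    mat = df["maternal_founder_hap"].to_numpy().reshape(len(ids), S)
    pat = df["paternal_founder_hap"].to_numpy().reshape(len(ids), S)
    return mat.astype(np.int32), pat.astype(np.int32), ids


def write_map(lmap: LinkageMap, path: str | Path) -> None:
    lmap.markers.to_csv(path, sep="\t", index=False)


def read_map(path: str | Path) -> LinkageMap:
    return LinkageMap(pd.read_csv(path, sep="\t"))


def write_grm(grm: GRMPair, path_a: str | Path, path_d: str | Path | None = None) -> None:
    """Matrices as TSV with an id header row/column (gzip if path ends .gz)."""
    a = pd.DataFrame(grm.A, index=grm.ids, columns=grm.ids)
    a.to_csv(path_a, sep="\t")
    if path_d is not None:
        pd.DataFrame(grm.D, index=grm.ids, columns=grm.ids).to_csv(path_d, sep="\t")


def read_grm(path_a: str | Path, path_d: str | Path | None = None) -> GRMPair:
    a = pd.read_csv(path_a, sep="\t", index_col=0)
    d = (pd.read_csv(path_d, sep="\t", index_col=0).to_numpy()
         if path_d is not None else np.zeros_like(a.to_numpy()))
    return GRMPair(ids=list(a.index), A=a.to_numpy(), D=d)


def write_diallel_report(fit, derived, path_json: str | Path,
                         path_blups: str | Path | None = None) -> None:
    """Fit report as JSON (variance components, SEs, BIC, marginal means,
    derived parameters) plus an optional per-parent BLUP CSV."""
    payload = {
        "model": fit.model, "n": fit.n, "k": fit.k, "bic": fit.bic,
        "loglik": fit.loglik, "converged": fit.converged,
        "varcomps": fit.varcomps, "varcomp_se": fit.varcomp_se,
        "S0_mean": fit.outcross_mean, "S1_mean": fit.selfed_mean,
        "ID_perc": 100.0 * derived.delta, "Additive": derived.sigma2_A,
        "Dominance": derived.sigma2_D, "h2": derived.h2,
        "rS0S1": derived.r_s0s1, "sigma_ADI": derived.sigma_ADI,
        "sigma2_DI": derived.sigma2_DI,
        "S1_var_ratio": derived.s1_var_ratio,
    }
    Path(path_json).write_text(json.dumps(payload, indent=2, default=float))
    if path_blups is not None:
        pd.DataFrame({"parent": fit.parents,
                      "gca": fit.gca_blup.to_numpy(),
                      "s1": fit.s1_blup.to_numpy()}).to_csv(path_blups,
                                                            index=False)


def write_truth_json(truth, path: str | Path) -> None:
    payload = {
        "expected_delta": truth.expected_delta,
        "expected_outcross_mean": truth.expected_outcross_mean,
        "sigma2_A": truth.sigma2_A,
        "sigma2_D": truth.sigma2_D,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
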