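"""Segregation-distortion scan: chi-square closed form, ENT estimators
against an eigen oracle, run-length calling, raw-marker confirmation,
recombination context."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard

from idscan import (
    ENTResult, LethalSpec, SimulationConfig, RateSegment, call_sdr,
    confirm_sdr, effective_number_of_tests, family_segregation_scan,
    sdr_recombination_context, simulate_population,
)
from idscan.maps import LinkageMap
from idscan.segdist import FamilyScan, SDRegion


def _map_for(n, chrom=0, bp_step=10 ** 6):
    return LinkageMap(pd.DataFrame({
        "chrom": chrom, "marker": [f"m{chrom}_{i}" for i in range(n)],
        "site": np.arange(n), "cM": np.arange(n, dtype=float),
        "bp": (np.arange(n) + 1) * bp_step,
    }))


def _family_codes(counts_by_marker):
    """Build selfed-family haplotype calls (parent 0) realizing the given
    per-marker genotype counts (n_h1h1, n_h1h2, n_h2h2)."""
    n = sum(counts_by_marker[0])
    S = len(counts_by_marker)
    mat = np.zeros((n, S), dtype=np.int32)
    pat = np.zeros((n, S), dtype=np.int32)
    for s, (n11, n12, n22) in enumerate(counts_by_marker):
        # h1 code = 0, h2 code = 1
        mat[:, s] = [0] * n11 + [0] * n12 + [1] * n22
        pat[:, s] = [0] * n11 + [1] * n12 + [1] * n22
    return mat, pat


class TestChiSquare:
    @pytest.mark.parametrize("counts,chi2,p", [
        ((10, 20, 10), 0.0, 1.0),
        ((0, 20, 20), 20.0, np.exp(-10.0)),
        ((5, 30, 5), 10.0, np.exp(-5.0)),
    ])
    def test_against_closed_form_tail(self, counts, chi2, p):
        # chi2 with 2 df has survival function exp(-x/2)
        mat, pat = _family_codes([counts])
        scan = family_segregation_scan(mat, pat, np.arange(mat.shape[0]), 0,
                                       _map_for(1), "fam")
        row = scan.table.iloc[0]
        assert row["chi2"] == pytest.approx(chi2, abs=1e-12)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_family_below_minimum_size_rejected(self):
        mat, pat = _family_codes([(2, 4, 2)])
        with pytest.raises(ValueError, match="below minimum"):
            family_segregation_scan(mat, pat, np.arange(8), 0, _map_for(1))


class TestENT:
    def test_orthogonal_markers_count_fully(self):
        # Hadamard columns are exactly orthogonal: correlation = identity
        H = hadamard(32).astype(float)
        G = H[:, 1:31]  # 30 mean-zero orthogonal columns
        lm = _map_for(30)
        ent = effective_number_of_tests(G, lm)
        assert ent.per_chrom[0] == pytest.approx(30.0)
        assert ent.alpha == pytest.approx(0.05 / 30.0)

    def test_perfect_ld_collapses_to_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=40)
        G = np.column_stack([col * s for s in (1, -1, 1, -1, 1)])
        ent = effective_number_of_tests(G, _map_for(5))
        assert ent.per_chrom[0] == pytest.approx(1.0)

    def test_intermediate_ld_matches_eigen_oracle(self):
        # exact pairwise correlation 0.5 via shared + unique orthogonal parts
        H = hadamard(8).astype(float) / np.sqrt(8)
        shared, e1, e2, e3 = H[:, 4], H[:, 1], H[:, 2], H[:, 3]
        b = np.sqrt(0.5)
        G = np.column_stack([b * shared + b * e for e in (e1, e2, e3)])
        ent = effective_number_of_tests(G, _map_for(3))
        # exact eigenvalues of the equicorrelation matrix: 1 + 2r, 1 - r (x2)
        lam = np.array([0.5, 0.5, 2.0])
        oracle = np.sum((lam >= 1) + (lam - np.floor(lam)))
        assert ent.per_chrom[0] == pytest.approx(oracle, abs=1e-9)

    def test_alternative_estimators_available(self):
        rng = np.random.default_rng(1)
        G = rng.normal(size=(50, 10))
        for method in ("cheverud-nyholt", "galwey"):
            ent = effective_number_of_tests(G, _map_for(10), method=method)
            assert 1.0 <= ent.ent_total <= 10.0


def _scan_with_p(pvals, counts=(0, 30, 20)):
    n = len(pvals)
    tab = _map_for(n).markers.copy()
    tab["n_aa"], tab["n_ab"], tab["n_bb"] = counts
    tab["n"] = sum(counts)
    tab["chi2"] = 1.0
    tab["p"] = pvals
    return FamilyScan(family="fam", table=tab)


class TestSDRCalling:
    ENT = ENTResult(per_chrom={0: 10}, ent_total=10.0, alpha=0.005)

    def test_run_of_three_becomes_region(self):
        scan = _scan_with_p([0.5, 1e-4, 1e-4, 1e-4, 0.5])
        regions = call_sdr(scan, self.ENT)
        assert len(regions) == 1
        r = regions[0]
        assert (r.cM_start, r.cM_end) == (1.0, 3.0)
        assert r.deficient_classes == ["aa"]
        assert not r.het_deficient

    def test_run_of_two_is_not_enough(self):
        scan = _scan_with_p([1e-4, 1e-4, 0.5, 0.5, 0.5])
        assert call_sdr(scan, self.ENT) == []

    def test_no_distortion_no_regions(self):
        scan = _scan_with_p([1.0] * 5)
        assert call_sdr(scan, self.ENT) == []


class TestConfirmation:
    def _sdr(self):
        return SDRegion(family="fam", chrom=0, marker_start="a",
                        marker_end="b", cM_start=0, cM_end=2,
                        bp_start=1, bp_end=4 * 10 ** 6, row_lo=0, row_hi=2,
                        pvalues=np.array([1e-4]), deficient_classes=["aa"],
                        het_deficient=False)

    def _raw(self, per_marker_counts, parent_het):
        """Raw genotypes for 4 markers inside the window."""
        n = sum(per_marker_counts[0])
        S = len(per_marker_counts)
        raw = np.zeros((n, S), dtype=np.int8)
        for s, (n0, n1, n2) in enumerate(per_marker_counts):
            raw[:, s] = [0] * n0 + [1] * n1 + [2] * n2
        sites = pd.DataFrame({"chrom": [0] * S,
                              "bp": (np.arange(S) + 1) * 10 ** 6})
        return raw, np.array(parent_het, dtype=np.int8), sites

    def test_three_of_four_significant_confirms(self):
        skew = (0, 40, 0)      # p << 0.05
        fair = (10, 20, 10)    # p = 1
        raw, pg, sites = self._raw([skew, skew, skew, fair], [1, 1, 1, 1])
        sdr = confirm_sdr(self._sdr(), raw, pg, sites, np.arange(40))
        assert sdr.confirmed is True

    def test_exactly_half_does_not_confirm(self):
        skew = (0, 40, 0)
        fair = (10, 20, 10)
        raw, pg, sites = self._raw([skew, skew, fair, fair], [1, 1, 1, 1])
        sdr = confirm_sdr(self._sdr(), raw, pg, sites, np.arange(40))
        assert sdr.confirmed is False

    def test_no_informative_markers_is_unverifiable(self):
        fair = (10, 20, 10)
        raw, pg, sites = self._raw([fair, fair], [0, 2])  # parent homozygous
        sdr = confirm_sdr(self._sdr(), raw, pg, sites, np.arange(40))
        assert sdr.confirmed is None


class TestRecombinationContext:
    def test_simple_arithmetic(self):
        sdr = SDRegion(family="f", chrom=0, marker_start="a", marker_end="b",
                       cM_start=10.0, cM_end=15.0, bp_start=0,
                       bp_end=10 * 10 ** 6, row_lo=0, row_hi=1,
                       pvalues=np.array([0.0]), deficient_classes=[],
                       het_deficient=False)
        region, _, _ = sdr_recombination_context(sdr, _map_for(30))
        assert region == pytest.approx(0.5)

    def test_region_equal_to_chromosome_matches_its_mean(self):
        lm = _map_for(20)
        mk = lm.markers
        sdr = SDRegion(family="f", chrom=0, marker_start="a", marker_end="b",
                       cM_start=float(mk["cM"].min()),
                       cM_end=float(mk["cM"].max()),
                       bp_start=int(mk["bp"].min()), bp_end=int(mk["bp"].max()),
                       row_lo=0, row_hi=19, pvalues=np.array([0.0]),
                       deficient_classes=[], het_deficient=False)
        region, chrom_rate, _ = sdr_recombination_context(sdr, lm)
        assert region == pytest.approx(chrom_rate)

    def test_zero_physical_length_is_an_error(self):
        sdr = SDRegion(family="f", chrom=0, marker_start="a", marker_end="b",
                       cM_start=0, cM_end=1, bp_start=100, bp_end=100,
                       row_lo=0, row_hi=1, pvalues=np.array([0.0]),
                       deficient_classes=[], het_deficient=False)
        with pytest.raises(ValueError, match="physical length"):
            sdr_recombination_context(sdr, _map_for(5))

    def test_simulated_cold_spot_has_below_average_rate(self):
        from idscan import build_linkage_map, random_pedigree
        from idscan import simulate_founders, simulate_progeny
        cfg = SimulationConfig(
            n_parents=4, n_chromosomes=1, chrom_length_cM=80,
            selfed_family_sizes=[80, 1, 1, 1], outcross_design=[], seed=23,
            rate_segments=[RateSegment(0, 30.0, 50.0, 0.2)])
        f = simulate_founders(cfg)
        ped = random_pedigree(cfg)
        mat, pat, _, _ = simulate_progeny(f, ped, cfg)
        lm = build_linkage_map(mat, pat, f.sites)
        mk = lm.markers
        inside = mk[(mk["cM"] >= 0)]
        # synthetic region spanning the configured cold spot
        cold = f.sites[(f.sites["cM"] >= 30) & (f.sites["cM"] <= 50)]
        sdr = SDRegion(family="f", chrom=0, marker_start="a", marker_end="b",
                       cM_start=30.0, cM_end=50.0,
                       bp_start=int(cold["bp"].min()),
                       bp_end=int(cold["bp"].max()), row_lo=0, row_hi=1,
                       pvalues=np.array([0.0]), deficient_classes=[],
                       het_deficient=False)
        region, chrom_rate, _ = sdr_recombination_context(sdr, lm)
        assert region < chrom_rate


class TestEndToEnd:
    def test_linked_lethal_detected_and_null_clean(self):
        cfg = SimulationConfig(
            n_parents=6, n_chromosomes=2, chrom_length_cM=80, seed=101,
            selfed_family_sizes=[70] * 6,
            outcross_design=[(0, 1, 15), (2, 3, 15), (4, 5, 15)],
            lethal_spec=[LethalSpec(0, 40.0, carrier_parent=0)])
        pop = simulate_population(cfg)
        surv = pop.surviving_index()
        mat, pat = pop.mat_code[surv], pop.pat_code[surv]
        ped = pop.pedigree.iloc[surv].reset_index(drop=True)
        from idscan import build_linkage_map
        lm = build_linkage_map(mat, pat, pop.founders.sites)
        ent = effective_number_of_tests(
            pop.genotypes[surv][:, lm.site_index()], lm)
        fam0 = np.flatnonzero((ped.progeny_type == "selfed")
                              & (ped.mother == "P000"))
        scan = family_segregation_scan(mat, pat, fam0, 0, lm, "P000")
        regions = call_sdr(scan, ent)
        assert any(r.chrom == 0 for r in regions)
        hit = [r for r in regions if r.chrom == 0][0]
        assert not hit.het_deficient  # recessive lethal: homozygote deficit
        # clean family shows nothing
        fam1 = np.flatnonzero((ped.progeny_type == "selfed")
                              & (ped.mother == "P001"))
        scan1 = family_segregation_scan(mat, pat, fam1, 1, lm, "P001")
        assert call_sdr(scan1, ent) == []


class TestExactMultinomial:
    def test_matches_brute_force_enumeration(self):
        from math import comb
        from idscan.segdist import _exact_multinomial_p
        n_aa, n_ab, n_bb = 1, 5, 0
        n = n_aa + n_ab + n_bb

        def pmf(a, b, c):
            return (comb(n, a) * comb(n - a, b)
                    * 0.25 ** a * 0.5 ** b * 0.25 ** c)

        obs = pmf(n_aa, n_ab, n_bb)
        total = sum(pmf(a, b, n - a - b)
                    for a in range(n + 1) for b in range(n + 1 - a)
                    if pmf(a, b, n - a - b) <= obs + 1e-15)
        assert _exact_multinomial_p(n_aa, n_ab, n_bb) == pytest.approx(
            total, rel=1e-10)

    def test_scan_option_produces_valid_p(self):
        mat, pat = _family_codes([(6, 10, 4)])
        scan = family_segregation_scan(mat, pat, np.arange(20), 0,
                                       _map_for(1), "f", exact=True)
        p = scan.table["p"].iloc[0]
        assert 0 < p <= 1
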