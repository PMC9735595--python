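"""Isotope patterns, XIC construction and peak-area integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pyteomics import mass as ptmass

from plasmalink.masses import ISOTOPE_SPACING, PeptideSpecies, mz, peptide_formula
from plasmalink.quantify import (
    XicTrace,
    auto_window,
    build_xic,
    integrate_area,
    isotope_pattern,
    timecourse,
)


def naive_convolution_oracle(formula: dict) -> np.ndarray:
    """Direct polynomial expansion, one atom at a time (no exponentiation)."""
    single = {
        "C": [0.9893, 0.0107],
        "H": [0.999885, 0.000115],
        "N": [0.99636, 0.00364],
        "O": [0.99757, 0.00038, 0.00205],
        "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
    }
    dist = np.array([1.0])
    for el, n in formula.items():
        for _ in range(n):
            dist = np.convolve(dist, np.array(single[el]))
    return dist / dist.sum()


small_formulas = st.fixed_dictionaries(
    {},
    optional={
        "C": st.integers(1, 30),
        "H": st.integers(1, 50),
        "N": st.integers(0, 10),
        "O": st.integers(0, 10),
        "S": st.integers(0, 3),
    },
).filter(lambda f: sum(f.values()) > 0)


class TestIsotopePattern:
    def test_glycine_free_peptide_monoisotopic_dominates(self):
        pat = isotope_pattern(peptide_formula("G"), charge=1)
        assert pat.most_intense_index == 0
        assert pat.offsets[0] == 0

    def test_large_carbon_count_shifts_most_intense(self):
        # A1/A0 ~ nC * 0.0107/0.9893 crosses 1 near 92 carbons
        pat = isotope_pattern({"C": 100, "H": 160}, charge=1)
        assert pat.offsets[pat.most_intense_index] >= 1

    def test_crosslink_pattern_against_expansion_oracle(self, albumin_fragment):
        species = PeptideSpecies(albumin_fragment, disulfide_partner=PeptideSpecies("VPCVS"))
        formula = species.formula()
        pat = isotope_pattern(formula, charge=3, prune_below=1e-6)
        oracle = naive_convolution_oracle(dict(formula))
        assert int(np.argmax(oracle)) == pat.offsets[pat.most_intense_index]
        np.testing.assert_allclose(
            pat.abundances[:8], oracle[pat.offsets[:8]], rtol=1e-6
        )
        # offset-k m/z = mz(M, 3) + k * spacing / 3
        expect = mz(formula.mono_mass, 3) + pat.offsets * ISOTOPE_SPACING / 3
        np.testing.assert_allclose(pat.mz_values, expect, rtol=1e-12)

    def test_small_formula_against_pyteomics_fine_structure(self):
        # independent oracle: enumerate isotopologues and bin by neutron count
        formula = {"C": 6, "H": 12, "O": 3, "S": 1}
        pat = isotope_pattern(formula, charge=1, prune_below=1e-8)
        comp = ptmass.Composition(formula="C6H12O3S")
        binned: dict[int, float] = {}
        mono = ptmass.calculate_mass(composition=comp)
        for iso, abundance in ptmass.isotopologues(
            composition=comp, report_abundance=True,
            overall_threshold=1e-10, isotope_threshold=1e-6,
        ):
            offset = round(ptmass.calculate_mass(composition=iso) - mono)
            binned[offset] = binned.get(offset, 0.0) + abundance
        for off, ab in zip(pat.offsets[:4], pat.abundances[:4]):
            assert ab == pytest.approx(binned[int(off)], rel=1e-3)

    @given(fa=small_formulas, fb=small_formulas)
    def test_convolution_identity(self, fa, fb):
        # pattern(A+B) equals the convolution of pattern(A) and pattern(B)
        combined = {el: fa.get(el, 0) + fb.get(el, 0) for el in set(fa) | set(fb)}
        pa = isotope_pattern(fa, prune_below=0.0).abundances
        pb = isotope_pattern(fb, prune_below=0.0).abundances
        pc = isotope_pattern(combined, prune_below=0.0)
        direct = np.convolve(pa, pb)
        np.testing.assert_allclose(
            pc.abundances[:10], direct[pc.offsets[:10]], rtol=1e-6, atol=1e-12
        )

    def test_abundances_normalized_and_offsets_increasing(self):
        pat = isotope_pattern({"C": 50, "H": 80, "N": 10, "O": 15, "S": 2},
                              prune_below=1e-4)
        assert pat.retained_fraction >= 0.999
        assert np.all(np.diff(pat.offsets) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            isotope_pattern({"C": 2}, charge=0)
        with pytest.raises(ValueError):
            isotope_pattern({}, charge=1)


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])


class TestBuildXic:
    def test_single_peak_at_target(self):
        trace = build_xic(peaks_df([(5.0, 500.0, 1234.0)]), 500.0, 20.0)
        assert trace.rt_min.tolist() == [5.0]
        assert trace.intensity.tolist() == [1234.0]

    def test_peak_outside_tolerance_gives_zero(self):
        trace = build_xic(peaks_df([(5.0, 500.0 * (1 + 100e-6), 1234.0)]), 500.0, 20.0)
        assert trace.intensity.tolist() == [0.0]

    def test_coeluting_peaks_summed(self):
        peaks = peaks_df([
            (5.0, 500.000, 100.0),
            (5.0, 500.005, 50.0),   # 10 ppm away
            (5.0, 600.0, 999.0),
        ])
        trace = build_xic(peaks, 500.0, 20.0)
        assert trace.intensity.tolist() == [150.0]

    def test_empty_peak_list(self):
        trace = build_xic(peaks_df([]), 500.0, 20.0)
        assert len(trace.rt_min) == 0

    @given(
        tol_a=st.floats(min_value=0.5, max_value=50),
        tol_b=st.floats(min_value=0.5, max_value=50),
    )
    def test_pointwise_monotone_in_tolerance(self, tol_a, tol_b):
        lo, hi = sorted([tol_a, tol_b])
        rng = np.random.default_rng(0)
        peaks = peaks_df([
            (t, 500.0 * (1 + d * 1e-6), 10.0)
            for t in (1.0, 2.0, 3.0)
            for d in rng.uniform(-60, 60, 5)
        ])
        narrow = build_xic(peaks, 500.0, lo).intensity
        wide = build_xic(peaks, 500.0, hi).intensity
        assert np.all(narrow <= wide + 1e-12)


class TestIntegrateArea:
    def test_rectangle(self):
        trace = XicTrace("", 0, 500.0, 20.0, np.array([0.0, 1.0, 2.0]),
                         np.array([10.0, 10.0, 10.0]))
        assert integrate_area(trace) == pytest.approx(20.0)

    def test_zero_trace(self):
        trace = XicTrace("", 0, 500.0, 20.0, np.array([0.0, 1.0]), np.zeros(2))
        assert integrate_area(trace) == 0.0

    def test_triangle_analytic(self):
        base, height = 2.0, 7.0
        rt = np.linspace(0, base, 401)
        y = height * (1 - np.abs(rt - base / 2) / (base / 2))
        trace = XicTrace("", 0, 500.0, 20.0, rt, y)
        assert integrate_area(trace) == pytest.approx(height * base / 2, rel=1e-4)

    def test_additive_over_disjoint_windows(self):
        rt = np.linspace(0, 10, 101)
        y = np.sin(rt) ** 2
        trace = XicTrace("", 0, 500.0, 20.0, rt, y)
        whole = integrate_area(trace, window=(0.0, 10.0))
        parts = integrate_area(trace, window=(0.0, 5.0)) + integrate_area(trace, (5.0, 10.0))
        assert parts == pytest.approx(whole, rel=1e-9)

    def test_invariant_to_zero_scan_insertion(self):
        rt = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 5.0, 5.0, 0.0])
        base = integrate_area(XicTrace("", 0, 1.0, 1.0, rt, y))
        rt2 = np.array([0.0, 0.5, 1.0, 2.0, 2.5, 3.0])
        y2 = np.array([0.0, 2.5, 5.0, 5.0, 2.5, 0.0])  # same piecewise-linear shape
        assert integrate_area(XicTrace("", 0, 1.0, 1.0, rt2, y2)) == pytest.approx(base)

    def test_inverted_window_rejected(self):
        trace = XicTrace("", 0, 1.0, 1.0, np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="inverted"):
            integrate_area(trace, window=(2.0, 1.0))

    def test_auto_window_brackets_apex(self):
        rt = np.linspace(0, 10, 501)
        y = np.exp(-0.5 * ((rt - 5) / 0.3) ** 2)
        lo, hi = auto_window(XicTrace("", 0, 1.0, 1.0, rt, y))
        assert lo < 5 < hi
        # 5% cut keeps |x| < sigma*sqrt(2 ln 20): ~98.6% of the Gaussian mass
        assert integrate_area(XicTrace("", 0, 1.0, 1.0, rt, y), (lo, hi)) == pytest.approx(
            0.3 * np.sqrt(2 * np.pi) * 0.9857, rel=0.005
        )


class TestTimecourse:
    def test_duplicate_time_replicate_rejected(self, jm21):
        from plasmalink.conjugates import enumerate_adducts

        species = enumerate_adducts(jm21, adducts=(), include_dimer=False, max_oxidation=0)
        peaks = peaks_df([(1.0, 500.0, 1.0)])
        with pytest.raises(ValueError, match="duplicate"):
            timecourse([(0.0, peaks), (0.0, peaks)], species)

    def test_absent_species_gives_zero_course(self, jm21):
        from plasmalink.conjugates import enumerate_adducts

        species = enumerate_adducts(jm21, adducts=(), include_dimer=False, max_oxidation=0)
        peaks = peaks_df([(1.0, 500.0, 100.0), (2.0, 501.0, 100.0)])
        course = timecourse([(0.0, peaks), (5.0, peaks)], species)
        assert (course["area"] == 0.0).all()
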