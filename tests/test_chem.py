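"""Formula arithmetic, ion math and formula decomposition."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sideroscan.chem import (
    DEFAULT_BOUNDS,
    FE54_FE56_SPACING,
    FE_MINUS_3H,
    MASS,
    ElementalFormula,
    FormulaError,
    decompose_mass,
    ferric_complex_mz,
    format_formula,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    protonated_mz,
    rdbe,
)


def _assert_ppm(observed: float, theoretical: float, tol_ppm: float = 5.0) -> None:
    assert abs(ppm_error(observed, theoretical)) <= tol_ppm


class TestParseFormat:
    @pytest.mark.parametrize(
        "text,counts",
        [
            ("C6H10O2", {"C": 6, "H": 10, "O": 2}),
            ("H2O", {"H": 2, "O": 1}),
            ("C33H62N6O13", {"C": 33, "H": 62, "N": 6, "O": 13}),
            ("CH4", {"C": 1, "H": 4}),
            ("Fe", {"Fe": 1}),
        ],
    )
    def test_parse(self, text, counts):
        assert parse_formula(text).as_dict() == counts

    @pytest.mark.parametrize("bad", ["C-3H", "", "Xx2", "C0H4", "C6 H10", "c6h10"])
    def test_malformed_raises(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_negative_count_rejected(self):
        with pytest.raises(FormulaError):
            ElementalFormula({"C": -1})

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S"]),
            st.integers(min_value=1, max_value=200),
            min_size=1,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, counts):
        f = ElementalFormula(counts)
        assert parse_formula(format_formula(f)) == f


class TestMasses:
    # printed measured values the theory must match within 5 ppm
    @pytest.mark.parametrize(
        "formula,protonated,measured",
        [
            ("C33H62N6O13", True, 751.4450),
            ("C6H10O2", False, 114.0681),
            ("C4H7NO", True, 86.0601),
            ("C5H10N2O2", True, 131.0816),
            ("C15H24O3", True, 253.1799),  # deoxyuvidin B
        ],
    )
    def test_printed_masses(self, formula, protonated, measured):
        m = monoisotopic_mass(parse_formula(formula))
        if protonated:
            m = protonated_mz(m)
        _assert_ppm(measured, m)

    def test_empty_formula_mass_zero(self):
        assert monoisotopic_mass(ElementalFormula({})) == 0.0

    def test_protonated_of_zero(self):
        assert protonated_mz(0.0) == pytest.approx(1.00728, abs=1e-4)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            protonated_mz(-1.0)

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S"]),
            st.integers(min_value=0, max_value=50),
        ),
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S"]),
            st.integers(min_value=0, max_value=50),
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_mass_additivity(self, c1, c2):
        f1, f2 = ElementalFormula(c1), ElementalFormula(c2)
        assert monoisotopic_mass(f1 + f2) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
        )


class TestFerricComplex:
    def test_iron_constants(self):
        assert abs(FE54_FE56_SPACING - 1.99533) <= 1e-4
        assert abs(MASS.fe_ratio - 0.0637) <= 1e-3

    def test_holo_ion_of_base_siderophore(self):
        m = monoisotopic_mass(parse_formula("C33H62N6O13"))
        assert ferric_complex_mz(m) == pytest.approx(804.3562, abs=1e-3)

    @given(st.floats(min_value=10.0, max_value=2000.0))
    @settings(max_examples=200, deadline=None)
    def test_constant_shift_from_apo_ion(self, m):
        assert ferric_complex_mz(m) - protonated_mz(m) == pytest.approx(
            52.91146, abs=1e-4
        )

    def test_too_small_mass_rejected(self):
        with pytest.raises(ValueError):
            ferric_complex_mz(1.0)


class TestRdbe:
    @pytest.mark.parametrize(
        "formula,expected",
        [("C6H10O2", 2.0), ("CH4", 0.0), ("C35H65N7O10", 7.0), ("C33H62N6O13", 6.0)],
    )
    def test_closed_form(self, formula, expected):
        assert rdbe(parse_formula(formula)) == expected


def naive_decompose(neutral_mass, tol_ppm, bounds):
    """Independent oracle: full nested enumeration over every element,
    with the same RDBE 0-40 plausibility rule computed inline."""
    tol_da = tol_ppm * 1e-6 * neutral_mass
    els = sorted(bounds)
    hits = []

    def rec(idx, acc, acc_mass):
        if acc_mass > neutral_mass + tol_da:
            return
        if idx == len(els):
            if acc and abs(acc_mass - neutral_mass) <= tol_da:
                ring_db = (
                    2 * acc.get("C", 0) + 2 + acc.get("N", 0) - acc.get("H", 0)
                ) / 2
                if 0 <= ring_db <= 40:
                    hits.append(ElementalFormula(dict(acc)))
            return
        el = els[idx]
        lo, hi = bounds[el]
        for n in range(lo, hi + 1):
            m = acc_mass + n * MASS.atomic[el]
            if m > neutral_mass + tol_da:
                break
            if n:
                acc[el] = n
            rec(idx + 1, acc, m)
            acc.pop(el, None)

    rec(0, {}, 0.0)
    return hits


class TestDecomposition:
    def test_water(self):
        cands = decompose_mass(18.0106, 5.0)
        assert [c.formula.hill() for c in cands] == ["H2O"]

    def test_contains_printed_formulas(self):
        assert "C6H10O2" in {
            c.formula.hill() for c in decompose_mass(114.0681, 5.0)
        }
        assert "C33H62N6O13" in {
            c.formula.hill() for c in decompose_mass(750.4375, 5.0)
        }

    def test_all_candidates_within_tolerance_and_sorted(self):
        cands = decompose_mass(750.4375, 5.0)
        errs = [abs(c.mass_error_ppm) for c in cands]
        assert all(e <= 5.0 for e in errs)
        assert errs == sorted(errs)
        assert all(0.0 <= c.rdbe <= 40.0 for c in cands)

    @pytest.mark.parametrize("mass", [114.0681, 250.1200, 342.1162])
    def test_equals_naive_oracle(self, mass):
        bounds = {"C": (0, 20), "H": (0, 40), "N": (0, 6), "O": (0, 12)}
        got = {c.formula.hill() for c in decompose_mass(mass, 5.0, bounds)}
        want = {f.hill() for f in naive_decompose(mass, 5.0, bounds)}
        assert got == want

    def test_empty_result_is_empty_list(self):
        # nothing sits 5 ppm from the electron-scale mass gap at 1.5 Da
        assert decompose_mass(1.5, 5.0) == []

    def test_rdbe_filter_applied(self):
        full = decompose_mass(750.4375, 5.0, rdbe_range=(0.0, 40.0))
        tight = decompose_mass(750.4375, 5.0, rdbe_range=(5.0, 8.0))
        assert {c.formula.hill() for c in tight} < {c.formula.hill() for c in full}
        assert all(5.0 <= c.rdbe <= 8.0 for c in tight)
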