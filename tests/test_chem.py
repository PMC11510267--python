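"""Formula parsing, mass arithmetic, ppm conventions, isotope envelopes.

Hand-computed oracles use independently typed isotope constants
(H 1.00782503, C 12, N 14.0030740, O 15.99491462; electron 0.000548579909)
so they do not share a code path with the implementation.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbaffinity import (ELECTRON_MASS, IonSpec, average_mass, ion_mz,
                        isotope_envelope, monoisotopic_mass, parse_formula,
                        ppm_error, truncate)
from dbaffinity.chem import FormulaError

H, C, N, O = 1.00782503, 12.0, 14.0030740, 15.99491462


@pytest.mark.parametrize("text,expected", [
    ("C15H11O4", {"C": 15, "H": 11, "O": 4}),
    ("C5H10NO2", {"C": 5, "H": 10, "N": 1, "O": 2}),
    ("H2O", {"H": 2, "O": 1}),
])
def test_parse_formula(text, expected):
    assert dict(parse_formula(text)) == expected


@pytest.mark.parametrize("bad", ["C15X2", "", "   ", "C0H2", "15C", "c2h4"])
def test_parse_formula_rejects(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_formula_round_trips_through_hill_writer():
    for text in ("C15H11O4", "C5H10NO2", "H2O", "C41H31O26"):
        f = parse_formula(text)
        assert parse_formula(f.hill()) == f


@pytest.mark.parametrize("formula,expected", [
    ("H2O", 2 * H + O),                      # 18.0106
    ("C15H11O4", 15 * C + 11 * H + 4 * O),   # 255.0657
    ("C7H5O5", 7 * C + 5 * H + 5 * O),
])
def test_monoisotopic_mass_hand_sum(formula, expected):
    assert monoisotopic_mass(formula) == pytest.approx(expected, abs=5e-6)


@pytest.mark.parametrize("formula,charge,expected", [
    ("C15H11O4", -1, 255.0663),  # liquiritigenin [M-H]-
    ("C7H5O5", -1, 169.0142),    # gallic acid [M-H]-
    ("C5H10NO2", +1, 116.0706),  # proline [M+H]+
])
def test_ion_mz_reproduces_tabulated_values(formula, charge, expected):
    assert round(ion_mz(IonSpec(parse_formula(formula), charge)), 4) == expected


def test_ion_mz_rejects_zero_charge():
    with pytest.raises(ValueError):
        IonSpec(parse_formula("H2O"), 0)


@pytest.mark.parametrize("formula,mw,places", [
    ("C7H6O5", 170.12, 2),    # gallic acid
    ("C12H22O11", 342.3, 1),  # sucrose
    ("C", 12.011, 3),
])
def test_average_mass(formula, mw, places):
    assert round(average_mass(formula), places) == mw


@pytest.mark.parametrize("obs,theo,convention,expected", [
    (255.0661, 255.0663, "nominal_denominator", 0.7843),
    (435.1280, 435.1297, "nominal_denominator", 3.9080),
    (300.9989, 300.9990, "nominal_denominator", 0.3333),  # denominator 300
    (255.0661, 255.0663, "theoretical_denominator", 0.7841),
])
def test_ppm_error_conventions(obs, theo, convention, expected):
    assert truncate(ppm_error(obs, theo, convention)) == pytest.approx(
        expected, abs=1e-4)


def test_ppm_error_zero_on_identity_and_symmetric():
    assert ppm_error(169.0142, 169.0142) == 0.0
    assert ppm_error(169.0, 169.0142) == pytest.approx(
        ppm_error(169.0284, 169.0142), rel=1e-9)


def test_ppm_error_rejects_nonpositive():
    with pytest.raises(ValueError):
        ppm_error(0.0, 100.0)


def test_isotope_envelope_single_carbon():
    env = isotope_envelope("C", n_peaks=2)
    assert env[0] == (0, pytest.approx(0.9893, abs=1e-4))
    assert env[1] == (1, pytest.approx(0.0107, abs=1e-4))


def test_isotope_envelope_c2_binomial_oracle():
    # two carbons: A+1/A ratio doubles the single-atom isotope ratio
    env = dict(isotope_envelope("C2", n_peaks=3))
    assert env[1] / env[0] == pytest.approx(2 * 0.0107 / 0.9893, rel=1e-6)


def test_isotope_envelope_requires_two_peaks():
    with pytest.raises(ValueError):
        isotope_envelope("C6H12O6", n_peaks=1)


formulas = st.builds(
    lambda c, h, n, o, s: {k: v for k, v in
                           zip("CHNOS", (c, h, n, o, s)) if v > 0},
    st.integers(0, 40), st.integers(0, 60), st.integers(0, 5),
    st.integers(0, 20), st.integers(0, 3),
).filter(bool).map(lambda d: "".join(f"{k}{v}" for k, v in d.items()))


@settings(derandomize=True, max_examples=60)
@given(formulas, formulas)
def test_monoisotopic_mass_is_additive(f1, f2):
    a, b = parse_formula(f1), parse_formula(f2)
    assert monoisotopic_mass(a + b) == pytest.approx(
        monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9)


@settings(derandomize=True, max_examples=60)
@given(formulas)
def test_electron_mass_asymmetry(f):
    ion = parse_formula(f)
    diff = ion_mz(IonSpec(ion, -1)) - ion_mz(IonSpec(ion, +1))
    assert diff == pytest.approx(2 * ELECTRON_MASS, abs=1e-12)


@settings(derandomize=True, max_examples=60)
@given(formulas, st.integers(2, 6))
def test_envelope_normalized_and_nonnegative(f, n_peaks):
    env = isotope_envelope(f, n_peaks=n_peaks)
    abundances = [a for _, a in env]
    assert all(a >= 0 for a in abundances)
    assert math.isclose(sum(abundances), 1.0, abs_tol=1e-12)
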