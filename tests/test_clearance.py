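import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from renalscale import make_subject
from renalscale.clearance import (
    blood_to_plasma,
    cl_ats,
    cl_gf,
    clearance_table,
    relative_clr,
    renal_clearance,
    rescale_fu,
    total_clint_sec,
)
from renalscale.drug_space import DrugSpec, grid_table

SETTINGS = settings(max_examples=200, derandomize=True)

fu_st = st.floats(0.001, 1.0, exclude_min=False)
ratio_st = st.floats(0.05, 20.0)


# --- fu rescaling -----------------------------------------------------------

@pytest.mark.parametrize(
    "fu_nw, ratio, expected",
    [
        (0.05, 1.0, 0.05),  # unchanged protein concentration
        (1.0, 2.0, 1.0),  # no binding: protein irrelevant
        (0.05, 0.8, 0.05 / (0.05 + 0.95 * 0.8)),  # constant-affinity relation
    ],
)
def test_rescale_fu_examples(fu_nw, ratio, expected):
    assert rescale_fu(fu_nw, ratio) == pytest.approx(expected, rel=1e-12)


@SETTINGS
@given(fu=fu_st, r1=ratio_st, r2=ratio_st)
def test_rescale_fu_decreasing_in_protein_ratio(fu, r1, r2):
    lo, hi = sorted((r1, r2))
    a, b = rescale_fu(fu, lo), rescale_fu(fu, hi)
    assert 0 < b <= 1 and 0 < a <= 1
    if fu < 1 and hi > lo:
        assert b < a
    if fu == 1:
        assert a == b == 1.0


def test_rescale_fu_domain_errors():
    with pytest.raises(ValueError):
        rescale_fu(0.5, 0.0)
    with pytest.raises(ValueError):
        rescale_fu(0.0, 1.0)
    with pytest.raises(ValueError):
        rescale_fu(1.2, 1.0)


# --- blood-to-plasma --------------------------------------------------------

@pytest.mark.parametrize(
    "hct, fu, kp, expected",
    [
        (0.45, 1.0, 1.0, 1.0),  # fu*kp = 1: whole blood = plasma
        (0.0, 0.3, 17.0, 1.0),  # no red cells
        (0.45, 1.0, 0.35, 1 + 0.45 * (0.35 - 1)),
    ],
)
def test_blood_to_plasma_examples(hct, fu, kp, expected):
    assert blood_to_plasma(hct, fu, kp) == pytest.approx(expected, rel=1e-12)


@SETTINGS
@given(hct=st.floats(0.0, 0.6), fu=fu_st, kp=st.floats(0.05, 40.0))
def test_blood_to_plasma_floor(hct, fu, kp):
    assert blood_to_plasma(hct, fu, kp) >= (1 - hct) - 1e-12


def test_blood_to_plasma_rejects_unit_hematocrit():
    with pytest.raises(ValueError):
        blood_to_plasma(1.0, 0.5, 1.0)


# --- intrinsic secretion clearance ------------------------------------------

def test_total_clint_sec_product_and_units():
    # 2 µl/min/mg x 99.4 x 300 g = 59,640 µl/min = 3.5784 L/h
    base = total_clint_sec(2.0, 300.0, 99.4, 1.0)
    assert base == pytest.approx(3.5784, rel=1e-12)
    assert total_clint_sec(123.0, 456.0, 99.4, 0.0) == 0.0
    # linear in clint_ats and rta
    assert total_clint_sec(500.0, 300.0, 99.4, 2.5) == pytest.approx(2.5 * 250 * base, rel=1e-12)
    assert total_clint_sec(500.0, 300.0, 99.4, 2.5) == pytest.approx(2236.5, rel=1e-12)


# --- pathway clearances -----------------------------------------------------

@pytest.mark.parametrize("fu, gfr, expected", [(1.0, 7.2, 7.2), (0.0, 7.2, 0.0), (0.5, 6.5, 3.25)])
def test_cl_gf_examples(fu, gfr, expected):
    assert cl_gf(fu, gfr) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "args, expected",
    [
        ((60, 6, 0.5, 0, 1), 0.0),
        ((60, 6, 0.5, 20, 1), 540 / 70),
        ((60, 6, 0.5, 1e9, 2), 108.0),  # flow-limited ceiling (qr - gfr) * bp
    ],
)
def test_cl_ats_examples(args, expected):
    assert cl_ats(*args) == pytest.approx(expected, rel=1e-4)


def test_cl_ats_requires_qr_above_gfr():
    with pytest.raises(ValueError):
        cl_ats(6.0, 6.0, 0.5, 10.0, 1.0)


@SETTINGS
@given(
    qr=st.floats(30.0, 120.0),
    gfr=st.floats(1.0, 25.0),
    fu=fu_st,
    clint=st.floats(0.0, 5000.0),
    bp=st.floats(0.4, 20.0),
)
def test_cl_ats_bounds_and_monotonicity(qr, gfr, fu, clint, bp):
    """CL_ATS stays strictly below the flow limit and grows with clint and fu."""
    v = cl_ats(qr, gfr, fu, clint, bp)
    assert 0 <= v < (qr - gfr) * bp
    assert cl_ats(qr, gfr, fu, clint * 2 + 1, bp) >= v
    assert cl_ats(qr, gfr, min(1.0, fu * 1.5), clint, bp) >= v - 1e-12


@SETTINGS
@given(qr=st.floats(30.0, 120.0), gfr=st.floats(1.0, 25.0), fu=fu_st, bp=st.floats(0.4, 20.0))
def test_cl_ats_low_clint_linearization(qr, gfr, fu, bp):
    """As clint_sec -> 0 the secretion term approaches (qr-gfr)*fu*clint/qr."""
    clint = 1e-7
    expected = (qr - gfr) * fu * clint / qr
    assert cl_ats(qr, gfr, fu, clint, bp) == pytest.approx(expected, rel=1e-5)


def test_cl_ats_matches_independent_symbolic_evaluation():
    """100 random draws against an exact-rational sympy evaluation, 1e-12 relative."""
    sympy = pytest.importorskip("sympy")
    Qr, G, F, C, B = sympy.symbols("Qr G F C B", positive=True)
    expr = (Qr - G) * F * C / (Qr + F * C / B)
    rng = np.random.default_rng(20260924)
    for _ in range(100):
        qr = rng.uniform(30, 120)
        gfr = rng.uniform(1, 25)
        fu = rng.uniform(0.01, 1.0)
        clint = rng.uniform(0.0, 3000.0)
        bp = rng.uniform(0.4, 20.0)
        exact = expr.subs(
            {Qr: sympy.Rational(qr), G: sympy.Rational(gfr), F: sympy.Rational(fu),
             C: sympy.Rational(clint), B: sympy.Rational(bp)}
        )
        assert cl_ats(qr, gfr, fu, clint, bp) == pytest.approx(float(exact), rel=1e-12)


# --- composition ------------------------------------------------------------

def test_renal_clearance_additivity_and_contributions(subjects):
    drug = DrugSpec(0.5, 2.0, 100.0, "HSA")
    res = renal_clearance(subjects[40.0], drug, rta=1.5, baseline=subjects[20.0])
    assert res.clr == res.cl_gf + res.cl_ats  # exact additivity
    assert res.contribution_gf + res.contribution_ats == pytest.approx(100.0, abs=1e-9)
    assert res.relative_clr is not None and res.relative_clr > 0


def test_renal_clearance_zero_rta_is_pure_filtration(baseline_subject):
    drug = DrugSpec(0.25, 3.0, 250.0, "AAG")
    res = renal_clearance(baseline_subject, drug, rta=0.0)
    assert res.cl_ats == 0.0
    assert res.clr == res.cl_gf
    assert res.contribution_gf == pytest.approx(100.0)


def test_renal_clearance_baseline_self_reference(baseline_subject):
    """At the baseline subject with rTA 1 the drug keeps its normal-weight fu."""
    drug = DrugSpec(0.05, 1.0, 2.0, "HSA")
    res = renal_clearance(baseline_subject, drug, rta=1.0, baseline=baseline_subject)
    assert res.fu == pytest.approx(0.05, rel=1e-12)
    assert res.relative_clr == pytest.approx(100.0, rel=1e-12)


def test_unbound_drug_identical_under_either_protein(subjects):
    """fu = 1 drugs cannot feel the binding-protein axis."""
    for bmi in (25.0, 60.0):
        a = renal_clearance(subjects[bmi], DrugSpec(1.0, 5.0, 50.0, "HSA"), 1.5, subjects[20.0])
        b = renal_clearance(subjects[bmi], DrugSpec(1.0, 5.0, 50.0, "AAG"), 1.5, subjects[20.0])
        assert a == b


def test_hsa_bound_drug_filtration_rises_with_bmi(subjects):
    """HSA falls with BMI, so fu and hence CL_GF rise for an HSA-bound drug."""
    drug = DrugSpec(0.05, 1.0, 100.0, "HSA")
    gf = [
        renal_clearance(subjects[b], drug, 1.0, subjects[20.0]).cl_gf
        for b in (20.0, 25.0, 30.0, 40.0, 50.0, 60.0)
    ]
    assert all(b > a for a, b in zip(gf, gf[1:]))


def test_relative_clr_arithmetic():
    assert relative_clr(5.0, 5.0) == 100.0
    assert relative_clr(6.5, 5.0) == pytest.approx(130.0)
    assert relative_clr(3.5, 5.0) == pytest.approx(70.0)
    with pytest.raises(ValueError):
        relative_clr(1.0, 0.0)


# --- batch table ------------------------------------------------------------

def test_clearance_table_matches_scalar_path(subjects):
    """Vectorised batch evaluation agrees with the scalar composition row by row."""
    grid = {
        "fu": [0.05, 0.75],
        "kp": [0.35, 10.0],
        "clint_ats": [2.0, 500.0],
        "rta": [0.5, 1.0],
        "bmi": [20.0, 50.0],
        "binding_protein": ["HSA", "AAG"],
    }
    df = clearance_table(grid_table(grid), subjects, baseline_bmi=20.0)
    assert len(df) == 2 * 2 * 2 * 2 * 2 * 2
    for row in df.sample(12, random_state=0).itertuples():
        drug = DrugSpec(row.fu_normal_weight, row.kp, row.clint_ats, row.binding_protein)
        res = renal_clearance(subjects[row.bmi], drug, row.rta, baseline=subjects[20.0])
        assert row.clr == pytest.approx(res.clr, rel=1e-12)
        assert row.fu == pytest.approx(res.fu, rel=1e-12)
        assert row.relative_clr == pytest.approx(res.relative_clr, rel=1e-12)


def test_clearance_table_requires_baseline_scenario(subjects):
    grid = {"fu": [0.5], "kp": [1.0], "clint_ats": [2.0], "rta": [0.5], "bmi": [20.0], "binding_protein": ["HSA"]}
    with pytest.raises(ValueError, match="baseline scenario"):
        clearance_table(grid_table(grid), subjects)
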