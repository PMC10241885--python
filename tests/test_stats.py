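import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpscreen as ss
from snpscreen.stats import nu_vector, omega_matrix, phi2_vector

from conftest import expand_to_samples, random_tables, table_from_rows


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_trend_z(case, control, x):
    """Direct arithmetic over the six counts, plain Python floats."""
    r, s = sum(case), sum(control)
    n = r + s
    ni = [case[i] + control[i] for i in range(3)]
    num = math.sqrt(n) * sum(x[i] * (s * case[i] - r * control[i]) for i in range(3))
    bracket = n * sum(x[i] ** 2 * ni[i] for i in range(3)) - sum(
        x[i] * ni[i] for i in range(3)
    ) ** 2
    if bracket <= 0:
        return None
    return num / math.sqrt(r * s * bracket)


def oracle_sample_correlation(counts, score):
    """Plain sample-moment Pearson correlation on the expanded vectors."""
    g, y = expand_to_samples(counts)
    x = score.as_array()
    coded = x[g.astype(int)]
    if coded.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(coded, y)[0, 1])


def oracle_chi2(case, control):
    """Textbook expected-count chi-square on a 2xk table (zero columns skipped)."""
    r, s = sum(case), sum(control)
    n = r + s
    chi2 = 0.0
    for i in range(3):
        ni = case[i] + control[i]
        if ni == 0:
            continue
        for obs, margin in ((case[i], r), (control[i], s)):
            e = margin * ni / n
            chi2 += (obs - e) ** 2 / e
    return chi2


# ---------------------------------------------------------------------------
# ScoreVector / GenotypeCounts / StatValue
# ---------------------------------------------------------------------------

def test_canonical_score_triples():
    assert ss.RECESSIVE.as_array().tolist() == [0, 0, 1]
    assert ss.ADDITIVE.as_array().tolist() == [0, 0.5, 1]
    assert ss.DOMINANT.as_array().tolist() == [0, 1, 1]


def test_constant_score_rejected():
    with pytest.raises(ValueError, match="constant"):
        ss.ScoreVector("flat", 1.0, 1.0, 1.0)


def test_unknown_score_label():
    with pytest.raises(ValueError, match="unknown score label"):
        ss.ScoreVector.canonical("codominant")


def test_counts_margins():
    c = ss.GenotypeCounts(1, 2, 3, 4, 5, 6)
    assert (c.r, c.s, c.n) == (6, 15, 21)
    assert c.totals().tolist() == [5, 7, 9]


def test_negative_count_rejected():
    with pytest.raises(ValueError, match="r1"):
        ss.GenotypeCounts(1, -2, 3, 4, 5, 6)


def test_empty_margin_rejected_by_statistics():
    c = ss.GenotypeCounts(0, 0, 0, 4, 5, 6)
    with pytest.raises(ValueError, match="case"):
        ss.catt_z(c, ss.ADDITIVE)


def test_statvalue_float():
    assert float(ss.StatValue(0.5)) == 0.5


# ---------------------------------------------------------------------------
# catt_z / adjusted_catt
# ---------------------------------------------------------------------------

def test_z_zero_for_identical_distributions():
    c = ss.GenotypeCounts(10, 20, 30, 10, 20, 30)
    sv = ss.catt_z(c, ss.ADDITIVE)
    assert sv.defined and sv.value == pytest.approx(0.0, abs=1e-12)


def test_z_extreme_recessive_table():
    # all cases AA, all controls aa: oracle gives exactly 10 under (0,0,1)
    c = ss.GenotypeCounts(0, 0, 50, 50, 0, 0)
    expected = oracle_trend_z([0, 0, 50], [50, 0, 0], [0, 0, 1])
    assert expected == pytest.approx(10.0)
    assert ss.catt_z(c, ss.RECESSIVE).value == pytest.approx(expected, rel=1e-12)
    assert ss.catt_z(c, ss.RECESSIVE).value > 0


def test_z_undefined_when_score_variance_zero():
    c = ss.GenotypeCounts(25, 25, 0, 25, 25, 0)
    sv = ss.catt_z(c, ss.RECESSIVE)
    assert not sv.defined and sv.value == 0.0
    assert not ss.adjusted_catt(c, ss.RECESSIVE).defined


def test_adjusted_identity_with_z(rng):
    case, control = random_tables(rng, 500)
    for cr, sr in zip(case, control):
        c = table_from_rows(cr, sr)
        for sv in ss.CANONICAL_SCORES:
            z = ss.catt_z(c, sv)
            om = ss.adjusted_catt(c, sv)
            assert z.defined == om.defined
            if z.defined:
                assert om.value * math.sqrt(c.n) == pytest.approx(z.value, rel=1e-10)


def test_adjusted_equals_sample_correlation_example():
    c = ss.GenotypeCounts(10, 20, 30, 30, 20, 10)
    expected = oracle_sample_correlation(c, ss.DOMINANT)
    got = ss.adjusted_catt(c, ss.DOMINANT)
    assert got.defined
    assert got.value == pytest.approx(expected, rel=1e-10)


def test_adjusted_zero_under_proportionality():
    c = ss.GenotypeCounts(5, 10, 15, 10, 20, 30)
    for sv in ss.CANONICAL_SCORES:
        assert ss.adjusted_catt(c, sv).value == pytest.approx(0.0, abs=1e-12)


@given(
    st.lists(st.integers(0, 60), min_size=6, max_size=6).filter(
        lambda v: sum(v[:3]) > 0 and sum(v[3:]) > 0
    )
)
@settings(max_examples=200, deadline=None)
def test_adjusted_bounded_and_matches_correlation(vals):
    c = ss.GenotypeCounts(*vals)
    for sv in ss.CANONICAL_SCORES:
        om = ss.adjusted_catt(c, sv)
        assert abs(om.value) <= 1 + 1e-12
        expected = oracle_sample_correlation(c, sv)
        if expected is None:
            assert not om.defined
        else:
            assert om.value == pytest.approx(expected, rel=1e-10, abs=1e-10)


def test_allele_flip_symmetry(rng):
    case, control = random_tables(rng, 300)
    for cr, sr in zip(case, control):
        c = table_from_rows(cr, sr)
        f = c.flipped()
        pairs = [(ss.RECESSIVE, ss.DOMINANT), (ss.ADDITIVE, ss.ADDITIVE),
                 (ss.DOMINANT, ss.RECESSIVE)]
        for sv, partner in pairs:
            a, b = ss.adjusted_catt(c, sv), ss.adjusted_catt(f, partner)
            assert a.defined == b.defined
            if a.defined:
                assert a.value == pytest.approx(-b.value, rel=1e-10, abs=1e-12)
        assert float(ss.amax(c)) == pytest.approx(float(ss.amax(f)), rel=1e-10)


# ---------------------------------------------------------------------------
# amax
# ---------------------------------------------------------------------------

def test_amax_zero_for_identical_distributions():
    c = ss.GenotypeCounts(10, 20, 30, 10, 20, 30)
    assert float(ss.amax(c)) == pytest.approx(0.0, abs=1e-12)


def test_amax_is_max_of_components():
    c = ss.GenotypeCounts(10, 20, 30, 30, 20, 10)
    parts = [abs(ss.adjusted_catt(c, sv).value) for sv in ss.CANONICAL_SCORES]
    assert float(ss.amax(c)) == pytest.approx(max(parts), rel=1e-12)


def test_amax_excludes_undefined_components():
    # no AA genotype anywhere: recessive score has zero variance
    c = ss.GenotypeCounts(10, 20, 0, 20, 10, 0)
    assert not ss.adjusted_catt(c, ss.RECESSIVE).defined
    defined = [abs(ss.adjusted_catt(c, sv).value)
               for sv in (ss.ADDITIVE, ss.DOMINANT)]
    got = ss.amax(c)
    assert got.defined
    assert got.value == pytest.approx(max(defined), rel=1e-12)


def test_amax_all_undefined():
    c = ss.GenotypeCounts(10, 0, 0, 20, 0, 0)
    got = ss.amax(c)
    assert not got.defined and got.value == 0.0


# ---------------------------------------------------------------------------
# population measures
# ---------------------------------------------------------------------------

def _model_one_population(lam=1.8, alpha=0.45, p=0.5):
    """Independent construction of the recessive-model population law."""
    q = 1 - p
    hwe = [(1 - alpha) ** 2, 2 * alpha * (1 - alpha), alpha**2]
    qj = [q * h for h in hwe]
    denom = qj[0] + qj[1] + lam * qj[2]
    pj = [p * qj[0] / denom, p * qj[1] / denom, p * lam * qj[2] / denom]
    return ss.PopulationSnpModel(p, *pj, *qj)


def _population_omega_oracle(model, x):
    pj, qj = model.case_joint(), model.control_joint()
    f = [pj[i] + qj[i] for i in range(3)]
    num = sum(x[i] * (model.q * pj[i] - model.p * qj[i]) for i in range(3))
    bracket = sum(x[i] ** 2 * f[i] for i in range(3)) - sum(
        x[i] * f[i] for i in range(3)
    ) ** 2
    return num / math.sqrt(model.p * model.q * bracket)


def test_population_omega_zero_under_independence():
    hwe = ss.control_genotype_probs(0.3)
    model = ss.PopulationSnpModel.from_conditionals(0.4, hwe, hwe)
    for sv in ss.CANONICAL_SCORES:
        assert ss.population_omega(model, sv).value == pytest.approx(0.0, abs=1e-12)
    assert float(ss.population_nu(model)) == pytest.approx(0.0, abs=1e-12)


def test_population_omega_model_one_oracle():
    model = _model_one_population()
    expected = _population_omega_oracle(model, [0, 0, 1])
    got = ss.population_omega(model, ss.RECESSIVE)
    assert got.defined
    assert got.value == pytest.approx(expected, rel=1e-12)
    assert abs(got.value) <= 1


def test_population_nu_is_component_max():
    model = _model_one_population()
    parts = [abs(ss.population_omega(model, sv).value) for sv in ss.CANONICAL_SCORES]
    assert float(ss.population_nu(model)) == pytest.approx(max(parts), rel=1e-12)


def test_population_dominant_attains_max_under_dominant_model():
    hwe = ss.control_genotype_probs(0.25)
    case = ss.case_genotype_probs("III", 1.6, hwe)
    model = ss.PopulationSnpModel.from_conditionals(0.5, case, hwe)
    parts = {sv.label: abs(ss.population_omega(model, sv).value)
             for sv in ss.CANONICAL_SCORES}
    assert parts["dominant"] == max(parts.values())


def test_adjusted_catt_consistent_with_population():
    # law of large numbers at n = 10^6
    model = _model_one_population()
    rng = np.random.default_rng(77)
    n = 10**6
    case = rng.multinomial(n // 2, model.case_conditional())
    control = rng.multinomial(n // 2, model.control_conditional())
    c = table_from_rows(case, control)
    pop = ss.population_omega(model, ss.RECESSIVE).value
    assert ss.adjusted_catt(c, ss.RECESSIVE).value == pytest.approx(pop, abs=0.01)


def test_population_model_validation():
    with pytest.raises(ValueError, match="sum to p"):
        ss.PopulationSnpModel(0.5, 0.1, 0.1, 0.1, 0.2, 0.2, 0.1)
    with pytest.raises(ValueError, match="distribution"):
        ss.PopulationSnpModel.from_conditionals(0.5, [0.5, 0.6, -0.1], [0.3, 0.3, 0.4])


def test_consistency_improves_with_sample_size():
    model = _model_one_population()
    pop = ss.population_omega(model, ss.RECESSIVE).value
    rng = np.random.default_rng(5)
    errs = []
    for n in (500, 5000, 50000):
        case = rng.multinomial(n // 2, model.case_conditional(), size=200)
        control = rng.multinomial(n // 2, model.control_conditional(), size=200)
        om = omega_matrix(case, control)[:, 0]
        errs.append(np.abs(om - pop).mean())
    assert errs[0] > errs[1] > errs[2]


# ---------------------------------------------------------------------------
# pc_index
# ---------------------------------------------------------------------------

def test_pc_index_zero_for_identical_distributions():
    c = ss.GenotypeCounts(10, 20, 30, 10, 20, 30)
    assert float(ss.pc_index(c)) == pytest.approx(0.0, abs=1e-12)


def test_pc_index_matches_textbook_chi_square():
    c = ss.GenotypeCounts(10, 20, 30, 30, 20, 10)
    expected = oracle_chi2([10, 20, 30], [30, 20, 10]) / 120
    assert float(ss.pc_index(c)) == pytest.approx(expected, rel=1e-10)


def test_pc_index_drops_empty_column():
    c = ss.GenotypeCounts(10, 0, 30, 30, 0, 10)
    reduced = oracle_chi2([10, 0, 30], [30, 0, 10]) / 80
    assert float(ss.pc_index(c)) == pytest.approx(reduced, rel=1e-10)


def test_pc_index_nonnegative_fuzz(rng):
    case, control = random_tables(rng, 200)
    phi2 = phi2_vector(case, control)
    assert np.all(phi2 >= -1e-12)
    for cr, sr in zip(case[:50], control[:50]):
        c = table_from_rows(cr, sr)
        assert float(ss.pc_index(c)) == pytest.approx(
            phi2_vector(cr, sr)[0], rel=1e-10, abs=1e-12
        )


# ---------------------------------------------------------------------------
# counts_from_genotypes
# ---------------------------------------------------------------------------

def test_tabulation_example():
    c = ss.counts_from_genotypes([0, 1, 2, 2], [1, 1, 0, 0])
    assert (c.r0, c.r1, c.r2) == (1, 1, 0)
    assert (c.s0, c.s1, c.s2) == (0, 0, 2)


def test_tabulation_drops_missing():
    c = ss.counts_from_genotypes([0, np.nan, 2], [1, 0, 0])
    assert (c.r0, c.r1, c.r2, c.s0, c.s1, c.s2) == (1, 0, 0, 0, 0, 1)
    assert c.n == 2


def test_tabulation_counting_oracle(rng):
    g = rng.choice([0, 1, 2, np.nan], size=120, p=[0.3, 0.3, 0.3, 0.1])
    y = rng.integers(0, 2, size=120)
    c = ss.counts_from_genotypes(g, y)
    assert c.n == int(np.isfinite(g).sum())


def test_tabulation_errors():
    with pytest.raises(ValueError, match="equal-length"):
        ss.counts_from_genotypes([0, 1], [1])
    with pytest.raises(ValueError, match="phenotype"):
        ss.counts_from_genotypes([0, 1], [1, 2])


# ---------------------------------------------------------------------------
# vectorized kernels agree with scalar path
# ---------------------------------------------------------------------------

def test_vectorized_matches_scalar(rng):
    case, control = random_tables(rng, 300)
    om = omega_matrix(case, control)
    nu = nu_vector(case, control)
    for k in range(0, 300, 7):
        c = table_from_rows(case[k], control[k])
        for j, sv in enumerate(ss.CANONICAL_SCORES):
            scal = ss.adjusted_catt(c, sv)
            if scal.defined:
                assert om[k, j] == pytest.approx(scal.value, rel=1e-12)
            else:
                assert math.isnan(om[k, j])
        sm = ss.amax(c)
        if sm.defined:
            assert nu[k] == pytest.approx(sm.value, rel=1e-12)
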