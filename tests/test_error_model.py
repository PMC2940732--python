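import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from trnaerr import (
    ElongationProbabilities,
    ModelParams,
    TRNAPool,
    calibrate_a,
    codon_error_profiles,
    derive_dropoff,
    elongation_rates,
    error_rates,
    missense_order_condition,
    sensitivity_sweep,
)

rates_st = st.floats(min_value=1e-6, max_value=1e3, allow_nan=False)


def test_single_cognate_species_rates(params):
    pool = TRNAPool.from_counts("g", {"UGU": 4})
    r_c, r_n = elongation_rates(pool, params)["ACA"]
    assert r_c == pytest.approx(params.scaling_a * params.probs.P_c * 4)
    assert r_n == 0.0


def test_rates_linear_in_gene_copies(toy_pool, params):
    doubled = TRNAPool.from_counts(
        "g2", {sp.anticodon: 2 * sp.gcn for sp in toy_pool.species.values()}
    )
    base = elongation_rates(toy_pool, params)
    two = elongation_rates(doubled, params)
    for cdn in base:
        assert two[cdn][0] == pytest.approx(2 * base[cdn][0])
        assert two[cdn][1] == pytest.approx(2 * base[cdn][1])


def test_toy_pool_matches_hand_summed_rates(toy_pool, params):
    """Oracle: classify the three species by hand for codon ACA.

    UGU is the perfect cognate (w=1), GGU a G.A wobble cognate (w=0.60),
    UGG (Pro) a near-cognate.
    """
    r_c, r_n = elongation_rates(toy_pool, params)["ACA"]
    p = params.probs
    assert r_c == pytest.approx(p.P_c * (1.0 * 3 + 0.60 * 2))
    assert r_n == pytest.approx(p.P_n * 5)


def test_calibration_hits_harmonic_mean_target(ecoli_pool, params):
    a = calibrate_a(ecoli_pool, params)
    rates = elongation_rates(ecoli_pool, replace(params, scaling_a=a))
    r_c = np.array([rc for rc, _ in rates.values()])
    hm = len(r_c) / np.sum(1.0 / r_c)
    assert hm == pytest.approx(params.target_mean_rate, rel=1e-9)


def test_calibration_scale_invariance(ecoli_pool, params):
    doubled = TRNAPool.from_counts(
        "g2", {sp.anticodon: 2 * sp.gcn for sp in ecoli_pool.species.values()}
    )
    assert calibrate_a(doubled, params) == pytest.approx(
        calibrate_a(ecoli_pool, params) / 2
    )


def test_calibration_closed_form_on_toy_target(params):
    pool = TRNAPool.from_counts("g", {ac: 2 for ac in _full_cover_anticodons()})
    p10 = replace(params, target_mean_rate=10.0)
    rates = elongation_rates(pool, replace(p10, scaling_a=1.0))
    r_c = np.array([rc for rc, _ in rates.values()])
    hm = len(r_c) / np.sum(1.0 / r_c)
    assert calibrate_a(pool, p10) == pytest.approx(10.0 / hm)


def _full_cover_anticodons():
    from trnaerr import genetic_code as gc

    return list(gc.SENSE_ANTICODONS)


def test_calibration_names_uncovered_codons(params):
    pool = TRNAPool.from_counts("g", {"UGU": 3})  # covers almost nothing
    with pytest.raises(ValueError, match="codons"):
        calibrate_a(pool, params)


@pytest.mark.parametrize(
    "rc,rn,d,expect",
    [
        (9.0, 1.0, 0.0, (0.1, 0.0)),
        (5.0, 0.0, 0.0, (0.0, 0.0)),   # no competing risks at all
        (0.0, 0.0, 2.0, (0.0, 1.0)),   # only drop-off can resolve the wait
    ],
)
def test_error_rate_branching_fractions(rc, rn, d, expect):
    assert error_rates(rc, rn, d) == pytest.approx(expect)


def test_error_rates_undefined_when_all_zero():
    with pytest.raises(ValueError):
        error_rates(0.0, 0.0, 0.0)


@settings(derandomize=True, deadline=None)
@given(rates_st, rates_st, st.floats(min_value=0, max_value=10))
def test_event_probabilities_normalize(rc, rn, d):
    eps_m, eps_n = error_rates(rc, rn, d)
    p_ok = rc / (rc + rn + d)
    assert eps_m + eps_n + p_ok == pytest.approx(1.0, abs=1e-12)


moderate = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


@settings(derandomize=True, deadline=None)
@given(moderate, moderate, st.floats(min_value=1e-3, max_value=10), moderate)
def test_error_rate_monotonicities(rc, rn, d, bump):
    """eps_N falls with either elongation rate; eps_M falls with R_c and
    rises with R_n."""
    eps_m, eps_n = error_rates(rc, rn, d)
    assert error_rates(rc + bump, rn, d)[1] < eps_n
    assert error_rates(rc, rn + bump, d)[1] < eps_n
    assert error_rates(rc + bump, rn, d)[0] < eps_m
    assert error_rates(rc, rn + bump, d)[0] > eps_m


def test_derive_dropoff_inversion():
    assert derive_dropoff(0.5, 10.0) == pytest.approx(10.0)
    # small-q limit: d ~ q R
    assert derive_dropoff(1e-6, 20.0) == pytest.approx(2e-5, rel=1e-3)
    d = derive_dropoff(4e-4, 10.0)
    assert d / (10.0 + d) == pytest.approx(4e-4)
    with pytest.raises(ValueError):
        derive_dropoff(1.0, 10.0)


def test_missense_order_condition_matches_direct_evaluation(rng):
    """Closed form R_n2 (R_c1 + d) > R_n1 (R_c2 + d) vs direct branching
    fractions on 1000 random synonymous profile pairs."""
    for _ in range(1000):
        rc1, rc2 = rng.uniform(0.01, 50, 2)
        rn1, rn2 = rng.uniform(0.0, 5, 2)
        d = rng.uniform(0.0, 1)
        direct = error_rates(rc2, rn2, d)[0] > error_rates(rc1, rn1, d)[0]
        assert missense_order_condition((rc1, rn1), (rc2, rn2), d) == direct


def test_missense_order_condition_edge_cases():
    assert not missense_order_condition((3.0, 1.0), (3.0, 1.0), 0.5)  # symmetry
    # d = 0 reduces to the R_n/R_c ratio comparison
    assert missense_order_condition((10.0, 1.0), (20.0, 3.0), 0.0) == (3 / 20 > 1 / 10)


def test_profiles_have_61_rows_and_valid_probabilities(ecoli_pool, params):
    prof = codon_error_profiles(ecoli_pool, params)
    assert len(prof) == 61
    assert ((prof.eps_M >= 0) & (prof.eps_N >= 0)).all()
    assert ((prof.eps_M + prof.eps_N) <= 1).all()
    assert prof.degeneracy.groupby(prof.amino_acid).first().sum() == 61


def test_uncorrelated_panel_shows_standard_model_average_behavior(params):
    """With no neighbor correlation the across-codon regression of eps_M on
    R_c is negative on average (the classical expectation)."""
    from trnaerr import SynthConfig, synth_panel

    pools = synth_panel(SynthConfig(n_genomes=30, rho_target=0.0, seed=7))
    slopes = []
    for pool in pools:
        prof = codon_error_profiles(pool, params, calibrate=False)
        ok = prof[(prof.R_c + prof.R_n) > 0]
        if ok.R_c.nunique() < 3:
            continue
        slopes.append(np.polyfit(ok.R_c, ok.eps_M, 1)[0])
    assert np.mean(slopes) < 0


def test_sensitivity_sweep_baseline_is_stable(ecoli_pool, params):
    res = sensitivity_sweep(ecoli_pool, params, d_factors=(1.0,), wobble_tables=((0.64, 0.60),))
    assert res.fraction_sign_stable.iloc[0] == 1.0


def test_dropoff_scaling_raises_every_nonsense_rate(ecoli_pool, params):
    base = codon_error_profiles(ecoli_pool, params)
    high = codon_error_profiles(ecoli_pool, replace(params, dropoff_d=10 * params.dropoff_d))
    assert (high.eps_N.to_numpy() > base.eps_N.to_numpy()).all()


def test_sweep_requires_nonempty_grid(ecoli_pool, params):
    with pytest.raises(ValueError):
        sensitivity_sweep(ecoli_pool, params, d_factors=())
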