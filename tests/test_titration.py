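"""Titration module: state classification, counting, fractions, Hill fits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phtitra.titration import (
    ChargeSet,
    PhRangeFlag,
    ProtonationCounts,
    ReferencePKaTable,
    StateCutoffs,
    TitrationModel,
    TitrationPoint,
    TitrationRecord,
    UndefinedFractionError,
    classify_state,
    count_states,
    cumulative_fraction_series,
    deprotonated_fraction,
    fit_titration_curve,
    hill_curve,
    interpolate_charges,
    pka_shift,
)

CUTS = StateCutoffs()


# -- classification ---------------------------------------------------------

@pytest.mark.parametrize(
    "lam, chi, expected",
    [
        (0.9, 0.1, "deprotonated"),  # pure deprotonated with pure tautomer
        (0.1, 0.5, "discarded"),  # mixed tautomer overrides pure lambda
        (0.5, 0.9, "discarded"),  # lambda in the open middle band
        (0.8, 0.19, "deprotonated"),  # boundary: lambda at the cutoff counts
        (0.2, 0.81, "protonated"),
        (0.1, None, "protonated"),  # single-site residue: chi condition vacuous
        (0.9, None, "deprotonated"),
        (0.9, 0.5, "discarded"),
    ],
)
def test_classify_state(lam, chi, expected):
    rec = TitrationRecord(0, "ASP6", lam, chi)
    assert classify_state(rec, CUTS) == expected


def test_classify_rejects_out_of_range_with_context():
    with pytest.raises(ValueError, match="ASP6.*frame 7"):
        classify_state(TitrationRecord(7, "ASP6", 1.2, 0.0), CUTS)


def test_cutoff_ordering_validated():
    with pytest.raises(ValueError):
        StateCutoffs(deprot_lambda_min=0.2, prot_lambda_max=0.8)


@settings(derandomize=True, max_examples=200)
@given(
    lam=st.floats(0.0, 1.0, allow_nan=False),
    chi=st.one_of(st.none(), st.floats(0.0, 1.0, allow_nan=False)),
)
def test_classification_is_a_partition(lam, chi):
    """Every valid record falls in exactly one of the three classes."""
    label = classify_state(TitrationRecord(0, "X1", lam, chi), CUTS)
    assert label in {"deprotonated", "protonated", "discarded"}


# -- counting ---------------------------------------------------------------

def test_count_states_direct_tally():
    recs = [TitrationRecord(i, "ASP6", 0.9, 0.1) for i in range(80)] + [
        TitrationRecord(80 + i, "ASP6", 0.1, 0.1) for i in range(20)
    ]
    c = count_states(recs, CUTS)
    assert (c.n_deprot, c.n_prot, c.n_discarded, c.n_total) == (80, 20, 0, 100)


def test_count_states_identity_case():
    recs = [TitrationRecord(i, "GLU10", 1.0, 0.0) for i in range(17)]
    c = count_states(recs, CUTS)
    assert (c.n_deprot, c.n_prot, c.n_discarded) == (17, 0, 0)


def test_count_states_empty_rejected():
    with pytest.raises(ValueError, match="empty"):
        count_states([], CUTS)


def test_count_states_mixed_residues_rejected():
    recs = [TitrationRecord(0, "ASP6", 0.9, 0.1), TitrationRecord(1, "GLU10", 0.9, 0.1)]
    with pytest.raises(ValueError, match="single residue"):
        count_states(recs, CUTS)


def test_count_states_matches_per_record_loop(rng):
    """Vectorised tally equals a naive one-record-at-a-time re-count."""
    n = 1000
    lam = rng.random(n)
    chi = np.where(rng.random(n) < 0.2, np.nan, rng.random(n))
    df = pd.DataFrame(
        {"frame": np.arange(n), "residue_id": "HIS26", "lambda": lam, "chi": chi}
    )
    c = count_states(df, CUTS)
    naive = {"deprotonated": 0, "protonated": 0, "discarded": 0}
    for i in range(n):
        rec = TitrationRecord(i, "HIS26", lam[i], None if np.isnan(chi[i]) else chi[i])
        naive[classify_state(rec, CUTS)] += 1
    assert c.n_deprot == naive["deprotonated"]
    assert c.n_prot == naive["protonated"]
    assert c.n_discarded == naive["discarded"]
    assert c.n_deprot + c.n_prot + c.n_discarded == c.n_total == n


# -- fractions --------------------------------------------------------------

@pytest.mark.parametrize(
    "nd, np_, expected", [(80, 20, 0.8), (0, 50, 0.0), (50, 0, 1.0)]
)
def test_deprotonated_fraction(nd, np_, expected):
    counts = ProtonationCounts("ASP6", nd, np_, 0)
    assert deprotonated_fraction(counts) == pytest.approx(expected)


def test_fraction_undefined_when_all_discarded():
    with pytest.raises(UndefinedFractionError):
        deprotonated_fraction(ProtonationCounts("ASP6", 0, 0, 10))


def test_cumulative_series_alternating_tends_to_half():
    recs = [
        TitrationRecord(i, "ASP6", 1.0 if i % 2 == 0 else 0.0, 0.0) for i in range(200)
    ]
    series = cumulative_fraction_series(recs, CUTS)
    assert series["fraction_deprot"].iloc[-1] == pytest.approx(0.5)


def test_cumulative_series_constant_one():
    recs = [TitrationRecord(i, "ASP6", 1.0, 0.0) for i in range(50)]
    series = cumulative_fraction_series(recs, CUTS)
    assert (series["fraction_deprot"] == 1.0).all()


def test_cumulative_series_final_matches_overall(rng):
    n = 500
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "residue_id": "GLU15",
            "lambda": rng.random(n),
            "chi": rng.random(n),
        }
    )
    series = cumulative_fraction_series(df, CUTS)
    overall = deprotonated_fraction(count_states(df, CUTS))
    assert series["fraction_deprot"].iloc[-1] == pytest.approx(overall)


def test_cumulative_series_flags_undefined_prefix():
    recs = [
        TitrationRecord(0, "ASP6", 0.5, 0.5),
        TitrationRecord(1, "ASP6", 0.9, 0.1),
    ]
    series = cumulative_fraction_series(recs, CUTS)
    assert not series["defined"].iloc[0]
    assert np.isnan(series["fraction_deprot"].iloc[0])
    assert series["fraction_deprot"].iloc[1] == 1.0


# -- charge interpolation ---------------------------------------------------

def test_charge_interpolation_endpoints_and_midpoint():
    cs = ChargeSet(("OD1",), q_prot=(0.1,), q_deprot=(-0.5,))
    assert interpolate_charges(1.0, cs) == pytest.approx([-0.5])
    assert interpolate_charges(0.0, cs) == pytest.approx([0.1])
    assert interpolate_charges(0.5, cs) == pytest.approx([-0.2])


def test_charge_set_length_mismatch_rejected():
    with pytest.raises(ValueError):
        ChargeSet(("OD1", "OD2"), q_prot=(0.1,), q_deprot=(-0.5, -0.5))


@settings(derandomize=True, max_examples=100)
@given(
    la=st.floats(0.0, 1.0, allow_nan=False),
    lb=st.floats(0.0, 1.0, allow_nan=False),
)
def test_charge_interpolation_is_linear(la, lb):
    cs = ChargeSet(("A", "B"), q_prot=(0.3, -0.1), q_deprot=(-0.6, 0.2))
    mid = interpolate_charges((la + lb) / 2.0, cs)
    np.testing.assert_allclose(
        interpolate_charges(la, cs) + interpolate_charges(lb, cs), 2 * mid, atol=1e-12
    )


# -- fitting ----------------------------------------------------------------

def _noiseless_points(pka, n, grid=(3, 4, 5, 6, 7)):
    return [TitrationPoint(ph, float(hill_curve(ph, pka, n))) for ph in grid]


def test_fit_recovers_noiseless_parameters():
    fit = fit_titration_curve(_noiseless_points(4.0, 1.0), "ASP6")
    assert fit.converged
    assert fit.pka == pytest.approx(4.0, abs=1e-6)
    assert fit.hill_n == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("pka,n", [(3.5, 0.8), (5.2, 1.3), (6.5, 1.0)])
def test_fitted_curve_is_half_at_fitted_pka(pka, n):
    """The curve midpoint sits at the fitted pKa by construction."""
    fit = fit_titration_curve(_noiseless_points(pka, n), "X")
    assert abs(fit.predict(fit.pka) - 0.5) <= 1e-9


def test_fit_curve_monotone_in_ph():
    fit = fit_titration_curve(_noiseless_points(4.5, 1.1), "X")
    grid = np.linspace(2, 9, 200)
    assert np.all(np.diff(fit.predict(grid)) > 0)


def test_fit_recovers_from_sampled_synthetic_data():
    from phtitra.synthetic import SyntheticSpec, simulate_titration_records

    spec = SyntheticSpec(pka_true=4.0, hill_true=1.0, n_samples_per_ph=50_000, seed=11)
    sim = simulate_titration_records(spec)
    fit = TitrationModel.from_records(sim.records).fit()
    assert fit.converged
    assert abs(fit.pka - 4.0) <= 0.05


@pytest.mark.parametrize(
    "level, flag, bound_edge",
    [(0.99, PhRangeFlag.BELOW_GRID, 3.0), (0.01, PhRangeFlag.ABOVE_GRID, 7.0)],
)
def test_saturated_data_reported_as_bound(level, flag, bound_edge):
    points = [TitrationPoint(ph, level) for ph in (3, 4, 5, 6, 7)]
    fit = fit_titration_curve(points, "LYS")
    assert not fit.converged
    assert fit.ph_range_flag == flag
    assert fit.pka == bound_edge
    assert math.isnan(fit.hill_n)


def test_fit_requires_enough_points():
    with pytest.raises(ValueError):
        fit_titration_curve(_noiseless_points(4.0, 1.0, grid=(4, 5)), "X")
    with pytest.raises(ValueError):
        TitrationModel([4, 4, 4], [0.2, 0.5, 0.7])


def test_weighted_fit_uses_counts():
    pts = [
        TitrationPoint(ph, float(hill_curve(ph, 4.0, 1.0)),
                       ProtonationCounts("ASP6", 50, 50, 0))
        for ph in (3, 4, 5, 6, 7)
    ]
    fit = TitrationModel.from_points(pts).fit(weighted=True)
    assert fit.pka == pytest.approx(4.0, abs=1e-6)


def test_summary_mentions_key_quantities():
    fit = fit_titration_curve(_noiseless_points(4.0, 1.0), "ASP6")
    text = fit.summary()
    assert "pKa" in text and "Hill" in text and "ASP6" in text


# -- reference table and shifts --------------------------------------------

def test_pka_shift_subtraction_and_identity():
    ref = ReferencePKaTable(values={"ASP": 4.0})
    fit = fit_titration_curve(_noiseless_points(3.0, 1.0), "ASP11")
    assert pka_shift(fit, ref) == pytest.approx(-1.0, abs=1e-6)
    fit2 = fit_titration_curve(_noiseless_points(4.0, 1.0), "ASP11")
    assert pka_shift(fit2, ref) == pytest.approx(0.0, abs=1e-6)


def test_pka_shift_sign_convention():
    """A pKa above the reference gives a positive shift (raised pKa)."""
    ref = ReferencePKaTable(values={"ASP": 4.0})
    fit = fit_titration_curve(_noiseless_points(5.2, 1.0), "ASP11")
    assert pka_shift(fit, ref) > 1.0


def test_pka_shift_missing_reference_and_unconverged():
    ref = ReferencePKaTable(values={"ASP": 4.0})
    fit = fit_titration_curve(_noiseless_points(6.0, 1.0), "HIS26")
    with pytest.raises(KeyError, match="HIS"):
        pka_shift(fit, ref)
    saturated = fit_titration_curve([TitrationPoint(p, 0.99) for p in (3, 4, 5)], "ASP6")
    with pytest.raises(ValueError, match="converge"):
        pka_shift(saturated, ref)


def test_reference_table_from_yaml(tmp_path):
    path = tmp_path / "ref.yaml"
    path.write_text("asp: 3.9\nGLU: 4.3\n")
    table = ReferencePKaTable.from_yaml(path)
    assert table.get("ASP16") == pytest.approx(3.9)
    assert table.get("GLU10") == pytest.approx(4.3)


def test_reference_table_resolves_tautomer_names():
    table = ReferencePKaTable.default()
    assert table.get("HSP26") == table.get("HIS26")
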