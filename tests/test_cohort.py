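"""Cohort simulator: distributions, flags, histogram, CSV roundtrip."""

import io

import numpy as np
import pytest

import hecohort as hc
from hecohort.cohort import (
    EXCEPTIONAL,
    STANDARD,
    CohortParams,
    cohort_to_frame,
)


def test_seed_determinism_bit_identical_csv():
    params = CohortParams(n_patients=150, seed=42)
    bufs = []
    for _ in range(2):
        buf = io.StringIO()
        hc.write_cohort_csv(hc.simulate_cohort(params), buf)
        bufs.append(buf.getvalue())
    assert bufs[0] == bufs[1]


def test_degenerate_zero_variance_survival():
    """With zero spread and no exceptional responders every survival is
    exactly 8 months x 30 days."""
    params = CohortParams(n_patients=25, p_exceptional=0.0,
                          sigma_std=0.0, sigma_exc=0.0, seed=1)
    cohort = hc.simulate_cohort(params)
    assert (cohort.survival_days() == 240).all()
    assert (cohort.groups() == STANDARD).all()


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        CohortParams(sigma_std=-1.0).validate()
    with pytest.raises(ValueError):
        CohortParams(p_exceptional=1.5).validate()
    with pytest.raises(ValueError):
        CohortParams(study_months=3, start_window_months=6).validate()


def test_exceptional_fraction_within_binomial_band():
    """n=5000, p=0.05: exceptional count within 250 +/- 3*sqrt(np(1-p))."""
    cohort = hc.simulate_cohort(CohortParams(n_patients=5000, seed=11))
    k = int((cohort.groups() == EXCEPTIONAL).sum())
    sd = np.sqrt(5000 * 0.05 * 0.95)
    assert 250 - 3 * sd <= k <= 250 + 3 * sd


def test_mixture_mean_survival():
    """Across seeds the mean survival approaches
    0.95*8 + 0.05*11 = 8.15 months = 244.5 days."""
    means = [
        hc.simulate_cohort(CohortParams(n_patients=2000, seed=s)).survival_days().mean()
        for s in range(25)
    ]
    # SE of the grand mean ~ 34d/sqrt(50000) ~ 0.15d; allow 5 sigma plus
    # the integer-rounding bias
    assert abs(np.mean(means) - 244.5) < 1.0


def test_groupwise_parameter_recovery():
    """Sample means/sds of survival recover (8,1) and (11,1) months within
    three standard errors at n=5000."""
    cohort = hc.simulate_cohort(CohortParams(n_patients=5000, seed=23))
    surv = cohort.survival_days() / 30.0
    groups = cohort.groups()
    for grp, mu, sigma in ((STANDARD, 8.0, 1.0), (EXCEPTIONAL, 11.0, 1.0)):
        x = surv[groups == grp]
        n = x.size
        se_mean = sigma / np.sqrt(n)
        se_sd = sigma / np.sqrt(2 * (n - 1))
        assert abs(x.mean() - mu) < 3 * se_mean
        assert abs(x.std(ddof=1) - sigma) < 3 * se_sd + 0.01  # day rounding


def test_weights_and_doses_within_truncation_bounds(tiny_cohort):
    for p in tiny_cohort.patients:
        assert p.weight_kg.size == p.visit_months.size
        assert ((p.weight_kg >= 40) & (p.weight_kg <= 150)).all()
        assert ((p.dose_mg_per_kg > 0) & (p.dose_mg_per_kg <= 6.0)).all()
        assert np.allclose(p.dose_mg_per_kg * 10, np.rint(p.dose_mg_per_kg * 10))


# --------------------------------------------------------------------------
# flags
# --------------------------------------------------------------------------


def test_all_standard_cohort_has_zero_flags():
    cohort = hc.simulate_cohort(CohortParams(n_patients=30, p_exceptional=0.0, seed=2))
    assert cohort.flags_matrix().sum() == 0


def test_flag_turns_on_at_death_month():
    """start_day 0, survival 330 days: flag first set at month 11."""
    cohort = hc.simulate_cohort(CohortParams(n_patients=1, p_exceptional=1.0, seed=0))
    p = cohort.patients[0]
    p.start_day = 0
    p.survival_days = 330
    hc.compute_flags(cohort)
    flags = cohort.patients[0].flag_by_month
    assert flags[10] == 0 and flags[11] == 1
    assert (flags[11:] == 1).all()


def test_flags_monotone_and_conserved():
    cohort = hc.simulate_cohort(CohortParams(n_patients=400, seed=5))
    flags = cohort.flags_matrix()
    assert (np.diff(flags, axis=1) >= 0).all()
    n_exc = int((cohort.groups() == EXCEPTIONAL).sum())
    # every exceptional death in this configuration occurs well before
    # month 48, so final flagged total equals the group count
    assert flags[:, -1].sum() == n_exc


# --------------------------------------------------------------------------
# histogram
# --------------------------------------------------------------------------


def test_histogram_single_patient_bin():
    cohort = hc.simulate_cohort(CohortParams(n_patients=1, p_exceptional=0.0,
                                             sigma_std=0.0, seed=0))
    edges, counts = hc.survival_histogram(cohort, bin_days=30)
    idx = np.searchsorted(edges, 240, side="right") - 1
    assert counts[idx] == 1 and counts.sum() == 1


def test_histogram_conserves_patients(tiny_cohort):
    _, counts = hc.survival_histogram(tiny_cohort, bin_days=30)
    assert counts.sum() == tiny_cohort.n_patients


def test_elevated_right_tail_beyond_ten_months():
    """With 5% long survivors the mass beyond 10 months matches the
    mixture tail ~0.064, far above the pure-standard tail ~0.023."""
    cohort = hc.simulate_cohort(CohortParams(n_patients=5000, seed=31))
    frac = float((cohort.survival_days() > 300).mean())
    expected = 0.95 * 0.02275 + 0.05 * 0.84134  # Phi tails at 2sd / -1sd
    sd = np.sqrt(expected * (1 - expected) / 5000)
    assert abs(frac - expected) < 3 * sd + 1e-3
    assert frac > 0.02275 + 3 * np.sqrt(0.02275 * (1 - 0.02275) / 5000)


def test_histogram_rejects_bad_bins(tiny_cohort):
    with pytest.raises(ValueError):
        hc.survival_histogram(tiny_cohort, bin_days=0)


# --------------------------------------------------------------------------
# CSV roundtrip
# --------------------------------------------------------------------------


def test_csv_roundtrip_lossless(tmp_path, tiny_cohort):
    path = tmp_path / "cohort.csv"
    hc.write_cohort_csv(tiny_cohort, path)
    back = hc.read_cohort_csv(path)
    assert back.n_patients == tiny_cohort.n_patients
    for a, b in zip(tiny_cohort.patients, back.patients):
        assert a.patient_id == b.patient_id
        assert a.start_day == b.start_day
        assert a.group == b.group
        assert a.survival_days == b.survival_days
        assert np.array_equal(a.visit_months, b.visit_months)
        assert np.array_equal(a.weight_kg, b.weight_kg)
        assert np.allclose(a.dose_mg_per_kg, b.dose_mg_per_kg)
        assert np.array_equal(a.flag_by_month, b.flag_by_month)


def test_csv_roundtrip_preserves_flags_large(tmp_path):
    cohort = hc.simulate_cohort(CohortParams(n_patients=5000, seed=17))
    path = tmp_path / "big.csv"
    hc.write_cohort_csv(cohort, path)
    back = hc.read_cohort_csv(path)
    assert np.array_equal(back.flags_matrix(), cohort.flags_matrix())


def test_csv_schema_errors(tmp_path, tiny_cohort):
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.raises(Exception):
        hc.read_cohort_csv(empty)
    wrong = tmp_path / "wrong.csv"
    df = cohort_to_frame(tiny_cohort)
    df["extra_column"] = 1
    df.to_csv(wrong, index=False)
    with pytest.raises(ValueError, match="schema"):
        hc.read_cohort_csv(wrong)
    bad = tmp_path / "bad.csv"
    df2 = cohort_to_frame(tiny_cohort)
    df2.loc[3, "group"] = "mystery"
    df2.to_csv(bad, index=False)
    with pytest.raises(ValueError, match="line 5"):
        hc.read_cohort_csv(bad)
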