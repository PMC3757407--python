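import numpy as np
import pandas as pd
import pytest

from leadtime import (
    CohortConfig,
    ScreeningSchedule,
    StableDiseaseParams,
    ValidationError,
    empirical_summary,
    simulate_case,
    simulate_cohort,
)


@pytest.fixture(scope="module")
def hip_cohort():
    p = StableDiseaseParams(w=0.004, beta=0.70, lam=2.50)
    s = ScreeningSchedule(t0=50.0, T=80.0, delta=1.0)
    return simulate_cohort(CohortConfig(p, s, n_cases=50_000, seed=123))


class TestSimulateCase:
    def test_case_invariants_hold_unconditionally(self):
        p = StableDiseaseParams(w=0.004, beta=0.70, lam=2.50)
        s = ScreeningSchedule(t0=50.0, T=80.0, delta=1.0)
        rng = np.random.default_rng(7)
        for _ in range(3000):
            c = simulate_case(p, s, rng)
            assert c.clinical_age == c.onset_age + c.sojourn
            assert c.d_indicator == int(s.t0 < c.clinical_age < s.T)
            if c.lead_time > 0:
                assert c.detection_age is not None and c.d_indicator == 1
                assert max(c.onset_age, s.t0) <= c.detection_age < c.clinical_age
                # detection lies on the exam grid
                i = round((c.detection_age - s.t0) / s.delta)
                assert c.detection_age == pytest.approx(s.t0 + i * s.delta)
                assert c.lead_time == pytest.approx(c.clinical_age - c.detection_age)
                assert c.lead_time <= c.sojourn

    def test_blind_exams_never_detect(self):
        p = StableDiseaseParams(w=0.004, beta=0.0, lam=2.50)
        s = ScreeningSchedule(t0=50.0, T=80.0, delta=1.0)
        rng = np.random.default_rng(7)
        cases = [simulate_case(p, s, rng) for _ in range(500)]
        assert all(c.detection_age is None and c.lead_time == 0.0 for c in cases)

    def test_perfect_first_exam_catches_prevalent_cases(self):
        """beta = 1 and onset before t0: detection at the first exam, lead
        time equal to clinical_age - t0 whenever the case counts as D=1."""
        p = StableDiseaseParams(w=0.004, beta=1.0, lam=2.50)
        s = ScreeningSchedule(t0=50.0, T=80.0, delta=1.0)
        rng = np.random.default_rng(7)
        cases = [simulate_case(p, s, rng) for _ in range(4000)]
        prevalent = [
            c for c in cases if c.onset_age < s.t0 < c.clinical_age
        ]
        assert prevalent, "seeded draw should produce prevalent preclinical cases"
        for c in prevalent:
            assert c.detection_age == s.t0
            if c.d_indicator == 1:
                assert c.lead_time == pytest.approx(c.clinical_age - s.t0)


class TestSimulateCohort:
    def test_fixed_seed_is_bit_identical(self, hip_cohort):
        again = simulate_cohort(hip_cohort.config)
        assert again.cases.equals(hip_cohort.cases)
        assert again.n_raw == hip_cohort.n_raw

    def test_exact_accepted_count_and_window(self, hip_cohort):
        cases = hip_cohort.cases
        s = hip_cohort.config.sched
        assert len(cases) == hip_cohort.config.n_cases
        assert (cases["d_indicator"] == 1).all()
        assert ((cases["clinical_age"] > s.t0) & (cases["clinical_age"] < s.T)).all()

    def test_accepted_case_invariants(self, hip_cohort):
        cases = hip_cohort.cases
        s = hip_cohort.config.sched
        assert np.allclose(
            cases["clinical_age"], cases["onset_age"] + cases["sojourn"], atol=1e-12
        )
        detected = cases["detection_age"].notna()
        assert ((cases["lead_time"] > 0) == detected).all()
        det = cases[detected]
        assert (det["detection_age"] >= np.maximum(det["onset_age"], s.t0)).all()
        assert (det["detection_age"] < det["clinical_age"]).all()
        grid_idx = np.round((det["detection_age"] - s.t0) / s.delta)
        assert np.allclose(det["detection_age"], s.t0 + grid_idx * s.delta)
        assert np.allclose(
            det["lead_time"], det["clinical_age"] - det["detection_age"]
        )
        assert (cases["lead_time"] <= cases["sojourn"] + 1e-12).all()

    def test_residual_lead_times_are_truncated_exponential(self):
        """Memorylessness: given detection at exam age t_d, the lead time is
        Exp(lam) truncated to (0, T - t_d).  Checked by transforming every
        screen-detected lead with its conditional CDF and testing the
        result against Uniform(0, 1)."""
        from scipy.stats import kstest

        p = StableDiseaseParams(w=0.004, beta=0.70, lam=2.50)
        s = ScreeningSchedule(t0=50.0, T=80.0, delta=1.0)
        res = simulate_cohort(CohortConfig(p, s, n_cases=100_000, seed=5))
        det = res.cases[res.cases["detection_age"].notna()]
        tau = s.T - det["detection_age"].to_numpy()
        lead = det["lead_time"].to_numpy()
        u = -np.expm1(-lead / p.lam) / -np.expm1(-tau / p.lam)
        ks = kstest(u, "uniform")
        assert ks.statistic < 0.01

    def test_empty_program_is_impossible_to_configure(self, hip):
        with pytest.raises(ValidationError):
            ScreeningSchedule(t0=50.0, T=50.0, delta=1.0)
        with pytest.raises(ValidationError):
            CohortConfig(hip, ScreeningSchedule(50.0, 80.0, 1.0), n_cases=0)


class TestEmpiricalSummary:
    @staticmethod
    def _frame(leads):
        leads = np.asarray(leads, dtype=float)
        return pd.DataFrame(
            {
                "onset_age": np.zeros_like(leads),
                "sojourn": leads + 1.0,
                "clinical_age": leads + 1.0,
                "detection_age": np.where(leads > 0, 1.0, np.nan),
                "lead_time": leads,
                "d_indicator": np.ones(leads.size, dtype=int),
            }
        )

    def test_hand_arithmetic(self):
        s = empirical_summary(self._frame([0.0, 2.0]), lam=2.5)
        assert s.P == 0.5 and s.Q == 0.5
        assert s.mean == 1.0
        assert s.ratio == pytest.approx(1.0 / 2.5)

    def test_all_zero_leads(self):
        s = empirical_summary(self._frame([0.0, 0.0, 0.0]), lam=2.5)
        assert s.P == 1.0 and s.mean == 0.0 and s.sd == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            empirical_summary(self._frame([]), lam=2.5)

    def test_non_clinical_cases_rejected(self):
        frame = self._frame([0.0, 1.0])
        frame.loc[0, "d_indicator"] = 0
        with pytest.raises(ValidationError):
            empirical_summary(frame, lam=2.5)

    def test_cohort_result_carries_lam(self, hip_cohort):
        s = empirical_summary(hip_cohort)
        assert s.ratio == pytest.approx(s.mean / 2.5)
        assert s.n == len(hip_cohort.cases)
        assert s.se_mean is not None and s.se_mean > 0
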