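"""Significance calls, consistency, ULN, Hy's-law counting, and the paired
condition assessment."""

import numpy as np
import pytest
from scipy import stats

from toxgan.data import ScalerState, StudyScalers, TreatmentCondition
from toxgan.tox import (
    ToxicityCall,
    assess_condition,
    compute_uln,
    consistency,
    hys_law_counts,
    significance_call,
)


class TestSignificanceCall:
    def test_identical_groups_not_significant(self):
        x = np.array([1.0, 2, 3, 4, 5])
        call = significance_call(x, x.copy())
        assert call.p_value > 0.9
        assert not call.significant

    def test_hugely_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        c = rng.normal(10, 1, size=5)
        t = c + 100.0
        call = significance_call(t, c)
        assert call.significant

    def test_pooled_t_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        t = rng.normal(10, 1, size=8)
        c = rng.normal(11, 1, size=6)
        call = significance_call(t, c)
        assert call.test_used == "pooled_t"
        n1, n2 = len(t), len(c)
        sp2 = ((n1 - 1) * t.var(ddof=1) + (n2 - 1) * c.var(ddof=1)) / (n1 + n2 - 2)
        tstat = (t.mean() - c.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(tstat), n1 + n2 - 2)
        assert call.p_value == pytest.approx(p, abs=1e-10)

    def test_non_normal_group_falls_back_to_mann_whitney(self):
        rng = np.random.default_rng(2)
        t = np.exp(rng.normal(0, 2, size=40))  # heavy-tailed, fails Shapiro
        c = rng.normal(10, 1, size=40)
        call = significance_call(t, c)
        assert call.test_used == "mann_whitney"

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            significance_call(np.array([1.0]), np.array([1.0, 2.0]))


def _call(cond, ep, sig, source):
    return ToxicityCall((cond,), ep, source, 0.01 if sig else 0.5, sig, "pooled_t")


class TestConsistency:
    def test_full_agreement(self):
        real = [_call(i, "ALT", True, "real") for i in range(5)]
        synth = [_call(i, "ALT", True, "synthetic") for i in range(5)]
        rep = consistency(real, synth)
        assert rep.per_endpoint.loc[0, "consistency"] == 1.0

    def test_three_of_four_agree(self):
        flags = [True, True, False, True]
        real = [_call(i, "AST", f, "real") for i, f in enumerate(flags)]
        synth = [_call(i, "AST", True, "synthetic") for i in range(4)]
        rep = consistency(real, synth)
        assert rep.per_endpoint.loc[0, "consistency"] == pytest.approx(0.75)

    def test_no_agreement(self):
        real = [_call(i, "ALT", True, "real") for i in range(3)]
        synth = [_call(i, "ALT", False, "synthetic") for i in range(3)]
        assert consistency(real, synth).per_endpoint.loc[0, "consistency"] == 0.0

    def test_symmetric_and_order_invariant(self):
        rng = np.random.default_rng(3)
        real = [_call(i, "ALT", bool(rng.integers(2)), "real") for i in range(10)]
        synth = [_call(i, "ALT", bool(rng.integers(2)), "synthetic") for i in range(10)]
        a = consistency(real, synth).per_endpoint["consistency"].iloc[0]
        b = consistency(synth, real).per_endpoint["consistency"].iloc[0]
        c = consistency(real[::-1], synth).per_endpoint["consistency"].iloc[0]
        assert a == b == c

    def test_misaligned_sets_rejected(self):
        real = [_call(0, "ALT", True, "real")]
        synth = [_call(1, "ALT", True, "synthetic")]
        with pytest.raises(ValueError, match="misaligned"):
            consistency(real, synth)


class TestULN:
    def test_max_over_controls(self, panel):
        M = np.ones((3, 38))
        i = panel.index("ALT")
        M[:, i] = [30.0, 45.0, 41.0]
        uln = compute_uln(M, panel)
        assert uln["ALT"] == 45.0

    def test_single_animal(self, panel):
        M = np.arange(38.0)[None, :]
        uln = compute_uln(M, panel)
        assert uln[panel.codes[5]] == 5.0

    def test_matches_brute_force_column_max(self, panel):
        rng = np.random.default_rng(4)
        M = rng.uniform(0, 100, size=(20, 38))
        uln = compute_uln(M, panel)
        for j, code in enumerate(panel.codes):
            assert uln[code] == max(M[a, j] for a in range(20))

    def test_empty_controls_rejected(self, panel):
        with pytest.raises(ValueError):
            compute_uln(np.empty((0, 38)), panel)


class TestHysLaw:
    def _uln(self, panel, alt=50.0, ast=90.0, tbil=0.5):
        M = np.zeros((1, 38))
        M[0, panel.index("ALT")] = alt
        M[0, panel.index("AST")] = ast
        M[0, panel.index("TBIL")] = tbil
        return compute_uln(M, panel)

    def test_three_subject_derived_case(self, panel):
        uln = self._uln(panel)
        rows = np.zeros((3, 38))
        ia, ib, ic = panel.index("ALT"), panel.index("AST"), panel.index("TBIL")
        rows[0, ia], rows[0, ic] = 60, 1.0   # ALT up, TBIL up -> Hy's
        rows[1, ib], rows[1, ic] = 100, 0.4  # AST up, TBIL normal
        counts = hys_law_counts(rows, uln, panel)
        assert counts == {"n_alt": 1, "n_ast": 1, "n_tbil": 1, "n_hys": 1}

    def test_exactly_at_uln_is_not_exceedance(self, panel):
        uln = self._uln(panel)
        row = np.zeros((4, 38))
        row[:, panel.index("ALT")] = 50.0
        row[:, panel.index("AST")] = 90.0
        row[:, panel.index("TBIL")] = 0.5
        assert hys_law_counts(row, uln, panel) == {
            "n_alt": 0, "n_ast": 0, "n_tbil": 0, "n_hys": 0
        }

    def test_empty_cohort_all_zero(self, panel):
        uln = self._uln(panel)
        assert hys_law_counts(np.empty((0, 38)), uln, panel)["n_hys"] == 0

    def test_set_logic_bounds_on_random_cohorts(self, panel):
        rng = np.random.default_rng(5)
        uln = self._uln(panel, 0.5, 0.5, 0.5)
        for _ in range(50):
            cohort = rng.uniform(0, 1, size=(30, 38))
            c = hys_law_counts(cohort, uln, panel)
            assert c["n_hys"] <= c["n_tbil"]
            assert c["n_hys"] <= c["n_alt"] + c["n_ast"]

    def test_missing_uln_rejected(self, panel):
        sub = panel.subset([c for c in panel.codes if c != "TBIL"])
        uln_vals = compute_uln(np.ones((2, len(sub))), sub)
        with pytest.raises(KeyError, match="TBIL"):
            hys_law_counts(np.ones((2, 38)), uln_vals, panel)


class _EchoTreatedModel:
    """Replays given (already scaled) profile rows cyclically."""

    def __init__(self, rows, noise_dim):
        self.rows = np.atleast_2d(rows)
        self.noise_dim = noise_dim
        self._i = 0

    def infer(self, x):
        n = x.shape[0]
        idx = (self._i + np.arange(n)) % self.rows.shape[0]
        self._i += n
        return self.rows[idx]


class TestAssessCondition:
    def _setup(self, panel, treated_shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        controls = rng.normal(10.0, 1.0, size=(12, 38))
        treated = rng.normal(10.0 + treated_shift, 1.0, size=(5, 38))
        scalers = StudyScalers(
            condition=ScalerState(np.full(6, -100.0), np.full(6, 100.0)),
            profile=ScalerState(np.full(38, -1.0), np.full(38, 1.0)),
        )
        cond = TreatmentCondition("c", "high", 28, descriptors=np.zeros(4))
        return controls, treated, scalers, cond

    def test_model_replaying_real_treated_agrees_everywhere(self, panel):
        controls, treated, scalers, cond = self._setup(panel)
        model = _EchoTreatedModel(treated, noise_dim=6)
        real_calls, synth_calls = assess_condition(
            model, cond, treated, controls, scalers, panel, seed=1, n_draws=5
        )
        rep = consistency(real_calls, synth_calls)
        assert (rep.per_endpoint["consistency"] == 1.0).all()

    def test_control_like_model_disagrees_on_toxic_condition(self, panel):
        controls, _, scalers, cond = self._setup(panel)
        # real treated strongly elevated; model emits control-like values
        treated = controls[:5] + 50.0
        model = _EchoTreatedModel(controls, noise_dim=6)
        real_calls, synth_calls = assess_condition(
            model, cond, treated, controls, scalers, panel, seed=2, n_draws=12
        )
        rep = consistency(real_calls, synth_calls)
        assert rep.per_endpoint["consistency"].mean() < 0.5

    def test_deterministic_given_seed(self, panel):
        controls, treated, scalers, cond = self._setup(panel, treated_shift=2.0)
        p1 = [
            c.p_value
            for c in assess_condition(
                _EchoTreatedModel(treated, 6), cond, treated, controls,
                scalers, panel, seed=7, n_draws=5,
            )[1]
        ]
        p2 = [
            c.p_value
            for c in assess_condition(
                _EchoTreatedModel(treated, 6), cond, treated, controls,
                scalers, panel, seed=7, n_draws=5,
            )[1]
        ]
        assert p1 == p2
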