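"""Generative-LM probe: batching, collection, q scores, and the downstream
statistics (t / d / CI, JZS Bayes factor, prestige correlation)."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereolang.errors import (DegenerateInputError, InsufficientDataError,
                               StereolangError)
from stereolang.llmprobe import (MockProvider, OccupationProbe, PromptSet,
                                 collect_probabilities, jzs_bayes_factor,
                                 make_batches, one_sample_summary,
                                 prestige_correlation, q_score,
                                 summary_from_stats)
from stereolang.synthetic import ProbeSpec, gen_probe_table


def _ps(n_occ=40, batch=20, min_app=10, seed=0):
    return PromptSet(
        benefit_templates=("benefit {MASK}",),
        replacement_templates=("replace {MASK}",),
        occupations=tuple(f"o{i}" for i in range(n_occ)),
        batch_size=batch, min_appearances=min_app, seed=seed)


class TestMakeBatches:
    def test_full_list_batch_degenerates_to_whole_set(self):
        ps = _ps(n_occ=20, batch=20, min_app=3)
        tasks = make_batches(ps)
        assert all(set(t.candidates) == set(ps.occupations) for t in tasks)

    def test_every_occupation_reaches_min_appearances_per_family(self):
        ps = _ps(n_occ=40, batch=20, min_app=10)
        tasks = make_batches(ps)
        counts = {"benefit": {}, "replacement": {}}
        for t in tasks:
            for occ in t.candidates:
                counts[t.family][occ] = counts[t.family].get(occ, 0) + 1
        for fam in counts:
            assert all(counts[fam].get(o, 0) >= 10 for o in ps.occupations)

    def test_same_seed_identical_schedule(self):
        assert make_batches(_ps(seed=4)) == make_batches(_ps(seed=4))

    def test_iteration_cap_guards_infeasible_runs(self):
        with pytest.raises(StereolangError, match="iterations"):
            make_batches(_ps(min_app=1000), max_iterations=3)

    def test_batch_size_larger_than_occupations_rejected(self):
        with pytest.raises(StereolangError):
            _ps(n_occ=10, batch=20)


class TestCollect:
    def test_mock_pass_through_reproduces_table(self):
        fx = gen_probe_table(ProbeSpec(n_occupations=8, n_obs_per_family=4,
                                       noise_sd=0.2, seed=1))
        tasks = make_batches(fx.prompt_set)
        probes = collect_probabilities(fx.provider, tasks, fx.prestige,
                                       k=len(fx.occupations))
        direct = {p.occupation: p for p in fx.probes}
        assert len(probes) == 8
        for p in probes:
            assert p.p_benefit == pytest.approx(direct[p.occupation].p_benefit)
            assert p.p_replacement == pytest.approx(direct[p.occupation].p_replacement)

    def test_occupation_outside_top_k_contributes_nothing(self):
        table = {"benefit {MASK}": {"a": 0.5, "b": 0.3, "c": 0.1},
                 "replace {MASK}": {"a": 0.5, "b": 0.3, "c": 0.1}}
        provider = MockProvider(table)
        ps = PromptSet(("benefit {MASK}",), ("replace {MASK}",), ("a", "b", "c"),
                       batch_size=3, min_appearances=1, seed=0)
        probes = collect_probabilities(provider, make_batches(ps), k=2)
        names = {p.occupation for p in probes}
        assert names == {"a", "b"}  # c fell outside top-2: missing, not zero

    def test_same_seed_identical_probes(self):
        fx = gen_probe_table(ProbeSpec(n_occupations=6, seed=3))
        a = collect_probabilities(fx.provider, make_batches(fx.prompt_set),
                                  fx.prestige, k=6)
        b = collect_probabilities(fx.provider, make_batches(fx.prompt_set),
                                  fx.prestige, k=6)
        assert [(p.occupation, p.p_benefit, p.p_replacement) for p in a] == \
               [(p.occupation, p.p_benefit, p.p_replacement) for p in b]


class TestQScore:
    def test_equal_means_give_zero(self):
        p = OccupationProbe("x", p_benefit=[0.02, 0.04], p_replacement=[0.03, 0.03])
        assert q_score(p) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_ln2(self):
        p = OccupationProbe("x", p_benefit=[0.02, 0.04], p_replacement=[0.01, 0.02])
        assert q_score(p) == pytest.approx(math.log(2), abs=1e-12)
        assert q_score(p) == pytest.approx(0.69315, abs=1e-5)

    def test_empty_family_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            q_score(OccupationProbe("x", p_benefit=[], p_replacement=[0.1]))

    @given(st.lists(st.floats(1e-4, 0.9), min_size=1, max_size=6),
           st.lists(st.floats(1e-4, 0.9), min_size=1, max_size=6),
           st.floats(0.01, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_and_scale_invariance(self, ben, rep, c):
        p = OccupationProbe("x", p_benefit=ben, p_replacement=rep)
        swapped = OccupationProbe("x", p_benefit=rep, p_replacement=ben)
        assert q_score(p) == pytest.approx(-q_score(swapped), abs=1e-9)
        scaled = OccupationProbe("x", p_benefit=[c * b for b in ben],
                                 p_replacement=[c * r for r in rep])
        assert q_score(scaled) == pytest.approx(q_score(p), abs=1e-9)


class TestOneSampleSummary:
    def test_closed_form_identities_on_fixture(self):
        rng = np.random.default_rng(2)
        q = rng.normal(-0.3, 1.1, size=40)
        s = one_sample_summary(q)
        assert s.t == pytest.approx(q.mean() / (q.std(ddof=1) / math.sqrt(40)),
                                    rel=1e-12)
        assert s.d * s.sd == pytest.approx(s.mean, rel=1e-12)
        assert s.df == 39
        from scipy import stats
        t_ref, p_ref = stats.ttest_1samp(q, 0.0)
        assert s.t == pytest.approx(t_ref, rel=1e-10)
        assert s.p == pytest.approx(p_ref, rel=1e-10)

    def test_published_study4_statistics_from_summary_inputs(self):
        s = summary_from_stats(-0.551, 1.920, 65)
        assert s.t == pytest.approx(-2.311, abs=0.005)
        assert s.d == pytest.approx(-0.287, abs=0.001)
        assert s.d_ci_low == pytest.approx(-0.534, abs=0.002)
        assert s.d_ci_high == pytest.approx(-0.039, abs=0.002)
        assert s.p < 0.05

    def test_degenerate_all_zero(self):
        with pytest.raises(DegenerateInputError):
            one_sample_summary([0.0, 0.0, 0.0])


class TestBayesFactor:
    def test_zero_t_favors_null(self):
        for n in (10, 30, 65):
            assert jzs_bayes_factor(0.0, n) < 1.0

    def test_monotone_in_abs_t(self):
        bfs = [jzs_bayes_factor(t, 40) for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_matches_independent_oracle(self):
        """Cross-check the integral against pingouin's JZS implementation."""
        pg = pytest.importorskip("pingouin")
        for t, n in ((-2.311, 65), (1.2, 20), (3.4, 50), (0.0, 12)):
            ref = float(pg.bayesfactor_ttest(t, n, paired=True,
                                             r=math.sqrt(2) / 2))
            assert jzs_bayes_factor(t, n) == pytest.approx(ref, rel=1e-6)

    def test_published_value_reproduced_at_default_prior(self):
        assert jzs_bayes_factor(-2.311, 65) == pytest.approx(1.605, abs=0.01)


class TestPrestigeCorrelation:
    def _probes(self, prestige, q):
        # build probes whose q equals the requested values exactly
        return [OccupationProbe(f"o{i}", prestige=p,
                                p_benefit=[0.01 * math.exp(qi)],
                                p_replacement=[0.01])
                for i, (p, qi) in enumerate(zip(prestige, q))]

    def test_perfect_line_gives_unit_correlation(self):
        res = prestige_correlation(self._probes([1, 2, 3], [1, 3, 5]))
        assert res["r"] == pytest.approx(1.0, abs=1e-9)

    def test_perfect_negative_line(self):
        res = prestige_correlation(self._probes([1, 2, 3], [-1, -2, -3]))
        assert res["r"] == pytest.approx(-1.0, abs=1e-9)

    def test_hand_computed_three_point_r(self):
        res = prestige_correlation(self._probes([1, 2, 3], [1, 2, 2]))
        assert res["r"] == pytest.approx(0.866, abs=0.001)

    def test_missing_prestige_dropped(self):
        probes = self._probes([1, 2, 3], [1, 3, 5])
        probes.append(OccupationProbe("nop", prestige=None,
                                      p_benefit=[0.5], p_replacement=[0.1]))
        res = prestige_correlation(probes)
        assert res["n"] == 3

    def test_recovery_of_planted_correlation_over_seeds(self):
        """With planted slope b and noise s the implied correlation is
        b / sqrt(b^2 + s^2); the estimate should match within MC error."""
        slope, noise = 0.8, 0.4
        implied = slope / math.sqrt(slope ** 2 + noise ** 2)
        rs = []
        for seed in range(8):
            fx = gen_probe_table(ProbeSpec(n_occupations=65, slope=slope,
                                           noise_sd=noise, seed=seed))
            rs.append(prestige_correlation(fx.probes)["r"])
        assert np.mean(rs) == pytest.approx(implied, abs=0.05)
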