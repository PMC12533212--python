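"""SC-WEAT: association scores, classic effect, permutation inference,
pooled standardized regression — each checked against independent brute force
where the spec of the statistic allows it."""
import itertools
import math

import numpy as np
import pytest

from stereolang.embeddings import EmbeddingModel
from stereolang.errors import DegenerateInputError, DesignError
from stereolang.lexicons import Lexicon, make_contrast
from stereolang.scweat import (AssociationRecord, association_score,
                               permutation_pvalue, pooled_regression,
                               scweat_effect, similarity_table)
from stereolang.synthetic import EmbeddingSpec, gen_embeddings


def brute_cosine(u, v):
    num = sum(a * b for a, b in zip(u, v))
    return num / (math.sqrt(sum(a * a for a in u)) * math.sqrt(sum(b * b for b in v)))


def brute_association(model, target, high, low):
    """Independent loop-based association score (no numpy, no shared code path)."""
    w = model.vectors[target]
    hi = sum(brute_cosine(w, model.vectors[a]) for a in high) / len(high)
    lo = sum(brute_cosine(w, model.vectors[b]) for b in low) / len(low)
    return hi - lo


class TestAssociationScore:
    def test_matches_brute_force_on_toy_sets(self, toy_model, toy_contrast):
        rec = association_score(toy_model, "robot", toy_contrast, "d")
        expected = brute_association(toy_model, "robot",
                                     ["smart", "clever"], ["dumb", "slow"])
        assert rec.score == pytest.approx(expected, abs=1e-12)
        assert rec.n_high == 2 and rec.n_low == 2

    def test_aligned_target_scores_one(self):
        m = EmbeddingModel("m", 2, {"w": np.array([1.0, 0.0]),
                                    "h": np.array([1.0, 0.0]),
                                    "l": np.array([0.0, 1.0])})
        pair = make_contrast(Lexicon("h", "attribute", ("h",), "high", "competence"),
                             Lexicon("l", "attribute", ("l",), "low", "competence"),
                             "c")
        assert association_score(m, "w", pair).score == pytest.approx(1.0)

    def test_equidistant_target_scores_zero(self, toy_model):
        pair = make_contrast(
            Lexicon("h", "attribute", ("smart",), "high", "competence"),
            Lexicon("l", "attribute", ("dumb",), "low", "competence"), "c")
        # clever=(1,1) is equidistant from smart=(1,0) and dumb=(0,1)
        assert association_score(toy_model, "clever", pair).score == pytest.approx(0.0)

    def test_swapping_poles_negates_score(self, toy_model, toy_contrast):
        a = association_score(toy_model, "robot", toy_contrast)
        b = association_score(toy_model, "robot", toy_contrast.mirror())
        assert a.score == pytest.approx(-b.score, abs=1e-12)

    def test_oov_skip_records_actual_counts(self, toy_model):
        pair = make_contrast(
            Lexicon("h", "attribute", ("smart", "zzz"), "high", "competence"),
            Lexicon("l", "attribute", ("dumb",), "low", "competence"), "c")
        rec = association_score(toy_model, "robot", pair, oov="skip")
        assert rec.n_high == 1 and rec.n_low == 1


class TestScweatEffect:
    def _records(self, scores):
        return [AssociationRecord(f"w{i}", "c", "m", "d", s, 2, 2)
                for i, s in enumerate(scores)]

    def test_hand_computed_d(self):
        eff = scweat_effect(self._records([0.1, 0.3]))
        # mean 0.2, sd 0.141421 -> d = 1.41421
        assert eff.estimate == pytest.approx(0.2 / np.std([0.1, 0.3], ddof=1), rel=1e-9)
        assert eff.estimate == pytest.approx(1.41421, abs=1e-5)

    def test_symmetric_scores_give_zero(self):
        assert scweat_effect(self._records([0.15, -0.15])).estimate == 0.0

    def test_zero_variance_is_undefined(self):
        with pytest.raises(DegenerateInputError):
            scweat_effect(self._records([0.2, 0.2, 0.2]))

    def test_target_order_invariance(self):
        a = scweat_effect(self._records([0.1, 0.3, -0.2]))
        b = scweat_effect(self._records([-0.2, 0.1, 0.3]))
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)


def brute_permutation_exhaustive(model, targets, high, low):
    """Enumerate every same-size re-partition of the pooled attribute set."""
    pooled = list(high) + list(low)
    observed = np.mean([brute_association(model, t, high, low) for t in targets])
    count = total = 0
    for combo in itertools.combinations(pooled, len(high)):
        rest = [w for w in pooled if w not in combo]
        stat = np.mean([brute_association(model, t, list(combo), rest)
                        for t in targets])
        count += stat >= observed - 1e-12
        total += 1
    return count / total


class TestPermutation:
    def test_exhaustive_matches_brute_force(self, toy_model, toy_contrast):
        targets = Lexicon("t", "target", ("robot",))
        p = permutation_pvalue(toy_model, targets, toy_contrast, n_perm="exhaustive")
        expected = brute_permutation_exhaustive(
            toy_model, ["robot"], ["smart", "clever"], ["dumb", "slow"])
        assert p == pytest.approx(expected, abs=1e-12)
        assert 0.0 < p <= 1.0

    def test_planted_maximal_separation_attains_smallest_p(self):
        # high attrs exactly at the target, low attrs orthogonal: no
        # re-partition beats the observed split, and none ties it
        vecs = {"w": np.array([1.0, 0.0])}
        for i in range(3):
            vecs[f"h{i}"] = np.array([1.0, 0.001 * i])
            vecs[f"l{i}"] = np.array([0.001 * i, 1.0])
        m = EmbeddingModel("m", 2, vecs)
        pair = make_contrast(
            Lexicon("h", "attribute", tuple(f"h{i}" for i in range(3)), "high",
                    "competence"),
            Lexicon("l", "attribute", tuple(f"l{i}" for i in range(3)), "low",
                    "competence"), "c")
        p = permutation_pvalue(m, Lexicon("t", "target", ("w",)), pair,
                               n_perm="exhaustive")
        assert p == pytest.approx(1 / math.comb(6, 3))

    def test_random_mode_is_seed_deterministic(self, toy_model, toy_contrast,
                                               toy_targets):
        a = permutation_pvalue(toy_model, toy_targets, toy_contrast, 50, seed=9)
        b = permutation_pvalue(toy_model, toy_targets, toy_contrast, 50, seed=9)
        assert a == b

    def test_null_type_one_error_near_nominal(self):
        """Under an exchangeable null (all attribute vectors i.i.d.) the
        exhaustive p rejects at about the nominal 0.05 rate; attainable p
        values are multiples of 1/20."""
        rejections = 0
        n_rep = 150
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            vecs = {w: rng.standard_normal(8)
                    for w in ["t0", "t1", "t2", "t3",
                              "h0", "h1", "h2", "l0", "l1", "l2"]}
            model = EmbeddingModel(f"null{seed}", 8, vecs)
            targets = Lexicon("t", "target", ("t0", "t1", "t2", "t3"))
            pair = make_contrast(
                Lexicon("h", "attribute", ("h0", "h1", "h2"), "high",
                        "competence"),
                Lexicon("l", "attribute", ("l0", "l1", "l2"), "low",
                        "competence"), "c")
            p = permutation_pvalue(model, targets, pair, n_perm="exhaustive")
            rejections += p <= 0.05
        rate = rejections / n_rep
        # C(6,3)=20 partitions -> null rejection prob 1/20; binomial 3-sigma band
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_rep)


class TestPooledRegression:
    def test_two_group_closed_form(self):
        """With unit-SD outcomes at group means ±0.25 the slope is 0.5."""
        rows = []
        vals_hi = np.array([0.25 - 0.5, 0.25 + 0.5, 0.25])
        vals_lo = np.array([-0.25 - 0.5, -0.25 + 0.5, -0.25])
        sd = np.std(np.r_[vals_hi, vals_lo], ddof=1)
        import pandas as pd
        table = pd.DataFrame({
            "model_id": "m", "dictionary_id": "d",
            "polarity": [1] * 3 + [0] * 3,
            "similarity": np.r_[vals_hi, vals_lo] / sd * 1.0,
        })
        # re-standardize inside pooled_regression; group-mean difference in SD
        # units is what the slope must equal
        eff = pooled_regression(table)
        std = table["similarity"] / table["similarity"].std(ddof=1)
        expected = std[:3].mean() - std[3:].mean()
        assert eff.estimate == pytest.approx(expected, abs=1e-12)

    def test_identical_distributions_give_zero(self):
        import pandas as pd
        table = pd.DataFrame({
            "model_id": "m", "dictionary_id": "d",
            "polarity": [1, 1, 0, 0], "similarity": [0.1, 0.3, 0.1, 0.3]})
        assert pooled_regression(table).estimate == pytest.approx(0.0, abs=1e-12)

    def test_single_polarity_is_design_error(self):
        import pandas as pd
        table = pd.DataFrame({"model_id": "m", "dictionary_id": "d",
                              "polarity": [1, 1], "similarity": [0.1, 0.3]})
        with pytest.raises(DesignError):
            pooled_regression(table)

    def test_sign_agrees_with_classic_effect_on_planted_bias(self):
        for seed in range(5):
            model, targets, pair, _ = gen_embeddings(EmbeddingSpec(
                n_targets=30, bias=0.5, seed=seed))
            table = similarity_table(model, targets, pair, "d")
            pooled = pooled_regression(table).estimate
            recs = [association_score(model, t, pair, "d") for t in targets.words]
            classic = scweat_effect(recs).estimate
            assert np.sign(pooled) == np.sign(classic)

    def test_reversing_contrast_negates_estimate(self, toy_model, toy_contrast,
                                                 toy_targets):
        fwd = pooled_regression(similarity_table(toy_model, toy_targets,
                                                 toy_contrast, "d"))
        rev = pooled_regression(similarity_table(toy_model, toy_targets,
                                                 toy_contrast.mirror(), "d"))
        assert fwd.estimate == pytest.approx(-rev.estimate, abs=1e-10)

    def test_target_order_invariance(self, toy_model, toy_contrast):
        t1 = Lexicon("t", "target", ("robot", "clever"))
        t2 = Lexicon("t", "target", ("clever", "robot"))
        a = pooled_regression(similarity_table(toy_model, t1, toy_contrast, "d"))
        b = pooled_regression(similarity_table(toy_model, t2, toy_contrast, "d"))
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
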