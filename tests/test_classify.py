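"""Seven-attribute decision rule, thresholds, calibration, evaluation."""

import itertools

import numpy as np
import pytest

from gnmiface import (
    AttributeVector,
    CalibrationError,
    PartitionError,
    ThresholdSet,
    calibrate_thresholds,
    compute_attributes,
    decide,
    decide_reduced,
    evaluate,
    read_thresholds,
    sample_attribute_vectors,
    select_regime,
    subset_stability,
    write_thresholds,
)
from gnmiface.classify import (
    ATTRIBUTE_DIRECTIONS,
    ATTRIBUTE_NAMES,
    NON_OBLIGATORY,
    OBLIGATORY,
    interface_anp,
)
from gnmiface.dynamics import AnchorSet
from gnmiface.gnm import CorrelationMap, ModeSet
from gnmiface.structure import CalphaTrace, Node, partition_subunits


def _trace_2x2():
    nodes = [Node("A", i + 1, " ", "GLY", (3.8 * i, 0, 0)) for i in range(2)]
    nodes += [Node("B", i + 1, " ", "GLY", (3.8 * i, 5, 0)) for i in range(2)]
    return CalphaTrace.from_nodes(nodes)


def _map_with_inter_block(block):
    c = np.eye(4)
    c[:2, 2:] = block
    c[2:, :2] = np.asarray(block).T
    c[0, 1] = c[1, 0] = 0.3
    c[2, 3] = c[3, 2] = 0.3
    return CorrelationMap(raw=c.copy(), mode_set=ModeSet("all", (1,)), normalized=c)


def _no_anchors():
    return AnchorSet(anchors=(), subunit_of_anchor=(), grooves=(), ar=0.0)


class TestComputeAttributes:
    def test_uniform_positive_block(self):
        trace = _trace_2x2()
        part = partition_subunits(trace)
        cmap = _map_with_inter_block(np.full((2, 2), 0.5))
        attrs = compute_attributes(cmap, cmap, part, _no_anchors(), trace)
        assert attrs.a_all == pytest.approx(0.5)
        assert attrs.p_all == pytest.approx(0.5)
        assert attrs.n_all == 0.0

    def test_hand_built_mixed_block(self):
        """{+0.4, -0.2, +0.6, -0.4}: A = 0.1, P = 0.5, N = -0.3 by direct arithmetic."""
        trace = _trace_2x2()
        part = partition_subunits(trace)
        cmap = _map_with_inter_block([[0.4, -0.2], [0.6, -0.4]])
        attrs = compute_attributes(cmap, cmap, part, _no_anchors(), trace)
        assert attrs.a_all == pytest.approx(0.1)
        assert attrs.p_all == pytest.approx(0.5)
        assert attrs.n_all == pytest.approx(-0.3)
        # the ten-slowest map was the same object here
        assert (attrs.a_slow, attrs.n_slow, attrs.p_slow) == (
            attrs.a_all, attrs.n_all, attrs.p_all,
        )

    def test_mean_decomposition_identity_on_fixture(self, anchor_toy_pipeline):
        """A * n_total == P * n_pos + N * n_neg over the inter-subunit block."""
        trace, part = anchor_toy_pipeline["trace"], anchor_toy_pipeline["partition"]
        a, n, p = interface_anp(anchor_toy_pipeline["all"], part, trace)
        idx1, idx2 = part.indices(trace)
        block = anchor_toy_pipeline["all"].normalized[np.ix_(idx1, idx2)].ravel()
        n_pos, n_neg = (block > 0).sum(), (block < 0).sum()
        assert a * block.size == pytest.approx(p * n_pos + n * n_neg, abs=1e-9)
        assert n <= a <= p

    def test_empty_subunit_rejected(self):
        trace = _trace_2x2()
        part = partition_subunits(trace)
        cmap = _map_with_inter_block(np.zeros((2, 2)))
        bad = np.zeros((0,), dtype=int)
        with pytest.raises(PartitionError):
            from gnmiface.classify import _block_stats

            _block_stats(cmap.normalized, bad, np.array([2, 3]))


def _thresholds(**over):
    base = dict(a_all=0.0, n_all=-0.3, p_all=0.3, a_slow=0.0, n_slow=-0.3,
                p_slow=0.3, ar=0.05)
    base.update(over)
    return ThresholdSet(**base)


def _attrs_for_pattern(ts, pattern):
    """Attribute vector passing exactly the attributes flagged in pattern."""
    eps = 0.01
    vals = {}
    for name, passes in zip(ATTRIBUTE_NAMES, pattern):
        t = getattr(ts, name)
        if ATTRIBUTE_DIRECTIONS[name] == ">":
            vals[name] = t + eps if passes else t - eps
        else:
            vals[name] = t - eps if passes else t + eps
    return AttributeVector(**vals)


class TestDecide:
    def test_all_128_verdict_patterns_sum_consistently(self):
        ts = _thresholds()
        for pattern in itertools.product([False, True], repeat=7):
            dec = decide(_attrs_for_pattern(ts, pattern), ts)
            assert dec.d == sum(pattern)
            assert list(dec.verdicts.values()) == list(pattern)
            assert dec.label == (OBLIGATORY if dec.d >= 4 else NON_OBLIGATORY)

    def test_p_attributes_use_less_than(self):
        ts = _thresholds()
        low_p = _attrs_for_pattern(ts, (False,) * 7)
        low_p = AttributeVector(**{**low_p.as_dict(), "p_all": ts.p_all - 0.1})
        assert decide(low_p, ts).verdicts["p_all"]

    def test_monotone_in_a_all_and_p_all(self):
        rng = np.random.default_rng(11)
        ts = _thresholds()
        for _ in range(50):
            vals = {
                name: rng.uniform(-0.6, 0.6) if name != "ar" else rng.uniform(0, 0.2)
                for name in ATTRIBUTE_NAMES
            }
            base = AttributeVector(**vals)
            up = AttributeVector(**{**vals, "a_all": vals["a_all"] + rng.uniform(0, 0.5)})
            down = AttributeVector(**{**vals, "p_all": vals["p_all"] - rng.uniform(0, 0.5)})
            assert decide(up, ts).d >= decide(base, ts).d
            assert decide(down, ts).d >= decide(base, ts).d

    def test_all_pass_gives_seven_and_obligatory(self):
        ts = _thresholds()
        dec = decide(_attrs_for_pattern(ts, (True,) * 7), ts)
        assert dec.d == 7 and dec.label == OBLIGATORY


class TestDecideReduced:
    def test_exhaustive_eight_patterns_against_majority_rule(self):
        thr = (0.0, -0.3, 0.3)
        for pattern in itertools.product([False, True], repeat=3):
            eps = 0.01
            a = thr[0] + (eps if pattern[0] else -eps)
            n = thr[1] + (eps if pattern[1] else -eps)
            p = thr[2] + (-eps if pattern[2] else eps)
            dec = decide_reduced((a, n, p), thr)
            assert dec.d == sum(pattern)
            assert dec.label == (OBLIGATORY if sum(pattern) >= 2 else NON_OBLIGATORY)


class TestSelectRegime:
    @pytest.mark.parametrize(
        "sizes,expected",
        [((227, 227), "large"), ((300, 40), "small"), ((65, 100), "large"),
         ((64, 100), "small"), ((66, 66), "large")],
    )
    def test_size_rule_with_boundary_convention(self, sizes, expected):
        assert select_regime(sizes) == expected


class TestCalibration:
    def test_separable_attribute_recovers_a_separating_cut(self):
        rng = np.random.default_rng(0)
        labeled = []
        for _ in range(20):
            vals = {name: rng.normal(0, 0.01) for name in ATTRIBUTE_NAMES}
            labeled.append((AttributeVector(**{**vals, "a_all": rng.uniform(0.5, 0.9)}),
                            OBLIGATORY))
            labeled.append((AttributeVector(**{**vals, "a_all": rng.uniform(-0.3, 0.2)}),
                            NON_OBLIGATORY))
        ts = calibrate_thresholds(labeled)
        assert 0.2 < ts.a_all < 0.5
        correct = sum(
            (av.a_all > ts.a_all) == (lab == OBLIGATORY) for av, lab in labeled
        )
        assert correct == len(labeled)

    def test_single_label_input_rejected(self):
        av = AttributeVector(0, 0, 0, 0, 0, 0, 0)
        with pytest.raises(CalibrationError):
            calibrate_thresholds([(av, OBLIGATORY), (av, OBLIGATORY)])

    def test_deterministic_given_same_input(self):
        labeled = sample_attribute_vectors(50, 123)
        assert calibrate_thresholds(labeled) == calibrate_thresholds(labeled)

    def test_matches_brute_force_cut_scan(self):
        """Independent scan over every midpoint cut, per attribute."""
        labeled = sample_attribute_vectors(60, 2024)
        ts = calibrate_thresholds(labeled)
        is_obl = np.array([lab == OBLIGATORY for _, lab in labeled])
        for name in ATTRIBUTE_NAMES:
            vals = np.array([getattr(av, name) for av, _ in labeled])
            uniq = np.unique(vals)
            mids = (uniq[:-1] + uniq[1:]) / 2
            best, best_score = None, -1.0
            for t in mids:
                pred = vals > t if ATTRIBUTE_DIRECTIONS[name] == ">" else vals < t
                tpr = pred[is_obl].mean()
                tnr = (~pred[~is_obl]).mean()
                score = (tpr + tnr) / 2
                if score > best_score + 1e-12:
                    best, best_score = t, score
            assert getattr(ts, name) == pytest.approx(best)

    def test_config_round_trip(self):
        labeled = sample_attribute_vectors(30, 5)
        sets = [calibrate_thresholds(labeled, regime=r) for r in ("large", "small")]
        back = read_thresholds(write_thresholds(sets))
        assert back["large"] == sets[0] and back["small"] == sets[1]


class TestEvaluate:
    def _dec(self, label):
        from gnmiface.classify import Decision

        d = 5 if label == OBLIGATORY else 2
        verdicts = {str(i): i < d for i in range(7)}
        return Decision(d=d, label=label, verdicts=verdicts, rule="full_7",
                        mode_config="slowest_10+all")

    def test_all_correct(self):
        pairs = [(self._dec(OBLIGATORY), OBLIGATORY)] * 3
        pairs += [(self._dec(NON_OBLIGATORY), NON_OBLIGATORY)] * 2
        res = evaluate(pairs)
        assert (res.rate_obligatory, res.rate_non_obligatory, res.rate_overall) == (1, 1, 1)
        assert res.d_histogram == {2: 2, 5: 3}

    def test_mixed_arithmetic(self):
        pairs = [(self._dec(OBLIGATORY), OBLIGATORY)] * 3
        pairs += [(self._dec(NON_OBLIGATORY), OBLIGATORY)]
        pairs += [(self._dec(NON_OBLIGATORY), NON_OBLIGATORY)]
        pairs += [(self._dec(OBLIGATORY), NON_OBLIGATORY)]
        res = evaluate(pairs)
        assert res.rate_obligatory == pytest.approx(0.75)
        assert res.rate_non_obligatory == pytest.approx(0.50)
        assert res.rate_overall == pytest.approx(4 / 6)

    def test_random_label_permutation_gives_chance_accuracy(self):
        """With labels shuffled, accuracy falls to the class balance."""
        rng = np.random.default_rng(99)
        labeled = sample_attribute_vectors(200, 7)
        ts = calibrate_thresholds(labeled)
        shuffled = [lab for _, lab in labeled]
        rng.shuffle(shuffled)
        res = evaluate(
            (decide(av, ts), lab) for (av, _), lab in zip(labeled, shuffled)
        )
        # balanced classes: chance level 0.5; 4 sigma of Binomial(400, .5)
        assert abs(res.rate_overall - 0.5) < 4 * 0.5 / np.sqrt(400)


class TestSubsetStability:
    def test_five_fold_replication_is_stable_and_deterministic(self):
        labeled = sample_attribute_vectors(100, 31)
        mean1, sd1, accs1 = subset_stability(labeled, 5, rng=8)
        mean2, sd2, accs2 = subset_stability(labeled, 5, rng=8)
        assert accs1 == accs2
        assert len(accs1) == 5
        assert 0.0 <= sd1 == sd2 <= 0.2
        assert mean1 > 0.7
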