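"""Naive-Bayes evidence integration vs a literal two-class oracle.

The oracle evaluates the posterior formula directly — plain products of
per-bin conditional probabilities with explicit normalization over the
related/unrelated classes — independently of the log-space vectorized
implementation it checks.
"""

import numpy as np
import pytest

from frnrank.bayes import (
    ChannelCPT,
    IntegrationModel,
    apply_model,
    build_frn,
    fit_cpt,
    posterior,
)
from frnrank.goldstd import GoldStandard
from frnrank.pairs import canonical_pair, pairs_to_matrix_channel


def literal_posterior(assignments, prior):
    """Direct product-form evaluation: assignments = [(cpt, bin-or-None)]."""
    num, den = prior, 1.0 - prior
    for cpt, b in assignments:
        if b is None:
            continue
        num *= cpt.p_given_fr[b]
        den *= cpt.p_given_not_fr[b]
    return num / (num + den)


def _cpt_with_lr(name, r):
    """Two-bin CPT with likelihood ratio r in bin 1 (and 1/r in bin 0).

    Both conditional vectors must sum to one, which forces the ratios to
    average to 1 under the null: p_not = [r, 1]/(1+r), p_fr = [1, r]/(1+r).
    """
    r = float(r)
    p_not = np.array([r, 1.0]) / (1.0 + r)
    p_fr = np.array([1.0, r]) / (1.0 + r)
    return ChannelCPT(name, np.array([0.5]), p_fr, p_not, binary=True)


class TestFitCpt:
    def test_binary_counts_with_laplace_smoothing(self):
        pos = np.array([1.0] * 80 + [0.0] * 20)
        neg = np.array([1.0] * 10 + [0.0] * 90)
        cpt = fit_cpt(pos, neg, smoothing=1, binary=True)
        assert cpt.p_given_fr[1] == pytest.approx(81 / 102)
        assert cpt.p_given_not_fr[1] == pytest.approx(11 / 102)

    def test_uninformative_channel_equal_conditionals(self, rng):
        vals = rng.normal(size=200)
        cpt = fit_cpt(vals, vals.copy(), n_bins=5)
        np.testing.assert_allclose(cpt.p_given_fr, cpt.p_given_not_fr)

    def test_smoothing_prevents_zero_bins(self):
        pos = np.array([1.0] * 50)  # no positive ever in bin 0
        neg = np.array([0.0] * 50)
        cpt = fit_cpt(pos, neg, binary=True)
        assert (cpt.p_given_fr > 0).all() and (cpt.p_given_not_fr > 0).all()

    def test_equal_frequency_bins_balance_counts(self, rng):
        vals = rng.normal(size=1000)
        cpt = fit_cpt(vals, rng.normal(size=1000), n_bins=10)
        counts = np.bincount(cpt.bin_index(vals), minlength=cpt.n_bins)
        assert counts.min() > 50  # near-equal occupancy on continuous scores

    def test_no_gold_coverage_names_channel(self):
        with pytest.raises(ValueError, match="docking"):
            fit_cpt(np.array([np.nan]), np.array([np.nan]), name="docking")


class TestPosterior:
    def test_all_missing_returns_prior(self):
        cpt = _cpt_with_lr("c", 10.0)
        assert posterior({"c": None}, [cpt], 0.2) == pytest.approx(0.2)

    def test_unit_likelihood_ratios_leave_prior(self):
        cpt = _cpt_with_lr("c", 1.0)
        assert posterior({"c": 1}, [cpt], 0.3) == pytest.approx(0.3)

    def test_hand_worked_two_channel_example(self):
        # prior 0.01, observed bins with likelihood ratios 10 and 5:
        # posterior = 0.01*50 / (0.01*50 + 0.99)
        c1 = _cpt_with_lr("c1", 10.0)
        c2 = _cpt_with_lr("c2", 5.0)
        got = posterior({"c1": 1, "c2": 1}, [c1, c2], 0.01)
        assert got == pytest.approx(0.01 * 50 / (0.01 * 50 + 0.99), rel=1e-12)
        assert got == pytest.approx(0.33557047, abs=1e-7)

    def test_strictly_increasing_in_channel_likelihood_ratio(self):
        base = _cpt_with_lr("a", 3.0)
        posts = [
            posterior({"a": 1, "b": 1}, [base, _cpt_with_lr("b", lr)], 0.05)
            for lr in [0.5, 1.0, 2.0, 8.0, 100.0]
        ]
        assert all(x < y for x, y in zip(posts, posts[1:]))

    def test_log_space_stable_for_200_extreme_channels(self):
        cpts = [_cpt_with_lr(f"c{i}", 1e6) for i in range(200)]
        hi = posterior({c.name: 1 for c in cpts}, cpts, 0.5)
        lo = posterior({c.name: 0 for c in cpts}, cpts, 0.5)
        assert hi == pytest.approx(1.0) and lo == pytest.approx(0.0)
        assert np.isfinite(hi) and np.isfinite(lo)


def _random_instance(seed, with_expression=False):
    rng = np.random.default_rng(seed)
    genes = list("ABCDE")[: int(rng.integers(4, 6))]
    pairs = [canonical_pair(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
    flags = rng.random(len(pairs)) < 0.5
    positives = {p for p, f in zip(pairs, flags) if f}
    negatives = set(pairs) - positives
    if not positives or not negatives:
        positives, negatives = {pairs[0]}, set(pairs[1:])
    gold = GoldStandard(positives, negatives, frozenset(genes))
    channels = []
    for c in range(3):
        scores = {
            p: float(rng.normal()) for p in pairs if rng.random() < 0.8
        }
        channels.append((f"ch{c}", scores, "score"))
    expression = []
    if with_expression:
        for d in range(2):
            scores = {p: float(rng.normal()) for p in pairs if rng.random() < 0.9}
            expression.append(pairs_to_matrix_channel(f"expr{d}", scores, genes))
    return genes, gold, expression, channels


def _oracle_network(genes, gold, expression, channels, model, n_bins):
    """Literal per-pair evaluation mirroring the fitted model's structure."""
    posts = {}
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            pair = canonical_pair(a, b)
            assignments = []
            cpt_iter = iter(model.layer2_cpts)
            if expression:
                l1 = []
                for cpt, ch in zip(model.layer1_cpts, expression):
                    v = ch.score(*pair)
                    l1.append((cpt, None if np.isnan(v) else int(cpt.bin_index(v))))
                combined_cpt = next(cpt_iter)
                if all(bin_ is None for _, bin_ in l1):
                    assignments.append((combined_cpt, None))
                else:
                    combined = literal_posterior(l1, model.prior)
                    assignments.append(
                        (combined_cpt, int(combined_cpt.bin_index(combined)))
                    )
            for (name, scores, kind), cpt in zip(channels, cpt_iter):
                v = scores.get(pair)
                assignments.append((cpt, None if v is None else int(cpt.bin_index(v))))
            posts[pair] = literal_posterior(assignments, model.prior)
    return posts


class TestBuildFrn:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("with_expression", [False, True])
    def test_matches_literal_two_class_oracle(self, seed, with_expression):
        genes, gold, expression, channels = _random_instance(seed, with_expression)
        net, model = build_frn(expression, channels, gold, genes, n_bins=3)
        oracle = _oracle_network(genes, gold, expression, channels, model, 3)
        for pair, expected in oracle.items():
            assert abs(net.score(*pair) - expected) < 1e-12

    def test_pair_without_evidence_gets_prior(self):
        gold = GoldStandard({("A", "B")}, {("A", "C")}, frozenset("ABC"))
        channels = [("c", {("A", "B"): 1.0, ("A", "C"): 0.0}, "score")]
        net, model = build_frn([], channels, gold, list("ABCD"))
        assert net.score("B", "D") == pytest.approx(model.prior)

    def test_symmetry_and_zero_diagonal(self, small_network):
        _, _, net, _ = small_network
        np.testing.assert_array_equal(net.posterior, net.posterior.T)
        assert (np.diag(net.posterior) == 0).all()
        assert net.posterior.min() >= 0 and net.posterior.max() <= 1

    def test_permuting_universe_permutes_consistently(self):
        genes, gold, _, channels = _random_instance(7)
        net1, _ = build_frn([], channels, gold, genes)
        perm = genes[::-1]
        net2, _ = build_frn([], channels, gold, perm)
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                assert net1.score(a, b) == pytest.approx(net2.score(a, b), rel=1e-12)

    def test_duplicate_universe_gene_rejected(self):
        genes, gold, _, channels = _random_instance(3)
        with pytest.raises(ValueError, match="duplicate"):
            build_frn([], channels, gold, genes + [genes[0]])

    def test_gold_positive_pairs_score_above_negatives(self, small_network):
        _, gold, net, _ = small_network
        pos = np.mean([net.score(*p) for p in sorted(gold.positives)[:2000]])
        neg = np.mean([net.score(*p) for p in sorted(gold.negatives)[:2000]])
        assert pos > neg

    def test_layer1_combination_reinforces_agreeing_channels(self):
        # two agreeing informative channels beat either alone
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        pairs = [
            canonical_pair(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]
        ]
        flags = rng.random(len(pairs)) < 0.3
        gold = GoldStandard(
            {p for p, f in zip(pairs, flags) if f},
            {p for p, f in zip(pairs, flags) if not f},
            frozenset(genes),
        )
        def channel(name):
            return pairs_to_matrix_channel(name, {
                p: (2.0 if p in gold.positives else 0.0) + rng.normal(scale=0.5)
                for p in pairs
            }, genes)
        both, _ = build_frn([channel("e1"), channel("e2")], [], gold, genes, n_bins=5)
        single, _ = build_frn([channel("e3")], [], gold, genes, n_bins=5)
        pos_pairs = sorted(gold.positives)
        mean_both = np.mean([both.score(*p) for p in pos_pairs])
        mean_single = np.mean([single.score(*p) for p in pos_pairs])
        assert mean_both > mean_single


class TestSerialization:
    def test_model_roundtrip_reproduces_posteriors(self, tmp_path):
        genes, gold, expression, channels = _random_instance(11, with_expression=True)
        net, model = build_frn(expression, channels, gold, genes)
        model.to_json(tmp_path / "model.json")
        reloaded = IntegrationModel.from_json(tmp_path / "model.json")
        net2 = apply_model(reloaded, expression, channels, genes)
        np.testing.assert_array_equal(net.posterior, net2.posterior)
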