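"""Block-wise cross-validation and the validity-analysis protocol."""

import numpy as np
import pytest

from ibceeg.evaluation import (
    CVResult,
    ValidityReport,
    blockwise_cv,
    de_fold_builder,
    ibc_fold_builder,
    icc_dcc,
    paired_t_test,
    run_validity,
    split_half_comparison,
    topk_curve,
)
from ibceeg.ibc import IBCConfig
from ibceeg.signal_prep import BandDEFeatures
from ibceeg.synthdata import SynthSpec, simulate_de_features


def _relabel(de, labels):
    return BandDEFeatures(
        values=de.values,
        bands=de.bands,
        labels=labels,
        block_ids=de.block_ids,
        channel_names=de.channel_names,
    )


class TestBlockwiseCV:
    def test_one_fold_per_block(self, small_de):
        de, labels, blocks, _ = small_de
        cv = blockwise_cv(lambda tr, te: labels[te], labels, blocks)
        assert len(cv.fold_accuracies) == 5
        assert set(cv.fold_blocks) == set(np.unique(blocks))

    def test_perfect_features_reach_full_accuracy(self, small_de):
        de, labels, blocks, _ = small_de
        cv = blockwise_cv(lambda tr, te: labels[te], labels, blocks)
        assert cv.mean_accuracy == 1.0

    def test_mean_is_arithmetic_mean_of_folds(self, small_de):
        de, labels, blocks, _ = small_de
        rng = np.random.default_rng(0)
        cv = blockwise_cv(
            lambda tr, te: rng.integers(0, 3, len(te)), labels, blocks
        )
        assert cv.mean_accuracy == pytest.approx(np.mean(cv.fold_accuracies))

    def test_shuffled_labels_score_at_chance(self, small_de):
        de, labels, blocks, _ = small_de
        rng = np.random.default_rng(1)
        shuffled = labels.copy()
        for b in np.unique(blocks):
            idx = np.flatnonzero(blocks == b)
            shuffled[idx] = rng.permutation(shuffled[idx])
        de_s = _relabel(de, shuffled)
        cv = blockwise_cv(de_fold_builder(de_s, seed=0), shuffled, blocks)
        assert 0.25 <= cv.mean_accuracy <= 0.42

    def test_single_block_rejected(self, small_de):
        de, labels, blocks, _ = small_de
        with pytest.raises(ValueError, match="2 distinct blocks"):
            blockwise_cv(lambda tr, te: labels[te], labels, np.zeros_like(blocks))

    def test_missing_test_class_warns_but_scores(self):
        labels = np.array([0, 1, 0, 1, 2, 2])
        blocks = np.array([0, 0, 1, 1, 2, 2])
        with pytest.warns(RuntimeWarning, match="absent from training"):
            cv = blockwise_cv(lambda tr, te: labels[te], labels, blocks)
        assert cv.mean_accuracy == 1.0


class TestSplitHalf:
    def test_leading_signal_favors_top_half(self, small_de, small_config):
        de, *_ = small_de
        top, bottom, p = split_half_comparison(de, small_config, seed=0)
        assert top > bottom
        assert 0 <= p <= 1

    def test_class_independent_data_shows_no_preference(self):
        # a null property over seeds: no systematic top-vs-bottom gap
        diffs, nonsig = [], 0
        for seed in (0, 1, 2, 3, 4):
            spec = SynthSpec(
                n_channels=10, n_epochs_per_block=135, class_effect=0.0, seed=seed
            )
            de, *_ = simulate_de_features(spec)
            top, bottom, p = split_half_comparison(de, IBCConfig(k=5), seed=seed)
            diffs.append(top - bottom)
            nonsig += bool(np.isnan(p) or p > 0.05)
        assert abs(np.mean(diffs)) < 0.08
        assert nonsig >= 4

    def test_requires_enough_channels(self, small_de):
        de, *_ = small_de
        with pytest.raises(ValueError, match="2k"):
            split_half_comparison(de, IBCConfig(k=6))


class TestTopK:
    def test_curve_has_one_entry_per_k(self, small_de, small_config):
        de, *_ = small_de
        curve = topk_curve(de, small_config, [1, 3, 5], seed=0)
        assert sorted(curve) == [1, 3, 5]

    def test_k_bounds_validated(self, small_de, small_config):
        de, *_ = small_de
        with pytest.raises(ValueError):
            topk_curve(de, small_config, [0, 3], seed=0)
        with pytest.raises(ValueError):
            topk_curve(de, small_config, [3, 99], seed=0)


class TestICCDCC:
    def test_dcc_equals_average_of_stored_rho(self, small_de, small_config):
        from ibceeg.ibc import build_ibc

        de, *_ = small_de
        icc, dcc, cc = icc_dcc(de, small_config)
        fset = build_ibc(de, small_config)
        expected = np.mean(
            [fset.models[p].rho[: small_config.k] for p in fset.pair_order], axis=0
        )
        np.testing.assert_allclose(dcc, expected, atol=1e-12)

    def test_null_labels_give_near_zero_icc(self):
        spec = SynthSpec(
            n_channels=10, n_epochs_per_block=200, class_effect=0.0, seed=30
        )
        de, *_ = simulate_de_features(spec)
        icc, dcc, cc = icc_dcc(de, IBCConfig(k=5))
        n = de.n_epochs
        frac_below = np.mean(icc < 2.58 / np.sqrt(n))
        # icc entries are means of 10 |r| values so they sit below the
        # single-correlation 99% null quantile almost surely
        assert frac_below >= 0.95

    def test_positive_cc_under_leading_signal(self, small_de, small_config):
        de, *_ = small_de
        _, _, cc = icc_dcc(de, small_config)
        assert cc > 0.0

    def test_needs_three_components(self, small_de):
        de, *_ = small_de
        with pytest.raises(ValueError, match="3 components"):
            icc_dcc(de, IBCConfig(k=2))

    def test_vectors_bounded(self, small_de, small_config):
        de, *_ = small_de
        icc, dcc, cc = icc_dcc(de, small_config)
        assert np.all((icc >= 0) & (icc <= 1))
        assert np.all((dcc >= 0) & (dcc <= 1))
        assert -1 <= cc <= 1


class TestPairedT:
    def test_identical_vectors_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test(a, a)

    def test_constant_shift_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test(a + 1.0, a)

    def test_textbook_example(self):
        # differences (-1, 0, -1, 0, -1): mean -0.6, sd 0.5477 ->
        # t = -0.6 / (0.5477 / sqrt(5)) = -2.4495, p = 0.0705 at df=4
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 2.0, 4.0, 4.0, 6.0])
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(-2.44949, abs=1e-4)
        assert p == pytest.approx(0.07048, abs=1e-4)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            paired_t_test(np.array([1.0]), np.array([2.0]))


class TestLeakageGuard:
    def test_block_permuted_labels_score_at_chance(self, small_de):
        # permuting labels across blocks destroys any feature-label link;
        # a leak of test-epoch information would push accuracy above chance
        de, labels, blocks, _ = small_de
        rng = np.random.default_rng(5)
        permuted = labels[rng.permutation(len(labels))]
        de_p = _relabel(de, permuted)
        cfg = IBCConfig(k=5)
        acc = blockwise_cv(ibc_fold_builder(de_p, cfg, seed=0), permuted, blocks).mean_accuracy
        assert 0.25 <= acc <= 0.42


def test_validity_report_round_trip(tmp_path, small_de, small_config):
    de, *_ = small_de
    report = run_validity(de, small_config, k_values=[1, 3, 5], seed=0)
    path = str(tmp_path / "report.json")
    report.to_json(path)
    loaded = ValidityReport.from_json(path)
    assert loaded.topk_accuracy == report.topk_accuracy
    np.testing.assert_allclose(loaded.icc, report.icc)
    np.testing.assert_allclose(loaded.dcc, report.dcc)
    assert loaded.cc == report.cc
    assert loaded.split_half == report.split_half
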