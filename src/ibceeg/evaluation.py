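"""Block-wise cross-validation and the IBC validity-analysis protocol.

Folds are defined by stimulus block (clip): each block in turn is the test
set and the whole pipeline — feature standardization, per-pair CCA, and the
SVM classifiers — is refitted on the remaining blocks, so nothing estimated
on test epochs ever leaks into training.  On top of the basic CV accuracy
the module implements the validity analyses of the IBC construction:

* split-half comparison — accuracy with the leading half of the canonical
  components versus the trailing half of the same fitted models;
* top-k curve — accuracy as a function of the number of leading components;
* ICC/DCC — per-component mean |correlation| between IBC features and the
  class label (ICC) versus the mean canonical correlation (DCC), and the
  Pearson correlation CC between the two curves;
* pairwise-band accuracy matrix — CV accuracy of each band pair on its own,
  diagonal fixed at zero.

For categorical labels the ICC uses the absolute Pearson correlation with
integer class codes 0..c-1; this choice is isolated in one helper so an
alternative association measure can be swapped in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .fusion_classify import fuse, train_classifier
from .ibc import IBCConfig, build_ibc, transform_ibc
from .signal_prep import BandDEFeatures

__all__ = [
    "CVResult",
    "ValidityReport",
    "blockwise_cv",
    "de_fold_builder",
    "ibc_fold_builder",
    "fused_fold_builder",
    "split_half_comparison",
    "topk_curve",
    "icc_dcc",
    "pairwise_band_accuracy",
    "paired_t_test",
    "run_validity",
]

FoldBuilder = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class CVResult:
    """Per-block fold accuracies and predictions of one block-wise CV run."""

    fold_accuracies: np.ndarray
    fold_blocks: np.ndarray
    predictions: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "fold_blocks": self.fold_blocks.tolist(),
            "fold_accuracies": self.fold_accuracies.tolist(),
            "mean_accuracy": self.mean_accuracy,
        }


@dataclass
class ValidityReport:
    """Results of the validity protocol on one dataset."""

    topk_accuracy: dict[int, float]
    icc: np.ndarray
    dcc: np.ndarray
    cc: float
    split_half: tuple[float, float, float]  # (acc_top, acc_bottom, p)

    def to_dict(self) -> dict:
        return {
            "topk_accuracy": {str(k): v for k, v in self.topk_accuracy.items()},
            "icc": np.asarray(self.icc).tolist(),
            "dcc": np.asarray(self.dcc).tolist(),
            "cc": self.cc,
            "split_half": {
                "accuracy_top": self.split_half[0],
                "accuracy_bottom": self.split_half[1],
                "p_value": self.split_half[2],
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ValidityReport":
        with open(path) as f:
            d = json.load(f)
        sh = d["split_half"]
        return cls(
            topk_accuracy={int(k): v for k, v in d["topk_accuracy"].items()},
            icc=np.asarray(d["icc"]),
            dcc=np.asarray(d["dcc"]),
            cc=d["cc"],
            split_half=(sh["accuracy_top"], sh["accuracy_bottom"], sh["p_value"]),
        )


# ---------------------------------------------------------------------------
# block-wise cross-validation
# ---------------------------------------------------------------------------

def blockwise_cv(
    fold_builder: FoldBuilder,
    labels: np.ndarray,
    block_ids: np.ndarray,
) -> CVResult:
    """One fold per distinct block: ``fold_builder(train_idx, test_idx)``
    must fit everything on the training epochs and return predicted labels
    for the test epochs."""
    labels = np.asarray(labels, dtype=int)
    block_ids = np.asarray(block_ids, dtype=int)
    blocks = np.unique(block_ids)
    if len(blocks) < 2:
        raise ValueError("block-wise CV requires at least 2 distinct blocks")

    accs, preds = [], {}
    for blk in blocks:
        test_idx = np.flatnonzero(block_ids == blk)
        train_idx = np.flatnonzero(block_ids != blk)
        missing = set(labels[test_idx]) - set(labels[train_idx])
        if missing:
            warnings.warn(
                f"block {blk}: class(es) {sorted(missing)} absent from training; "
                "fold scored anyway",
                RuntimeWarning,
                stacklevel=2,
            )
        y_hat = np.asarray(fold_builder(train_idx, test_idx))
        accs.append(float(np.mean(y_hat == labels[test_idx])))
        preds[int(blk)] = y_hat
    return CVResult(
        fold_accuracies=np.asarray(accs),
        fold_blocks=blocks,
        predictions=preds,
    )


def de_fold_builder(
    de: BandDEFeatures, seed: int = 0, cost: float = 1.0
) -> FoldBuilder:
    """Fold builder classifying on the flattened (channels x bands) DE rows."""
    X = de.flattened()
    y = de.labels

    def build(train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
        clf = train_classifier(X[train_idx], y[train_idx], seed=seed, cost=cost, feature_tag="DE")
        return clf.predict(X[test_idx])

    return build


def _subset(de: BandDEFeatures, idx: np.ndarray) -> BandDEFeatures:
    return BandDEFeatures(
        values=de.values[idx],
        bands=de.bands,
        labels=de.labels[idx],
        block_ids=de.block_ids[idx],
        channel_names=de.channel_names,
    )


def ibc_fold_builder(
    de: BandDEFeatures, config: IBCConfig, seed: int = 0, cost: float = 1.0
) -> FoldBuilder:
    """Fold builder refitting the per-pair CCAs and the SVM per fold."""
    y = de.labels

    def build(train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
        fset = build_ibc(_subset(de, train_idx), config)
        clf = train_classifier(
            fset.concatenated, y[train_idx], seed=seed, cost=cost, feature_tag="IBC"
        )
        return clf.predict(transform_ibc(fset, _subset(de, test_idx)))

    return build


def fused_fold_builder(
    de: BandDEFeatures,
    config: IBCConfig,
    seed: int = 0,
    cost: float = 1.0,
    weights: tuple[float, float] = (1.0, 1.0),
    de_features: BandDEFeatures | None = None,
) -> FoldBuilder:
    """Fold builder fusing the DE and IBC classifiers by the probability
    sum rule.  ``de_features`` lets the raw-feature classifier use a
    different feature container than the one the CCAs are built from."""
    raw = de_features if de_features is not None else de
    X_raw = raw.flattened()
    y = de.labels

    def build(train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
        clf_de = train_classifier(
            X_raw[train_idx], y[train_idx], seed=seed, cost=cost, feature_tag="DE"
        )
        fset = build_ibc(_subset(de, train_idx), config)
        clf_ibc = train_classifier(
            fset.concatenated, y[train_idx], seed=seed, cost=cost, feature_tag="IBC"
        )
        p_de = clf_de.predict_proba(X_raw[test_idx])
        p_ibc = clf_ibc.predict_proba(transform_ibc(fset, _subset(de, test_idx)))
        return fuse(p_de, p_ibc, weights=weights).fused_label

    return build


# ---------------------------------------------------------------------------
# validity protocol
# ---------------------------------------------------------------------------

def split_half_comparison(
    de: BandDEFeatures,
    config: IBCConfig,
    seed: int = 0,
) -> tuple[float, float, float]:
    """CV accuracy with the leading k canonical components versus the
    trailing k of the same construction; paired t-test over fold accuracies.

    Returns ``(acc_top, acc_bottom, p_value)``; ``p_value`` is NaN when the
    per-fold differences are constant (degenerate paired test).
    """
    if de.n_channels < 2 * config.k:
        raise ValueError(
            f"split-half needs n_channels >= 2k, got {de.n_channels} < {2 * config.k}"
        )
    top_cfg = IBCConfig(
        k=config.k, alpha1=config.alpha1, alpha2=config.alpha2,
        pair_order=config.pair_order, ridge=config.ridge, component_slice="leading",
    )
    bot_cfg = IBCConfig(
        k=config.k, alpha1=config.alpha1, alpha2=config.alpha2,
        pair_order=config.pair_order, ridge=config.ridge, component_slice="trailing",
    )
    cv_top = blockwise_cv(ibc_fold_builder(de, top_cfg, seed=seed), de.labels, de.block_ids)
    cv_bot = blockwise_cv(ibc_fold_builder(de, bot_cfg, seed=seed), de.labels, de.block_ids)
    try:
        _, p = paired_t_test(cv_top.fold_accuracies, cv_bot.fold_accuracies)
    except ValueError:
        p = float("nan")
    return cv_top.mean_accuracy, cv_bot.mean_accuracy, p


def topk_curve(
    de: BandDEFeatures,
    config: IBCConfig,
    k_values: list[int],
    seed: int = 0,
) -> dict[int, float]:
    """Block-wise CV accuracy as a function of the number of leading
    canonical components per pair."""
    if min(k_values) < 1:
        raise ValueError("k values must be >= 1")
    if max(k_values) > de.n_channels:
        raise ValueError("k cannot exceed the channel count")
    out = {}
    for k in k_values:
        cfg = IBCConfig(
            k=k, alpha1=config.alpha1, alpha2=config.alpha2,
            pair_order=config.pair_order, ridge=config.ridge,
        )
        cv = blockwise_cv(ibc_fold_builder(de, cfg, seed=seed), de.labels, de.block_ids)
        out[int(k)] = cv.mean_accuracy
    return out


def _label_feature_correlation(column: np.ndarray, labels: np.ndarray) -> float:
    """|Pearson r| between one feature column and integer class codes."""
    if np.std(column) == 0 or np.std(labels) == 0:
        return 0.0
    return float(abs(np.corrcoef(column, labels.astype(float))[0, 1]))


def icc_dcc(
    de: BandDEFeatures,
    config: IBCConfig,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-component feature-label correlation (ICC) versus canonical
    correlation (DCC), both averaged over the band pairs, and their Pearson
    correlation CC.

    Descriptive analysis: the IBC set is fitted on all provided epochs.
    Needs at least 3 components for CC to be meaningful.
    """
    if config.k < 3:
        raise ValueError("ICC/DCC correlation requires at least 3 components")
    fset = build_ibc(de, config)
    K = config.k
    pairs = fset.pair_order
    icc = np.zeros(K)
    dcc = np.zeros(K)
    for k in range(K):
        icc[k] = np.mean(
            [
                _label_feature_correlation(fset.per_pair[p][:, k], de.labels)
                for p in pairs
            ]
        )
        dcc[k] = np.mean([fset.models[p].rho[k] for p in pairs])
    cc = float(stats.pearsonr(icc, dcc)[0])
    return icc, dcc, cc


def pairwise_band_accuracy(
    de: BandDEFeatures,
    config: IBCConfig,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric (n_bands x n_bands) matrix of block-wise CV accuracies using
    each band pair's IBC features alone; diagonal fixed at zero."""
    if de.n_bands < 2:
        raise ValueError("need at least 2 bands")
    nb = de.n_bands
    acc = np.zeros((nb, nb))
    y, blk = de.labels, de.block_ids
    for i in range(nb):
        for j in range(i + 1, nb):
            cfg = IBCConfig(
                k=config.k, alpha1=config.alpha1, alpha2=config.alpha2,
                pair_order=[(i, j)], ridge=config.ridge,
            )
            cv = blockwise_cv(ibc_fold_builder(de, cfg, seed=seed), y, blk)
            acc[i, j] = acc[j, i] = cv.mean_accuracy
    return acc


def paired_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test; errors when the differences have zero
    variance (t undefined)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired t-test needs two equal-length vectors of length >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def run_validity(
    de: BandDEFeatures,
    config: IBCConfig,
    k_values: list[int] | None = None,
    seed: int = 0,
) -> ValidityReport:
    """Full validity protocol: top-k curve, ICC/DCC/CC, split-half."""
    if k_values is None:
        step = max(1, config.k // 8)
        k_values = list(range(1, config.k + 1, step))
    icc, dcc, cc = icc_dcc(de, config)
    split = split_half_comparison(de, config, seed=seed)
    curve = topk_curve(de, config, k_values, seed=seed)
    return ValidityReport(
        topk_accuracy=curve, icc=icc, dcc=dcc, cc=cc, split_half=split
    )
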