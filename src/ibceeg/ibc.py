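"""Inter-band correlation (IBC) features.

For every unordered pair of frequency bands, a CCA is fitted between the two
bands' per-channel differential-entropy matrices.  The pair's canonical
variates ``X1' = W1^T X1`` and ``X2' = W2^T X2`` are fused by a convex
weighted sum ``XF = alpha1 * X1' + alpha2 * X2'`` (``alpha1 + alpha2 = 1``),
and the ten per-pair blocks (for five bands) are concatenated into the final
feature matrix ``X_IBC``.  Within a pair, columns are ordered by descending
canonical correlation, so "top-k" always means the k most strongly coupled
component directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import h5py
import numpy as np

from .cca_core import (
    CCAModel,
    DEFAULT_RIDGE,
    canonical_transform,
    fit_cca,
    load_cca_h5,
    save_cca_h5,
)
from .signal_prep import BandDEFeatures

__all__ = [
    "IBCConfig",
    "IBCFeatureSet",
    "default_pair_order",
    "pair_ibc",
    "build_ibc",
    "transform_ibc",
    "save_ibc_h5",
    "load_ibc_h5",
]


def default_pair_order(n_bands: int) -> list[tuple[int, int]]:
    """Lexicographic unordered band pairs: for five bands
    (0,1) (0,2) (0,3) (0,4) (1,2) (1,3) (1,4) (2,3) (2,4) (3,4),
    i.e. delta-theta, delta-alpha, ..., beta-gamma."""
    return list(combinations(range(n_bands), 2))


@dataclass
class IBCConfig:
    """Configuration for IBC construction.

    ``k`` is the number of canonical components kept per band pair
    (convention: half the channel count — 31 for 62 channels, 30 for 60).
    ``alpha1``/``alpha2`` weight the two canonical variates in the fusion
    and must sum to 1; equal weights are the default.
    """

    k: int = 31
    alpha1: float = 0.5
    alpha2: float = 0.5
    pair_order: list[tuple[int, int]] | None = None
    ridge: float = DEFAULT_RIDGE
    component_slice: str = "leading"  # or "trailing": which end of the spectrum

    def __post_init__(self) -> None:
        if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-9:
            raise ValueError(f"alpha1 + alpha2 must equal 1, got {self.alpha1 + self.alpha2}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.component_slice not in ("leading", "trailing"):
            raise ValueError("component_slice must be 'leading' or 'trailing'")
        if self.pair_order is not None:
            pairs = [tuple(sorted(p)) for p in self.pair_order]
            if len(set(pairs)) != len(pairs):
                raise ValueError("pair_order contains a duplicate band pair")
            self.pair_order = [tuple(p) for p in self.pair_order]


@dataclass
class IBCFeatureSet:
    """Fitted IBC features: per-pair XF blocks, their concatenation X_IBC,
    and the per-pair CCA models needed to transform held-out epochs."""

    per_pair: dict[tuple[int, int], np.ndarray]
    concatenated: np.ndarray
    models: dict[tuple[int, int], CCAModel]
    config: IBCConfig
    band_names: list[str] = field(default_factory=list)

    @property
    def pair_order(self) -> list[tuple[int, int]]:
        return list(self.per_pair.keys())

    def pair_name(self, pair: tuple[int, int]) -> str:
        if self.band_names:
            return f"{self.band_names[pair[0]]}-{self.band_names[pair[1]]}"
        return f"band{pair[0]}-band{pair[1]}"

    def column_names(self) -> list[str]:
        return [
            f"{self.pair_name(p)}_{i + 1:02d}"
            for p in self.pair_order
            for i in range(self.config.k)
        ]


def _component_indices(config: IBCConfig, n_comp: int) -> np.ndarray:
    """Column indices into the descending-rho component axis for this config."""
    if config.k > n_comp:
        raise ValueError(
            f"k={config.k} exceeds the {n_comp} available canonical components"
        )
    if config.component_slice == "leading":
        return np.arange(config.k)
    return np.arange(n_comp - config.k, n_comp)


def pair_ibc(
    de_x: np.ndarray,
    de_y: np.ndarray,
    config: IBCConfig,
) -> tuple[np.ndarray, CCAModel]:
    """Fit one band pair: CCA, canonical projections, alpha-weighted fusion.

    Returns ``(XF, model)`` where ``XF = alpha1 * X' + alpha2 * Y'`` has
    ``config.k`` columns ordered by descending canonical correlation (or the
    trailing k when ``component_slice='trailing'``).
    """
    model = fit_cca(de_x, de_y, ridge=config.ridge, k="all")
    idx = _component_indices(config, model.n_components)
    Xp, Yp = canonical_transform(model, de_x, de_y, k=model.n_components)
    XF = config.alpha1 * Xp[:, idx] + config.alpha2 * Yp[:, idx]
    return XF, model


def build_ibc(de: BandDEFeatures, config: IBCConfig) -> IBCFeatureSet:
    """Fit IBC features over every band pair and concatenate into X_IBC."""
    if de.n_bands < 2:
        raise ValueError("IBC requires at least 2 bands")
    pairs = config.pair_order or default_pair_order(de.n_bands)
    per_pair: dict[tuple[int, int], np.ndarray] = {}
    models: dict[tuple[int, int], CCAModel] = {}
    for i, j in pairs:
        XF, model = pair_ibc(de.band_matrix(i), de.band_matrix(j), config)
        per_pair[(i, j)] = XF
        models[(i, j)] = model
    concatenated = np.hstack([per_pair[p] for p in per_pair])
    return IBCFeatureSet(
        per_pair=per_pair,
        concatenated=concatenated,
        models=models,
        config=config,
        band_names=[b.name for b in de.bands],
    )


def transform_ibc(feature_set: IBCFeatureSet, de_new: BandDEFeatures) -> np.ndarray:
    """Apply the frozen per-pair models (standardization + projections +
    alpha-weighted sum) to new epochs; concatenate blocks in pair order."""
    config = feature_set.config
    blocks = []
    for pair in feature_set.pair_order:
        model = feature_set.models[pair]
        Xn = de_new.band_matrix(pair[0])
        Yn = de_new.band_matrix(pair[1])
        if Xn.shape[1] != model.dim_x or Yn.shape[1] != model.dim_y:
            raise ValueError(
                f"channel-count mismatch for pair {pair}: model expects "
                f"({model.dim_x}, {model.dim_y}), got ({Xn.shape[1]}, {Yn.shape[1]})"
            )
        idx = _component_indices(config, model.n_components)
        Xp, Yp = canonical_transform(model, Xn, Yn, k=model.n_components)
        blocks.append(config.alpha1 * Xp[:, idx] + config.alpha2 * Yp[:, idx])
    return np.hstack(blocks)


def save_ibc_h5(feature_set: IBCFeatureSet, path: str) -> None:
    with h5py.File(path, "w") as f:
        cfg = feature_set.config
        f.attrs["k"] = cfg.k
        f.attrs["alpha1"] = cfg.alpha1
        f.attrs["alpha2"] = cfg.alpha2
        f.attrs["ridge"] = cfg.ridge
        f.attrs["component_slice"] = cfg.component_slice
        f.attrs["band_names"] = feature_set.band_names
        f.attrs["pair_order"] = np.array(feature_set.pair_order)
        f.create_dataset("concatenated", data=feature_set.concatenated)
        for pair in feature_set.pair_order:
            grp = f.create_group(f"pair_{pair[0]}_{pair[1]}")
            grp.create_dataset("XF", data=feature_set.per_pair[pair])
            save_cca_h5(feature_set.models[pair], grp.create_group("model"))


def load_ibc_h5(path: str) -> IBCFeatureSet:
    with h5py.File(path, "r") as f:
        pairs = [tuple(int(v) for v in row) for row in f.attrs["pair_order"]]
        config = IBCConfig(
            k=int(f.attrs["k"]),
            alpha1=float(f.attrs["alpha1"]),
            alpha2=float(f.attrs["alpha2"]),
            pair_order=pairs,
            ridge=float(f.attrs["ridge"]),
            component_slice=str(f.attrs["component_slice"]),
        )
        per_pair, models = {}, {}
        for pair in pairs:
            grp = f[f"pair_{pair[0]}_{pair[1]}"]
            per_pair[pair] = grp["XF"][()]
            models[pair] = load_cca_h5(grp["model"])
        return IBCFeatureSet(
            per_pair=per_pair,
            concatenated=np.hstack([per_pair[p] for p in pairs]),
            models=models,
            config=config,
            band_names=[str(b) for b in f.attrs["band_names"]],
        )
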