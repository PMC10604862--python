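"""Seeded generators for epoched EEG and band-DE feature matrices with
planted cross-band canonical structure.

The statistical model
---------------------
Each band ``b`` gets a channel-loading matrix ``L_b`` (orthonormal columns
scaled by ``loading_scale``) over ``latent_dims`` factors.  A shared factor
``Z`` couples the designated bands: band ``b``'s factor scores are

    F_b = sqrt(gamma) * Z + sqrt(1 - gamma) * E_b,      E_b iid N(0, I)

so that ``corr(F_b, F_b') = gamma`` between coupled bands, and the band's
DE-feature matrix is

    X_b = baseline + F_b @ L_b.T + class shift + noise_sd * N.

With orthonormal loadings of scale ``g``, the population canonical
correlation between two coupled bands along each factor is

    rho = gamma * g**2 / (g**2 + noise_sd**2)

(the whitened cross-covariance has singular values gamma * g^2/(g^2+s^2)
on the factor subspace and 0 off it).  ``gamma`` is solved from the target
``latent_corr`` so the *planted* canonical correlations equal the target
exactly at the population level; infeasible targets (needing gamma > 1)
raise with the attainable bound.

Class structure is injected as mean shifts: along the shared factors
(``leading-canonical``), along per-band directions orthogonal to the factor
subspace (``trailing-canonical``), only into one band pair's shared factors
(``specific-pair``), or not at all (``none``).  Epochs are organized into
blocks (stimulus clips) with every class present in every block, matching
the block-wise cross-validation layout.

``simulate_raw_eeg`` re-expresses the same latent DE targets as band-limited
oscillations: per epoch/channel/band a random-phase sinusoid inside the band
whose variance equals ``exp(2*DE)/(2*pi*e)``, plus a weak 1/f background, so
that band-pass filtering and variance-based DE extraction recover the
planted structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_prep import DEFAULT_BANDS, BandDefinition, BandDEFeatures, EpochedEEG

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "simulate_de_features",
    "simulate_complementary_de",
    "simulate_raw_eeg",
]


@dataclass(frozen=True)
class SynthSpec:
    """Study-geometry and effect-size parameters of the generator.

    Defaults mirror a 62-channel, five-band, five-block, three-class
    recording with 135 five-second epochs per block (45 per class), the
    desk-scale analogue of cutting three ~4-minute clips per block into
    5-s epochs.
    """

    n_channels: int = 62
    n_bands: int = 5
    n_epochs_per_block: int = 135
    n_blocks: int = 5
    classes: int = 3
    latent_dims: int = 3
    latent_corr: float | tuple[float, ...] = 0.8
    class_effect: float = 1.0
    class_codes: tuple[float, ...] | None = None
    signal_placement: str = "leading-canonical"
    target_pair: tuple[int, int] = (3, 4)  # beta-gamma by default
    noise_sd: float = 1.0
    loading_scale: float = 3.0
    baseline: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.latent_dims > self.n_channels:
            raise ValueError("latent_dims cannot exceed n_channels")
        if self.n_epochs_per_block < self.classes:
            raise ValueError("each block must be able to contain every class")
        if self.signal_placement not in (
            "leading-canonical",
            "trailing-canonical",
            "specific-pair",
            "none",
        ):
            raise ValueError(f"unknown signal_placement {self.signal_placement!r}")
        corr = np.atleast_1d(np.asarray(self.latent_corr, dtype=float))
        if np.any(corr < 0) or np.any(corr >= 1):
            raise ValueError("latent_corr entries must lie in [0, 1)")

    @property
    def n_epochs(self) -> int:
        return self.n_epochs_per_block * self.n_blocks

    def latent_corr_vector(self) -> np.ndarray:
        corr = np.atleast_1d(np.asarray(self.latent_corr, dtype=float))
        if corr.size == 1:
            corr = np.full(self.latent_dims, corr[0])
        if corr.size != self.latent_dims:
            raise ValueError("latent_corr must be scalar or length latent_dims")
        return corr


@dataclass
class GroundTruth:
    """Planted quantities: per-band loadings, the factor-coupling gammas,
    and the population canonical-correlation spectrum per coupled pair
    (computed in closed form from the planted covariance, not the sample)."""

    loadings: dict[int, np.ndarray]
    gamma: np.ndarray
    population_rho: np.ndarray  # descending, length min dims of a pair
    coupled_pairs: list[tuple[int, int]]
    class_means: np.ndarray  # (classes, latent_dims) factor-space shifts
    shift_directions: dict[int, np.ndarray] = field(default_factory=dict)


def _signal_fraction(spec: SynthSpec) -> float:
    g2 = spec.loading_scale**2
    return g2 / (g2 + spec.noise_sd**2)


def _solve_gamma(spec: SynthSpec) -> np.ndarray:
    """Coupling gamma_i achieving the target canonical correlations."""
    frac = _signal_fraction(spec)
    target = spec.latent_corr_vector()
    gamma = target / frac
    if np.any(gamma > 1 + 1e-12):
        raise ValueError(
            f"latent_corr {target.max():.3f} infeasible: with loading_scale "
            f"{spec.loading_scale} and noise_sd {spec.noise_sd} the attainable "
            f"canonical correlation is at most {frac:.4f}"
        )
    return np.clip(gamma, 0.0, 1.0)


def _orthonormal_loadings(rng: np.random.Generator, p: int, r: int) -> np.ndarray:
    Q, R = np.linalg.qr(rng.standard_normal((p, r)))
    return Q * np.sign(np.diag(R))  # (p, r), orthonormal columns


def _block_labels(spec: SynthSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Labels and block ids: every class present in every block, order
    shuffled within block."""
    labels, blocks = [], []
    for b in range(spec.n_blocks):
        lab = np.arange(spec.n_epochs_per_block) % spec.classes
        rng.shuffle(lab)
        labels.append(lab)
        blocks.append(np.full(spec.n_epochs_per_block, b))
    return np.concatenate(labels), np.concatenate(blocks)


def _class_mean_codes(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-class mean shifts in factor space, scaled to class_effect.

    With explicit ``class_codes`` (one scalar per class) the shift lies along
    the first factor axis with those centered codes — e.g. codes (1, 0, 0)
    separate class 0 from the others and nothing else.  Otherwise every class
    gets a random zero-sum direction of norm ``class_effect``.
    """
    if spec.class_codes is not None:
        codes = np.asarray(spec.class_codes, dtype=float)
        if codes.size != spec.classes:
            raise ValueError("class_codes must have one entry per class")
        codes = codes - codes.mean()
        span = np.abs(codes).max()
        if span == 0:
            raise ValueError("class_codes are all equal: no contrast")
        M = np.zeros((spec.classes, spec.latent_dims))
        M[:, 0] = spec.class_effect * codes / span
        return M
    M = rng.standard_normal((spec.classes, spec.latent_dims))
    M -= M.mean(axis=0)
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    return spec.class_effect * M / np.maximum(norms, 1e-12)


def simulate_de_features(
    spec: SynthSpec,
    labels: np.ndarray | None = None,
    block_ids: np.ndarray | None = None,
) -> tuple[BandDEFeatures, np.ndarray, np.ndarray, GroundTruth]:
    """Draw a band-DE feature tensor with planted canonical structure.

    Returns ``(features, labels, block_ids, ground_truth)``; labels and
    block ids are also carried inside the feature container.  Passing
    ``labels``/``block_ids`` reuses an existing epoch layout (e.g. to build
    two feature containers over the same epochs).
    """
    rng = np.random.default_rng(spec.seed)
    gamma = _solve_gamma(spec)
    n, p, r = spec.n_epochs, spec.n_channels, spec.latent_dims

    if labels is None or block_ids is None:
        labels, block_ids = _block_labels(spec, rng)
    else:
        labels = np.asarray(labels, dtype=int)
        block_ids = np.asarray(block_ids, dtype=int)
        if len(labels) != n or len(block_ids) != n:
            raise ValueError("provided labels/block_ids must match spec.n_epochs")

    if spec.signal_placement == "specific-pair":
        coupled = [tuple(sorted(spec.target_pair))]
        coupled_bands = set(coupled[0])
    elif np.all(gamma == 0):
        coupled, coupled_bands = [], set()
    else:
        coupled_bands = set(range(spec.n_bands))
        coupled = [
            (i, j)
            for i in range(spec.n_bands)
            for j in range(i + 1, spec.n_bands)
        ]

    loadings = {b: _orthonormal_loadings(rng, p, r) for b in range(spec.n_bands)}
    class_means = _class_mean_codes(spec, rng)

    Z = rng.standard_normal((n, r))
    if spec.class_effect > 0 and spec.signal_placement in (
        "leading-canonical",
        "specific-pair",
    ):
        Z = Z + class_means[labels]

    sq_g = np.sqrt(gamma)
    sq_c = np.sqrt(1.0 - gamma)
    values = np.empty((n, p, spec.n_bands))
    shift_directions: dict[int, np.ndarray] = {}
    for b in range(spec.n_bands):
        if b in coupled_bands:
            F_b = sq_g * Z + sq_c * rng.standard_normal((n, r))
        else:
            F_b = rng.standard_normal((n, r))
        X_b = spec.baseline + (F_b * spec.loading_scale) @ loadings[b].T
        X_b = X_b + spec.noise_sd * rng.standard_normal((n, p))
        if spec.class_effect > 0 and spec.signal_placement == "trailing-canonical":
            # shift along a direction orthogonal to the factor subspace so the
            # class signal lives in low-canonical-correlation components
            basis = np.hstack([loadings[b], rng.standard_normal((p, 1))])
            q, _ = np.linalg.qr(basis)
            d = q[:, -1]
            shift_directions[b] = d
            if spec.class_codes is not None:
                code = class_means[:, 0]
            else:
                code = np.arange(spec.classes) - (spec.classes - 1) / 2.0
                code = spec.class_effect * code / np.abs(code).max()
            X_b = X_b + np.outer(code[labels], d)
        values[:, :, b] = X_b

    frac = _signal_fraction(spec)
    rho = np.zeros(min(p, p))
    rho[:r] = np.sort(gamma * frac)[::-1]

    bands = list(DEFAULT_BANDS[: spec.n_bands])
    if spec.n_bands > len(DEFAULT_BANDS):
        bands = [
            BandDefinition(f"band{i}", 1.0 + i, 2.0 + i) for i in range(spec.n_bands)
        ]
    de = BandDEFeatures(
        values=values,
        bands=bands,
        labels=labels,
        block_ids=block_ids,
        channel_names=[f"ch{i:02d}" for i in range(p)],
    )
    truth = GroundTruth(
        loadings=loadings,
        gamma=gamma,
        population_rho=rho,
        coupled_pairs=coupled,
        class_means=class_means,
        shift_directions=shift_directions,
    )
    return de, labels, block_ids, truth


def simulate_complementary_de(
    spec: SynthSpec,
) -> tuple[BandDEFeatures, BandDEFeatures, np.ndarray, np.ndarray]:
    """Two feature containers over one epoch layout carrying complementary
    class information.

    The first container separates only class 0 from the rest, in directions
    orthogonal to the factor subspace (visible to a classifier on the raw
    features).  The second separates only the last class, along the leading
    canonical directions (visible to the IBC features).  A classifier fused
    across the two can resolve all classes; either alone cannot.
    Returns ``(de_raw, de_ibc_source, labels, block_ids)``.
    """
    first = tuple(1.0 if k == 0 else 0.0 for k in range(spec.classes))
    last = tuple(1.0 if k == spec.classes - 1 else 0.0 for k in range(spec.classes))
    spec_raw = replace(spec, signal_placement="trailing-canonical", class_codes=first)
    spec_src = replace(
        spec, signal_placement="leading-canonical", class_codes=last,
        seed=spec.seed + 1_000_003,
    )
    de_raw, labels, block_ids, _ = simulate_de_features(spec_raw)
    de_src, _, _, _ = simulate_de_features(spec_src, labels=labels, block_ids=block_ids)
    return de_raw, de_src, labels, block_ids


def simulate_raw_eeg(
    spec: SynthSpec,
    fs: float = 200.0,
    epoch_seconds: float = 5.0,
    background_sd: float = 0.05,
    modulated_bands: list[int] | None = None,
) -> tuple[EpochedEEG, GroundTruth]:
    """Epoched raw EEG whose band-variance structure encodes the planted
    DE-feature model.

    Per epoch/channel/band a sinusoid with a random frequency inside the
    band and random phase carries variance ``exp(2*DE)/(2*pi*e)``; a weak
    1/f background (``background_sd``) is added on top.  Running the result
    through band-pass filtering + variance DE recovers features whose
    cross-band canonical structure matches the planted one (up to filter
    edge effects and the background floor).

    ``modulated_bands`` restricts the epoch-to-epoch amplitude modulation to
    the listed band indices; the others keep a constant baseline amplitude.
    """
    if spec.n_bands > len(DEFAULT_BANDS):
        raise ValueError("raw simulation supports at most the 5 canonical bands")
    bands = DEFAULT_BANDS[: spec.n_bands]
    if fs < 2 * max(b.high for b in bands):
        raise ValueError("fs must be at least twice the highest band edge")
    n_samp = int(round(fs * epoch_seconds))

    # latent DE targets; shrink so exp(2*DE) spans a realistic dynamic range
    de, labels, block_ids, truth = simulate_de_features(spec)
    target_de = spec.baseline + 0.25 * (de.values - spec.baseline)
    if modulated_bands is not None:
        frozen = [j for j in range(spec.n_bands) if j not in set(modulated_bands)]
        target_de[:, :, frozen] = spec.baseline
    target_var = np.exp(2.0 * target_de) / (2.0 * math.pi * math.e)

    rng = np.random.default_rng(spec.seed + 1)
    t = np.arange(n_samp) / fs
    n, p = spec.n_epochs, spec.n_channels
    data = np.zeros((n, p, n_samp))
    for j, band in enumerate(bands):
        width = band.high - band.low
        freqs = rng.uniform(band.low + 0.25 * width, band.high - 0.25 * width, (n, p))
        phases = rng.uniform(0, 2 * math.pi, (n, p))
        amps = np.sqrt(2.0 * target_var[:, :, j])
        data += amps[:, :, None] * np.sin(
            2 * math.pi * freqs[:, :, None] * t + phases[:, :, None]
        )

    if background_sd > 0:
        data += background_sd * _pink_noise(rng, (n, p, n_samp), fs)

    eeg = EpochedEEG(
        data=data,
        fs=fs,
        channel_names=[f"ch{i:02d}" for i in range(p)],
        labels=labels,
        block_ids=block_ids,
    )
    return eeg, truth


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = rng.standard_normal(shape[:-1] + (len(freqs),)) + 1j * rng.standard_normal(
        shape[:-1] + (len(freqs),)
    )
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-30)
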