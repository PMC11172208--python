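"""Synthetic fixtures with planted ground truth.

Two generators, both fully seeded:

* :func:`generate_features` — a two-class Gaussian feature matrix in which a
  known subset of columns carries a class-mean shift (the "planted"
  informative features), optional redundant copies of them, and the rest is
  label-independent noise. The planted mask allows precision/recall scoring
  of any feature-selection result.
* :func:`generate_toy_images` — two classes of small textured images that
  differ in stripe frequency and blob texture, so that oriented-gradient
  and local-binary-pattern descriptors carry class signal end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator conditions for the planted-feature matrix.

    ``effect_size`` is the class-mean separation of each informative column
    in noise-standard-deviation units (class means sit at ±effect_size/2).
    ``correlation`` in [0, 1) controls how tightly redundant columns track
    the informative column they copy (0 = fully independent noise added).
    """

    n_samples: int = 200
    n_features: int = 20
    n_informative: int = 5
    effect_size: float = 2.0
    n_redundant: int = 0
    correlation: float = 0.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1 or self.n_informative > self.n_features:
            raise ValueError("need 1 <= n_informative <= n_features")
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("informative + redundant columns exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")


@dataclass(frozen=True)
class SyntheticDataset:
    features: np.ndarray
    labels: np.ndarray
    true_mask: np.ndarray  # 1 marks planted informative columns

    @property
    def informative_indices(self) -> np.ndarray:
        return np.flatnonzero(self.true_mask)


def generate_features(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw the planted-feature matrix described by ``spec``.

    Column layout: the informative columns, then redundant copies, then pure
    noise, all in a seeded random column order so selection cannot exploit
    position.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    n_pos = int(round(spec.class_balance * n))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    signs = np.where(labels == 1, 1.0, -1.0)
    x = rng.normal(size=(n, d))
    shift = spec.effect_size / 2.0
    for j in range(spec.n_informative):
        x[:, j] += signs * shift
    for r in range(spec.n_redundant):
        src = r % spec.n_informative
        noise_sd = 1.0 - spec.correlation
        x[:, spec.n_informative + r] = x[:, src] + rng.normal(
            scale=noise_sd, size=n
        )

    order = rng.permutation(d)
    x = x[:, order]
    true_mask = np.zeros(d, dtype=np.int8)
    true_mask[np.isin(order, np.arange(spec.n_informative))] = 1
    return SyntheticDataset(features=x, labels=labels, true_mask=true_mask)


def planted_precision_recall(
    selected: np.ndarray, true_mask: np.ndarray
) -> tuple[float, float]:
    """Precision and recall of a selected index set against the planted set."""
    selected = np.asarray(selected)
    truth = set(np.flatnonzero(true_mask).tolist())
    chosen = set(int(i) for i in selected)
    if not chosen:
        return 0.0, 0.0
    hits = len(chosen & truth)
    recall = hits / len(truth) if truth else 0.0
    return hits / len(chosen), recall


def generate_toy_images(
    n: int,
    size: int = 224,
    texture_contrast: float = 1.0,
    seed: int | None = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Two classes of textured grayscale images with balanced labels.

    Class 0 carries low-frequency oblique stripes, class 1 high-frequency
    stripes at a different orientation plus denser blob speckle;
    ``texture_contrast`` scales the class-specific texture relative to the
    shared noise floor (0 makes the classes statistically identical).
    Pixel values lie in [0, 1]. Returns (images, labels).
    """
    if n < 2:
        raise ValueError("need at least 2 images")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    labels = np.arange(n) % 2
    rng.shuffle(labels)
    images = []
    for lab in labels:
        if lab == 0:
            stripes = np.sin(2 * np.pi * (3 * xx + 1 * yy))
            blob_density = 0.002
        else:
            stripes = np.sin(2 * np.pi * (9 * yy - 3 * xx))
            blob_density = 0.01
        img = 0.5 + 0.25 * texture_contrast * stripes
        n_blobs = rng.binomial(size * size, blob_density)
        if n_blobs and texture_contrast > 0:
            cy = rng.integers(0, size, n_blobs)
            cx = rng.integers(0, size, n_blobs)
            img[cy, cx] += 0.4 * texture_contrast
        img += rng.normal(scale=0.05, size=(size, size))
        images.append(np.clip(img, 0.0, 1.0))
    return images, labels
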