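"""Per-image feature blocks: HOG, LBP, and pluggable deep embeddings.

Each image contributes a concatenated descriptor made of named blocks with
declared lengths. The hand-crafted blocks are the histogram of oriented
gradients (9 orientations, 74×74-pixel cells, 1×1-cell blocks on a 224×224
image) and the local binary pattern histogram (8 points, radius 1). Deep
embedding blocks are supplied through the :class:`EmbeddingProvider`
contract — pretrained networks are deliberately not bundled; a seeded
random-projection mock ships for testing and any fc-layer or pooled CNN
embedding can be plugged in its place.

Where a descriptor's natural length differs from a declared target (the
reference configuration declares 80 for HOG where 3×3 cells × 9
orientations gives 81, and 66 for LBP), a deterministic adapter truncates
or zero-pads and logs the adjustment, so the bookkeeping of the declared
total (80+66+1024+1024 = 2194) stays exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import hog, local_binary_pattern
from skimage.transform import resize

logger = logging.getLogger(__name__)

TARGET_SIZE = 224

#: reference block dimensions of the concatenated descriptor
REFERENCE_DIMS = {"hog": 80, "lbp": 66, "vgg": 1024, "mobilenet": 1024}

LBP_BINS = {"default": 256, "uniform": 10, "nri_uniform": 59, "ror": 256}


@dataclass
class ImageRecord:
    """A preprocessed image: grayscale or RGB pixels at 224×224."""

    pixels: np.ndarray
    label: int = 0
    identifier: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D grayscale or 3-D RGB")
        if px.shape[0] != TARGET_SIZE or px.shape[1] != TARGET_SIZE:
            px = resize(px, (TARGET_SIZE, TARGET_SIZE), anti_aliasing=True)
        if px.max() > 1.0:
            px = px / 255.0
        self.pixels = px

    @property
    def gray(self) -> np.ndarray:
        return rgb2gray(self.pixels) if self.pixels.ndim == 3 else self.pixels


@dataclass(frozen=True)
class FeatureBlock:
    name: str
    vector: np.ndarray
    declared_dim: int

    def __post_init__(self) -> None:
        if self.vector.shape != (self.declared_dim,):
            raise ValueError(
                f"block {self.name!r}: vector length {self.vector.shape[0]} "
                f"!= declared_dim {self.declared_dim}"
            )


class EmbeddingProvider(Protocol):
    """Contract for deep-feature blocks: deterministic, fixed output length."""

    name: str
    declared_dim: int

    def embed(self, image: ImageRecord) -> np.ndarray: ...


def _adapt(vector: np.ndarray, name: str, target_dim: int | None) -> np.ndarray:
    """Deterministic truncate/zero-pad to the declared dimension (logged)."""
    if target_dim is None or vector.shape[0] == target_dim:
        return vector
    if vector.shape[0] > target_dim:
        logger.info(
            "%s: truncating %d -> %d features", name, vector.shape[0], target_dim
        )
        return vector[:target_dim]
    logger.info("%s: zero-padding %d -> %d features", name, vector.shape[0], target_dim)
    return np.pad(vector, (0, target_dim - vector.shape[0]))


def hog_block(
    image: ImageRecord,
    orientations: int = 9,
    cell_size: int = 74,
    block_size: int = 1,
    target_dim: int | None = 80,
) -> FeatureBlock:
    """Histogram-of-oriented-gradients block (grayscale, block-normalized)."""
    gray = image.gray
    if cell_size > gray.shape[0] or cell_size > gray.shape[1]:
        raise ValueError("cell_size exceeds image size")
    vec = hog(
        gray,
        orientations=orientations,
        pixels_per_cell=(cell_size, cell_size),
        cells_per_block=(block_size, block_size),
        feature_vector=True,
    )
    vec = _adapt(np.asarray(vec, dtype=float), "hog", target_dim)
    return FeatureBlock("hog", vec, len(vec))


def lbp_block(
    image: ImageRecord,
    n_points: int = 8,
    radius: float = 1.0,
    variant: str = "nri_uniform",
    target_dim: int | None = 66,
) -> FeatureBlock:
    """Local-binary-pattern histogram block, normalized to sum 1.

    ``variant`` selects the LBP code mapping; the non-rotation-invariant
    uniform mapping (59 bins for 8 points) is the default, zero-padded to
    the declared 66.
    """
    if variant not in LBP_BINS:
        raise ValueError(f"unknown LBP variant {variant!r}; choose from {sorted(LBP_BINS)}")
    # LBP compares pixel intensities; quantize to 8-bit so float round-off
    # between near-equal neighbours cannot flip code bits
    gray8 = np.clip(np.round(image.gray * 255.0), 0, 255).astype(np.uint8)
    codes = local_binary_pattern(gray8, n_points, radius, method=variant)
    n_bins = LBP_BINS[variant] if variant != "default" else 2**n_points
    hist, _ = np.histogram(codes, bins=n_bins, range=(0, n_bins))
    hist = hist.astype(float)
    total = hist.sum()
    if total > 0:
        hist /= total
    vec = _adapt(hist, "lbp", target_dim)
    return FeatureBlock("lbp", vec, len(vec))


def concat_features(blocks: list[FeatureBlock]) -> np.ndarray:
    """Concatenate blocks in declared order; total length is additive."""
    if not blocks:
        raise ValueError("need at least one feature block")
    return np.concatenate([b.vector for b in blocks])


class MockEmbeddingProvider:
    """Seeded random projection of downsampled pixels — a synthetic stand-in
    for a CNN embedding (deterministic per image, fixed output length).

    The projection matrix is drawn once from the seed; embeddings are linear
    in the image, so distinct textures map to distinct directions, which is
    all the selection pipeline needs from a deep block in tests.
    """

    def __init__(self, name: str = "mock", declared_dim: int = 1024, seed: int = 0,
                 downsample: int = 8):
        self.name = name
        self.declared_dim = declared_dim
        self._downsample = downsample
        side = TARGET_SIZE // downsample
        rng = np.random.default_rng(seed)
        self._proj = rng.normal(size=(declared_dim, side * side)) / np.sqrt(side * side)

    def embed(self, image: ImageRecord) -> np.ndarray:
        g = image.gray
        side = TARGET_SIZE // self._downsample
        small = g[: side * self._downsample, : side * self._downsample]
        small = small.reshape(side, self._downsample, side, self._downsample).mean(
            axis=(1, 3)
        )
        return self._proj @ small.ravel()


def embedding_block(provider: EmbeddingProvider, image: ImageRecord) -> FeatureBlock:
    vec = np.asarray(provider.embed(image), dtype=float)
    return FeatureBlock(provider.name, vec, provider.declared_dim)


def extract_matrix(
    images: list[ImageRecord],
    providers: list[EmbeddingProvider] | None = None,
    hog_kwargs: dict | None = None,
    lbp_kwargs: dict | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-image HOG + LBP (+ provider) blocks, stacked into a matrix.

    Returns (matrix, column_names) with block-prefixed column names
    (hog_0…, lbp_0…, <provider>_0…).
    """
    providers = providers or []
    rows, names = [], None
    for img in images:
        blocks = [
            hog_block(img, **(hog_kwargs or {})),
            lbp_block(img, **(lbp_kwargs or {})),
        ]
        blocks += [embedding_block(p, img) for p in providers]
        rows.append(concat_features(blocks))
        if names is None:
            names = [
                f"{b.name}_{i}" for b in blocks for i in range(b.declared_dim)
            ]
    return np.vstack(rows), names
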