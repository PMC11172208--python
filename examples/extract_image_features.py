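"""Hand-crafted plus embedding descriptors from toy textured images.

Builds two texture classes (coarse vs fine stripes with different blob
density), extracts HOG and LBP blocks plus two mock 1024-dimensional
embedding blocks per image, and checks that a k-nearest-neighbour
classifier separates the classes from the concatenated descriptors.
"""

import numpy as np

from fraccs import BinaryMask, ImageRecord, MockEmbeddingProvider, knn_error
from fraccs.features import extract_matrix
from fraccs.synthetic import generate_toy_images

images, labels = generate_toy_images(60, seed=0)
records = [ImageRecord(px, label=int(y)) for px, y in zip(images, labels)]

providers = [
    MockEmbeddingProvider("vgg", 1024, seed=0),
    MockEmbeddingProvider("mobilenet", 1024, seed=1),
]
matrix, names = extract_matrix(records, providers=providers)
print(f"descriptor matrix: {matrix.shape[0]} images x {matrix.shape[1]} features")
print("blocks:", names[0], names[80], names[146], names[1170])

full_mask = BinaryMask(np.ones(matrix.shape[1], dtype=int))
err = knn_error(matrix, labels, full_mask, k=7, seed=0)
print(f"k-NN validation error on all features: {err:.3f}")
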