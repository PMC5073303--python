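"""Texton dictionary learning and histogram models.

Training follows the texton pipeline: filter-response vectors are sampled
from one randomly placed block per stack (default 50 x 50 x 5 voxels =
12,500 vectors, keeping clustering affordable), pooled across training
stacks, and clustered with k-means into K response centers ("textons",
default K = 40).  Each stack is then summarized as the normalized K-bin
histogram of nearest-texton assignments of its sampled vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans, MiniBatchKMeans

from .exceptions import ConsistencyError, ParameterError, SizeError
from .filterbank import ResponseField

__all__ = [
    "SampleBlock",
    "TextonDictionary",
    "TextonHistogram",
    "DEFAULT_BLOCK_SHAPE",
    "sample_block",
    "sample_responses",
    "learn_dictionary",
    "assign_textons",
    "assign_and_histogram",
]

DEFAULT_BLOCK_SHAPE: tuple[int, int, int] = (5, 50, 50)  # (z, y, x) voxels


@dataclass(frozen=True)
class SampleBlock:
    """A voxel block from which response vectors are drawn."""

    origin: tuple[int, int, int]
    shape: tuple[int, int, int]
    seed: int

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def roi(self) -> tuple[tuple[int, int], ...]:
        return tuple((o, o + s) for o, s in zip(self.origin, self.shape))


@dataclass
class TextonDictionary:
    """K cluster centers in collapsed-response space."""

    centers: np.ndarray  # (K, n_channels)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers))
        if self.K < 1:
            raise ParameterError("dictionary needs at least one center")

    @property
    def K(self) -> int:
        return self.centers.shape[0]

    @property
    def n_channels(self) -> int:
        return self.centers.shape[1]


@dataclass
class TextonHistogram:
    """Normalized K-bin texton frequency vector for one stack."""

    freqs: np.ndarray
    label: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.ndim != 1 or (self.freqs < 0).any():
            raise ParameterError("freqs must be a 1D nonnegative vector")
        total = self.freqs.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ParameterError(f"freqs must sum to 1, got {total}")


def sample_block(
    field_shape: tuple[int, int, int],
    block_shape: tuple[int, int, int] = DEFAULT_BLOCK_SHAPE,
    seed: int | None = None,
) -> SampleBlock:
    """Uniformly place a sampling block inside a field of the given extents.

    Placement depends only on ``field_shape``, ``block_shape`` and ``seed``,
    so the block can be chosen *before* filtering and the convolution
    restricted to it.
    """
    block_shape = tuple(int(b) for b in block_shape)
    if any(b < 1 for b in block_shape):
        raise ParameterError(f"block shape must be positive, got {block_shape}")
    if any(b > n for b, n in zip(block_shape, field_shape)):
        raise SizeError(f"block {block_shape} does not fit field extents {field_shape}")
    rng = np.random.default_rng(seed)
    origin = tuple(
        int(rng.integers(0, n - b + 1)) for b, n in zip(block_shape, field_shape)
    )
    return SampleBlock(origin=origin, shape=block_shape, seed=-1 if seed is None else int(seed))


def _field_values(field) -> np.ndarray:
    if isinstance(field, ResponseField):
        return field.values
    arr = np.asarray(field)
    if arr.ndim != 4:
        raise ConsistencyError(f"expected a (z, y, x, channel) field, got shape {arr.shape}")
    return arr


def sample_responses(
    field,
    block_shape: tuple[int, int, int] = DEFAULT_BLOCK_SHAPE,
    seed: int | None = None,
) -> np.ndarray:
    """Draw the response vectors of one randomly placed block.

    Returns exactly ``prod(block_shape)`` vectors (12,500 with the default
    50 x 50 x 5 block) in C order; the same seed always yields the same block.
    """
    values = _field_values(field)
    block = sample_block(values.shape[:3], block_shape, seed)
    (z0, z1), (y0, y1), (x0, x1) = block.roi
    return values[z0:z1, y0:y1, x0:x1].reshape(-1, values.shape[-1])


def learn_dictionary(
    samples: np.ndarray,
    K: int = 40,
    seed: int | None = None,
    algorithm: str = "lloyd",
    n_init: int = 5,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> TextonDictionary:
    """Cluster pooled response vectors into K textons.

    ``algorithm='lloyd'`` runs full k-means (k-means++ init, best of
    ``n_init`` restarts); ``'minibatch'`` runs seeded mini-batch k-means,
    which the cross-validation pipeline uses to keep per-fold dictionary
    refits affordable.  Both are deterministic given ``seed``.
    """
    samples = np.asarray(samples)
    if samples.ndim != 2:
        raise ParameterError(f"samples must be (n, channels), got shape {samples.shape}")
    if samples.shape[0] < K:
        raise ParameterError(f"need at least K={K} samples, got {samples.shape[0]}")
    if algorithm == "lloyd":
        est = KMeans(
            n_clusters=K,
            init="k-means++",
            n_init=n_init,
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
            algorithm="lloyd",
        )
    elif algorithm == "minibatch":
        # one k-means++ init and two full epochs: for a ~40-center vocabulary
        # in 20 dimensions the refinement converges almost immediately
        est = MiniBatchKMeans(
            n_clusters=K,
            init="k-means++",
            n_init=1,
            max_iter=max(2, max_iter // 150),
            batch_size=16384,
            random_state=seed,
        )
    else:
        raise ParameterError(f"unknown algorithm {algorithm!r}")
    est.fit(samples)
    return TextonDictionary(
        centers=est.cluster_centers_.astype(np.float64),
        training_meta=dict(
            seed=seed,
            algorithm=algorithm,
            n_iter=int(est.n_iter_),
            inertia=float(est.inertia_),
            n_samples=int(samples.shape[0]),
        ),
    )


def assign_textons(vectors: np.ndarray, dictionary: TextonDictionary) -> np.ndarray:
    """Nearest-center (Euclidean) texton index per vector, lowest index on ties."""
    vectors = np.atleast_2d(np.asarray(vectors))
    if vectors.shape[1] != dictionary.n_channels:
        raise ConsistencyError(
            f"vector dimension {vectors.shape[1]} does not match dictionary "
            f"dimension {dictionary.n_channels}"
        )
    d = cdist(vectors.astype(np.float64), dictionary.centers, metric="sqeuclidean")
    return np.argmin(d, axis=1)  # argmin returns the lowest index on ties


def assign_and_histogram(
    field_or_samples,
    dictionary: TextonDictionary,
    label: str | None = None,
    source: str | None = None,
) -> TextonHistogram:
    """Histogram the nearest-texton assignments into a normalized K-vector."""
    arr = np.asarray(
        field_or_samples.values if isinstance(field_or_samples, ResponseField) else field_or_samples
    )
    if arr.ndim == 4:
        arr = arr.reshape(-1, arr.shape[-1])
    labels = assign_textons(arr, dictionary)
    counts = np.bincount(labels, minlength=dictionary.K).astype(np.float64)
    return TextonHistogram(freqs=counts / counts.sum(), label=label, source=source)
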