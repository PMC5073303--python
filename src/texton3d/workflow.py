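"""End-to-end orchestration: volumes -> filter responses -> textons -> CV.

This module glues the pipeline stages together for the CLI, the experiment
runner and the acceptance script.  The per-stack path is:

1. preprocess (isotropic resampling, optional depth crop, intensity z-score),
2. choose the sampling block from the stack extents and a per-stack seed,
3. compute the collapsed 20-channel responses *on that block only* (the
   restriction is exact: values equal the full-volume computation),
4. flatten to the stack's response-vector sample.

``run_phantom_experiment`` generates a labeled phantom dataset, runs
stratified 10-fold one-vs-rest cross-validation, and (optionally) repeats
the evaluation using only the middle optical section's responses — the
single-section analogue against which the volumetric analysis is compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import classify, phantoms, textons, volumeio
from .filterbank import FilterBank, build_filter_bank, response_field

logger = logging.getLogger(__name__)

__all__ = [
    "stack_samples",
    "preprocess",
    "ExperimentResult",
    "run_phantom_experiment",
]


def preprocess(
    volume: volumeio.Volume,
    crop_depth_um: float | None = None,
    normalize: bool = True,
) -> volumeio.Volume:
    """Standard per-stack preprocessing: isotropic pitch, depth crop, z-score."""
    v = volumeio.interpolate_isotropic(volume)
    if crop_depth_um is not None:
        v = volumeio.crop_depth(v, crop_depth_um)
    if normalize:
        v = volumeio.normalize_intensity(v)
    return v


def stack_samples(
    volume,
    bank: FilterBank,
    block_shape: tuple[int, int, int] = textons.DEFAULT_BLOCK_SHAPE,
    seed: int | None = None,
    middle_slice: bool = False,
    dtype=np.float32,
) -> np.ndarray:
    """Sampled response vectors of one preprocessed stack.

    With ``middle_slice=True`` the block is confined to the stack's middle
    optical section (z fixed, block depth 1): the single-section baseline.
    The convolution is restricted to the block but uses the full surrounding
    volume, so there are no block-edge artifacts.
    """
    arr = volume.values if isinstance(volume, volumeio.Volume) else np.asarray(volume)
    arr = arr.astype(dtype, copy=False)
    shape = arr.shape
    if middle_slice:
        bs = (1, block_shape[1], block_shape[2])
        lateral = textons.sample_block(shape[1:], bs[1:], seed)
        origin = (shape[0] // 2,) + lateral.origin
        block = textons.SampleBlock(origin=origin, shape=bs, seed=lateral.seed)
    else:
        block = textons.sample_block(shape, block_shape, seed)
    f = response_field(arr, bank, roi=block.roi)
    return f.values.reshape(-1, f.n_channels)


def stack_block_samples(
    volume,
    bank: FilterBank,
    block_shape: tuple[int, int, int] = textons.DEFAULT_BLOCK_SHAPE,
    seed: int = 0,
    blocks_per_stack: int = 1,
    dtype=np.float32,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled block responses plus a single-section subset.

    Draws ``blocks_per_stack`` independently placed blocks (seeds derived
    from ``seed``) and pools their response vectors; pooling several blocks
    averages out block-placement sampling noise in the stack histogram.
    Also returns the vectors of the first block's central z slice — one
    optical section, the subset a planar (2D) analysis of the same stack
    would see.
    """
    arr = volume.values if isinstance(volume, volumeio.Volume) else np.asarray(volume)
    arr = arr.astype(dtype, copy=False)
    pooled = []
    single_section = None
    for b in range(blocks_per_stack):
        block_seed = int(np.random.SeedSequence([seed, b]).generate_state(1)[0] % (2**31))
        block = textons.sample_block(arr.shape, block_shape, block_seed)
        f = response_field(arr, bank, roi=block.roi)
        pooled.append(f.values.reshape(-1, f.n_channels))
        if b == 0:
            mid = block.shape[0] // 2
            single_section = f.values[mid].reshape(-1, f.n_channels)
    return np.concatenate(pooled), single_section


def _stack_sample_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, 77, index]).generate_state(1)[0] % (2**31))


@dataclass
class ExperimentResult:
    """Cross-validated phantom experiment outcome."""

    result_3d: classify.CrossValResult
    result_2d: classify.CrossValResult | None
    classes: list[str]
    params: dict = field(default_factory=dict)

    @property
    def per_class_auroc(self) -> dict[str, float]:
        return {c: self.result_3d.auroc(c) for c in self.classes}

    @property
    def mean_auroc(self) -> float:
        return self.result_3d.mean_auroc

    @property
    def mean_auroc_2d(self) -> float | None:
        return None if self.result_2d is None else self.result_2d.mean_auroc

    def binary_auroc(self, class_a: str, class_b: str) -> float:
        """AUROC separating two classes from their pooled OvR scores."""
        return self.result_3d.restricted_auroc(class_b, [class_a, class_b])


def run_phantom_experiment(
    stacks_per_class: int = 12,
    dataset_seed: int = 0,
    presets: list | None = None,
    bank: FilterBank | None = None,
    block_shape: tuple[int, int, int] = textons.DEFAULT_BLOCK_SHAPE,
    blocks_per_stack: int = 2,
    K: int = 40,
    nn: int = 10,
    folds: int = 10,
    q="auto",
    with_2d_baseline: bool = False,
    dict_algorithm: str = "minibatch",
) -> ExperimentResult:
    """Generate phantoms, run the texture pipeline, cross-validate one-vs-rest.

    One experiment = ``stacks_per_class`` phantom volumes per morphology
    preset, each filtered once; the 3D evaluation pools ``blocks_per_stack``
    sampling blocks per stack, and the optional single-section baseline
    reuses the central z slice of the first block — one optical section per
    stack, same lateral region.  Everything derives from ``dataset_seed``.
    """
    presets = presets if presets is not None else phantoms.preset_library()
    bank = bank if bank is not None else build_filter_bank()
    samples_3d, samples_2d, labels, sources = [], [], [], []
    for i, (vol, label, source) in enumerate(
        phantoms.generate_dataset_volumes(presets, stacks_per_class, dataset_seed)
    ):
        v = preprocess(vol)
        seed = _stack_sample_seed(dataset_seed, i)
        s3, s2 = stack_block_samples(v, bank, block_shape, seed, blocks_per_stack)
        samples_3d.append(s3)
        if with_2d_baseline:
            samples_2d.append(s2)
        labels.append(label)
        sources.append(source)
    logger.info("sampled %d stacks (%d vectors each)", len(labels), samples_3d[0].shape[0])
    res3d = classify.cross_validate(
        samples_3d, labels, folds=folds, seed=dataset_seed, K=K, nn=nn, q=q,
        dict_algorithm=dict_algorithm, sources=sources,
    )
    res2d = None
    if with_2d_baseline:
        res2d = classify.cross_validate(
            samples_2d, labels, folds=folds, seed=dataset_seed, K=K, nn=nn, q=q,
            dict_algorithm=dict_algorithm, sources=sources,
        )
    return ExperimentResult(
        result_3d=res3d,
        result_2d=res2d,
        classes=res3d.classes,
        params=dict(
            stacks_per_class=stacks_per_class,
            dataset_seed=dataset_seed,
            K=K,
            nn=nn,
            folds=folds,
            block_shape=tuple(block_shape),
            blocks_per_stack=blocks_per_stack,
        ),
    )
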