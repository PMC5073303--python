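"""Synthetic 3D fibrillar phantoms for end-to-end pipeline testing.

No public image library exists for SHG ovarian-stroma stacks, so the
pipeline is exercised on synthetic volumes of fibrillar texture.  Fibers are
grown as persistent random walks: the principal direction of each fiber is
drawn from a von Mises-Fisher distribution about a shared mean axis
(``alignment_kappa = 0`` is isotropic, large kappa is strongly aligned), and
the walk direction diffuses per unit step with angular standard deviation
``waviness``.  The walks are splatted into the voxel grid, blurred with a
Gaussian combining fiber cross-section and microscope PSF, and degraded with
Poisson photon noise plus Gaussian read noise, emulating photon-counting SHG
detection.

Six presets mirror the qualitative morphologies of the ovarian tissue
classes: ``normal`` (short fibers in an isotropic mesh), ``high_risk``
(heterogeneous mixture of longer curvy/straight fibers), ``benign`` (thick,
short, wavy), ``endometrioid`` (sparse but highly aligned), ``lgs``
(fibrotic: dense short fibers) and ``hgs`` (long, wavy, highly aligned).
The presets are deliberately well separated in density, width, length and
alignment; they validate the pipeline's discriminative machinery, not the
quantitative statistics of real tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as _ndi
from scipy.stats import vonmises_fisher

from .exceptions import ParameterError, Texton3DError
from .volumeio import LabeledStackManifest, Volume, write_manifest, write_stack

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "ClassPreset",
    "generate_fiber_volume",
    "preset_library",
    "generate_dataset",
    "generate_dataset_volumes",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic fiber volume.

    Lengths are in micrometres with a default isotropic 1 um voxel pitch, so
    micrometres and voxels coincide.
    """

    shape: tuple[int, int, int] = (20, 128, 128)  # (z, y, x) voxels
    n_fibers: int = 80
    fiber_length: float = 20.0  # mean length, um
    fiber_width: float = 1.0  # Gaussian cross-section sigma, um
    waviness: float = 0.2  # per-step turning-angle SD, rad
    alignment_kappa: float = 0.0  # vMF concentration about mean_axis; 0 = isotropic
    mean_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # (z, y, x): in-plane +x
    intensity: float = 30.0  # peak fiber brightness, photons
    psf_sigma: tuple[float, float, float] = (1.2, 0.6, 0.6)  # per-axis blur, voxels
    poisson_scale: float = 1.0  # photons per intensity unit; 0 disables shot noise
    read_noise: float = 1.0  # Gaussian read noise SD; 0 disables
    depth_heterogeneity: float = 0.5  # amplitude of the random axial density modulation
    spacing: float = 1.0  # um per voxel (isotropic)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape):
            raise ParameterError(f"phantom extents must be >= 16 voxels, got {self.shape}")
        if self.n_fibers < 0 or self.fiber_length <= 0 or self.fiber_width <= 0:
            raise ParameterError("fiber count/length/width must be nonnegative/positive")
        if self.waviness < 0 or self.alignment_kappa < 0:
            raise ParameterError("waviness and alignment_kappa must be >= 0")
        if not 0 <= self.depth_heterogeneity < 1:
            raise ParameterError("depth_heterogeneity must be in [0, 1)")
        if self.intensity <= 0 or self.poisson_scale < 0 or self.read_noise < 0:
            raise ParameterError("intensity must be positive; noise terms nonnegative")


@dataclass(frozen=True)
class ClassPreset:
    """A named phantom morphology (one tissue-class analogue)."""

    name: str
    spec: PhantomSpec


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sample_direction(rng: np.random.Generator, mean_axis, kappa: float) -> np.ndarray:
    """Fiber principal direction: vMF about mean_axis, uniform sphere at kappa=0."""
    if kappa <= 0:
        v = rng.normal(size=3)
        return _unit(v)
    mu = _unit(np.asarray(mean_axis, dtype=float))
    return vonmises_fisher.rvs(mu, kappa, size=1, random_state=rng)[0]


def _walk_positions(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    n_steps: int,
    step: float,
    turn_sd: float,
) -> np.ndarray:
    """Persistent random-walk centerline: per-step transverse direction noise."""
    noise = rng.normal(scale=turn_sd, size=(n_steps, 3)) if turn_sd > 0 else None
    pts = np.empty((n_steps, 3))
    d = direction
    p = start
    for i in range(n_steps):
        pts[i] = p
        if noise is not None:
            e = noise[i]
            e = e - d * (e @ d)  # keep perturbation transverse
            d = _unit(d + e)
        p = p + step * d
    return pts


def _splat(canvas: np.ndarray, pts: np.ndarray, w: float) -> None:
    """Trilinear deposition of weight w at continuous (z, y, x) positions.

    Positions are wrapped periodically into the box, which keeps the expected
    fiber density spatially stationary (no rarefaction near the faces)."""
    i0 = np.floor(pts).astype(np.intp)
    f = pts - i0
    shape = np.asarray(canvas.shape)
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = np.mod(i0 + off, shape)
        weight = np.prod(np.where(off, f, 1.0 - f), axis=1) * w
        np.add.at(canvas, tuple(idx.T), weight)


def render_fibers(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Noiseless fiber render: random-walk centerlines blurred to width + PSF.

    Additive in fibers and nonnegative; the amplitude is scaled so a straight
    fiber peaks near ``spec.intensity`` regardless of its width.
    """
    shape = spec.shape
    canvas = np.zeros(shape, dtype=np.float64)
    diagonal = float(np.linalg.norm(shape))
    step = 0.5  # voxels per walk step
    # real stacks are not uniform through depth (collagen density varies and
    # SHG decays into the tissue): modulate the axial fiber density with a
    # smooth random profile, periodic in z to stay consistent with wrapping
    nz = shape[0]
    if spec.depth_heterogeneity > 0:
        n_waves = int(rng.integers(1, 3))
        phase = rng.uniform(0, 2 * np.pi)
        zc = np.arange(nz) + 0.5
        profile = 1.0 + spec.depth_heterogeneity * np.sin(2 * np.pi * n_waves * zc / nz + phase)
        cdf = np.concatenate([[0.0], np.cumsum(profile)])
        cdf /= cdf[-1]
    else:
        cdf = None
    for _ in range(spec.n_fibers):
        length = max(2.0, rng.normal(spec.fiber_length, 0.25 * spec.fiber_length))
        if length > diagonal:
            logger.warning("fiber length %.1f exceeds volume diagonal %.1f; clipping", length, diagonal)
            length = diagonal
        d = _sample_direction(rng, spec.mean_axis, spec.alignment_kappa)
        start = rng.uniform(0, 1, size=3) * (np.asarray(shape) - 1)
        if cdf is not None:
            start[0] = np.interp(rng.uniform(), cdf, np.arange(nz + 1.0)) / nz * (nz - 1)
        n_steps = int(round(length / step))
        pts = _walk_positions(rng, start, d, n_steps, step, spec.waviness * np.sqrt(step))
        _splat(canvas, pts, step)
    sigma = np.sqrt(np.asarray(spec.psf_sigma) ** 2 + spec.fiber_width**2)
    blurred = _ndi.gaussian_filter(canvas, sigma=sigma, mode="wrap")
    # line of unit linear density blurred in 3D peaks at ~1/(2 pi s_t1 s_t2)
    amplitude = spec.intensity * 2 * np.pi * sigma[1] * sigma[2]
    return blurred * amplitude


def generate_fiber_volume(spec: PhantomSpec) -> Volume:
    """One synthetic SHG-like stack: rendered fibers plus detection noise.

    Reproducible from ``spec.seed``.  Intensities are clipped at zero after
    read noise, as a photon-counting detector reports nonnegative counts.
    """
    rng = np.random.default_rng(spec.seed)
    signal = render_fibers(spec, rng)
    if spec.poisson_scale > 0:
        counts = rng.poisson(np.clip(signal * spec.poisson_scale, 0, None)) / spec.poisson_scale
    else:
        counts = signal
    if spec.read_noise > 0:
        counts = counts + rng.normal(scale=spec.read_noise, size=spec.shape)
    values = np.clip(counts, 0, None).astype(np.float32)
    return Volume(
        values=values,
        spacing=(spec.spacing,) * 3,
        provenance=[f"phantom seed={spec.seed}"],
    )


def preset_library(base: PhantomSpec | None = None) -> list[ClassPreset]:
    """The six morphology presets (deltas from a shared base spec)."""
    base = base or PhantomSpec()
    deltas = {
        # short fibers, isotropic mesh
        "normal": dict(n_fibers=650, fiber_length=12, fiber_width=0.6, waviness=0.35, alignment_kappa=0.0),
        # heterogeneous mixture of longer curvy/straight fibers, mild alignment
        "high_risk": dict(n_fibers=280, fiber_length=26, fiber_width=1.2, waviness=0.12, alignment_kappa=2.0),
        # thick short wavy fibers
        "benign": dict(n_fibers=300, fiber_length=12, fiber_width=2.2, waviness=0.30, alignment_kappa=1.0),
        # sparse but highly aligned
        "endometrioid": dict(n_fibers=160, fiber_length=34, fiber_width=0.8, waviness=0.06, alignment_kappa=10.0),
        # fibrotic: dense short fibers
        "lgs": dict(n_fibers=1100, fiber_length=8, fiber_width=1.5, waviness=0.25, alignment_kappa=1.0),
        # long wavy aligned fibers
        "hgs": dict(n_fibers=450, fiber_length=50, fiber_width=1.0, waviness=0.20, alignment_kappa=10.0),
    }
    return [ClassPreset(name=k, spec=replace(base, **v)) for k, v in deltas.items()]


def _stack_seed(base_seed: int, class_index: int, stack_index: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, class_index, stack_index]).generate_state(1)[0]
        % (2**31)
    )


def generate_dataset_volumes(
    presets: list[ClassPreset],
    stacks_per_class: int,
    base_seed: int = 0,
):
    """In-memory dataset: yields (volume, class_label, source_id) triples.

    Per-stack seeds are derived deterministically from ``base_seed`` and the
    (class, stack) indices, so the dataset is reproducible.
    """
    for ci, preset in enumerate(presets):
        for si in range(stacks_per_class):
            seed = _stack_seed(base_seed, ci, si)
            vol = generate_fiber_volume(replace(preset.spec, seed=seed))
            yield vol, preset.name, f"{preset.name}_{si:03d}"


def generate_dataset(
    presets: list[ClassPreset],
    stacks_per_class: int,
    base_seed: int,
    out_dir,
    force: bool = False,
) -> LabeledStackManifest:
    """Write a labeled TIFF dataset + CSV manifest (same schema as real data)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for vol, label, source in generate_dataset_volumes(presets, stacks_per_class, base_seed):
        path = out_dir / f"{source}.tif"
        if path.exists() and not force:
            raise Texton3DError(f"{path} exists; pass force=True to overwrite")
        write_stack(path, vol)
        entries.append((str(path), label, source))
    manifest = LabeledStackManifest(entries=entries, classes=[p.name for p in presets])
    write_manifest(out_dir / "manifest.csv", manifest)
    return manifest
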