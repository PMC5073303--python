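"""Multi-scale, multi-orientation 3D filter bank for fibrillar texture analysis.

The bank is built from first- and second-order derivatives of anisotropic 3D
Gaussians (edge- and bar-like detectors, elongated along the fiber direction),
rotated about each coordinate axis at evenly spaced angles, at three scales,
plus one isotropic Gaussian and one Laplacian-of-Gaussian.  With the default
parameters (6 orientations x 3 scales x 2 derivative orders x 3 axes + 2)
the bank holds 110 kernels.  Collapsing each orientation set to its per-voxel
maximum response reduces the 110 responses to 20 channels and makes the
representation tolerant to rotations about each axis.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``; the physical axes are (x, y, z).
* The anisotropic Gaussian has widths ``sigma = (sx, sy, sz)`` with the
  derivative taken along the short x axis and the elongation along z
  (``sz = 3 sx`` for the default scales); rotations about x, y and z then
  generate the orientation set.  Rotations are right-handed about the
  physical axis; the continuous function is rotated first and sampled on the
  integer grid afterwards.
* Filtering is *cross-correlation* with the centered kernel
  (``resp[p] = sum_t K[t] V[p + t - h]``): the response to a unit impulse is
  the point-reflected kernel.  Boundaries are handled by symmetric
  reflection, applied repeatedly when a kernel extends beyond the volume.
* All kernels are L1-normalized by total absolute mass; derivative and LoG
  kernels are then shifted to exactly zero sum, so constant image regions
  produce exactly zero response on those channels.

Kernel supports are tight per axis: half-extent ``ceil(f * std)`` along each
array axis from the rotated covariance (``f = support_factor``, default 3,
capturing >99.7% of the mass), taken as the union box over the orientations
of a group so that all kernels in one orientation group share a support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as _fft
from scipy import ndimage as _ndi

from .exceptions import ConsistencyError, ParameterError
from .volumeio import Volume

__all__ = [
    "Kernel3D",
    "FilterBank",
    "ResponseField",
    "DEFAULT_SCALES",
    "make_gaussian_kernel",
    "make_log_kernel",
    "make_oriented_derivative_kernel",
    "build_filter_bank",
    "isotropic_bank_size",
    "convolve_volume",
    "max_collapse",
    "response_field",
    "save_bank",
    "load_bank",
]

DEFAULT_SCALES: tuple[tuple[float, float, float], ...] = ((1, 1, 3), (2, 2, 6), (4, 4, 12))

_AXIS_TO_DIM = {"z": 0, "y": 1, "x": 2}  # physical axis -> array dimension


# ---------------------------------------------------------------------------
# 1D factor functions (unnormalized)

def _g(t: np.ndarray, s: float) -> np.ndarray:
    return np.exp(-0.5 * (t / s) ** 2)


def _dg(t: np.ndarray, s: float) -> np.ndarray:
    return -(t / s**2) * np.exp(-0.5 * (t / s) ** 2)


def _d2g(t: np.ndarray, s: float) -> np.ndarray:
    return (t**2 / s**4 - 1.0 / s**2) * np.exp(-0.5 * (t / s) ** 2)


def _deriv(t: np.ndarray, s: float, order: int) -> np.ndarray:
    return _dg(t, s) if order == 1 else _d2g(t, s)


def _grid(h: int) -> np.ndarray:
    return np.arange(-h, h + 1, dtype=np.float64)


# ---------------------------------------------------------------------------
# Separable execution plans

@dataclass
class _OrientedPlan:
    """kernel = outer(k2d over plane_dims, f1d along batch_dim), minus `shift`."""

    batch_dim: int
    plane_dims: tuple[int, int]
    f1d: np.ndarray
    k2d: np.ndarray
    shift: float


@dataclass
class _SeparablePlan:
    """kernel = sum of fully separable terms (fz, fy, fx), minus `shift`."""

    terms: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    shift: float


@dataclass
class Kernel3D:
    """One bank kernel: a sampled 3D grid plus its metadata.

    ``kind`` is one of ``deriv1``, ``deriv2``, ``gaussian``, ``log``;
    ``scale_index``/``rotation_axis``/``orientation_index`` are ``None`` for
    the Gaussian and LoG kernels.
    """

    values: np.ndarray
    kind: str
    scale_index: int | None = None
    rotation_axis: str | None = None
    orientation_index: int | None = None
    sigma: tuple[float, ...] | float | None = None
    angle: float | None = None
    plan: _OrientedPlan | _SeparablePlan | None = field(default=None, repr=False)

    @property
    def half_extents(self) -> tuple[int, int, int]:
        return tuple(s // 2 for s in self.values.shape)  # type: ignore[return-value]


def _finalize(raw: np.ndarray, zero_sum: bool) -> tuple[np.ndarray, float, float]:
    """L1-normalize and optionally shift to exact zero sum.

    Returns (values, l1_of_raw, shift_subtracted_after_normalization).
    """
    l1 = np.abs(raw).sum()
    if l1 == 0:
        raise ParameterError("degenerate kernel with zero mass")
    values = raw / l1
    shift = 0.0
    if zero_sum:
        shift = values.sum() / values.size
        values = values - shift
    return values, l1, shift


def _check_sigma(sigma) -> tuple[float, float, float]:
    sigma = tuple(float(s) for s in np.atleast_1d(sigma).ravel())
    if len(sigma) == 1:
        sigma = sigma * 3
    if len(sigma) != 3 or any(s <= 0 for s in sigma):
        raise ParameterError(f"sigma must be 1 or 3 positive widths, got {sigma}")
    return sigma  # (sx, sy, sz)


def _check_support(support) -> tuple[int, int, int]:
    support = tuple(int(s) for s in np.atleast_1d(support).ravel())
    if len(support) == 1:
        support = support * 3
    if len(support) != 3 or any(s < 1 for s in support):
        raise ParameterError(f"support must be 1 or 3 half-extents >= 1, got {support}")
    return support  # (hz, hy, hx)


def make_gaussian_kernel(sigma, support=None, support_factor: float = 3.0) -> Kernel3D:
    """Separable 3D Gaussian, sampled on the integer grid, unit L1 mass.

    ``sigma`` is per-axis ``(sx, sy, sz)`` in voxels (a scalar is broadcast);
    ``support`` is the per-axis half-extent ``(hz, hy, hx)`` (default
    ``ceil(support_factor * sigma)``).
    """
    sx, sy, sz = _check_sigma(sigma)
    if support is None:
        support = tuple(max(1, int(np.ceil(support_factor * s))) for s in (sz, sy, sx))
    hz, hy, hx = _check_support(support)
    fz, fy, fx = _g(_grid(hz), sz), _g(_grid(hy), sy), _g(_grid(hx), sx)
    raw = np.einsum("z,y,x->zyx", fz, fy, fx)
    values, l1, _ = _finalize(raw, zero_sum=False)
    plan = _SeparablePlan(terms=[(fz / l1, fy, fx)], shift=0.0)
    return Kernel3D(values=values, kind="gaussian", sigma=(sx, sy, sz), plan=plan)


def make_log_kernel(
    sigma: float,
    support=None,
    support_factor: float = 3.0,
    normalize: bool = False,
) -> Kernel3D:
    """3D Laplacian of Gaussian, scale-normalized (x sigma^2), exact zero sum.

    The kernel is rotationally symmetric with a negative center and a positive
    annulus; the sign change sits near radius ``sigma * sqrt(3)``.  With
    ``normalize=True`` (used when assembling a bank) the kernel is in addition
    L1-normalized before the zero-sum adjustment.
    """
    sigma = float(sigma)
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    if support is None:
        support = (max(1, int(np.ceil(support_factor * sigma))),) * 3
    hz, hy, hx = _check_support(support)
    tz, ty, tx = _grid(hz), _grid(hy), _grid(hx)
    # dense sampling of sigma^2 * Laplacian(G); identical to the sum of the
    # three separable second-derivative terms
    Z, Y, X = np.meshgrid(tz, ty, tx, indexing="ij")
    r2 = X**2 + Y**2 + Z**2
    raw = sigma**2 * (r2 / sigma**4 - 3.0 / sigma**2) * np.exp(-0.5 * r2 / sigma**2)
    if normalize:
        values, l1, shift = _finalize(raw, zero_sum=True)
        scale = sigma**2 / l1
    else:
        shift = raw.sum() / raw.size
        values = raw - shift
        scale = sigma**2
    gz, gy, gx = _g(tz, sigma), _g(ty, sigma), _g(tx, sigma)
    terms = [
        (scale * _d2g(tz, sigma), gy, gx),
        (gz, scale * _d2g(ty, sigma), gx),
        (gz, gy, scale * _d2g(tx, sigma)),
    ]
    return Kernel3D(values=values, kind="log", sigma=sigma, plan=_SeparablePlan(terms, shift))


def _rotated_stds(sigma: tuple[float, float, float], axis: str, angle: float) -> np.ndarray:
    """Per-array-axis std dev (z, y, x order) of the rotated Gaussian envelope."""
    sx, sy, sz = sigma
    c2, s2 = np.cos(angle) ** 2, np.sin(angle) ** 2
    if axis == "x":
        vx, vy, vz = sx**2, c2 * sy**2 + s2 * sz**2, s2 * sy**2 + c2 * sz**2
    elif axis == "y":
        vx, vy, vz = c2 * sx**2 + s2 * sz**2, sy**2, s2 * sx**2 + c2 * sz**2
    elif axis == "z":
        vx, vy, vz = c2 * sx**2 + s2 * sy**2, s2 * sx**2 + c2 * sy**2, sz**2
    else:
        raise ParameterError(f"rotation axis must be one of x, y, z; got {axis!r}")
    return np.sqrt([vz, vy, vx])


def make_oriented_derivative_kernel(
    order: int,
    sigma,
    axis: str,
    angle: float,
    support=None,
    support_factor: float = 3.0,
    scale_index: int | None = None,
    orientation_index: int | None = None,
) -> Kernel3D:
    """Oriented Gaussian-derivative kernel (order 1 = edge, order 2 = bar).

    The anisotropic Gaussian ``G(x; sx) G(y; sy) G(z; sz)`` is differentiated
    along its short x axis, rigidly rotated about the given physical
    coordinate axis by ``angle`` (radians), sampled on the integer grid,
    L1-normalized, and shifted to exact zero sum.
    """
    if order not in (1, 2):
        raise ParameterError(f"derivative order must be 1 or 2, got {order}")
    sx, sy, sz = _check_sigma(sigma)
    if axis not in _AXIS_TO_DIM:
        raise ParameterError(f"rotation axis must be one of x, y, z; got {axis!r}")
    if support is None:
        stds = _rotated_stds((sx, sy, sz), axis, angle)
        support = tuple(max(1, int(np.ceil(support_factor * s))) for s in stds)
    hz, hy, hx = _check_support(support)
    tz, ty, tx = _grid(hz), _grid(hy), _grid(hx)
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        Zg, Yg = np.meshgrid(tz, ty, indexing="ij")
        yr = c * Yg + s * Zg
        zr = -s * Yg + c * Zg
        k2d = _g(yr, sy) * _g(zr, sz)
        f1d = _deriv(tx, sx, order)
        batch_dim, plane_dims, sub = 2, (0, 1), "zy,x->zyx"
    elif axis == "y":
        Zg, Xg = np.meshgrid(tz, tx, indexing="ij")
        xr = c * Xg - s * Zg
        zr = s * Xg + c * Zg
        k2d = _deriv(xr, sx, order) * _g(zr, sz)
        f1d = _g(ty, sy)
        batch_dim, plane_dims, sub = 1, (0, 2), "zx,y->zyx"
    else:  # 'z'
        Yg, Xg = np.meshgrid(ty, tx, indexing="ij")
        xr = c * Xg + s * Yg
        yr = -s * Xg + c * Yg
        k2d = _deriv(xr, sx, order) * _g(yr, sy)
        f1d = _g(tz, sz)
        batch_dim, plane_dims, sub = 0, (1, 2), "yx,z->zyx"
    raw = np.einsum(sub, k2d, f1d)
    values, l1, shift = _finalize(raw, zero_sum=True)
    plan = _OrientedPlan(batch_dim, plane_dims, f1d, k2d / l1, shift)
    return Kernel3D(
        values=values,
        kind=f"deriv{order}",
        scale_index=scale_index,
        rotation_axis=axis,
        orientation_index=orientation_index,
        sigma=(sx, sy, sz),
        angle=float(angle),
        plan=plan,
    )


@dataclass
class FilterBank:
    """Ordered kernel set plus the orientation-collapse channel map.

    ``channel_map[i]`` is the collapsed channel (0..n_channels-1) that kernel
    ``i`` contributes to; each oriented channel groups the orientations of one
    (derivative order, scale, rotation axis) triple, and the Gaussian and LoG
    each get a channel of their own.
    """

    kernels: list[Kernel3D]
    channel_map: np.ndarray
    channel_names: list[str]
    params: dict = field(default_factory=dict)
    _spectra: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channel_groups(self) -> list[np.ndarray]:
        """Kernel indices contributing to each channel, in channel order."""
        return [np.flatnonzero(self.channel_map == c) for c in range(self.n_channels)]


def build_filter_bank(
    n_orientations: int = 6,
    scales=DEFAULT_SCALES,
    gauss_log_sigma: float = 10.0,
    support_factor: float = 3.0,
) -> FilterBank:
    """Assemble the oriented-derivative bank plus Gaussian and LoG.

    Kernel count is ``n_orientations * len(scales) * 2 orders * 3 axes + 2``
    (110 with defaults); collapsed channel count is ``2 * len(scales) * 3 + 2``
    (20 with defaults).  Orientations are evenly spaced over [0, pi).
    """
    if n_orientations < 1:
        raise ParameterError("n_orientations must be >= 1")
    scales = [_check_sigma(s) for s in scales]
    if not scales:
        raise ParameterError("scales must be non-empty")
    angles = [o * np.pi / n_orientations for o in range(n_orientations)]
    kernels: list[Kernel3D] = []
    channel_map: list[int] = []
    channel_names: list[str] = []
    for order in (1, 2):
        for si, sigma in enumerate(scales):
            for axis in ("x", "y", "z"):
                channel = len(channel_names)
                channel_names.append(f"deriv{order}_s{si}_{axis}")
                # union support over the orientation set, shared by the group
                stds = np.max(
                    [_rotated_stds(sigma, axis, a) for a in angles], axis=0
                )
                support = tuple(max(1, int(np.ceil(support_factor * s))) for s in stds)
                for oi, angle in enumerate(angles):
                    kernels.append(
                        make_oriented_derivative_kernel(
                            order,
                            sigma,
                            axis,
                            angle,
                            support=support,
                            scale_index=si,
                            orientation_index=oi,
                        )
                    )
                    channel_map.append(channel)
    kernels.append(
        make_gaussian_kernel(gauss_log_sigma, support_factor=support_factor)
    )
    channel_map.append(len(channel_names))
    channel_names.append("gaussian")
    kernels.append(
        make_log_kernel(gauss_log_sigma, support_factor=support_factor, normalize=True)
    )
    channel_map.append(len(channel_names))
    channel_names.append("log")
    return FilterBank(
        kernels=kernels,
        channel_map=np.asarray(channel_map),
        channel_names=channel_names,
        params=dict(
            n_orientations=n_orientations,
            scales=[tuple(s) for s in scales],
            gauss_log_sigma=float(gauss_log_sigma),
            support_factor=float(support_factor),
        ),
    )


def isotropic_bank_size(
    n_per_axis: int = 6, n_scales: int = 3, n_types: int = 2
) -> int:
    """Kernel count of the hypothetical isotropically distributed bank.

    Distributing orientations over all three Euler directions instead of
    around the three coordinate axes would need
    ``n^3 * scales * types + 2`` kernels (1298 with the defaults) — the
    reason the axis-restricted 110-kernel bank is used instead.
    """
    return n_per_axis**3 * n_scales * n_types + 2


# ---------------------------------------------------------------------------
# Convolution engine
#
# Boundary model: the volume is extended by symmetric reflection
# (..., v1, v0 | v0, v1, ..., v_{n-1} | v_{n-1}, ...), which is periodic with
# period 2n, so a circular FFT over one period of the extension computes the
# reflected correlation *exactly*, for kernels of any size.


def _reflect_indices(idx: np.ndarray, n: int) -> np.ndarray:
    if n == 1:
        return np.zeros_like(idx)
    j = np.mod(idx, 2 * n)
    return np.where(j < n, j, 2 * n - 1 - j)


def _take_reflected(arr: np.ndarray, axis: int, start: int, stop: int) -> np.ndarray:
    """arr sliced along `axis` on the symmetric extension over [start, stop)."""
    idx = _reflect_indices(np.arange(start, stop), arr.shape[axis])
    return np.take(arr, idx, axis=axis)


def _corr1d(arr: np.ndarray, k: np.ndarray, axis: int, out_range=None) -> np.ndarray:
    """Centered 1D cross-correlation, symmetric boundary, 'same' output.

    ``out_range=(a, b)`` restricts the output (and hence the work) to indices
    [a, b) along ``axis``; other axes are untouched.
    """
    k = np.asarray(k, dtype=arr.dtype)
    h = len(k) // 2
    a, b = (0, arr.shape[axis]) if out_range is None else out_range
    seg = _take_reflected(arr, axis, a - h, b + h)
    out = _ndi.correlate1d(seg, k, axis=axis, mode="constant")
    sl = [slice(None)] * arr.ndim
    sl[axis] = slice(h, h + (b - a))
    return out[tuple(sl)]


def _kernel2d_spectrum(k2d: np.ndarray, periods: tuple[int, int], dtype) -> np.ndarray:
    """rfft2 of the centered kernel wrapped onto the (P1, P2) torus.

    Wrapping (adding kernel taps that alias onto the same torus cell) is exact
    because the symmetric extension is (P1, P2)-periodic.
    """
    P1, P2 = periods
    h1, h2 = k2d.shape[0] // 2, k2d.shape[1] // 2
    wrapped = np.zeros((P1, P2), dtype=dtype)
    i1 = np.mod(np.arange(k2d.shape[0]) - h1, P1)
    i2 = np.mod(np.arange(k2d.shape[1]) - h2, P2)
    np.add.at(wrapped, (i1[:, None], i2[None, :]), k2d.astype(dtype))
    return np.conj(_fft.rfft2(wrapped))


def _corr2d_periodic(
    slab: np.ndarray,
    plane_dims: tuple[int, int],
    spectrum: np.ndarray,
) -> np.ndarray:
    """Exact symmetric-boundary 2D correlation over `plane_dims` via the
    periodized extension; `slab` may be batch-restricted along the third dim."""
    d1, d2 = plane_dims
    n1, n2 = slab.shape[d1], slab.shape[d2]
    ext = _take_reflected(slab, d1, 0, max(2 * n1, 2))
    ext = _take_reflected(ext, d2, 0, max(2 * n2, 2))
    moved = np.moveaxis(ext, (d1, d2), (-2, -1))
    F = _fft.rfft2(moved)
    out = _fft.irfft2(F * spectrum, s=moved.shape[-2:])
    out = out[..., :n1, :n2]
    return np.moveaxis(out, (-2, -1), (d1, d2))


def _box_sum(arr: np.ndarray, box: tuple[int, int, int], roi) -> np.ndarray:
    """Sliding-window sum over a centered box, symmetric boundary, roi-restricted.

    Computed per axis with cumulative sums (O(n) per voxel instead of O(n*k))."""
    out = arr
    for axis, extent in enumerate(box):
        h = extent // 2
        a, b = roi[axis]
        seg = _take_reflected(out, axis, a - h, b + h)
        seg = np.moveaxis(seg, axis, 0)
        cs = np.cumsum(seg, axis=0, dtype=seg.dtype)
        cs = np.concatenate([np.zeros_like(cs[:1]), cs], axis=0)
        out = np.moveaxis(cs[extent:] - cs[: b - a], 0, axis)
    return out


def _full_roi(shape) -> tuple[tuple[int, int], ...]:
    return tuple((0, n) for n in shape)


def _corr_separable(arr: np.ndarray, plan: _SeparablePlan, roi, box_field=None) -> np.ndarray:
    total = None
    for fz, fy, fx in plan.terms:
        out = arr
        for axis, f in enumerate((fz, fy, fx)):
            out = _corr1d(out, f, axis, out_range=roi[axis])
        total = out if total is None else total + out
    if plan.shift != 0.0:
        if box_field is None:
            box = tuple(len(f) for f in plan.terms[0])
            box_field = _box_sum(arr, box, roi)
        total = total - arr.dtype.type(plan.shift) * box_field
    return total


def _corr_oriented(
    arr: np.ndarray,
    plan: _OrientedPlan,
    roi,
    bank: FilterBank | None = None,
    spec_key=None,
    box_field=None,
    slab: np.ndarray | None = None,
) -> np.ndarray:
    d1, d2 = plan.plane_dims
    if slab is None:
        slab = _corr1d(arr, plan.f1d, plan.batch_dim, out_range=roi[plan.batch_dim])
    periods = (max(2 * arr.shape[d1], 2), max(2 * arr.shape[d2], 2))
    cache = bank._spectra if bank is not None else None
    key = (spec_key, periods, arr.dtype.str) if spec_key is not None else None
    spectrum = cache.get(key) if (cache is not None and key is not None) else None
    if spectrum is None:
        cdtype = np.complex64 if arr.dtype == np.float32 else np.complex128
        spectrum = _kernel2d_spectrum(plan.k2d, periods, arr.dtype).astype(cdtype)
        if cache is not None and key is not None:
            cache[key] = spectrum
    out = _corr2d_periodic(slab, plan.plane_dims, spectrum)
    # crop plane dims to the roi
    sl = [slice(None)] * 3
    sl[d1] = slice(roi[d1][0], roi[d1][1])
    sl[d2] = slice(roi[d2][0], roi[d2][1])
    out = out[tuple(sl)]
    if plan.shift != 0.0:
        if box_field is None:
            box = [0, 0, 0]
            box[plan.batch_dim] = len(plan.f1d)
            box[d1], box[d2] = plan.k2d.shape
            box_field = _box_sum(arr, tuple(box), roi)
        out = out - arr.dtype.type(plan.shift) * box_field
    return out


def _as_array(volume) -> np.ndarray:
    if isinstance(volume, Volume):
        if not volume.is_isotropic:
            raise ConsistencyError(
                "volume must have equal voxel pitch on all axes; "
                "run volumeio.interpolate_isotropic first"
            )
        arr = volume.values
    else:
        arr = np.asarray(volume)
    if arr.ndim != 3:
        raise ConsistencyError(f"expected a 3D volume, got shape {arr.shape}")
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float64)
    return arr


def correlate_kernel(volume, kernel: Kernel3D, roi=None) -> np.ndarray:
    """Response of one kernel (same extents as the volume, or the roi box)."""
    arr = _as_array(volume)
    roi = _full_roi(arr.shape) if roi is None else roi
    if isinstance(kernel.plan, _OrientedPlan):
        return _corr_oriented(arr, kernel.plan, roi)
    return _corr_separable(arr, kernel.plan, roi)


def convolve_volume(volume, bank: FilterBank) -> np.ndarray:
    """Filter the volume with every kernel of the bank.

    Returns an array of shape ``(len(bank), nz, ny, nx)``: one same-sized
    response grid per kernel, in bank order.  Responses are cross-correlations
    with symmetric-reflection boundary handling; kernels larger than the
    volume are supported through repeated reflection.
    """
    arr = _as_array(volume)
    out = np.empty((len(bank),) + arr.shape, dtype=arr.dtype)
    roi = _full_roi(arr.shape)
    box_fields: dict[tuple, np.ndarray] = {}
    for i, kern in enumerate(bank.kernels):
        box = tuple(kern.values.shape)
        bf = None
        if kern.plan.shift != 0.0:
            if box not in box_fields:
                box_fields[box] = _box_sum(arr, box, roi)
            bf = box_fields[box]
        if isinstance(kern.plan, _OrientedPlan):
            out[i] = _corr_oriented(arr, kern.plan, roi, bank=bank, spec_key=i, box_field=bf)
        else:
            out[i] = _corr_separable(arr, kern.plan, roi, box_field=bf)
    return out


@dataclass
class ResponseField:
    """Per-voxel collapsed response vectors.

    ``values`` has shape ``(nz, ny, nx, n_channels)`` (20 channels with the
    default bank); ``origin`` is the offset of this field inside the source
    volume when only a sub-box was computed.
    """

    values: np.ndarray
    source_shape: tuple[int, int, int]
    channel_names: list[str]
    origin: tuple[int, int, int] = (0, 0, 0)

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]


def max_collapse(responses: np.ndarray, bank: FilterBank) -> ResponseField:
    """Collapse per-kernel responses to one channel per orientation group.

    Each oriented channel takes the per-voxel maximum over its orientation
    set (rotation tolerance about the group's axis); the Gaussian and LoG
    responses pass through unchanged.
    """
    responses = np.asarray(responses)
    if responses.shape[0] != len(bank):
        raise ConsistencyError(
            f"response stack has {responses.shape[0]} entries for a bank of {len(bank)}"
        )
    shape = responses.shape[1:]
    out = np.empty(shape + (bank.n_channels,), dtype=responses.dtype)
    for c, idx in enumerate(bank.channel_groups()):
        out[..., c] = responses[idx].max(axis=0) if len(idx) > 1 else responses[idx[0]]
    return ResponseField(values=out, source_shape=shape, channel_names=list(bank.channel_names))


def response_field(volume, bank: FilterBank, roi=None) -> ResponseField:
    """Collapsed response field, computed group-by-group (memory-lean).

    Equivalent to ``max_collapse(convolve_volume(volume, bank), bank)`` but
    never materializes the full per-kernel stack, and accepts an optional
    ``roi = ((z0, z1), (y0, y1), (x0, x1))`` restricting computation to a
    sub-box of the volume (responses inside the roi are identical to the
    full-volume computation).
    """
    arr = _as_array(volume)
    roi = _full_roi(arr.shape) if roi is None else tuple(tuple(r) for r in roi)
    for (a, b), n in zip(roi, arr.shape):
        if not (0 <= a < b <= n):
            raise ConsistencyError(f"roi {roi} does not fit volume shape {arr.shape}")
    out_shape = tuple(b - a for a, b in roi)
    out = np.empty(out_shape + (bank.n_channels,), dtype=arr.dtype)
    for c, idx in enumerate(bank.channel_groups()):
        kernels = [bank.kernels[i] for i in idx]
        shifts = [k.plan.shift for k in kernels]
        box_field = None
        if any(s != 0.0 for s in shifts):
            box = tuple(kernels[0].values.shape)  # group kernels share support
            box_field = _box_sum(arr, box, roi)
        acc = None
        slab = None
        if isinstance(kernels[0].plan, _OrientedPlan):
            # all orientations of a group share the 1D factor along the
            # rotation axis: convolve it once
            p0 = kernels[0].plan
            slab = _corr1d(arr, p0.f1d, p0.batch_dim, out_range=roi[p0.batch_dim])
        for i, kern in zip(idx, kernels):
            if isinstance(kern.plan, _OrientedPlan):
                r = _corr_oriented(
                    arr, kern.plan, roi, bank=bank, spec_key=int(i),
                    box_field=box_field, slab=slab,
                )
            else:
                r = _corr_separable(arr, kern.plan, roi, box_field=box_field)
            acc = r if acc is None else np.maximum(acc, r)
        out[..., c] = acc
    return ResponseField(
        values=out,
        source_shape=arr.shape,
        channel_names=list(bank.channel_names),
        origin=tuple(a for a, _ in roi),
    )


# ---------------------------------------------------------------------------
# Export / import


def save_bank(path_prefix, bank: FilterBank) -> None:
    """Write kernels to ``<prefix>.npz`` and metadata to ``<prefix>.json``."""
    prefix = Path(path_prefix)
    arrays = {f"kernel_{i:03d}": k.values for i, k in enumerate(bank.kernels)}
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
    meta = {
        "params": bank.params,
        "channel_map": bank.channel_map.tolist(),
        "channel_names": bank.channel_names,
        "kernels": [
            {
                "kind": k.kind,
                "scale_index": k.scale_index,
                "rotation_axis": k.rotation_axis,
                "orientation_index": k.orientation_index,
                "sigma": k.sigma if not isinstance(k.sigma, tuple) else list(k.sigma),
                "angle": k.angle,
                "support": [s // 2 for s in k.values.shape],
            }
            for k in bank.kernels
        ],
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_bank(path_prefix) -> FilterBank:
    """Rebuild a bank saved by :func:`save_bank` (kernels re-derived from
    parameters so the separable execution plans are available)."""
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    p = meta["params"]
    bank = build_filter_bank(
        n_orientations=p["n_orientations"],
        scales=[tuple(s) for s in p["scales"]],
        gauss_log_sigma=p["gauss_log_sigma"],
        support_factor=p["support_factor"],
    )
    with np.load(prefix.with_suffix(".npz")) as arrays:
        for i, kern in enumerate(bank.kernels):
            stored = arrays[f"kernel_{i:03d}"]
            if stored.shape != kern.values.shape or not np.allclose(
                stored, kern.values, atol=1e-12
            ):
                raise ConsistencyError(f"stored kernel {i} does not match its metadata")
    return bank
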