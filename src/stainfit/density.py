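"""Density-map data model: MRC2014 I/O, map simulation, mirroring, envelopes.

A :class:`DensityMap` is a scalar field on a regular 3D grid with a physical
origin and per-axis voxel spacing, the common currency of simulation,
mirroring and scoring. Values are stored in a ``(nz, ny, nx)`` array (section,
row, column order as in the MRC format); all physical positions are in
Ångström, and the *center* of voxel ``(0, 0, 0)`` sits at ``origin``.

Negative-stain maps carry no absolute intensity scale, so thresholds such as
the 0.06 envelope cutoff are interpreted on a max-normalized ``[0, 1]`` scale
(:meth:`DensityMap.normalized`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy import ndimage

logger = logging.getLogger("stainfit")

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class DensityMap:
    """Scalar values on a regular 3D grid.

    Parameters
    ----------
    values:
        Array of shape ``(nz, ny, nx)``; finite floats.
    voxel_size:
        Å per voxel along ``(x, y, z)``; all components positive.
    origin:
        Physical position (Å) of the center of voxel ``(0, 0, 0)``,
        in ``(x, y, z)`` order.
    label:
        Free-text provenance note.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D grid with every dimension >= 1")
        if self.voxel_size.shape != (3,) or not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be 3 positive components")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid dimensions as ``(nz, ny, nx)``."""
        return self.values.shape  # type: ignore[return-value]

    @property
    def shape_xyz(self) -> np.ndarray:
        return np.array(self.values.shape[::-1])

    def normalized(self) -> "DensityMap":
        """Clamp negative values to zero and rescale so the maximum is 1.

        Stain maps have arbitrary intensity units (and reconstruction noise
        can go negative); thresholds are defined on this ``[0, 1]`` scale.
        """
        v = np.clip(self.values, 0.0, None)
        peak = v.max()
        if peak <= 0:
            raise ValueError("cannot normalize a map with no positive density")
        return replace(self, values=v / peak)

    def index_to_position(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) centers of voxels given ``(k, j, i)`` indices."""
        idx = np.atleast_2d(np.asarray(idx_zyx, dtype=np.float64))
        return self.origin + idx[:, ::-1] * self.voxel_size

    def position_to_index(self, pos_xyz: np.ndarray) -> np.ndarray:
        """Fractional ``(k, j, i)`` grid indices of physical positions."""
        pos = np.atleast_2d(np.asarray(pos_xyz, dtype=np.float64))
        return ((pos - self.origin) / self.voxel_size)[:, ::-1]


@dataclass
class Envelope:
    """Binary envelope congruent with a :class:`DensityMap`.

    Records the threshold actually applied, for provenance.
    """

    mask: np.ndarray
    threshold: float
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D grid")

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def contains(self, pos_xyz: np.ndarray) -> np.ndarray:
        """Membership test: does each position fall in a mask voxel?"""
        idx = np.rint(((np.atleast_2d(pos_xyz) - self.origin) / self.voxel_size)).astype(int)
        nzyx = np.array(self.mask.shape)[::-1]
        inside = np.all((idx >= 0) & (idx < nzyx), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.mask[ii[:, 2], ii[:, 1], ii[:, 0]]
        return out


@dataclass
class SimulationParams:
    """Parameters of Gaussian map simulation from atomic coordinates.

    resolution:
        Target resolution in Å (stain-map benchmark default 30 Å).
    voxel_size:
        Grid spacing in Å (isotropic).
    sigma_factor:
        Dimensionless factor converting resolution to the Gaussian width,
        ``sigma = sigma_factor * resolution``; 0.225 is the convention of the
        Chimera-family fitting tools.
    padding:
        Å added around the model bounding box; ``None`` means ``4 * sigma``,
        matching the radial truncation of the atom Gaussians so that sums
        over the grid do not depend on grid alignment.
    """

    resolution: float = 30.0
    voxel_size: float = 4.0
    sigma_factor: float = 0.225
    padding: float | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.voxel_size <= 0:
            raise ValueError("resolution and voxel_size must be positive")
        if not 0 < self.sigma_factor < 1:
            raise ValueError("sigma_factor must be in (0, 1)")
        if self.padding is not None and self.padding < 0:
            raise ValueError("padding must be >= 0")

    @property
    def sigma(self) -> float:
        return self.sigma_factor * self.resolution

    @property
    def effective_padding(self) -> float:
        return 4.0 * self.sigma if self.padding is None else self.padding


# ---------------------------------------------------------------------------
# MRC2014 I/O (via gemmi)
# ---------------------------------------------------------------------------

def read_map(path) -> DensityMap:
    """Read an MRC2014 map file.

    The origin is taken from the ORIGIN header words when any is nonzero,
    otherwise computed from the start-voxel words as ``start * voxel_size``.
    Axis order is normalized to the internal (section=z, row=y, column=x)
    convention; maps whose axes cannot be brought to that order raise.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"not a readable MRC2014 map: {path}: {exc}") from exc
    axis_order = tuple(ccp4.header_i32(w) for w in (17, 18, 19))
    if axis_order != (1, 2, 3):
        try:
            ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
        except Exception as exc:  # pragma: no cover - gemmi-internal failure
            raise ValueError(
                f"unsupported MRC axis order MAPC,MAPR,MAPS={axis_order} in {path}"
            ) from exc
        if tuple(ccp4.header_i32(w) for w in (17, 18, 19)) != (1, 2, 3):
            raise ValueError(
                f"unsupported MRC axis order MAPC,MAPR,MAPS={axis_order} in {path}"
            )
    arr = np.array(ccp4.grid.array, dtype=np.float64)  # (nx, ny, nz)
    values = arr.transpose(2, 1, 0)  # -> (nz, ny, nx)
    cell = ccp4.grid.unit_cell
    sampling = [max(ccp4.header_i32(w), 1) for w in (8, 9, 10)]  # MX, MY, MZ
    voxel = np.array([cell.a, cell.b, cell.c]) / np.array(sampling, dtype=np.float64)
    header_origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    if np.any(header_origin != 0.0):
        origin = header_origin
    else:
        start = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=np.float64)
        origin = start * voxel
    return DensityMap(values=values, voxel_size=voxel, origin=origin, label=str(path))


def write_map(density_map: DensityMap, path) -> None:
    """Write a :class:`DensityMap` as an MRC2014 file (mode 2, float32).

    Voxel size is encoded in the unit cell; the origin goes into the ORIGIN
    header words so that ``read_map(write_map(m)) == m``.
    """
    m = density_map
    nz, ny, nx = m.values.shape
    grid = gemmi.FloatGrid(np.ascontiguousarray(m.values.transpose(2, 1, 0), dtype=np.float32))
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * m.voxel_size[0], ny * m.voxel_size[1], nz * m.voxel_size[2], 90, 90, 90
        )
    )
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), m.origin):
        ccp4.set_header_float(word, float(value))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write map to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Simulation from coordinates
# ---------------------------------------------------------------------------

def simulate_map(model, params: SimulationParams, like: DensityMap | None = None) -> DensityMap:
    """Simulate a density map from an atomic model by Gaussian blurring.

    Each atom contributes an isotropic Gaussian of width
    ``sigma = sigma_factor * resolution`` centered at its position with peak
    amplitude equal to its weight; contributions are summed on the grid. By
    default the grid covers the model bounding box plus ``padding``; passing
    ``like`` evaluates on that map's grid instead (for scoring a placement
    against an experimental map).
    """
    positions = np.asarray(model.positions, dtype=np.float64)
    weights = np.asarray(model.weights, dtype=np.float64)
    if positions.size == 0:
        raise ValueError("cannot simulate a map from an empty model")
    sigma = params.sigma
    if like is not None:
        origin = like.origin.copy()
        voxel = like.voxel_size.copy()
        shape = like.values.shape
    else:
        pad = params.effective_padding
        voxel = np.full(3, float(params.voxel_size))
        lo = positions.min(axis=0) - pad
        hi = positions.max(axis=0) + pad
        nxyz = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 1)
        origin = lo
        shape = (int(nxyz[2]), int(nxyz[1]), int(nxyz[0]))
    values = np.zeros(shape, dtype=np.float64)
    _stamp_gaussians(values, origin, voxel, positions, weights, sigma)
    return DensityMap(values=values, voxel_size=voxel, origin=origin,
                      label=f"simulated sigma={sigma:.3f}")


def _stamp_gaussians(values, origin, voxel, positions, weights, sigma, cutoff=4.0):
    """Accumulate atom Gaussians into ``values`` using local windows.

    Contributions are truncated on a sphere of radius ``cutoff`` sigma
    (99.9% of the 3D Gaussian mass at the default 4 sigma). The radial —
    not rectangular — cutoff makes the per-atom grid sum independent of how
    the atom sits relative to the voxel lattice, so sums over
    well-separated atoms are exactly additive.
    """
    nzyx = np.array(values.shape)
    reach = cutoff * sigma
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for pos, w in zip(positions, weights):
        lo = np.floor((pos - reach - origin) / voxel).astype(int)
        hi = np.ceil((pos + reach - origin) / voxel).astype(int) + 1
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, nzyx[::-1])
        if np.any(lo_c >= hi_c):
            continue
        ax = [origin[d] + np.arange(lo_c[d], hi_c[d]) * voxel[d] - pos[d] for d in range(3)]
        d2 = (
            ax[2][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[0][None, None, :] ** 2
        )
        values[lo_c[2]:hi_c[2], lo_c[1]:hi_c[1], lo_c[0]:hi_c[0]] += \
            np.where(d2 <= reach * reach, w * np.exp(-d2 * inv2s2), 0.0)


# ---------------------------------------------------------------------------
# Mirroring, envelopes, surfaces
# ---------------------------------------------------------------------------

def mirror_map(density_map: DensityMap, axis: str = "x") -> DensityMap:
    """Reflect a map through the plane through its center normal to ``axis``.

    Values are reversed along the chosen axis; because the reflection plane
    passes through the grid center, the origin is unchanged and total density
    is conserved exactly. Mirroring twice restores the original map.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    ax_np = 2 - _AXES[axis]  # values are (z, y, x)
    flipped = np.flip(density_map.values, axis=ax_np).copy()
    return replace(density_map, values=flipped,
                   label=f"{density_map.label} [mirrored {axis}]")


def binarize(density_map: DensityMap, threshold: float) -> Envelope:
    """Binarize a map at an intensity threshold (strictly greater-than)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return Envelope(
        mask=density_map.values > threshold,
        threshold=float(threshold),
        voxel_size=density_map.voxel_size.copy(),
        origin=density_map.origin.copy(),
    )


#: default width (voxels) of the Gaussian prefilter used when extracting
#: envelopes: voxel-scale intensity fluctuations cannot represent signal at
#: the map's resolution, but they dimple a raw threshold contour
ENVELOPE_PREFILTER_VOX = 1.0


def extract_envelope(norm_map: DensityMap, threshold: float,
                     prefilter_vox: float = ENVELOPE_PREFILTER_VOX,
                     clean: bool = True) -> Envelope:
    """Extract the envelope of a max-normalized map at a threshold.

    The map is lightly low-pass filtered (``prefilter_vox`` voxels, well
    below the map resolution) and re-normalized before thresholding, so the
    contour follows shape rather than voxel noise; with ``clean`` the mask
    is restricted to its largest connected component. The same extraction
    must be applied to experimental and simulated maps wherever their
    envelopes are compared. ``prefilter_vox=0`` reduces to plain
    :func:`binarize`.
    """
    values = norm_map.values
    if prefilter_vox > 0:
        values = ndimage.gaussian_filter(values, sigma=prefilter_vox, mode="constant")
        peak = values.max()
        if peak <= 0:
            raise ValueError("map has no positive density after filtering")
        values = values / peak
    env = Envelope(mask=values > threshold, threshold=float(threshold),
                   voxel_size=norm_map.voxel_size.copy(), origin=norm_map.origin.copy())
    if clean and env.mask.any():
        env = largest_component(env)
    return env


def largest_component(envelope: Envelope) -> Envelope:
    """Restrict an envelope to its largest 6-connected component.

    Shot noise above the threshold produces isolated speck voxels that would
    otherwise dominate surface-based scores; the particle envelope of a
    stain map is its single large component.
    """
    if not envelope.mask.any():
        raise ValueError("envelope mask is empty")
    labels, n = ndimage.label(envelope.mask,
                              structure=ndimage.generate_binary_structure(3, 1))
    if n <= 1:
        return envelope
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = sizes.argmax()
    return Envelope(mask=labels == keep, threshold=envelope.threshold,
                    voxel_size=envelope.voxel_size.copy(), origin=envelope.origin.copy())


def surface_points(envelope: Envelope) -> np.ndarray:
    """Centers (Å, xyz) of mask voxels with a face-adjacent outside neighbor.

    The grid boundary counts as outside, so a mask touching the edge of the
    grid is surface there.
    """
    mask = envelope.mask
    if not mask.any():
        raise ValueError("envelope mask is empty")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    surf = mask & ~interior
    idx = np.argwhere(surf)  # (k, j, i)
    return envelope.origin + idx[:, ::-1] * envelope.voxel_size
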