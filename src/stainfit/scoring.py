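"""Fit-quality metrics and fit significance.

Four metrics rate how well a placed atomic model explains an experimental
map: the *overlap* (sum of aligned density products, the quantity the local
optimizer climbs), the about-zero normalized *cross-correlation*, the
*Chamfer distance* between the binarized envelopes' surfaces, and the
*envelope score* — realized here as the Dice coefficient of the binary
masks, a deliberate, documented definition choice that implements the
interpretation of a stain map as an approximation of the complex's surface.
Chamfer and Dice compare surfaces, which is what makes them informative for
stain maps; overlap and cross-correlation compare interiors.

Significance of a top fit is judged against the remaining cluster
representatives: ``z = (s_top - mean(rest)) / sd(rest)`` with an upper-tail
normal probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .density import (DensityMap, Envelope, SimulationParams, binarize,
                      extract_envelope, largest_component, simulate_map,
                      surface_points)
from .structure import AtomicModel, RigidTransform

logger = logging.getLogger("stainfit")


@dataclass
class FitScores:
    """The four fit metrics for one placement.

    overlap is in arbitrary (density-product) units; ccc in [-1, 1]; chamfer
    in Å (lower is better); envelope (Dice) in [0, 1].
    """

    overlap: float
    ccc: float
    chamfer: float
    envelope: float

    def __post_init__(self) -> None:
        for name in ("overlap", "ccc", "chamfer", "envelope"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")
        if not -1.0 - 1e-9 <= self.ccc <= 1.0 + 1e-9:
            raise ValueError(f"ccc out of [-1, 1]: {self.ccc}")
        if not 0.0 <= self.envelope <= 1.0 + 1e-9:
            raise ValueError(f"envelope score out of [0, 1]: {self.envelope}")
        if self.chamfer < 0:
            raise ValueError("chamfer must be >= 0")

    @property
    def chamfer_similarity(self) -> float:
        """Negated Chamfer distance, so that higher is better for every metric."""
        return -self.chamfer

    def as_dict(self) -> dict[str, float]:
        return {"overlap": self.overlap, "ccc": self.ccc,
                "chamfer": self.chamfer, "envelope": self.envelope}

    #: metric names on the higher-is-better convention used for ranking
    SIMILARITY_KEYS = ("overlap", "ccc", "chamfer_similarity", "envelope")

    def similarity(self, key: str) -> float:
        return float(getattr(self, key))


@dataclass
class SignificanceResult:
    """Standard score of the top fit against the remaining representatives."""

    z: float
    p: float
    n_fits: int
    significant: bool
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_onto(target: DensityMap, source: DensityMap) -> np.ndarray:
    """Trilinearly resample ``source`` values onto ``target``'s grid.

    Positions outside the source grid contribute zero.
    """
    nz, ny, nx = target.values.shape
    zi, yi, xi = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    pos = target.origin + np.stack([xi, yi, zi], axis=-1).reshape(-1, 3) * target.voxel_size
    frac = (pos - source.origin) / source.voxel_size  # (n, 3) in x,y,z index units
    coords = frac[:, ::-1].T  # (3, n) in z,y,x order
    out = map_coordinates(source.values, coords, order=1, mode="constant", cval=0.0)
    return out.reshape(target.values.shape)


# ---------------------------------------------------------------------------
# The four metrics
# ---------------------------------------------------------------------------

def overlap_score(exp_map: DensityMap, model_map: DensityMap) -> float:
    """Sum of aligned density products.

    The model map is resampled onto the experimental grid by trilinear
    interpolation; negative experimental values (stain-reconstruction noise)
    are clamped to zero. Disjoint grids give 0 with a warning.
    """
    exp_vals = np.clip(exp_map.values, 0.0, None)
    if _grids_disjoint(exp_map, model_map):
        warnings.warn("overlap_score: experimental and model grids are disjoint",
                      stacklevel=2)
        return 0.0
    model_vals = model_map.values if _same_grid(exp_map, model_map) \
        else resample_onto(exp_map, model_map)
    return float(np.sum(exp_vals * model_vals))


def cross_correlation(exp_map: DensityMap, model_map: DensityMap,
                      envelope: Envelope | None = None) -> float:
    """About-zero normalized cross-correlation, optionally inside an envelope.

    ``sum(e*m) / sqrt(sum(e^2) * sum(m^2))`` over the included voxels. The
    about-zero (rather than about-mean) form is deliberate: clamped stain
    maps are non-negative and mostly empty, where the about-mean variant is
    dominated by the empty background.
    """
    exp_vals = np.clip(exp_map.values, 0.0, None)
    model_vals = model_map.values if _same_grid(exp_map, model_map) \
        else resample_onto(exp_map, model_map)
    if envelope is not None:
        exp_vals = exp_vals[envelope.mask]
        model_vals = model_vals[envelope.mask]
    norm = np.sqrt(np.sum(exp_vals ** 2) * np.sum(model_vals ** 2))
    if norm == 0:
        raise ValueError("cross-correlation undefined for zero-norm input")
    return float(np.sum(exp_vals * model_vals) / norm)


def chamfer_distance(env_a: Envelope, env_b: Envelope) -> float:
    """Symmetrized mean nearest-neighbor distance (Å) between two surfaces.

    ``0.5 * (mean_a min_b ||a-b|| + mean_b min_a ||a-b||)`` over the
    envelopes' surface voxels.
    """
    pts_a = surface_points(env_a)
    pts_b = surface_points(env_b)
    d_ab = cKDTree(pts_b).query(pts_a)[0]
    d_ba = cKDTree(pts_a).query(pts_b)[0]
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


def envelope_score(env_a: Envelope, env_b: Envelope) -> float:
    """Dice coefficient of two binary masks on a common grid."""
    if env_a.mask.shape != env_b.mask.shape:
        raise ValueError("envelope_score needs masks on a common grid")
    total = env_a.count + env_b.count
    if total == 0:
        raise ValueError("both envelopes are empty")
    inter = int(np.sum(env_a.mask & env_b.mask))
    return 2.0 * inter / total


# ---------------------------------------------------------------------------
# Scoring a fit
# ---------------------------------------------------------------------------

def score_fit(exp_map: DensityMap, model: AtomicModel, transform: RigidTransform,
              params: SimulationParams | None = None,
              envelope_threshold: float = 0.06,
              clean_envelope: bool = True) -> FitScores:
    """Compute all four metrics for one placement.

    The model is simulated on the experimental grid at the placement, both
    maps are max-normalized, and envelopes are taken at the (normalized)
    threshold. By default the experimental envelope is restricted to its
    largest connected component so shot noise above the threshold does not
    dominate the surface-based metrics. Raises if either envelope is empty
    at the threshold (a placement entirely outside the grid).
    """
    params = params or SimulationParams(voxel_size=float(exp_map.voxel_size[0]))
    exp_norm = exp_map.normalized()
    placed = model.transformed(transform)
    model_map = simulate_map(placed, params, like=exp_map)
    if model_map.values.max() <= 0:
        raise ValueError("placed model has no density on the experimental grid")
    env_exp = extract_envelope(exp_norm, envelope_threshold, clean=clean_envelope)
    return score_density(exp_norm, env_exp, model_map.values, envelope_threshold)


def score_density(exp_norm: DensityMap, env_exp: Envelope, model_values: np.ndarray,
                  envelope_threshold: float) -> FitScores:
    """Score precomputed model density values on the experimental grid.

    Shared fast path for scoring many placements (representatives, combined
    two-body fits) without re-deriving the experimental envelope each time.
    ``exp_norm`` must already be clamped and max-normalized. The overlap uses
    the *raw* model density (so that, on a self-simulated map, no placement
    can outscore the truth); the envelope is taken on the max-normalized
    model density, where the threshold is defined.
    """
    peak = model_values.max()
    if peak <= 0:
        raise ValueError("model density is empty on the experimental grid")
    model_norm = DensityMap(values=model_values / peak, voxel_size=exp_norm.voxel_size,
                            origin=exp_norm.origin)
    env_model = extract_envelope(model_norm, envelope_threshold, clean=False)
    # a placement with no density inside the experimental envelope is simply
    # uncorrelated with it, not an error
    if np.any(model_norm.values[env_exp.mask] != 0.0):
        ccc = cross_correlation(exp_norm, model_norm, envelope=env_exp)
    else:
        ccc = 0.0
    return FitScores(
        overlap=float(np.sum(exp_norm.values * model_values)),
        ccc=ccc,
        chamfer=chamfer_distance(env_exp, env_model),
        envelope=envelope_score(env_exp, env_model),
    )


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

def fit_significance(scores, score_key: str = "overlap",
                     alpha: float = 0.05) -> SignificanceResult:
    """Assess whether the top fit stands out from the remaining representatives.

    ``scores`` is a FitEnsemble, a list of Fit objects, or a plain sequence
    of similarity values (higher = better). The top value is compared with
    the mean and standard deviation of the rest; the reported p-value is the
    upper-tail normal probability. At least 3 values are required.
    """
    values = _similarities(scores, score_key)
    if len(values) < 3:
        raise ValueError("significance needs at least 3 representative fits")
    values = np.sort(values)[::-1]
    top, rest = values[0], values[1:]
    sd = rest.std(ddof=1)
    if sd == 0:
        if top == rest[0]:
            return SignificanceResult(z=0.0, p=0.5, n_fits=len(values),
                                      significant=False, degenerate=True)
        tiny = np.finfo(float).tiny
        return SignificanceResult(z=np.inf, p=tiny, n_fits=len(values),
                                  significant=True, degenerate=True)
    z = float((top - rest.mean()) / sd)
    p = float(stats.norm.sf(z))
    p = min(max(p, np.finfo(float).tiny), 1.0 - np.finfo(float).epsneg)
    return SignificanceResult(z=z, p=p, n_fits=len(values), significant=p < alpha)


def _similarities(scores, score_key: str) -> np.ndarray:
    if hasattr(scores, "fits"):  # FitEnsemble
        scores = scores.fits
    out = []
    for s in scores:
        if hasattr(s, "scores") and s.scores is not None:
            out.append(s.scores.similarity(score_key))
        elif hasattr(s, "similarity"):
            out.append(s.similarity(score_key))
        else:
            out.append(float(s))
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _same_grid(a: DensityMap, b: DensityMap) -> bool:
    return (a.values.shape == b.values.shape
            and np.allclose(a.voxel_size, b.voxel_size)
            and np.allclose(a.origin, b.origin))


def _grids_disjoint(a: DensityMap, b: DensityMap) -> bool:
    a_lo, a_hi = a.origin, a.origin + (a.shape_xyz - 1) * a.voxel_size
    b_lo, b_hi = b.origin, b.origin + (b.shape_xyz - 1) * b.voxel_size
    return bool(np.any(a_hi < b_lo) or np.any(b_hi < a_lo))
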