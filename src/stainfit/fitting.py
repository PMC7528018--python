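"""Multi-start rigid-body fitting of one body into a density map.

The pipeline mirrors the global-fitting approach used for low-resolution
stain maps: place the body at many random positions and orientations, locally
optimize each placement against the *overlap* score (sum of aligned density
products), discard placements whose simulated envelope is insufficiently
covered by the experimental envelope, cluster the survivors by transform
similarity keeping the best-scoring member of each cluster, then score the
representatives with all four metrics.

Because each atom contributes a Gaussian of width ``sigma``, the overlap of
the simulated model density with the experimental map equals the sum, over
atoms, of the experimental map *convolved with that Gaussian* evaluated at
the atom positions. The optimizer therefore climbs a single precomputed
smoothed field with trilinear interpolation — exact up to discretization and
far cheaper than re-simulating the model map at every trial transform.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial.transform import Rotation

from .density import (DensityMap, Envelope, SimulationParams, binarize,
                      extract_envelope, simulate_map)
from .scoring import FitScores, score_density
from .structure import AtomicModel, RigidTransform

logger = logging.getLogger("stainfit")


@dataclass
class FitConfig:
    """Configuration of a global fitting run.

    Desk-scale defaults; the production-scale analog of this procedure used
    100,000 placements. ``cluster_rot_deg``/``cluster_trans`` default to the
    tight ("high") clustering regime; :data:`LOW_CLUSTERING` is the loose
    regime used before two-body combination.
    """

    n_placements: int = 2000
    opt_steps: int = 100
    coverage_min: float = 0.30
    envelope_threshold: float = 0.06
    cluster_rot_deg: float = 3.0
    cluster_trans: float = 2.0
    rng_seed: int = 0
    sim_params: SimulationParams | None = None
    score_key: str = "overlap"
    clean_envelope: bool = True

    def __post_init__(self) -> None:
        if self.n_placements < 1:
            raise ValueError("n_placements must be >= 1")
        if not 0.0 <= self.coverage_min <= 1.01:
            raise ValueError("coverage_min must be a fraction")
        if self.envelope_threshold <= 0 or self.cluster_rot_deg <= 0 or self.cluster_trans <= 0:
            raise ValueError("thresholds must be positive")


#: loose clustering preset used before combinatorial two-body assembly;
#: coarse enough to keep the product tractable, fine enough that orientation
#: variants of a basin survive as their own representatives
LOW_CLUSTERING = {"cluster_rot_deg": 10.0, "cluster_trans": 5.0}


@dataclass
class Fit:
    """One placement of a body, with its optimization objective and scores."""

    transform: RigidTransform
    objective: float
    coverage: float = float("nan")
    scores: FitScores | None = None
    cluster_size: int = 1

    def similarity(self, key: str) -> float:
        if key == "objective" or self.scores is None:
            return self.objective
        return self.scores.similarity(key)


@dataclass
class FitEnsemble:
    """Clustered representative fits of one body in one map."""

    map_id: str
    body_id: str
    fits: list[Fit]
    config: FitConfig
    score_key: str = "overlap"

    def __len__(self) -> int:
        return len(self.fits)

    @property
    def top(self) -> Fit:
        if not self.fits:
            raise ValueError("empty ensemble has no top fit")
        return self.fits[0]

    def best_by(self, key: str) -> Fit:
        """Best representative under one similarity key (higher = better)."""
        if not self.fits:
            raise ValueError("empty ensemble")
        return max(self.fits, key=lambda f: f.similarity(key))

    def to_json(self) -> str:
        payload = {
            "map_id": self.map_id,
            "body_id": self.body_id,
            "score_key": self.score_key,
            "config": _config_dict(self.config),
            "fits": [
                {
                    "quaternion_xyzw": [float(v) for v in f.transform.as_quaternion()],
                    "translation": [float(v) for v in f.transform.translation],
                    "objective": float(f.objective),
                    "coverage": float(f.coverage),
                    "cluster_size": f.cluster_size,
                    "scores": {k: float(v) for k, v in f.scores.as_dict().items()}
                    if f.scores is not None else None,
                }
                for f in self.fits
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FitEnsemble":
        payload = json.loads(text)
        cfg_d = dict(payload["config"])
        sim = cfg_d.pop("sim_params", None)
        config = FitConfig(**cfg_d, sim_params=SimulationParams(**sim) if sim else None)
        fits = []
        for fd in payload["fits"]:
            scores = FitScores(**fd["scores"]) if fd.get("scores") else None
            fits.append(Fit(
                transform=RigidTransform.from_quaternion(fd["quaternion_xyzw"],
                                                         fd["translation"]),
                objective=fd["objective"], coverage=fd["coverage"],
                scores=scores, cluster_size=fd["cluster_size"],
            ))
        return cls(map_id=payload["map_id"], body_id=payload["body_id"], fits=fits,
                   config=config, score_key=payload["score_key"])


def _config_dict(config: FitConfig) -> dict:
    d = asdict(config)
    return d


# ---------------------------------------------------------------------------
# Overlap objective
# ---------------------------------------------------------------------------

class OverlapObjective:
    """Overlap score of a placed model against a fixed experimental map.

    Precomputes the experimental map (clamped at zero) convolved with the
    simulation Gaussian; evaluating a transform is then one trilinear
    interpolation per atom.
    """

    def __init__(self, exp_map: DensityMap, sim_params: SimulationParams):
        self.exp_map = exp_map
        self.sim_params = sim_params
        sigma_vox = sim_params.sigma / exp_map.voxel_size  # (x, y, z)
        clamped = np.clip(exp_map.values, 0.0, None)
        smoothed = gaussian_filter(clamped, sigma=sigma_vox[::-1], mode="constant")
        # gaussian_filter uses a unit-sum kernel; rescale to the physical
        # Gaussian integral so the value matches a voxel-sum of products
        kernel_sum = (2.0 * np.pi * sim_params.sigma ** 2) ** 1.5 / np.prod(exp_map.voxel_size)
        self.field = smoothed * kernel_sum
        self.origin = exp_map.origin
        self.voxel = exp_map.voxel_size

    def value_at_positions(self, positions: np.ndarray, weights: np.ndarray) -> float:
        frac = (positions - self.origin) / self.voxel
        coords = frac[:, ::-1].T  # (3, n) in z,y,x
        vals = map_coordinates(self.field, coords, order=1, mode="constant", cval=0.0)
        return float(np.dot(weights, vals))

    def value(self, model: AtomicModel, transform: RigidTransform) -> float:
        return self.value_at_positions(transform.apply(model.positions), model.weights)

    def value_batch(self, positions: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Evaluate many placements at once: positions ``(n, m, 3)`` -> ``(n,)``."""
        n, m, _ = positions.shape
        frac = (positions.reshape(-1, 3) - self.origin) / self.voxel
        coords = frac[:, ::-1].T
        vals = map_coordinates(self.field, coords, order=1, mode="constant", cval=0.0)
        return vals.reshape(n, m) @ weights


# ---------------------------------------------------------------------------
# Random placements
# ---------------------------------------------------------------------------

def random_placements(envelope: Envelope, model: AtomicModel, n: int,
                      rng: np.random.Generator) -> list[RigidTransform]:
    """Uniform random rigid placements of a body inside an envelope's bbox.

    Rotations are uniform on SO(3) (quaternion sampling); translations place
    the model centroid uniformly inside the bounding box of the envelope's
    occupied voxels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not envelope.mask.any():
        raise ValueError("cannot place into an empty envelope")
    idx = np.argwhere(envelope.mask)  # (k, j, i)
    centers = envelope.origin + idx[:, ::-1] * envelope.voxel_size
    lo, hi = centers.min(axis=0), centers.max(axis=0)
    rotations = Rotation.random(n, random_state=rng)
    targets = rng.uniform(lo, hi, size=(n, 3))
    centroid = model.centroid
    out = []
    matrices = rotations.as_matrix().reshape(n, 3, 3)
    for rot, target in zip(matrices, targets):
        out.append(RigidTransform(rot, target - rot @ centroid))
    return out


# ---------------------------------------------------------------------------
# Local optimization
# ---------------------------------------------------------------------------

def local_optimize(objective_or_map, model: AtomicModel, t0: RigidTransform,
                   steps: int = 100,
                   sim_params: SimulationParams | None = None) -> Fit:
    """Iteratively improve a placement by ascent on the overlap score.

    Coordinate ascent on the 6 rigid parameters (rotation about the current
    model centroid, translation) via a finite-difference gradient with
    backtracking step size; only improving steps are accepted, so the score
    sequence is non-decreasing. ``steps`` caps the number of iterations;
    ``steps=0`` returns the scored initial placement unchanged. Accepts a
    prebuilt :class:`OverlapObjective` or a raw map.
    """
    if isinstance(objective_or_map, OverlapObjective):
        objective = objective_or_map
    else:
        params = sim_params or SimulationParams(
            voxel_size=float(objective_or_map.voxel_size[0]))
        objective = OverlapObjective(objective_or_map.normalized(), params)
    if steps < 0:
        raise ValueError("steps must be >= 0")

    base_positions = model.positions
    weights = model.weights
    # scale rotations by the gyration radius so all 6 parameters are in Å
    centroid = base_positions.mean(axis=0)
    gyration = float(np.sqrt(np.mean(np.sum((base_positions - centroid) ** 2, axis=1))))
    gyration = max(gyration, 1.0)

    current = t0
    pos = current.apply(base_positions)
    score = objective.value_at_positions(pos, weights)
    if score <= 0.0 and steps > 0:
        # entirely outside nonzero density: the field is flat, nothing to climb
        logger.debug("placement outside density; returning zero-score fit")
        return Fit(transform=current, objective=0.0)

    eps = 0.25  # Å-equivalent finite-difference step
    step_size = 2.0  # Å-equivalent initial line-search step

    def transform_from(params6: np.ndarray, base: RigidTransform,
                       pivot: np.ndarray) -> RigidTransform:
        rot = Rotation.from_rotvec(params6[:3] / gyration).as_matrix()
        new_rot = rot @ base.rotation
        new_trans = rot @ (base.translation - pivot) + pivot + params6[3:]
        return RigidTransform(new_rot, new_trans)

    for _ in range(steps):
        pivot = current.apply(centroid)
        grad = np.zeros(6)
        for k in range(6):
            dq = np.zeros(6)
            dq[k] = eps
            plus = objective.value(model, transform_from(dq, current, pivot))
            minus = objective.value(model, transform_from(-dq, current, pivot))
            grad[k] = (plus - minus) / (2 * eps)
        norm = np.linalg.norm(grad)
        if norm < 1e-12:
            break
        direction = grad / norm
        improved = False
        alpha = step_size
        for _try in range(8):
            cand = transform_from(alpha * direction, current, pivot)
            cand_score = objective.value(model, cand)
            if cand_score > score:
                current, score = cand, cand_score
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    return Fit(transform=current, objective=score)


def _optimize_batch(objective: OverlapObjective, model: AtomicModel,
                    transforms: list[RigidTransform], steps: int) -> list[Fit]:
    """Vectorized ascent of many placements at once.

    Applies the same rule as :func:`local_optimize` — finite-difference
    gradient on the 6 rigid parameters, backtracking line search, only
    improving steps accepted — to every placement simultaneously, so one
    grid interpolation call serves the whole batch. Placements whose line
    search fails converge and drop out of the active set.
    """
    n = len(transforms)
    base = model.positions
    weights = model.weights
    centroid = base.mean(axis=0)
    gyration = max(float(np.sqrt(np.mean(np.sum((base - centroid) ** 2, axis=1)))), 1.0)
    eps = 0.25
    step_size = 2.0

    rot = np.stack([t.rotation for t in transforms])       # (n, 3, 3)
    trans = np.stack([t.translation for t in transforms])  # (n, 3)

    def evaluate(rot_b: np.ndarray, trans_b: np.ndarray) -> np.ndarray:
        pos = np.einsum("nij,mj->nmi", rot_b, base) + trans_b[:, None, :]
        return objective.value_batch(pos, weights)

    scores = evaluate(rot, trans)
    active = scores > 0.0  # flat field outside the density: nothing to climb

    # constant small-rotation matrices for the finite differences
    from scipy.spatial.transform import Rotation as _R
    rot_plus = [_R.from_rotvec(eps / gyration * np.eye(3)[k]).as_matrix() for k in range(3)]
    rot_minus = [m.T for m in rot_plus]

    for _ in range(steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        r_act, t_act, s_act = rot[idx], trans[idx], scores[idx]
        pivots = np.einsum("nij,j->ni", r_act, centroid) + t_act
        grads = np.empty((len(idx), 6))
        for k in range(3):
            s_plus = evaluate(rot_plus[k] @ r_act,
                              (t_act - pivots) @ rot_plus[k].T + pivots)
            s_minus = evaluate(rot_minus[k] @ r_act,
                               (t_act - pivots) @ rot_minus[k].T + pivots)
            grads[:, k] = (s_plus - s_minus) / (2 * eps)
        for k in range(3):
            dt = eps * np.eye(3)[k]
            grads[:, 3 + k] = (evaluate(r_act, t_act + dt)
                               - evaluate(r_act, t_act - dt)) / (2 * eps)
        norms = np.linalg.norm(grads, axis=1)
        flat = norms < 1e-12
        active[idx[flat]] = False
        live = ~flat
        if not live.any():
            continue
        sub = idx[live]
        dirs = grads[live] / norms[live, None]
        alpha = np.full(len(sub), step_size)
        remaining = np.ones(len(sub), dtype=bool)
        for _try in range(8):
            rem = np.flatnonzero(remaining)
            if len(rem) == 0:
                break
            rvec = (alpha[rem, None] * dirs[rem, :3]) / gyration
            rmat = _R.from_rotvec(rvec).as_matrix()          # (r, 3, 3)
            r_base, t_base = rot[sub[rem]], trans[sub[rem]]
            piv = np.einsum("nij,j->ni", r_base, centroid) + t_base
            r_cand = np.einsum("nij,njk->nik", rmat, r_base)
            t_cand = (np.einsum("nij,nj->ni", rmat, t_base - piv) + piv
                      + alpha[rem, None] * dirs[rem, 3:])
            s_cand = evaluate(r_cand, t_cand)
            better = s_cand > scores[sub[rem]]
            commit = rem[better]
            rot[sub[commit]] = r_cand[better]
            trans[sub[commit]] = t_cand[better]
            scores[sub[commit]] = s_cand[better]
            remaining[commit] = False
            alpha[rem[~better]] *= 0.5
        active[sub[np.flatnonzero(remaining)]] = False  # line search exhausted

    from scipy.spatial.transform import Rotation as _R2
    fits = []
    for i in range(n):
        clean = _R2.from_matrix(rot[i]).as_matrix()  # re-orthonormalize drift
        fits.append(Fit(transform=RigidTransform(clean, trans[i]),
                        objective=float(scores[i])))
    return fits


# ---------------------------------------------------------------------------
# Coverage filter
# ---------------------------------------------------------------------------

def model_envelope_points(model: AtomicModel, sim_params: SimulationParams,
                          threshold: float) -> np.ndarray:
    """Occupied-voxel centers of the body's own normalized envelope (model frame)."""
    sim = simulate_map(model, sim_params).normalized()
    env = extract_envelope(sim, threshold, clean=False)
    idx = np.argwhere(env.mask)
    if len(idx) == 0:
        raise ValueError("model envelope empty at this threshold")
    return env.origin + idx[:, ::-1] * env.voxel_size


def coverage_fraction(envelope: Envelope, model: AtomicModel, transform: RigidTransform,
                      sim_params: SimulationParams | None = None) -> float:
    """Fraction of the placed body's envelope covered by the experimental envelope.

    The *placed* body's map is simulated on its own grid and binarized at
    the experimental envelope's (normalized) threshold; the fraction of its
    occupied-voxel centers that fall inside the experimental envelope is
    returned. On a noiseless self-simulated map the truth placement covers
    itself exactly.
    """
    sim_params = sim_params or SimulationParams(voxel_size=float(envelope.voxel_size[0]))
    placed = model.transformed(transform)
    points = model_envelope_points(placed, sim_params, envelope.threshold)
    return float(envelope.contains(points).mean())


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_fits(fits: list[Fit], rot_deg: float, trans: float,
                 centroid: np.ndarray | None = None,
                 key: str = "objective") -> list[Fit]:
    """Greedy similarity clustering keeping the best-scoring member.

    Fits are visited in descending score order; a fit joins an existing
    representative when its rotation is within ``rot_deg`` (geodesic) AND its
    centroid displacement is within ``trans`` Å of that representative,
    otherwise it founds a new cluster. Representatives carry the number of
    merged fits as ``cluster_size``.
    """
    if centroid is None:
        centroid = np.zeros(3)
    order = sorted(range(len(fits)), key=lambda i: (-fits[i].similarity(key), i))
    reps: list[Fit] = []
    rep_centers: list[np.ndarray] = []
    for i in order:
        fit = fits[i]
        center = fit.transform.apply(centroid[None, :])[0]
        joined = False
        for rep, rep_center in zip(reps, rep_centers):
            if np.linalg.norm(center - rep_center) <= trans \
                    and fit.transform.rotation_angle_to(rep.transform) <= rot_deg:
                rep.cluster_size += 1
                joined = True
                break
        if not joined:
            reps.append(Fit(transform=fit.transform, objective=fit.objective,
                            coverage=fit.coverage, scores=fit.scores, cluster_size=1))
            rep_centers.append(center)
    return reps


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------

def global_fit(exp_map: DensityMap, model: AtomicModel, config: FitConfig | None = None,
               map_id: str = "map", body_id: str = "body") -> FitEnsemble:
    """Multi-start fitting pipeline: place, optimize, filter, cluster, score.

    Deterministic for a fixed ``config.rng_seed``. Returns representatives
    sorted by ``config.score_key`` (higher = better; Chamfer enters negated).
    An empty ensemble (with a warning) results when every placement fails the
    coverage filter.
    """
    config = config or FitConfig()
    sim_params = config.sim_params or SimulationParams(
        voxel_size=float(exp_map.voxel_size[0]))
    exp_norm = exp_map.normalized()
    env_exp = extract_envelope(exp_norm, config.envelope_threshold,
                               clean=config.clean_envelope)
    if not env_exp.mask.any():
        raise ValueError("experimental envelope empty at the configured threshold")
    objective = OverlapObjective(exp_norm, sim_params)
    rng = np.random.default_rng(config.rng_seed)
    placements = random_placements(env_exp, model, config.n_placements, rng)

    optimized = _optimize_batch(objective, model, placements, config.opt_steps)

    kept: list[Fit] = []
    for fit in optimized:
        fit.coverage = coverage_fraction(env_exp, model, fit.transform, sim_params)
        if fit.coverage >= config.coverage_min:
            kept.append(fit)
    if not kept:
        warnings.warn("all placements removed by the coverage filter; empty ensemble",
                      stacklevel=2)
        return FitEnsemble(map_id=map_id, body_id=body_id, fits=[], config=config,
                           score_key=config.score_key)

    reps = cluster_fits(kept, config.cluster_rot_deg, config.cluster_trans,
                        centroid=model.centroid)

    for rep in reps:
        placed = model.transformed(rep.transform)
        model_map = simulate_map(placed, sim_params, like=exp_map)
        rep.scores = score_density(exp_norm, env_exp, model_map.values,
                                   config.envelope_threshold)

    reps.sort(key=lambda f: -f.similarity(config.score_key))
    return FitEnsemble(map_id=map_id, body_id=body_id, fits=reps, config=config,
                       score_key=config.score_key)
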