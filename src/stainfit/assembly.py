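"""Mirror-image (handedness) determination and combinatorial two-body fitting.

A single-particle reconstruction and its mirror image explain the projection
data equally well, so the correct enantiomer of a stain map must be chosen
by fitting known chiral structures into both mirrors and comparing. The
decision rule here is deliberately conservative: a mirror is chosen only
when its best fit is superior under *all four* metrics for every body, and
within that mirror the same top fit wins regardless of metric; anything
weaker is reported as ambiguous.

For two-body assembly, representative fits of each body (from a loose
clustering run) are combined as a Cartesian product, sterically impossible
pairs are removed by a Cα-clash filter, each surviving pair is scored as a
*union model* (additive density of both placed bodies), and pairs are ranked
by mean rank across the four metrics, with crosslink satisfaction as a soft
reordering criterion among the near-top candidates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .density import (DensityMap, SimulationParams, extract_envelope,
                      mirror_map, simulate_map)
from .fitting import Fit, FitConfig, FitEnsemble, global_fit
from .scoring import FitScores, score_density
from .structure import AtomicModel, RigidTransform, merge_models
from .xlinks import Crosslink, XlinkConfig, map_crosslinks

logger = logging.getLogger("stainfit")

METRICS = ("overlap", "ccc", "chamfer_similarity", "envelope")


@dataclass
class HandednessDecision:
    """Outcome of comparative fitting into a map and its mirror.

    ``chosen`` is ``"original"``, ``"mirror"`` or ``"ambiguous"``. A mirror
    is chosen only if, for every body, its best fit beats the other mirror's
    under every one of the four metrics AND the same top fit wins under every
    metric within the chosen mirror (``agreement``).
    """

    chosen: str
    best_scores: dict[str, dict[str, float]]
    agreement: dict[str, bool]
    ensembles: dict[str, list[FitEnsemble]] = field(default_factory=dict)
    diagnostic: str = ""


@dataclass
class CombinedFit:
    """A candidate assembly pairing one fit of body A with one of body B.

    ``clash_fraction`` is the steric-overlap measure the retention filter
    used (by default the *relieved* clash — see :func:`combine_fits`);
    ``clash_fraction_raw`` is the plain fraction of body-A Cα atoms within
    the clash radius of any body-B Cα at the reported poses.
    """

    fit_a: Fit
    fit_b: Fit
    scores: FitScores
    clash_fraction: float
    clash_fraction_raw: float = 0.0
    index: tuple[int, int] = (0, 0)
    xlink_satisfaction: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.clash_fraction <= 1.0:
            raise ValueError("clash_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Handedness
# ---------------------------------------------------------------------------

def _best_per_metric(ensembles: list[FitEnsemble]) -> dict[str, float]:
    """Best similarity value per metric over every body's representatives."""
    out = {}
    for key in METRICS:
        out[key] = max(e.best_by(key).similarity(key) for e in ensembles)
    return out


def _agreement(ensembles: list[FitEnsemble], bodies: list[AtomicModel],
               pose_tol: float) -> bool:
    """Does the same top fit win under every metric, for every body?

    Two top fits count as the same fit when the poses they give the body
    differ by less than ``pose_tol`` Å Cα RMSD — placements closer than the
    simulation kernel width are indistinguishable at the map's resolution.
    """
    from .structure import ca_rmsd
    for ens, body in zip(ensembles, bodies):
        tops = [max(ens.fits, key=lambda f: f.similarity(key)) for key in METRICS]
        for other in tops[1:]:
            if ca_rmsd(body, tops[0].transform, other.transform) > pose_tol:
                return False
    return True


def assess_handedness(exp_map: DensityMap, bodies: list[AtomicModel],
                      config: FitConfig | None = None,
                      mirror_axis: str = "x",
                      jitter_factor: float = 3.0) -> HandednessDecision:
    """Determine the correct mirror image of a map by comparative fitting.

    Runs :func:`~stainfit.fitting.global_fit` for every body against the map
    and its mirror, then applies the unanimity rule documented on
    :class:`HandednessDecision`, with one further necessary condition: the
    winning mirror's overlap margin must exceed ``jitter_factor`` times the
    pipeline's own sampling uncertainty. That uncertainty is measured by a
    replicate fitting run with a different placement seed — for an achiral
    body the mirror map contains the *same* (reflected) noise realization,
    so the null margin between mirrors is set by multi-start sampling
    scatter, not by map noise, and a margin within that scatter is a tie.
    """
    if not bodies:
        raise ValueError("at least one body required")
    config = config or FitConfig()
    sim_params = config.sim_params or SimulationParams(
        voxel_size=float(exp_map.voxel_size[0]))
    pose_tol = sim_params.sigma  # the map cannot resolve poses closer than this
    mirrored = mirror_map(exp_map, mirror_axis)
    replicate = replace(config, rng_seed=config.rng_seed + 1)
    ensembles: dict[str, list[FitEnsemble]] = {"original": [], "mirror": []}
    replicas: dict[str, list[FitEnsemble]] = {"original": [], "mirror": []}
    for label, target in (("original", exp_map), ("mirror", mirrored)):
        for i, body in enumerate(bodies):
            ensembles[label].append(
                global_fit(target, body, config, map_id=label, body_id=f"body{i}"))
            replicas[label].append(
                global_fit(target, body, replicate, map_id=label, body_id=f"body{i}"))

    return decide_handedness(ensembles, replicas, bodies, pose_tol, jitter_factor)


def decide_handedness(ensembles: dict[str, list[FitEnsemble]],
                      replicas: dict[str, list[FitEnsemble]],
                      bodies: list[AtomicModel],
                      pose_tol: float,
                      jitter_factor: float = 3.0) -> HandednessDecision:
    """Apply the handedness decision rule to per-mirror fit ensembles.

    Pure decision logic, separated from the fitting runs so constructed
    ensembles can exercise the rule directly.
    """
    for label in ("original", "mirror"):
        if any(len(e) == 0 for e in ensembles[label] + replicas[label]):
            return HandednessDecision(
                chosen="ambiguous", best_scores={}, agreement={},
                ensembles=ensembles,
                diagnostic=f"empty ensemble for the {label} map",
            )

    best = {label: _best_per_metric(ensembles[label]) for label in ("original", "mirror")}
    agreement = {label: _agreement(ensembles[label], bodies, pose_tol)
                 for label in ("original", "mirror")}

    # per-body sampling jitter of the best overlap, worst case over mirrors
    jitter = [
        max(abs(_body_best(ensembles[label][i], "overlap")
                - _body_best(replicas[label][i], "overlap"))
            for label in ("original", "mirror"))
        for i in range(len(bodies))
    ]

    chosen = "ambiguous"
    diagnostic = ""
    for label, other in (("original", "mirror"), ("mirror", "original")):
        wins_all = all(
            _body_best(ensembles[label][i], key) > _body_best(ensembles[other][i], key)
            for i in range(len(bodies)) for key in METRICS
        )
        if not (wins_all and agreement[label]):
            continue
        beyond_jitter = True
        for i in range(len(bodies)):
            margin = (_body_best(ensembles[label][i], "overlap")
                      - _body_best(ensembles[other][i], "overlap"))
            scale = abs(_body_best(ensembles[label][i], "overlap"))
            if margin <= max(jitter_factor * jitter[i], 1e-7 * scale):
                beyond_jitter = False
                diagnostic = (f"{label} superior on all metrics but the overlap margin "
                              f"is within sampling jitter for body {i}")
        if beyond_jitter:
            chosen = label
            break
    return HandednessDecision(chosen=chosen, best_scores=best, agreement=agreement,
                              ensembles=ensembles, diagnostic=diagnostic)


def _body_best(ensemble: FitEnsemble, key: str) -> float:
    return ensemble.best_by(key).similarity(key)


# ---------------------------------------------------------------------------
# Combined two-body fits
# ---------------------------------------------------------------------------

def clash_fraction(model_a: AtomicModel, t_a: RigidTransform,
                   model_b: AtomicModel, t_b: RigidTransform,
                   clash_radius: float = 4.0) -> float:
    """Fraction of body-A Cα atoms within ``clash_radius`` of any body-B Cα."""
    ca_a = t_a.apply(model_a.ca_positions() if len(model_a.ca_positions()) else model_a.positions)
    ca_b = t_b.apply(model_b.ca_positions() if len(model_b.ca_positions()) else model_b.positions)
    counts = cKDTree(ca_b).query_ball_point(ca_a, clash_radius, return_length=True)
    return float(np.mean(counts > 0))


def relieved_clash_fraction(model_a: AtomicModel, t_a: RigidTransform,
                            model_b: AtomicModel, t_b: RigidTransform,
                            clash_radius: float = 4.0, relief: float = 0.0,
                            step: float = 1.0) -> float:
    """Clash fraction minimized over a small rigid push-out of body B.

    Independent overlap fitting biases each body into the shared density by
    up to roughly the simulation kernel width, so contact interfaces read as
    apparent clashes at atomic radii. Translating B away from A's centroid by
    up to ``relief`` Å (below what the map can resolve) relieves contact
    bias but cannot relieve gross interpenetration, which is what the filter
    must remove. ``relief=0`` reduces to :func:`clash_fraction`.
    """
    base = clash_fraction(model_a, t_a, model_b, t_b, clash_radius)
    if relief <= 0 or base == 0.0:
        return base
    ca = t_a.apply(model_a.centroid[None, :])[0]
    cb = t_b.apply(model_b.centroid[None, :])[0]
    axis = cb - ca
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    best = base
    for delta in np.arange(step, relief + step / 2, step):
        shifted = RigidTransform(t_b.rotation, t_b.translation + delta * axis)
        best = min(best, clash_fraction(model_a, t_a, model_b, shifted, clash_radius))
        if best == 0.0:
            break
    return best


def combine_fits(exp_map: DensityMap,
                 model_a: AtomicModel, ens_a: FitEnsemble,
                 model_b: AtomicModel, ens_b: FitEnsemble,
                 clash_radius: float = 4.0, clash_max: float = 0.05,
                 sim_params: SimulationParams | None = None,
                 envelope_threshold: float = 0.06,
                 clash_relief: float | None = None) -> list[CombinedFit]:
    """Cartesian product of two fit ensembles, clash-filtered and union-scored.

    Each surviving pair is scored with all four metrics on the *union model*:
    one density simulated from both placed bodies jointly (additive), not an
    average of per-body scores. Pairs whose *relieved* clash fraction (see
    :func:`relieved_clash_fraction`) exceeds ``clash_max`` are removed;
    ``clash_relief`` defaults to the simulation kernel width sigma and can
    be set to 0 for the plain atomic-radius criterion.
    """
    if len(ens_a) == 0 or len(ens_b) == 0:
        warnings.warn("combine_fits: empty input ensemble; no combinations",
                      stacklevel=2)
        return []
    sim_params = sim_params or SimulationParams(voxel_size=float(exp_map.voxel_size[0]))
    if clash_relief is None:
        clash_relief = sim_params.sigma
    exp_norm = exp_map.normalized()
    env_exp = extract_envelope(exp_norm, envelope_threshold)

    # per-representative simulated grids, reused across the product
    grids_a = [simulate_map(model_a.transformed(f.transform), sim_params,
                            like=exp_map).values for f in ens_a.fits]
    grids_b = [simulate_map(model_b.transformed(f.transform), sim_params,
                            like=exp_map).values for f in ens_b.fits]

    out: list[CombinedFit] = []
    for i, fit_a in enumerate(ens_a.fits):
        for j, fit_b in enumerate(ens_b.fits):
            raw = clash_fraction(model_a, fit_a.transform, model_b, fit_b.transform,
                                 clash_radius)
            cf = raw
            if raw > clash_max and clash_relief > 0:
                cf = relieved_clash_fraction(model_a, fit_a.transform,
                                             model_b, fit_b.transform,
                                             clash_radius, clash_relief)
            if cf > clash_max:
                continue
            union = grids_a[i] + grids_b[j]
            scores = score_density(exp_norm, env_exp, union, envelope_threshold)
            out.append(CombinedFit(fit_a=fit_a, fit_b=fit_b, scores=scores,
                                   clash_fraction=cf, clash_fraction_raw=raw,
                                   index=(i, j)))
    return out


def rank_combined(combined: list[CombinedFit],
                  xlinks: list[Crosslink] | None = None,
                  model_a: AtomicModel | None = None,
                  model_b: AtomicModel | None = None,
                  xlink_config: XlinkConfig | None = None,
                  rank_window: float = 0.10) -> list[CombinedFit]:
    """Order combined fits by mean rank across the four metrics.

    Chamfer enters negated so all four are higher-is-better. When a crosslink
    set is supplied (with the body models and chain mapping needed to build
    each candidate assembly), candidates within the top ``rank_window``
    fraction of the mean-rank ordering are reordered by descending crosslink
    satisfaction; the ordering is otherwise stable in the input index, so
    permuting the input does not change the result.
    """
    if not combined:
        raise ValueError("no combined fits to rank")
    sims = {key: np.array([c.scores.similarity(key) for c in combined])
            for key in METRICS}
    # rankdata is ascending; negate so rank 1 = best
    ranks = np.mean([rankdata(-sims[key], method="average") for key in METRICS], axis=0)
    order = sorted(range(len(combined)), key=lambda i: (ranks[i], combined[i].index))
    ordered = [combined[i] for i in order]

    if xlinks is not None:
        if model_a is None or model_b is None or xlink_config is None:
            raise ValueError("crosslink reordering needs model_a, model_b and xlink_config")
        n_window = max(1, int(np.ceil(rank_window * len(ordered))))
        head = ordered[:n_window]
        for cand in head:
            assembly = merge_models([
                model_a.transformed(cand.fit_a.transform),
                model_b.transformed(cand.fit_b.transform),
            ])
            result = map_crosslinks(assembly, xlinks, xlink_config)
            cand.xlink_satisfaction = (result.satisfaction if result.n_mapped else 0.0)
        head.sort(key=lambda c: (-(c.xlink_satisfaction or 0.0), c.index))
        ordered = head + ordered[n_window:]
    return ordered
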