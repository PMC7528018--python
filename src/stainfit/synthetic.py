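"""Ground-truth benchmark generator: toy chiral bodies, two-body complexes,
stain-like maps (true + mirrored, optionally noisy), and crosslink tables
with planted violations.

The default two-body case stands in for the study conditions this package
targets: two bodies of unequal size fitted independently into one shared
~30 Å map of the whole complex, the map's mirror image, and a DSS-style
crosslink table in which most links are distance-satisfied, a few confident
links are violated, and low-confidence decoys sit below the ld threshold so
the confidence filter is meaningful.

Chirality is controlled through ``helical_fraction``: residues laid on a
right-handed helix cannot be superposed onto their mirror image by any
proper rotation, which is what makes handedness determination possible.
Toy chains are Cα-only with uniform weight 1 — at 30 Å resolution atomic
detail is irrelevant to fit ranking.

Every case is reproducible bit-exactly from (params, seed): the noise model
is i.i.d. Gaussian per voxel (stain artifacts such as flattening or uneven
stain are deliberately not modelled).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .density import DensityMap, SimulationParams, mirror_map, simulate_map, write_map
from .structure import AtomicModel, RigidTransform, merge_models, write_structure
from .xlinks import Crosslink, write_xlink_table

logger = logging.getLogger("stainfit")

CA_CA = 3.8          # consecutive Cα–Cα distance, Å
HELIX_RISE = 1.5     # Å per residue
HELIX_TWIST = 100.0  # degrees per residue, right-handed
MIN_CLEARANCE = 3.5  # self-avoidance radius of the random-walk segment, Å


@dataclass
class SyntheticParams:
    """Study-condition parameters of the generated benchmark.

    Defaults describe the package's canonical desk-scale case: two unequal
    bodies (72 and 48 residues), half-helical (chiral but globular), a 30 Å
    map on 4 Å voxels, noiseless, with 21 satisfied + 4 violated confident
    crosslinks (25 mapped in total), low-ld decoys, and a few monolinks.
    """

    n_residues: tuple[int, int] = (72, 48)
    helical_fraction: float = 0.5
    resolution: float = 30.0
    voxel_size: float = 4.0
    noise_sd: float = 0.0
    n_satisfied: int = 21
    n_violated: int = 4
    n_decoys: int = 6
    n_monolinks: int = 3
    ld_true: tuple[float, float] = (45.0, 60.0)
    ld_decoy: tuple[float, float] = (20.0, 39.5)
    ld_threshold: float = 40.0
    max_distance: float = 35.0
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.helical_fraction <= 1.0:
            raise ValueError("helical_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def sim_params(self) -> SimulationParams:
        return SimulationParams(resolution=self.resolution, voxel_size=self.voxel_size)


@dataclass
class SyntheticCase:
    """A generated two-body ground-truth complex and all its artifacts.

    ``bodies`` are in their own centered frames; ``truth`` transforms place
    them into map space. ``map`` carries the (optionally noisy) density of
    the assembled complex; ``mirrored_map`` is its x-mirror.
    """

    bodies: list[AtomicModel]
    truth: list[RigidTransform]
    map: DensityMap
    mirrored_map: DensityMap
    xlinks: list[Crosslink]
    chain_map: dict[str, list[str]]
    params: SyntheticParams

    def assembled(self) -> AtomicModel:
        return merge_models([b.transformed(t) for b, t in zip(self.bodies, self.truth)])

    def save(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for label, body in zip("ab", self.bodies):
            paths[f"body_{label}"] = outdir / f"body{label.upper()}.pdb"
            write_structure(body, paths[f"body_{label}"])
        paths["map"] = outdir / "map.mrc"
        write_map(self.map, paths["map"])
        paths["map_mirror"] = outdir / "map_mirror.mrc"
        write_map(self.mirrored_map, paths["map_mirror"])
        paths["links"] = outdir / "links.tsv"
        write_xlink_table(self.xlinks, paths["links"])
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps({
            f"body{label.upper()}": {
                "quaternion_xyzw": [round(v, 12) for v in t.as_quaternion()],
                "translation": [round(v, 10) for v in t.translation],
            } for label, t in zip("ab", self.truth)
        }, indent=2, sort_keys=True))
        paths["params"] = outdir / "params.yaml"
        payload = asdict(self.params)
        payload["chain_map"] = self.chain_map
        paths["params"].write_text(yaml.safe_dump(payload, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# Toy chains
# ---------------------------------------------------------------------------

def make_toy_chain(n: int, helical_fraction: float, seed: int,
                   chain_id: str = "A") -> AtomicModel:
    """Build a Cα-only chain: a right-handed helical segment plus a
    self-avoiding random walk.

    Consecutive Cα–Cα distances are exactly 3.8 Å. ``helical_fraction`` of
    the residues lie on a right-handed helix (rise 1.5 Å, 100°/residue),
    guaranteeing chirality; the remainder is a self-avoiding random walk
    with 3.5 Å clearance. Reproducible by seed.
    """
    if n < 10:
        raise ValueError("toy chains need n >= 10")
    if not 0.0 <= helical_fraction <= 1.0:
        raise ValueError("helical_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_helix = int(round(helical_fraction * n))
    positions = np.zeros((n, 3))
    radius = np.sqrt(CA_CA ** 2 - HELIX_RISE ** 2) / (2.0 * np.sin(np.radians(HELIX_TWIST / 2)))
    i = np.arange(n_helix)
    theta = np.radians(HELIX_TWIST) * i
    positions[:n_helix, 0] = radius * np.cos(theta)
    positions[:n_helix, 1] = radius * np.sin(theta)
    positions[:n_helix, 2] = HELIX_RISE * i
    for k in range(max(n_helix, 1), n):
        prev = positions[k - 1]
        placed = False
        for _attempt in range(500):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = prev + CA_CA * direction
            d = np.linalg.norm(positions[:k] - cand, axis=1)
            # the step back to the previous residue is CA_CA by construction
            if np.all(d[:-1] > MIN_CLEARANCE) if k > 1 else True:
                positions[k] = cand
                placed = True
                break
        if not placed:
            raise RuntimeError("self-avoiding walk failed; try another seed")
    resnums = np.arange(1, n + 1)
    return AtomicModel(
        chains=np.array([chain_id] * n, dtype=object),
        resnums=resnums,
        resnames=np.array(["ALA"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        positions=positions,
        weights=np.ones(n),
    )


def _centered(model: AtomicModel) -> AtomicModel:
    shift = RigidTransform(np.eye(3), -model.centroid)
    return model.transformed(shift)


# ---------------------------------------------------------------------------
# Two-body cases
# ---------------------------------------------------------------------------

def make_two_body_case(params: SyntheticParams | None = None) -> SyntheticCase:
    """Generate the full two-body benchmark case.

    Two chains are built, docked with a defined interface (minimum
    inter-body Cα distance between 5 and 8 Å), the joint map is simulated at
    the configured resolution (plus seeded Gaussian noise), the x-mirrored
    map is produced, and a crosslink table with planted satisfied/violated
    links, decoys and monolinks is generated. Planted satisfied links have
    truth Cα–Cα at most ``max_distance - 5`` Å; planted violated links
    exceed ``max_distance + 5`` Å.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(params.seed)
    body_a = _centered(make_toy_chain(params.n_residues[0], params.helical_fraction,
                                      seed=params.seed, chain_id="A"))
    body_b = _centered(make_toy_chain(params.n_residues[1], params.helical_fraction,
                                      seed=params.seed + 1, chain_id="B"))

    rot_a = Rotation.random(random_state=rng).as_matrix()
    rot_b = Rotation.random(random_state=rng).as_matrix()
    placed_a = rot_a @ body_a.positions.T
    placed_b = rot_b @ body_b.positions.T
    dx = _dock_offset(placed_a.T, placed_b.T)
    truth_a = RigidTransform(rot_a, np.zeros(3))
    truth_b = RigidTransform(rot_b, np.array([dx, 0.0, 0.0]))
    truth = [truth_a, truth_b]

    assembled = merge_models([body_a.transformed(truth_a), body_b.transformed(truth_b)])
    density = simulate_map(assembled, params.sim_params)
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd * density.values.max(),
                           size=density.values.shape)
        density = DensityMap(values=density.values + noise,
                             voxel_size=density.voxel_size,
                             origin=density.origin, label=density.label + " +noise")
    mirrored = mirror_map(density, "x")

    xlinks = _plant_crosslinks(assembled, params, rng)
    chain_map = {"bodyA": ["A"], "bodyB": ["B"]}
    return SyntheticCase(bodies=[body_a, body_b], truth=truth, map=density,
                         mirrored_map=mirrored, xlinks=xlinks,
                         chain_map=chain_map, params=params)


def _dock_offset(pos_a: np.ndarray, pos_b: np.ndarray,
                 gap_lo: float = 5.0, gap_hi: float = 8.0) -> float:
    """Offset along +x placing body B so the minimum inter-Cα gap is 5–8 Å."""
    tree = cKDTree(pos_a)
    dx = (pos_a[:, 0].max() - pos_a[:, 0].min()
          + pos_b[:, 0].max() - pos_b[:, 0].min()) / 2 + gap_hi + 5.0
    while dx > 0:
        min_dist = tree.query(pos_b + np.array([dx, 0.0, 0.0]))[0].min()
        if min_dist <= gap_hi:
            if min_dist < gap_lo:
                dx += 0.25
            return float(dx)
        dx -= 0.25
    raise RuntimeError("docking search failed")


def _plant_crosslinks(assembled: AtomicModel, params: SyntheticParams,
                      rng: np.random.Generator) -> list[Crosslink]:
    """Plant satisfied/violated links with a 5 Å margin around the bound,
    plus sub-threshold decoys and monolinks."""
    protein_of = {"A": "bodyA", "B": "bodyB"}
    residues = [(protein_of[str(c)], int(r))
                for c, r in zip(assembled.chains, assembled.resnums)]
    pos = assembled.positions
    n = len(residues)
    dmat = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    satisfied_pool, violated_pool = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pi, ri = residues[i]
            pj, rj = residues[j]
            if pi == pj and abs(ri - rj) < 5:
                continue  # trivially close in sequence, uninformative
            if dmat[i, j] <= params.max_distance - 5.0:
                satisfied_pool.append((i, j))
            elif dmat[i, j] > params.max_distance + 5.0:
                violated_pool.append((i, j))
    if len(satisfied_pool) < params.n_satisfied or len(violated_pool) < params.n_violated:
        raise ValueError("chains too small for the requested link plant")
    sat_idx = rng.choice(len(satisfied_pool), size=params.n_satisfied, replace=False)
    vio_idx = rng.choice(len(violated_pool), size=params.n_violated, replace=False)

    def link(i: int, j: int, ld: float) -> Crosslink:
        pi, ri = residues[i]
        pj, rj = residues[j]
        return Crosslink(protein1=pi, residue1=ri, protein2=pj, residue2=rj,
                         ld_score=round(float(ld), 2),
                         link_type="intra" if pi == pj else "inter")

    links = [link(*satisfied_pool[k], rng.uniform(*params.ld_true)) for k in sat_idx]
    links += [link(*violated_pool[k], rng.uniform(*params.ld_true)) for k in vio_idx]
    for _ in range(params.n_decoys):
        i, j = rng.choice(n, size=2, replace=False)
        if residues[i] == residues[j]:
            continue
        links.append(link(min(i, j), max(i, j), rng.uniform(*params.ld_decoy)))
    for _ in range(params.n_monolinks):
        i = int(rng.integers(0, n))
        pi, ri = residues[i]
        links.append(Crosslink(protein1=pi, residue1=ri, protein2=None, residue2=None,
                               ld_score=round(float(rng.uniform(*params.ld_true)), 2),
                               link_type="monolink"))
    return links


# ---------------------------------------------------------------------------
# Score tables and handedness cases
# ---------------------------------------------------------------------------

def make_score_table(params: SyntheticParams | None = None, path=None) -> list[Crosslink]:
    """Generate a stand-alone crosslink score table (no geometry needed).

    ``n_satisfied + n_violated`` "true" distance links draw their ld scores
    above ``ld_threshold``, decoys below it, so filtering at the threshold
    retains exactly the true links. Written as xQuest-style TSV when ``path``
    is given; counts and score quantiles are reproducible by seed.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(params.seed)
    links = []
    n_true = params.n_satisfied + params.n_violated
    for k in range(n_true):
        links.append(Crosslink(
            protein1="bodyA", residue1=int(rng.integers(1, params.n_residues[0] + 1)),
            protein2="bodyB", residue2=int(rng.integers(1, params.n_residues[1] + 1)),
            ld_score=round(float(rng.uniform(*params.ld_true)), 2), link_type="inter"))
    for k in range(params.n_decoys):
        links.append(Crosslink(
            protein1="bodyA", residue1=int(rng.integers(1, params.n_residues[0] + 1)),
            protein2="bodyB", residue2=int(rng.integers(1, params.n_residues[1] + 1)),
            ld_score=round(float(rng.uniform(*params.ld_decoy)), 2), link_type="inter"))
    for k in range(params.n_monolinks):
        links.append(Crosslink(
            protein1="bodyA", residue1=int(rng.integers(1, params.n_residues[0] + 1)),
            protein2=None, residue2=None,
            ld_score=round(float(rng.uniform(*params.ld_true)), 2), link_type="monolink"))
    if path is not None:
        write_xlink_table(links, path)
    return links


def make_handedness_case(n: int = 60, helical_fraction: float = 0.8,
                         noise_sd: float = 0.05, seed: int = 0,
                         resolution: float = 30.0, voxel_size: float = 4.0,
                         planar: bool = False):
    """One body with its map and the map's mirror — the input of a
    handedness benchmark run.

    Returns ``(body, map, mirrored_map)``. By default the body is chiral
    (helical); with ``planar=True`` a strictly planar, achiral body is used
    instead — the control for which handedness must come out ambiguous.
    """
    rng = np.random.default_rng(seed)
    if planar:
        body = make_planar_body(n, seed=seed)
    else:
        body = _centered(make_toy_chain(n, helical_fraction, seed=seed))
    sim = SimulationParams(resolution=resolution, voxel_size=voxel_size)
    density = simulate_map(body, sim)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd * density.values.max(),
                           size=density.values.shape)
        density = DensityMap(values=density.values + noise,
                             voxel_size=density.voxel_size, origin=density.origin,
                             label="handedness case")
    return body, density, mirror_map(density, "x")


def make_planar_body(n: int = 60, seed: int = 0, chain_id: str = "A") -> AtomicModel:
    """A strictly planar (achiral) Cα chain: its mirror image is superposable
    by a proper rotation, so handedness assessment must come out ambiguous."""
    if n < 10:
        raise ValueError("toy chains need n >= 10")
    rng = np.random.default_rng(seed)
    positions = np.zeros((n, 3))
    k = 1
    stuck = 0
    while k < n:
        placed = False
        for _attempt in range(200):
            angle = rng.uniform(0, 2 * np.pi)
            cand = positions[k - 1] + CA_CA * np.array([np.cos(angle), np.sin(angle), 0.0])
            d = np.linalg.norm(positions[:k] - cand, axis=1)
            if np.all(d[:-1] > MIN_CLEARANCE) if k > 1 else True:
                positions[k] = cand
                placed = True
                break
        if placed:
            k += 1
            continue
        # 2D walks trap themselves in spirals: back up and retry
        stuck += 1
        if stuck > 200:
            raise RuntimeError("planar walk failed; try another seed")
        k = max(1, k - 5)
    return _centered(AtomicModel(
        chains=np.array([chain_id] * n, dtype=object),
        resnums=np.arange(1, n + 1),
        resnames=np.array(["ALA"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        positions=positions,
        weights=np.ones(n),
    ))
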