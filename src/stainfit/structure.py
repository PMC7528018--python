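"""Atomic models, PDB/mmCIF I/O, rigid transforms, SASA and buried area.

The model container is deliberately flat — parallel numpy arrays over atoms —
because every downstream consumer (map simulation, fitting, crosslink
mapping) works on coordinate arrays, not on a residue hierarchy. gemmi does
the format work; residues are keyed by ``(number, insertion code)`` and
crosslink tables, which carry plain numbers, match the blank insertion code
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

logger = logging.getLogger("stainfit")

#: van der Waals radii (Å), Bondi (1964) main-group values; fallback 1.70 Å.
#: COCOMAPS-style interface areas depend mildly on the radii set chosen;
#: this table is the package's fixed, documented choice.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "ZN": 1.39, "MG": 1.73, "FE": 1.70, "CA": 1.70, "MN": 1.70, "NA": 2.27,
    "K": 2.75,
}
DEFAULT_VDW = 1.70


@dataclass
class RigidTransform:
    """A proper rotation plus translation, ``p -> R @ p + t`` (Å).

    Mirroring is never represented here: the determinant must be +1 to
    1e-9. Handedness changes are handled at the map level only.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1); reflections forbidden")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "RigidTransform":
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def rotation_angle_to(self, other: "RigidTransform") -> float:
        """Geodesic angle (degrees) between the two rotations."""
        rel = Rotation.from_matrix(self.rotation.T @ other.rotation)
        return float(np.degrees(np.linalg.norm(rel.as_rotvec())))

    def as_quaternion(self) -> np.ndarray:
        """Quaternion (x, y, z, w) of the rotation part."""
        return Rotation.from_matrix(self.rotation).as_quat()

    @classmethod
    def from_quaternion(cls, quat, translation) -> "RigidTransform":
        return cls(Rotation.from_quat(np.asarray(quat, float)).as_matrix(),
                   np.asarray(translation, float))


@dataclass
class Selection:
    """A chain plus inclusive residue-number intervals, e.g. ``C:566-592``."""

    chain: str
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("selection needs at least one interval")
        for lo, hi in self.intervals:
            if hi < lo:
                raise ValueError(f"empty interval {lo}-{hi}")

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse ``"C:566-592,600-610"`` (single residues allowed as ``"C:42"``)."""
        chain, _, rest = text.partition(":")
        if not rest:
            raise ValueError(f"selection {text!r} must look like 'chain:lo-hi[,lo-hi...]'")
        intervals = []
        for part in rest.split(","):
            lo, dash, hi = part.partition("-")
            intervals.append((int(lo), int(hi) if dash else int(lo)))
        return cls(chain=chain, intervals=intervals)

    def covers(self, resnum: int) -> bool:
        return any(lo <= resnum <= hi for lo, hi in self.intervals)


@dataclass
class AtomicModel:
    """Flat atom-table model: parallel arrays over atoms.

    ``chains``/``resnums``/``icodes``/``resnames``/``atom_names``/``elements``
    are 1D object/int arrays; ``positions`` is ``(n, 3)`` Å; ``weights`` are
    the per-atom map-simulation amplitudes (atomic mass for real structures,
    1.0 for Cα-only toys).
    """

    chains: np.ndarray
    resnums: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    positions: np.ndarray
    weights: np.ndarray
    icodes: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.icodes is None:
            self.icodes = np.array([""] * len(self.positions), dtype=object)
        n = len(self.positions)
        for name in ("chains", "resnums", "resnames", "atom_names", "elements",
                     "weights", "icodes"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"field {name} has length {len(arr)}, expected {n}")
            setattr(self, name, arr)
        if n and not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom positions")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def transformed(self, transform: RigidTransform) -> "AtomicModel":
        return AtomicModel(
            chains=self.chains.copy(), resnums=self.resnums.copy(),
            resnames=self.resnames.copy(), atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            positions=transform.apply(self.positions),
            weights=self.weights.copy(), icodes=self.icodes.copy(),
        )

    def subset(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            chains=self.chains[mask], resnums=self.resnums[mask],
            resnames=self.resnames[mask], atom_names=self.atom_names[mask],
            elements=self.elements[mask], positions=self.positions[mask],
            weights=self.weights[mask], icodes=self.icodes[mask],
        )

    def select(self, selection: Selection) -> "AtomicModel":
        in_chain = self.chains == selection.chain
        in_range = np.array([selection.covers(int(r)) for r in self.resnums])
        return self.subset(in_chain & in_range)

    def selection_mask(self, selection: Selection) -> np.ndarray:
        in_chain = self.chains == selection.chain
        in_range = np.array([selection.covers(int(r)) for r in self.resnums])
        return in_chain & in_range

    def ca_positions(self) -> np.ndarray:
        return self.positions[self.atom_names == "CA"]

    def ca_position(self, chain: str, resnum: int) -> np.ndarray | None:
        """Cα position of a residue (blank insertion code), or None if absent."""
        mask = (
            (self.chains == chain)
            & (self.resnums == resnum)
            & (self.atom_names == "CA")
            & (self.icodes == "")
        )
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            return None
        return self.positions[idx[0]]


def merge_models(models: list[AtomicModel]) -> AtomicModel:
    """Concatenate models into one assembly (chain ids kept as-is)."""
    if not models:
        raise ValueError("nothing to merge")
    return AtomicModel(
        chains=np.concatenate([m.chains for m in models]),
        resnums=np.concatenate([m.resnums for m in models]),
        resnames=np.concatenate([m.resnames for m in models]),
        atom_names=np.concatenate([m.atom_names for m in models]),
        elements=np.concatenate([m.elements for m in models]),
        positions=np.concatenate([m.positions for m in models]),
        weights=np.concatenate([m.weights for m in models]),
        icodes=np.concatenate([m.icodes for m in models]),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_structure(path, include_waters: bool = False) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    Alternate locations are resolved to the highest-occupancy conformer;
    waters are excluded by default; for multi-model (NMR-style) files the
    first model is used with a logged notice. Atom weights are atomic masses.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in structure file {path}")
    if len(st) > 1:
        logger.info("%s has %d models; using the first", path, len(st))
    st.setup_entities()
    model = st[0]
    rows: dict = {k: [] for k in
                  ("chain", "resnum", "icode", "resname", "atom", "element", "pos", "w")}
    for chain in model:
        for residue in chain:
            if not include_waters and residue.is_water():
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            icode = residue.seqid.icode.strip()
            for atom in best.values():
                rows["chain"].append(chain.name)
                rows["resnum"].append(residue.seqid.num)
                rows["icode"].append(icode)
                rows["resname"].append(residue.name)
                rows["atom"].append(atom.name)
                rows["element"].append(atom.element.name.upper())
                rows["pos"].append([atom.pos.x, atom.pos.y, atom.pos.z])
                rows["w"].append(atom.element.weight)
    if not rows["pos"]:
        raise ValueError(f"no atoms parsed from {path}")
    return AtomicModel(
        chains=np.array(rows["chain"], dtype=object),
        resnums=np.array(rows["resnum"], dtype=int),
        resnames=np.array(rows["resname"], dtype=object),
        atom_names=np.array(rows["atom"], dtype=object),
        elements=np.array(rows["element"], dtype=object),
        positions=np.array(rows["pos"], dtype=np.float64),
        weights=np.array(rows["w"], dtype=np.float64),
        icodes=np.array(rows["icode"], dtype=object),
    )


def _to_gemmi(model: AtomicModel, name: str = "stainfit") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    gm = gemmi.Model("1")
    for chain_id in dict.fromkeys(model.chains):  # preserve order
        chain = gemmi.Chain(str(chain_id))
        mask = model.chains == chain_id
        idx = np.flatnonzero(mask)
        current_res = None
        current_key = None
        for i in idx:
            key = (int(model.resnums[i]), str(model.icodes[i]))
            if key != current_key:
                res = gemmi.Residue()
                res.name = str(model.resnames[i])
                res.seqid = gemmi.SeqId(key[0], key[1] or " ")
                current_res = chain.add_residue(res)  # returns the stored copy
                current_key = key
            atom = gemmi.Atom()
            atom.name = str(model.atom_names[i])
            atom.element = gemmi.Element(str(model.elements[i]).capitalize())
            atom.pos = gemmi.Position(*model.positions[i])
            atom.occ = 1.0
            current_res.add_atom(atom)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: AtomicModel, path) -> None:
    """Write a model as PDB or mmCIF depending on the file extension."""
    st = _to_gemmi(model)
    path = str(path)
    if path.endswith((".cif", ".mmcif")):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


def apply_transform(model: AtomicModel, transform: RigidTransform) -> AtomicModel:
    """Functional form of :meth:`AtomicModel.transformed`."""
    return model.transformed(transform)


# ---------------------------------------------------------------------------
# Solvent accessibility / buried area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere quadrature points (golden-spiral lattice)."""
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radii(model: AtomicModel) -> np.ndarray:
    return np.array([VDW_RADII.get(str(e).upper(), DEFAULT_VDW) for e in model.elements])


def sasa(model: AtomicModel, probe_radius: float = 1.4, n_points: int = 256,
         ignore_hydrogens: bool = True) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley style.

    Each atom's expanded sphere (vdW + probe) is sampled at ``n_points``
    quasi-uniform points; a point is accessible if it lies outside every
    neighbor's expanded sphere. Hydrogens are ignored by default (deposited
    models have none).
    """
    if len(model) == 0:
        raise ValueError("empty model")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    keep = np.ones(len(model), dtype=bool)
    if ignore_hydrogens:
        keep = np.array([str(e).upper() != "H" for e in model.elements])
    positions = model.positions[keep]
    radii = atom_radii(model.subset(keep)) + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(positions)
    areas_kept = np.zeros(len(positions))
    max_r = radii.max()
    for i, (pos, r) in enumerate(zip(positions, radii)):
        pts = pos + r * sphere
        neighbors = [j for j in tree.query_ball_point(pos, r + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - positions[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas_kept[i] = 4.0 * np.pi * r * r * accessible.mean()
    areas = np.zeros(len(model))
    areas[keep] = areas_kept
    return areas


def buried_area(model: AtomicModel, sel_a: Selection, sel_b: Selection,
                probe_radius: float = 1.4, n_points: int = 256) -> float:
    """Interface area buried between two selections (Å²).

    ``SASA(A alone) + SASA(B alone) - SASA(A and B assembled)``, computed
    with all atoms outside the two selections removed. Symmetric in its
    arguments and non-negative up to quadrature noise.
    """
    mask_a = model.selection_mask(sel_a)
    mask_b = model.selection_mask(sel_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both selections must be non-empty")
    if (mask_a & mask_b).any():
        raise ValueError("selections overlap")
    part_a = model.subset(mask_a)
    part_b = model.subset(mask_b)
    both = model.subset(mask_a | mask_b)
    total_a = sasa(part_a, probe_radius, n_points).sum()
    total_b = sasa(part_b, probe_radius, n_points).sum()
    total_ab = sasa(both, probe_radius, n_points).sum()
    return float(total_a + total_b - total_ab)


def ca_rmsd(model: AtomicModel, t1: RigidTransform, t2: RigidTransform) -> float:
    """Cα RMSD (Å) between two placements of the same model."""
    ca = model.positions[model.atom_names == "CA"]
    if len(ca) == 0:
        ca = model.positions
    diff = t1.apply(ca) - t2.apply(ca)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
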