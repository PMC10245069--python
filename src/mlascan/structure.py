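"""Multi-chain structure handling, inter-chain contact mapping and rigid-body
geometry for predicted protein complexes.

Contacts follow the convention used throughout the package: two residues on
opposite sides of a chain grouping are in contact when any pair of heavy
atoms (one from each side) lies strictly closer than the cutoff, 4.0 A by
default. Hydrogens are dropped on load; predicted models carry none anyway.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

ResidueKey = tuple[str, int]  # (chain id, author residue number)


@dataclass
class StructureModel:
    """Flat atom table of a (multi-chain) model.

    ``numbering_offset`` maps author residue numbers to full-length sequence
    numbering (reported number = author number + offset); predicted models
    often omit signal peptides or disordered termini, e.g. a mature-carrier
    model whose first residue is author-numbered 1 but is residue 22 of the
    full-length protein gets offset 21.
    """

    chain_ids: np.ndarray          # (n_atoms,) unicode
    res_ids: np.ndarray            # (n_atoms,) int, author numbering
    res_names: np.ndarray          # (n_atoms,) unicode
    atom_names: np.ndarray         # (n_atoms,) unicode
    elements: np.ndarray           # (n_atoms,) unicode
    coords: np.ndarray             # (n_atoms, 3) float64, Angstrom
    source: str = ""
    numbering_offset: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return len(self.res_ids)

    def atom_mask(self, chains: set[str] | list[str]) -> np.ndarray:
        return np.isin(self.chain_ids, list(chains))

    def ca_coords(self, chains: set[str] | list[str]) -> tuple[list[ResidueKey], np.ndarray]:
        """(chain, residue) keys and coordinates of CA atoms in the given chains."""
        mask = self.atom_mask(chains) & (self.atom_names == "CA")
        keys = [(str(c), int(r)) for c, r in zip(self.chain_ids[mask], self.res_ids[mask])]
        return keys, self.coords[mask]

    def offset_residue(self, chain: str, res_id: int) -> int:
        return res_id + self.numbering_offset.get(chain, 0)


@dataclass
class ContactMap:
    """Inter-chain residue contacts below a heavy-atom distance cutoff."""

    cutoff: float
    group_a: frozenset[str]
    group_b: frozenset[str]
    #: ((chainA, resA), (chainB, resB)) -> minimum heavy-atom distance (A)
    pairs: dict[tuple[ResidueKey, ResidueKey], float]

    def __post_init__(self) -> None:
        for (_, _), d in self.pairs.items():
            if not d < self.cutoff:
                raise ValueError("stored contact at or beyond the cutoff")

    def swapped(self) -> "ContactMap":
        return ContactMap(
            cutoff=self.cutoff,
            group_a=self.group_b,
            group_b=self.group_a,
            pairs={(b, a): d for (a, b), d in self.pairs.items()},
        )


@dataclass
class RigidTransform:
    """Least-squares rigid-body superposition result."""

    rotation: np.ndarray      # (3, 3) proper rotation
    translation: np.ndarray   # (3,)
    rmsd: float               # A
    rotation_angle: float     # degrees, in [0, 180]

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} != +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# IO

def load_structure(path: str | Path, numbering_offset: dict[str, int] | None = None) -> StructureModel:
    """Load a PDB or mmCIF file into a flat heavy-atom model.

    Hydrogens and waters are dropped; alternate locations are resolved to the
    highest-occupancy conformer per atom name. Only the first model of
    multi-model files is read.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    chain_ids, res_ids, res_names, atom_names, elements, coords = [], [], [], [], [], []
    for chain in model:
        for residue in chain:
            if residue.name == "HOH":
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                chain_ids.append(chain.name)
                res_ids.append(residue.seqid.num)
                res_names.append(residue.name)
                atom_names.append(name)
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ValueError(f"no heavy atoms found in {path}")
    return StructureModel(
        chain_ids=np.array(chain_ids),
        res_ids=np.array(res_ids, dtype=np.int64),
        res_names=np.array(res_names),
        atom_names=np.array(atom_names),
        elements=np.array(elements),
        coords=np.array(coords, dtype=np.float64),
        source=str(path),
        numbering_offset=dict(numbering_offset or {}),
    )


def save_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB."""
    st = gemmi.Structure()
    st.name = "mlascan"
    md = gemmi.Model("1")
    for cid in model.chains:
        chain = gemmi.Chain(cid)
        idx = np.flatnonzero(model.chain_ids == cid)
        # group consecutive atoms by residue number; gemmi copies on add, so
        # each residue is fully assembled before being appended
        current_res = None
        res = None
        for i in idx:
            rid = int(model.res_ids[i])
            if rid != current_res:
                if res is not None:
                    chain.add_residue(res)
                res = gemmi.Residue()
                res.name = str(model.res_names[i])
                res.seqid = gemmi.SeqId(rid, " ")
                current_res = rid
            atom = gemmi.Atom()
            atom.name = str(model.atom_names[i])
            atom.element = gemmi.Element(str(model.elements[i]))
            x, y, z = model.coords[i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.occ = 1.0
            res.add_atom(atom)
        if res is not None:
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# contacts

def interchain_contacts(
    model: StructureModel,
    group_a: set[str] | list[str],
    group_b: set[str] | list[str],
    cutoff: float = 4.0,
) -> ContactMap:
    """Residue-level contact map between two disjoint chain groups.

    A residue pair is a contact when any heavy-atom pair across the groups is
    at distance strictly less than ``cutoff``; the minimum atom distance per
    pair is stored. Uses a KD-tree over one group's atoms.
    """
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise ValueError("chain groups must be non-empty")
    if ga & gb:
        raise ValueError(f"chain groups overlap: {sorted(ga & gb)}")
    mask_a = model.atom_mask(ga)
    mask_b = model.atom_mask(gb)
    xa, xb = model.coords[mask_a], model.coords[mask_b]
    if xa.size == 0 or xb.size == 0:
        raise ValueError("a chain group has no atoms")
    keys_a = list(zip(model.chain_ids[mask_a], model.res_ids[mask_a]))
    keys_b = list(zip(model.chain_ids[mask_b], model.res_ids[mask_b]))

    tree_b = cKDTree(xb)
    neighbors = cKDTree(xa).query_ball_tree(tree_b, r=cutoff)
    pairs: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for ia, nbrs in enumerate(neighbors):
        if not nbrs:
            continue
        ka = (str(keys_a[ia][0]), int(keys_a[ia][1]))
        d = np.linalg.norm(xb[nbrs] - xa[ia], axis=1)
        for ib, dist in zip(nbrs, d):
            if dist < cutoff:  # strict inequality at the boundary
                kb = (str(keys_b[ib][0]), int(keys_b[ib][1]))
                key = (ka, kb)
                if dist < pairs.get(key, math.inf):
                    pairs[key] = float(dist)
    return ContactMap(cutoff=cutoff, group_a=frozenset(ga), group_b=frozenset(gb), pairs=pairs)


def footprint(
    contacts: ContactMap,
    side: set[str] | list[str],
    model: StructureModel | None = None,
) -> set[int]:
    """Residues on one side of the interface (union over the side's chains).

    Returns residue numbers; if ``model`` is given its per-chain numbering
    offsets are applied so the footprint is in full-length coordinates.
    """
    side = frozenset(side)
    if side == contacts.group_a:
        keys = (a for a, _ in contacts.pairs)
    elif side == contacts.group_b:
        keys = (b for _, b in contacts.pairs)
    else:
        raise ValueError(f"side {sorted(side)} matches neither contact group")
    if model is None:
        return {res for _, res in keys}
    return {model.offset_residue(chain, res) for chain, res in keys}


def footprint_by_chain(contacts: ContactMap, side: set[str]) -> dict[str, set[int]]:
    """Per-chain breakdown of a footprint (author numbering, no offsets)."""
    side = frozenset(side)
    if side == contacts.group_a:
        keys = [a for a, _ in contacts.pairs]
    elif side == contacts.group_b:
        keys = [b for _, b in contacts.pairs]
    else:
        raise ValueError("side matches neither contact group")
    out: dict[str, set[int]] = {}
    for chain, res in keys:
        out.setdefault(chain, set()).add(res)
    return out


@dataclass
class OverlapReport:
    intersection: set[int]
    footprint_only: set[int]
    hits_only: set[int]

    @property
    def n_intersection(self) -> int:
        return len(self.intersection)


def overlap_with_dms(fp: set[int], hits: set[int]) -> OverlapReport:
    """Overlap of an interface footprint with a set of screen-derived residues.

    Both sets must already be in full-length numbering. Disjoint numeric
    ranges (suggesting an unapplied numbering offset) trigger a warning.
    """
    fp, hits = set(fp), set(hits)
    if fp and hits:
        if max(fp) < min(hits) or max(hits) < min(fp):
            warnings.warn(
                "footprint and hit ranges are disjoint; check numbering offsets",
                stacklevel=2,
            )
    return OverlapReport(
        intersection=fp & hits,
        footprint_only=fp - hits,
        hits_only=hits - fp,
    )


# ---------------------------------------------------------------------------
# rigid-body geometry

def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of ``mobile`` onto ``reference`` (Kabsch).

    Reflections are excluded: the rotation is always proper (det = +1). The
    rotation angle is ``arccos((trace(R) - 1) / 2)`` in degrees.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    p, q = mobile - mc, reference - rc
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    cos_theta = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_theta)))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd, rotation_angle=angle)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit symmetry axis of a ring of points: the least-variance principal
    direction of the point cloud (normal to the ring plane)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[-1]
    return axis / np.linalg.norm(axis)


def _common_ca(models: list[StructureModel], chains: list[str]) -> list[ResidueKey]:
    common: set[ResidueKey] | None = None
    for m in models:
        keys, _ = m.ca_coords(chains)
        common = set(keys) if common is None else common & set(keys)
    return sorted(common or set())


def _ca_matrix(model: StructureModel, chains: list[str], keys: list[ResidueKey]) -> np.ndarray:
    all_keys, coords = model.ca_coords(chains)
    index = {k: i for i, k in enumerate(all_keys)}
    return coords[[index[k] for k in keys]]


@dataclass
class ConformationReport:
    """Hinge-angle and inward/outward metrics for a set of ring+carrier models."""

    axis_distances: list[float]       # carrier centroid to ring axis, per model (A)
    labels: list[str]                 # "inward" (min), "outward" (max), "" otherwise
    pairwise_angles: np.ndarray       # (n, n) carrier rotation angles, degrees
    ring_rmsds: list[float]           # ring superposition rmsd onto model 0 (A)

    @property
    def max_angle(self) -> float:
        return float(self.pairwise_angles.max()) if self.pairwise_angles.size else 0.0

    @property
    def inward_index(self) -> int:
        return self.labels.index("inward")

    @property
    def outward_index(self) -> int:
        return self.labels.index("outward")


def conformation_metrics(
    models: list[StructureModel],
    ring_chains: list[str],
    carrier_chain: str,
    ring_rmsd_warn: float = 3.0,
) -> ConformationReport:
    """Carrier orientation metrics across models sharing a ring scaffold.

    Each model is superposed on the first via the ring CA atoms common to all
    models. The pairwise carrier angle between two models is the rotation
    angle of the rigid transform mapping one aligned carrier CA set onto the
    other. The inward/outward score is the distance from the carrier CA
    centroid to the ring symmetry axis (least-variance principal axis through
    the ring centroid); the minimum-score model is labelled ``inward`` and
    the maximum ``outward``.
    """
    if not models:
        raise ValueError("no models")
    for m in models:
        if carrier_chain not in m.chains:
            raise ValueError(f"carrier chain {carrier_chain!r} missing from a model")
    ring_keys = _common_ca(models, ring_chains)
    carrier_keys = _common_ca(models, [carrier_chain])
    if len(ring_keys) < 3 or len(carrier_keys) < 3:
        raise ValueError("too few shared CA atoms for superposition")

    ref_ring = _ca_matrix(models[0], ring_chains, ring_keys)
    aligned_carriers: list[np.ndarray] = []
    ring_rmsds: list[float] = []
    for m in models:
        ring = _ca_matrix(m, ring_chains, ring_keys)
        tr = superpose(ring, ref_ring)
        ring_rmsds.append(tr.rmsd)
        if tr.rmsd > ring_rmsd_warn:
            warnings.warn(
                f"ring superposition rmsd {tr.rmsd:.2f} A exceeds {ring_rmsd_warn} A",
                stacklevel=2,
            )
        aligned_carriers.append(tr.apply(_ca_matrix(m, [carrier_chain], carrier_keys)))

    n = len(models)
    angles = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tr = superpose(aligned_carriers[i], aligned_carriers[j])
            angles[i, j] = angles[j, i] = tr.rotation_angle

    axis = _principal_axis(ref_ring)
    center = ref_ring.mean(axis=0)
    scores: list[float] = []
    for car in aligned_carriers:
        v = car.mean(axis=0) - center
        radial = v - np.dot(v, axis) * axis
        scores.append(float(np.linalg.norm(radial)))
    labels = [""] * n
    labels[int(np.argmin(scores))] = "inward"
    labels[int(np.argmax(scores))] = "outward"
    return ConformationReport(
        axis_distances=scores,
        labels=labels,
        pairwise_angles=angles,
        ring_rmsds=ring_rmsds,
    )
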