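"""Synthetic structures and trajectories with exact, known ground truth.

Every pipeline stage in this package is testable without downloading any
experimental structure: the generators here build idealized multi-domain
proteins (helical Cα trace, template atom offsets) where the quantities a
test will measure — per-domain rigid displacements, missing-residue
counts, planted confidence means, key-residue distances, contact
frame-fractions — are inputs, not estimates. Geometry is deliberately
idealized rather than physically relaxed: tests need exact ground truth,
not realism.

All generators are deterministic: the same seed produces byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structure_io import Atom, DomainScheme, Residue, Structure
from .trajectory_analysis import Trajectory

__all__ = [
    "ToySpec",
    "Motion",
    "PlantedContact",
    "TrajSpec",
    "make_toy_protein",
    "make_toy_pocket",
    "make_toy_trajectory",
    "axis_angle_rotation",
]

# helix parameters: ~3.8 Å Cα–Cα spacing, 100°/residue twist, 1.5 Å rise
_HELIX_RADIUS = 2.3
_HELIX_TWIST = math.radians(100.0)
_HELIX_RISE = 1.5

# local heavy-atom offsets from CA (Å), rotated with the helix twist
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.60, -0.50]),
    "C": np.array([1.25, 0.25, 0.55]),
    "O": np.array([1.90, 1.30, 0.55]),
    "CB": np.array([-0.45, -1.30, 0.70]),
}

_SIDECHAIN_TEMPLATES: Dict[str, Dict[str, np.ndarray]] = {
    "ALA": {},
    "ARG": {
        "CG": np.array([-0.9, -2.6, 1.1]),
        "CD": np.array([-1.3, -3.9, 1.6]),
        "NE": np.array([-1.7, -5.1, 2.1]),
        "CZ": np.array([-2.1, -6.3, 2.5]),
        "NH1": np.array([-2.0, -7.3, 1.7]),
        "NH2": np.array([-2.6, -6.5, 3.7]),
    },
    "GLU": {
        "CG": np.array([-0.9, -2.6, 1.1]),
        "CD": np.array([-1.3, -3.9, 1.6]),
        "OE1": np.array([-1.1, -4.9, 0.9]),
        "OE2": np.array([-1.9, -4.0, 2.7]),
    },
    "ASP": {
        "CG": np.array([-0.9, -2.6, 1.1]),
        "OD1": np.array([-0.7, -3.6, 0.4]),
        "OD2": np.array([-1.5, -2.7, 2.2]),
    },
    "PHE": {
        "CG": np.array([-0.9, -2.6, 1.1]),
        "CD1": np.array([-2.1, -3.2, 1.3]),
        "CD2": np.array([-0.1, -3.3, 2.0]),
        "CE1": np.array([-2.4, -4.4, 1.9]),
        "CE2": np.array([-0.4, -4.5, 2.6]),
        "CZ": np.array([-1.6, -5.1, 2.7]),
    },
    "TYR": {
        "CG": np.array([-0.9, -2.6, 1.1]),
        "CD1": np.array([-2.1, -3.2, 1.3]),
        "CD2": np.array([-0.1, -3.3, 2.0]),
        "CE1": np.array([-2.4, -4.4, 1.9]),
        "CE2": np.array([-0.4, -4.5, 2.6]),
        "CZ": np.array([-1.6, -5.1, 2.7]),
        "OH": np.array([-1.9, -6.3, 3.3]),
    },
    "ILE": {
        "CG1": np.array([-0.9, -2.6, 1.1]),
        "CG2": np.array([0.9, -1.8, 1.5]),
        "CD1": np.array([-1.3, -3.9, 1.6]),
    },
}

_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_FROM_NAME.get(atom_name[0], "C")


def axis_angle_rotation(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (normalised) axis, Rodrigues formula."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        return np.eye(3)
    k = axis / norm
    a = math.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(a) * kx + (1 - math.cos(a)) * (kx @ kx)


@dataclass
class ToySpec:
    """Recipe for a synthetic multi-domain protein model/reference pair."""

    n_domains: int = 3
    residues_per_domain: int = 30
    #: per-domain (axis, angle°, translation Å) applied to the *model*
    transforms: Optional[List[Tuple[Sequence[float], float, Sequence[float]]]] = None
    noise_sigma: float = 0.0  # Å, isotropic Gaussian on model atoms
    #: per-domain fraction of residues deleted from the *reference*
    missing_fractions: Optional[List[float]] = None
    #: per-domain planted confidence mean (written into model B-factors)
    confidence_means: Optional[List[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1 or self.residues_per_domain < 3:
            raise ValueError("need ≥1 domain and ≥3 residues per domain")
        for name in ("transforms", "missing_fractions", "confidence_means"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_domains:
                raise ValueError(f"{name} must have one entry per domain")
        if self.missing_fractions is not None:
            if any(not (0.0 <= f <= 1.0) for f in self.missing_fractions):
                raise ValueError("missing fractions must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


def _helical_residue(number: int, name: str = "ALA", chain_id: str = "A") -> Residue:
    theta = number * _HELIX_TWIST
    ca = np.array(
        [
            _HELIX_RADIUS * math.cos(theta),
            _HELIX_RADIUS * math.sin(theta),
            number * _HELIX_RISE,
        ]
    )
    rz = np.array(
        [
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    atoms = [Atom(name="CA", element="C", coords=ca)]
    offsets = dict(_BACKBONE_OFFSETS)
    for aname, off in offsets.items():
        atoms.append(Atom(name=aname, element=_element_of(aname), coords=ca + rz @ off))
    return Residue(chain_id=chain_id, number=number, icode="", name=name, atoms=atoms)


def _n_missing(fraction: float, n: int) -> int:
    # round-half-up, so 0.318 of 110 residues deletes exactly 35
    return int(math.floor(fraction * n + 0.5))


def make_toy_protein(spec: ToySpec) -> Tuple[Structure, Structure, Dict]:
    """Build a (model, reference) pair with exact ground truth.

    The reference is an idealized helical poly-alanine chain partitioned
    into labelled domains D1..Dn; the model is the reference with each
    domain's rigid transform (rotation about the domain centroid, then
    translation) and Gaussian coordinate noise applied, and with planted
    per-residue confidence written into B-factors. The reference
    additionally loses its per-domain missing fraction of residues at
    random (seeded), emulating missing experimental density.

    Returns ``(model, reference, truth)`` where ``truth`` carries the
    :class:`DomainScheme`, per-domain transforms, deleted residue numbers
    and planted confidence means — enough to predict every downstream
    metric exactly.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.residues_per_domain
    scheme_ranges = {
        f"D{k + 1}": (k * m + 1, (k + 1) * m) for k in range(spec.n_domains)
    }
    scheme = DomainScheme(ranges=scheme_ranges)

    ref_residues = [
        _helical_residue(i) for i in range(1, spec.n_domains * m + 1)
    ]

    # model: per-domain rigid transform + noise + planted confidence
    model_residues: List[Residue] = []
    for k in range(spec.n_domains):
        dom = ref_residues[k * m : (k + 1) * m]
        coords = np.array([a.coords for r in dom for a in r.atoms])
        centroid = coords.mean(axis=0)
        if spec.transforms is not None:
            axis, angle, trans = spec.transforms[k]
            rot = axis_angle_rotation(axis, angle)
            trans = np.asarray(trans, dtype=float)
        else:
            rot, trans = np.eye(3), np.zeros(3)
        conf = spec.confidence_means[k] if spec.confidence_means is not None else 80.0
        for r in dom:
            new_atoms = []
            for a in r.atoms:
                c = rot @ (a.coords - centroid) + centroid + trans
                if spec.noise_sigma > 0:
                    c = c + rng.normal(0.0, spec.noise_sigma, size=3)
                new_atoms.append(
                    Atom(name=a.name, element=a.element, coords=c, bfactor=conf)
                )
            model_residues.append(
                Residue(chain_id=r.chain_id, number=r.number, icode="", name=r.name, atoms=new_atoms)
            )

    # reference: delete the per-domain missing fraction of residues
    deleted: Dict[str, List[int]] = {}
    keep: List[Residue] = []
    for k in range(spec.n_domains):
        dom = ref_residues[k * m : (k + 1) * m]
        frac = spec.missing_fractions[k] if spec.missing_fractions is not None else 0.0
        n_del = _n_missing(frac, len(dom))
        drop_idx = set(rng.choice(len(dom), size=n_del, replace=False).tolist())
        deleted[f"D{k + 1}"] = sorted(dom[i].number for i in drop_idx)
        keep.extend(r for i, r in enumerate(dom) if i not in drop_idx)

    model = Structure(id="toy-model", chains={"A": model_residues})
    reference = Structure(id="toy-reference", chains={"A": keep})
    truth = {
        "scheme": scheme,
        "transforms": spec.transforms,
        "noise_sigma": spec.noise_sigma,
        "deleted_residues": deleted,
        "confidence_means": (
            {f"D{k + 1}": spec.confidence_means[k] for k in range(spec.n_domains)}
            if spec.confidence_means is not None
            else {f"D{k + 1}": 80.0 for k in range(spec.n_domains)}
        ),
        "residues_per_domain": m,
    }
    return model, reference, truth


_KEY_RESIDUE_NAMES = {
    228: "ALA",
    411: "ILE",
    443: "TYR",
    575: "PHE",
    578: "ARG",
    629: "GLU",
    636: "GLU",
    662: "ASP",
}


def _embed_distances(numbers: List[int], geometry: Dict[Tuple[int, int], float]) -> np.ndarray:
    """Classical MDS embedding of a complete pairwise distance set into 3D."""
    n = len(numbers)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (numbers[i], numbers[j])
            alt = (numbers[j], numbers[i])
            if key in geometry:
                v = geometry[key]
            elif alt in geometry:
                v = geometry[alt]
            else:
                raise ValueError(f"missing pairwise distance for residues {key}")
            if v <= 0:
                raise ValueError(f"distance for pair {key} must be positive")
            d[i, j] = d[j, i] = v
    for num in numbers:
        if (num, num) in geometry:
            raise ValueError(f"self-distance given for residue {num}")
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:3]
    top = np.clip(vals[order], 0.0, None)
    x = vecs[:, order] * np.sqrt(top)
    if x.shape[1] < 3:  # fewer points than dimensions: pad
        x = np.hstack([x, np.zeros((n, 3 - x.shape[1]))])
    # feasibility check: the embedding must reproduce the targets
    dd = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    if np.max(np.abs(dd - d)) > 1e-6:
        raise ValueError("target distances are not realizable in 3D (infeasible geometry)")
    return x


def make_toy_pocket(
    geometry: Dict[Tuple[int, int], float],
    seed: int = 0,
    planted_salt_bridge: Optional[Tuple[int, int, float]] = None,
) -> Structure:
    """Place key residues achieving specified pairwise Cα distances.

    ``geometry`` must give a complete, 3D-realizable pairwise distance set
    over the residue numbers it mentions; residue identities follow the
    NLRP3 key-residue table (228 Ala, 578 Arg, 629/636 Glu, 662 Asp, ...),
    defaulting to alanine. ``planted_salt_bridge=(cation_res, anion_res, d)``
    additionally places the cation's NH1 and the anion's OE1/OD1 exactly
    ``d`` Å apart.
    """
    numbers = sorted({n for pair in geometry for n in pair})
    if len(numbers) < 2:
        raise ValueError("need at least two residues")
    coords = _embed_distances(numbers, geometry)
    rng = np.random.default_rng(seed)
    centroid = coords.mean(axis=0)
    residues: List[Residue] = []
    for num, ca in zip(numbers, coords):
        name = _KEY_RESIDUE_NAMES.get(num, "ALA")
        # side chains point away from the pocket centroid so planted
        # contacts (placed toward a partner) stay unambiguous
        out = ca - centroid
        nrm = np.linalg.norm(out)
        u = out / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        atoms = [Atom(name="CA", element="C", coords=ca)]
        for aname, off in _BACKBONE_OFFSETS.items():
            if aname == "CB" and name == "GLY":
                continue
            atoms.append(Atom(name=aname, element=_element_of(aname), coords=ca + off))
        for aname, off in _SIDECHAIN_TEMPLATES.get(name, {}).items():
            atoms.append(
                Atom(
                    name=aname,
                    element=_element_of(aname),
                    coords=ca + np.linalg.norm(off) * u,
                )
            )
        residues.append(Residue(chain_id="A", number=num, icode="", name=name, atoms=atoms))

    if planted_salt_bridge is not None:
        c_res, a_res, dist = planted_salt_bridge
        if dist <= 0:
            raise ValueError("planted salt-bridge distance must be positive")
        by_num = {r.number: r for r in residues}
        rc, ra = by_num[c_res], by_num[a_res]
        direction = ra.atom("CA").coords - rc.atom("CA").coords
        u = direction / np.linalg.norm(direction)
        cation_atom = {"ARG": "NH1", "LYS": "NZ"}.get(rc.name, "NH1")
        anion_atom = {"GLU": "OE1", "ASP": "OD1"}.get(ra.name, "OE1")
        n_pos = rc.atom("CA").coords + 2.0 * u
        rc.atom(cation_atom).coords = n_pos
        ra.atom(anion_atom).coords = n_pos + dist * u
    return Structure(id="toy-pocket", chains={"A": residues})


@dataclass
class Motion:
    """Linear drift or oscillation applied to a selection over frames."""

    selection: str  # "protein" | "ligand" | "all"
    kind: str = "drift"  # drift | oscillate
    vector: Sequence[float] = (0.0, 0.0, 0.0)  # Å/frame (drift) or amplitude
    period: int = 10  # frames, oscillation only

    def displacement(self, frame: int) -> np.ndarray:
        v = np.asarray(self.vector, dtype=float)
        if self.kind == "drift":
            return frame * v
        if self.kind == "oscillate":
            return math.sin(2 * math.pi * frame / self.period) * v
        raise ValueError(f"unknown motion kind {self.kind!r}")


@dataclass
class PlantedContact:
    """A donor→acceptor contact present in an exact fraction of frames."""

    donor: Tuple[str, int, str]  # (chain, residue number, atom name)
    acceptor: Tuple[str, int, str]
    fraction: float
    bound_distance: float = 2.9  # Å when present
    unbound_distance: float = 6.5  # Å when absent

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("contact fraction must lie in [0, 1]")


@dataclass
class TrajSpec:
    base: Structure
    n_frames: int
    motions: List[Motion] = field(default_factory=list)
    contacts: List[PlantedContact] = field(default_factory=list)
    seed: int = 0
    dt_ps: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def _flat_atoms(s: Structure) -> List[Tuple[Residue, Atom]]:
    return [(r, a) for ch in s.chains.values() for r in ch for a in r.atoms]


def make_toy_trajectory(spec: TrajSpec) -> Trajectory:
    """Realize a motion program and planted contacts as a Trajectory.

    Each planted contact is satisfied in exactly
    ``round(fraction · n_frames)`` frames (chosen at random, seeded): in
    those frames the donor atom sits ``bound_distance`` Å from the
    acceptor along their separation vector, otherwise ``unbound_distance``.
    Motions are applied first, contact placement afterwards, so occupancy
    counts are exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    flat = _flat_atoms(spec.base)
    base_coords = np.array([a.coords for _, a in flat])
    n_atoms = len(flat)

    sel_cache: Dict[str, np.ndarray] = {}

    def _indices(selection: str) -> np.ndarray:
        if selection not in sel_cache:
            if selection == "protein":
                idx = [i for i, (r, _) in enumerate(flat) if not r.het]
            elif selection == "ligand":
                idx = [i for i, (r, _) in enumerate(flat) if r.het]
            elif selection == "all":
                idx = list(range(n_atoms))
            else:
                raise ValueError(f"unknown motion selection {selection!r}")
            if not idx:
                raise ValueError(f"motion selection {selection!r} matches no atoms")
            sel_cache[selection] = np.array(idx, dtype=int)
        return sel_cache[selection]

    atom_pos = {
        (r.chain_id, r.number, a.name): i for i, (r, a) in enumerate(flat)
    }
    contact_frames: List[np.ndarray] = []
    for c in spec.contacts:
        for role, key in (("donor", c.donor), ("acceptor", c.acceptor)):
            if key not in atom_pos:
                raise ValueError(f"planted contact {role} atom {key} not in base structure")
        n_on = int(round(c.fraction * spec.n_frames))
        on = rng.choice(spec.n_frames, size=n_on, replace=False)
        contact_frames.append(np.sort(on))

    coords = np.empty((spec.n_frames, n_atoms, 3))
    for k in range(spec.n_frames):
        frame = base_coords.copy()
        for motion in spec.motions:
            frame[_indices(motion.selection)] += motion.displacement(k)
        for c, on_frames in zip(spec.contacts, contact_frames):
            di = atom_pos[c.donor]
            ai = atom_pos[c.acceptor]
            sep = frame[di] - frame[ai]
            nrm = np.linalg.norm(sep)
            u = sep / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
            d = c.bound_distance if k in on_frames else c.unbound_distance
            frame[di] = frame[ai] + d * u
        coords[k] = frame
    return Trajectory(topology=spec.base, coords=coords, dt_ps=spec.dt_ps)
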