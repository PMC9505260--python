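"""Salt-bridge and hydrogen-bond detection, static or per trajectory frame.

Geometric criteria (all configurable; defaults are stated conventions):

* salt bridge — any side-chain nitrogen of Arg/Lys (and protonated His)
  within 4.0 Å of any side-chain carboxylate oxygen of Asp/Glu; one record
  per residue pair, at the minimum-distance atom pair.
* hydrogen bond — donor–acceptor heavy-atom distance ≤ 3.5 Å and, when an
  explicit hydrogen is bonded to the donor, D–H···A angle ≥ 135°. Without
  hydrogens the criterion degrades to distance-only.

Occupancy over a trajectory is the fraction of frames in which a contact
satisfies its criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structure_io import Atom, Residue, ResidueId, Structure
from .trajectory_analysis import Trajectory

__all__ = [
    "ContactRecord",
    "OccupancyTable",
    "detect_salt_bridges",
    "detect_hbonds",
    "hbond_occupancy",
]

_SALT_CATION_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    # protonated histidine variants only; neutral HIS excluded by default
    "HIP": ("ND1", "NE2"),
    "HSP": ("ND1", "NE2"),
}
_SALT_ANION_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# protein donor heavy atoms (polar H carriers) and acceptors, by residue
_DONORS: Dict[str, Tuple[str, ...]] = {
    "*": ("N",),  # backbone amide (PRO excluded below)
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "HIE": ("NE2",),
    "HID": ("ND1",),
    "HIP": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}
_ACCEPTORS: Dict[str, Tuple[str, ...]] = {
    "*": ("O", "OXT"),  # backbone carbonyl / terminal carboxylate
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "HIE": ("ND1",),
    "HID": ("NE2",),
    "MET": ("SD",),
}

_COVALENT_H_CUT = 1.25  # Å, H considered bonded to its donor heavy atom


@dataclass(frozen=True)
class ContactRecord:
    kind: str  # salt-bridge | hbond
    donor_residue: ResidueId
    donor_atom: str
    partner_residue: ResidueId
    partner_atom: str
    distance: float  # Å
    angle: Optional[float] = None  # degrees, D–H…A, when hydrogens available

    @property
    def key(self) -> Tuple:
        """Identity of the contact across frames (atoms, not geometry)."""
        return (
            self.kind,
            self.donor_residue,
            self.donor_atom,
            self.partner_residue,
            self.partner_atom,
        )


@dataclass
class OccupancyTable:
    """Contact key → fraction of frames in which the contact is present."""

    fractions: Dict[Tuple, float]
    n_frames: int
    records: Dict[Tuple, ContactRecord]  # representative record per key

    def to_tsv(self) -> str:
        lines = ["kind\tdonor\tdonor_atom\tpartner\tpartner_atom\toccupancy"]
        for key, frac in sorted(self.fractions.items(), key=lambda kv: -kv[1]):
            r = self.records[key]
            dr = f"{r.donor_residue[0]}:{r.donor_residue[1]}"
            pr = f"{r.partner_residue[0]}:{r.partner_residue[1]}"
            lines.append(
                f"{r.kind}\t{dr}\t{r.donor_atom}\t{pr}\t{r.partner_atom}\t{frac:.3f}"
            )
        return "\n".join(lines) + "\n"


def _iter_residues(s: Structure, chains: Optional[Sequence[str]]) -> List[Residue]:
    cids = list(s.chains) if chains is None else list(chains)
    out: List[Residue] = []
    for cid in cids:
        out.extend(s.chain(cid))
    return out


def detect_salt_bridges(
    s: Structure,
    chains: Optional[Sequence[str]] = None,
    cutoff: float = 4.0,
    include_neutral_his: bool = False,
    all_atom_pairs: bool = False,
) -> List[ContactRecord]:
    """Salt bridges between basic side-chain N and acidic carboxylate O.

    One record per residue pair at the minimum-distance atom pair, unless
    ``all_atom_pairs`` is set. Neutral histidine participates only when
    ``include_neutral_his`` is set (protonated forms HIP/HSP always do).
    """
    cation_table = dict(_SALT_CATION_ATOMS)
    if include_neutral_his:
        cation_table["HIS"] = ("ND1", "NE2")
        cation_table["HSD"] = ("ND1", "NE2")
        cation_table["HSE"] = ("ND1", "NE2")
    residues = _iter_residues(s, chains)
    cations = [(r, n) for r in residues for n in cation_table.get(r.name.upper(), ())]
    anions = [(r, n) for r in residues for n in _SALT_ANION_ATOMS.get(r.name.upper(), ())]
    best: Dict[Tuple[ResidueId, ResidueId], ContactRecord] = {}
    all_records: List[ContactRecord] = []
    for rc, cn in cations:
        ac = rc.atom(cn)
        if ac is None:
            continue
        for ra, an in anions:
            if ra.rid == rc.rid:
                continue
            aa = ra.atom(an)
            if aa is None:
                continue
            d = float(np.linalg.norm(ac.coords - aa.coords))
            if d > cutoff:
                continue
            rec = ContactRecord(
                kind="salt-bridge",
                donor_residue=rc.rid,
                donor_atom=cn,
                partner_residue=ra.rid,
                partner_atom=an,
                distance=d,
            )
            all_records.append(rec)
            pair = (rc.rid, ra.rid)
            if pair not in best or d < best[pair].distance:
                best[pair] = rec
    if all_atom_pairs:
        return sorted(all_records, key=lambda r: r.distance)
    return sorted(best.values(), key=lambda r: r.distance)


def _bonded_hydrogens(r: Residue, heavy: Atom) -> List[Atom]:
    return [
        a
        for a in r.atoms
        if a.is_hydrogen and np.linalg.norm(a.coords - heavy.coords) <= _COVALENT_H_CUT
    ]


def _ligand_roles(r: Residue) -> Tuple[List[str], List[str]]:
    """Donor/acceptor heavy atoms of a HET residue from element + bonded H."""
    donors, acceptors = [], []
    for a in r.atoms:
        el = a.element.upper()
        if el in ("N", "O"):
            acceptors.append(a.name)
            if _bonded_hydrogens(r, a):
                donors.append(a.name)
    return donors, acceptors


def _roles_for(r: Residue, include_ligand: bool) -> Tuple[List[str], List[str]]:
    if r.het and r.name not in ("HOH", "WAT"):
        return _ligand_roles(r) if include_ligand else ([], [])
    name = r.name.upper()
    donors = list(_DONORS.get(name, ()))
    if name != "PRO":
        donors = list(_DONORS["*"]) + donors
    acceptors = list(_ACCEPTORS["*"]) + list(_ACCEPTORS.get(name, ()))
    return donors, acceptors


def detect_hbonds(
    frame: Structure,
    chains: Optional[Sequence[str]] = None,
    donors: Optional[Sequence[Tuple[ResidueId, str]]] = None,
    acceptors: Optional[Sequence[Tuple[ResidueId, str]]] = None,
    d_cut: float = 3.5,
    angle_cut: float = 135.0,
    include_ligand: bool = False,
) -> List[ContactRecord]:
    """Hydrogen bonds in a single structure/frame.

    Donor and acceptor roles default to standard residue tables (plus
    element-derived roles for HET ligands when ``include_ligand``); explicit
    ``donors``/``acceptors`` lists of ``(residue_id, atom_name)`` override
    them. When a bonded hydrogen is present on the donor, the best
    D–H···A angle must be ≥ ``angle_cut``; otherwise distance-only.
    """
    residues = _iter_residues(frame, chains)
    index = {r.rid: r for r in residues}

    def _expand(explicit, which):
        if explicit is not None:
            return [(index[rid], name) for rid, name in explicit if rid in index]
        out = []
        for r in residues:
            ds, as_ = _roles_for(r, include_ligand)
            for name in (ds if which == "donor" else as_):
                out.append((r, name))
        return out

    donor_list = [(r, n, r.atom(n)) for r, n in _expand(donors, "donor")]
    donor_list = [(r, n, a) for r, n, a in donor_list if a is not None]
    acc_list = [(r, n, r.atom(n)) for r, n in _expand(acceptors, "acceptor")]
    acc_list = [(r, n, a) for r, n, a in acc_list if a is not None]
    if not donor_list or not acc_list:
        warnings.warn("no hydrogen-bond donors or acceptors found")
        return []

    records: List[ContactRecord] = []
    for rd, dn, da in donor_list:
        hydrogens = _bonded_hydrogens(rd, da)
        for ra, an, aa in acc_list:
            if ra.rid == rd.rid:
                continue
            d = float(np.linalg.norm(da.coords - aa.coords))
            if d > d_cut:
                continue
            angle = None
            if hydrogens:
                angle = max(_dha_angle(da.coords, h.coords, aa.coords) for h in hydrogens)
                if angle < angle_cut:
                    continue
            records.append(
                ContactRecord(
                    kind="hbond",
                    donor_residue=rd.rid,
                    donor_atom=dn,
                    partner_residue=ra.rid,
                    partner_atom=an,
                    distance=d,
                    angle=angle,
                )
            )
    return sorted(records, key=lambda r: r.distance)


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_occupancy(
    traj: Trajectory,
    chains: Optional[Sequence[str]] = None,
    donors: Optional[Sequence[Tuple[ResidueId, str]]] = None,
    acceptors: Optional[Sequence[Tuple[ResidueId, str]]] = None,
    d_cut: float = 3.5,
    angle_cut: float = 135.0,
    include_ligand: bool = True,
) -> OccupancyTable:
    """Hydrogen-bond occupancy over all supplied frames.

    For every contact observed in at least one frame, the fraction of
    frames in which it satisfies the criteria. Counts are integer-exact.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    counts: Dict[Tuple, int] = {}
    reps: Dict[Tuple, ContactRecord] = {}
    for i in range(traj.n_frames):
        frame = traj.frame_structure(i)
        seen = set()
        for rec in detect_hbonds(
            frame,
            chains=chains,
            donors=donors,
            acceptors=acceptors,
            d_cut=d_cut,
            angle_cut=angle_cut,
            include_ligand=include_ligand,
        ):
            if rec.key in seen:
                continue  # count a contact once per frame
            seen.add(rec.key)
            counts[rec.key] = counts.get(rec.key, 0) + 1
            reps.setdefault(rec.key, rec)
    fractions = {k: c / traj.n_frames for k, c in counts.items()}
    return OccupancyTable(fractions=fractions, n_frames=traj.n_frames, records=reps)
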