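"""Macromolecular structure containers and PDB/mmCIF I/O.

The in-memory model is deliberately small: a :class:`Structure` is an
ordered mapping of chain id to a list of :class:`Residue`, each holding
:class:`Atom` records. Author (deposited) residue numbering is the only
coordinate system used anywhere in the package, so that residues can be
addressed the way structural biologists name them (R578, A228) across
predicted models and experimental structures alike.

Parsing and serialisation are delegated to ``gemmi``; this module owns the
altloc policy (highest occupancy wins, file order breaks ties) and the
domain bookkeeping (subdomain assignment, missing-density accounting,
per-residue confidence extraction from the B-factor column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "DomainScheme",
    "NLRP3_SCHEME",
    "read_structure",
    "write_structure",
    "extract_plddt",
    "assign_domains",
    "missing_fraction",
]

#: residue-id triple: (chain_id, author number, insertion code)
ResidueId = Tuple[str, int, str]

_HYDROGEN = {"H", "D"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # protonation variants map to parent
    "HID": "H", "HIE": "H", "HIP": "H", "HSD": "H", "HSE": "H", "HSP": "H",
}


@dataclass
class Atom:
    """A single atom record.

    ``bfactor`` carries the per-residue pLDDT in predicted models
    (AlphaFold/RoseTTAFold convention).
    """

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN


@dataclass
class Residue:
    chain_id: str
    number: int  # author numbering
    icode: str
    name: str  # 3-letter code
    atoms: List[Atom] = field(default_factory=list)
    het: bool = False  # HETATM record (ligand, water, modified residue)

    @property
    def rid(self) -> ResidueId:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> List[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name.upper(), "X")


@dataclass
class Structure:
    """Chains of residues in file order; ``chains`` maps chain id → residues."""

    id: str
    chains: Dict[str, List[Residue]]
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError(f"structure {self.id!r} has no chains")
        seen: set = set()
        for residues in self.chains.values():
            for r in residues:
                if r.rid in seen:
                    raise ValueError(f"duplicate residue id {r.rid} in structure {self.id!r}")
                seen.add(r.rid)

    def chain(self, chain_id: str) -> List[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not in structure {self.id!r}; "
                f"available: {sorted(self.chains)}"
            ) from None

    def residue(self, chain_id: str, number: int, icode: str = "") -> Optional[Residue]:
        for r in self.chain(chain_id):
            if r.number == number and r.icode == icode:
                return r
        return None

    def first_protein_chain(self) -> str:
        for cid, residues in self.chains.items():
            if any(r.one_letter != "X" and not r.het for r in residues):
                return cid
        return next(iter(self.chains))


@dataclass
class DomainScheme:
    """Named residue ranges plus key-residue and sequence-motif constants.

    Ranges are inclusive author-numbered intervals and must not overlap.
    """

    ranges: Dict[str, Tuple[int, int]]
    key_residues: List[Tuple[int, str]] = field(default_factory=list)
    motifs: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans = sorted(self.ranges.items(), key=lambda kv: kv[1][0])
        for (na, (sa, ea)), (nb, (sb, eb)) in zip(spans, spans[1:]):
            if ea >= sb:
                raise ValueError(f"domain ranges {na!r} and {nb!r} overlap")
        for name, (s, e) in self.ranges.items():
            if s > e:
                raise ValueError(f"domain {name!r}: start {s} > end {e}")

    def domain_of(self, number: int) -> str:
        for name, (s, e) in self.ranges.items():
            if s <= number <= e:
                return name
        return "other"

    def length(self, domain: str) -> int:
        s, e = self.ranges[domain]
        return e - s + 1


#: NLRP3 subdomain scheme (human numbering). Residue 629 is listed under two
#: labels (E629 and G629) because published descriptions of the MCC950 pocket
#: use both; validation against the actual sequence is left to the caller.
NLRP3_SCHEME = DomainScheme(
    ranges={
        "PYD": (3, 95),
        "FISNA": (96, 218),
        "NBD": (219, 372),
        "HD1": (373, 434),
        "WHD": (435, 541),
        "HD2": (542, 651),
        "LRR": (652, 1036),
    },
    key_residues=[
        (228, "ALA"),
        (411, "ILE"),
        (443, "TYR"),
        (575, "PHE"),
        (578, "ARG"),
        (629, "GLU"),
        (629, "GLY"),
        (636, "GLU"),
        (662, "ASP"),
    ],
    motifs={
        "walker_a": "GAAGIGKTIL",
        "walker_b": "RILFMDGFDELQGAFDEHI",
    },
)


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffixes = "".join(path.suffixes).lower()
    if ".cif" in suffixes or ".mmcif" in suffixes:
        return "mmcif"
    return "pdb"


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM/HETATM records are represented. For alternate locations the
    highest-occupancy altloc is kept (ties broken by file order). Hydrogens
    are retained. mmCIF chains/numbers use auth_asym_id / auth_seq_id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _detect_format(path, format)
    try:
        if fmt == "mmcif":
            g = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            g = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    g.setup_entities()
    if len(g) == 0:
        raise ValueError(f"{path}: no models in file")
    model = g[0]

    chains: Dict[str, List[Residue]] = {}
    for ch in model:
        residues: List[Residue] = []
        for res in ch:
            icode = res.seqid.icode.strip()
            atoms: List[Atom] = []
            # altloc policy: per atom name keep the highest-occupancy altloc
            best: Dict[str, Atom] = {}
            order: List[str] = []
            for a in res:
                atom = Atom(
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=(a.altloc or "").strip(),
                    bfactor=a.b_iso,
                )
                if a.name not in best:
                    best[a.name] = atom
                    order.append(a.name)
                elif atom.occupancy > best[a.name].occupancy:
                    best[a.name] = atom
            atoms = [best[n] for n in order]
            residues.append(
                Residue(
                    chain_id=ch.name,
                    number=res.seqid.num,
                    icode=icode,
                    name=res.name,
                    atoms=atoms,
                    het=res.het_flag == "H",
                )
            )
        if residues:
            chains[ch.name] = residues
    if not chains:
        raise ValueError(f"{path}: empty structure (no atoms)")
    return Structure(id=path.stem, chains=chains, source_format=fmt)


def _to_gemmi(s: Structure) -> gemmi.Structure:
    g = gemmi.Structure()
    g.name = s.id
    model = gemmi.Model("1")
    for cid, residues in s.chains.items():
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.number, r.icode if r.icode else " ")
            gr.het_flag = "H" if r.het else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                if a.altloc:
                    ga.altloc = a.altloc
                gr.add_atom(ga)
            ch.add_residue(gr)
        model.add_chain(ch)
    g.add_model(model)
    g.setup_entities()
    return g


def write_structure(s: Structure, path, format: str = "auto") -> None:
    """Write a :class:`Structure` as PDB (fixed-column v3.3) or mmCIF."""
    path = Path(path)
    fmt = _detect_format(path, format)
    g = _to_gemmi(s)
    if fmt == "mmcif":
        g.make_mmcif_document().write_file(str(path))
    else:
        g.write_pdb(str(path))


def extract_plddt(s: Structure, scale: str = "auto") -> Dict[ResidueId, float]:
    """Per-residue confidence from the B-factor column, on a 0–100 scale.

    The score of a residue is the B-factor of its Cα atom, falling back to
    the mean over all atoms. ``scale='auto'`` detects 0–1 encodings (all
    values ≤ 1.0) and rescales by 100; ``'0-100'`` is the identity;
    ``'0-1'`` always multiplies by 100.
    """
    if scale not in ("auto", "0-100", "0-1"):
        raise ValueError(f"unknown scale {scale!r}")
    raw: Dict[ResidueId, float] = {}
    for residues in s.chains.values():
        for r in residues:
            if r.het:
                continue
            ca = r.atom("CA")
            if ca is not None:
                raw[r.rid] = ca.bfactor
            elif r.atoms:
                raw[r.rid] = float(np.mean([a.bfactor for a in r.atoms]))
            else:
                warnings.warn(f"residue {r.rid} has no atoms; omitted from pLDDT map")
    if not raw:
        return raw
    factor = 1.0
    if scale == "0-1" or (scale == "auto" and max(raw.values()) <= 1.0):
        factor = 100.0
    return {rid: v * factor for rid, v in raw.items()}


def assign_domains(
    s: Structure, scheme: DomainScheme, chain: str
) -> Dict[str, List[ResidueId]]:
    """Partition a chain's residues into the scheme's named domains.

    Every residue lands in exactly one bucket; residues outside all ranges
    go to ``"other"``.
    """
    out: Dict[str, List[ResidueId]] = {name: [] for name in scheme.ranges}
    out["other"] = []
    for r in s.chain(chain):
        out[scheme.domain_of(r.number)].append(r.rid)
    return out


def missing_fraction(
    s: Structure, scheme: DomainScheme, domain: str, chain: str
) -> Tuple[float, List[int]]:
    """Fraction of a domain's residues absent from the structure.

    A residue counts as present when it exists in the chain with at least
    one non-hydrogen atom. Returns ``(fraction, absent_residue_numbers)``.
    """
    if domain not in scheme.ranges:
        raise KeyError(f"unknown domain {domain!r}; scheme has {sorted(scheme.ranges)}")
    start, end = scheme.ranges[domain]
    present = {
        r.number
        for r in s.chain(chain)
        if start <= r.number <= end and r.heavy_atoms() and not r.het
    }
    absent = [n for n in range(start, end + 1) if n not in present]
    return len(absent) / (end - start + 1), absent


def chain_sequence(s: Structure, chain: str) -> Tuple[str, List[Residue]]:
    """One-letter sequence of a chain's standard residues, with the residues."""
    residues = [r for r in s.chain(chain) if not r.het and r.one_letter != "X"]
    return "".join(r.one_letter for r in residues), residues
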