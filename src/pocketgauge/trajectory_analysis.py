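"""MD-trajectory containers and RMSD-vs-first-frame analysis.

The package consumes trajectories, it never produces them: frames arrive
from standard MD formats (via MDAnalysis) or from the synthetic generator,
and are held as a plain ``(n_frames, n_atoms, 3)`` coordinate array over a
topology :class:`~pocketgauge.structure_io.Structure`.

Periodic-boundary unwrapping is NOT performed; supply imaged trajectories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .structure_io import Residue, ResidueId, Structure, write_structure
from .superposition import kabsch

__all__ = [
    "Trajectory",
    "RmsdSeries",
    "load_trajectory",
    "write_trajectory",
    "rmsd_series",
    "indicator_series",
]

Selection = Union[str, Sequence[Tuple[str, int]]]


@dataclass
class Trajectory:
    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    dt_ps: Optional[float] = None  # time between frames

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n_atoms = len(self.atom_index())
        if self.coords.ndim != 3 or self.coords.shape[1] != n_atoms or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords shape {self.coords.shape} does not match topology "
                f"({n_atoms} atoms)"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def atom_index(self) -> List[Tuple[Residue, str]]:
        """Flattened (residue, atom name) list in topology order."""
        out = []
        for residues in self.topology.chains.values():
            for r in residues:
                for a in r.atoms:
                    out.append((r, a.name))
        return out

    def frame_structure(self, i: int) -> Structure:
        """Topology with the coordinates of frame ``i`` substituted."""
        s = copy.deepcopy(self.topology)
        k = 0
        frame = self.coords[i]
        for residues in s.chains.values():
            for r in residues:
                for a in r.atoms:
                    a.coords = frame[k].copy()
                    k += 1
        return s

    def select(self, selection: Selection) -> np.ndarray:
        """Atom indices for a named or explicit selection.

        Named selections: ``protein-ca`` (Cα of non-HET residues),
        ``protein-heavy``, ``ligand-heavy`` (heavy atoms of HET residues,
        waters excluded), ``all-heavy``. An explicit selection is a list of
        ``(chain_id, residue_number)`` pairs, taken heavy-atom-wise.
        """
        index = self.atom_index()
        idx: List[int] = []
        if isinstance(selection, str):
            for i, (r, name) in enumerate(index):
                atom = r.atom(name)
                assert atom is not None
                if atom.is_hydrogen and selection != "protein-ca":
                    continue
                if selection == "protein-ca":
                    if not r.het and name == "CA":
                        idx.append(i)
                elif selection == "protein-heavy":
                    if not r.het:
                        idx.append(i)
                elif selection == "ligand-heavy":
                    if r.het and r.name not in ("HOH", "WAT"):
                        idx.append(i)
                elif selection == "all-heavy":
                    idx.append(i)
                else:
                    raise ValueError(f"unknown selection {selection!r}")
        else:
            wanted = {(c, n) for c, n in selection}
            for i, (r, name) in enumerate(index):
                atom = r.atom(name)
                if not atom.is_hydrogen and (r.chain_id, r.number) in wanted:
                    idx.append(i)
        if not idx:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return np.array(idx, dtype=int)


@dataclass
class RmsdSeries:
    label: str
    values: np.ndarray  # per-frame Å, relative to frame 1
    fit_on: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_tsv(self) -> str:
        lines = ["frame\trmsd_angstrom"]
        lines += [f"{i}\t{v:.4f}" for i, v in enumerate(self.values)]
        return "\n".join(lines) + "\n"


def load_trajectory(topology_path, traj_path, dt_ps: Optional[float] = None) -> Trajectory:
    """Read an MD trajectory (DCD/XTC/TRR/NetCDF/multi-model PDB) + topology.

    The topology is parsed with this package's reader; frame coordinates are
    pulled through MDAnalysis and must match the topology's atom count
    (trajectory files are assumed altloc-free, as MD output is).
    """
    import MDAnalysis as mda

    from .structure_io import read_structure

    topo = read_structure(topology_path)
    u = mda.Universe(str(topology_path), str(traj_path))
    n_atoms = sum(len(r.atoms) for ch in topo.chains.values() for r in ch)
    if len(u.atoms) != n_atoms:
        raise ValueError(
            f"topology has {n_atoms} atoms but trajectory frames have {len(u.atoms)}"
        )
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    if dt_ps is None:
        dt_ps = getattr(u.trajectory, "dt", None)
    return Trajectory(topology=topo, coords=frames, dt_ps=dt_ps)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write frames as a multi-model PDB (plain-text, broadly readable)."""
    import gemmi

    from .structure_io import _to_gemmi

    g = gemmi.Structure()
    g.name = traj.topology.id
    for i in range(traj.n_frames):
        frame = _to_gemmi(traj.frame_structure(i))
        model = frame[0]
        if hasattr(model, "num"):
            model.num = i + 1
        else:  # older gemmi
            model.name = str(i + 1)
        g.add_model(model)
    g.setup_entities()
    g.write_pdb(str(path))


def rmsd_series(
    traj: Trajectory,
    fit_selection: Selection = "protein-ca",
    measure_selection: Selection = "protein-ca",
    label: Optional[str] = None,
) -> RmsdSeries:
    """Per-frame RMSD relative to the first frame.

    Each frame is superposed onto frame 1 over ``fit_selection`` (Kabsch),
    then the RMSD is measured over ``measure_selection`` after that fit —
    the standard convention for ligand RMSD after a protein-frame fit.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    fit_idx = traj.select(fit_selection)
    meas_idx = traj.select(measure_selection)
    if len(fit_idx) < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    ref_fit = traj.coords[0][fit_idx]
    ref_meas = traj.coords[0][meas_idx]
    values = np.empty(traj.n_frames)
    values[0] = 0.0
    for k in range(1, traj.n_frames):
        sup = kabsch(traj.coords[k][fit_idx], ref_fit)
        moved = sup.transform(traj.coords[k][meas_idx])
        d = moved - ref_meas
        values[k] = np.sqrt(np.einsum("ij,ij->i", d, d).mean())
    return RmsdSeries(
        label=label or str(measure_selection),
        values=values,
        fit_on=str(fit_selection),
    )


def indicator_series(
    traj: Trajectory,
    res_i: int,
    res_j: int,
    chain: Optional[str] = None,
) -> Dict[str, object]:
    """Per-frame Cα distance between two residues, plus summary stats.

    Returns ``{"values": array, "first": Å, "last": Å, "mean": Å}``.
    """
    if chain is None:
        chain = traj.topology.first_protein_chain()
    index = traj.atom_index()
    pos = {}
    for i, (r, name) in enumerate(index):
        if r.chain_id == chain and name == "CA" and r.number in (res_i, res_j):
            pos[r.number] = i
    for num in (res_i, res_j):
        if num not in pos:
            raise ValueError(f"residue {num} has no CA in chain {chain!r} of the topology")
    d = np.linalg.norm(traj.coords[:, pos[res_i]] - traj.coords[:, pos[res_j]], axis=1)
    return {
        "values": d,
        "first": float(d[0]),
        "last": float(d[-1]),
        "mean": float(d.mean()),
    }
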