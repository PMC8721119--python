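"""Trajectory and topology handling.

Reads multi-model PDB files, or DCD/XTC trajectories with a PDB topology,
through MDAnalysis; selects Cα and side-chain heavy atoms; performs iterative
least-squares superposition onto the mean Cα structure; and maps chains onto
subunits with an explicit neighbor relation (domain-swapped channels couple a
subunit's voltage sensor to the pore of the *neighboring* subunit, so the
relation direction is part of the configuration, never guessed).

All coordinates are in Å. Input residue numbering is preserved verbatim:
residues are addressed by ``"<chain>:<resid>"`` keys throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    ConfigError,
    ConsistencyError,
    EmptySelectionError,
    FluctnetError,
    FormatError,
    ResidueLookupError,
)

logger = logging.getLogger(__name__)

#: Backbone heavy-atom names excluded from the side-chain set.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "OT1", "OT2"})

#: Consecutive-Cα distances below this (Å) suggest nm-scaled coordinates.
_NM_HEURISTIC_CA_DIST = 2.0


def residue_key(chain: str, resid: int) -> str:
    """Canonical residue key, e.g. ``"A:377"``."""
    return f"{chain}:{int(resid)}"


@dataclass(frozen=True)
class ResidueEntry:
    key: str
    chain: str
    resid: int
    resname: str
    calpha_index: int
    sidechain_indices: tuple[int, ...]


class ResidueTable:
    """Ordered table of residues with atom-role indices.

    ``sidechain_indices`` are all non-hydrogen atoms excluding the backbone
    N/CA/C/O; for glycine (no side-chain heavy atom) the Cα is used as a
    surrogate so the side-chain contact rule remains defined.
    """

    def __init__(self, entries: Sequence[ResidueEntry]):
        self.entries: tuple[ResidueEntry, ...] = tuple(entries)
        self._index = {e.key: i for i, e in enumerate(self.entries)}
        if len(self._index) != len(self.entries):
            raise ConsistencyError("duplicate residue keys in residue table")
        for e in self.entries:
            if not e.sidechain_indices:
                raise ConsistencyError(
                    f"residue {e.key} has no side-chain atoms and no Cα surrogate"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, key: str) -> ResidueEntry:
        try:
            return self.entries[self._index[key]]
        except KeyError:
            raise ResidueLookupError(f"unknown residue key {key!r}") from None

    def index_of(self, key: str) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise ResidueLookupError(f"unknown residue key {key!r}") from None

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(e.key for e in self.entries)

    @property
    def chains(self) -> tuple[str, ...]:
        """Distinct chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.chain, None)
        return tuple(seen)

    @property
    def calpha_indices(self) -> np.ndarray:
        return np.array([e.calpha_index for e in self.entries], dtype=int)


@dataclass
class Trajectory:
    """Per-frame coordinates (Å) for a fixed atom set plus its residue table."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    residue_table: ResidueTable
    superposed: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ConsistencyError(f"coordinates must be (frames, atoms, 3), got {c.shape}")
        if c.shape[0] < 2:
            raise ConsistencyError(f"need at least 2 frames, got {c.shape[0]}")
        if not np.isfinite(c).all():
            raise ConsistencyError("non-finite coordinates")
        self.coordinates = c

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def calpha_coordinates(self) -> np.ndarray:
        """(n_frames, n_residues, 3) view of the Cα positions."""
        return self.coordinates[:, self.residue_table.calpha_indices, :]

    def with_stride(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ConfigError(f"stride must be >= 1, got {stride}")
        if stride == 1:
            return self
        return replace(self, coordinates=self.coordinates[::stride])


@dataclass(frozen=True)
class SubunitMap:
    """Cyclic subunit order plus the VSD→neighbor-PD relation."""

    order: tuple[str, ...]
    neighbor: Mapping[str, str]
    label_of_chain: Mapping[str, str]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.order

    def neighbor_of(self, label: str) -> str:
        return self.neighbor[label]

    def chains_of(self, label: str) -> tuple[str, ...]:
        return tuple(c for c, lab in self.label_of_chain.items() if lab == label)

    def label_of(self, chain: str) -> str:
        try:
            return self.label_of_chain[chain]
        except KeyError:
            raise ConfigError(f"chain {chain!r} has no subunit assignment") from None


def _build_residue_table(atoms) -> ResidueTable:
    """Residue table from an MDAnalysis AtomGroup (indices into the group)."""
    entries = []
    # Map universe-level atom index -> position inside the selection.
    local = {a.ix: i for i, a in enumerate(atoms)}
    for res in atoms.residues:
        res_atoms = [a for a in res.atoms if a.ix in local]
        ca = [a for a in res_atoms if a.name == "CA"]
        if len(ca) != 1:
            raise FormatError(
                f"residue {res.resname} {res.resid} has {len(ca)} Cα atoms in the "
                "selection; exactly one is required"
            )
        chain = getattr(ca[0], "chainID", "") or getattr(res, "segid", "") or "A"
        sidechain = tuple(
            local[a.ix]
            for a in res_atoms
            if a.name not in BACKBONE_NAMES
            and not a.name.startswith("H")
            and getattr(a, "element", "") != "H"
        )
        if not sidechain:  # glycine and friends: Cα surrogate
            sidechain = (local[ca[0].ix],)
        entries.append(
            ResidueEntry(
                key=residue_key(chain, res.resid),
                chain=str(chain),
                resid=int(res.resid),
                resname=str(res.resname),
                calpha_index=local[ca[0].ix],
                sidechain_indices=sidechain,
            )
        )
    return ResidueTable(entries)


def _check_units(traj: Trajectory) -> None:
    """Reject coordinates that look nm-scaled (median bonded Cα–Cα ≪ 3.8 Å)."""
    ca = traj.calpha_coordinates[0]
    table = traj.residue_table
    dists = []
    for a, b in zip(table.entries[:-1], table.entries[1:]):
        if a.chain == b.chain and b.resid == a.resid + 1:
            dists.append(np.linalg.norm(ca[table.index_of(b.key)] - ca[table.index_of(a.key)]))
    if dists and float(np.median(dists)) < _NM_HEURISTIC_CA_DIST:
        raise FormatError(
            "consecutive Cα distances are far below peptide geometry; coordinates "
            "appear to be in nm — convert to Å before loading"
        )


def load_trajectory(
    trajectory_path: str | Path,
    topology_path: str | Path | None = None,
    atom_selection: str = "protein",
    stride: int = 1,
) -> Trajectory:
    """Load a multi-model PDB, or a DCD/XTC with a PDB topology.

    Parameters
    ----------
    trajectory_path
        Multi-model PDB, DCD, or XTC file.
    topology_path
        PDB (or PSF-style) topology; required for coordinate-only formats.
    atom_selection
        MDAnalysis selection string; must match at least one atom.
    stride
        Keep every ``stride``-th frame (default: all frames).
    """
    import MDAnalysis as mda

    trajectory_path = Path(trajectory_path)
    if not trajectory_path.exists():
        raise FormatError(f"no such trajectory file: {trajectory_path}")
    try:
        if topology_path is not None:
            u = mda.Universe(str(topology_path), str(trajectory_path))
        else:
            u = mda.Universe(str(trajectory_path))
    except FluctnetError:
        raise
    except Exception as exc:  # MDAnalysis raises a zoo of parse errors
        raise FormatError(f"could not read {trajectory_path}: {exc}") from exc

    atoms = u.select_atoms(atom_selection)
    if len(atoms) == 0:
        raise EmptySelectionError(f"selection {atom_selection!r} matched zero atoms")

    frames = []
    for ts in u.trajectory[::stride]:
        if ts.positions.shape[0] != len(u.atoms):
            raise ConsistencyError(
                f"frame {ts.frame} has {ts.positions.shape[0]} atoms; topology has "
                f"{len(u.atoms)}"
            )
        frames.append(atoms.positions.astype(float).copy())
    if len(frames) < 2:
        raise ConsistencyError(
            f"{trajectory_path} holds {len(frames)} frame(s); at least 2 are required"
        )

    table = _build_residue_table(atoms)
    traj = Trajectory(np.stack(frames), table)
    _check_units(traj)
    logger.info(
        "loaded %s: %d frames, %d atoms, %d residues",
        trajectory_path.name, traj.n_frames, traj.n_atoms, len(table),
    )
    return traj


def _kabsch_rotations(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Kabsch fit of each frame onto ``ref``.

    Returns per-frame rotation matrices ``R`` (applied as ``x @ R``) and the
    frame centroids; ``ref`` must already be centered at the origin.
    """
    cm = mobile.mean(axis=1, keepdims=True)  # (F,1,3)
    H = np.einsum("fni,nj->fij", mobile - cm, ref)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
    U[:, :, 2] *= d[:, None]
    R = np.einsum("fij,fjk->fik", U, Vt)
    return R, cm


def superpose(traj: Trajectory, max_iter: int = 10, tol: float = 1e-6) -> Trajectory:
    """Least-squares superpose every frame on the iteratively refined Cα mean.

    Each frame is rigid-body fitted (Kabsch) onto the running mean Cα
    structure; the mean is recomputed and the procedure repeats until its RMS
    change drops below ``tol`` (Å) or ``max_iter`` is reached. Removing rigid
    drift is essential before the fluctuation correlation matrix: unremoved
    global rotation correlates every residue with every other.
    """
    ca_idx = traj.residue_table.calpha_indices
    if len(ca_idx) < 3:
        raise ConsistencyError("superposition needs at least 3 Cα atoms")
    coords = traj.coordinates.copy()
    ref = coords[0, ca_idx]
    ref = ref - ref.mean(axis=0)
    for _ in range(max_iter):
        R, cm = _kabsch_rotations(coords[:, ca_idx], ref)
        coords = np.einsum("fai,fij->faj", coords - cm, R)
        new_ref = coords[:, ca_idx].mean(axis=0)
        new_ref = new_ref - new_ref.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1))))
        ref = new_ref
        if shift < tol:
            break
    return replace(traj, coordinates=coords, superposed=True)


def assign_subunits(residue_table: ResidueTable, chain_map: Mapping) -> SubunitMap:
    """Build the subunit map from a configuration mapping.

    ``chain_map`` must provide ``chains`` (chain id → subunit label),
    ``order`` (cyclic subunit order), and ``neighbor`` (subunit label → the
    subunit whose pore its voltage sensor packs against). The neighbor
    relation must be a bijection on the labels with no fixed points when more
    than one subunit is present.
    """
    try:
        chains = dict(chain_map["chains"])
        order = tuple(chain_map["order"])
        neighbor = dict(chain_map["neighbor"])
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"chain_map must define 'chains', 'order', 'neighbor': {exc}") from exc

    labels = set(order)
    if len(order) != len(labels):
        raise ConfigError("subunit cyclic order contains duplicate labels")
    for chain in residue_table.chains:
        if chain not in chains:
            raise ConfigError(f"chain {chain!r} present in topology but not in chain map")
    for chain, lab in chains.items():
        if lab not in labels:
            raise ConfigError(f"chain {chain!r} mapped to unknown subunit {lab!r}")
    if set(neighbor) != labels or set(neighbor.values()) != labels:
        raise ConfigError("neighbor relation is not a bijection on the subunit labels")
    if len(labels) > 1 and any(k == v for k, v in neighbor.items()):
        raise ConfigError("neighbor relation must have no fixed points")
    return SubunitMap(order=order, neighbor=neighbor, label_of_chain=chains)


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> Path:
    """Write a multi-model PDB (MODEL/ENDMDL records) usable as a fixture."""
    import MDAnalysis as mda

    path = Path(path)
    table = traj.residue_table
    n_res = len(table)
    atom_res = []
    names = []
    for i, e in enumerate(table):
        n_in_res = 1 + len([j for j in e.sidechain_indices if j != e.calpha_index])
        atom_res.extend([i] * n_in_res)
        names.append("CA")
        names.extend(f"CB" for j in e.sidechain_indices if j != e.calpha_index)

    # Column order inside the written file: per residue, CA then side chain.
    order = []
    for e in table:
        order.append(e.calpha_index)
        order.extend(j for j in e.sidechain_indices if j != e.calpha_index)
    order = np.array(order, dtype=int)

    u = mda.Universe.empty(
        n_atoms=len(order), n_residues=n_res, n_segments=len(table.chains),
        atom_resindex=np.array(atom_res),
        residue_segindex=np.array(
            [table.chains.index(e.chain) for e in table]
        ),
        trajectory=True,
    )
    u.add_TopologyAttr("name", names)
    u.add_TopologyAttr("resname", [e.resname for e in table])
    u.add_TopologyAttr("resid", [e.resid for e in table])
    u.add_TopologyAttr("segid", list(table.chains))
    u.add_TopologyAttr("chainID", [table.entries[r].chain for r in atom_res])
    with mda.Writer(str(path), n_atoms=len(order), multiframe=True) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coordinates[f, order, :]
            w.write(u.atoms)
    return path


def residue_table_tsv(
    table: ResidueTable, path: str | Path, smap: SubunitMap | None = None
) -> Path:
    """Write the residue table as TSV (chain, resid, resname, subunit)."""
    import pandas as pd

    rows = [
        {
            "chain": e.chain,
            "resid": e.resid,
            "resname": e.resname,
            "subunit": smap.label_of(e.chain) if smap is not None else e.chain,
        }
        for e in table
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
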