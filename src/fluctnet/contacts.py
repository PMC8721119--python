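"""Residue contact probabilities and persistent-contact maps.

Two residues are in contact in a frame when any pair of their side-chain
heavy atoms is closer than the cutoff (5.0 Å by default); a *persistent*
contact is one present in at least the occupancy fraction of frames (75% by
default, inclusive). Glycine, having no side-chain heavy atom, is represented
by its Cα. The single-subunit consensus map keeps the contacts formed in at
least ``min_subunits`` of the subunits (3 of 4 by default), folding
swap-interface pairs through the configured neighbor relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError
from .trajectory import SubunitMap, Trajectory

#: Above this many frame×atom² distance evaluations, switch to the k-d tree.
_DENSE_BUDGET = 2e9


@dataclass
class ContactMap:
    """Contact probabilities plus the occupancy-thresholded boolean map."""

    probabilities: np.ndarray  # (n_res, n_res), symmetric, zero diagonal
    keys: tuple[str, ...]
    cutoff: float
    occupancy: float
    atom_rule: str = "side-chain heavy atoms (Cα surrogate for Gly)"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        n = len(self.keys)
        if p.shape != (n, n):
            raise ConsistencyError(f"probability matrix shape {p.shape} != ({n}, {n})")
        if p.min() < 0 or p.max() > 1:
            raise ConsistencyError("contact probabilities outside [0, 1]")
        if not np.allclose(p, p.T):
            raise ConsistencyError("contact probabilities not symmetric")
        self.probabilities = p

    @property
    def bool_map(self) -> np.ndarray:
        """True iff the pair is in contact for >= occupancy of frames.

        In the degenerate occupancy = 0 limit this marks every pair that is
        *ever* within the cutoff (never-touching pairs stay excluded).
        """
        b = (self.probabilities >= self.occupancy) & (self.probabilities > 0)
        np.fill_diagonal(b, False)
        return b

    def probability(self, key_i: str, key_j: str) -> float:
        i = self.keys.index(key_i)
        j = self.keys.index(key_j)
        return float(self.probabilities[i, j])


@dataclass
class ConsensusMap:
    """Single-subunit boolean map: true where >= min_subunits subunits agree."""

    counts: np.ndarray  # (n_local, n_local) int
    resids: tuple[int, ...]  # within-subunit residue numbers
    min_subunits: int
    n_subunits: int

    @property
    def bool_map(self) -> np.ndarray:
        b = self.counts >= self.min_subunits
        np.fill_diagonal(b, False)
        return b


def _sidechain_layout(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat side-chain atom indices, their residue ids, residue start offsets."""
    table = traj.residue_table
    atom_idx, res_of = [], []
    starts = []
    for r, e in enumerate(table):
        starts.append(len(atom_idx))
        atom_idx.extend(e.sidechain_indices)
        res_of.extend([r] * len(e.sidechain_indices))
    return np.array(atom_idx, int), np.array(res_of, int), np.array(starts, int)


def _counts_dense(traj: Trajectory, cutoff: float, chunk: int = 256) -> np.ndarray:
    """All-pairs scan, vectorized: per-frame residue-pair minimum distance."""
    atom_idx, _, starts = _sidechain_layout(traj)
    n_res = len(traj.residue_table)
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    sc = traj.coordinates[:, atom_idx, :]
    for lo in range(0, traj.n_frames, chunk):
        block = sc[lo : lo + chunk]  # (C, A, 3)
        d = np.linalg.norm(block[:, :, None, :] - block[:, None, :, :], axis=-1)
        # Reduce atoms -> residues with a running minimum along both axes.
        d = np.minimum.reduceat(d, starts, axis=1)
        d = np.minimum.reduceat(d, starts, axis=2)
        counts += (d < cutoff).sum(axis=0)
    np.fill_diagonal(counts, 0)
    return counts


def _counts_kdtree(traj: Trajectory, cutoff: float) -> np.ndarray:
    """Spatial-neighbor acceleration; result identical to the all-pairs scan."""
    atom_idx, res_of, _ = _sidechain_layout(traj)
    n_res = len(traj.residue_table)
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    for f in range(traj.n_frames):
        pts = traj.coordinates[f, atom_idx, :]
        pairs = cKDTree(pts).query_pairs(cutoff, output_type="ndarray")
        if pairs.size == 0:
            continue
        # query_pairs uses <=; the contact rule is strictly '<'.
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
        ri, rj = res_of[pairs[:, 0]], res_of[pairs[:, 1]]
        keep = ri != rj
        pair_ids = np.unique(
            np.minimum(ri[keep], rj[keep]) * n_res + np.maximum(ri[keep], rj[keep])
        )
        counts[pair_ids // n_res, pair_ids % n_res] += 1
    return counts + counts.T


def contact_map(
    traj: Trajectory,
    cutoff: float = 5.0,
    occupancy: float = 0.75,
    method: str = "auto",
) -> ContactMap:
    """Full symmetric contact map over all residue pairs.

    ``method`` is ``"dense"`` (vectorized all-pairs scan), ``"kdtree"``
    (spatial-neighbor acceleration, identical result), or ``"auto"``.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError(f"occupancy must be in [0, 1], got {occupancy}")
    n_atoms = sum(len(e.sidechain_indices) for e in traj.residue_table)
    if method == "auto":
        method = "kdtree" if traj.n_frames * n_atoms**2 > _DENSE_BUDGET else "dense"
    if method == "dense":
        counts = _counts_dense(traj, cutoff)
    elif method == "kdtree":
        counts = _counts_kdtree(traj, cutoff)
    else:
        raise ValueError(f"unknown method {method!r}")
    probs = counts.astype(float) / traj.n_frames
    sym = 0.5 * (probs + probs.T)
    return ContactMap(sym, traj.residue_table.keys, cutoff=cutoff, occupancy=occupancy)


def contact_probability(
    traj: Trajectory, pair: tuple[str, str], cutoff: float = 5.0
) -> float:
    """Fraction of frames in which the pair's side chains are within cutoff."""
    table = traj.residue_table
    ei, ej = table[pair[0]], table[pair[1]]
    pi = traj.coordinates[:, list(ei.sidechain_indices), :]
    pj = traj.coordinates[:, list(ej.sidechain_indices), :]
    d = np.linalg.norm(pi[:, :, None, :] - pj[:, None, :, :], axis=-1)
    dmin = d.min(axis=(1, 2))
    return float(np.mean(dmin < cutoff))


def _local_indices(cmap: ContactMap, smap: SubunitMap):
    """Per-subunit residue index arrays, checked for identical numbering."""
    by_label: dict[str, list[tuple[int, int]]] = {lab: [] for lab in smap.labels}
    for idx, key in enumerate(cmap.keys):
        chain, resid = key.split(":")
        by_label[smap.label_of(chain)].append((int(resid), idx))
    resids_ref: tuple[int, ...] | None = None
    order: dict[str, np.ndarray] = {}
    for lab, items in by_label.items():
        items.sort()
        resids = tuple(r for r, _ in items)
        if resids_ref is None:
            resids_ref = resids
        elif resids != resids_ref:
            raise ConsistencyError(
                f"subunit {lab!r} residue numbering differs from the first subunit; "
                "a common within-subunit coordinate is required"
            )
        order[lab] = np.array([i for _, i in items], int)
    assert resids_ref is not None
    return resids_ref, order


def subunit_consensus(
    cmap: ContactMap, smap: SubunitMap, min_subunits: int = 3
) -> ConsensusMap:
    """Fold the whole-protein map into one subunit, voting across subunits.

    For each subunit k, a local pair (a, b) is *present in k* if it is an
    intra-subunit contact in k or a swap-interface contact between k and
    neighbor(k) in either orientation. The consensus keeps pairs present in at
    least ``min_subunits`` subunits.
    """
    if min_subunits < 1:
        raise ValueError("min_subunits must be >= 1")
    resids, order = _local_indices(cmap, smap)
    b = cmap.bool_map
    counts = np.zeros((len(resids), len(resids)), dtype=np.int64)
    for lab in smap.labels:
        k = order[lab]
        nk = order[smap.neighbor_of(lab)]
        intra = b[np.ix_(k, k)]
        swap = b[np.ix_(k, nk)]
        present = intra | swap | swap.T
        counts += present
    return ConsensusMap(counts, resids, min_subunits=min_subunits,
                        n_subunits=len(smap.labels))


# ---------------------------------------------------------------------------
# exports

def contacts_tsv(cmap: ContactMap, path: str | Path, all_pairs: bool = False) -> Path:
    import pandas as pd

    rows = []
    n = len(cmap.keys)
    b = cmap.bool_map
    for i in range(n):
        for j in range(i + 1, n):
            if all_pairs or cmap.probabilities[i, j] > 0:
                rows.append(
                    {
                        "res_i": cmap.keys[i],
                        "res_j": cmap.keys[j],
                        "probability": cmap.probabilities[i, j],
                        "contact": bool(b[i, j]),
                    }
                )
    path = Path(path)
    pd.DataFrame(rows, columns=["res_i", "res_j", "probability", "contact"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def contact_map_mtx(matrix: np.ndarray, path: str | Path) -> Path:
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    path = Path(path)
    mmwrite(str(path), coo_matrix(matrix.astype(np.int8)))
    return path


def render_contact_map(matrix: np.ndarray, path: str | Path, title: str = "") -> Path:
    """Dot-style contact map rendering (black dots on white)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ii, jj = np.nonzero(matrix)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(ii, jj, s=2, c="black", marker="s")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
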