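"""Fluctuation correlation matrix and the weighted residue network.

The correlation coefficient between residues *i* and *j* is the normalized
covariance of their Cα displacement vectors over the trajectory,

    Corr_ij = <δr_i · δr_j> / sqrt(<|δr_i|²> <|δr_j|²>),   δr = r − <r>,

and the network edge weight is d_ij = −ln|Corr_ij|: zero for perfectly
correlated motion, growing without bound as the correlation vanishes. Edges
exist exactly for residue pairs in persistent side-chain contact, so the
graph encodes motion propagation through physically interacting residues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np

from .errors import ConsistencyError, DegenerateVarianceError
from .trajectory import Trajectory

if TYPE_CHECKING:  # pragma: no cover
    from .contacts import ContactMap

logger = logging.getLogger(__name__)

#: |corr| may exceed 1 by at most this much before it is a domain error.
CORR_TOL = 1e-8


@dataclass
class CorrelationMatrix:
    """Symmetric residue×residue matrix of normalized Cα covariances."""

    values: np.ndarray
    keys: tuple[str, ...]
    n_frames: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.keys)
        if v.shape != (n, n):
            raise ConsistencyError(f"matrix shape {v.shape} does not match {n} residues")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ConsistencyError("correlation matrix is not symmetric")
        if np.abs(np.diag(v) - 1.0).max() > 1e-10:
            raise ConsistencyError("correlation matrix diagonal is not 1")
        if np.abs(v).max() > 1.0 + CORR_TOL:
            raise ConsistencyError("correlation entries outside [-1, 1]")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.keys.index(pair[0])
        j = self.keys.index(pair[1])
        return float(self.values[i, j])


def correlation_matrix(traj: Trajectory, require_superposed: bool = True) -> CorrelationMatrix:
    """Normalized covariance of Cα positions over the trajectory frames.

    ``require_superposed`` guards against computing correlations on frames
    still carrying rigid-body drift; pass ``False`` only deliberately.
    """
    if require_superposed and not traj.superposed:
        raise ConsistencyError(
            "trajectory is not superposed; call superpose() first or pass "
            "require_superposed=False to override"
        )
    ca = traj.calpha_coordinates
    delta = ca - ca.mean(axis=0, keepdims=True)
    # <δr_i · δr_j>: average over frames of the 3-D dot product.
    cov = np.einsum("fia,fja->ij", delta, delta) / traj.n_frames
    var = np.diag(cov).copy()
    bad = np.flatnonzero(var <= 0.0)
    if bad.size:
        keys = [traj.residue_table.keys[i] for i in bad[:5]]
        raise DegenerateVarianceError(
            f"zero positional variance for residue(s) {', '.join(keys)}"
        )
    corr = cov / np.sqrt(np.outer(var, var))
    over = np.abs(corr).max() - 1.0
    if over > CORR_TOL:
        raise ConsistencyError(f"correlation exceeds 1 by {over:.3e}")
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, traj.residue_table.keys, n_frames=traj.n_frames)


def edge_weight(corr):
    """Edge weight d = −ln|corr| (natural log; +inf for |corr| = 0).

    Natural log makes a path-length difference of two units correspond to
    roughly one order of magnitude (e² ≈ 7.4) in the correlation product.
    Negative correlations are taken in absolute value: anti-correlated motion
    transmits information equally well, and −log of a negative number is
    undefined. Accepts scalars or arrays.
    """
    a = np.abs(np.asarray(corr, dtype=float))
    if a.size and a.max() > 1.0 + CORR_TOL:
        raise ValueError(f"|corr| = {a.max():.6g} outside [0, 1]")
    a = np.minimum(a, 1.0)
    with np.errstate(divide="ignore"):
        w = -np.log(a)
    return float(w) if np.isscalar(corr) or np.asarray(corr).ndim == 0 else w


def build_network(corr: CorrelationMatrix, contacts: "ContactMap") -> nx.Graph:
    """Weighted undirected residue graph gated by persistent contacts.

    One node per residue; an edge for exactly the residue pairs marked as
    persistent contacts, weighted by −ln|Corr_ij|. Pairs with Corr_ij = 0
    (infinite weight) are dropped and logged. Each edge stores the underlying
    correlation (``corr``) and its sign.
    """
    if tuple(contacts.keys) != tuple(corr.keys):
        raise ConsistencyError("correlation matrix and contact map residue orders differ")
    g = nx.Graph()
    g.add_nodes_from(corr.keys)
    ii, jj = np.nonzero(np.triu(contacts.bool_map, k=1))
    dropped = 0
    for i, j in zip(ii.tolist(), jj.tolist()):
        c = float(corr.values[i, j])
        if c == 0.0:
            dropped += 1
            continue
        g.add_edge(
            corr.keys[i],
            corr.keys[j],
            weight=edge_weight(c),
            corr=c,
            sign=1 if c > 0 else -1,
        )
    if dropped:
        logger.info("dropped %d zero-correlation contact pair(s) (infinite weight)", dropped)
    return g


# ---------------------------------------------------------------------------
# exports

def correlation_to_tsv(corr: CorrelationMatrix, path: str | Path) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame(corr.values, index=list(corr.keys), columns=list(corr.keys)).to_csv(
        path, sep="\t"
    )
    return path


def save_correlation(corr: CorrelationMatrix, path: str | Path) -> Path:
    """Dense binary matrix (.npy) plus a JSON sidecar with residue order."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), corr.values)
    sidecar = {
        "residues": list(corr.keys),
        "n_frames": corr.n_frames,
        "matrix_file": path.with_suffix(".npy").name,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npy")


def load_correlation(path: str | Path) -> CorrelationMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    values = np.load(path.with_suffix(".npy"))
    return CorrelationMatrix(values, tuple(meta["residues"]), n_frames=meta.get("n_frames"))


def network_to_graphml(net: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(net, path)
    return path


def network_edges_tsv(net: nx.Graph, path: str | Path) -> Path:
    import pandas as pd

    rows = [
        {"res_i": u, "res_j": v, "corr": d["corr"], "weight": d["weight"]}
        for u, v, d in net.edges(data=True)
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["res_i", "res_j", "corr", "weight"]).to_csv(
        path, sep="\t", index=False
    )
    return path
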