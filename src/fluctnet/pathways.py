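"""Source/sink regions, shortest allosteric pathways, and centrality.

Regions are spheres (default radius 6 Å) around anchor Cα atoms, with
membership requiring the residue's Cα inside the sphere for at least the
occupancy fraction of frames. Shortest paths between regions minimize the
summed edge weights −ln|Corr_ij| over all source-member × sink-member pairs
(Dijkstra with a deterministic lexicographic tie-break). Betweenness is the
source/sink-restricted Brandes accumulation; the centrality index (CI) of a
residue is the fraction of near-optimal source–sink paths that contain it.
"""

from __future__ import annotations

import heapq
import logging
import math
import warnings
from dataclasses import dataclass
from itertools import count
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import DisconnectionError, ResidueLookupError
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

#: Relative tolerance when testing d(s,v) + d(v,t) == d(s,t) for floats
#: accumulated in different association orders.
_PATH_SUM_RTOL = 1e-9

VSD_SF = "VSD-SF"
PD_SF = "PD-SF"


@dataclass(frozen=True)
class Region:
    """Sphere-defined residue set around an anchor Cα."""

    anchor: str
    radius: float
    occupancy: float
    members: tuple[str, ...]
    subunit: str | None = None

    def __contains__(self, key: str) -> bool:
        return key in self.members


@dataclass
class PathResult:
    """An optimal source→sink residue path and its length."""

    residues: tuple[str, ...]
    edge_weights: tuple[float, ...]
    total_length: float
    subunit: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        assert len(self.edge_weights) == max(len(self.residues) - 1, 0)
        assert abs(self.total_length - sum(self.edge_weights)) <= 1e-10


@dataclass
class CentralityRecord:
    """Per-residue betweenness/CI row, banded as in the reporting tables."""

    residue: str | int
    betweenness: float
    centrality_index: float | None
    band: str
    zero_betweenness: bool = False


def define_region(
    traj: Trajectory,
    anchor: str,
    radius: float = 6.0,
    occupancy: float = 0.75,
    subunit: str | None = None,
) -> Region:
    """Residues whose Cα stays within ``radius`` of the anchor Cα.

    Membership requires the Cα–Cα distance below ``radius`` in at least
    ``occupancy`` (inclusive) of the frames; the anchor is always a member.
    """
    table = traj.residue_table
    a = table[anchor]  # raises ResidueLookupError for unknown anchors
    ca = traj.calpha_coordinates
    anchor_pos = traj.coordinates[:, a.calpha_index, :]
    d = np.linalg.norm(ca - anchor_pos[:, None, :], axis=-1)
    frac = np.mean(d < radius, axis=0)
    members = [k for k, f in zip(table.keys, frac) if f >= occupancy]
    if anchor not in members:
        members.append(anchor)
    return Region(
        anchor=anchor,
        radius=radius,
        occupancy=occupancy,
        members=tuple(sorted(members)),
        subunit=subunit,
    )


def _dijkstra_lex(
    net: nx.Graph, sources: Sequence[str], targets: frozenset[str]
) -> tuple[float, tuple[str, ...]] | None:
    """Min-weight path from any source to any target.

    Heap entries are ``(distance, path)`` so that among equal-length
    alternatives the lexicographically smallest residue-key sequence is
    settled first, making the output deterministic.
    """
    heap: list[tuple[float, tuple[str, ...]]] = [
        (0.0, (s,)) for s in sorted(sources) if s in net
    ]
    heapq.heapify(heap)
    settled: set[str] = set()
    while heap:
        dist, path = heapq.heappop(heap)
        u = path[-1]
        if u in settled:
            continue
        settled.add(u)
        if u in targets:
            return dist, path
        for v, data in sorted(net[u].items()):
            if v not in settled:
                heapq.heappush(heap, (dist + data["weight"], path + (v,)))
    return None


def shortest_path(
    net: nx.Graph,
    source: Region,
    sink: Region,
    family: str | None = None,
    subunit: str | None = None,
) -> PathResult:
    """Minimum-total-weight path over all source-member × sink-member pairs.

    If the regions share a residue the result is a zero-length single-node
    path. Raises :class:`DisconnectionError`, listing component sizes, when
    no member pair is connected.
    """
    src = [s for s in source.members if s in net]
    dst = frozenset(t for t in sink.members if t in net)
    if not src or not dst:
        raise DisconnectionError("source or sink region has no residue in the network")
    hit = _dijkstra_lex(net, src, dst)
    if hit is None:
        sizes = sorted((len(c) for c in nx.connected_components(net)), reverse=True)
        raise DisconnectionError(
            f"no path between source {source.anchor} and sink {sink.anchor}; "
            f"network component sizes: {sizes[:10]}"
        )
    dist, path = hit
    weights = tuple(net[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
    return PathResult(
        residues=path,
        edge_weights=weights,
        total_length=float(sum(weights)),
        subunit=subunit if subunit is not None else source.subunit,
        family=family,
    )


def average_path_length(paths: Sequence[PathResult]) -> float:
    """Arithmetic mean of the per-subunit path lengths of one family."""
    if not paths:
        raise ValueError("average_path_length needs at least one path")
    families = {p.family for p in paths}
    if len(families) > 1:
        raise ValueError(f"paths mix families {sorted(map(str, families))}")
    return float(np.mean([p.total_length for p in paths]))


def _sssp_counts(net: nx.Graph, s: str) -> tuple[dict[str, float], dict[str, float]]:
    """Dijkstra distances and shortest-path counts (σ) from ``s``."""
    dist: dict[str, float] = {}
    sigma: dict[str, float] = {s: 1.0}
    seen: dict[str, float] = {s: 0.0}
    c = count()
    heap: list[tuple[float, int, str]] = [(0.0, next(c), s)]
    while heap:
        d, _, u = heapq.heappop(heap)
        if u in dist:
            continue
        dist[u] = d
        for v, data in net[u].items():
            dv = d + data["weight"]
            if v not in dist and (v not in seen or dv < seen[v]):
                seen[v] = dv
                sigma[v] = sigma[u]
                heapq.heappush(heap, (dv, next(c), v))
            elif v not in dist and dv == seen[v]:
                sigma[v] += sigma[u]
    return dist, sigma


def betweenness(
    net: nx.Graph,
    sources: Sequence[Region],
    sinks: Sequence[Region],
) -> dict[str, float]:
    """Source/sink-restricted node betweenness (Brandes-style accumulation).

    For every region pair (zipped ``sources``/``sinks``, one per subunit) and
    every member pair (s, t), each node v ∉ {s, t} accrues σ_st(v)/σ_st, the
    fraction of shortest s–t paths through v. Disconnected pairs contribute
    nothing.
    """
    if len(sources) != len(sinks):
        raise ValueError("sources and sinks must pair up one per subunit")
    b: dict[str, float] = {v: 0.0 for v in net.nodes}
    cache: dict[str, tuple[dict[str, float], dict[str, float]]] = {}

    def counts(node: str):
        if node not in cache:
            cache[node] = _sssp_counts(net, node)
        return cache[node]

    for src, snk in zip(sources, sinks):
        for s in src.members:
            if s not in net:
                continue
            dist_s, sigma_s = counts(s)
            for t in snk.members:
                if t == s or t not in net or t not in dist_s:
                    continue
                dist_t, sigma_t = counts(t)
                d_st = dist_s[t]
                tol = _PATH_SUM_RTOL * (1.0 + abs(d_st))
                for v in net.nodes:
                    if v == s or v == t or v not in dist_s or v not in dist_t:
                        continue
                    if abs(dist_s[v] + dist_t[v] - d_st) <= tol:
                        b[v] += sigma_s[v] * sigma_t[v] / sigma_s[t]
    return b


def near_optimal_paths(
    net: nx.Graph,
    source: Region,
    sink: Region,
    epsilon: float = 1.0,
    k_max: int = 200,
) -> list[tuple[tuple[str, ...], float]]:
    """Enumerate source→sink paths with length ≤ shortest + epsilon.

    Uses Yen's k-shortest-paths on an auxiliary graph with zero-weight super
    source/sink nodes, capped at ``k_max`` paths (warning if the cap is hit
    before the length bound).
    """
    aux = net.copy()
    SRC, SNK = "\x00SRC", "\x00SNK"
    aux.add_node(SRC)
    aux.add_node(SNK)
    for s in source.members:
        if s in net:
            aux.add_edge(SRC, s, weight=0.0)
    for t in sink.members:
        if t in net:
            aux.add_edge(SNK, t, weight=0.0)
    if aux.degree(SRC) == 0 or aux.degree(SNK) == 0:
        raise DisconnectionError("source or sink region has no residue in the network")
    out: list[tuple[tuple[str, ...], float]] = []
    best: float | None = None
    try:
        gen = nx.shortest_simple_paths(aux, SRC, SNK, weight="weight")
        for k, path in enumerate(gen):
            length = sum(aux[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
            if best is None:
                best = length
            if length > best + epsilon + 1e-12:
                break
            out.append((tuple(path[1:-1]), length))
            if k + 1 >= k_max:
                warnings.warn(
                    f"k_max={k_max} paths enumerated before reaching the length "
                    "bound; CI computed on the enumerated set",
                    stacklevel=2,
                )
                break
    except nx.NetworkXNoPath:
        raise DisconnectionError(
            f"no path between source {source.anchor} and sink {sink.anchor}"
        ) from None
    return out


def centrality_index(
    net: nx.Graph,
    source: Region,
    sink: Region,
    epsilon: float = 1.0,
    k_max: int = 200,
) -> dict[str, float]:
    """CI(v): fraction of near-optimal source–sink paths containing v."""
    paths = near_optimal_paths(net, source, sink, epsilon=epsilon, k_max=k_max)
    ci: dict[str, float] = {v: 0.0 for v in net.nodes}
    for path, _ in paths:
        for v in set(path):
            ci[v] += 1.0
    n = len(paths)
    return {v: c / n for v, c in ci.items()}


def pooled_centrality_index(
    paths_per_pair: Sequence[Sequence[tuple[tuple[str, ...], float]]],
    fold=None,
) -> dict:
    """CI pooled over several region pairs (one per subunit).

    ``fold`` optionally maps a residue key onto a shared label (e.g. the
    within-subunit residue number) so that symmetry-equivalent residues
    accumulate together, as in a per-residue reporting table.
    """
    total = 0
    hits: dict = {}
    for paths in paths_per_pair:
        for path, _ in paths:
            total += 1
            labels = {fold(v) if fold else v for v in path}
            for lab in labels:
                hits[lab] = hits.get(lab, 0) + 1
    if total == 0:
        return {}
    return {lab: c / total for lab, c in hits.items()}


def band_betweenness(b: float, b_max: float) -> str:
    """Band a betweenness value: low (0, 1], medium (1, 4], high (4, B_max]."""
    if b < 0:
        raise ValueError(f"betweenness must be >= 0, got {b}")
    if b > b_max + 1e-12:
        raise ValueError(f"betweenness {b} exceeds the stated maximum {b_max}")
    if b <= 1.0:
        return "low"
    if b <= 4.0:
        return "medium"
    return "high"


def centrality_records(
    bet: Mapping, ci: Mapping | None = None
) -> list[CentralityRecord]:
    """Assemble banded records from betweenness (and optional CI) maps."""
    b_max = max(bet.values(), default=0.0)
    records = []
    for key in sorted(bet, key=str):
        b = bet[key]
        records.append(
            CentralityRecord(
                residue=key,
                betweenness=float(b),
                centrality_index=float(ci[key]) if ci and key in ci else None,
                band=band_betweenness(b, b_max),
                zero_betweenness=(b == 0.0),
            )
        )
    return records


def compare_runs(reference, variant) -> dict[str, dict]:
    """Per-family path-length comparison between two analysis results.

    Both arguments need ``settings`` (dict) and ``average_lengths``
    (family → mean per-subunit length). Reports Δlength = variant − reference,
    the correlation-product ratio exp(Δlength), and a qualitative flag:
    ``hindered`` for Δ ≥ 2 (one order of magnitude lost in the correlation
    product), ``enhanced`` for Δ ≤ −0.3, else ``comparable``.
    """
    from .errors import ComparisonError

    if reference.settings != variant.settings:
        diff = {
            k
            for k in set(reference.settings) | set(variant.settings)
            if reference.settings.get(k) != variant.settings.get(k)
        }
        raise ComparisonError(f"settings differ between runs: {sorted(diff)}")
    report: dict[str, dict] = {}
    for fam, ref_len in reference.average_lengths.items():
        if fam not in variant.average_lengths:
            raise ComparisonError(f"family {fam!r} missing from the variant result")
        delta = variant.average_lengths[fam] - ref_len
        if delta >= 2.0:
            flag = "hindered"
        elif delta <= -0.3:
            flag = "enhanced"
        else:
            flag = "comparable"
        report[fam] = {
            "reference_length": float(ref_len),
            "variant_length": float(variant.average_lengths[fam]),
            "delta": float(delta),
            "ratio": float(math.exp(delta)),
            "flag": flag,
        }
    return report
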