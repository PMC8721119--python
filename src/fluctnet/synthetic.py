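"""Synthetic trajectories with analytically known correlation structure.

The generator is a bead-spring (Gaussian-network) model of a four-fold
symmetric toy channel: each subunit carries an "S4" (voltage-sensor) segment,
an "S5" and "S6" (pore) segment, and an "SF" (selectivity-filter) segment,
arranged so every subunit's S4 sits against the *neighboring* subunit's S5 —
the swap interface of domain-swapped channels. Equilibrium displacement
covariance is the scaled pseudo-inverse of the spring-connectivity
(Kirchhoff) matrix, so the fluctuation correlation of every bead pair is
known in closed form and serves as the oracle for the estimator built from
sampled frames.

A *planted pathway* — a bead chain running up S4, crossing to the neighbor's
S5, and descending through S6 to the SF — gets stiffer springs (the
``boost``), raising its correlations so the chain is, by construction, the
minimum −ln|Corr| route between the voltage-sensor and filter regions.

Frames are sampled independently (the correlation estimator is static, so
autocorrelation would only shrink the effective sample size) with isotropic
per-bead displacements, the Gaussian-network convention. Each bead carries
one co-located dummy side-chain heavy atom so the side-chain contact rule is
exercised without an all-atom model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .correlation import CorrelationMatrix
from .errors import ConsistencyError, DegeneracyError
from .trajectory import ResidueEntry, ResidueTable, Trajectory, residue_key

SEGMENTS = ("S4", "S5", "S6", "SF")
SUBUNITS = ("A", "B", "C", "D")

#: Vertical bead spacing (Å), the canonical Cα–Cα step.
Z_STEP = 3.8
#: (radius Å, angle °) of each segment's bead column in subunit A.
_S5_POLAR = (10.0, 0.0)
_S6_POLAR = (6.0, 10.0)
_SF_POLAR = (2.6, 20.0)
_S4_POLAR = (11.0, 70.0)
#: Outward tilt (Å of extra radius) of S4 per level away from the cross level.
_S4_TILT = 2.2
#: SF column is shifted one level up: the filter caps the pore.
_SF_Z_OFFSET = Z_STEP


@dataclass(frozen=True)
class BeadTopology:
    """Reference bead geometry with labels and the spring graph."""

    positions: np.ndarray  # (n_beads, 3) Å
    chains: tuple[str, ...]
    resids: tuple[int, ...]
    segments: tuple[str, ...]
    levels: tuple[int, ...]  # z-level index within the segment
    spring_pairs: np.ndarray  # (m, 2) int
    spring_cutoff: float
    n_res_per_subunit: int
    seed: int = 0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(residue_key(c, r) for c, r in zip(self.chains, self.resids))

    def bead(self, chain: str, segment: str, level: int) -> int:
        for i in range(self.n_beads):
            if (
                self.chains[i] == chain
                and self.segments[i] == segment
                and self.levels[i] == level
            ):
                return i
        raise KeyError(f"no bead {chain}/{segment}[{level}]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Sampling conditions for the toy channel.

    ``temperature`` scales the displacement covariance (Å² per unit inverse
    spring constant); the default gives per-axis bead fluctuations of a few
    tenths of an Å, typical of a folded protein's Cα RMSF, and small enough
    that the native contact topology persists in sampled frames.
    """

    n_frames: int = 20_000
    seed: int = 0
    spring_constant: float = 1.0
    boost: float = 15.0  # spring multiplier along the planted chain
    temperature: float = 0.1
    planted: bool = True
    rigid_motion: bool = False
    rigid_amplitude: float = 5.0  # translation range (Å) when injecting drift

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConsistencyError("n_frames must be >= 2")


def segment_sizes(n_res_per_subunit: int) -> dict[str, int]:
    """Bead count per segment; every segment keeps at least two beads."""
    if n_res_per_subunit < 8:
        raise ValueError("need at least 8 residues per subunit")
    k, r = divmod(n_res_per_subunit, 4)
    return {"S4": k + (r > 0), "S5": k + (r > 1), "S6": k + (r > 2), "SF": k}


def _quarter_turn(xy: np.ndarray, times: int) -> np.ndarray:
    """Exact rotation by 90°·times about z: (x, y) → (−y, x)."""
    out = xy.copy()
    for _ in range(times % 4):
        out = np.stack([-out[:, 1], out[:, 0], out[:, 2]], axis=1)
    return out


def build_toy_tetramer(
    n_res_per_subunit: int = 10, seed: int = 0, spring_cutoff: float = 4.6
) -> BeadTopology:
    """Four-fold symmetric toy channel with a swap interface.

    Subunit A is built explicitly; B, C, D are exact quarter-turn images, so
    the reference coordinates have exact C4 symmetry. Within each chain,
    residues are numbered 1..n in segment order S4, S5, S6, SF, bottom-up.
    """
    sizes = segment_sizes(n_res_per_subunit)
    jc = min(sizes["S4"], sizes["S5"]) - 1  # swap-interface crossing level

    pos_a, seg_a, lvl_a = [], [], []
    for seg in SEGMENTS:
        n = sizes[seg]
        if seg == "S4":
            for i in range(n):
                radius = _S4_POLAR[0] + _S4_TILT * abs(i - jc)
                theta = np.deg2rad(_S4_POLAR[1])
                pos_a.append((radius * np.cos(theta), radius * np.sin(theta), Z_STEP * i))
                seg_a.append(seg)
                lvl_a.append(i)
        else:
            radius, theta_deg = {"S5": _S5_POLAR, "S6": _S6_POLAR, "SF": _SF_POLAR}[seg]
            theta = np.deg2rad(theta_deg)
            z0 = _SF_Z_OFFSET if seg == "SF" else 0.0
            for i in range(n):
                pos_a.append((radius * np.cos(theta), radius * np.sin(theta), z0 + Z_STEP * i))
                seg_a.append(seg)
                lvl_a.append(i)

    pos_a = np.asarray(pos_a, dtype=float)
    positions, chains, resids, segments, levels = [], [], [], [], []
    for s, chain in enumerate(SUBUNITS):
        positions.append(_quarter_turn(pos_a, s))
        chains.extend([chain] * len(pos_a))
        resids.extend(range(1, len(pos_a) + 1))
        segments.extend(seg_a)
        levels.extend(lvl_a)
    positions = np.concatenate(positions, axis=0)

    d = squareform(pdist(positions))
    ii, jj = np.nonzero(np.triu(d < spring_cutoff, k=1))
    pairs = np.stack([ii, jj], axis=1)

    topo = BeadTopology(
        positions=positions,
        chains=tuple(chains),
        resids=tuple(resids),
        segments=tuple(segments),
        levels=tuple(levels),
        spring_pairs=pairs,
        spring_cutoff=spring_cutoff,
        n_res_per_subunit=n_res_per_subunit,
        seed=seed,
    )
    adj = csr_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(len(positions),) * 2
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise DegeneracyError(
            f"spring graph splits into {n_comp} components at cutoff "
            f"{spring_cutoff} Å; the covariance pseudo-inverse would be degenerate"
        )
    return topo


def neighbor_subunit(chain: str) -> str:
    """Cyclic A→B→C→D→A: whose S5/pore a given subunit's S4 packs against."""
    return SUBUNITS[(SUBUNITS.index(chain) + 1) % 4]


def toy_chain_map() -> dict:
    return {
        "chains": {c: c for c in SUBUNITS},
        "order": list(SUBUNITS),
        "neighbor": {c: neighbor_subunit(c) for c in SUBUNITS},
    }


def toy_anchor_resids(n_res_per_subunit: int = 10) -> dict[str, int]:
    """Default region anchors: bottom of S4, bottom of S6, top of SF."""
    sizes = segment_sizes(n_res_per_subunit)
    return {
        "s4_anchor": 1,
        "s6_anchor": sizes["S4"] + sizes["S5"] + 1,
        "sf_anchor": n_res_per_subunit,
    }


def planted_chain(topo: BeadTopology, chain: str = "A") -> tuple[str, ...]:
    """The boosted bead chain seeded in ``chain``: S4 up, cross, pore down.

    Runs from the bottom of the subunit's S4 to the crossing level, jumps to
    the neighboring subunit's S5, descends to the pore level, and ends on the
    neighbor's selectivity filter.
    """
    sizes = segment_sizes(topo.n_res_per_subunit)
    jc = min(sizes["S4"], sizes["S5"]) - 1
    nk = neighbor_subunit(chain)
    beads = [topo.bead(chain, "S4", i) for i in range(jc + 1)]
    beads += [topo.bead(nk, "S5", i) for i in range(jc, 0, -1)]
    beads += [topo.bead(nk, "S6", 1), topo.bead(nk, "SF", 0)]
    return tuple(topo.keys[b] for b in beads)


def _planted_pair_set(topo: BeadTopology) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    key_index = {k: i for i, k in enumerate(topo.keys)}
    for chain in SUBUNITS:
        keys = planted_chain(topo, chain)
        for a, b in zip(keys[:-1], keys[1:]):
            i, j = key_index[a], key_index[b]
            pairs.add((min(i, j), max(i, j)))
    return pairs


def kirchhoff_matrix(topo: BeadTopology, spec: SyntheticSpec) -> np.ndarray:
    """Spring-connectivity matrix Γ with per-pair spring constants."""
    n = topo.n_beads
    gamma = np.zeros((n, n))
    planted = _planted_pair_set(topo) if spec.planted else set()
    for i, j in topo.spring_pairs:
        k = spec.spring_constant
        if (min(i, j), max(i, j)) in planted:
            k *= spec.boost
        gamma[i, j] -= k
        gamma[j, i] -= k
    np.fill_diagonal(gamma, -gamma.sum(axis=1))
    return gamma


def _kirchhoff_pinv(topo: BeadTopology, spec: SyntheticSpec) -> np.ndarray:
    """Pseudo-inverse of the Kirchhoff matrix (per-axis covariance kernel)."""
    gamma = kirchhoff_matrix(topo, spec)
    evals, evecs = np.linalg.eigh(gamma)
    tol = 1e-9 * evals.max()
    null = evals < tol
    if null.sum() != 1:
        raise DegeneracyError(
            f"Kirchhoff matrix has {int(null.sum())} null modes; expected exactly 1 "
            "(connected spring graph)"
        )
    inv = np.where(null, 0.0, 1.0 / np.where(null, 1.0, evals))
    return (evecs * inv) @ evecs.T


def _rigid_basis(positions: np.ndarray) -> np.ndarray:
    """Orthonormal basis of rigid-body displacement fields, (3N, k), k ≤ 6."""
    n = positions.shape[0]
    centered = positions - positions.mean(axis=0)
    modes = []
    for a in range(3):  # translations
        m = np.zeros((n, 3))
        m[:, a] = 1.0
        modes.append(m.ravel())
    for a in range(3):  # infinitesimal rotations about the centroid
        axis = np.zeros(3)
        axis[a] = 1.0
        modes.append(np.cross(axis, centered).ravel())
    b = np.stack(modes, axis=1)
    u, s, _ = np.linalg.svd(b, full_matrices=False)
    return u[:, s > 1e-9 * s.max()]


def _covariance3(topo: BeadTopology, spec: SyntheticSpec) -> np.ndarray:
    """Full 3N×3N displacement covariance, rigid-body subspace projected out.

    The per-axis kernel is temperature × Γ⁺ (isotropic, the Gaussian-network
    convention). Equilibrium fluctuations are defined modulo rigid motion —
    exactly what frame superposition removes — so the covariance is projected
    orthogonal to the six rigid-body modes; superposition of sampled frames
    is then a no-op in expectation and the closed-form correlations remain an
    exact oracle for the superposed estimator. Layout: index 3·bead + axis.
    """
    pinv = _kirchhoff_pinv(topo, spec)
    n = topo.n_beads
    cov = np.zeros((3 * n, 3 * n))
    for a in range(3):
        cov[a::3, a::3] = spec.temperature * pinv
    q = _rigid_basis(topo.positions)
    cov -= q @ (q.T @ cov)
    cov -= (cov @ q) @ q.T
    return 0.5 * (cov + cov.T)


def analytic_correlations(topo: BeadTopology, spec: SyntheticSpec) -> CorrelationMatrix:
    """Closed-form fluctuation correlations of the bead model.

    Corr_ij = tr C_ij / sqrt(tr C_ii · tr C_jj), where C_ij is the 3×3
    cross-covariance block of beads i and j — the population value of the
    normalized Cα covariance the estimator computes from frames.
    """
    cov = _covariance3(topo, spec)
    n = topo.n_beads
    dot = cov.reshape(n, 3, n, 3)
    traces = np.einsum("iaja->ij", dot)
    d = np.sqrt(np.diag(traces))
    corr = traces / np.outer(d, d)
    corr = 0.5 * (corr + corr.T)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, topo.keys, n_frames=None)


def _residue_table(topo: BeadTopology) -> ResidueTable:
    entries = []
    for i in range(topo.n_beads):
        entries.append(
            ResidueEntry(
                key=topo.keys[i],
                chain=topo.chains[i],
                resid=topo.resids[i],
                resname="ALA",
                calpha_index=2 * i,
                sidechain_indices=(2 * i + 1,),
            )
        )
    return ResidueTable(entries)


def _beads_to_atoms(bead_coords: np.ndarray) -> np.ndarray:
    """(F, N, 3) bead coordinates → (F, 2N, 3) with a co-located CB per bead."""
    return np.repeat(bead_coords, 2, axis=1)


def reference_trajectory(topo: BeadTopology, n_frames: int = 2) -> Trajectory:
    """Zero-fluctuation trajectory: the reference structure repeated."""
    beads = np.broadcast_to(
        topo.positions, (n_frames, topo.n_beads, 3)
    ).copy()
    return Trajectory(_beads_to_atoms(beads), _residue_table(topo), superposed=True)


def sample_frames(topo: BeadTopology, spec: SyntheticSpec) -> Trajectory:
    """Draw independent Gaussian frames with the analytic covariance.

    Displacements are drawn from the rigid-body-free covariance of
    :func:`analytic_correlations` (per-axis kernel ``temperature × Γ⁺``) and
    added to the reference structure. Optional rigid-body motion (random
    rotation plus uniform translation) is injected afterwards for
    superposition tests. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cov = _covariance3(topo, spec)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-10 * max(evals.max(), 1.0):
        raise DegeneracyError("covariance is not positive semidefinite")
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((spec.n_frames, 3 * topo.n_beads))
    disp = (z @ root.T).reshape(spec.n_frames, topo.n_beads, 3)
    beads = topo.positions[None, :, :] + disp
    if spec.rigid_motion:
        from scipy.spatial.transform import Rotation

        rots = Rotation.random(spec.n_frames, random_state=rng).as_matrix()
        trans = rng.uniform(-spec.rigid_amplitude, spec.rigid_amplitude,
                            size=(spec.n_frames, 3))
        beads = np.einsum("fni,fij->fnj", beads, rots) + trans[:, None, :]
    return Trajectory(
        _beads_to_atoms(beads), _residue_table(topo), superposed=not spec.rigid_motion
    )


def scripted_contact_fixture(
    fractions: Sequence[float],
    n_frames: int,
    seed: int = 0,
    cutoff: float = 5.0,
) -> tuple[Trajectory, dict[tuple[str, str], float]]:
    """Trajectory with scripted residue-pair contact fractions.

    Builds one well-separated residue pair per requested fraction (residues
    ``A:2k+1``/``A:2k+2``); in a seeded random subset of ``round(f·n_frames)``
    frames the pair sits 3 Å apart (< cutoff), otherwise at cutoff + 3 Å, so
    the realized in-contact fraction equals the request to within
    ``1/n_frames``. Returns the trajectory and the mapping pair → realized
    fraction.
    """
    if n_frames < 2:
        raise ConsistencyError("n_frames must be >= 2")
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"contact fraction {f} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_pairs = len(fractions)
    beads = np.zeros((n_frames, 2 * n_pairs, 3))
    expected: dict[tuple[str, str], float] = {}
    entries = []
    for k, f in enumerate(fractions):
        y = 30.0 * k
        zig = 5.0 * (k % 2)  # keep the Cα set non-collinear for superposition
        i, j = 2 * k, 2 * k + 1
        beads[:, i] = (0.0, y, zig)
        x = np.full(n_frames, cutoff + 3.0)
        n_in = int(round(f * n_frames))
        in_frames = rng.permutation(n_frames)[:n_in]
        x[in_frames] = 3.0
        beads[:, j, 0] = x
        beads[:, j, 1] = y
        beads[:, j, 2] = zig
        key_i, key_j = residue_key("A", i + 1), residue_key("A", j + 1)
        expected[(key_i, key_j)] = n_in / n_frames
        for idx, key in ((i, key_i), (j, key_j)):
            entries.append(
                ResidueEntry(
                    key=key, chain="A", resid=idx + 1, resname="ALA",
                    calpha_index=2 * idx, sidechain_indices=(2 * idx + 1,),
                )
            )
    traj = Trajectory(_beads_to_atoms(beads), ResidueTable(entries), superposed=True)
    return traj, expected


def write_fixture(
    traj: Trajectory,
    topo: BeadTopology,
    spec: SyntheticSpec,
    out_dir: str | Path,
    name: str = "toy_tetramer",
) -> dict[str, Path]:
    """Write the fixture as a multi-model PDB plus a JSON manifest."""
    from dataclasses import asdict

    from .correlation import save_correlation
    from .trajectory import write_trajectory_pdb

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb = write_trajectory_pdb(traj, out_dir / f"{name}.pdb")
    corr = analytic_correlations(topo, spec)
    corr_file = save_correlation(corr, out_dir / f"{name}_analytic_corr")
    manifest = {
        "spec": asdict(spec),
        "n_res_per_subunit": topo.n_res_per_subunit,
        "spring_cutoff": topo.spring_cutoff,
        "seed": spec.seed,
        "trajectory": pdb.name,
        "analytic_correlations": corr_file.name,
    }
    (out_dir / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"pdb": pdb, "correlations": corr_file,
            "manifest": out_dir / f"{name}_manifest.json"}
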