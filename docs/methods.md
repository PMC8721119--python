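# Methods

`fluctnet` implements dynamical network analysis of equilibrium protein
trajectories: it quantifies how motion propagates between distant functional
regions (allosteric coupling) by combining a fluctuation-correlation metric
with graph shortest-path machinery. The package was designed around the
voltage-gated K⁺ channel use case — detecting the routes that couple the
voltage-sensor domain (VSD) and the pore domain (PD) to the selectivity
filter (SF) in a domain-swapped homotetramer — but every stage operates on
generic chains/residues.

## The model

**Correlation metric.** For residues *i*, *j* with Cα positions
r⃗ᵢ(t), r⃗ⱼ(t) over frames t:

    Corr_ij = ⟨δr⃗ᵢ · δr⃗ⱼ⟩ / √(⟨|δr⃗ᵢ|²⟩ ⟨|δr⃗ⱼ|²⟩),   δr⃗ = r⃗ − ⟨r⃗⟩,

the normalized covariance of the 3-D displacement vectors, in [−1, 1].
Frames are iteratively least-squares superposed on the mean Cα structure
first (default on, disable with `--no-superpose`): unremoved rigid-body
drift correlates every residue with every other and would dominate the
metric. Whether to superpose is genuinely open in this kind of analysis; we
default to superposing because the alternative is only correct if the input
trajectory was already aligned upstream.

**Edge weights.** The residue graph weights each edge

    d_ij = −ln |Corr_ij|,

zero only for perfect correlation, +∞ (edge dropped) for zero correlation.
*Natural* logarithm: a path-length difference of two units then corresponds
to roughly one order of magnitude (e² ≈ 7.4) in the product of correlations
along the path, which is the interpretation used when comparing wild-type
and mutant runs. Negative correlations enter through their absolute value —
anti-correlated motion transmits information equally well, and the log of a
negative number is undefined — with the sign kept as an edge attribute for
reporting.

**Edge gating.** Edges exist exactly for residue pairs in *persistent
contact*: a pair of side-chain heavy atoms closer than 5.0 Å (strict) in at
least 75% (inclusive) of frames. Glycine contributes its Cα as a side-chain
surrogate. Sequential neighbors (i, i±1) are *not* excluded: physically
meaningful pathways run through consecutive helix residues. Gating by
contacts rather than by a correlation floor keeps edges physical
(information flows through interacting residues), at the cost of depending
on the contact thresholds; both are exposed in the config.

**Regions and paths.** Source and sink regions are spheres (default 6 Å
radius) around anchor Cα atoms, membership requiring the residue's Cα inside
the sphere in ≥ 75% of frames. Anchors are mandatory config fields — they
encode the biological question (e.g. an S4 residue for the voltage sensor, a
filter tyrosine for the sink) and have no universal default. Two path
families are computed per subunit: VSD→SF, whose sink is the filter of the
*neighboring* subunit (the swap interface of domain-swapped channels, with
the neighbor relation an explicit, directed part of the configuration), and
PD→SF within one subunit. The reported path is the minimum total-weight
route over all source-member × sink-member pairs (Dijkstra); family lengths
are arithmetic means over the four subunits. Ties are broken toward the
lexicographically smallest residue-key sequence, making outputs fully
deterministic.

**Centrality.** Betweenness is the source/sink-restricted Brandes
accumulation: node v accrues σ_st(v)/σ_st over all member pairs (s, t) of
all subunits' region pairs. All-pairs betweenness on a ~2000-node protein
graph would produce values orders of magnitude above the low/medium/high
reporting bands (low 0 < B ≤ 1, medium 1 < B ≤ 4, high 4 < B ≤ B_max), so
restriction to the analysis endpoints is the only consistent reading. The
centrality index CI(v) is the fraction of *near-optimal* source–sink paths
containing v: paths within `ci_epsilon` (default 1.0, i.e. within a factor
≈ e of the optimal correlation product) of the shortest length, enumerated
with Yen's algorithm capped at `ci_k_max` (default 200; a warning is issued
and CI is computed on the enumerated set if the cap is hit first). This CI
definition is a reconstruction — near-optimal-path fraction is the standard
family of such indices — and both parameters are config-exposed. In
reporting tables, betweenness and CI are aggregated by within-subunit
residue number, so the four symmetry copies of a residue accumulate into one
row.

**Comparison.** `compare_runs` requires identical settings, then reports per
family Δlength = variant − reference, the correlation-product ratio
exp(Δlength), and a flag: *hindered* for Δ ≥ 2 (an order of magnitude of
correlation lost), *enhanced* for Δ ≤ −0.3, else *comparable*. The −0.3
threshold is a reporting heuristic chosen to flag shifts clearly outside
per-subunit scatter, not a modeling statement.

## The synthetic generator

`fluctnet.synthetic` emulates equilibrium Cα fluctuations with a bead-spring
Gaussian network model (GNM), giving every pipeline stage an exact oracle.

**Geometry.** `build_toy_tetramer(n)` places four exact quarter-turn images
of one subunit around the z axis (rotation by multiples of 90° is applied as
the exact index/sign map (x, y) → (−y, x), so the reference has *exact* C4
symmetry). Each subunit is four vertical bead columns at 3.8 Å spacing:
"S4" (radius 11 Å, tilted outward away from one crossing level), "S5"
(10 Å), "S6" (6 Å), and "SF" (2.6 Å, shifted one level up: the filter caps
the pore). Angles are chosen so each S4's crossing bead sits 3.8 Å from the
*neighboring* subunit's S5 column — the swap interface — while all other
inter-column gaps respect the 5 Å contact cutoff's intent (bonded ~3.5–4.4 Å,
non-bonded > 5 Å), so the persistent-contact graph of sampled frames equals
the spring graph. Spring cutoff 4.6 Å.

**Statistics.** With Kirchhoff matrix Γ (spring constants on the diagonal
sums), the per-axis displacement covariance is temperature × Γ⁺. Because
equilibrium fluctuation analysis is defined modulo rigid-body motion —
exactly what superposition removes — the full 3N×3N covariance is projected
orthogonal to the six rigid-body modes before use. Sampling from the
projected covariance makes superposition a no-op in expectation, and the
closed-form correlations Corr_ij = tr C_ij / √(tr C_ii tr C_jj) remain an
exact oracle for the superposed estimator; without the projection, the
torsional content of the soft GNM modes is partially removed by the fit and
the estimator would be biased by ~0.3 at some pairs. Frames are drawn
independently (the estimator is static; autocorrelation would only shrink
the effective sample size) with isotropic per-bead displacements, the GNM
convention. The default temperature (0.1) gives per-axis bead fluctuations
of ~0.15–0.3 Å, typical folded-protein Cα RMSF and small enough that the
native contact topology persists in sampled frames. Each bead carries one
co-located dummy side-chain heavy atom so the side-chain contact rule is
exercised without an all-atom model.

**Planted pathway.** The chain bottom-of-S4 → crossing level → neighbor's S5
→ neighbor's S6 → neighbor's SF (and its three C4 images) receives springs
multiplied by `boost` (default 15), which raises its correlations to ~0.9
per step; every off-chain step costs ≥ 3× more weight, so the chain is the
minimum-weight source→sink route by construction. "Mutants" are made by
lowering the boost. With 10 beads per subunit the analytic wild-type VSD→SF
family length is ≈ 0.82 and drops of boost to 1 raise it to ≈ 1.79.

**Scripted contacts.** `scripted_contact_fixture` builds isolated residue
pairs whose in-contact frame counts are placed exactly (3 Å in a seeded
random subset of round(f·n) frames, cutoff + 3 Å otherwise), to test the
inclusive-75% rule at the boundary (750/1000 in, 749/1000 out).

**Toy-model region radius.** Pipeline runs on the toy tetramer use a 4.2 Å
region radius instead of the 6 Å real-protein default: with 3.8 Å bead
spacing and a miniature pore, 6 Å spheres leak across segments (the S6 and
SF spheres would overlap, collapsing the PD→SF family to zero-length paths).
At 4.2 Å the source sphere is exactly the planted chain's first bead and the
sink sphere contains its last, so "recovery" is literal equality of the
returned path with the planted chain.

## What passing tests do and do not show

The generator reproduces the *statistics* the estimator assumes — Gaussian,
stationary, independent frames, exact symmetry, one dominant pathway — not
the physics of a membrane protein. Passing tests therefore validate the
estimator, the gating, the graph algorithms, their determinism, and the
statistical error scaling (max error ≤ 3·n^(−1/2), halving per 4× frames).
They do not validate force-field realism, sampling convergence of real MD,
contact definitions for all-atom side chains beyond the rule as stated, or
anchor choices for any particular protein.

## Numerical choices and degenerate inputs

- |Corr| ≤ 1 is enforced with tolerance 1e−8 (clamped); larger excursions
  are errors. A residue with zero positional variance raises an error naming
  the residue.
- Shortest-path tie-breaks are lexicographic; betweenness path counting uses
  exact float equality within a single Dijkstra (as is standard) and a
  1e−9 relative tolerance when combining forward/backward distances.
- The Kirchhoff pseudo-inverse requires exactly one null mode; disconnected
  spring graphs are rejected.
- Coordinates are Å everywhere; inputs whose median bonded Cα–Cα distance is
  below 2 Å are rejected as likely nm-scaled.
- Superposition: iterative mean-structure fit, tolerance 1e−6 Å, max 10
  iterations; fewer than 3 Cα atoms is an error.
- Problem sizes in the validation suite (40-bead tetramer, 10³–10⁵ frames,
  ≤ 9-node enumeration graphs, 10-seed recovery runs) are chosen so the
  statistical claims are sharp at desk scale.

## Known limitations

- The CI definition and the region-anchor choices are reconstructions
  exposed as configuration; published tables computed with other tools may
  bin residues differently.
- Contact-map acceleration assumes non-periodic coordinates; trajectories
  must be unwrapped upstream.
- The whole-protein contact map applies the plain occupancy threshold; the
  3-of-4 consensus vote is only used for the single-subunit (folded) map.
- Betweenness on graphs with many exactly tied shortest paths depends on
  float-equality path counting; with empirical (noisy) weights exact ties do
  not occur.
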