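# fluctnet

Dynamical network analysis of protein trajectories: find the residue
pathways along which motion propagates between distant functional regions.

`fluctnet` is written for structural biologists and simulators studying
allosteric coupling — the motivating system is C-type inactivation in
voltage-gated K⁺ channels, where conformational changes of the voltage
sensor (S4) and of the pore-lining helix (S6) must reach the selectivity
filter — but it works on any multi-chain protein trajectory.

## The method

From an equilibrium trajectory the package computes, per residue pair, the
normalized covariance of Cα displacements

    Corr_ij = ⟨δr⃗ᵢ · δr⃗ⱼ⟩ / √(⟨|δr⃗ᵢ|²⟩ ⟨|δr⃗ⱼ|²⟩),

and builds a weighted residue graph with edge weights

    d_ij = −ln |Corr_ij|

(zero only for perfect correlation), where edges exist exactly for
*persistent contacts*: side-chain heavy atoms closer than 5.0 Å in at least
75% of frames. Source and sink regions are 6 Å spheres around configurable
anchor residues, held for ≥ 75% of frames. The analysis reports, per
subunit, the minimum-weight (Dijkstra) path for two families — voltage
sensor → filter of the *neighboring* subunit (the domain-swap interface)
and pore → filter of the same subunit — plus family-averaged path lengths,
source/sink-restricted betweenness with low/medium/high banding, a
near-optimal-path centrality index, and wild-type-vs-mutant path-length
comparison (a Δ of two units ≈ one order of magnitude in the correlation
product).

A built-in synthetic generator (`fluctnet.synthetic`) produces Gaussian-
network trajectories of a four-fold symmetric toy channel with exactly
known correlations and a planted high-correlation pathway crossing the
subunit interface, so the whole pipeline is testable without any downloads.
See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

Generate a synthetic toy tetramer (10 residues per subunit, 20 000 frames)
and run the full pipeline:

```python
from fluctnet.pipeline import run_toy_pipeline
from fluctnet.pathways import compare_runs

wt = run_toy_pipeline(n_frames=20_000, seed=42)
for p in wt.paths:
    print(f"{p.family:7s} {p.subunit:7s} {p.total_length:.3f}  {'->'.join(p.residues)}")
```

```
VSD-SF  A       0.820  A:1->A:2->A:3->B:6->B:5->B:8->B:9
VSD-SF  B       0.820  B:1->B:2->B:3->C:6->C:5->C:8->C:9
VSD-SF  C       0.823  C:1->C:2->C:3->D:6->D:5->D:8->D:9
VSD-SF  D       0.820  D:1->D:2->D:3->A:6->A:5->A:8->A:9
PD-SF   A       0.154  A:8->A:9
PD-SF   B       0.154  B:8->B:9
PD-SF   C       0.153  C:8->C:9
PD-SF   D       0.155  D:8->D:9
```

Each VSD→SF path climbs the subunit's S4 column (residues 1–3), crosses the
swap interface to the *neighboring* subunit's S5 (residue 6), and descends
through S6 (8) to the filter (9) — exactly the pathway planted in the
generator's boosted springs, recovered independently in all four subunits
with near-identical lengths (~0.82; small scatter is sampling noise). The
short PD→SF paths reflect the direct S6–filter contact. Weakening the
planted springs mimics a pathway-breaking mutation:

```python
mut = run_toy_pipeline(n_frames=20_000, seed=42, boost=1.0)
rep = compare_runs(wt, mut)["VSD-SF"]
print(f"delta={rep['delta']:+.3f} ratio={rep['ratio']:.2f} flag={rep['flag']}")
```

```
delta=+1.375 ratio=3.96 flag=comparable
```

the coupling weakens by a factor ≈ 4 in correlation product (a Δ ≥ 2, i.e.
an order of magnitude, would be flagged `hindered`).

For real trajectories, use the CLI: `fluctnet report --config config.yaml`
runs load → superpose → contacts → correlation → network → paths → report
from a YAML config naming the trajectory, the chain→subunit map with its
neighbor relation, and the three region anchors (S4, S6, SF residue
numbers). `fluctnet simulate`, `contacts`, `correlate`, `network`, `paths`,
and `compare` expose the individual stages; every run writes its fully
resolved config next to its outputs.

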