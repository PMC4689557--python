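# phosdyn

BI/BII backbone dynamics of B-DNA duplexes: state classification from
ε/ζ torsions, facing-phosphate combination statistics with an independence
framework, ³¹P chemical-shift bridging to BII populations, and
state-conditional inter-base-pair parameter coupling — plus a synthetic
duplex-trajectory generator that makes the whole pipeline testable without
trajectories or downloads.

## The problem

The phosphodiester linkage of B-DNA interconverts between two substates,
**BI** (ε *trans*, ζ *gauche−*) and **BII** (ε *gauche−*, ζ *trans*),
and this equilibrium shapes the double helix: BII-containing steps carry
more positive slide, more negative roll and higher twist. For each
complementary dinucleotide NpN·NpN the two *facing* phosphates (one per
strand) jointly occupy BI·BI, BI·BII|BII·BI (hybrid) or BII·BII. Writing
P_i(BII), P_j(BII) for the two marginal BII probabilities,

```
P_ij(hybrid) + 2·P_ij(BII·BII) = P_i(BII) + P_j(BII)        (always)
P_ij(BII·BII) = P_i(BII)·P_j(BII)                           (independence)
P_ij(hybrid)  = P_i + P_j − 2·P_i·P_j                       (independence)
```

The first line is a counting identity; the last two hold when the facing
states are statistically independent — in which case per-phosphate BII
percentages inferred from ³¹P chemical shifts (BII% = 143·δP + 621, δP in
ppm) are enough to reconstruct the pair populations experimentally.
`phosdyn` implements the classification, the combination/transition
statistics, the independence diagnostic, the shift bridge with ±10-point
tolerance propagation, and the combination-conditional helical statistics,
for anyone post-processing DNA MD trajectories or ³¹P NMR tables.

The package consumes plain CSV tables (per-frame torsions/phases and
helical parameters; per-phosphate shifts) that any standard dihedral or
helicoidal post-processor can export; it does not read trajectories or
compute parameters from coordinates.

## Worked example

```python
import phosdyn as P
from phosdyn.synthetic import EmissionSpec, StepDynamicsSpec, default_bii_targets
from phosdyn.topology import enumerate_complementary_steps

topo = P.build_topology("CGCACGTACGCG", "Oligo 4")
targets = default_bii_targets(topo)           # sequence-dependent BII targets
specs = {
    (s1.strand, s1.pos5): StepDynamicsSpec(
        target_bii=(targets[s1], targets[s2]), persistence=0.99
    )
    for s1, s2 in enumerate_complementary_steps(topo)
}
model = P.DuplexBackboneModel.from_synthetic(
    topo, specs, EmissionSpec.pmd_defaults(), n_frames=100_000, seed=42
)
res = model.fit(cutoff=0.0)
print(res.summary())
```

prints

```
Duplex backbone dynamics results
======================================================
duplex:          Oligo 4 (12 bp)
strand 1 (5'-3'): CGCACGTACGCG
strand 2 (5'-3'): CGCGTACGTGCG
frames:          100000
(eps-zeta) cutoff: +0.0 deg (BII strictly above)

mean BII occupancy: 22.0% over 18 phosphates

facing-phosphate combinations (mean over steps, %):
  BI.BI   62.5   BI.BII|BII.BI   31.0   BII.BII    6.4

transition census (types 1-4): 3933 1527 5 8  simultaneous (3+4): 0.24%

independence diagnostic (empirical vs factorised predictions):
  Pearson r hybrid:  0.9930
  Pearson r BII.BII: 0.9962
  counting-identity max |residual|: 5.55e-17

classified vs shift-derived BII% (matched phosphates):
  CC 0.99   mean |diff| 1.2 (1.2)   within +/-10: 100%

helical coupling, BII.BII - BI.BI conditional means:
  slide +0.80 A   roll -11.0 deg   twist +9.8 deg
```

Reading the output: each of the 18 non-terminal phosphates was simulated
as a two-state chain with nanosecond dwell times (persistence 0.99 at
1 ps/frame) and its ε/ζ angles emitted and re-classified at the 0° cutoff.
The facing states were generated independently, and the diagnostic
recovers that: empirical hybrid and BII·BII populations track the
factorised predictions with Pearson r ≥ 0.99, simultaneous two-phosphate
transitions are a fraction of a percent of all transitions, and the
counting identity holds to machine precision. The conditional helical
means recover the generating coupling: BII·BII frames sit +0.8 Å in slide,
−11° in roll and +9.8° in twist relative to BI·BI.

A thin CLI wraps the same library (`phosdyn simulate | states | pairs |
nmr | couple | all`); `phosdyn all --config run.yaml` drives the full
graph from a YAML config and writes a CSV/JSON bundle with provenance
headers.

## Layout

```
src/phosdyn/
  topology.py   duplex sequences, step numbering, facing-step map
  states.py     torsion/pucker classifiers, BI/BII assignment, diagnostics
  pairs.py      combinations, transition census, independence framework
  nmr.py        shift conversion, tolerance bands, comparison statistics
  helical.py    combination-conditional helical statistics
  synthetic.py  two-state Markov generator with coupled emissions
  io.py         CSV formats, run config, pipeline driver
  model.py      DuplexBackboneModel / BackboneResults facade
  cli.py        command-line entry points
docs/methods.md   models, defaults, numerical choices, limitations
```
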