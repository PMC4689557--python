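# Methods

`phosdyn` analyses the BI/BII conformational equilibrium of the B-DNA
phosphodiester backbone from derived per-frame tables (torsions, sugar
phases, inter-base-pair parameters) and per-phosphate ³¹P chemical shifts.
This note records the models, defaults and numerical choices, and what the
synthetic generator does and does not emulate.

## State definition and classification

The phosphate linkage is two-state: BI (ε *trans*, ζ *gauche−*) and BII
(ε *gauche−*, ζ *trans*). Operationally a frame is BII when the wrapped
pseudo-angle δ = (ε − ζ) ∈ [−180°, 180°) strictly exceeds a cutoff; δ equal
to the cutoff is BI. The strict/non-strict choice is immaterial for
continuous data but is fixed and documented here. Two named cutoffs are
provided: 0° (the conventional separation, suited to AMBER-family
histograms whose inter-mode region is flat) and +30° (suited to
CHARMM-family histograms, whose minimum sits at +30° and above which 5′
north sugars vanish). Canonical mode centres are δ ≈ −90° (BI) and
δ ≈ +100° (BII).

Torsions are categorised by the threefold staggered windows g+ = 60 ± 40°,
*trans* = 180 ± 40°, g− = 300 ± 40° (inclusive; anything else is `other`).
Sugar pseudorotation phases are north (300°→50° through the wrap), east
(50–120°), south (120–220°); 220–300° belongs to no category and is
labelled `other`. Half-open upper bounds make the categories a partition.
Note that some figure conventions elsewhere draw north as 0–50° only; we
follow the 300°→50° reading and say so in the run log.

Frames with both ε and ζ *trans* are flagged "ambiguous": they sit in the
inter-mode region (roughly δ ∈ [−60°, +70°]) where BI/BII categorisation is
intrinsically unclear. They are still classified by the cutoff rule (no
third state), the mask is informational.

### Cutoff suggestion

`suggest_cutoff` pools δ over phosphates, bins at 5° (configurable),
applies a 3-bin moving average, finds the two highest interior local maxima
separated by at least 60°, and proposes the minimum between them; ties
across a flat minimum resolve to the middle tied bin. The valley is
accepted only when (smaller mode peak)/(valley height) ≥ 1.5; otherwise the
result is "ambiguous" with the conventional fallback of 0°. No standard
numeric rule exists for this decision; these defaults are exposed as
parameters.

## Facing-phosphate statistics

Facing phosphates of a complementary dinucleotide NpN·NpN are joined into
ordered combinations (BI·BI, BI·BII, BII·BI, BII·BII); the hybrids are
pooled as BI·BII|BII·BI throughout, with the ordered split retained
internally. For marginals P_i(BII), P_j(BII) the counting identity

    P_ij(hybrid) + 2 P_ij(BII·BII) = P_i(BII) + P_j(BII)

holds for any joint law and is computed as a per-step residual — an exact
invariant used as a labelling self-check. Under independence the pair
probabilities factorise: P_ij(BII·BII) = P_i P_j and
P_ij(hybrid) = P_i + P_j − 2 P_i P_j. The independence diagnostic compares
frame-counted populations against these predictions built from each step's
own empirical marginals, and reports one Pearson correlation per pooled
category across steps (the two coefficients are reported separately).
Degenerate steps (a marginal exactly 0 or 1) are excluded from the
correlation and listed.

Each step additionally carries a 2×2 odds ratio with Haldane–Anscombe 0.5
correction for empty cells. Because trajectory frames are serially
correlated, the log-OR standard error is inflated by an effective sample
size n_eff = n(1 − ρ)/(1 + ρ) from the lag-1 autocorrelation ρ of the state
indicators; this significance is advisory only and labelled as such.

Transitions are counted between consecutive saved frames with no
minimum-dwell filtering, in four types: (1) BI·BI ↔ hybrid, (2) hybrid ↔
BII·BII, (3) BI·BII ↔ BII·BI, (4) BI·BI ↔ BII·BII. Types 3 and 4 require
both phosphates to change within one frame interval; their share of all
transitions is the "simultaneous transition" fraction. The frame interval
is carried as metadata (default 1 ps) so users can coarsen.

## Shift bridge

³¹P shifts (ppm, trimethyl-phosphate reference, 30 °C assumed; no
re-referencing logic) convert by the empirical calibration
BII% = 143·δP + 621. The conversion can exceed [0, 100]; values are clamped
with the raw value preserved, because the calibration is empirical. Its
exact inverse, δP = (BII% − 621)/143, is what the generator uses to
synthesise shift tables, so the round trip is exact at zero noise. A
±10-point tolerance half-width (configurable) is attached to every
converted value; note that δP_av = −4.20 ppm converts to 20.4% by direct
arithmetic — the implementation always reports the raw arithmetic rather
than any rounded convention.

NMR-based combination populations apply the factorised predictions to the
shift-derived BII fractions of the two facing phosphates. All three
populations are bilinear in (p_i, p_j), so tolerance bands propagate
exactly by evaluating the four corners of the band rectangle (a bilinear
function has no interior extrema, only saddles); widening the band widens
every interval (monotone by construction).

Comparison statistics between matched BII% vectors: Pearson (linear)
correlation, reported as undefined when either vector has zero variance;
Δ_av = mean |sim − exp| with its SD computed across phosphates; and the
fraction of phosphates agreeing within the tolerance.
Per-dinucleotide aggregation types steps by their single-strand NpN and
reports occurrence count, mean and SD for types above a minimum count
(default N > 3).

## Helical coupling

Conditional means/SDs of shift, slide, rise, tilt, roll and twist are
computed per pooled combination, either merging frames across all
complementary steps ("pooled") or per step; frames are weighted equally in
both scopes. Combinations observed fewer than `min_frames` (default 100)
frames are omitted — SDs on tiny samples are noise. `delta_extremes`
reports the BII·BII minus BI·BI mean difference per parameter;
`variability_by_combination` tabulates per-step SDs and summarises whether
BI·BI is at least as variable as the BII-containing combinations in every
retained step (the stiffening comparison).

## Synthetic generator

The generator exists so every downstream stage is testable without MD or
downloads; its defaults are the study conditions.

**Latent dynamics.** Each phosphate is a stationary two-state Markov chain
with stationary BII probability p and persistence a: per frame it refreshes
with probability (1 − a) and redraws Bernoulli(p), i.e. q(BI→BII) = (1−a)p,
q(BII→BI) = (1−a)(1−p); mean sojourns are 1/((1−a)p) frames in BI and
1/((1−a)(1−p)) in BII. Default a = 0.99 at 1 ps frames gives
nanosecond-scale dwellings, matching the rapid (nano-picosecond)
BI↔BII exchange regime; no kinetic model is claimed beyond controllable
marginals and dwell times.

**Cross-strand coupling.** A log odds ratio κ selects the 2×2 joint law
with the two marginals and odds ratio e^κ via the closed-form Plackett
solution (valid for every finite κ). Each phosphate refreshes independently
with probability (1 − a); on a joint refresh the pair redraws jointly, on a
single refresh the phosphate redraws from the conditional given its
partner's current state. Every move (identity, Gibbs coordinate update,
joint redraw) leaves the target law invariant, so the stationary per-frame
joint is exact; at κ = 0 the kernel reduces exactly to two independent
chains.

**Emissions.** Torsions are state-conditional Gaussians (wrapped):
BI ε ~ N(185°, 8°), ζ ~ N(275°, 8°); BII ε ~ N(260°, 8°), ζ ~ N(160°, 8°),
centring δ at −90°/+100°. Sugar phases come from a north/east/south
Gaussian mixture (components N(20°, 15°), N(85°, 15°), N(160°, 20°)) with
state-dependent weights; BII 5′ sugars are south-only, so generated BII
frames never carry 5′ north phases. Helical parameters are drawn from
combination-conditional Gaussians; the two presets are the pooled
conditional tables of the AMBER-family and CHARMM-family trajectories
(slide −0.2/+0.2/+0.6 Å, roll +4/−0.5/−7°, twist 31.9/37.9/41.7° for
BI·BI/hybrid/BII·BII in the AMBER-family preset, with the quoted SDs);
shift and tilt are centred at 0 (invariant), rise at 3.3/3.4/3.5 Å so the
extreme difference stays within the 0.2 Å bound. Shift tables are
synthesised by exact inversion of the conversion plus optional Gaussian
ppm noise.

**Per-sequence defaults.** Convenience stationary BII targets per
dinucleotide type ship with the package (seeded from the NMR aggregation
over the study dodecamers: CpT/GpT/TpT 0, ApC 0.12, ApA 0.16, TpA 0.17,
ApG 0.19, GpC 0.31, CpG 0.41; fallback 0.19, the overall average). They are
editable convenience values, not a propensity-scale model.

**Seeding.** One integer seed expands through `numpy.random.SeedSequence`
substreams per pair and per stage, so chains, angle emissions, helical
emissions and shift noise are independently reproducible.

**What the generator does not emulate.** No atomic coordinates, energetics,
solvent or sequence-dependent kinetics; emissions are unimodal Gaussians
per state (real torsion distributions are skewed and cross-correlated
beyond the two-state structure); the latent dynamics are memoryless given
the state, so non-Markovian dwell-time distributions are not represented.
Passing tests therefore validate the counting, identities and estimator
behaviour of the pipeline — not force-field realism.

## Benchmark problem sizes

The packaged statistical checks run 36 synthetic complementary steps (the
four study dodecamers, central-step convention) for 10⁵ frames at 1 ps,
stationary BII probabilities spaced over 0.05–0.8 and assigned pairwise to
the 72 phosphates, persistence 0.99. With these settings the per-step
effective sample size is ≈ 10³, enough for the independence correlations
(≥ 0.99) while keeping a full run in seconds on one core. The coupling
recovery benchmark uses one dodecamer (9 steps) with p_i = p_j = 0.4, which
populates all three pooled combinations heavily (≈ 36%/48%/16%).

## Design choices and limitations

- 1-based continuous base numbering (1..L, L+1..2L; base j pairs 2L+1−j)
  matches the residue-label convention of dodecamer studies and appears in
  all outputs.
- Terminal steps are excluded by default (central-base-pair convention);
  narrower windows are a user-supplied step subset.
- Sequences are unmodified ACGT, fully complementary; no mismatches,
  overhangs or modified bases.
- Missing frames are rejected, not imputed, to keep transition statistics
  well defined.
- No hidden-Markov smoothing, no kinetic rate fitting, no helical-parameter
  computation from coordinates, no δP prediction from structure.
- The per-step association test's significance is advisory (autocorrelated
  frames); the primary independence evidence is the across-step
  empirical-versus-predicted agreement.
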