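"""Synthetic duplex trajectories with the statistical structure of B-DNA backbones.

Each phosphate linkage is modelled as a two-state (BI/BII) discrete-time
Markov chain parameterised by its stationary BII probability p and a
persistence a in [0, 1): per frame the chain refreshes with probability
(1 - a) and redraws its state from Bernoulli(p), equivalent to transition
probabilities q(BI->BII) = (1-a) p and q(BII->BI) = (1-a)(1-p).  At a 1 ps
frame interval the default a = 0.99 gives the nanosecond-scale dwell times
seen for the BI <-> BII exchange.

Facing phosphates may be coupled: a log-odds-ratio kappa selects the 2x2
joint law with the two stationary marginals and odds ratio exp(kappa)
(Plackett construction, closed form).  Each phosphate still refreshes
independently with probability (1 - a); a refresh redraws from the joint
law (jointly when both refresh, from the conditional given the partner's
current state when only one does).  Every move leaves the joint law
invariant, so the stationary per-frame joint distribution is exact, and at
kappa = 0 the kernel reduces exactly to two independent chains.

On top of the latent states the generator emits state-conditional
epsilon/zeta torsions (BI centred at (eps - zeta) = -90 deg, BII at
+100 deg), sugar pseudorotation phases (BII restricted to 5' south),
combination-conditional helical parameters, and 31P shifts obtained by
inverting the shift-to-BII conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .helical import HELICAL_PARAMS, HelicalSeries
from .nmr import ShiftTable, shift_for_bii
from .pairs import POOLED_LABELS, PairSeries
from .states import BackboneSeries, StateSeries
from .topology import DuplexTopology, StepIdentity, enumerate_complementary_steps

__all__ = [
    "StepDynamicsSpec",
    "EmissionSpec",
    "plackett_joint",
    "simulate_state_chains",
    "emit_backbone",
    "simulate_backbone",
    "simulate_helical",
    "simulate_shifts",
    "default_bii_targets",
    "sojourn_lengths",
    "DEFAULT_DINUCLEOTIDE_BII",
]


@dataclass(frozen=True)
class StepDynamicsSpec:
    """Dynamics of one facing-phosphate pair.

    Parameters
    ----------
    target_bii : float or (float, float)
        Stationary BII probability; a pair gives (strand-1, strand-2)
        separately, a scalar applies to both.
    persistence : float
        Autocorrelation parameter a in [0, 1); per-frame refresh
        probability is 1 - a.  Mean sojourns are 1/((1-a) p) frames in BI
        and 1/((1-a)(1-p)) in BII.
    cross_strand_association : float
        Log odds ratio kappa of the per-frame joint law of the two facing
        states; 0 means statistically independent phosphates.
    """

    target_bii: float | tuple[float, float] = 0.2
    persistence: float = 0.99
    cross_strand_association: float = 0.0

    def __post_init__(self) -> None:
        p1, p2 = self.targets
        for p in (p1, p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"target_bii {p} outside [0, 1]")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError(f"persistence {self.persistence} outside [0, 1)")
        # implied transition probabilities (1-a)p and (1-a)(1-p) are then in [0,1]
        if not np.isfinite(self.cross_strand_association):
            raise ValueError("cross_strand_association must be finite")

    @property
    def targets(self) -> tuple[float, float]:
        t = self.target_bii
        if isinstance(t, (tuple, list)):
            return float(t[0]), float(t[1])
        return float(t), float(t)


def plackett_joint(p_i: float, p_j: float, kappa: float = 0.0) -> np.ndarray:
    """2x2 joint law with marginals (p_i, p_j) and odds ratio exp(kappa).

    Returns ``pi`` with ``pi[x, y] = P(strand1 = x, strand2 = y)`` where 1
    means BII.  The closed-form Plackett solution of
    ``(p11 p00)/(p10 p01) = psi`` is used; it exists and is a valid
    distribution for every finite kappa and marginals in [0, 1].
    """
    if not (0.0 <= p_i <= 1.0 and 0.0 <= p_j <= 1.0):
        raise ValueError("marginals must lie in [0, 1]")
    psi = float(np.exp(kappa))
    if psi == 1.0 or p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        p11 = p_i * p_j
    else:
        s = 1.0 + (p_i + p_j) * (psi - 1.0)
        disc = s * s - 4.0 * psi * (psi - 1.0) * p_i * p_j
        p11 = (s - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    pi = np.array(
        [
            [1.0 - p_i - p_j + p11, p_j - p11],
            [p_i - p11, p11],
        ]
    )
    if np.any(pi < -1e-12) or np.any(pi > 1.0 + 1e-12):
        raise ValueError(
            f"association kappa={kappa} incompatible with marginals "
            f"({p_i}, {p_j}): joint cell outside [0, 1]"
        )
    return np.clip(pi, 0.0, 1.0)


def _independent_chain(p: float, a: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """One stationary two-state chain via the refresh representation."""
    refresh = rng.random(n) < (1.0 - a)
    refresh[0] = True  # frame 0 drawn from the stationary law
    draws = rng.random(n) < p
    last = np.maximum.accumulate(np.where(refresh, np.arange(n), -1))
    return draws[last]


def _coupled_pair_chain(
    pi: np.ndarray, a: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Joint chain of a facing pair with stationary 2x2 law ``pi``."""
    m_i = pi[1, :].sum()  # P(strand1 = BII)
    m_j = pi[:, 1].sum()
    # conditionals P(x=1 | y) and P(y=1 | x)
    col = pi.sum(axis=0)
    row = pi.sum(axis=1)
    cond_i = np.array(
        [pi[1, y] / col[y] if col[y] > 0 else m_i for y in (0, 1)]
    )
    cond_j = np.array(
        [pi[x, 1] / row[x] if row[x] > 0 else m_j for x in (0, 1)]
    )
    cum = np.cumsum(pi.ravel())  # order: (0,0), (0,1), (1,0), (1,1)

    r1 = rng.random(n) < (1.0 - a)
    r2 = rng.random(n) < (1.0 - a)
    r1[0] = r2[0] = True
    u_joint = rng.random(n)
    u1 = rng.random(n)
    u2 = rng.random(n)
    x = np.empty(n, dtype=bool)
    y = np.empty(n, dtype=bool)
    cx = cy = False
    for t in range(n):
        if r1[t] and r2[t]:
            k = int(np.searchsorted(cum, u_joint[t], side="right"))
            cx, cy = bool(k & 2), bool(k & 1)
        elif r1[t]:
            cx = u1[t] < cond_i[int(cy)]
        elif r2[t]:
            cy = u2[t] < cond_j[int(cx)]
        x[t] = cx
        y[t] = cy
    return x, y


def _normalise_specs(
    pairs: list[tuple[StepIdentity, StepIdentity]],
    specs,
) -> dict[tuple[int, int], StepDynamicsSpec]:
    if isinstance(specs, StepDynamicsSpec):
        return {(s1.strand, s1.pos5): specs for s1, _ in pairs}
    out = {}
    by_key = {}
    for key, sp in specs.items():
        if isinstance(key, StepIdentity):
            by_key[(key.strand, key.pos5)] = sp
        else:
            by_key[tuple(key)] = sp
    for s1, _ in pairs:
        k = (s1.strand, s1.pos5)
        if k not in by_key:
            raise KeyError(f"no dynamics spec for step {s1.label()}")
        out[k] = by_key[k]
    return out


def simulate_state_chains(
    topology: DuplexTopology,
    specs,
    n_frames: int,
    seed,
    exclude_terminal: bool = True,
    frame_interval: float = 1.0,
) -> StateSeries:
    """Latent BI/BII chains for every complementary step of the duplex.

    ``specs`` is one :class:`StepDynamicsSpec` for all steps or a mapping
    from strand-1 step (or ``(strand, pos5)``) to specs.  Returns the exact
    latent states; emit observable angles with :func:`emit_backbone`.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    pairs = enumerate_complementary_steps(topology, exclude_terminal)
    spec_of = _normalise_specs(pairs, specs)
    ss = np.random.SeedSequence(_as_entropy(seed))
    children = ss.spawn(len(pairs))
    phosphates: list[StepIdentity] = []
    rows: list[np.ndarray] = []
    for (s1, s2), child in zip(pairs, children):
        sp = spec_of[(s1.strand, s1.pos5)]
        p1, p2 = sp.targets
        rng = np.random.default_rng(child)
        if sp.cross_strand_association == 0.0:
            x = _independent_chain(p1, sp.persistence, n_frames, rng)
            y = _independent_chain(p2, sp.persistence, n_frames, rng)
        else:
            pi = plackett_joint(p1, p2, sp.cross_strand_association)
            x, y = _coupled_pair_chain(pi, sp.persistence, n_frames, rng)
        phosphates.extend([s1, s2])
        rows.extend([x, y])
    return StateSeries(
        phosphates=phosphates,
        is_bii=np.vstack(rows),
        cutoff=float("nan"),  # latent truth, not threshold-derived
        ambiguous=np.zeros((len(rows), n_frames), dtype=bool),
    )


def _as_entropy(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        raise TypeError("pass an integer seed")
    return int(seed)


_DEF_PUCKER_COMPONENTS = {"north": (20.0, 15.0), "east": (85.0, 15.0), "south": (160.0, 20.0)}


def _pmd_helical() -> dict[str, dict[str, tuple[float, float]]]:
    return {
        "BI.BI": {
            "shift": (0.0, 0.4), "slide": (-0.2, 0.3), "rise": (3.3, 0.2),
            "tilt": (0.0, 3.0), "roll": (4.0, 3.7), "twist": (31.9, 1.9),
        },
        "BI.BII|BII.BI": {
            "shift": (0.0, 0.4), "slide": (0.2, 0.3), "rise": (3.4, 0.2),
            "tilt": (0.0, 3.0), "roll": (-0.5, 3.3), "twist": (37.9, 2.3),
        },
        "BII.BII": {
            "shift": (0.0, 0.4), "slide": (0.6, 0.3), "rise": (3.5, 0.2),
            "tilt": (0.0, 3.0), "roll": (-7.0, 4.3), "twist": (41.7, 3.8),
        },
    }


def _cmd_helical() -> dict[str, dict[str, tuple[float, float]]]:
    return {
        "BI.BI": {
            "shift": (0.0, 0.4), "slide": (-0.2, 0.2), "rise": (3.3, 0.2),
            "tilt": (0.0, 3.0), "roll": (3.8, 3.7), "twist": (33.7, 3.0),
        },
        "BI.BII|BII.BI": {
            "shift": (0.0, 0.4), "slide": (0.2, 0.2), "rise": (3.4, 0.2),
            "tilt": (0.0, 3.0), "roll": (-3.0, 3.6), "twist": (36.5, 2.6),
        },
        "BII.BII": {
            "shift": (0.0, 0.4), "slide": (0.6, 0.2), "rise": (3.5, 0.2),
            "tilt": (0.0, 3.0), "roll": (-9.9, 4.1), "twist": (39.3, 2.6),
        },
    }


@dataclass
class EmissionSpec:
    """State-conditional emission distributions for the generator.

    Torsion entries are (mean, SD) in degrees; the BI pair centres
    (eps - zeta) at -90 deg and the BII pair at +100 deg.  Sugar phases are
    drawn from a north/east/south Gaussian mixture with state-dependent
    weights; BII 5' sugars are south-only, reflecting the suppression of 5'
    north puckers in BII.  Helical entries are (mean, SD) per pooled
    combination per parameter; the two presets correspond to the pooled
    conditional tables of the AMBER-family ("pmd") and CHARMM-family
    ("cmd") trajectories.
    """

    bi_epsilon: tuple[float, float] = (185.0, 8.0)
    bi_zeta: tuple[float, float] = (275.0, 8.0)
    bii_epsilon: tuple[float, float] = (260.0, 8.0)
    bii_zeta: tuple[float, float] = (160.0, 8.0)
    pucker_components: dict = field(default_factory=lambda: dict(_DEF_PUCKER_COMPONENTS))
    phase5_weights: dict = field(
        default_factory=lambda: {
            "BI": {"north": 0.10, "east": 0.15, "south": 0.75},
            "BII": {"south": 1.0},
        }
    )
    phase3_weights: dict = field(
        default_factory=lambda: {
            "BI": {"north": 0.05, "east": 0.10, "south": 0.85},
            "BII": {"east": 0.05, "south": 0.95},
        }
    )
    helical: dict = field(default_factory=_pmd_helical)
    shift_noise_sd: float = 0.0  # ppm

    @classmethod
    def pmd_defaults(cls) -> "EmissionSpec":
        return cls(helical=_pmd_helical())

    @classmethod
    def cmd_defaults(cls) -> "EmissionSpec":
        return cls(helical=_cmd_helical())

    def zero_noise(self) -> "EmissionSpec":
        """Copy with all emission SDs set to zero (means only)."""
        z = EmissionSpec(
            bi_epsilon=(self.bi_epsilon[0], 0.0),
            bi_zeta=(self.bi_zeta[0], 0.0),
            bii_epsilon=(self.bii_epsilon[0], 0.0),
            bii_zeta=(self.bii_zeta[0], 0.0),
            pucker_components={k: (m, 0.0) for k, (m, s) in self.pucker_components.items()},
            phase5_weights=self.phase5_weights,
            phase3_weights=self.phase3_weights,
            helical={
                comb: {p: (m, 0.0) for p, (m, s) in d.items()}
                for comb, d in self.helical.items()
            },
            shift_noise_sd=0.0,
        )
        return z


def _draw_phase_mixture(
    state_bii: np.ndarray, weights: dict, components: dict, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty(state_bii.shape, dtype=float)
    for state, mask in (("BI", ~state_bii), ("BII", state_bii)):
        n = int(mask.sum())
        if n == 0:
            continue
        w = weights[state]
        names = list(w)
        probs = np.array([w[k] for k in names], dtype=float)
        probs = probs / probs.sum()
        idx = rng.choice(len(names), size=n, p=probs)
        means = np.array([components[k][0] for k in names])
        sds = np.array([components[k][1] for k in names])
        out[mask] = rng.normal(means[idx], sds[idx])
    return np.mod(out, 360.0)


def emit_backbone(
    latent: StateSeries,
    emissions: EmissionSpec,
    seed,
    frame_interval: float = 1.0,
) -> BackboneSeries:
    """Draw observable torsions/phases conditional on latent BI/BII states."""
    rng = np.random.default_rng(np.random.SeedSequence(_as_entropy(seed)))
    b = latent.is_bii
    eps = np.where(
        b,
        rng.normal(emissions.bii_epsilon[0], emissions.bii_epsilon[1], b.shape),
        rng.normal(emissions.bi_epsilon[0], emissions.bi_epsilon[1], b.shape),
    )
    zet = np.where(
        b,
        rng.normal(emissions.bii_zeta[0], emissions.bii_zeta[1], b.shape),
        rng.normal(emissions.bi_zeta[0], emissions.bi_zeta[1], b.shape),
    )
    p5 = _draw_phase_mixture(b, emissions.phase5_weights, emissions.pucker_components, rng)
    p3 = _draw_phase_mixture(b, emissions.phase3_weights, emissions.pucker_components, rng)
    return BackboneSeries(
        phosphates=list(latent.phosphates),
        epsilon=np.mod(eps, 360.0),
        zeta=np.mod(zet, 360.0),
        phase5=p5,
        phase3=p3,
        frame_interval=frame_interval,
    )


def simulate_backbone(
    topology: DuplexTopology,
    specs,
    emissions: EmissionSpec,
    n_frames: int,
    frame_interval: float = 1.0,
    seed=0,
    exclude_terminal: bool = True,
) -> tuple[BackboneSeries, StateSeries]:
    """Full backbone generation: latent chains plus emitted angle series.

    Returns ``(series, latent)``; the latent :class:`StateSeries` is the
    ground truth against which classification can be scored.
    """
    ss = np.random.SeedSequence(_as_entropy(seed))
    chain_seed, emit_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    latent = simulate_state_chains(
        topology, specs, n_frames, chain_seed,
        exclude_terminal=exclude_terminal, frame_interval=frame_interval,
    )
    series = emit_backbone(latent, emissions, emit_seed, frame_interval=frame_interval)
    return series, latent


def simulate_helical(
    pair_series: PairSeries, emissions: EmissionSpec, seed=0
) -> HelicalSeries:
    """Draw the six helical parameters conditional on each frame's combination.

    The two hybrid orderings share one conditional (they are pooled
    throughout the conditional-statistics analysis).
    """
    for comb in POOLED_LABELS:
        if comb not in emissions.helical:
            raise KeyError(f"no helical emission entry for combination {comb!r}")
    rng = np.random.default_rng(np.random.SeedSequence(_as_entropy(seed)))
    pooled = pair_series.pooled_codes
    values: dict[str, np.ndarray] = {}
    for p in HELICAL_PARAMS:
        means = np.array([emissions.helical[c][p][0] for c in POOLED_LABELS])
        sds = np.array([emissions.helical[c][p][1] for c in POOLED_LABELS])
        values[p] = rng.normal(means[pooled], sds[pooled])
    return HelicalSeries(
        steps=[s for s, _ in pair_series.steps],
        values=values,
        frame_interval=pair_series.frame_interval,
    )


def simulate_shifts(
    bii_targets: dict[StepIdentity, float],
    noise_sd: float = 0.0,
    seed=0,
    tolerance: float = 10.0,
    oligo: str = "",
) -> ShiftTable:
    """Synthesise a 31P shift table whose conversion recovers the targets.

    deltaP = (100 p - 621)/143 + N(0, noise_sd); with ``noise_sd = 0`` the
    shift-to-BII conversion round-trips exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(_as_entropy(seed)))
    rows = []
    for step, p in bii_targets.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"BII target {p} for {step.label()} outside [0, 1]")
        dp = float(shift_for_bii(100.0 * p))
        if noise_sd > 0:
            dp += rng.normal(0.0, noise_sd)
        rows.append(
            {
                "oligo": oligo,
                "strand": step.strand,
                "pos5": step.pos5,
                "dinucleotide": step.dinucleotide,
                "delta_p_ppm": dp,
            }
        )
    return ShiftTable(data=pd.DataFrame(rows), tolerance=tolerance)


#: Convenience stationary BII targets per dinucleotide type, seeded from the
#: NMR aggregation over the study dodecamers (types observed in more than
#: three occurrences).  These are editable defaults for generating plausible
#: sequence-dependent synthetic data, not a propensity-scale reimplementation.
DEFAULT_DINUCLEOTIDE_BII: dict[str, float] = {
    "CT": 0.00, "GT": 0.00, "TT": 0.00,
    "AC": 0.12, "AA": 0.16, "TA": 0.17, "AG": 0.19,
    "GC": 0.31, "CG": 0.41,
}
#: Fallback for types without an aggregated value: the overall average BII
#: fraction of the study's 72 steps.
DEFAULT_BII_FALLBACK = 0.19


def default_bii_targets(
    topology: DuplexTopology, exclude_terminal: bool = True
) -> dict[StepIdentity, float]:
    """Per-phosphate stationary BII targets from the dinucleotide defaults."""
    return {
        s: DEFAULT_DINUCLEOTIDE_BII.get(s.dinucleotide, DEFAULT_BII_FALLBACK)
        for s in topology.all_steps(exclude_terminal)
    }


def sojourn_lengths(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lengths (frames) of maximal constant runs of a boolean state vector.

    Returns ``(bi_runs, bii_runs)``; truncated first/last runs are included,
    which is immaterial for long stationary chains.
    """
    x = np.asarray(states, dtype=bool)
    if x.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    change = np.flatnonzero(np.diff(x.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [x.size]))
    lengths = np.diff(bounds)
    run_states = x[bounds[:-1]]
    return lengths[~run_states], lengths[run_states]
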