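"""Facing-phosphate combination statistics and the independence framework.

The two phosphate linkages of a complementary dinucleotide NpN.NpN (one on
each strand) jointly occupy one of four ordered combinations — BI.BI,
BI.BII, BII.BI, BII.BII — with the two hybrid states pooled as
BI.BII|BII.BI.  Writing P_i(BII), P_j(BII) for the marginal BII
probabilities of the two phosphates, the counting identity

    P_ij(hybrid) + 2 P_ij(BII.BII) = P_i(BII) + P_j(BII)

holds for *any* joint law, while under statistical independence the pair
probabilities factorise:

    P_ij(BII.BII) = P_i(BII) P_j(BII)
    P_ij(hybrid)  = P_i(BII) + P_j(BII) - 2 P_i(BII) P_j(BII)

This module labels frames with their combinations, tallies the four
transition types between consecutive frames, evaluates the identity and the
independence predictions, and provides the empirical-versus-predicted
correlation diagnostic together with per-step odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .states import StateSeries
from .topology import DuplexTopology, StepIdentity, enumerate_complementary_steps

__all__ = [
    "ORDERED_LABELS",
    "POOLED_LABELS",
    "PairSeries",
    "CombinationPopulations",
    "TransitionCensus",
    "combine_states",
    "combination_populations",
    "transition_census",
    "independence_predictions",
    "independence_test",
    "IndependenceReport",
    "StepIndependence",
    "counting_identity_check",
]

# ordered combination codes: bit 0 = strand-1 phosphate, bit 1 = strand-2
ORDERED_LABELS = ("BI.BI", "BII.BI", "BI.BII", "BII.BII")
POOLED_LABELS = ("BI.BI", "BI.BII|BII.BI", "BII.BII")
#: pooled index for each ordered code (hybrids merge)
_POOLED_OF_CODE = np.array([0, 1, 1, 2])


@dataclass
class PairSeries:
    """Per-frame combination codes for each complementary step.

    ``codes`` has shape (n_steps, n_frames) with values 0..3 encoding
    (strand-1 state, strand-2 state): 0 = BI.BI, 1 = BII.BI, 2 = BI.BII,
    3 = BII.BII.  ``steps`` pairs each strand-1 step with its facing step.
    """

    steps: list[tuple[StepIdentity, StepIdentity]]
    codes: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.codes)
        if c.ndim != 2 or c.shape[0] != len(self.steps):
            raise ValueError("codes must be (n_steps, n_frames)")
        if c.size and (c.min() < 0 or c.max() > 3):
            raise ValueError("combination codes must lie in 0..3")
        self.codes = c.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.codes.shape[1]

    @property
    def pooled_codes(self) -> np.ndarray:
        """Codes mapped onto {0: BI.BI, 1: hybrid, 2: BII.BII}."""
        return _POOLED_OF_CODE[self.codes]

    def strand1_is_bii(self) -> np.ndarray:
        return (self.codes & 1).astype(bool)

    def strand2_is_bii(self) -> np.ndarray:
        return (self.codes & 2).astype(bool)


@dataclass
class CombinationPopulations:
    """Percentages of the three pooled combinations per complementary step."""

    steps: list[tuple[StepIdentity, StepIdentity]]
    bi_bi: np.ndarray  # %
    hybrid: np.ndarray  # %
    bii_bii: np.ndarray  # %
    provenance: str = "frame-counted"  # or "independence-predicted"
    intervals: dict | None = None  # optional {category: (lo, hi) arrays}

    def __post_init__(self) -> None:
        for name in ("bi_bi", "hybrid", "bii_bii"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any((v < -1e-9) | (v > 100.0 + 1e-9)):
                raise ValueError(f"{name} percentages outside [0, 100]")
            setattr(self, name, v)
        total = self.bi_bi + self.hybrid + self.bii_bii
        if np.any(np.abs(total - 100.0) > 1e-6):
            raise ValueError("combination percentages do not sum to 100")

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": [s.label() for s, _ in self.steps],
                "facing": [t.label() for _, t in self.steps],
                "BI.BI_%": self.bi_bi,
                "BI.BII|BII.BI_%": self.hybrid,
                "BII.BII_%": self.bii_bii,
                "provenance": self.provenance,
            }
        )


@dataclass
class TransitionCensus:
    """Counts of the four transition types between consecutive frames.

    Type 1: BI.BI <-> hybrid (one phosphate flips, out of/into BI.BI)
    Type 2: hybrid <-> BII.BII (one phosphate flips)
    Type 3: BI.BII <-> BII.BI (both phosphates flip, hybrid to hybrid)
    Type 4: BI.BI <-> BII.BII (both phosphates flip)
    """

    counts: np.ndarray  # shape (4,)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        t = self.total
        return self.counts / t if t else np.zeros(4)

    @property
    def simultaneous_fraction(self) -> float:
        """Fraction of transitions in which both phosphates change (types 3+4)."""
        t = self.total
        return float((self.counts[2] + self.counts[3]) / t) if t else 0.0


def combine_states(states: StateSeries, topology: DuplexTopology,
                   exclude_terminal: bool = True) -> PairSeries:
    """Join the per-frame states of facing phosphates into combination labels.

    Every complementary step whose two phosphates are both present in
    ``states`` is included; the strand-1 state is the first member of the
    ordered label.
    """
    pairs = enumerate_complementary_steps(topology, exclude_terminal)
    have = {(p.strand, p.pos5) for p in states.phosphates}
    steps, rows = [], []
    for s1, s2 in pairs:
        if (s1.strand, s1.pos5) in have and (s2.strand, s2.pos5) in have:
            b1 = states.is_bii[states.index_of(s1)]
            b2 = states.is_bii[states.index_of(s2)]
            if b1.shape != b2.shape:
                raise ValueError(f"frame-count mismatch at {s1.label()}")
            rows.append(b1.astype(np.uint8) + 2 * b2.astype(np.uint8))
            steps.append((s1, s2))
    if not steps:
        raise ValueError("no complementary step has both phosphates in the state series")
    return PairSeries(steps=steps, codes=np.vstack(rows))


def combination_populations(pairs: PairSeries) -> CombinationPopulations:
    """Frame-counted percentages of BI.BI, hybrid and BII.BII per step."""
    if pairs.n_frames < 1:
        raise ValueError("empty pair series")
    pooled = pairs.pooled_codes
    n = pairs.n_frames
    pct = [100.0 * (pooled == k).sum(axis=1) / n for k in range(3)]
    return CombinationPopulations(
        steps=list(pairs.steps), bi_bi=pct[0], hybrid=pct[1], bii_bii=pct[2]
    )


def transition_census(pairs: PairSeries) -> TransitionCensus:
    """Tally combination changes between consecutive frames into types 1-4.

    Identical consecutive labels are not transitions.  Counts are pooled
    over all steps of the series.
    """
    if pairs.n_frames < 2:
        raise ValueError("need at least 2 frames to count transitions")
    a, b = pairs.codes[:, :-1], pairs.codes[:, 1:]
    changed = a != b
    pooled_a, pooled_b = _POOLED_OF_CODE[a], _POOLED_OF_CODE[b]
    t1 = changed & ((pooled_a == 0) & (pooled_b == 1) | (pooled_a == 1) & (pooled_b == 0))
    t2 = changed & ((pooled_a == 1) & (pooled_b == 2) | (pooled_a == 2) & (pooled_b == 1))
    t3 = changed & (pooled_a == 1) & (pooled_b == 1)  # BI.BII <-> BII.BI
    t4 = changed & ((pooled_a == 0) & (pooled_b == 2) | (pooled_a == 2) & (pooled_b == 0))
    counts = np.array([t1.sum(), t2.sum(), t3.sum(), t4.sum()], dtype=np.int64)
    return TransitionCensus(counts=counts)


def independence_predictions(p_i, p_j, steps=None) -> CombinationPopulations:
    """Pooled-combination populations implied by independent facing phosphates.

    BII.BII = p_i p_j, hybrid = p_i + p_j - 2 p_i p_j, BI.BI the remainder
    (= (1-p_i)(1-p_j)); inputs are probabilities, outputs percentages.
    """
    p_i = np.atleast_1d(np.asarray(p_i, dtype=float))
    p_j = np.atleast_1d(np.asarray(p_j, dtype=float))
    if np.any((p_i < 0) | (p_i > 1)) or np.any((p_j < 0) | (p_j > 1)):
        raise ValueError("marginal probabilities must lie in [0, 1]")
    bii_bii = p_i * p_j
    hybrid = p_i + p_j - 2.0 * p_i * p_j
    bi_bi = 1.0 - hybrid - bii_bii
    if steps is None:
        steps = [
            (StepIdentity(1, k + 2), StepIdentity(2, k + 2)) for k in range(len(p_i))
        ]
    return CombinationPopulations(
        steps=list(steps),
        bi_bi=100.0 * bi_bi,
        hybrid=100.0 * hybrid,
        bii_bii=100.0 * bii_bii,
        provenance="independence-predicted",
    )


@dataclass
class StepIndependence:
    """Per-step comparison of empirical and independence-predicted populations."""

    step: tuple[StepIdentity, StepIdentity]
    p_i: float
    p_j: float
    empirical_hybrid: float  # probabilities, not %
    predicted_hybrid: float
    empirical_bii_bii: float
    predicted_bii_bii: float
    odds_ratio: float
    log_or_se: float  # naive SE of log OR (Haldane-corrected cells)
    n_effective: float  # frames corrected for autocorrelation
    degenerate: bool  # True when either marginal is 0 or 1


@dataclass
class IndependenceReport:
    """Across-step independence diagnostic (empirical vs predicted scatter)."""

    per_step: list[StepIndependence]
    corr_hybrid: float
    corr_bii_bii: float
    n_steps_used: int
    excluded_steps: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "corr_hybrid": self.corr_hybrid,
            "corr_bii_bii": self.corr_bii_bii,
            "n_steps_used": self.n_steps_used,
            "excluded_steps": list(self.excluded_steps),
            "per_step": [
                {
                    "step": s.step[0].label(),
                    "facing": s.step[1].label(),
                    "p_i": s.p_i,
                    "p_j": s.p_j,
                    "empirical_hybrid": s.empirical_hybrid,
                    "predicted_hybrid": s.predicted_hybrid,
                    "empirical_bii_bii": s.empirical_bii_bii,
                    "predicted_bii_bii": s.predicted_bii_bii,
                    "odds_ratio": s.odds_ratio,
                    "log_or_se": s.log_or_se,
                    "n_effective": s.n_effective,
                    "degenerate": s.degenerate,
                }
                for s in self.per_step
            ],
        }


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x.astype(float)
    if x.std() == 0:
        return 0.0
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def independence_test(pairs: PairSeries) -> IndependenceReport:
    """Compare frame-counted combination populations with the factorised law.

    For every complementary step the empirical hybrid and BII.BII
    probabilities are set against the predictions computed from that step's
    own empirical marginals.  Across steps, one Pearson correlation is
    reported per pooled category.  Each step also carries a 2x2 odds ratio
    (Haldane-Anscombe 0.5 correction) with an effective sample size deflated
    by the lag-1 autocorrelation of the state indicators — advisory only,
    since trajectory frames are serially correlated.
    """
    n = pairs.n_frames
    s1 = pairs.strand1_is_bii()
    s2 = pairs.strand2_is_bii()
    pooled = pairs.pooled_codes
    per_step: list[StepIndependence] = []
    excluded: list[str] = []
    for k, step in enumerate(pairs.steps):
        p_i = float(s1[k].mean())
        p_j = float(s2[k].mean())
        emp_h = float((pooled[k] == 1).mean())
        emp_bb = float((pooled[k] == 2).mean())
        pred_bb = p_i * p_j
        pred_h = p_i + p_j - 2.0 * pred_bb
        degenerate = p_i in (0.0, 1.0) or p_j in (0.0, 1.0)
        # 2x2 table with Haldane-Anscombe correction
        n11 = (s1[k] & s2[k]).sum() + 0.5
        n10 = (s1[k] & ~s2[k]).sum() + 0.5
        n01 = (~s1[k] & s2[k]).sum() + 0.5
        n00 = (~s1[k] & ~s2[k]).sum() + 0.5
        odds = float(n11 * n00 / (n10 * n01))
        se = float(np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00))
        rho = max(_lag1_autocorr(s1[k]), _lag1_autocorr(s2[k]))
        rho = min(max(rho, 0.0), 0.999)
        neff = n * (1 - rho) / (1 + rho)
        se_eff = se * np.sqrt(n / neff) if neff > 0 else np.inf
        per_step.append(
            StepIndependence(
                step=step,
                p_i=p_i,
                p_j=p_j,
                empirical_hybrid=emp_h,
                predicted_hybrid=pred_h,
                empirical_bii_bii=emp_bb,
                predicted_bii_bii=pred_bb,
                odds_ratio=odds,
                log_or_se=se_eff,
                n_effective=neff,
                degenerate=degenerate,
            )
        )
        if degenerate:
            excluded.append(step[0].label())

    usable = [s for s in per_step if not s.degenerate]
    def _corr(xs, ys):
        if len(xs) < 2 or np.std(xs) == 0 or np.std(ys) == 0:
            return float("nan")
        return float(stats.pearsonr(xs, ys).statistic)

    corr_h = _corr([s.empirical_hybrid for s in usable], [s.predicted_hybrid for s in usable])
    corr_bb = _corr([s.empirical_bii_bii for s in usable], [s.predicted_bii_bii for s in usable])
    return IndependenceReport(
        per_step=per_step,
        corr_hybrid=corr_h,
        corr_bii_bii=corr_bb,
        n_steps_used=len(usable),
        excluded_steps=excluded,
    )


def counting_identity_check(pairs: PairSeries) -> np.ndarray:
    """Residual of the counting identity per step; exactly zero on any input.

    residual = P(hybrid) + 2 P(BII.BII) - P_i(BII) - P_j(BII), computed from
    frame counts.  This is an accounting identity, independent of whether
    the facing phosphates are correlated, so any nonzero residual signals a
    labelling bug rather than a statistical effect.
    """
    pooled = pairs.pooled_codes
    hyb = (pooled == 1).mean(axis=1)
    bb = (pooled == 2).mean(axis=1)
    p_i = pairs.strand1_is_bii().mean(axis=1)
    p_j = pairs.strand2_is_bii().mean(axis=1)
    return hyb + 2.0 * bb - p_i - p_j
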