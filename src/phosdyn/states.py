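"""BI/BII state classification from backbone torsions and sugar puckers.

The phosphodiester linkage of B-DNA interconverts between two substates
defined by the epsilon/zeta torsion pair: BI (epsilon trans, zeta gauche-)
and BII (epsilon gauche-, zeta trans).  Operationally a frame is BII when
the wrapped pseudo-angle (epsilon - zeta) exceeds a cutoff; the two common
cutoffs are 0 deg (AMBER-family trajectories) and +30 deg (CHARMM-family).
This module holds the per-frame torsion containers, the classifiers, BII
percentage and convergence diagnostics, and a histogram-based cutoff
suggestion that mimics the "minimum between the two modes" convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import StepIdentity

__all__ = [
    "BackboneSeries",
    "StateSeries",
    "wrap_delta",
    "classify_torsion",
    "classify_pucker",
    "classify_backbone_state",
    "bii_percentage",
    "convergence_profile",
    "window_difference",
    "suggest_cutoff",
    "CutoffSuggestion",
    "joint_state_pucker_histogram",
    "TORSION_WINDOWS",
    "PUCKER_RANGES",
]

#: Staggered torsion windows (degrees), each mean +/- 40.
TORSION_WINDOWS = {"g+": (20.0, 100.0), "t": (140.0, 220.0), "g-": (260.0, 340.0)}

#: Pseudorotation phase categories (degrees); north wraps through 0.
PUCKER_RANGES = {"north": (300.0, 50.0), "east": (50.0, 120.0), "south": (120.0, 220.0)}


def _wrap360(a):
    return np.mod(a, 360.0)


def wrap_delta(epsilon, zeta):
    """Wrapped pseudo-angle (epsilon - zeta) in [-180, 180).

    Invariant under adding any multiple of 360 deg to either torsion.
    Canonical values: BI sits near -90 deg, BII near +100 deg.
    """
    d = np.mod(np.asarray(epsilon, dtype=float) - np.asarray(zeta, dtype=float) + 180.0, 360.0) - 180.0
    return d if d.ndim else float(d)


def classify_torsion(angle):
    """Classify a torsion as 'g+', 't', 'g-' or 'other'.

    Windows are gauche plus 60+/-40, trans 180+/-40, gauche minus 300+/-40
    (degrees, inclusive), applied after wrapping to [0, 360).
    """
    a = _wrap360(np.asarray(angle, dtype=float))
    out = np.full(a.shape, "other", dtype=object)
    for name, (lo, hi) in TORSION_WINDOWS.items():
        out[(a >= lo) & (a <= hi)] = name
    return out if out.ndim else str(out[()])


def classify_pucker(phase):
    """Classify a pseudorotation phase as 'north', 'east', 'south' or 'other'.

    North spans 300->360 and 0->50 (through the wrap); 220-300 deg belongs to
    no category and is labelled 'other'.  Boundaries are half-open on the
    upper edge so every angle gets exactly one label.
    """
    p = _wrap360(np.asarray(phase, dtype=float))
    out = np.full(p.shape, "other", dtype=object)
    out[(p >= 300.0) | (p < 50.0)] = "north"
    out[(p >= 50.0) & (p < 120.0)] = "east"
    out[(p >= 120.0) & (p < 220.0)] = "south"
    return out if out.ndim else str(out[()])


@dataclass
class BackboneSeries:
    """Per-phosphate, per-frame backbone torsions and sugar phases.

    All angle arrays have shape (n_phosphates, n_frames) and are stored
    wrapped to [0, 360).  ``phase5``/``phase3`` are the pseudorotation
    phases of the sugars 5' and 3' of each phosphate.
    """

    phosphates: list[StepIdentity]
    epsilon: np.ndarray
    zeta: np.ndarray
    phase5: np.ndarray
    phase3: np.ndarray
    frame_interval: float = 1.0  # ps between saved frames

    def __post_init__(self) -> None:
        arrs = {}
        for nm in ("epsilon", "zeta", "phase5", "phase3"):
            a = np.asarray(getattr(self, nm), dtype=float)
            if a.ndim != 2:
                raise ValueError(f"{nm} must be 2-D (phosphates x frames)")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite angles in {nm}")
            arrs[nm] = _wrap360(a)
        shapes = {a.shape for a in arrs.values()}
        if len(shapes) != 1:
            raise ValueError(f"angle arrays disagree in shape: {shapes}")
        (shape,) = shapes
        if shape[0] != len(self.phosphates):
            raise ValueError(
                f"{len(self.phosphates)} phosphates but angle arrays have {shape[0]} rows"
            )
        for nm, a in arrs.items():
            setattr(self, nm, a)

    @property
    def n_frames(self) -> int:
        return self.epsilon.shape[1]

    @property
    def delta(self) -> np.ndarray:
        """Wrapped (epsilon - zeta), shape (n_phosphates, n_frames)."""
        return wrap_delta(self.epsilon, self.zeta)

    def index_of(self, phosphate: StepIdentity) -> int:
        key = (phosphate.strand, phosphate.pos5)
        for i, p in enumerate(self.phosphates):
            if (p.strand, p.pos5) == key:
                return i
        raise KeyError(f"phosphate {phosphate} not in series")


@dataclass
class StateSeries:
    """Per-frame BI/BII labels for each phosphate.

    ``is_bii`` is boolean, shape (n_phosphates, n_frames); a frame is BII
    exactly when its wrapped (epsilon - zeta) is strictly greater than
    ``cutoff``.  ``ambiguous`` marks frames where both epsilon and zeta are
    trans — the region where BI/BII categorisation is intrinsically unclear.
    """

    phosphates: list[StepIdentity]
    is_bii: np.ndarray
    cutoff: float
    ambiguous: np.ndarray = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return self.is_bii.shape[1]

    def index_of(self, phosphate: StepIdentity) -> int:
        key = (phosphate.strand, phosphate.pos5)
        for i, p in enumerate(self.phosphates):
            if (p.strand, p.pos5) == key:
                return i
        raise KeyError(f"phosphate {phosphate} not in series")


def classify_backbone_state(series: BackboneSeries, cutoff: float = 0.0) -> StateSeries:
    """Assign BI/BII per frame by thresholding (epsilon - zeta) at ``cutoff``.

    Strict inequality: delta > cutoff is BII, delta == cutoff is BI.  The
    ambiguous mask flags epsilon/zeta trans/trans frames.
    """
    if not -180.0 < cutoff < 180.0:
        raise ValueError(f"cutoff {cutoff} outside (-180, 180)")
    delta = series.delta
    amb = (classify_torsion(series.epsilon) == "t") & (classify_torsion(series.zeta) == "t")
    return StateSeries(
        phosphates=list(series.phosphates),
        is_bii=delta > cutoff,
        cutoff=float(cutoff),
        ambiguous=amb,
    )


def bii_percentage(states: StateSeries, phosphate: StepIdentity | None = None):
    """BII occupancy in percent: 100 x (BII frames)/(frames).

    With ``phosphate`` given, a scalar for that linkage; otherwise a vector
    over all phosphates of the series.
    """
    if states.n_frames == 0:
        raise ValueError("empty state series")
    frac = states.is_bii.mean(axis=1) * 100.0
    if phosphate is None:
        return frac
    return float(frac[states.index_of(phosphate)])


def convergence_profile(states: StateSeries, checkpoints) -> np.ndarray:
    """Cumulative BII%% at increasing trajectory lengths.

    ``checkpoints`` are increasing frame counts; returns an array of shape
    (n_phosphates, n_checkpoints) with the BII percentage of frames
    0..checkpoint for each phosphate.  A flat profile (after burn-in) is the
    usual operational convergence check.
    """
    cp = np.asarray(checkpoints, dtype=int)
    if np.any(np.diff(cp) <= 0):
        raise ValueError("checkpoints must be strictly increasing")
    if cp[0] < 1 or cp[-1] > states.n_frames:
        raise ValueError(
            f"checkpoints must lie in 1..{states.n_frames}, got {cp.tolist()}"
        )
    csum = np.cumsum(states.is_bii, axis=1)
    return 100.0 * csum[:, cp - 1] / cp


def window_difference(states: StateSeries, window_a, window_b) -> np.ndarray:
    """Per-phosphate |BII%%(window_a) - BII%%(window_b)|.

    Windows are (start, stop) frame slices; this is the early-versus-late
    trajectory comparison used to probe stationarity.
    """
    a0, a1 = window_a
    b0, b1 = window_b
    for lo, hi in ((a0, a1), (b0, b1)):
        if not (0 <= lo < hi <= states.n_frames):
            raise ValueError(f"window ({lo}, {hi}) outside 0..{states.n_frames}")
    pa = states.is_bii[:, a0:a1].mean(axis=1) * 100.0
    pb = states.is_bii[:, b0:b1].mean(axis=1) * 100.0
    return np.abs(pa - pb)


@dataclass
class CutoffSuggestion:
    """Outcome of the histogram-valley cutoff search."""

    cutoff: float  # suggested separation (deg); fallback 0 when ambiguous
    ambiguous: bool
    valley_clarity: float  # smaller-mode peak height / valley height
    mode_positions: tuple[float, float] | None
    bin_centers: np.ndarray = field(repr=False, default=None)
    smoothed_counts: np.ndarray = field(repr=False, default=None)


def suggest_cutoff(
    series: BackboneSeries,
    bin_width: float = 5.0,
    min_clarity: float = 1.5,
) -> CutoffSuggestion:
    """Locate the (epsilon - zeta) histogram minimum between the two modes.

    Pools delta over all phosphates, bins at ``bin_width`` degrees over
    [-180, 180), applies a 3-bin moving average, finds the two highest local
    maxima, and proposes the minimum between them.  If the valley is not
    clearly below the smaller mode (peak/valley ratio < ``min_clarity``) or
    the histogram is unimodal, the suggestion is flagged ambiguous with the
    conventional fallback of 0 deg.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = series.delta.ravel()
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(counts.astype(float), kernel, mode="same")

    # interior local maxima of the smoothed histogram
    peaks = [
        i
        for i in range(1, len(smooth) - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 0
    ]
    peaks.sort(key=lambda i: smooth[i], reverse=True)
    # keep peaks separated by at least 60 deg so shoulder bins do not count
    main: list[int] = []
    for i in peaks:
        if all(abs(centers[i] - centers[j]) >= 60.0 for j in main):
            main.append(i)
        if len(main) == 2:
            break
    ambiguous_result = CutoffSuggestion(
        cutoff=0.0,
        ambiguous=True,
        valley_clarity=np.nan,
        mode_positions=None,
        bin_centers=centers,
        smoothed_counts=smooth,
    )
    if len(main) < 2:
        return ambiguous_result

    lo, hi = sorted(main)
    segment = smooth[lo : hi + 1]
    ties = np.flatnonzero(segment == segment.min())
    valley = lo + int(ties[len(ties) // 2])  # middle of a flat minimum region
    valley_h = smooth[valley]
    smaller_peak = min(smooth[lo], smooth[hi])
    clarity = np.inf if valley_h == 0 else smaller_peak / valley_h
    if clarity < min_clarity:
        ambiguous_result.valley_clarity = clarity
        ambiguous_result.mode_positions = (float(centers[lo]), float(centers[hi]))
        return ambiguous_result
    return CutoffSuggestion(
        cutoff=float(centers[valley]),
        ambiguous=False,
        valley_clarity=float(clarity),
        mode_positions=(float(centers[lo]), float(centers[hi])),
        bin_centers=centers,
        smoothed_counts=smooth,
    )


def joint_state_pucker_histogram(
    series: BackboneSeries,
    states: StateSeries,
    delta_bins: int = 72,
    phase_bins: int = 72,
):
    """Joint (epsilon - zeta) x 5' phase density plus a state/pucker table.

    Returns ``(H, delta_edges, phase_edges, contingency)`` where ``H`` is the
    2-D histogram of (delta, phase5) pooled over phosphates and
    ``contingency`` is a pandas DataFrame of frame counts indexed by BI/BII
    state with one column per pucker category.  The hallmark of a sane
    BI/BII assignment is an empty (BII, north) cell.
    """
    import pandas as pd

    if series.epsilon.shape != states.is_bii.shape:
        raise ValueError("series and states are not frame-aligned")
    d = series.delta.ravel()
    p5 = series.phase5.ravel()
    H, de, pe = np.histogram2d(
        d, p5, bins=[delta_bins, phase_bins], range=[[-180.0, 180.0], [0.0, 360.0]]
    )
    state = np.where(states.is_bii.ravel(), "BII", "BI")
    pucker = classify_pucker(p5)
    contingency = (
        pd.crosstab(pd.Series(state, name="state"), pd.Series(pucker, name="pucker"))
        .reindex(index=["BI", "BII"], fill_value=0)
        .reindex(columns=["north", "east", "south", "other"], fill_value=0)
    )
    return H, de, pe, contingency
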