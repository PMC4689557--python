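"""Bridging 31P chemical shifts to BII populations and combination estimates.

The 31P chemical shift of a phosphate linkage (delta-P, ppm, referenced to
trimethyl phosphate at 30 C) is an ensemble average over the BI <-> BII
equilibrium and converts empirically to a BII percentage,

    BII% = 143 * deltaP + 621,

with a +/-10 percentage-point tolerance conventionally attached to absorb
the calibration's assumption that the pure-BI and pure-BII endpoints are
sequence independent.  Under the facing-phosphate independence result, the
per-phosphate NMR percentages further yield the populations of the pooled
combinations of each complementary step.  This module also provides the
simulated-versus-experimental comparison statistics (Pearson CC, mean
absolute difference, within-tolerance fraction) and per-dinucleotide
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import CombinationPopulations, independence_predictions
from .topology import DuplexTopology, StepIdentity, facing_step

__all__ = [
    "SHIFT_SLOPE",
    "SHIFT_INTERCEPT",
    "ShiftTable",
    "bii_from_shift",
    "shift_for_bii",
    "shift_tolerance_band",
    "nmr_combination_populations",
    "compare_bii_sets",
    "ComparisonReport",
    "group_by_dinucleotide",
]

#: Empirical conversion BII% = SHIFT_SLOPE * deltaP + SHIFT_INTERCEPT
SHIFT_SLOPE = 143.0
SHIFT_INTERCEPT = 621.0


def bii_from_shift(delta_p, clamp: bool = True):
    """Convert a 31P shift (ppm) to a BII percentage.

    The conversion is empirical and can fall outside [0, 100]; by default
    the result is clamped, with ``clamp=False`` returning the raw value.
    """
    raw = SHIFT_SLOPE * np.asarray(delta_p, dtype=float) + SHIFT_INTERCEPT
    out = np.clip(raw, 0.0, 100.0) if clamp else raw
    return out if out.ndim else float(out)


def shift_for_bii(bii_percent):
    """Exact inverse of the conversion: the deltaP (ppm) giving ``bii_percent``."""
    return (np.asarray(bii_percent, dtype=float) - SHIFT_INTERCEPT) / SHIFT_SLOPE


@dataclass
class ShiftTable:
    """Per-phosphate 31P shifts with derived BII percentages.

    ``data`` columns: oligo, strand, pos5, dinucleotide, delta_p_ppm, plus
    derived bii_raw (unclamped) and bii_percent (clamped to [0, 100]).
    ``tolerance`` is the half-width, in percentage points, of the band
    attached to each converted value (default 10).
    """

    data: pd.DataFrame
    tolerance: float = 10.0

    REQUIRED = ("strand", "pos5", "dinucleotide", "delta_p_ppm")

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"shift table missing columns: {missing}")
        if "oligo" not in df.columns:
            df["oligo"] = ""
        df["bii_raw"] = bii_from_shift(df["delta_p_ppm"].to_numpy(), clamp=False)
        df["bii_percent"] = np.clip(df["bii_raw"], 0.0, 100.0)
        self.data = df

    def bii_percent(self, strand: int, pos5: int) -> float:
        row = self.data[(self.data.strand == strand) & (self.data.pos5 == pos5)]
        if row.empty:
            raise KeyError(f"no shift entry for strand {strand} pos5 {pos5}")
        return float(row.bii_percent.iloc[0])

    def has(self, strand: int, pos5: int) -> bool:
        return bool(
            ((self.data.strand == strand) & (self.data.pos5 == pos5)).any()
        )

    @classmethod
    def from_csv(cls, path, tolerance: float = 10.0) -> "ShiftTable":
        return cls(data=pd.read_csv(path, comment="#"), tolerance=tolerance)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def shift_tolerance_band(table: ShiftTable) -> pd.DataFrame:
    """Per-phosphate BII%% interval [BII - tol, BII + tol] cut to [0, 100]."""
    t = table.tolerance
    df = table.data.copy()
    df["bii_lo"] = np.clip(df["bii_percent"] - t, 0.0, 100.0)
    df["bii_hi"] = np.clip(df["bii_percent"] + t, 0.0, 100.0)
    return df[["oligo", "strand", "pos5", "dinucleotide", "bii_percent", "bii_lo", "bii_hi"]]


def _rectangle_extrema(f, lo_i, hi_i, lo_j, hi_j):
    # f is bilinear in (p_i, p_j): extrema over the rectangle sit at corners
    corners = [f(a, b) for a in (lo_i, hi_i) for b in (lo_j, hi_j)]
    return min(corners), max(corners)


def nmr_combination_populations(
    table: ShiftTable, topology: DuplexTopology, exclude_terminal: bool = True
) -> tuple[CombinationPopulations, list[str]]:
    """Facing-combination populations inferred from NMR under independence.

    For every complementary step whose two phosphates both have shift
    entries, the clamped BII fractions feed the factorised predictions.
    Tolerance bands propagate by evaluating each bilinear population over
    the band rectangle (extrema at the corners).  Returns the populations
    (with ``intervals``) and labels of the skipped steps.
    """
    pairs = [
        (s, facing_step(topology, s)) for s in topology.steps(1, exclude_terminal)
    ]
    steps, p_is, p_js = [], [], []
    intervals = {"bi_bi": [], "hybrid": [], "bii_bii": []}
    skipped: list[str] = []
    t = table.tolerance / 100.0
    for s1, s2 in pairs:
        if not (table.has(s1.strand, s1.pos5) and table.has(s2.strand, s2.pos5)):
            skipped.append(s1.label())
            continue
        p_i = table.bii_percent(s1.strand, s1.pos5) / 100.0
        p_j = table.bii_percent(s2.strand, s2.pos5) / 100.0
        steps.append((s1, s2))
        p_is.append(p_i)
        p_js.append(p_j)
        lo_i, hi_i = max(0.0, p_i - t), min(1.0, p_i + t)
        lo_j, hi_j = max(0.0, p_j - t), min(1.0, p_j + t)
        for name, f in (
            ("bi_bi", lambda a, b: (1 - a) * (1 - b)),
            ("hybrid", lambda a, b: a + b - 2 * a * b),
            ("bii_bii", lambda a, b: a * b),
        ):
            lo, hi = _rectangle_extrema(f, lo_i, hi_i, lo_j, hi_j)
            intervals[name].append((100.0 * lo, 100.0 * hi))
    if not steps:
        raise ValueError("no complementary step has shift entries for both phosphates")
    pops = independence_predictions(p_is, p_js, steps=steps)
    pops.intervals = {k: np.array(v) for k, v in intervals.items()}
    return pops, skipped


@dataclass
class ComparisonReport:
    """Simulated-versus-experimental BII%% agreement statistics."""

    cc: float  # Pearson linear correlation (nan when undefined)
    delta_av: float  # mean |sim - exp| in percentage points
    delta_sd: float  # SD of |sim - exp| across phosphates
    within_tolerance_fraction: float  # share of phosphates with |diff| <= tol
    n: int
    tolerance: float


def compare_bii_sets(simulated, experimental, tolerance: float = 10.0) -> ComparisonReport:
    """Compare matched per-phosphate BII percentage vectors.

    Pearson CC (undefined — reported as nan — when either vector has zero
    variance), the mean absolute difference with its SD across phosphates,
    and the fraction of phosphates agreeing within ``tolerance`` points.
    """
    sim = np.asarray(simulated, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if sim.shape != exp.shape:
        raise ValueError("simulated and experimental vectors differ in length")
    if sim.size < 3:
        raise ValueError("need at least 3 matched phosphates")
    diff = np.abs(sim - exp)
    if sim.std() == 0 or exp.std() == 0:
        cc = float("nan")
    else:
        cc = float(stats.pearsonr(sim, exp).statistic)
    return ComparisonReport(
        cc=cc,
        delta_av=float(diff.mean()),
        delta_sd=float(diff.std(ddof=0)),
        within_tolerance_fraction=float((diff <= tolerance).mean()),
        n=sim.size,
        tolerance=tolerance,
    )


def group_by_dinucleotide(
    values: dict[StepIdentity, float] | pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Aggregate per-phosphate BII%% by single-strand dinucleotide type.

    ``values`` maps steps to BII percentages (or is a DataFrame with
    ``dinucleotide`` and ``bii_percent`` columns).  Types occurring more
    than ``min_n`` times are reported with occurrence count, mean and SD.
    """
    if isinstance(values, pd.DataFrame):
        df = values[["dinucleotide", "bii_percent"]].rename(
            columns={"bii_percent": "value"}
        )
    else:
        df = pd.DataFrame(
            {
                "dinucleotide": [s.dinucleotide for s in values],
                "value": list(values.values()),
            }
        )
    g = df.groupby("dinucleotide")["value"]
    out = pd.DataFrame(
        {"N": g.size(), "mean": g.mean(), "sd": g.std(ddof=0).fillna(0.0)}
    )
    out = out[out["N"] > min_n].sort_values("mean").reset_index()
    return out
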