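"""State-conditional statistics of inter-base-pair parameters.

Slide, roll and twist of a complementary dinucleotide are strongly coupled
to the combination of its two facing phosphate states: relative to BI.BI,
BII-containing combinations shift towards more positive slide, more
negative roll and higher twist, while shift and tilt are invariant and rise
moves by at most ~0.2 A.  This module joins a helical-parameter series to a
pair-combination series and reports conditional means/SDs (pooled over
steps or per step), the BI.BI -> BII.BII extreme differences, and the
combination-resolved variability comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairs import POOLED_LABELS, PairSeries
from .topology import StepIdentity

__all__ = [
    "HELICAL_PARAMS",
    "HelicalSeries",
    "ConditionalStats",
    "conditional_helical_stats",
    "delta_extremes",
    "variability_by_combination",
]

#: Canonical inter-base-pair parameter order (translations in A, rotations in deg).
HELICAL_PARAMS = ("shift", "slide", "rise", "tilt", "roll", "twist")


@dataclass
class HelicalSeries:
    """Six inter-base-pair parameters per complementary step per frame.

    ``values`` maps each parameter name to an array of shape
    (n_steps, n_frames); ``steps`` are the strand-1 members identifying the
    complementary steps, in row order.
    """

    steps: list[StepIdentity]
    values: dict[str, np.ndarray]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        missing = [p for p in HELICAL_PARAMS if p not in self.values]
        if missing:
            raise ValueError(f"helical series missing parameters: {missing}")
        shapes = set()
        vals = {}
        for p in HELICAL_PARAMS:
            a = np.asarray(self.values[p], dtype=float)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite values in {p}")
            shapes.add(a.shape)
            vals[p] = a
        if len(shapes) != 1:
            raise ValueError(f"parameter arrays disagree in shape: {shapes}")
        (shape,) = shapes
        if shape[0] != len(self.steps):
            raise ValueError("row count does not match number of steps")
        self.values = vals

    @property
    def n_frames(self) -> int:
        return self.values["shift"].shape[1]


@dataclass
class ConditionalStats:
    """Conditional means/SDs of the six parameters per pooled combination.

    ``table`` is indexed by (scope key, combination) where the scope key is
    ``"pooled"`` or a step label, with columns ``<param>_mean``,
    ``<param>_sd`` and ``n_frames``.  Combinations observed fewer than the
    stated minimum number of frames are omitted (listed in ``omitted``).
    """

    table: pd.DataFrame
    scope: str  # "pooled" | "per-step"
    min_frames: int
    omitted: list[tuple[str, str]]

    def get(self, combination: str, param: str, field: str = "mean", key: str = "pooled") -> float:
        return float(self.table.loc[(key, combination), f"{param}_{field}"])

    def combinations(self, key: str = "pooled") -> list[str]:
        return list(self.table.loc[key].index)


def conditional_helical_stats(
    helical: HelicalSeries,
    pairs: PairSeries,
    scope: str = "pooled",
    min_frames: int = 100,
) -> ConditionalStats:
    """Mean and SD of each parameter conditional on the pooled combination.

    ``scope="pooled"`` merges frames from all steps before conditioning (the
    across-sequence coupling table); ``scope="per-step"`` conditions within
    each complementary step separately (the per-step construction used to
    compare force fields step by step).
    """
    if scope not in ("pooled", "per-step"):
        raise ValueError("scope must be 'pooled' or 'per-step'")
    hs = {(s.strand, s.pos5) for s in helical.steps}
    ps = {(s.strand, s.pos5) for s, _ in pairs.steps}
    if hs != ps:
        raise ValueError("helical and pair series cover different steps")
    if helical.n_frames != pairs.n_frames:
        raise ValueError("helical and pair series are not frame-aligned")
    order = {key: i for i, key in enumerate((s.strand, s.pos5) for s, _ in pairs.steps)}
    row_of = [order[(s.strand, s.pos5)] for s in helical.steps]
    pooled = pairs.pooled_codes[row_of, :]  # aligned to helical rows

    records, omitted = [], []
    if scope == "pooled":
        groups = [("pooled", np.ones(len(helical.steps), dtype=bool))]
    else:
        groups = [
            (helical.steps[i].label(), np.eye(1, len(helical.steps), i, dtype=bool)[0])
            for i in range(len(helical.steps))
        ]
    for key, row_mask in groups:
        for code, comb in enumerate(POOLED_LABELS):
            mask = (pooled == code) & row_mask[:, None]
            n = int(mask.sum())
            if n < min_frames:
                omitted.append((key, comb))
                continue
            rec = {"scope_key": key, "combination": comb, "n_frames": n}
            for p in HELICAL_PARAMS:
                v = helical.values[p][mask]
                rec[f"{p}_mean"] = float(v.mean())
                rec[f"{p}_sd"] = float(v.std(ddof=0))
            records.append(rec)
    if not records:
        raise ValueError(
            f"no combination reaches min_frames={min_frames}; nothing to report"
        )
    table = pd.DataFrame.from_records(records).set_index(["scope_key", "combination"])
    return ConditionalStats(table=table, scope=scope, min_frames=min_frames, omitted=omitted)


def delta_extremes(stats: ConditionalStats, key: str = "pooled") -> dict[str, float]:
    """Signed difference of conditional means, BII.BII minus BI.BI.

    The two homogeneous combinations are the conformational extremes; their
    mean difference summarises the backbone -> helical coupling per
    parameter.  Raises when either extreme is absent from the statistics.
    """
    have = stats.combinations(key)
    for comb in ("BI.BI", "BII.BII"):
        if comb not in have:
            raise ValueError(f"extreme combination {comb} absent for {key!r}")
    return {
        p: stats.get("BII.BII", p, key=key) - stats.get("BI.BI", p, key=key)
        for p in HELICAL_PARAMS
    }


def variability_by_combination(
    helical: HelicalSeries,
    pairs: PairSeries,
    steps: list[StepIdentity] | None = None,
    params: tuple[str, ...] = ("slide", "roll", "twist"),
    min_frames: int = 100,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Per-step, per-combination SDs and a stiffening summary.

    Returns the SD table (rows: step x combination) restricted to ``steps``
    (all by default; steps lacking any combination above ``min_frames`` are
    dropped) and, per parameter, a boolean saying whether the BI.BI SD is
    at least as large as every BII-containing SD in *all* retained steps —
    the "BII-containing combinations are stiffer" comparison.
    """
    st = conditional_helical_stats(helical, pairs, scope="per-step", min_frames=min_frames)
    keep = None if steps is None else {s.label() for s in steps}
    rows = []
    for (key, comb), rec in st.table.iterrows():
        if keep is not None and key not in keep:
            continue
        rows.append(
            {"step": key, "combination": comb, "n_frames": int(rec["n_frames"])}
            | {f"sd_{p}": rec[f"{p}_sd"] for p in params}
        )
    df = pd.DataFrame(rows)
    # keep only steps where all three combinations were observed
    complete = df.groupby("step")["combination"].transform("nunique") == len(POOLED_LABELS)
    df = df[complete].reset_index(drop=True)
    summary: dict[str, bool] = {}
    for p in params:
        ok = True
        for _, grp in df.groupby("step"):
            sd = grp.set_index("combination")[f"sd_{p}"]
            bi_bi = sd["BI.BI"]
            others = sd.drop("BI.BI")
            if not np.all(bi_bi >= others.to_numpy()):
                ok = False
                break
        summary[p] = ok and not df.empty
    return df, summary
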