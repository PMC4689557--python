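"""Tabular readers/writers, run configuration and the pipeline driver.

The package consumes derived per-frame tables rather than raw trajectories:
a *torsion table* (columns ``frame, strand, pos5, epsilon, zeta, phase5,
phase3``) and a *helical table* (columns ``frame, step_pos5, shift, slide,
rise, tilt, roll, twist``), both plain CSV with the frame interval carried
in a ``# frame_interval_ps = ...`` header comment.  Any standard helicoidal
or dihedral post-processor can export these layouts.  ``run_pipeline``
drives the full analysis graph (generate/ingest -> classify -> pair
analysis -> shift bridging -> helical coupling) and writes a CSV/JSON
report bundle with provenance headers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import helical as hel
from . import nmr as nmr_mod
from . import pairs as pair_mod
from . import states as state_mod
from . import synthetic as syn
from .topology import DuplexTopology, build_topology

__all__ = [
    "read_torsion_table",
    "write_torsion_table",
    "read_helical_table",
    "write_helical_table",
    "RunConfig",
    "run_pipeline",
    "CUTOFF_PRESETS",
]

logger = logging.getLogger("phosdyn")

#: Named (eps - zeta) cutoffs: the conventional 0 deg separation
#: ("parm-like", AMBER-family histograms) and +30 deg ("charmm-like").
CUTOFF_PRESETS = {"parm-like": 0.0, "charmm-like": 30.0}

_TORSION_COLS = ["frame", "strand", "pos5", "epsilon", "zeta", "phase5", "phase3"]
_HELICAL_COLS = ["frame", "step_pos5", "shift", "slide", "rise", "tilt", "roll", "twist"]


def _read_frame_interval(path: Path) -> float:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "frame_interval_ps" in line:
                return float(line.split("=", 1)[1])
    return 1.0


def write_torsion_table(series: state_mod.BackboneSeries, path) -> None:
    """Write a backbone series as a long-format torsion CSV."""
    path = Path(path)
    n = series.n_frames
    frames = np.tile(np.arange(n), len(series.phosphates))
    rows = {
        "frame": frames,
        "strand": np.repeat([p.strand for p in series.phosphates], n),
        "pos5": np.repeat([p.pos5 for p in series.phosphates], n),
        "epsilon": series.epsilon.ravel(),
        "zeta": series.zeta.ravel(),
        "phase5": series.phase5.ravel(),
        "phase3": series.phase3.ravel(),
    }
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_ps = {series.frame_interval}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_torsion_table(path, topology: DuplexTopology | None = None) -> state_mod.BackboneSeries:
    """Read a torsion CSV into a :class:`BackboneSeries`.

    Angles are wrapped to [0, 360); rows are ordered deterministically by
    (strand, pos5, frame).  Missing columns, non-numeric angles and ragged
    frame counts are rejected with the offending location.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _TORSION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"torsion table {path} missing columns: {missing}")
    for col in ("epsilon", "zeta", "phase5", "phase3"):
        num = pd.to_numeric(df[col], errors="coerce")
        if num.isna().any():
            row = int(num.isna().idxmax()) + 2  # 1-based, + header line
            raise ValueError(f"non-numeric or missing {col} at file row {row} of {path}")
        df[col] = num
    df = df.sort_values(["strand", "pos5", "frame"]).reset_index(drop=True)
    groups = df.groupby(["strand", "pos5"], sort=True)
    counts = groups.size()
    if counts.nunique() != 1:
        raise ValueError(
            f"ragged frame counts across phosphates in {path}: {dict(counts)}"
        )
    phosphates, blocks = [], {c: [] for c in ("epsilon", "zeta", "phase5", "phase3")}
    for (strand, pos5), g in groups:
        if topology is not None:
            step = topology.step(int(strand), int(pos5))
        else:
            from .topology import StepIdentity

            step = StepIdentity(int(strand), int(pos5))
        phosphates.append(step)
        for c in blocks:
            blocks[c].append(g[c].to_numpy())
    return state_mod.BackboneSeries(
        phosphates=phosphates,
        epsilon=np.vstack(blocks["epsilon"]),
        zeta=np.vstack(blocks["zeta"]),
        phase5=np.vstack(blocks["phase5"]),
        phase3=np.vstack(blocks["phase3"]),
        frame_interval=_read_frame_interval(path),
    )


def write_helical_table(series: hel.HelicalSeries, path) -> None:
    """Write a helical series as a long-format CSV keyed by strand-1 pos5."""
    path = Path(path)
    n = series.n_frames
    rows = {
        "frame": np.tile(np.arange(n), len(series.steps)),
        "step_pos5": np.repeat([s.pos5 for s in series.steps], n),
    }
    for p in hel.HELICAL_PARAMS:
        rows[p] = series.values[p].ravel()
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_ps = {series.frame_interval}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_helical_table(path, topology: DuplexTopology) -> hel.HelicalSeries:
    """Read a helical CSV; steps are validated against the topology.

    Unknown extra columns are accepted with a warning; a ``step_pos5``
    outside the topology's strand-1 steps is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _HELICAL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"helical table {path} missing columns: {missing}")
    extra = [c for c in df.columns if c not in _HELICAL_COLS]
    if extra:
        logger.warning("helical table %s: ignoring extra columns %s", path, extra)
    df = df.sort_values(["step_pos5", "frame"]).reset_index(drop=True)
    steps, values = [], {p: [] for p in hel.HELICAL_PARAMS}
    counts = df.groupby("step_pos5").size()
    if counts.nunique() > 1:
        raise ValueError(f"ragged frame counts across steps in {path}")
    for pos5, g in df.groupby("step_pos5", sort=True):
        steps.append(topology.step(1, int(pos5)))  # raises if unknown
        for p in hel.HELICAL_PARAMS:
            values[p].append(pd.to_numeric(g[p]).to_numpy())
    return hel.HelicalSeries(
        steps=steps,
        values={p: np.vstack(v) for p, v in values.items()},
        frame_interval=_read_frame_interval(path),
    )


@dataclass
class RunConfig:
    """Configuration for one end-to-end pipeline run.

    Exactly one of ``generator`` (synthetic inputs) or ``inputs`` (paths to
    torsion/helical tables) must be present.
    """

    name: str
    strand1: str
    outdir: str = "phosdyn_out"
    cutoff: float | str = "parm-like"
    exclude_terminal: bool = True
    seed: int = 0
    checkpoints: list[int] | None = None
    generator: dict | None = None  # n_frames, persistence, kappa, targets...
    inputs: dict | None = None  # torsion=..., helical=...
    shifts: str | None = None  # path to a shift CSV; generator runs synthesise one

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.inputs is None):
            raise ValueError("exactly one of 'generator' or 'inputs' must be given")
        if self.inputs is not None:
            for key, p in self.inputs.items():
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"input {key} path not found: {p}")
        if self.shifts is not None and not Path(self.shifts).exists():
            raise FileNotFoundError(f"shift table not found: {self.shifts}")

    @property
    def cutoff_value(self) -> float:
        if isinstance(self.cutoff, str):
            return CUTOFF_PRESETS[self.cutoff]
        return float(self.cutoff)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "strand1": self.strand1,
            "outdir": self.outdir,
            "cutoff": self.cutoff,
            "exclude_terminal": self.exclude_terminal,
            "seed": self.seed,
            "checkpoints": self.checkpoints,
            "generator": self.generator,
            "inputs": self.inputs,
            "shifts": self.shifts,
        }


def _provenance(config: RunConfig) -> str:
    from . import __version__

    cfg = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    blob = json.dumps(cfg, sort_keys=True).encode()
    h = hashlib.sha256(blob).hexdigest()[:12]
    return f"# phosdyn {__version__} | config sha256:{h} | seed {config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis graph and write the report bundle.

    Stages: obtain the backbone series (generate or read), classify BI/BII
    at the configured cutoff, facing-pair analysis (populations, transition
    census, independence diagnostic), the shift bridge when shifts are
    available, and helical coupling when a helical series is available.
    Returns a dict of in-memory results; tables land in ``config.outdir``
    with provenance headers.  Reruns with the same config are numerically
    identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    prov = _provenance(config)
    results: dict = {}
    try:
        stage = "topology"
        topo = build_topology(config.strand1, config.name)
        results["topology"] = topo
        logger.info(
            "topology %s: %s / %s (%d bp); pucker north follows the 300->50 "
            "convention (the alternative 0->50 reading differs)",
            topo.name, topo.strand1, topo.strand2, topo.length,
        )

        stage = "ingest/generate"
        shift_table = None
        helical_series = None
        if config.generator is not None:
            g = dict(config.generator)
            n_frames = int(g.get("n_frames", 20000))
            persistence = float(g.get("persistence", 0.99))
            kappa = float(g.get("kappa", 0.0))
            targets = g.get("targets")  # optional {pos5-or-"strand:pos5": p}
            emissions = (
                syn.EmissionSpec.cmd_defaults()
                if g.get("emissions", "pmd") == "cmd"
                else syn.EmissionSpec.pmd_defaults()
            )
            target_of = syn.default_bii_targets(topo, config.exclude_terminal)
            if targets:
                for key, p in targets.items():
                    strand, pos5 = (
                        (int(str(key).split(":")[0]), int(str(key).split(":")[1]))
                        if ":" in str(key)
                        else (1, int(key))
                    )
                    for s in list(target_of):
                        if (s.strand, s.pos5) == (strand, pos5):
                            target_of[s] = float(p)
            specs = {}
            from .topology import enumerate_complementary_steps, facing_step

            for s1, s2 in enumerate_complementary_steps(topo, config.exclude_terminal):
                specs[(s1.strand, s1.pos5)] = syn.StepDynamicsSpec(
                    target_bii=(target_of[s1], target_of[s2]),
                    persistence=persistence,
                    cross_strand_association=kappa,
                )
            series, latent = syn.simulate_backbone(
                topo, specs, emissions, n_frames,
                seed=config.seed, exclude_terminal=config.exclude_terminal,
            )
            results["latent"] = latent
            write_torsion_table(series, outdir / "torsions.csv")
            shift_table = syn.simulate_shifts(
                target_of, noise_sd=float(g.get("shift_noise_sd", 0.0)),
                seed=config.seed + 1, oligo=config.name,
            )
        else:
            series = read_torsion_table(config.inputs["torsion"], topo)
            if config.inputs.get("helical"):
                helical_series = read_helical_table(config.inputs["helical"], topo)
        if config.shifts is not None:
            shift_table = nmr_mod.ShiftTable.from_csv(config.shifts)
        results["backbone"] = series

        stage = "classify"
        cutoff = config.cutoff_value
        states = state_mod.classify_backbone_state(series, cutoff)
        results["states"] = states
        bii = state_mod.bii_percentage(states)
        bii_df = pd.DataFrame(
            {
                "strand": [p.strand for p in states.phosphates],
                "pos5": [p.pos5 for p in states.phosphates],
                "dinucleotide": [p.dinucleotide for p in states.phosphates],
                "bii_percent": bii,
            }
        )
        results["bii_percent"] = bii_df
        _write_csv(bii_df, outdir / "bii_percent.csv", prov)
        if config.checkpoints:
            prof = state_mod.convergence_profile(states, config.checkpoints)
            prof_df = pd.DataFrame(
                prof, columns=[f"f{c}" for c in config.checkpoints]
            )
            prof_df.insert(0, "pos5", [p.pos5 for p in states.phosphates])
            prof_df.insert(0, "strand", [p.strand for p in states.phosphates])
            _write_csv(prof_df, outdir / "convergence.csv", prov)
            results["convergence"] = prof_df

        stage = "pair analysis"
        pair_series = pair_mod.combine_states(states, topo, config.exclude_terminal)
        results["pairs"] = pair_series
        pops = pair_mod.combination_populations(pair_series)
        results["combination_populations"] = pops
        _write_csv(pops.as_frame(), outdir / "combinations.csv", prov)
        census = pair_mod.transition_census(pair_series)
        results["transition_census"] = census
        census_df = pd.DataFrame(
            {
                "type": [1, 2, 3, 4],
                "count": census.counts,
                "fraction": census.fractions,
            }
        )
        _write_csv(census_df, outdir / "transitions.csv", prov)
        indep = pair_mod.independence_test(pair_series)
        results["independence"] = indep
        with open(outdir / "independence.json", "w") as fh:
            json.dump(indep.to_dict(), fh, indent=1)
        if indep.excluded_steps:
            logger.warning("independence scatter excluded steps: %s", indep.excluded_steps)

        stage = "shift bridge"
        if shift_table is not None:
            results["shift_table"] = shift_table
            _write_csv(nmr_mod.shift_tolerance_band(shift_table),
                       outdir / "shift_bii.csv", prov)
            nmr_pops, skipped = nmr_mod.nmr_combination_populations(
                shift_table, topo, config.exclude_terminal
            )
            results["nmr_combinations"] = nmr_pops
            _write_csv(nmr_pops.as_frame(), outdir / "nmr_combinations.csv", prov)
            if skipped:
                logger.warning("shift bridge skipped steps without partners: %s", skipped)
            # simulated-vs-NMR comparison on the common phosphates
            common = [
                p for p in states.phosphates
                if shift_table.has(p.strand, p.pos5)
            ]
            if len(common) >= 3:
                sim = [bii_df.set_index(["strand", "pos5"]).bii_percent[(p.strand, p.pos5)]
                       for p in common]
                exp = [shift_table.bii_percent(p.strand, p.pos5) for p in common]
                results["comparison"] = nmr_mod.compare_bii_sets(
                    sim, exp, tolerance=shift_table.tolerance
                )

        stage = "helical coupling"
        if config.generator is not None:
            g = dict(config.generator)
            emis = (
                syn.EmissionSpec.cmd_defaults()
                if g.get("emissions", "pmd") == "cmd"
                else syn.EmissionSpec.pmd_defaults()
            )
            helical_series = syn.simulate_helical(
                pair_series, emis, seed=config.seed + 2
            )
            write_helical_table(helical_series, outdir / "helical.csv")
        if helical_series is not None:
            results["helical"] = helical_series
            cstats = hel.conditional_helical_stats(helical_series, pair_series)
            results["conditional_stats"] = cstats
            _write_csv(cstats.table.reset_index(), outdir / "coupling.csv", prov)
            try:
                results["delta_extremes"] = hel.delta_extremes(cstats)
            except ValueError as exc:
                logger.warning("delta extremes unavailable: %s", exc)
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results
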