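"""End-to-end analysis pipeline: gate → trace → fit → descriptors → stats.

Ties the modules together for whole samples and cohorts, either from FCS
files on disk or straight from the synthetic generator.  The cohort runner
reproduces the study design: per sample (donor/day), one not-activated
control tube plus one tube per activating agent, all gated with
sample-specific FMO thresholds, each population's normalized median trace
fitted and reduced to the nine descriptors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from . import gating, kinetics, stats, synthetic
from .fcs_io import KineticRecording, read_fcs, append_recordings
from .gating import PopulationSet, apply_gate_tree, default_gate_tree, fmo_threshold, min_event_check
from .kinetics import (
    KineticDescriptors,
    KineticFit,
    bin_median_trace,
    derive_descriptors,
    descriptor_table,
    fit_kinetic,
    normalize_trace,
)
from .synthetic import SyntheticSpec, assemble_recording, generate_fmo

__all__ = [
    "RunConfig",
    "SampleResult",
    "CohortResult",
    "fmo_thresholds_for_sample",
    "analyze_recording",
    "run_cohort",
    "subset_comparison",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MARKER_CHANNELS = ("Fluo4", "CD3", "CD19", "CD27", "IgD", "CD38")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulation-driven or file-driven)."""

    out_dir: Path
    seed: int = 0
    n_samples: int = 15
    agents: Sequence[str] = synthetic.AGENTS
    event_rate: float = 300.0
    gap_seconds: float = 0.0
    t_end: float = 780.0
    bin_width: float = 5.0
    model: str = "auto"
    auc_baseline: Literal["start", "zero"] = "start"
    norm_stat: Literal["median", "mean"] = "median"
    fmo_quantile: float = 0.999
    high_multiplier: float = 10.0
    min_total: int = 300
    min_per_bin: int = 5
    # file-driven runs
    baseline_path: Path | None = None
    activation_path: Path | None = None
    fmo_paths: Mapping[str, Path] = field(default_factory=dict)
    gate_tree_path: Path | None = None


@dataclass
class SampleResult:
    populations: PopulationSet
    traces: dict[str, kinetics.PopulationTrace]
    fits: dict[str, KineticFit]
    descriptors: dict[str, KineticDescriptors]


@dataclass
class CohortResult:
    long: pd.DataFrame
    pivot: pd.DataFrame
    prevalences: pd.DataFrame
    fits: dict[tuple[str, str, str], KineticFit]
    excluded: list[tuple[str, str, str]]


def fmo_thresholds_for_sample(
    spec: SyntheticSpec,
    sample: int = 0,
    channels: Sequence[str] = MARKER_CHANNELS,
    quantile: float = 0.999,
    fmo_duration: float = 30.0,
) -> dict[str, float]:
    """Positivity thresholds from freshly generated FMO controls."""
    return {
        ch: fmo_threshold(
            generate_fmo(spec, ch, duration=fmo_duration, sample=sample),
            ch, quantile,
        )
        for ch in channels
    }


def analyze_recording(
    recording: KineticRecording,
    thresholds: Mapping[str, float],
    tree: Sequence[gating.GateNode] | None = None,
    config: RunConfig | None = None,
    leaves: Sequence[str] | None = None,
) -> SampleResult:
    """Gate one recording and fit every non-excluded leaf population.

    ``leaves`` restricts fitting to a subset of the leaf populations.
    """
    cfg = config or RunConfig(out_dir=Path("."))
    if tree is None:
        tree = default_gate_tree(recording.t_end, high_multiplier=cfg.high_multiplier)
    popset = apply_gate_tree(recording, tree, thresholds)
    popset = min_event_check(
        recording, popset, cfg.min_total, cfg.min_per_bin, cfg.bin_width
    )
    wanted = popset.leaves if leaves is None else [l for l in popset.leaves
                                                  if l in set(leaves)]
    traces: dict[str, kinetics.PopulationTrace] = {}
    fits: dict[str, KineticFit] = {}
    descs: dict[str, KineticDescriptors] = {}
    for leaf in wanted:
        if leaf in popset.excluded:
            logger.info("skipping %s: %s", leaf, popset.excluded[leaf])
            continue
        trace = bin_median_trace(
            recording, popset.masks[leaf], cfg.bin_width,
            min_per_bin=cfg.min_per_bin, name=leaf,
        )
        trace = normalize_trace(trace, stat=cfg.norm_stat)
        fit = fit_kinetic(trace, model=cfg.model)
        traces[leaf] = trace
        fits[leaf] = fit
        descs[leaf] = derive_descriptors(
            fit, recording.t_act, recording.t_end, auc_baseline=cfg.auc_baseline
        )
    return SampleResult(popset, traces, fits, descs)


def run_cohort(
    spec: SyntheticSpec,
    n_samples: int = 15,
    agents: Sequence[str] = synthetic.AGENTS,
    config: RunConfig | None = None,
) -> CohortResult:
    """Simulate and analyze a full cohort (n samples × one tube per agent)."""
    cfg = config or RunConfig(out_dir=Path("."), n_samples=n_samples)
    all_desc: dict[tuple[str, str, str], KineticDescriptors] = {}
    all_fits: dict[tuple[str, str, str], KineticFit] = {}
    excluded: list[tuple[str, str, str]] = []
    prev_rows = []
    for s in range(n_samples):
        thresholds = fmo_thresholds_for_sample(spec, s, quantile=cfg.fmo_quantile)
        for agent in agents:
            rec, _ = assemble_recording(spec, agent, sample=s)
            res = analyze_recording(rec, thresholds, config=cfg)
            for leaf, d in res.descriptors.items():
                all_desc[(f"s{s}", leaf, agent)] = d
                all_fits[(f"s{s}", leaf, agent)] = res.fits[leaf]
            for leaf in res.populations.leaves:
                if leaf in res.populations.excluded:
                    excluded.append((f"s{s}", leaf, agent))
            pf = res.populations.prevalence_frame()
            pf.insert(0, "sample", f"s{s}")
            pf.insert(1, "agent", agent)
            prev_rows.append(pf)
    long, pivot = descriptor_table(all_desc)
    return CohortResult(long, pivot, pd.concat(prev_rows, ignore_index=True),
                        all_fits, excluded)


def subset_comparison(
    long: pd.DataFrame,
    agent: str,
    descriptor: str,
    populations: Sequence[str] | None = None,
) -> list[stats.StatResult]:
    """Friedman + BH-adjusted pairwise Wilcoxon across subsets, matched by
    sample, for one agent and descriptor."""
    sub = long[(long["agent"] == agent) & (long["descriptor"] == descriptor)]
    wide = sub.pivot_table(index="sample", columns="population", values="value")
    if populations is not None:
        wide = wide[list(populations)]
    wide = wide.dropna()
    groups = [wide[c].to_numpy() for c in wide.columns]
    return stats.compare_paired(groups, labels=list(wide.columns))


def run_pipeline(config: RunConfig, spec: SyntheticSpec | None = None) -> dict:
    """Execute the full pipeline and write the output bundle.

    Simulation-driven when ``spec`` is given (or no file paths are set);
    otherwise reads the configured baseline/activation/FMO FCS files.
    Writes prevalence and descriptor tables (CSV), the median pivot, fit
    parameters (JSON) and a stats summary (JSON); returns the bundle paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    if spec is None and config.baseline_path is None:
        spec = synthetic.default_spec(
            event_rate=config.event_rate, seed=config.seed,
            gap_seconds=config.gap_seconds,
        )

    if spec is not None:
        cohort = run_cohort(spec, config.n_samples, config.agents, config)
        long, pivot, prev = cohort.long, cohort.pivot, cohort.prevalences
        fits = cohort.fits
        spec.save(out / "spec.yaml")
        bundle["spec"] = out / "spec.yaml"
    else:
        for name, p in {"baseline": config.baseline_path,
                        "activation": config.activation_path,
                        **config.fmo_paths}.items():
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"configured {name} file missing: {p}")
        baseline = read_fcs(config.baseline_path, "baseline")
        activation = read_fcs(config.activation_path, "activation")
        rec = append_recordings(baseline, activation, config.gap_seconds,
                                config.t_end)
        thresholds = {
            ch: fmo_threshold(read_fcs(p, "fmo"), ch, config.fmo_quantile)
            for ch, p in config.fmo_paths.items()
        }
        tree = (gating.load_gate_tree(config.gate_tree_path)
                if config.gate_tree_path else None)
        res = analyze_recording(rec, thresholds, tree=tree, config=config)
        fits = {("s0", leaf, "sample"): f for leaf, f in res.fits.items()}
        long, pivot = descriptor_table(
            {("s0", leaf, "sample"): d for leaf, d in res.descriptors.items()}
        )
        prev = res.populations.prevalence_frame()

    long.to_csv(out / "descriptors_long.csv", index=False)
    pivot.to_csv(out / "descriptors_pivot.csv")
    prev.to_csv(out / "prevalences.csv", index=False)
    with open(out / "fits.json", "w") as fh:
        json.dump({"|".join(k): f.to_dict() for k, f in fits.items()}, fh, indent=1)
    bundle.update(
        descriptors_long=out / "descriptors_long.csv",
        descriptors_pivot=out / "descriptors_pivot.csv",
        prevalences=out / "prevalences.csv",
        fits=out / "fits.json",
    )

    # statistics layer on the cohort tables
    stats_out: dict[str, list[dict]] = {}
    if "sample" in long.columns and long["sample"].nunique() >= 5:
        for agent in sorted(set(long["agent"])):
            for desc in ("max", "ending", "auc"):
                try:
                    res_list = subset_comparison(long, agent, desc)
                except ValueError:
                    continue
                stats_out[f"{agent}:{desc}"] = [r.to_dict() for r in res_list]
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=1)
    bundle["stats"] = out / "stats.json"
    logger.info("pipeline outputs written to %s", out)
    return bundle
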