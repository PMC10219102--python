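"""Ground-truth-labeled synthetic kinetic cytometry datasets.

Emulates the acquisition design of a Fluo-4 B-cell kinetic experiment:
events arrive as a Poisson process; each event belongs to one population
(five B-cell subsets plus non-B lymphocytes) drawn by prevalence; scatter
and surface-marker channels come from per-population lognormal mixtures
with configurable separation; the Fluo-4 channel follows the population's
true double-logistic trajectory (midpoints measured from agent contact)
times a per-cell dye-loading factor and multiplicative noise.  Because the
analysis consumes per-bin population medians, per-cell heterogeneity beyond
loading and noise is deliberately not modeled — all cells of a population
share one trajectory.

Every generator is deterministic given the spec's seed; a baseline stream
carries the resting level only (the agent has not yet met the cells), the
activation stream evaluates the trajectory at time-since-activation
``t + gap_seconds``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fcs_io import (
    DEFAULT_T_END,
    EventStream,
    KineticRecording,
    TIME_CHANNEL,
    append_recordings,
    write_fcs,
)
from .kinetics import double_logistic

__all__ = [
    "CurveParams",
    "PopulationSpec",
    "SyntheticSpec",
    "default_spec",
    "generate_recording",
    "generate_fmo",
    "generate_titration",
    "assemble_recording",
    "write_sample",
    "AGENTS",
    "B_SUBSETS",
    "TITRATION_UG_ML",
]

DEFAULT_PANEL = [
    "Time", "FSC-A", "FSC-H", "SSC-A", "Fluo4", "CD3", "CD19", "CD27",
    "IgD", "CD38",
]
B_SUBSETS = ("naive", "NSw", "Sw", "DN", "ASC")
AGENTS = ("NA", "IgG", "IgM", "IgG+M", "CpG", "ionomycin")

# anti-IgG+M titration series (µg/mL)
TITRATION_UG_ML = (0.1, 0.5, 1.0, 2.5, 5.0, 7.5, 10.0, 20.0)

_MARKER_SIGMA = 0.35
_NEG_MEDIAN = 100.0


@dataclass(frozen=True)
class CurveParams:
    """True double-logistic trajectory in standardized units (S is the
    resting level; midpoints are seconds after agent contact)."""

    S: float = 1.0
    H1: float = 0.0
    k1: float = 1.0
    m1: float = 0.0
    H2: float = 0.0
    k2: float = 1.0
    m2: float = 0.0

    def values(self) -> tuple[float, ...]:
        return (self.S, self.H1, self.k1, self.m1, self.H2, self.k2, self.m2)

    def __call__(self, t_since_activation):
        return double_logistic(t_since_activation, *self.values())

    @property
    def ending(self) -> float:
        return self.S + self.H1 - self.H2

    def peak(self, t_end: float = 720.0) -> float:
        """Trajectory maximum within t_end seconds of activation."""
        grid = np.linspace(0.0, t_end, 14401)
        return float(np.max(self(grid)))

    def scaled(self, occupancy: float) -> "CurveParams":
        """Receptor-occupancy scaling: both amplitudes shrink together so
        Max−S and Ending−S stay proportional to the occupancy."""
        return replace(self, H1=self.H1 * occupancy, H2=self.H2 * occupancy)


@dataclass
class PopulationSpec:
    name: str
    prevalence: float
    markers: dict[str, tuple[float, float]]      # channel -> (median, sigma_log)
    baseline_mfi: float                          # resting Fluo-4 MFI (a.u.)
    kinetics: dict[str, CurveParams] = field(default_factory=dict)


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic sample.

    Defaults mirror the acquisition protocol: 60 s of baseline, 720 s after
    activation, curves standardized to end at 780 s; 5% multiplicative
    per-cell noise and a 25% dye-loading spread.
    """

    populations: list[PopulationSpec]
    panel: list[str] = field(default_factory=lambda: list(DEFAULT_PANEL))
    event_rate: float = 300.0            # events/s
    baseline_duration: float = 60.0      # s
    activation_duration: float = 720.0   # s
    gap_seconds: float = 0.0             # measured tube-out interval
    t_end: float = DEFAULT_T_END
    noise_cv: float = 0.05
    loading_cv: float = 0.25
    fsch_ratio_sigma: float = 0.03       # FSC-H/FSC-A spread (singlets)
    autofluorescence: dict[str, float] = field(default_factory=dict)
    drift_per_s: float = 0.0             # optional linear instrument drift
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p.prevalence for p in self.populations)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"population prevalences sum to {total}, not 1")
        if min(self.baseline_duration, self.activation_duration) <= 0:
            raise ValueError("durations must be positive")
        if self.noise_cv < 0 or self.loading_cv < 0:
            raise ValueError("noise_cv and loading_cv must be >= 0")

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "event_rate": self.event_rate,
            "baseline_duration": self.baseline_duration,
            "activation_duration": self.activation_duration,
            "gap_seconds": self.gap_seconds,
            "t_end": self.t_end,
            "noise_cv": self.noise_cv,
            "loading_cv": self.loading_cv,
            "fsch_ratio_sigma": self.fsch_ratio_sigma,
            "autofluorescence": self.autofluorescence,
            "drift_per_s": self.drift_per_s,
            "seed": self.seed,
            "populations": [
                {
                    "name": p.name,
                    "prevalence": p.prevalence,
                    "baseline_mfi": p.baseline_mfi,
                    "markers": {c: list(v) for c, v in p.markers.items()},
                    "kinetics": {a: list(cp.values()) for a, cp in p.kinetics.items()},
                }
                for p in self.populations
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        pops = [
            PopulationSpec(
                name=p["name"], prevalence=p["prevalence"],
                baseline_mfi=p["baseline_mfi"],
                markers={c: tuple(v) for c, v in p["markers"].items()},
                kinetics={a: CurveParams(*v) for a, v in p["kinetics"].items()},
            )
            for p in d["populations"]
        ]
        kw = {k: v for k, v in d.items() if k != "populations"}
        return cls(populations=pops, **kw)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Default study spec


def _marker_set(separation: float, **levels: str) -> dict[str, tuple[float, float]]:
    """Per-channel (median, sigma) from qualitative levels neg/pos/hi."""
    s = _MARKER_SIGMA
    med = {
        "neg": _NEG_MEDIAN,
        "pos": _NEG_MEDIAN * float(np.exp(separation * s)),
        "hi": _NEG_MEDIAN * float(np.exp(2.0 * separation * s)),
    }
    out = {"FSC-A": (100_000.0, 0.12), "SSC-A": (30_000.0, 0.25)}
    for ch, level in levels.items():
        out[ch] = (med[level], s)
    return out


# True trajectories per subset and agent, in standardized units, encoding the
# study's qualitative pattern: under BCR cross-linking (IgG+M) memory subsets
# out-respond naive cells; ASCs respond but decay back without a plateau;
# ionomycin drives every subset hard with ASCs plateauing lowest; CpG gives a
# slow gradual rise; the not-activated control is flat.
_KINETICS: dict[str, dict[str, CurveParams]] = {
    "naive": {
        "NA": CurveParams(),
        "IgG": CurveParams(1, 0.15, 0.05, 80, 0.10, 0.010, 280),
        "IgM": CurveParams(1, 0.50, 0.05, 70, 0.30, 0.010, 260),
        "IgG+M": CurveParams(1, 0.60, 0.06, 60, 0.35, 0.012, 240),
        "CpG": CurveParams(1, 0.50, 0.010, 350),
        "ionomycin": CurveParams(1, 3.0, 0.25, 25, 1.0, 0.008, 320),
    },
    "NSw": {
        "NA": CurveParams(),
        "IgG": CurveParams(1, 0.30, 0.06, 70, 0.20, 0.010, 260),
        "IgM": CurveParams(1, 1.00, 0.08, 50, 0.55, 0.012, 240),
        "IgG+M": CurveParams(1, 1.10, 0.08, 50, 0.60, 0.012, 240),
        "CpG": CurveParams(1, 0.50, 0.010, 350),
        "ionomycin": CurveParams(1, 3.6, 0.25, 25, 1.1, 0.008, 320),
    },
    "Sw": {
        "NA": CurveParams(),
        "IgG": CurveParams(1, 1.40, 0.09, 45, 0.80, 0.012, 230),
        "IgM": CurveParams(1, 0.40, 0.05, 70, 0.25, 0.010, 260),
        "IgG+M": CurveParams(1, 1.60, 0.09, 45, 0.90, 0.012, 230),
        "CpG": CurveParams(1, 0.50, 0.010, 350),
        "ionomycin": CurveParams(1, 4.0, 0.25, 25, 1.2, 0.008, 320),
    },
    "DN": {
        "NA": CurveParams(),
        "IgG": CurveParams(1, 1.50, 0.09, 45, 0.85, 0.012, 230),
        "IgM": CurveParams(1, 0.45, 0.05, 70, 0.28, 0.010, 260),
        "IgG+M": CurveParams(1, 1.70, 0.09, 45, 0.95, 0.012, 230),
        "CpG": CurveParams(1, 0.50, 0.010, 350),
        "ionomycin": CurveParams(1, 4.0, 0.25, 25, 1.2, 0.008, 320),
    },
    "ASC": {
        "NA": CurveParams(),
        "IgG": CurveParams(1, 0.60, 0.07, 55, 0.55, 0.008, 280),
        "IgM": CurveParams(),
        "IgG+M": CurveParams(1, 0.70, 0.07, 55, 0.62, 0.008, 280),
        "CpG": CurveParams(1, 0.15, 0.008, 400),
        "ionomycin": CurveParams(1, 2.0, 0.25, 25, 1.7, 0.008, 300),
    },
    "nonB": {
        "NA": CurveParams(),
        "IgG": CurveParams(),
        "IgM": CurveParams(),
        "IgG+M": CurveParams(),
        "CpG": CurveParams(),
        "ionomycin": CurveParams(1, 3.0, 0.25, 25, 1.0, 0.008, 320),
    },
}

_BASELINE_MFI = {"naive": 300.0, "NSw": 400.0, "Sw": 450.0, "DN": 420.0,
                 "ASC": 500.0, "nonB": 350.0}
_PREVALENCE = {"naive": 0.60, "NSw": 0.10, "Sw": 0.12, "DN": 0.05,
               "ASC": 0.01, "nonB": 0.12}


def default_spec(
    separation: float = 6.0,
    event_rate: float = 300.0,
    seed: int = 0,
    noise_cv: float = 0.05,
    gap_seconds: float = 0.0,
    **overrides,
) -> SyntheticSpec:
    """The default five-subset study spec.

    ``separation`` is the marker-mixture separation in units of the
    log-scale sigma (6 gives near-perfect gating; 2 heavy overlap).
    """
    marker_levels = {
        "naive": dict(CD3="neg", CD19="pos", CD27="neg", IgD="pos", CD38="neg"),
        "NSw":   dict(CD3="neg", CD19="pos", CD27="pos", IgD="pos", CD38="neg"),
        "Sw":    dict(CD3="neg", CD19="pos", CD27="pos", IgD="neg", CD38="neg"),
        "DN":    dict(CD3="neg", CD19="pos", CD27="neg", IgD="neg", CD38="neg"),
        "ASC":   dict(CD3="neg", CD19="pos", CD27="hi", IgD="neg", CD38="hi"),
        "nonB":  dict(CD3="pos", CD19="neg", CD27="neg", IgD="neg", CD38="neg"),
    }
    pops = [
        PopulationSpec(
            name=name,
            prevalence=_PREVALENCE[name],
            markers=_marker_set(separation, **marker_levels[name]),
            baseline_mfi=_BASELINE_MFI[name],
            kinetics=dict(_KINETICS[name]),
        )
        for name in ("naive", "NSw", "Sw", "DN", "ASC", "nonB")
    ]
    # Unstained/unloaded events sit at the autofluorescence level, which is
    # exactly the negative mixture component of each marker; only Fluo-4
    # differs (an unloaded cell is far dimmer than a resting loaded one).
    autofluo = {ch: _NEG_MEDIAN for ch in ("CD3", "CD19", "CD27", "IgD", "CD38")}
    autofluo["Fluo4"] = 30.0
    return SyntheticSpec(
        populations=pops, event_rate=event_rate, seed=seed,
        noise_cv=noise_cv, gap_seconds=gap_seconds,
        autofluorescence=autofluo, **overrides,
    )


# ---------------------------------------------------------------------------
# Event generation


def _rng(spec: SyntheticSpec, *context: str | int) -> np.random.Generator:
    words = [spec.seed & 0x7FFFFFFF]
    for c in context:
        words.append(zlib.crc32(str(c).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(words)


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _draw_events(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    duration: float,
    fluo_curve_offset: float | None,
    agent: str | None,
    omit_channel: str | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One stream: Poisson arrivals, mixture channels, trajectory Fluo-4.

    ``fluo_curve_offset`` maps stream time to time-since-activation; None
    means resting level (baseline stream or FMO).  ``omit_channel`` draws
    that channel from autofluorescence only (FMO control).
    """
    n = int(rng.poisson(spec.event_rate * duration))
    times = np.sort(rng.uniform(0.0, duration, size=n))
    prev = np.array([p.prevalence for p in spec.populations])
    labels_idx = rng.choice(len(spec.populations), size=n, p=prev / prev.sum())
    labels = np.array(spec.population_names, dtype=object)[labels_idx]

    cols: dict[str, np.ndarray] = {TIME_CHANNEL: times}
    fsca = np.empty(n)
    for i, pop in enumerate(spec.populations):
        m = labels_idx == i
        med, sig = pop.markers["FSC-A"]
        fsca[m] = rng.lognormal(np.log(med), sig, size=int(m.sum()))
    cols["FSC-A"] = fsca
    cols["FSC-H"] = fsca * rng.lognormal(0.0, spec.fsch_ratio_sigma, size=n)

    marker_channels = [c for c in spec.panel
                       if c not in (TIME_CHANNEL, "FSC-A", "FSC-H", "Fluo4")]
    for ch in marker_channels:
        vals = np.empty(n)
        if ch == omit_channel:
            med = spec.autofluorescence.get(ch, 30.0)
            vals = rng.lognormal(np.log(med), _MARKER_SIGMA, size=n)
        else:
            for i, pop in enumerate(spec.populations):
                m = labels_idx == i
                med, sig = pop.markers.get(ch, (spec.autofluorescence.get(ch, 30.0),
                                                _MARKER_SIGMA))
                vals[m] = rng.lognormal(np.log(med), sig, size=int(m.sum()))
        cols[ch] = vals

    # Fluo-4: population trajectory x loading x noise (medians untouched:
    # both lognormal factors have median 1)
    s_load = _cv_to_sigma(spec.loading_cv)
    s_noise = _cv_to_sigma(spec.noise_cv)
    fluo = np.empty(n)
    if omit_channel == "Fluo4":
        med = spec.autofluorescence.get("Fluo4", 30.0)
        fluo = rng.lognormal(np.log(med), 0.4, size=n)
    else:
        loading = rng.lognormal(0.0, s_load, size=n)
        noise = rng.lognormal(0.0, s_noise, size=n)
        for i, pop in enumerate(spec.populations):
            m = labels_idx == i
            if fluo_curve_offset is None:
                level = np.full(int(m.sum()), 1.0)
            else:
                params = pop.kinetics[agent]
                level = params(times[m] + fluo_curve_offset)
            fluo[m] = pop.baseline_mfi * level
        fluo = fluo * loading * noise
        if spec.drift_per_s:
            fluo = fluo * (1.0 + spec.drift_per_s * times)
    cols["Fluo4"] = fluo

    df = pd.DataFrame({c: cols[c] for c in spec.panel})
    return df, labels


def generate_recording(
    spec: SyntheticSpec, agent: str, sample: int = 0
) -> tuple[EventStream, EventStream, dict[str, np.ndarray]]:
    """Baseline + activation event streams with ground-truth labels.

    The baseline stream carries the resting Fluo-4 level; the activation
    stream evaluates each population's trajectory at ``t + gap_seconds``
    seconds after agent contact.  Deterministic in (spec.seed, agent,
    sample).
    """
    for pop in spec.populations:
        if agent not in pop.kinetics:
            raise KeyError(
                f"population {pop.name!r} has no truth curve for agent {agent!r}"
            )
    meta = {"$TIMESTEP": "0.01", "agent": agent, "sample": str(sample)}

    rng_b = _rng(spec, "baseline", agent, sample)
    df_b, labels_b = _draw_events(spec, rng_b, spec.baseline_duration,
                                  fluo_curve_offset=None, agent=agent)
    baseline = EventStream(df_b, list(spec.panel), "baseline",
                           {**meta, "$FIL": f"s{sample}_{agent}_baseline.fcs"})

    rng_a = _rng(spec, "activation", agent, sample)
    df_a, labels_a = _draw_events(spec, rng_a, spec.activation_duration,
                                  fluo_curve_offset=spec.gap_seconds, agent=agent)
    activation = EventStream(df_a, list(spec.panel), "activation",
                             {**meta, "$FIL": f"s{sample}_{agent}_activation.fcs"})
    truth = {"baseline_labels": labels_b, "activation_labels": labels_a}
    return baseline, activation, truth


def generate_fmo(
    spec: SyntheticSpec,
    omitted_channel: str,
    duration: float = 60.0,
    sample: int = 0,
) -> EventStream:
    """FMO control: full stain except ``omitted_channel``, which is drawn
    from the autofluorescence (negative) component only."""
    if omitted_channel not in spec.panel:
        raise KeyError(f"channel {omitted_channel!r} not in panel {spec.panel}")
    rng = _rng(spec, "fmo", omitted_channel, sample)
    df, _ = _draw_events(spec, rng, duration, fluo_curve_offset=None,
                         agent=None, omit_channel=omitted_channel)
    return EventStream(df, list(spec.panel), "fmo",
                       {"$TIMESTEP": "0.01", "fmo_channel": omitted_channel,
                        "$FIL": f"s{sample}_fmo_{omitted_channel}.fcs"})


def generate_titration(
    spec: SyntheticSpec,
    concentrations: Sequence[float] = TITRATION_UG_ML,
    ec50_truth: Mapping[str, float] | float = 2.5,
    agent: str = "IgG+M",
    sample: int = 0,
) -> list[dict]:
    """Titration series: per concentration X, every population's truth
    amplitudes are scaled by the receptor occupancy X/(EC50 + X).

    Returns one dict per concentration with keys ``concentration``,
    ``baseline``, ``activation``, ``truth``, ``spec``.
    """
    out = []
    for conc in concentrations:
        if conc < 0:
            raise ValueError("concentrations must be non-negative")
        pops = []
        for pop in spec.populations:
            ec50 = (ec50_truth.get(pop.name, 2.5)
                    if isinstance(ec50_truth, Mapping) else float(ec50_truth))
            if ec50 <= 0:
                raise ValueError("ec50_truth must be positive")
            occ = conc / (ec50 + conc)
            kin = dict(pop.kinetics)
            kin[agent] = pop.kinetics[agent].scaled(occ)
            pops.append(replace(pop, kinetics=kin))
        sub = replace(spec, populations=pops)
        b, a, t = generate_recording(sub, agent, sample=hash_conc(sample, conc))
        out.append({"concentration": conc, "baseline": b, "activation": a,
                    "truth": t, "spec": sub})
    return out


def hash_conc(sample: int, conc: float) -> int:
    return (sample * 1000 + int(round(conc * 10))) & 0x7FFFFFFF


def assemble_recording(
    spec: SyntheticSpec, agent: str, sample: int = 0
) -> tuple[KineticRecording, np.ndarray]:
    """Generate, append and truncate one sample; returns the merged
    recording plus per-event truth labels aligned with its event table."""
    baseline, activation, truth = generate_recording(spec, agent, sample)
    rec = append_recordings(baseline, activation, spec.gap_seconds, spec.t_end)
    t_act = rec.t_act
    all_times = np.concatenate(
        [baseline.times(), activation.times() + t_act]
    )
    keep = all_times <= rec.t_end
    labels = np.concatenate(
        [truth["baseline_labels"], truth["activation_labels"]]
    )[keep]
    assert len(labels) == rec.n_events
    return rec, labels


def write_sample(
    spec: SyntheticSpec,
    agent: str,
    out_dir,
    sample: int = 0,
    fmo_channels: Iterable[str] = ("Fluo4", "CD3", "CD19", "CD27", "IgD", "CD38"),
) -> dict[str, Path]:
    """Materialize one sample as FCS 3.1 pairs + FMOs + truth-label CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    baseline, activation, truth = generate_recording(spec, agent, sample)
    paths = {
        "baseline": write_fcs(baseline, out_dir / f"s{sample}_{agent}_baseline.fcs"),
        "activation": write_fcs(activation, out_dir / f"s{sample}_{agent}_activation.fcs"),
    }
    for ch in fmo_channels:
        fmo = generate_fmo(spec, ch, sample=sample)
        paths[f"fmo_{ch}"] = write_fcs(fmo, out_dir / f"s{sample}_fmo_{ch}.fcs")
    labels = pd.DataFrame(
        {
            "role": ["baseline"] * len(truth["baseline_labels"])
            + ["activation"] * len(truth["activation_labels"]),
            "population": np.concatenate(
                [truth["baseline_labels"], truth["activation_labels"]]
            ),
        }
    )
    label_path = out_dir / f"s{sample}_{agent}_truth.csv"
    labels.to_csv(label_path, index=False)
    paths["truth"] = label_path
    spec_path = out_dir / "spec.yaml"
    spec.save(spec_path)
    paths["spec"] = spec_path
    return paths
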