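"""Hierarchical gating of kinetic recordings into B-cell subsets.

The default tree follows the standard B-cell kinetic panel: a time-stability
interval, singlets (FSC-H/FSC-A ratio band), lymphocytes (FSC/SSC polygon),
live dye-loaded cells (Fluo-4⁺ against the Fluo-4 FMO), B cells
(CD3⁻CD19⁺), and the five leaf subsets

    naive  IgD⁺ CD27⁻          NSw  IgD⁺ CD27⁺        Sw  IgD⁻ CD27⁺
    DN     IgD⁻ CD27⁻          ASC  IgD⁻ CD27ʰⁱ CD38ʰⁱ

ASC events are carved out of the IgD⁻ fraction before Sw/DN assignment so
the leaves stay disjoint.  Positivity thresholds come from
fluorescence-minus-one (FMO) controls via an upper quantile; the "high"
gates (ASC) multiply the FMO threshold by a configurable factor.  All gates
operate on compensated linear values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath

from .fcs_io import EventStream, KineticRecording, TIME_CHANNEL

__all__ = [
    "GateNode",
    "PopulationSet",
    "fmo_threshold",
    "apply_gate_tree",
    "min_event_check",
    "relative_expression",
    "default_gate_tree",
    "reduced_cd27_tree",
    "load_gate_tree",
    "save_gate_tree",
]

logger = logging.getLogger(__name__)

GateKind = Literal[
    "interval", "rectangle", "polygon", "ratio_singlet",
    "quantile_threshold", "marker_combo",
]

FMO_MIN_EVENTS = 100
DEFAULT_FMO_QUANTILE = 0.999
DEFAULT_HIGH_MULTIPLIER = 10.0


@dataclass
class GateNode:
    """One node of a gating hierarchy.

    ``parameters`` depend on ``kind``:
      interval          low/high on channels[0]
      rectangle         xlow/xhigh/ylow/yhigh on channels[0]/[1]
      polygon           vertices: [[x, y], ...] (>= 3) on channels[0]/[1]
      ratio_singlet     low/high band on channels[0]/channels[1]
      quantile_threshold optional multiplier on the FMO threshold of channels[0]
      marker_combo      criteria: [{channel, side: '+'/'-', multiplier}, ...]
    ``side`` applies to threshold kinds ('above'/'below'); ``exclude`` names
    sibling populations whose events are removed from this gate (carve-out).
    """

    name: str
    parent: str | None
    kind: GateKind
    channels: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    side: str = "above"
    exclude: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == "polygon" and len(self.parameters.get("vertices", [])) < 3:
            raise ValueError(f"polygon gate {self.name!r} needs >= 3 vertices")
        if self.kind == "interval":
            if not self.parameters["low"] < self.parameters["high"]:
                raise ValueError(f"interval gate {self.name!r}: low must be < high")


@dataclass
class PopulationSet:
    """Event-to-population assignments for one recording."""

    masks: dict[str, np.ndarray]            # population -> boolean event mask
    counts: dict[str, int]
    prevalences: dict[str, float]           # % of parent population
    parents: dict[str, str | None]
    leaves: list[str]
    excluded: dict[str, str] = field(default_factory=dict)  # name -> reason

    def indices(self, name: str) -> np.ndarray:
        return np.nonzero(self.masks[name])[0]

    def leaf_labels(self, n_events: int) -> np.ndarray:
        """Per-event leaf label ('' where unassigned); leaves are disjoint."""
        labels = np.full(n_events, "", dtype=object)
        for leaf in self.leaves:
            labels[self.masks[leaf]] = leaf
        return labels

    def prevalence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": list(self.counts),
                "parent": [self.parents[p] for p in self.counts],
                "count": list(self.counts.values()),
                "prevalence_pct": [self.prevalences[p] for p in self.counts],
                "excluded": [self.excluded.get(p, "") for p in self.counts],
            }
        )


def fmo_threshold(
    fmo: EventStream, channel: str, quantile: float = DEFAULT_FMO_QUANTILE
) -> float:
    """Positivity threshold from an FMO control: an upper empirical quantile.

    Events above the returned value on ``channel`` are called positive.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    values = fmo.events[channel].to_numpy(float)
    if len(values) < FMO_MIN_EVENTS:
        raise ValueError(
            f"FMO control has {len(values)} events on {channel!r}; "
            f"at least {FMO_MIN_EVENTS} required"
        )
    return float(np.quantile(values, quantile))


def _node_mask(
    node: GateNode,
    events: pd.DataFrame,
    thresholds: Mapping[str, float],
) -> np.ndarray:
    p = node.parameters
    if node.kind == "interval":
        v = events[node.channels[0]].to_numpy(float)
        return (v >= p["low"]) & (v <= p["high"])
    if node.kind == "rectangle":
        x = events[node.channels[0]].to_numpy(float)
        y = events[node.channels[1]].to_numpy(float)
        return (x >= p["xlow"]) & (x <= p["xhigh"]) & (y >= p["ylow"]) & (y <= p["yhigh"])
    if node.kind == "polygon":
        x = events[node.channels[0]].to_numpy(float)
        y = events[node.channels[1]].to_numpy(float)
        path = MplPath(np.asarray(p["vertices"], float))
        return path.contains_points(np.column_stack([x, y]))
    if node.kind == "ratio_singlet":
        num = events[node.channels[0]].to_numpy(float)
        den = events[node.channels[1]].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den != 0, num / den, np.inf)
        return (ratio >= p.get("low", 0.85)) & (ratio <= p.get("high", 1.15))
    if node.kind == "quantile_threshold":
        ch = node.channels[0]
        thr = p.get("threshold", thresholds.get(ch))
        if thr is None:
            raise ValueError(f"no threshold available for channel {ch!r}")
        thr = thr * p.get("multiplier", 1.0)
        v = events[ch].to_numpy(float)
        return v > thr if node.side == "above" else v <= thr
    if node.kind == "marker_combo":
        mask = np.ones(len(events), dtype=bool)
        for crit in p["criteria"]:
            ch = crit["channel"]
            thr = crit.get("threshold", thresholds.get(ch))
            if thr is None:
                raise ValueError(f"no threshold available for channel {ch!r}")
            thr = thr * crit.get("multiplier", 1.0)
            v = events[ch].to_numpy(float)
            mask &= v > thr if crit["side"] == "+" else v <= thr
        return mask
    raise ValueError(f"unknown gate kind {node.kind!r}")


def apply_gate_tree(
    recording: KineticRecording,
    tree: Sequence[GateNode],
    thresholds: Mapping[str, float] | None = None,
) -> PopulationSet:
    """Evaluate a gate hierarchy on a recording.

    Nodes must be listed parents-before-children; a node's ``exclude`` list
    names earlier siblings whose events are subtracted (used to carve the
    ASC gate out of the IgD⁻ fraction before Sw/DN assignment).
    """
    thresholds = dict(thresholds or {})
    events = recording.events
    needed = {c for n in tree for c in n.channels} | {
        crit["channel"] for n in tree if n.kind == "marker_combo"
        for crit in n.parameters["criteria"]
    }
    missing = sorted(needed - set(events.columns))
    if missing:
        raise ValueError(f"channels referenced by gate tree absent: {missing}")

    n = len(events)
    masks: dict[str, np.ndarray] = {"root": np.ones(n, dtype=bool)}
    parents: dict[str, str | None] = {"root": None}
    if n == 0:
        logger.warning("recording holds no events; empty population set")
    for node in tree:
        parent = node.parent or "root"
        if parent not in masks:
            raise ValueError(f"gate {node.name!r} listed before parent {parent!r}")
        mask = masks[parent] & _node_mask(node, events, thresholds)
        for sib in node.exclude:
            if sib not in masks:
                raise ValueError(f"exclusion {sib!r} of {node.name!r} not yet gated")
            mask &= ~masks[sib]
        masks[node.name] = mask
        parents[node.name] = parent

    counts = {name: int(m.sum()) for name, m in masks.items() if name != "root"}
    prevalences = {}
    for name in counts:
        pcount = int(masks[parents[name]].sum())
        prevalences[name] = 100.0 * counts[name] / pcount if pcount else 0.0
    children = {p for p in parents.values() if p is not None}
    leaves = [name for name in counts if name not in children]
    return PopulationSet(
        masks={k: v for k, v in masks.items() if k != "root"},
        counts=counts, prevalences=prevalences,
        parents={k: v for k, v in parents.items() if k != "root"},
        leaves=leaves,
    )


def min_event_check(
    recording: KineticRecording,
    populations: PopulationSet,
    min_total: int = 300,
    min_per_bin: int = 5,
    bin_width: float = 5.0,
    max_sparse_fraction: float = 0.2,
) -> PopulationSet:
    """Mark populations whose event numbers are too low for curve fitting.

    A population is excluded when its total event count falls below
    ``min_total`` or when more than ``max_sparse_fraction`` of the
    ``bin_width``-second bins spanning [0, t_end] hold fewer than
    ``min_per_bin`` events.  Excluded populations are only marked; the
    fitting layer refuses them.
    """
    t = recording.times()
    edges = np.arange(0.0, recording.t_end + bin_width, bin_width)
    for name, mask in populations.masks.items():
        total = int(mask.sum())
        if total == 0:
            populations.excluded[name] = "empty"
            continue
        if total < min_total:
            populations.excluded[name] = f"too few events ({total} < {min_total})"
            continue
        counts, _ = np.histogram(t[mask], bins=edges)
        sparse = float(np.mean(counts < min_per_bin))
        if sparse > max_sparse_fraction:
            populations.excluded[name] = (
                f"{sparse:.0%} of {bin_width:.0f}s bins hold < {min_per_bin} events"
            )
    return populations


def relative_expression(sample_mfi: float, fmo_mfi: float) -> float:
    """Relative marker expression: sample MFI divided by the FMO MFI."""
    if fmo_mfi <= 0:
        raise ValueError(f"FMO MFI must be positive, got {fmo_mfi}")
    return sample_mfi / fmo_mfi


# ---------------------------------------------------------------------------
# Default trees


def default_gate_tree(
    t_end: float = 780.0,
    singlet_band: tuple[float, float] = (0.85, 1.15),
    lymph_polygon: Sequence[tuple[float, float]] | None = None,
    high_multiplier: float = DEFAULT_HIGH_MULTIPLIER,
) -> list[GateNode]:
    """The standard kinetic B-cell gating hierarchy (see module docstring).

    The lymphocyte polygon and the ASC high-gate multiplier are declared
    defaults sized for the bundled simulator's scatter scales; on real data
    supply instrument-appropriate values (or a YAML tree).
    """
    if lymph_polygon is None:
        lymph_polygon = [
            (3_000, 20_000), (200_000, 20_000), (200_000, 400_000),
            (3_000, 400_000),
        ]
    hi = high_multiplier
    return [
        GateNode("stable", None, "interval", [TIME_CHANNEL],
                 {"low": 0.0, "high": t_end}),
        GateNode("singlets", "stable", "ratio_singlet", ["FSC-H", "FSC-A"],
                 {"low": singlet_band[0], "high": singlet_band[1]}),
        GateNode("lymphocytes", "singlets", "polygon", ["SSC-A", "FSC-A"],
                 {"vertices": [list(v) for v in lymph_polygon]}),
        GateNode("live", "lymphocytes", "quantile_threshold", ["Fluo4"], {},
                 side="above"),
        GateNode("Bcells", "live", "marker_combo", [],
                 {"criteria": [
                     {"channel": "CD3", "side": "-"},
                     {"channel": "CD19", "side": "+"},
                 ]}),
        GateNode("ASC", "Bcells", "marker_combo", [],
                 {"criteria": [
                     {"channel": "IgD", "side": "-"},
                     {"channel": "CD27", "side": "+", "multiplier": hi},
                     {"channel": "CD38", "side": "+", "multiplier": hi},
                 ]}),
        GateNode("naive", "Bcells", "marker_combo", [],
                 {"criteria": [
                     {"channel": "IgD", "side": "+"},
                     {"channel": "CD27", "side": "-"},
                 ]}),
        GateNode("NSw", "Bcells", "marker_combo", [],
                 {"criteria": [
                     {"channel": "IgD", "side": "+"},
                     {"channel": "CD27", "side": "+"},
                 ]}),
        GateNode("Sw", "Bcells", "marker_combo", [],
                 {"criteria": [
                     {"channel": "IgD", "side": "-"},
                     {"channel": "CD27", "side": "+"},
                 ]}, exclude=["ASC"]),
        GateNode("DN", "Bcells", "marker_combo", [],
                 {"criteria": [
                     {"channel": "IgD", "side": "-"},
                     {"channel": "CD27", "side": "-"},
                 ]}, exclude=["ASC"]),
    ]


def reduced_cd27_tree(t_end: float = 780.0) -> list[GateNode]:
    """Reduced panel without IgD: leaves are CD27⁻ (naive) and CD27⁺ (memory)."""
    tree = [n for n in default_gate_tree(t_end)
            if n.name in {"stable", "singlets", "lymphocytes", "live", "Bcells"}]
    tree += [
        GateNode("CD27-", "Bcells", "quantile_threshold", ["CD27"], {},
                 side="below"),
        GateNode("CD27+", "Bcells", "quantile_threshold", ["CD27"], {},
                 side="above"),
    ]
    return tree


# ---------------------------------------------------------------------------
# YAML round-trip


def save_gate_tree(tree: Sequence[GateNode], path) -> None:
    payload = [
        {"name": n.name, "parent": n.parent, "kind": n.kind,
         "channels": n.channels, "parameters": n.parameters, "side": n.side,
         "exclude": n.exclude}
        for n in tree
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_gate_tree(path) -> list[GateNode]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [GateNode(**entry) for entry in payload]
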