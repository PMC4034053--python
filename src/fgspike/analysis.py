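"""Observables and experiments: counts, onsets, winners, area ratios.

The network's decision is read from the two output cells by first-spike
latency: the cell that fires first names the category (cell 1 for
vertical-border-dominant shapes, cell 2 for horizontal).  Experiments run a
whole image set (original, mirror, contrast and FG reversal) and summarize
the per-cell responses together with the figure-ground verdict flags.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Optional

import numpy as np
import pandas as pd

from .izhikevich import SpikeRaster
from .network import NetworkConfig, NetworkRun, run_network
from .stimuli import (
    BinaryImage,
    ImageSet,
    default_circle_sets,
    default_fixtures,
    rotate90,
)

__all__ = [
    "CellResponse",
    "ClassificationResult",
    "ExperimentReport",
    "classify_by_onset",
    "dice_coefficient",
    "first_spike_time",
    "point_rate",
    "run_circle_experiment",
    "run_image_set_experiment",
    "run_rotation_experiment",
    "spike_count",
    "spiking_area_ratio",
]


def spike_count(train: np.ndarray) -> int:
    """Number of spikes in a train."""
    return int(len(train))


def first_spike_time(train: np.ndarray) -> Optional[float]:
    """Time of the first spike (ms), or None for a silent train."""
    return float(train[0]) if len(train) else None


def point_rate(raster: SpikeRaster, site: tuple[int, ...], duration: Optional[float] = None) -> float:
    """Firing rate (Hz) of one unit over the simulation."""
    dur = raster.duration if duration is None else duration
    return spike_count(raster.spike_times(site)) / dur * 1000.0


def spiking_area_ratio(raster: SpikeRaster) -> float:
    """Fraction of grid sites that spiked at least once."""
    mask = raster.spiked_mask()
    return float(mask.sum()) / mask.size


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1.0 = identical, 0.0 = disjoint)."""
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


@dataclasses.dataclass(frozen=True)
class CellResponse:
    count: int
    onset_ms: Optional[float]

    def onset_or_inf(self) -> float:
        return math.inf if self.onset_ms is None else self.onset_ms


@dataclasses.dataclass(frozen=True)
class ClassificationResult:
    """Winner of the first-spike-latency race between the two output cells."""

    winner: str  # "cell1" | "cell2" | "none"
    cells: tuple[CellResponse, CellResponse]
    decision_rule_used: str  # "onset" | "count-tiebreak" | "silent"


def classify_by_onset(run: NetworkRun) -> ClassificationResult:
    """Earlier first spike wins; exact onset ties fall to the larger count;
    a full tie (or two silent cells) is reported as no decision."""
    t1, t2 = run.area5_trains()
    cells = (
        CellResponse(spike_count(t1), first_spike_time(t1)),
        CellResponse(spike_count(t2), first_spike_time(t2)),
    )
    o1, o2 = cells[0].onset_or_inf(), cells[1].onset_or_inf()
    if math.isinf(o1) and math.isinf(o2):
        return ClassificationResult("none", cells, "silent")
    if o1 != o2:
        winner = "cell1" if o1 < o2 else "cell2"
        return ClassificationResult(winner, cells, "onset")
    if cells[0].count != cells[1].count:
        winner = "cell1" if cells[0].count > cells[1].count else "cell2"
        return ClassificationResult(winner, cells, "count-tiebreak")
    return ClassificationResult("none", cells, "silent")


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExperimentReport:
    """Machine-readable summary of one image-set experiment.

    ``members`` maps transform name -> dict with per-cell counts/onsets, the
    winner, and the per-channel area-2 spiking-area ratios.  The verdict
    flags are pure functions of those numbers:

    * ``fg_suppressed_by_count`` — the FG member's count is <= every other
      transform's and strictly below the original's, at both cells.
    * ``fg_suppressed_by_onset`` — the FG member starts strictly later than
      the original and no earlier than any other transform, at both cells
      (a silent cell counts as infinitely late).
    * ``generalization_held`` — original, mirror and contrast give the same
      (non-none) winner.
    """

    label: str
    members: dict
    config_hash: str
    flags: dict = dataclasses.field(default_factory=dict)

    def compute_flags(self) -> None:
        def counts(m):
            return [m["cells"][0]["count"], m["cells"][1]["count"]]

        def onsets(m):
            return [
                math.inf if m["cells"][i]["onset_ms"] is None else m["cells"][i]["onset_ms"]
                for i in (0, 1)
            ]

        others = ("original", "mirror", "contrast")
        fg = self.members.get("fg")
        flags = {}
        if fg is not None and all(t in self.members for t in others):
            fg_c, fg_o = counts(fg), onsets(fg)
            orig_c, orig_o = counts(self.members["original"]), onsets(self.members["original"])
            by_count = all(fg_c[i] < orig_c[i] for i in (0, 1)) and all(
                fg_c[i] <= counts(self.members[t])[i] for t in others for i in (0, 1)
            )
            by_onset = all(fg_o[i] > orig_o[i] for i in (0, 1)) and all(
                fg_o[i] >= onsets(self.members[t])[i] for t in others for i in (0, 1)
            )
            flags["fg_suppressed_by_count"] = bool(by_count)
            flags["fg_suppressed_by_onset"] = bool(by_onset)
        winners = {self.members[t]["winner"] for t in others if t in self.members}
        flags["generalization_held"] = len(winners) == 1 and "none" not in winners
        self.flags = flags

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "config_hash": self.config_hash,
            "members": self.members,
            "flags": self.flags,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for name, m in self.members.items():
            rows.append(
                {
                    "transform": name,
                    "cell1_count": m["cells"][0]["count"],
                    "cell1_onset_ms": m["cells"][0]["onset_ms"],
                    "cell2_count": m["cells"][1]["count"],
                    "cell2_onset_ms": m["cells"][1]["onset_ms"],
                    "winner": m["winner"],
                    "area2_ratio_F1": m["area2_ratio"][0],
                    "area2_ratio_F2": m["area2_ratio"][1],
                }
            )
        return pd.DataFrame(rows)


def _member_summary(run: NetworkRun) -> dict:
    cls = classify_by_onset(run)
    return {
        "winner": cls.winner,
        "decision_rule_used": cls.decision_rule_used,
        "cells": [dataclasses.asdict(c) for c in cls.cells],
        "area2_ratio": [
            spiking_area_ratio(run.rasters[("area2", 1)]),
            spiking_area_ratio(run.rasters[("area2", 2)]),
        ],
    }


def run_image_set_experiment(
    image_set: ImageSet, config: Optional[NetworkConfig] = None,
    keep_runs: bool = False,
) -> ExperimentReport:
    """Run all four members of a set and produce the summary report."""
    cfg = config or NetworkConfig()
    members = {}
    runs = {}
    for name in ImageSet.MEMBERS:
        run = run_network(image_set.member(name), cfg)
        members[name] = _member_summary(run)
        if keep_runs:
            runs[name] = run
    report = ExperimentReport(
        label=image_set.label, members=members, config_hash=cfg.config_hash()
    )
    report.compute_flags()
    if keep_runs:
        report.runs = runs  # type: ignore[attr-defined]
    return report


def run_rotation_experiment(
    image_set: ImageSet, config: Optional[NetworkConfig] = None
) -> ExperimentReport:
    """Original vs its quarter-turn: per-cell counts and onsets must swap."""
    cfg = config or NetworkConfig()
    members = {}
    for name, img in (
        ("original", image_set.original),
        ("rotated", rotate90(image_set.original)),
    ):
        members[name] = _member_summary(run_network(img, cfg))
    report = ExperimentReport(
        label=f"{image_set.label}-rotation", members=members, config_hash=cfg.config_hash()
    )
    o, r = members["original"], members["rotated"]
    report.flags = {
        "counts_swapped": o["cells"][0]["count"] == r["cells"][1]["count"]
        and o["cells"][1]["count"] == r["cells"][0]["count"],
        "onsets_swapped": o["cells"][0]["onset_ms"] == r["cells"][1]["onset_ms"]
        and o["cells"][1]["onset_ms"] == r["cells"][0]["onset_ms"],
        "winner_swapped": {o["winner"], r["winner"]} == {"cell1", "cell2"},
    }
    return report


def run_circle_experiment(
    config: Optional[NetworkConfig] = None,
) -> dict[str, ExperimentReport]:
    """The two circle controls.

    For the disconnected disc no transform preserves the border length, the
    FG reversal is not comparable, and the weakest response among the
    comparable transforms {original, mirror, contrast} should be the
    contrast-reversed one.  The frame-connected variant restores the
    polygon-like geometry and the ordinary FG-suppression reading.
    """
    cfg = config or NetworkConfig()
    disc_set, conn_set = default_circle_sets()
    reports = {}
    for s in (disc_set, conn_set):
        reports[s.label] = run_image_set_experiment(s, cfg)

    disc = reports["circle-disconnected"]
    comps = ("original", "mirror")
    c = disc.members["contrast"]

    def counts(m):
        return [m["cells"][i]["count"] for i in (0, 1)]

    def onsets(m):
        return [
            math.inf if m["cells"][i]["onset_ms"] is None else m["cells"][i]["onset_ms"]
            for i in (0, 1)
        ]

    tot = lambda m: sum(counts(m))  # noqa: E731
    earliest = lambda m: min(onsets(m))  # noqa: E731
    disc.flags["contrast_lowest_count"] = all(tot(c) < tot(disc.members[t]) for t in comps)
    disc.flags["contrast_latest_onset"] = all(
        earliest(c) > earliest(disc.members[t]) for t in comps
    )
    return reports


def run_default_experiments(config: Optional[NetworkConfig] = None) -> dict:
    """Every experiment on the built-in fixtures; basis of the CLI reports."""
    cfg = config or NetworkConfig()
    set1, set2 = default_fixtures()
    out = {
        "set1": run_image_set_experiment(set1, cfg),
        "set2": run_image_set_experiment(set2, cfg),
        "rotation": run_rotation_experiment(set1, cfg),
    }
    out.update(run_circle_experiment(cfg))
    return out
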