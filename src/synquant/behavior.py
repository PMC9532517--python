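"""Spatial-object-recognition scoring from nose-point trajectories.

A sample counts as exploring an object when the nose is strictly closer
than 2 cm to the object's boundary; the memory readout is the percentage
of exploration time spent with each object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as sqstats

EXPLORATION_RADIUS_CM = 2.0


@dataclass
class Trajectory:
    """Nose-point samples (t in s, x/y in cm) at a fixed sample rate."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float
    arena: tuple[float, float]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        w, h = self.arena
        if len(self.t) and (
            np.any(self.x < 0) or np.any(self.x > w) or np.any(self.y < 0) or np.any(self.y > h)
        ):
            raise ValueError("trajectory points outside arena")

    @property
    def duration(self) -> float:
        return len(self.t) / self.sample_rate

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "x": self.x, "y": self.y}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sample_rate: float, arena: tuple[float, float]) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
                   sample_rate=sample_rate, arena=arena)


@dataclass
class ObjectLayout:
    """Arena objects as name -> (x, y, radius) in cm, plus the displaced one."""

    objects: dict[str, tuple[float, float, float]]
    displaced: str | None = None

    def validate(self, arena: tuple[float, float] | None = None) -> None:
        names = list(self.objects)
        for i, a in enumerate(names):
            ax, ay, ar = self.objects[a]
            if ar < 0:
                raise ValueError(f"object {a!r} has negative radius")
            for b in names[i + 1 :]:
                bx, by, br = self.objects[b]
                if math.hypot(ax - bx, ay - by) < ar + br:
                    raise ValueError(f"objects {a!r} and {b!r} overlap")
        if arena is not None:
            w, h = arena
            for name, (ox, oy, orad) in self.objects.items():
                if not (orad <= ox <= w - orad and orad <= oy <= h - orad):
                    raise ValueError(f"object {name!r} not inside arena")
        if self.displaced is not None and self.displaced not in self.objects:
            raise ValueError(f"displaced object {self.displaced!r} unknown")


@dataclass
class ExplorationResult:
    """Per-object exploration time and percentage for one session."""

    time_per_object: dict[str, float]
    percent_per_object: dict[str, float]
    exploring_total: float
    session_duration: float
    percent_defined: bool = True
    params: dict = field(default_factory=dict)


def score_exploration(
    traj: Trajectory,
    layout: ObjectLayout,
    radius_cm: float = EXPLORATION_RADIUS_CM,
    from_boundary: bool = True,
) -> ExplorationResult:
    """Score a session: time per object, percentage of exploration time.

    A sample explores object i iff its distance to the object (boundary by
    default, centre if ``from_boundary`` is False) is strictly below
    ``radius_cm``; a sample within range of several objects is assigned to
    the nearest.  Percentages are over total exploring time and flagged
    undefined when that total is zero.
    """
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    layout.validate()
    names = list(layout.objects)
    pts = np.stack([traj.x, traj.y], axis=1)
    dists = np.empty((len(pts), len(names)))
    for j, name in enumerate(names):
        ox, oy, orad = layout.objects[name]
        d = np.linalg.norm(pts - np.array([ox, oy]), axis=1)
        dists[:, j] = d - orad if from_boundary else d
    nearest = np.argmin(dists, axis=1)
    exploring = dists[np.arange(len(pts)), nearest] < radius_cm
    dt = 1.0 / traj.sample_rate
    time_per = {
        name: float(np.sum(exploring & (nearest == j))) * dt for j, name in enumerate(names)
    }
    total = sum(time_per.values())
    defined = total > 0
    percent = {
        name: (100.0 * tp / total) if defined else float("nan") for name, tp in time_per.items()
    }
    return ExplorationResult(
        time_per_object=time_per,
        percent_per_object=percent,
        exploring_total=total,
        session_duration=traj.duration,
        percent_defined=defined,
        params={"radius_cm": radius_cm, "from_boundary": from_boundary},
    )


def preference_test(
    results_trained: list[ExplorationResult],
    results_test: list[ExplorationResult],
    displaced: str,
) -> sqstats.StatReport:
    """Compare displaced-object preference across training and test sessions.

    One value per animal per (session, object) cell: the percentage of
    exploration time on that object.  Cells are compared by one-way ANOVA
    followed by Fisher's LSD pairwise tests, and summarized as group
    means ± SEM.
    """
    if len(results_trained) < 2 or len(results_test) < 2:
        raise ValueError("preference_test requires >= 2 animals per condition")
    names = list(results_trained[0].percent_per_object)
    if displaced not in names:
        raise ValueError(f"displaced object {displaced!r} not scored")
    other = [n for n in names if n != displaced]
    cells, labels = [], []
    for session, results in (("train", results_trained), ("test", results_test)):
        for obj_label, obj_names in ((f"{session}_displaced", [displaced]), (f"{session}_other", other)):
            vals = [
                float(np.mean([r.percent_per_object[n] for n in obj_names]))
                for r in results
                if r.percent_defined
            ]
            cells.append(vals)
            labels.append(obj_label)
    report = sqstats.fisher_lsd(cells, names=labels)
    report.test = "sor_preference_lsd"
    report.params["displaced"] = displaced
    return report
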