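"""Synthetic confocal-like neuron images, trajectories and band tables.

Every downstream quantification stage is testable against known ground
truth generated here:

* three-channel neuron images — a cell-fill channel rendering a random
  dendritic tree (tube + soma disk) and two puncta channels carrying
  Gaussian spots at colocalized "synapse" positions on the skeleton plus
  channel-specific distractors; Poisson shot noise and Gaussian read
  noise are applied after the PSF;
* nose-point trajectories following a dwell plan over arena objects;
* lognormal band/loading-control intensity tables for densitometry.

Identical configurations (including the seed) give bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .behavior import ObjectLayout, Trajectory
from .dendrite import DendriteTrace
from .imgio import ImageSet


class PackingError(ValueError):
    """Requested puncta cannot be placed on the skeleton at the minimum spacing."""


@dataclass
class SimConfig:
    """Conditions for one synthetic neuron image.

    Defaults emulate a 60x confocal field: 1024 x 1024 pixels at
    0.2 μm/pixel (≈205 μm field), 16-bit, diffraction-scale puncta
    (sigma 0.15 μm, lateral FWHM ≈ 0.35 μm), bright spots over dim
    background with shot noise
    and read noise.  Densities are per μm of dendritic skeleton.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.2
    n_branches: int = 5
    branch_length_range: tuple[float, float] = (40.0, 80.0)
    true_density: float = 0.25
    distractor_density_a: float = 0.3
    distractor_density_b: float = 0.3
    punctum_sigma: float = 0.15
    punctum_amplitude: float = 3000.0
    colocalization_jitter: float = 0.1
    background: float = 200.0
    read_noise_sd: float = 30.0
    shot_noise: bool = True
    min_spacing: float = 1.0
    tube_radius: float = 0.5
    soma_radius: float = 5.0
    cell_fill_amplitude: float = 1500.0
    n_slices: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.punctum_sigma <= 0:
            raise ValueError("punctum_sigma must be > 0")
        if self.true_density < 0 or self.distractor_density_a < 0 or self.distractor_density_b < 0:
            raise ValueError("densities must be >= 0")
        if self.min_spacing <= 0 or self.tube_radius <= 0 or self.soma_radius <= 0:
            raise ValueError("geometry parameters must be > 0")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        lo, hi = self.branch_length_range
        if not 0 < lo <= hi:
            raise ValueError("branch_length_range must satisfy 0 < lo <= hi")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


@dataclass
class GroundTruth:
    """True geometry paired with a rendered image."""

    skeleton_polylines: list[np.ndarray]  # (N, 2) arrays of (row, col) μm
    skeleton_length: float
    soma_center: tuple[float, float]
    synapse_centers: np.ndarray  # (n, 2) μm
    true_density: float
    distractor_centers_a: np.ndarray
    distractor_centers_b: np.ndarray

    def to_trace(self) -> DendriteTrace:
        """The ground-truth skeleton as a dendrite trace (length denominator)."""
        return DendriteTrace(
            polylines=[p.copy() for p in self.skeleton_polylines],
            soma_center=self.soma_center,
            source="imported",
        )

    def to_json(self, path: str | Path) -> None:
        d = {
            "skeleton_polylines": [p.tolist() for p in self.skeleton_polylines],
            "skeleton_length": self.skeleton_length,
            "soma_center": list(self.soma_center),
            "synapse_centers": np.asarray(self.synapse_centers).tolist(),
            "true_density": self.true_density,
            "distractor_centers_a": np.asarray(self.distractor_centers_a).tolist(),
            "distractor_centers_b": np.asarray(self.distractor_centers_b).tolist(),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            skeleton_polylines=[np.asarray(p, dtype=float) for p in d["skeleton_polylines"]],
            skeleton_length=d["skeleton_length"],
            soma_center=tuple(d["soma_center"]),
            synapse_centers=np.asarray(d["synapse_centers"], dtype=float).reshape(-1, 2),
            true_density=d["true_density"],
            distractor_centers_a=np.asarray(d["distractor_centers_a"], dtype=float).reshape(-1, 2),
            distractor_centers_b=np.asarray(d["distractor_centers_b"], dtype=float).reshape(-1, 2),
        )


# ---------------------------------------------------------------------------
# geometry

def _grow_tree(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Random binary tree of straight segments from a central soma, in μm.

    Primary branches leave the soma at jittered regular angles; each
    bifurcates once partway along into two children.  Endpoints are kept
    inside the field with a margin.
    """
    h, w = cfg.image_shape
    field_h, field_w = h * cfg.pixel_size, w * cfg.pixel_size
    margin = 4.0 * cfg.punctum_sigma + 2.0
    soma = np.array([field_h / 2.0, field_w / 2.0])

    def clamp(p: np.ndarray) -> np.ndarray:
        return np.clip(p, margin, [field_h - margin, field_w - margin])

    polylines = []
    lo, hi = cfg.branch_length_range
    for i in range(cfg.n_branches):
        theta = 2.0 * math.pi * i / cfg.n_branches + rng.uniform(-0.25, 0.25)
        total = rng.uniform(lo, hi)
        u = np.array([math.sin(theta), math.cos(theta)])
        trunk_frac = rng.uniform(0.4, 0.7)
        bif = clamp(soma + total * trunk_frac * u)
        polylines.append(np.stack([soma, bif]))
        rest = total * (1.0 - trunk_frac)
        for sign in (-1.0, 1.0):
            phi = theta + sign * rng.uniform(0.35, 0.7)
            v = np.array([math.sin(phi), math.cos(phi)])
            tip = clamp(bif + rest * rng.uniform(0.7, 1.0) * v)
            polylines.append(np.stack([bif, tip]))
    return polylines


def _arc_table(polylines: list[np.ndarray]):
    """Vectorized arc-length lookup table: (starts, lengths, p0s, units)."""
    starts, lengths, p0s, units = [], [], [], []
    arc = 0.0
    for poly in polylines:
        for p0, p1 in zip(poly[:-1], poly[1:]):
            d = p1 - p0
            ln = float(np.linalg.norm(d))
            if ln > 0:
                starts.append(arc)
                lengths.append(ln)
                p0s.append(p0)
                units.append(d / ln)
                arc += ln
    return np.asarray(starts), np.asarray(lengths), np.asarray(p0s), np.asarray(units), arc


def _arc_points(polylines: list[np.ndarray], positions: np.ndarray) -> np.ndarray:
    """Map global arc-length positions to (row, col) μm points."""
    starts, lengths, p0s, units, total = _arc_table(polylines)
    s = np.clip(np.asarray(positions, dtype=float), 0.0, total - 1e-9)
    idx = np.searchsorted(starts, s, side="right") - 1
    return p0s[idx] + (s - starts[idx])[:, None] * units[idx]


def _place_synapses(
    cfg: SimConfig,
    polylines: list[np.ndarray],
    soma: np.ndarray,
    length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hard-core placement of colocalized puncta along the skeleton.

    Exactly ``round(true_density * skeleton_length)`` centres, pairwise at
    least ``min_spacing`` apart (Euclidean) and clear of the soma disk.
    """
    n = int(round(cfg.true_density * length))
    if n == 0:
        return np.empty((0, 2))
    exclusion = cfg.soma_radius + 2.0
    # crude packing bound on eligible arc length
    eligible = max(0.0, length - cfg.n_branches * exclusion)
    if n > eligible / cfg.min_spacing:
        raise PackingError(
            f"cannot place {n} puncta at spacing {cfg.min_spacing} μm on "
            f"{eligible:.1f} μm of eligible skeleton (density too high)"
        )
    starts, lengths, p0s, units, total = _arc_table(polylines)
    accepted: list[np.ndarray] = []
    attempts = 0
    max_attempts = 4000 * n
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"placed only {len(accepted)}/{n} puncta after {max_attempts} attempts; "
                "reduce true_density or min_spacing"
            )
        s = rng.uniform(0.0, total)
        i = int(np.searchsorted(starts, s, side="right")) - 1
        p = p0s[i] + (s - starts[i]) * units[i]
        if np.linalg.norm(p - soma) < exclusion:
            continue
        if accepted and np.min(np.linalg.norm(np.asarray(accepted) - p, axis=1)) < cfg.min_spacing:
            continue
        accepted.append(p)
    return np.asarray(accepted)


# ---------------------------------------------------------------------------
# rendering

def _render_spots(shape, centers_um, sigma_um, amplitude, pixel_size) -> np.ndarray:
    """Sum of isotropic Gaussian spots at subpixel centres (already PSF-shaped)."""
    img = np.zeros(shape, dtype=np.float64)
    if len(centers_um) == 0:
        return img
    sig = sigma_um / pixel_size
    half = max(2, int(math.ceil(4.0 * sig)))
    for r_um, c_um in np.asarray(centers_um):
        r, c = r_um / pixel_size, c_um / pixel_size
        r0, c0 = int(round(r)), int(round(c))
        rs = slice(max(0, r0 - half), min(shape[0], r0 + half + 1))
        cs = slice(max(0, c0 - half), min(shape[1], c0 + half + 1))
        rr = np.arange(rs.start, rs.stop)[:, None]
        cc = np.arange(cs.start, cs.stop)[None, :]
        img[rs, cs] += amplitude * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sig**2))
    return img


def _render_cell_fill(cfg: SimConfig, polylines, soma) -> np.ndarray:
    """Dendritic tube of radius tube_radius plus soma disk, PSF-blurred."""
    h, w = cfg.image_shape
    on = np.zeros((h, w), dtype=bool)
    # rasterize skeleton densely, then threshold the EDT to make the tube
    step = cfg.pixel_size / 2.0
    for poly in polylines:
        for p0, p1 in zip(poly[:-1], poly[1:]):
            ln = float(np.linalg.norm(p1 - p0))
            k = max(2, int(ln / step))
            t = np.linspace(0.0, 1.0, k)
            pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
            idx = np.round(pts / cfg.pixel_size).astype(int)
            valid = (idx[:, 0] >= 0) & (idx[:, 0] < h) & (idx[:, 1] >= 0) & (idx[:, 1] < w)
            on[idx[valid, 0], idx[valid, 1]] = True
    dist = ndimage.distance_transform_edt(~on) * cfg.pixel_size
    tube = dist <= cfg.tube_radius
    rr = (np.arange(h)[:, None] * cfg.pixel_size - soma[0]) ** 2
    cc = (np.arange(w)[None, :] * cfg.pixel_size - soma[1]) ** 2
    tube |= rr + cc <= cfg.soma_radius**2
    img = tube.astype(np.float64) * cfg.cell_fill_amplitude
    return ndimage.gaussian_filter(img, sigma=cfg.punctum_sigma / cfg.pixel_size)


def _apply_noise(signal: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    expected = signal + cfg.background
    if cfg.shot_noise:
        noisy = rng.poisson(expected).astype(np.float64)
    else:
        noisy = expected.copy()
    if cfg.read_noise_sd > 0:
        noisy += rng.normal(0.0, cfg.read_noise_sd, size=noisy.shape)
    return np.clip(noisy, 0, 65535).astype(np.uint16)


def generate_neuron_image(config: SimConfig) -> tuple[ImageSet, GroundTruth]:
    """Render one three-channel neuron image with known synapse ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    polylines = _grow_tree(config, rng)
    length = sum(float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))) for p in polylines)
    h, w = config.image_shape
    soma = np.array([h * config.pixel_size / 2.0, w * config.pixel_size / 2.0])
    synapses = _place_synapses(config, polylines, soma, length, rng)

    def jitter(centers: np.ndarray) -> np.ndarray:
        if len(centers) == 0 or config.colocalization_jitter == 0:
            return centers
        ang = rng.uniform(0, 2 * math.pi, size=len(centers))
        rad = rng.uniform(0, config.colocalization_jitter / 2.0, size=len(centers))
        return centers + np.stack([rad * np.sin(ang), rad * np.cos(ang)], axis=1)

    margin = 4.0 * config.punctum_sigma
    def distractors(density: float) -> np.ndarray:
        n = int(round(density * length))
        if n == 0:
            return np.empty((0, 2))
        return np.stack(
            [
                rng.uniform(margin, h * config.pixel_size - margin, size=n),
                rng.uniform(margin, w * config.pixel_size - margin, size=n),
            ],
            axis=1,
        )

    centers_a = jitter(synapses)
    centers_b = jitter(synapses)
    dist_a = distractors(config.distractor_density_a)
    dist_b = distractors(config.distractor_density_b)

    cell = _render_cell_fill(config, polylines, soma)
    spots_a = _render_spots((h, w), np.vstack([centers_a, dist_a]), config.punctum_sigma,
                            config.punctum_amplitude, config.pixel_size)
    spots_b = _render_spots((h, w), np.vstack([centers_b, dist_b]), config.punctum_sigma,
                            config.punctum_amplitude, config.pixel_size)

    def to_channel(signal: np.ndarray) -> np.ndarray:
        if config.n_slices == 1:
            return _apply_noise(signal, config, rng)
        # simple axial falloff around the focal slice, noise per slice
        mid = (config.n_slices - 1) / 2.0
        weights = [math.exp(-((z - mid) ** 2) / 2.0) for z in range(config.n_slices)]
        return np.stack([_apply_noise(signal * wz, config, rng) for wz in weights])

    channels = {
        "cell_fill": to_channel(cell),
        "puncta_A": to_channel(spots_a),
        "puncta_B": to_channel(spots_b),
    }
    image_set = ImageSet(
        channels=channels,
        pixel_size=config.pixel_size,
        z_step=0.75 if config.n_slices > 1 else None,
        bit_depth=16,
        meta={"seed": config.seed},
    )
    truth = GroundTruth(
        skeleton_polylines=polylines,
        skeleton_length=length,
        soma_center=(float(soma[0]), float(soma[1])),
        synapse_centers=synapses,
        true_density=config.true_density,
        distractor_centers_a=dist_a,
        distractor_centers_b=dist_b,
    )
    return image_set, truth


# ---------------------------------------------------------------------------
# trajectories

ROAM = "roam"


def generate_trajectory(
    arena_size: tuple[float, float],
    layout: ObjectLayout,
    dwell_plan: list[tuple[str, float]],
    sample_rate: float = 10.0,
    seed: int = 0,
    exploration_radius: float = 2.0,
) -> Trajectory:
    """Synthesize a nose-point trajectory following a dwell plan.

    During a dwell segment for object ``i`` the nose stays strictly within
    the exploration radius of that object's boundary; during ``roam``
    segments it stays strictly farther than the radius from every object.
    """
    layout.validate(arena_size)
    rng = np.random.default_rng(seed)
    w, hgt = arena_size
    dt = 1.0 / sample_rate
    ts, xs, ys = [], [], []
    t = 0.0
    for target, duration in dwell_plan:
        if duration <= 0:
            raise ValueError("dwell durations must be positive")
        n = int(round(duration * sample_rate))
        for _ in range(n):
            t += dt
            if target == ROAM:
                for _try in range(10000):
                    x = rng.uniform(0.0, w)
                    y = rng.uniform(0.0, hgt)
                    clear = all(
                        math.hypot(x - ox, y - oy) - orad > exploration_radius * 1.25
                        for ox, oy, orad in layout.objects.values()
                    )
                    if clear:
                        break
                else:
                    raise ValueError("arena too crowded to roam clear of all objects")
            else:
                if target not in layout.objects:
                    raise ValueError(f"dwell plan references unknown object {target!r}")
                ox, oy, orad = layout.objects[target]
                ang = rng.uniform(0, 2 * math.pi)
                d = orad + rng.uniform(0.1, 0.85) * exploration_radius
                x = min(max(ox + d * math.cos(ang), 0.0), w)
                y = min(max(oy + d * math.sin(ang), 0.0), hgt)
            ts.append(t)
            xs.append(x)
            ys.append(y)
    return Trajectory(
        t=np.asarray(ts), x=np.asarray(xs), y=np.asarray(ys),
        sample_rate=sample_rate, arena=arena_size,
    )


# ---------------------------------------------------------------------------
# band tables

def generate_band_table(
    group_means: list[float],
    cv: float = 0.2,
    n_per_group: int = 4,
    seed: int = 0,
    group_names: list[str] | None = None,
    loading_mean: float = 1000.0,
) -> pd.DataFrame:
    """Lognormal band/loading intensities with prescribed normalized means.

    ``target/loading`` for group g is ``group_means[g]`` times a unit-mean
    lognormal factor with coefficient of variation ``cv``; at cv = 0 the
    normalized values equal ``group_means`` exactly.
    """
    if any(m <= 0 for m in group_means):
        raise ValueError("group means must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if group_names is None:
        group_names = [f"group{i}" for i in range(len(group_means))]
    rng = np.random.default_rng(seed)
    s = math.sqrt(math.log(1.0 + cv**2))  # unit-mean lognormal sigma

    def lognorm(n: int, mean: float) -> np.ndarray:
        if s == 0.0:
            return np.full(n, mean)
        return mean * rng.lognormal(-(s**2) / 2.0, s, size=n)

    rows = []
    for g, (gm, name) in enumerate(zip(group_means, group_names)):
        loading = lognorm(n_per_group, loading_mean)
        ratio = lognorm(n_per_group, gm)
        for i in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{name}_{i}",
                    "group": name,
                    "target_intensity": ratio[i] * loading[i],
                    "loading_intensity": loading[i],
                }
            )
    return pd.DataFrame(rows)
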