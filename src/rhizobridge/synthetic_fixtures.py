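"""Synthetic inputs with analytic ground truth for every pipeline stage.

Everything needed to exercise the full workflow without any external data:
seasonal weather series, rooting cohorts drawn from a known log-logistic,
root masks stroked from analytic polylines (with exact length, width and
orientation truth carried alongside), and full simulate→render→extract
round trips packaged with the simulator's own geometry as the oracle.

Every fixture is reproducible from (spec, seed) and carries its ground
truth in a machine-readable dict so tests never re-derive truth from the
rendered image.
"""

from __future__ import annotations

import math
import datetime as _dt

import numpy as np
from PIL import Image, ImageDraw

from .parameterization import RootTypeParameters
from .root_simulator import RootSystem, SimulationConfig, render_projection, simulate
from .thermal_time import DailyWeatherRecord, RootingCohort, ThermalSeries
from .trait_extraction import RootImage, TraitRecord, extract_traits_from_mask

__all__ = [
    "synth_weather",
    "synth_rooting_cohort",
    "synth_root_mask",
    "synth_roundtrip",
    "random_line_spec",
]


def synth_weather(
    n_days: int,
    mean_temp: float = 10.0,
    annual_amplitude: float = 8.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    start_date: _dt.date = _dt.date(2022, 10, 15),
) -> ThermalSeries:
    """Sinusoidal seasonal temperature plus Gaussian noise.

    t_mean follows mean_temp + annual_amplitude·sin(2π·day/365) + noise;
    t_max/t_min bracket it by an absolute half-range draw whose scale
    follows noise_sd, so a noiseless series is exactly constant.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    days = np.arange(n_days)
    t_mean = (
        mean_temp
        + annual_amplitude * np.sin(2 * np.pi * days / 365.0)
        + (rng.normal(0.0, noise_sd, n_days) if noise_sd > 0 else 0.0)
    )
    half_range = np.abs(rng.normal(0.0, 2.0 * noise_sd, n_days)) if noise_sd > 0 else (
        np.zeros(n_days)
    )
    records = [
        DailyWeatherRecord(
            date=start_date + _dt.timedelta(days=int(d)),
            t_mean=float(t_mean[d]),
            t_max=float(t_mean[d] + half_range[d]),
            t_min=float(t_mean[d] - half_range[d]),
        )
        for d in days
    ]
    return ThermalSeries(records)


def synth_rooting_cohort(
    true_t50: float,
    slope: float,
    n: int,
    max_day: int = 60,
    seed: int = 0,
    cohort_id: str = "synthetic",
    collection_date: _dt.date = _dt.date(2022, 12, 15),
) -> tuple[RootingCohort, dict]:
    """Cohort of rooting days drawn from a log-logistic with median true_t50.

    F(t) = 1/(1 + (t/true_t50)^(−slope)); continuous draws are rounded to
    the nearest whole day (observation is daily) and days beyond
    ``max_day`` are censored. Returns the cohort plus its ground truth.
    """
    if not true_t50 > 0:
        raise ValueError("true_t50 must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, n)
    t = true_t50 * (u / (1.0 - u)) ** (1.0 / slope)
    days = np.maximum(np.rint(t).astype(int), 1)
    observed = [int(d) for d in days if d <= max_day]
    cohort = RootingCohort(
        cohort_id=cohort_id,
        collection_date=collection_date,
        n_cuttings=n,
        root_day=observed,
        max_day=max_day,
    )
    truth = {
        "true_t50": float(true_t50),
        "slope": float(slope),
        "n": int(n),
        "max_day": int(max_day),
        "n_censored": int(n - len(observed)),
        "seed": int(seed),
    }
    return cohort, truth


def synth_root_mask(
    polylines: list[dict],
    image_size_mm: tuple[float, float] = (280.0, 380.0),
    scale: float = 0.5,
    seed: int = 0,
) -> tuple[RootImage, TraitRecord, dict]:
    """Stroke analytic polylines into a binary mask with exact ground truth.

    Each polyline dict has ``points`` — (x_mm, z_mm) pairs with z the depth
    (image row) direction — and ``width_mm``. Truth covers summed length,
    tip count (two per open polyline), length-weighted mean absolute
    orientation from the downward vertical, and width statistics.
    ``seed`` only fixes provenance bookkeeping; the geometry itself is
    deterministic in the spec.
    """
    w_mm, h_mm = image_size_mm
    w_px = int(round(w_mm / scale))
    h_px = int(round(h_mm / scale))
    img = Image.new("L", (w_px, h_px), 0)
    draw = ImageDraw.Draw(img)

    seg_lengths, seg_angles, seg_widths = [], [], []
    for line in polylines:
        pts = [(float(x), float(z)) for x, z in line["points"]]
        width_mm = float(line["width_mm"])
        for (x, z) in pts:
            if not (0 <= x <= w_mm and 0 <= z <= h_mm):
                raise ValueError(f"polyline point ({x}, {z}) exits image bounds")
        width_px = max(int(round(width_mm / scale)), 1)
        # +0.5 targets pixel centers so thin strokes do not jitter across
        # a pixel boundary.
        px_pts = [(x / scale + 0.5, z / scale + 0.5) for x, z in pts]
        draw.line(px_pts, fill=255, width=width_px)
        half = width_px / 2.0
        for (cx, cz) in px_pts:
            draw.ellipse([cx - half, cz - half, cx + half, cz + half], fill=255)
        for (x1, z1), (x2, z2) in zip(pts, pts[1:]):
            length = math.hypot(x2 - x1, z2 - z1)
            if length == 0:
                continue
            seg_lengths.append(length)
            seg_angles.append(
                math.degrees(math.atan2(abs(x2 - x1), abs(z2 - z1)))
            )
            seg_widths.append(width_mm)

    lengths = np.asarray(seg_lengths)
    angles = np.asarray(seg_angles)
    widths = np.asarray(seg_widths)
    total_len = float(lengths.sum())
    truth = TraitRecord(
        number_of_root_tips=2.0 * len(polylines),
        total_root_length=total_len,
        avg_root_orientation=(
            float(np.average(angles, weights=lengths)) if total_len else 0.0
        ),
        avg_diameter=(
            float(np.average(widths, weights=lengths)) if total_len else 0.0
        ),
        max_diameter=float(widths.max()) if widths.size else 0.0,
    )
    sidecar = {
        "total_root_length_mm": truth.total_root_length,
        "number_of_root_tips": truth.number_of_root_tips,
        "avg_root_orientation_deg": truth.avg_root_orientation,
        "avg_diameter_mm": truth.avg_diameter,
        "scale_mm_per_px": scale,
        "seed": int(seed),
    }
    image = RootImage(mask=np.asarray(img) > 0, scale=scale, provenance="simulated")
    return image, truth, sidecar


def random_line_spec(
    seed: int,
    n_lines: tuple[int, int] = (2, 4),
    length_mm: tuple[float, float] = (60.0, 100.0),
    angle_deg: tuple[float, float] = (0.0, 50.0),
    width_choices_px: tuple[int, ...] = (1, 3, 5),
    scale: float = 0.5,
    margin_mm: float = 8.0,
) -> tuple[list[dict], tuple[float, float]]:
    """Random disjoint straight-line polylines in separate vertical strips.

    Lines share one stroke width (odd pixel counts, where the distance
    transform diameter convention is exact) and never overlap, so summed
    length and tip-count truth hold exactly. Returns (polylines,
    image_size_mm).
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(n_lines[0], n_lines[1] + 1))
    width_px = int(rng.choice(width_choices_px))
    width_mm = width_px * scale
    polylines = []
    x_cursor = margin_mm
    max_depth = 0.0
    for _ in range(k):
        length = float(rng.uniform(*length_mm))
        angle = math.radians(float(rng.uniform(*angle_deg)))
        dx = length * math.sin(angle)
        dz = length * math.cos(angle)
        x0 = x_cursor + width_mm
        z0 = margin_mm
        polylines.append(
            {"points": [(x0, z0), (x0 + dx, z0 + dz)], "width_mm": width_mm}
        )
        x_cursor = x0 + dx + width_mm + margin_mm
        max_depth = max(max_depth, z0 + dz)
    image_size = (x_cursor + margin_mm, max_depth + margin_mm + width_mm)
    return polylines, image_size


def synth_roundtrip(
    params_by_order: dict[int, RootTypeParameters],
    config: SimulationConfig,
    scale: float = 0.5,
    plane: str = "xz",
    trim_radius_mm: float | None = None,
) -> dict:
    """Simulate, render, re-extract; package the simulator's own geometry
    as ground truth for recovery tests.

    Returns a dict with the RootSystem, the rendered RootImage, the
    extracted TraitRecord, and analytic truth (total polyline length, node
    mean diameter, axis/tip counts, the input parameters and config seed).
    """
    system: RootSystem = simulate(params_by_order, config)
    image = render_projection(
        system, plane=plane, scale_mm_per_px=scale, trim_radius_mm=trim_radius_mm
    )
    traits = extract_traits_from_mask(
        image.mask, scale=scale, provenance="simulated"
    )
    diameters = [
        2.0 * ax.radius_at(i, system.clock)
        for ax in system.axes
        for i in range(len(ax.nodes))
    ]
    truth = {
        "total_length_mm": system.total_length_mm(),
        "mean_diameter_mm": float(np.mean(diameters)) if diameters else 0.0,
        "n_axes": len(system.axes),
        "seed": config.seed,
        "params": {k: p.as_dict() for k, p in params_by_order.items()},
    }
    return {"system": system, "image": image, "traits": traits, "truth": truth}
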