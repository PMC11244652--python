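"""Synthetic microscopy generators with recorded ground truth.

Every generator is a pure function of its parameters and seed and records a
:class:`GroundTruth` sufficient to score the downstream pipeline: the exact
transport parameters behind a dextran time-lapse, per-frame surviving-cell
counts behind a T-cell perfusion stack, and the placed per-cell distances
behind an infiltration endpoint image.

Default parameterizations emulate the study conditions of the chip assays:
two dextran sizes imaged every 5 min for an hour; T-cell stacks at 0, 5 and
10 min with whole-device survival of 55% (naive) / 60% (Th1) at 5 min and
20% / 45% at 10 min and stronger low-shear retention early on; infiltration
endpoints with ~22 cells averaging 233 um from the nearest vessel when the
epidermis is present versus ~15 cells at 68 um without it.  The distance model
is half-normal (only the mean and maximum are constrained by observation;
the distribution shape is this package's declared assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .trafficking import ImageStack, RegionOfInterest
from .transport import TransportDomain, TransportParams, simulate_transport

DEFAULT_NOISE_SD = 0.05
DEFAULT_CELL_RADIUS_PX = 3
DEFAULT_BLUR_SIGMA_PX = 1.0
#: pixel size for rendered cell imagery (3 px radius ~ a 15 um T cell diameter)
CELL_PIXEL_SIZE_UM = 5.0
#: attempts to redraw a sampled distance that exceeds the device extent
RESAMPLE_CAP = 100

#: (D um^2/s, P um/s) per dye — the fitted transport parameters of the study
DEFAULT_DYES: dict[str, dict[str, float]] = {
    "dex20kda": {"d_um2_s": 16.0, "p_um_s": 0.62},
    "dex40kda": {"d_um2_s": 53.0, "p_um_s": 0.41},
}

#: whole-device survival at 5 and 10 min, cumulative relative to baseline
NAIVE_SURVIVAL = (0.55, 0.20)
TH1_SURVIVAL = (0.60, 0.45)


def interval_survival_from_cumulative(cumulative: Sequence[float]) -> list[float]:
    """Convert cumulative survival fractions to per-interval probabilities.

    E.g. cumulative (0.55, 0.20) relative to baseline becomes per-interval
    (0.55, 0.20/0.55): the probability of persisting through each interval
    conditional on having survived the previous ones.
    """
    out, prev = [], 1.0
    for c in cumulative:
        if not 0 <= c <= prev:
            raise SynthError("cumulative survival must be non-increasing within [0, 1]")
        out.append(c / prev if prev > 0 else 0.0)
        prev = c
    return out

#: per-zone 5-min survival expressing the early shear dependence
DEFAULT_ZONE_SURVIVAL_5MIN = {"LS": 0.80, "MS": 0.55, "HS": 0.45}

INFILTRATION_MODELS = {
    "with_epidermis": {"kind": "half_normal", "mean_um": 233.0, "n_cells": 22},
    "without_epidermis": {"kind": "half_normal", "mean_um": 68.0, "n_cells": 15},
}


class SynthError(ValueError):
    """Invalid synthetic-scenario request."""


@dataclass
class GroundTruth:
    """Everything needed to score a pipeline run on generated data."""

    scenario_id: str
    seed: int
    transport: dict = field(default_factory=dict)      # per-dye D/P, c_lumen
    trafficking: dict = field(default_factory=dict)    # per-zone counts/survival
    infiltration: dict = field(default_factory=dict)   # placed distances, flags
    noise: dict = field(default_factory=dict)

    def lookup_parameter(self, parameter: str, label: str | None = None) -> float:
        """Resolve a fitted-parameter name (e.g. ``P_um_s``) to its true value."""
        key = {"P_um_s": "p_um_s", "D_um2_s": "d_um2_s"}.get(parameter)
        if key is None:
            raise SynthError(f"unknown parameter {parameter!r}")
        dyes = self.transport.get("dyes", {})
        if label is None:
            if len(dyes) != 1:
                raise SynthError(
                    f"scenario {self.scenario_id!r} has {len(dyes)} dyes; "
                    "a fit label is required"
                )
            label = next(iter(dyes))
        if label not in dyes:
            raise SynthError(f"no dye {label!r} in scenario {self.scenario_id!r}")
        return float(dyes[label][key])


def gen_dextran_timelapse(
    domain: TransportDomain,
    dyes: Mapping[str, Mapping[str, float]] | None = None,
    c_lumen: float = 1.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    frame_interval_s: float = 300.0,
    duration_s: float = 3600.0,
    scenario_id: str = "dextran",
) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Simulated dextran leakage time-lapse, one stack per dye.

    Concentration maps linearly to intensity; multiplicative Gaussian noise of
    relative standard deviation ``noise_sd`` is applied per pixel (clipped at
    zero).  Frames every ``frame_interval_s`` for ``duration_s``.
    """
    if noise_sd < 0:
        raise SynthError("noise_sd must be >= 0")
    dyes = dict(dyes) if dyes is not None else {k: dict(v) for k, v in DEFAULT_DYES.items()}
    times = np.arange(0.0, duration_s + 1e-9, frame_interval_s)
    rng = np.random.default_rng(seed)
    stacks: dict[str, ImageStack] = {}
    for name, pars in dyes.items():
        params = TransportParams(
            d_um2_s=pars["d_um2_s"],
            p_um_s=pars["p_um_s"],
            c_lumen=c_lumen,
            duration_s=duration_s,
            output_times_s=times,
        )
        series = simulate_transport(domain, params)
        frames = series.fields.astype(np.float32)
        if noise_sd > 0:
            frames = frames * (1.0 + noise_sd * rng.standard_normal(frames.shape))
            frames = np.clip(frames, 0.0, None).astype(np.float32)
        stacks[name] = ImageStack(
            frames=frames,
            timestamps_s=times,
            pixel_size_um=domain.spacing_um,
            channel=name,
        )
    truth = GroundTruth(
        scenario_id=scenario_id,
        seed=seed,
        transport={"dyes": {k: dict(v) for k, v in dyes.items()}, "c_lumen": c_lumen},
        noise={"model": "multiplicative_gaussian", "sd": noise_sd},
    )
    return stacks, truth


def _render_cells(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    radius_px: int,
    blur_sigma_px: float,
) -> np.ndarray:
    """Float frame with blurred unit-intensity disks at the given centers."""
    frame = np.zeros(shape)
    if len(centers_px):
        yy, xx = np.mgrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
        disk = (yy**2 + xx**2 <= radius_px**2).astype(float)
        for r, c in centers_px:
            r, c = int(round(r)), int(round(c))
            r0, r1 = max(r - radius_px, 0), min(r + radius_px + 1, shape[0])
            c0, c1 = max(c - radius_px, 0), min(c + radius_px + 1, shape[1])
            frame[r0:r1, c0:c1] = np.maximum(
                frame[r0:r1, c0:c1],
                disk[r0 - (r - radius_px): disk.shape[0] - ((r + radius_px + 1) - r1),
                     c0 - (c - radius_px): disk.shape[1] - ((c + radius_px + 1) - c1)],
            )
    if blur_sigma_px > 0:
        frame = ndimage.gaussian_filter(frame, blur_sigma_px)
    return frame


def _separated_choice(
    rng: np.random.Generator,
    candidates_rc: np.ndarray,
    n: int,
    min_separation_px: float,
    occupied: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Pick n candidate pixels at least ``min_separation_px`` from each other
    and from every already-``occupied`` position."""
    order = rng.permutation(len(candidates_rc))
    chosen: list[np.ndarray] = []
    keepout = list(occupied) if occupied else []
    for idx in order:
        cand = candidates_rc[idx]
        if all(np.hypot(*(cand - c)) >= min_separation_px for c in keepout):
            chosen.append(cand)
            keepout.append(cand)
            if len(chosen) == n:
                return np.array(chosen)
    raise SynthError(
        f"could not place {n} cells with {min_separation_px:.0f} px separation; "
        f"only {len(chosen)} positions available"
    )


def gen_tcell_perfusion(
    vessel_mask: np.ndarray,
    pixel_size_um: float,
    zones: Sequence[RegionOfInterest],
    attach_counts: Mapping[str, int],
    survival: Mapping[str, Sequence[float]],
    frame_times_s: Sequence[float] = (0.0, 300.0, 600.0),
    cell_radius_px: int = DEFAULT_CELL_RADIUS_PX,
    blur_sigma_px: float = DEFAULT_BLUR_SIGMA_PX,
    seed: int = 0,
    scenario_id: str = "tcell_perfusion",
) -> tuple[ImageStack, GroundTruth]:
    """T-cell attachment/detachment time-lapse with zone-dependent kinetics.

    ``attach_counts[zone]`` cells are placed uniformly on vessel pixels inside
    each zone polygon at baseline (pairwise separated so noise-free counting
    is exact); at each subsequent frame every surviving cell independently
    persists with ``survival[zone][interval]``.  Exact per-frame per-zone
    counts are recorded in the truth.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    frame_times = np.asarray(frame_times_s, dtype=float)
    n_intervals = len(frame_times) - 1
    rng = np.random.default_rng(seed)

    rr, cc = np.nonzero(vessel_mask)
    centers_um = np.column_stack([(cc + 0.5) * pixel_size_um, (rr + 0.5) * pixel_size_um])
    cells_per_zone: dict[str, np.ndarray] = {}
    for zone in zones:
        n = int(attach_counts[zone.label])
        probs = list(survival[zone.label])
        if len(probs) != n_intervals:
            raise SynthError(
                f"zone {zone.label!r}: {len(probs)} survival probabilities for "
                f"{n_intervals} intervals"
            )
        if any(not 0 <= p <= 1 for p in probs):
            raise SynthError(f"zone {zone.label!r}: survival probabilities must be in [0, 1]")
        inside = zone.contains_points(centers_um)
        candidates = np.column_stack([rr[inside], cc[inside]])
        if n > len(candidates):
            raise SynthError(
                f"zone {zone.label!r}: requested {n} cells but only "
                f"{len(candidates)} vessel pixels available"
            )
        occupied = [c for placed in cells_per_zone.values() for c in placed]
        cells_per_zone[zone.label] = _separated_choice(
            rng, candidates, n, 2.0 * cell_radius_px + 3.0, occupied=occupied
        )

    frames, counts = [], []
    alive = {z: np.ones(len(cells_per_zone[z]), dtype=bool) for z in cells_per_zone}
    for i, _t in enumerate(frame_times):
        if i > 0:
            for zone in zones:
                p = survival[zone.label][i - 1]
                keep = rng.random(alive[zone.label].sum()) < p
                idx = np.nonzero(alive[zone.label])[0]
                alive[zone.label][idx[~keep]] = False
        centers = np.concatenate(
            [cells_per_zone[z][alive[z]] for z in cells_per_zone]
            or [np.empty((0, 2))]
        )
        frames.append(_render_cells(vessel_mask.shape, centers, cell_radius_px, blur_sigma_px))
        counts.append({z: int(alive[z].sum()) for z in cells_per_zone})

    stack = ImageStack(
        frames=np.array(frames, dtype=np.float32),
        timestamps_s=frame_times,
        pixel_size_um=pixel_size_um,
        channel="tcells",
    )
    truth = GroundTruth(
        scenario_id=scenario_id,
        seed=seed,
        trafficking={
            "attach_counts": {z: int(attach_counts[z]) for z in cells_per_zone},
            "survival": {z: list(map(float, survival[z])) for z in cells_per_zone},
            "per_frame_counts": counts,
            "cell_radius_px": cell_radius_px,
        },
    )
    return stack, truth


def gen_infiltration_endpoint(
    vessel_mask: np.ndarray,
    pixel_size_um: float,
    n_cells: int | None = None,
    distance_model: str | Mapping = "with_epidermis",
    cell_radius_px: int = DEFAULT_CELL_RADIUS_PX,
    blur_sigma_px: float = DEFAULT_BLUR_SIGMA_PX,
    seed: int = 0,
    scenario_id: str = "infiltration",
) -> tuple[np.ndarray, GroundTruth]:
    """Endpoint infiltration image: cells at model-sampled vessel distances.

    ``distance_model`` is ``"with_epidermis"`` / ``"without_epidermis"``
    (half-normal with the corresponding mean) or a mapping, either
    ``{"kind": "half_normal", "mean_um": ...}`` or
    ``{"kind": "fixed", "distances_um": [...]}``.  Each cell lands on the
    non-vessel pixel whose distance-transform value best matches its sampled
    distance; the realized pixel distance is recorded alongside the sampled
    one.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise SynthError("vessel mask is empty")
    if isinstance(distance_model, str):
        if distance_model not in INFILTRATION_MODELS:
            raise SynthError(f"unknown distance model {distance_model!r}")
        model = dict(INFILTRATION_MODELS[distance_model])
        epidermis = distance_model == "with_epidermis"
    else:
        model = dict(distance_model)
        epidermis = bool(model.get("epidermis", False))
    if n_cells is None:
        n_cells = int(model.get("n_cells", 0))
    if n_cells < 0:
        raise SynthError("n_cells must be >= 0")

    rng = np.random.default_rng(seed)
    dist_px = ndimage.distance_transform_edt(~vessel_mask)
    max_avail_um = float(dist_px.max()) * pixel_size_um
    if model["kind"] == "half_normal":
        # sigma of the underlying normal: half-normal mean = sigma * sqrt(2/pi)
        sigma = model["mean_um"] * np.sqrt(np.pi / 2.0)
        sampled = np.abs(rng.standard_normal(n_cells)) * sigma
        for i in range(n_cells):
            tries = 0
            while sampled[i] > max_avail_um and tries < RESAMPLE_CAP:
                sampled[i] = abs(rng.standard_normal()) * sigma
                tries += 1
    elif model["kind"] == "fixed":
        sampled = np.asarray(model["distances_um"], dtype=float)
        if n_cells and len(sampled) != n_cells:
            raise SynthError("fixed distances length != n_cells")
        n_cells = len(sampled)
    else:
        raise SynthError(f"unknown distance model kind {model['kind']!r}")

    dist_um = dist_px * pixel_size_um
    outside = dist_px > 0
    rr, cc = np.nonzero(outside)
    dvals = dist_um[outside]

    centers, realized = [], []
    min_sep = 2.0 * cell_radius_px + 3.0
    n_best = min(2000, len(dvals))
    for d in sampled:
        if d > max_avail_um + pixel_size_um:
            raise SynthError(
                f"sampled distance {d:.0f} um exceeds the available extent "
                f"({max_avail_um:.0f} um); enlarge the image or shrink the model mean"
            )
        err = np.abs(dvals - d)
        # among near-best matches, pick one far enough from cells already placed
        part = np.argpartition(err, n_best - 1)[:n_best]
        order = part[np.argsort(err[part])]
        placed = False
        for idx in order:
            cand = np.array([rr[idx], cc[idx]])
            if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
                centers.append(cand)
                realized.append(float(dvals[idx]))
                placed = True
                break
        if not placed:
            raise SynthError("could not place cell without overlap; too many cells")

    image = _render_cells(vessel_mask.shape, np.array(centers), cell_radius_px, blur_sigma_px) \
        if centers else np.zeros(vessel_mask.shape)
    truth = GroundTruth(
        scenario_id=scenario_id,
        seed=seed,
        infiltration={
            "model": model,
            "epidermis": epidermis,
            "sampled_distances_um": [float(d) for d in sampled],
            "placed_distances_um": realized,
            "n_cells": n_cells,
        },
    )
    return image.astype(np.float32), truth
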