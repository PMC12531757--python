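"""Seeded synthetic-data generators with ground-truth records.

Every generator emits a :class:`GroundTruth` next to its artifact so the
analysis modules can be exercised by parameter recovery: beat trains with
controlled frequency/amplitude statistics, rendered planar microvascular
networks with known centerline length, diameters, junction/endpoint counts
and coverage, tracer time-lapses following a linear influx model with known
permeability, and liposome/vessel image pairs with a known extravascular
signal fraction.

Modelling choices (documented in the methods note):

* inter-beat intervals are gamma distributed (shape = 1/CV², scale =
  mean·CV²) so the requested mean and CV hold exactly in expectation;
* per-beat amplitudes are lognormal with matched mean and CV;
* a transient is a linear rise to the peak over ``time_to_peak`` followed
  by an exponential decay with τ = decay80/ln 5, which makes time-to-peak
  and the 80 %-decay time analytically exact;
* vessel networks are edge subsets of a Delaunay triangulation over
  blue-noise node placements — planar by construction, so junction and
  endpoint counts follow from graph degrees;
* tracer influx is linear in time, I_t(t) = I_b + P·(I_v−I_b)·(4/d)·t,
  the cylindrical surface-to-volume form of the single-vessel flux model.

All randomness flows through one explicit integer seed per call; no global
random state is touched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay

from .calcium import FluorescenceTrace, InvalidParameterError

__all__ = [
    "GroundTruth",
    "BeatTrainParams",
    "VesselNetworkParams",
    "PermeabilitySimParams",
    "beat_waveform",
    "gen_calcium_trace",
    "render_network",
    "gen_vessel_network",
    "gen_permeability_stack",
    "gen_extravasation_pair",
]


class CoverageUnreachableError(ValueError):
    """Target vessel coverage cannot be reached with the given geometry."""


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class GroundTruth:
    """Generator name, full parameter record, and derived true values."""

    generator: str
    params: dict
    truth: dict
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "generator": self.generator,
                "params": _jsonable(self.params),
                "truth": _jsonable(self.truth),
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            generator=d["generator"],
            params=d["params"],
            truth=d["truth"],
            seed=d["seed"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# calcium beat trains
# ---------------------------------------------------------------------------

@dataclass
class BeatTrainParams:
    """Parameters of a simulated spontaneous beating recording.

    Defaults match the acquisition used for on-chip Ca²⁺ imaging: 30 s at a
    10 ms capture interval.  ``noise_sd`` and ``bleach_rate`` act on the raw
    fluorescence F(t) = baseline_f0·exp(−bleach_rate·t)·(1 + Σ transients)
    + ε.
    """

    mean_frequency: float = 1.04  # beats/s
    ibi_cv: float = 0.05
    mean_amplitude: float = 1.0  # ΔF/F0
    amplitude_cv: float = 0.05
    time_to_peak: float = 0.2  # s
    decay80: float = 0.4  # s
    duration: float = 30.0  # s
    dt: float = 0.01  # s
    baseline_f0: float = 100.0
    noise_sd: float = 0.0  # raw-intensity units
    bleach_rate: float = 0.0  # fraction/s
    seed: int = 0

    def validate(self) -> None:
        if self.mean_frequency <= 0:
            raise InvalidParameterError("mean_frequency must be positive")
        if self.ibi_cv < 0 or self.amplitude_cv < 0:
            raise InvalidParameterError("CVs must be non-negative")
        if self.dt <= 0 or self.duration <= 0:
            raise InvalidParameterError("dt and duration must be positive")
        if self.time_to_peak <= 0 or self.decay80 <= 0:
            raise InvalidParameterError("beat kinetics must be positive")
        if self.time_to_peak + self.decay80 >= 1.0 / self.mean_frequency:
            raise InvalidParameterError(
                "beats would fully overlap: time_to_peak + decay80 must be "
                "< 1/mean_frequency"
            )
        if self.dt > self.time_to_peak / 2:
            raise InvalidParameterError("dt must resolve the rise (dt <= time_to_peak/2)")
        if self.baseline_f0 <= 0:
            raise InvalidParameterError("baseline_f0 must be positive")
        if self.noise_sd < 0 or self.bleach_rate < 0:
            raise InvalidParameterError("noise_sd and bleach_rate must be non-negative")


def beat_waveform(
    time_to_peak: float,
    decay80: float,
    amplitude: float,
    dt: float,
    n_decay_constants: float = 5.0,
):
    """Single-transient template: linear rise, then exponential decay.

    The rise goes from 0 to ``amplitude`` over exactly ``time_to_peak``;
    the decay constant is τ = decay80/ln 5, so the value at
    ``time_to_peak + decay80`` is exactly 0.2·amplitude.

    Returns ``(t, samples, record)`` where ``record`` holds the analytic
    parameters (including τ).
    """
    if min(time_to_peak, decay80, amplitude, dt) <= 0:
        raise InvalidParameterError("all waveform parameters must be positive")
    if dt >= time_to_peak / 2:
        raise InvalidParameterError("dt must be < time_to_peak/2")
    tau = decay80 / math.log(5.0)
    t_end = time_to_peak + n_decay_constants * tau
    t = np.arange(0.0, t_end + dt / 2, dt)
    y = _eval_transient(t, time_to_peak, tau, amplitude)
    record = {
        "time_to_peak": time_to_peak,
        "decay80": decay80,
        "amplitude": amplitude,
        "tau": tau,
        "dt": dt,
    }
    return t, y, record


def _eval_transient(t: np.ndarray, ttp: float, tau: float, amplitude: float) -> np.ndarray:
    """Evaluate the rise/decay template at times ``t`` (0 at onset)."""
    y = np.zeros_like(t, dtype=float)
    rising = (t >= 0) & (t <= ttp)
    y[rising] = amplitude * t[rising] / ttp
    falling = t > ttp
    y[falling] = amplitude * np.exp(-(t[falling] - ttp) / tau)
    return y


def gen_calcium_trace(params: BeatTrainParams):
    """Simulate one raw-fluorescence recording of spontaneous beating.

    Returns ``(FluorescenceTrace, GroundTruth)``; the ground truth records
    every drawn onset, peak time, amplitude and the realized inter-beat
    intervals.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    mean_ibi = 1.0 / params.mean_frequency
    tau = params.decay80 / math.log(5.0)

    # draw onsets: first onset uniform early in the record, then gamma
    # IBIs; a beat only counts if its peak fits inside the recording
    last_onset = params.duration - params.time_to_peak - 2.0 * params.dt
    onsets = [float(rng.uniform(0.05, 0.05 + mean_ibi))]
    ibis: list[float] = []
    while True:
        if params.ibi_cv == 0:
            ibi = mean_ibi
        else:
            shape = 1.0 / params.ibi_cv**2
            scale = mean_ibi * params.ibi_cv**2
            ibi = float(rng.gamma(shape, scale))
        nxt = onsets[-1] + ibi
        if nxt >= last_onset:
            break
        onsets.append(nxt)
        ibis.append(ibi)

    n = len(onsets)
    if params.amplitude_cv == 0:
        amps = np.full(n, params.mean_amplitude)
    else:
        sigma2 = math.log(1.0 + params.amplitude_cv**2)
        mu = math.log(params.mean_amplitude) - sigma2 / 2.0
        amps = rng.lognormal(mu, math.sqrt(sigma2), size=n)

    t = np.arange(0.0, params.duration, params.dt)
    s = np.zeros_like(t)
    support = params.time_to_peak + 12.0 * tau
    for onset, amp in zip(onsets, amps):
        i0 = max(0, int(math.floor(onset / params.dt)))
        i1 = min(len(t), int(math.ceil((onset + support) / params.dt)) + 1)
        s[i0:i1] += _eval_transient(t[i0:i1] - onset, params.time_to_peak, tau, amp)

    f = params.baseline_f0 * np.exp(-params.bleach_rate * t) * (1.0 + s)
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=t.shape)

    trace = FluorescenceTrace(time=t, intensity=f, roi_id=f"sim_seed{params.seed}")
    gt = GroundTruth(
        generator="gen_calcium_trace",
        params=asdict(params),
        truth={
            "onsets": list(onsets),
            "peak_times": [o + params.time_to_peak for o in onsets],
            "amplitudes": amps.tolist(),
            "ibis": ibis,
            "n_beats": n,
            "tau": tau,
        },
        seed=params.seed,
    )
    return trace, gt


# ---------------------------------------------------------------------------
# vessel networks
# ---------------------------------------------------------------------------

@dataclass
class VesselNetworkParams:
    """Parameters of a rendered planar microvascular network.

    ``target_coverage`` is the requested foreground fraction of the field;
    edges of a Delaunay graph over blue-noise nodes are added (in seeded
    random order, skipping edges that would meet a kept edge at < ``min_angle_deg``)
    until the measured coverage reaches the target.  Intensity defaults
    emulate a CD31 max projection: a tight dark background peak with a
    broad, per-segment-variable bright foreground, which is the histogram
    shape the triangle threshold expects.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 1.0  # µm/px
    target_coverage: float | None = 0.645
    n_segments: int | None = None
    tube_diameter_mean: float = 22.9  # µm
    tube_diameter_sd: float = 0.0  # µm
    node_spacing: float = 62.0  # µm, minimum node separation
    min_angle_deg: float = 27.0
    branch_prob: float = 1.0  # acceptance prob. of edges that create a branch (degree >= 3)
    enforce_clearance: bool = False  # reject edges whose tube would touch unrelated tubes
    clearance_px: float = 3.0
    intensity_vessel: float = 350.0
    intensity_background: float = 200.0
    segment_brightness_cv: float = 0.1
    noise_sd: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.target_coverage is None and self.n_segments is None:
            raise InvalidParameterError("give target_coverage or n_segments")
        if self.target_coverage is not None and not (0.0 < self.target_coverage < 1.0):
            raise InvalidParameterError("target_coverage must be in (0, 1)")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.tube_diameter_mean < 2.0 * self.pixel_size:
            raise InvalidParameterError("tubes must span at least 2 pixels")
        if self.intensity_vessel <= self.intensity_background:
            raise InvalidParameterError("vessel intensity must exceed background")


def _stamp_segment(mask: np.ndarray, p0, p1, radius: float) -> None:
    """Set pixels within ``radius`` of segment p0-p1 (rows, cols) to True."""
    r0, c0 = p0
    r1, c1 = p1
    rmin = max(0, int(math.floor(min(r0, r1) - radius)))
    rmax = min(mask.shape[0] - 1, int(math.ceil(max(r0, r1) + radius)))
    cmin = max(0, int(math.floor(min(c0, c1) - radius)))
    cmax = min(mask.shape[1] - 1, int(math.ceil(max(c0, c1) + radius)))
    if rmax < rmin or cmax < cmin:
        return
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    dr, dc = r1 - r0, c1 - c0
    seg_len2 = dr * dr + dc * dc
    if seg_len2 == 0:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    else:
        tpar = ((rr - r0) * dr + (cc - c0) * dc) / seg_len2
        tpar = np.clip(tpar, 0.0, 1.0)
        d2 = (rr - (r0 + tpar * dr)) ** 2 + (cc - (c0 + tpar * dc)) ** 2
    mask[rmin : rmax + 1, cmin : cmax + 1] |= d2 <= radius * radius


def render_network(
    image_shape: tuple[int, int],
    pixel_size: float,
    nodes: np.ndarray,
    edges: Sequence[tuple[int, int]],
    diameters: Sequence[float],
    intensity_vessel: float = 500.0,
    intensity_background: float = 100.0,
    segment_brightness: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Rasterize an explicit centerline graph into (image, mask, truth).

    ``nodes`` are (row, col) pixel coordinates; ``diameters`` are per-edge
    tube diameters in µm.  Pixels within d/2 of a centerline segment are
    foreground (round caps, no anti-aliasing, so pixel counts are exact).
    The truth dict reports graph-degree junction (degree ≥ 3) and endpoint
    (degree 1) counts, exact centerline length in µm, per-segment
    diameters, and the realized coverage of the emitted mask.
    """
    nodes = np.asarray(nodes, dtype=float)
    mask = np.zeros(image_shape, dtype=bool)
    img = np.full(image_shape, float(intensity_background))
    if segment_brightness is None:
        segment_brightness = np.ones(len(edges))
    degree = np.zeros(len(nodes), dtype=int)
    total_len = 0.0
    for k, (i, j) in enumerate(edges):
        seg = np.zeros(image_shape, dtype=bool)
        radius_px = diameters[k] / pixel_size / 2.0
        _stamp_segment(seg, nodes[i], nodes[j], radius_px)
        img[seg & ~mask] = intensity_vessel * segment_brightness[k]
        mask |= seg
        degree[i] += 1
        degree[j] += 1
        total_len += float(np.linalg.norm(nodes[i] - nodes[j])) * pixel_size
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd, size=image_shape)
    truth = {
        "n_junctions": int(np.sum(degree >= 3)),
        "n_endpoints": int(np.sum(degree == 1)),
        "centerline_length_um": total_len,
        "diameters_um": list(map(float, diameters)),
        "coverage": float(mask.mean()),
        "n_segments": len(edges),
    }
    return img, mask, truth


def _blue_noise_nodes(rng, shape, spacing_px, margin):
    """Dart-throwing Poisson-disk-ish node placement (vectorized rejection)."""
    h, w = shape
    target = int(2.2 * (h - 2 * margin) * (w - 2 * margin) / spacing_px**2)
    attempts = 40 * max(target, 1)
    cand = rng.uniform([margin, margin], [h - margin, w - margin], size=(attempts, 2))
    pts = np.empty((attempts, 2))
    n = 0
    min2 = spacing_px**2
    for p in cand:
        if n == 0 or np.min(np.sum((pts[:n] - p) ** 2, axis=1)) >= min2:
            pts[n] = p
            n += 1
    return pts[:n].copy()


def _edge_angle_ok(nodes, kept_by_node, candidate, min_angle_rad):
    i, j = candidate
    v = nodes[j] - nodes[i]
    v = v / np.linalg.norm(v)
    for node, other in ((i, j), (j, i)):
        for k in kept_by_node[node]:
            u = nodes[k] - nodes[node]
            u = u / np.linalg.norm(u)
            w = v if node == i else -v
            cosang = float(np.clip(np.dot(w, u), -1.0, 1.0))
            if math.acos(cosang) < min_angle_rad:
                return False
    return True


def gen_vessel_network(params: VesselNetworkParams):
    """Render a seeded random planar vessel network.

    Returns ``(image, GroundTruth)``; the ground-truth mask is stored under
    ``truth["mask"]`` on the returned object (as a numpy array, excluded
    from JSON round-trips of large networks only by the caller's choice).
    Raises :class:`CoverageUnreachableError` if the requested coverage
    cannot be met — never clips silently.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    spacing_px = params.node_spacing / params.pixel_size
    margin = params.tube_diameter_mean / params.pixel_size / 2.0 + 2.0
    nodes = _blue_noise_nodes(rng, (h, w), spacing_px, margin)
    if len(nodes) < 4:
        raise CoverageUnreachableError("image too small for the node spacing")
    tri = Delaunay(nodes)
    edge_set = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edge_set.add((i, j))
    edges = [
        e
        for e in edge_set
        if np.linalg.norm(nodes[e[0]] - nodes[e[1]]) < 2.2 * spacing_px
    ]
    order = rng.permutation(len(edges))

    mask = np.zeros((h, w), dtype=bool)
    img = np.full((h, w), float(params.intensity_background))
    kept_by_node: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    degree = np.zeros(len(nodes), dtype=int)
    kept_edges: list[tuple[int, int]] = []
    diameters: list[float] = []
    total_len = 0.0
    min_angle = math.radians(params.min_angle_deg)
    target = params.target_coverage
    max_segments = params.n_segments if params.n_segments is not None else len(edges)

    # rounds: chains (degree <= 2) fill first; edges that would create a
    # branch point are admitted with probability branch_prob per round, so
    # junction density stays low unless coverage demands more edges
    remaining = list(order)
    done = False
    while remaining and not done:
        next_round: list[int] = []
        progressed = False
        for idx in remaining:
            if (target is not None and mask.mean() >= target) or len(
                kept_edges
            ) >= max_segments:
                done = True
                break
            i, j = edges[idx]
            if not _edge_angle_ok(nodes, kept_by_node, (i, j), min_angle):
                continue
            if (degree[i] >= 2 or degree[j] >= 2) and params.branch_prob < 1.0:
                if rng.uniform() >= params.branch_prob:
                    next_round.append(idx)
                    continue
            d = params.tube_diameter_mean
            if params.tube_diameter_sd > 0:
                d = float(rng.normal(d, params.tube_diameter_sd))
            d = max(d, 2.0 * params.pixel_size)
            r_px = d / params.pixel_size / 2.0
            if params.enforce_clearance:
                # candidate tube (padded by the clearance gap) may touch the
                # existing mask only near its own nodes, where tubes of the
                # same graph vertex legitimately meet
                pad = np.zeros((h, w), dtype=bool)
                _stamp_segment(pad, nodes[i], nodes[j], r_px + params.clearance_px)
                zone_r = (2.0 * r_px + params.clearance_px) / (
                    2.0 * math.sin(min_angle / 2.0)
                ) + 2.0
                zones = np.zeros((h, w), dtype=bool)
                _stamp_segment(zones, nodes[i], nodes[i], zone_r)
                _stamp_segment(zones, nodes[j], nodes[j], zone_r)
                if (pad & mask & ~zones).any():
                    continue
            seg = np.zeros((h, w), dtype=bool)
            _stamp_segment(seg, nodes[i], nodes[j], r_px)
            bright = 1.0
            if params.segment_brightness_cv > 0:
                sigma2 = math.log(1.0 + params.segment_brightness_cv**2)
                bright = float(rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2)))
            img[seg & ~mask] = params.intensity_vessel * bright
            mask |= seg
            kept_by_node[i].append(j)
            kept_by_node[j].append(i)
            degree[i] += 1
            degree[j] += 1
            kept_edges.append((i, j))
            diameters.append(d)
            total_len += float(np.linalg.norm(nodes[i] - nodes[j])) * params.pixel_size
            progressed = True
        if not progressed and len(next_round) == len(remaining):
            break  # a full round added nothing
        remaining = next_round

    coverage = float(mask.mean())
    if target is not None and coverage < target - 0.02:
        raise CoverageUnreachableError(
            f"reached coverage {coverage:.3f} < target {target:.3f} with all "
            "usable edges; enlarge diameter or shrink node_spacing"
        )
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=(h, w))

    gt = GroundTruth(
        generator="gen_vessel_network",
        params=asdict(params),
        truth={
            "n_junctions": int(np.sum(degree >= 3)),
            "n_endpoints": int(np.sum(degree == 1)),
            "centerline_length_um": total_len,
            "diameters_um": diameters,
            "mean_diameter_um": float(np.mean(diameters)) if diameters else 0.0,
            "coverage": coverage,
            "n_segments": len(kept_edges),
            "nodes": nodes.tolist(),
            "edges": [list(map(int, e)) for e in kept_edges],
            "mask": mask,
        },
        seed=params.seed,
    )
    return img, gt


def diameter_recovery_params(
    tube_diameter_mean: float, seed: int, image_shape=(1024, 1024), pixel_size=1.0
) -> VesselNetworkParams:
    """Stated world for mean-diameter recovery experiments.

    Chain-dominated sparse networks (long segments, few branch points,
    clearance between unrelated tubes): the regime in which the
    area/skeleton-length diameter estimator is identifiable.  On dense
    meshes the estimator systematically under-reads because junction
    overlap area is counted once; see the methods note.
    """
    return VesselNetworkParams(
        image_shape=image_shape,
        pixel_size=pixel_size,
        tube_diameter_mean=tube_diameter_mean,
        target_coverage=0.25,
        node_spacing=70.0,
        min_angle_deg=45.0,
        branch_prob=0.1,
        enforce_clearance=True,
        seed=seed,
    )


def topology_recovery_params(
    seed: int, image_shape=(1024, 1024), pixel_size=1.0
) -> VesselNetworkParams:
    """Stated world for junction/endpoint-count recovery experiments.

    Thin tubes relative to segment length, wide branching angles and
    enforced clearance keep the rendered mask's skeleton graph-faithful,
    so graph-degree counts are recoverable exactly.
    """
    return VesselNetworkParams(
        image_shape=image_shape,
        pixel_size=pixel_size,
        tube_diameter_mean=12.0,
        target_coverage=0.12,
        node_spacing=70.0,
        min_angle_deg=60.0,
        branch_prob=0.3,
        enforce_clearance=True,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# permeability stacks
# ---------------------------------------------------------------------------

@dataclass
class PermeabilitySimParams:
    """Parameters of a simulated tracer-influx time lapse.

    The default frame times are 0, 3, 6, 9 and 12 minutes.  The perivascular
    tissue follows the linear influx model
    I_t(t) = I_b + P·(I_v − I_b)·(4/d)·t with d in cm, the
    surface-to-volume factor of a cylindrical vessel.
    """

    permeability_true: float = 3.3e-6  # cm/s
    vessel_diameter: float = 22.9  # µm
    intensity_vessel: float = 1100.0
    intensity_background: float = 100.0
    frame_times: tuple[float, ...] = (0.0, 180.0, 360.0, 540.0, 720.0)
    image_shape: tuple[int, int] = (256, 256)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.permeability_true < 0:
            raise InvalidParameterError("permeability must be non-negative")
        if self.intensity_vessel <= self.intensity_background:
            raise InvalidParameterError("vessel intensity must exceed background")
        ft = np.asarray(self.frame_times)
        if ft[0] != 0 or np.any(np.diff(ft) <= 0):
            raise InvalidParameterError("frame_times must start at 0 and strictly increase")
        if self.vessel_diameter <= 0:
            raise InvalidParameterError("vessel_diameter must be positive")


def gen_permeability_stack(params: PermeabilitySimParams):
    """Simulate a tracer time lapse around one straight vessel.

    Returns ``(stack, vessel_mask, GroundTruth)``.  The vessel is a
    horizontal band of the requested diameter through the image center at
    ``intensity_vessel`` in every frame; tissue pixels follow the linear
    influx model.  If the model predicts tissue intensity above the vessel
    intensity within the frame window, the ground truth carries a
    ``linear_regime_violated`` flag (the forward model stays linear).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    d_px = params.vessel_diameter / 1.0  # geometry rendered at 1 µm/px
    r = int(round(d_px / 2.0))
    mask = np.zeros((h, w), dtype=bool)
    mask[h // 2 - r : h // 2 + r + 1, :] = True
    d_cm = params.vessel_diameter * 1e-4
    sv = 4.0 / d_cm  # surface/volume of a cylinder, 1/cm
    delta = params.intensity_vessel - params.intensity_background
    frames = []
    tissue_values = []
    for t in params.frame_times:
        tissue = params.intensity_background + params.permeability_true * delta * sv * t
        frame = np.full((h, w), tissue)
        frame[mask] = params.intensity_vessel
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=(h, w))
        frames.append(frame)
        tissue_values.append(tissue)
    stack = np.stack(frames)
    gt = GroundTruth(
        generator="gen_permeability_stack",
        params=asdict(params),
        truth={
            "permeability_true": params.permeability_true,
            "geometric_factor_cm": d_cm / 4.0,
            "surface_to_volume_per_cm": sv,
            "tissue_intensity": tissue_values,
            "linear_regime_violated": bool(
                max(tissue_values) > params.intensity_vessel
            ),
        },
        seed=params.seed,
    )
    return stack, mask, gt


# ---------------------------------------------------------------------------
# liposome extravasation pairs
# ---------------------------------------------------------------------------

def gen_extravasation_pair(
    outside_fraction: float,
    vessel_mask: np.ndarray,
    n_positive: int = 1000,
    seed: int = 0,
):
    """Place liposome-positive pixels at a known extravascular fraction.

    Exactly ``round(outside_fraction * n_positive)`` positive pixels land
    outside ``vessel_mask`` and the remainder inside.  Returns
    ``(liposome_image, vessel_mask, GroundTruth)`` where the image is
    binary-valued (0/255).
    """
    if not 0.0 <= outside_fraction <= 1.0:
        raise InvalidParameterError("outside_fraction must be in [0, 1]")
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    inside = np.flatnonzero(vessel_mask.ravel())
    outside = np.flatnonzero(~vessel_mask.ravel())
    n_out = int(round(outside_fraction * n_positive))
    n_in = n_positive - n_out
    if n_out > 0 and outside.size == 0:
        raise InvalidParameterError("mask is all-foreground; no room outside")
    if n_in > 0 and inside.size == 0:
        raise InvalidParameterError("mask is all-background; no room inside")
    if n_out > outside.size or n_in > inside.size:
        raise InvalidParameterError("not enough pixels to place the requested signal")
    rng = np.random.default_rng(seed)
    img = np.zeros(vessel_mask.shape, dtype=np.uint8)
    if n_in:
        img.ravel()[rng.choice(inside, size=n_in, replace=False)] = 255
    if n_out:
        img.ravel()[rng.choice(outside, size=n_out, replace=False)] = 255
    gt = GroundTruth(
        generator="gen_extravasation_pair",
        params={"outside_fraction": outside_fraction, "n_positive": n_positive},
        truth={
            "realized_fraction": n_out / n_positive if n_positive else float("nan"),
            "n_outside": n_out,
            "n_inside": n_in,
        },
        seed=seed,
    )
    return img, vessel_mask, gt
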