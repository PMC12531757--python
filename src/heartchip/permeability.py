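"""Apparent vascular permeability from tracer time-lapse imaging.

A membrane-limited, linear-regime flux model relates the rate of
perivascular intensity increase to the apparent permeability P (cm s⁻¹):

    dI_t/dt = P · (I_v − I_b) · S/V        with S/V = 4/d for a cylinder,

so P = slope / (I_v − I_b) × (d/4), with the vessel diameter d expressed
in cm.  The slope is an ordinary least-squares fit of the tissue intensity
against time over all usable frames (typically 0, 3, 6, 9 and 12 min),
which uses the whole linear window rather than a two-point difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.morphology import dilation, disk

from .calcium import InvalidParameterError
from .vessels import VesselMask

__all__ = [
    "PermeabilityResult",
    "measure_tracer_intensities",
    "estimate_permeability",
    "estimate_from_stack",
]


@dataclass
class PermeabilityResult:
    permeability: float  # cm/s
    flux_slope: float  # intensity/s
    delta_i: float  # I_vessel − I_background
    geometric_factor: float  # cm (V/S = d/4)
    fit_r2: float
    frames_used: int
    warnings: list[str] = field(default_factory=list)


def measure_tracer_intensities(
    stack: np.ndarray,
    vessel_mask: np.ndarray | VesselMask,
    band_px: tuple[int, int] = (1, 20),
    background_roi: tuple[int, int, int, int] | None = None,
):
    """Mean vessel / perivascular-tissue / background intensity per frame.

    The tissue band is the annulus between ``band_px[0]`` and
    ``band_px[1]`` pixels outside the vessel mask.  When no background ROI
    is given, the background intensity is the tissue intensity of the
    first frame (pre-influx baseline) for every frame.

    Returns a dict of arrays ``{"i_vessel", "i_tissue", "i_background"}``.
    """
    vm = vessel_mask.mask if isinstance(vessel_mask, VesselMask) else np.asarray(vessel_mask, dtype=bool)
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise InvalidParameterError("stack must be (T, H, W) with >= 2 frames")
    if stack.shape[1:] != vm.shape:
        raise InvalidParameterError("stack and mask shapes differ")
    inner = dilation(vm, disk(band_px[0])) if band_px[0] > 0 else vm
    outer = dilation(vm, disk(band_px[1]))
    band = outer & ~inner
    if not vm.any() or not band.any():
        raise InvalidParameterError("empty vessel or tissue compartment")
    i_v = stack[:, vm].mean(axis=1)
    i_t = stack[:, band].mean(axis=1)
    if background_roi is not None:
        r0, c0, r1, c1 = background_roi
        bg = stack[:, r0:r1, c0:c1]
        if bg[0].size == 0:
            raise InvalidParameterError("empty background ROI")
        i_b = bg.mean(axis=(1, 2))
    else:
        i_b = np.full_like(i_t, i_t[0])
    return {"i_vessel": i_v, "i_tissue": i_t, "i_background": i_b}


def estimate_permeability(
    times: np.ndarray,
    i_tissue: np.ndarray,
    i_vessel: float,
    i_background: float,
    geometric_factor: float | None = None,
    vessel_diameter_um: float | None = None,
    saturation_fraction: float = 0.95,
) -> PermeabilityResult:
    """Fit the flux slope and convert it to permeability in cm s⁻¹.

    Provide either ``geometric_factor`` (V/S in cm) or
    ``vessel_diameter_um`` (converted via d/4).  Frames with tissue
    intensity at or above ``saturation_fraction`` × I_v are excluded with
    a warning; a negative slope is reported as-is with a warning flag
    (photobleaching or washout, not physical influx).
    """
    times = np.asarray(times, dtype=float)
    i_tissue = np.asarray(i_tissue, dtype=float)
    if times.shape != i_tissue.shape or times.size < 2:
        raise InvalidParameterError("need >= 2 matched (time, intensity) samples")
    if np.any(np.diff(times) <= 0):
        raise InvalidParameterError("times must be strictly increasing")
    if i_vessel <= i_background:
        raise InvalidParameterError("vessel intensity must exceed background")
    if geometric_factor is None:
        if vessel_diameter_um is None:
            raise InvalidParameterError("give geometric_factor or vessel_diameter_um")
        geometric_factor = vessel_diameter_um * 1e-4 / 4.0
    if geometric_factor <= 0:
        raise InvalidParameterError("geometric_factor must be positive")

    warns: list[str] = []
    keep = i_tissue < saturation_fraction * i_vessel
    if not keep.all():
        if keep.sum() >= 2:
            warns.append(f"excluded {int((~keep).sum())} saturated frame(s)")
            times, i_tissue = times[keep], i_tissue[keep]
        else:
            warns.append("saturation exclusion would leave < 2 frames; kept all")
    fit = sps.linregress(times, i_tissue)
    slope = float(fit.slope)
    if slope < 0:
        warns.append("negative flux slope (photobleaching/washout?)")
    delta = float(i_vessel - i_background)
    p = slope / delta * geometric_factor
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return PermeabilityResult(
        permeability=float(p),
        flux_slope=slope,
        delta_i=delta,
        geometric_factor=float(geometric_factor),
        fit_r2=r2,
        frames_used=int(times.size),
        warnings=warns,
    )


def save_fit_plot(times, i_tissue, result: PermeabilityResult, path) -> None:
    """Write a PNG of the tissue-intensity time course and the fitted line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    times = np.asarray(times, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(times / 60.0, i_tissue, "o", label="tissue")
    intercept = np.mean(np.asarray(i_tissue) - result.flux_slope * times)
    ax.plot(times / 60.0, intercept + result.flux_slope * times, "-",
            label=f"P = {result.permeability:.2e} cm/s (R² = {result.fit_r2:.3f})")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def estimate_from_stack(
    stack: np.ndarray,
    times: np.ndarray,
    vessel_mask: np.ndarray | VesselMask,
    vessel_diameter_um: float,
    band_px: tuple[int, int] = (1, 20),
    background_roi: tuple[int, int, int, int] | None = None,
) -> PermeabilityResult:
    """Measure compartment intensities and estimate permeability in one call."""
    meas = measure_tracer_intensities(stack, vessel_mask, band_px, background_roi)
    return estimate_permeability(
        times,
        meas["i_tissue"],
        i_vessel=float(meas["i_vessel"].mean()),
        i_background=float(meas["i_background"][0]),
        vessel_diameter_um=vessel_diameter_um,
    )
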