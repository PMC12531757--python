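"""File formats, run configuration, and the end-to-end demo pipeline.

TIFF in/out goes through :mod:`tifffile` with pixel-size metadata in the
image description; tables are CSV/JSON via pandas.  A :class:`RunConfig`
round-trips through YAML, and every pipeline report embeds the config it
ran with (plus a hash, seed and package version) so any analysis is
reproducible from its own output.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .calcium import InvalidParameterError

__all__ = ["RunConfig", "read_image", "write_image", "write_table", "run_pipeline"]


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a (multi-frame) TIFF; returns ``(array, metadata)``.

    Pixel size is taken from the image-description JSON written by
    :func:`write_image` when present; TIFF resolution tags are used only
    as a fallback default and flagged as such in the metadata.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"no such image file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta: dict = {"path": str(path)}
            desc = tf.pages[0].description
            if desc:
                try:
                    meta.update(json.loads(desc))
                except (json.JSONDecodeError, TypeError):
                    pass
            if "pixel_size" not in meta:
                tags = tf.pages[0].tags
                if "XResolution" in tags:
                    num, den = tags["XResolution"].value
                    if num:
                        meta["pixel_size"] = den / num
                        meta["pixel_size_from_tags"] = True
    except (tifffile.TiffFileError, ValueError) as exc:
        raise InvalidParameterError(f"unreadable TIFF {path}: {exc}") from exc
    return arr, meta


def write_image(path, array: np.ndarray, pixel_size: float | None = None, **meta) -> None:
    """Write a single- or multi-frame TIFF with JSON metadata description."""
    md = dict(meta)
    if pixel_size is not None:
        md["pixel_size"] = pixel_size
    tifffile.imwrite(path, np.asarray(array), description=json.dumps(md))


def write_table(records, path) -> None:
    """Write records (DataFrame or list of dicts) as CSV or JSON by suffix."""
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if path.suffix == ".json":
        df.to_json(path, orient="records", indent=2)
    else:
        df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Serializable run configuration; units are explicit everywhere."""

    seed: int = 0
    out_dir: str = "heartchip_out"
    pixel_size: float = 1.0  # µm/px
    frame_interval: float = 0.01  # s
    calcium: dict = field(default_factory=dict)  # BeatTrainParams overrides
    vessels: dict = field(default_factory=dict)  # VesselNetworkParams overrides
    permeability: dict = field(default_factory=dict)  # PermeabilitySimParams overrides
    extravasation: dict = field(default_factory=lambda: {"outside_fraction": 0.618})
    analysis: dict = field(default_factory=dict)  # detector / pipeline overrides

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Seeded synthetic bundle through every analysis; recovery report.

    Generates one calcium trace, one vessel network, one permeability
    stack and one extravasation pair from ``config``, analyzes each, and
    returns a report of ground-truth versus recovered values with the full
    config embedded.
    """
    from . import calcium as ca
    from . import permeability as pm
    from . import synthetic as syn
    from . import vessels as vs

    report: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {"heartchip": __version__, "python": platform.python_version()},
        "results": {},
    }

    bp = syn.BeatTrainParams(seed=config.seed, dt=config.frame_interval, **config.calcium)
    trace, gt = syn.gen_calcium_trace(bp)
    summ = ca.analyze_trace(trace, **config.analysis.get("calcium", {}))
    report["results"]["calcium"] = {
        "true_frequency": bp.mean_frequency,
        "recovered_frequency": summ.frequency,
        "true_amplitude": bp.mean_amplitude,
        "recovered_amplitude": summ.mean_amplitude,
        "true_n_beats": gt.truth["n_beats"],
        "recovered_n_beats": summ.n_beats,
    }

    vp = syn.VesselNetworkParams(
        seed=config.seed, pixel_size=config.pixel_size, **config.vessels
    )
    img, vgt = syn.gen_vessel_network(vp)
    _, _, metrics = vs.analyze_vessel_image(img, vp.pixel_size)
    report["results"]["vessels"] = {
        "true_coverage": vgt.truth["coverage"],
        "recovered_area_fraction": metrics.area_fraction,
        "true_mean_diameter_um": vgt.truth["mean_diameter_um"],
        "recovered_mean_diameter_um": metrics.mean_diameter,
        "true_junctions": vgt.truth["n_junctions"],
        "true_endpoints": vgt.truth["n_endpoints"],
    }

    pp = syn.PermeabilitySimParams(seed=config.seed, **config.permeability)
    stack, pmask, pgt = syn.gen_permeability_stack(pp)
    pres = pm.estimate_from_stack(
        stack, np.asarray(pp.frame_times), pmask, vessel_diameter_um=pp.vessel_diameter
    )
    report["results"]["permeability"] = {
        "true_cm_per_s": pp.permeability_true,
        "recovered_cm_per_s": pres.permeability,
        "fit_r2": pres.fit_r2,
    }

    frac = config.extravasation.get("outside_fraction", 0.618)
    lip, lmask, egt = syn.gen_extravasation_pair(
        frac, vgt.truth["mask"], seed=config.seed
    )
    rec = vs.extravascular_fraction(lip, lmask, dilation_px=0)
    report["results"]["extravasation"] = {
        "true_fraction": egt.truth["realized_fraction"],
        "recovered_fraction": rec,
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clean = json.loads(json.dumps(report, default=_json_default))
    (out / "report.json").write_text(json.dumps(clean, indent=2))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist() if obj.size < 10000 else f"<array shape={obj.shape}>"
    return str(obj)
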