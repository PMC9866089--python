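"""File formats for simulated and recorded data.

Traces travel as CSV (time_s, f340, f380) with a JSON sidecar holding
protocol events and generator ground truth; images as single-channel 16-bit
TIFF with the contact region as a label TIFF; monolayers as JSON; voltage
clamp as one CSV per sweep plus a manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cluster_quant import ContactRegion, FluorescenceImage
from .dye_coupling import MonolayerGraph
from .transients import RatioTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_image",
    "read_image",
    "write_monolayer",
    "read_monolayer",
    "write_vclamp",
]


def write_trace(trace: RatioTrace, path: str | Path, *, ground_truth: dict | None = None) -> None:
    """Write a trace CSV plus `<stem>.meta.json` sidecar."""
    path = Path(path)
    cols = {"time_s": trace.time}
    if trace.f340 is not None and trace.f380 is not None:
        cols["f340"] = trace.f340
        cols["f380"] = trace.f380
    else:
        cols["ratio"] = trace.ratio
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "sample_rate": trace.sample_rate,
        "events": [[t, kind] for t, kind in trace.annotations],
        "ground_truth": ground_truth or {},
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_trace(path: str | Path) -> RatioTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    time = df["time_s"].to_numpy()
    if "f340" in df.columns:
        f340 = df["f340"].to_numpy()
        f380 = df["f380"].to_numpy()
        ratio = f340 / f380
    else:
        f340 = f380 = None
        ratio = df["ratio"].to_numpy()
    sample_rate = meta.get("sample_rate")
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(time)))
    return RatioTrace(
        time=time,
        ratio=ratio,
        sample_rate=float(sample_rate),
        f340=f340,
        f380=f380,
        annotations=[(float(t), str(k)) for t, k in meta.get("events", [])],
    )


def write_image(
    img: FluorescenceImage,
    region: ContactRegion,
    path: str | Path,
    *,
    ground_truth: list | None = None,
) -> None:
    """Write `<stem>.tif` (16-bit image), `<stem>.mask.tif` and sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.clip(img.pixels, 0, 65535).astype(np.uint16))
    tifffile.imwrite(
        path.with_suffix(".mask.tif"), region.mask.astype(np.uint8)
    )
    meta = {
        "pixel_size_um": img.pixel_size,
        "ground_truth": [
            {
                "area_um2": c.area,
                "centroid": list(c.centroid),
                "peak_intensity": c.mean_intensity,
            }
            for c in (ground_truth or [])
        ],
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_image(path: str | Path) -> tuple[FluorescenceImage, ContactRegion]:
    path = Path(path)
    meta_path = path.with_suffix(".meta.json")
    pixel_size = 0.1581
    if meta_path.exists():
        pixel_size = json.loads(meta_path.read_text()).get("pixel_size_um", pixel_size)
    pixels = tifffile.imread(path).astype(float)
    mask = tifffile.imread(path.with_suffix(".mask.tif")).astype(bool)
    return (
        FluorescenceImage(pixels=pixels, pixel_size=pixel_size),
        ContactRegion(mask=mask, pixel_size=pixel_size),
    )


def write_monolayer(monolayer: MonolayerGraph, path: str | Path) -> None:
    Path(path).write_text(monolayer.to_json())


def read_monolayer(path: str | Path) -> MonolayerGraph:
    return MonolayerGraph.from_json(Path(path).read_text())


def write_vclamp(rec, out_dir: str | Path) -> None:
    """One CSV per sweep (time_s, command_mV, current_pA) plus manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for v, current in rec.sweeps.items():
        pd.DataFrame(
            {"time_s": rec.time, "command_mV": v, "current_pA": current}
        ).to_csv(out / f"sweep_{v:+.0f}mV.csv", index=False)
    pd.DataFrame(
        {"time_s": rec.time, "command_mV": rec.holding + rec.subtraction_dv,
         "current_pA": rec.subtraction}
    ).to_csv(out / "subtraction.csv", index=False)
    for name, sweep, dv in (
        ("passive_plus", rec.passive_plus, rec.passive_dv),
        ("passive_minus", rec.passive_minus, -rec.passive_dv),
    ):
        pd.DataFrame(
            {"time_s": rec.passive_time, "command_mV": rec.holding + dv,
             "current_pA": sweep}
        ).to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "holding_mV": rec.holding,
        "sample_rate_hz": rec.sample_rate,
        "pulse_start_s": rec.pulse_start,
        "pulse_dur_s": rec.pulse_dur,
        "passive_pulse_start_s": rec.passive_pulse_start,
        "passive_pulse_dur_s": rec.passive_pulse_dur,
        "passive_dv_mV": rec.passive_dv,
        "subtraction_dv_mV": rec.subtraction_dv,
        "ground_truth": rec.manifest,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
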