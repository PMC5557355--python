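"""Readers and writers for the pipeline's file formats.

Images travel as TIFF (single- or multi-page), ROIs as JSON polygon lists in
μm, tables as CSV with documented headers, configuration as YAML, and
results as CSV with JSON sidecars.  Every writer's output round-trips
through its reader with value equality.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .puncta import PairingResult, Punctum

__all__ = [
    "read_image",
    "write_image",
    "read_roi_json",
    "write_roi_json",
    "read_spine_table",
    "write_spine_table",
    "puncta_to_dataframe",
    "write_puncta_csv",
    "pairing_result_to_dict",
    "write_pairing_result",
    "read_ct_table",
    "write_ct_table",
    "write_overlay_png",
]

SPINE_COLUMNS = [
    "length_um",
    "mean_width_head_um",
    "max_width_neck_um",
    "min_width_um",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF image or stack as a float array (pages stack along z)."""
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - single named error per contract
        raise ValueError(f"cannot read TIFF file {path}: {exc}") from exc
    return np.asarray(data, dtype=float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32),
                     photometric="minisblack")


def read_roi_json(path: str | Path) -> list[tuple[float, float]]:
    """Read an ROI polygon as a list of (x_um, y_um) vertices.

    Accepts either a bare list of [x, y] pairs or an object with a
    ``polygon_um`` key.
    """
    with open(path) as fh:
        obj = json.load(fh)
    if isinstance(obj, dict):
        obj = obj["polygon_um"]
    poly = [(float(x), float(y)) for x, y in obj]
    if len(poly) < 3:
        raise ValueError(f"ROI polygon in {path} has fewer than 3 vertices")
    return poly


def write_roi_json(path: str | Path, polygon_um: list[tuple[float, float]]
                   ) -> None:
    with open(path, "w") as fh:
        json.dump({"polygon_um": [[float(x), float(y)] for x, y in polygon_um]},
                  fh, indent=1)
        fh.write("\n")


def read_spine_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(SPINE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(
            f"spine table {path} is missing columns: {sorted(missing)}"
        )
    return table


def write_spine_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def puncta_to_dataframe(puncta: list[Punctum]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in puncta],
            "channel": [p.channel for p in puncta],
            "area_px": [p.area_px for p in puncta],
            "area_um2": [p.area_um2 for p in puncta],
            "centroid_x_um": [p.centroid_um[0] for p in puncta],
            "centroid_y_um": [p.centroid_um[1] for p in puncta],
            "mean_intensity": [p.mean_intensity for p in puncta],
            "snr": [p.snr for p in puncta],
        }
    )


def write_puncta_csv(path: str | Path, puncta: list[Punctum]) -> None:
    puncta_to_dataframe(puncta).to_csv(path, index=False)


def pairing_result_to_dict(result: PairingResult) -> dict:
    return {
        "singles_red": result.singles_red,
        "singles_green": result.singles_green,
        "paired_red": result.paired_red,
        "paired_green": result.paired_green,
        "total_red": result.total_red,
        "total_green": result.total_green,
        "multisynaptic_contacts": result.multisynaptic_contacts,
        "roi_area_um2": result.roi_area_um2,
        "densities_per_um2": result.densities_per_um2,
        "overlap_objects": [
            {"red_id": r, "green_id": g, "overlap_px": n, "overlap_um2": a}
            for r, g, n, a in result.overlap_objects
        ],
    }


def write_pairing_result(path: str | Path, result: PairingResult) -> None:
    with open(path, "w") as fh:
        json.dump(pairing_result_to_dict(result), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"gene", "condition", "ct"} - set(table.columns)
    if missing:
        raise ValueError(f"Ct table {path} is missing columns: {sorted(missing)}")
    return table


def write_ct_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_overlay_png(path: str | Path, red: np.ndarray, green: np.ndarray,
                      result: PairingResult | None = None,
                      roi_polygon_um: list[tuple[float, float]] | None = None,
                      pixel_size_um: float = 0.07) -> None:
    """QC overlay: red/green composite with ROI outline and pair count."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = np.zeros(red.shape + (3,))
    for i, chan in enumerate((red, green)):
        hi = np.percentile(chan, 99.5)
        lo = chan.min()
        rgb[..., i] = np.clip((chan - lo) / max(hi - lo, 1e-9), 0, 1)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(rgb)
    if roi_polygon_um is not None:
        xs = [x / pixel_size_um for x, _ in roi_polygon_um]
        ys = [y / pixel_size_um for _, y in roi_polygon_um]
        ax.plot(xs + xs[:1], ys + ys[:1], "w--", lw=0.8)
    title = "puncta overlay"
    if result is not None:
        title += (f" - {len(result.overlap_objects)} pairs, "
                  f"{result.singles_red}/{result.singles_green} singles (R/G)")
    ax.set_title(title, fontsize=9)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def dataclass_to_yaml_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def write_yaml(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
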