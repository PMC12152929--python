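"""TIFF and CSV input/output.

Images travel as single-channel 16-bit grayscale TIFF, one file per
channel, with the physical pixel size and channel label recorded in a
JSON sidecar (``<image>.tif.json``).  Tables are plain CSV with units in
the column headers (``x_nm``, ``volume_um3``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import Image2D, ImageStats, ParticleRecord

__all__ = [
    "write_image",
    "read_image",
    "particles_to_dataframe",
    "write_particles_csv",
    "read_centers_csv",
    "write_centers_csv",
]


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_image(image: Image2D, path) -> None:
    """Write a 16-bit grayscale TIFF plus its JSON metadata sidecar."""
    path = Path(path)
    values = np.asarray(image.values)
    if values.dtype != np.uint16:
        values = np.clip(np.rint(values), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, values)
    meta = {"pixel_size_nm": image.pixel_size_nm, "channel": image.channel}
    meta.update({k: v for k, v in image.meta.items() if isinstance(v, (int, float, str))})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_image(path, pixel_size_nm: float | None = None, channel: str = "") -> Image2D:
    """Read a single-channel TIFF; pixel size from the sidecar unless given.

    Raises
    ------
    FileNotFoundError
        Naming the missing image file.
    ValueError
        If no pixel size is available from either the sidecar or the caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        values = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - corrupt input path
        raise ValueError(f"unreadable TIFF: {path}: {exc}") from exc
    meta: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError(f"no pixel size for {path}: pass pixel_size_nm or provide a sidecar")
    return Image2D(values, float(px), channel=channel or meta.get("channel", ""), meta=meta)


def particles_to_dataframe(particles: list[ParticleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [p.id for p in particles],
            "area_px": [p.area_px for p in particles],
            "area_um2": [p.area_um2 for p in particles],
            "x_nm": [p.centroid_nm[0] for p in particles],
            "y_nm": [p.centroid_nm[1] for p in particles],
            "volume_um3": [p.equivalent_volume_um3 for p in particles],
            "circularity": [p.circularity for p in particles],
            "ellipse_x_nm": [p.ellipse_center_nm[0] for p in particles],
            "ellipse_y_nm": [p.ellipse_center_nm[1] for p in particles],
        }
    )


def write_particles_csv(particles: list[ParticleRecord], path) -> None:
    particles_to_dataframe(particles).to_csv(path, index=False)


def write_centers_csv(centers: np.ndarray, channel: str, path) -> None:
    """Write an (n, 2) nm center list as (id, x_nm, y_nm, channel)."""
    centers = np.asarray(centers).reshape(-1, 2)
    pd.DataFrame(
        {
            "id": np.arange(len(centers)),
            "x_nm": centers[:, 0],
            "y_nm": centers[:, 1],
            "channel": channel,
        }
    ).to_csv(path, index=False)


def read_centers_csv(path, channel: str | None = None) -> np.ndarray:
    """Read droplet centers (nm) from CSV; optionally filter by channel.

    Accepts externally supplied ROI center lists, so manually annotated
    droplets can be classified through the same distance-criterion path.
    """
    df = pd.read_csv(path)
    if channel is not None and "channel" in df.columns:
        df = df[df["channel"] == channel]
    return df[["x_nm", "y_nm"]].to_numpy(dtype=float)


def stats_row(image_id: str, stats: ImageStats) -> dict:
    return {
        "image": image_id,
        "particle_count": stats.particle_count,
        "mean_volume_um3": stats.mean_volume_um3,
    }
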