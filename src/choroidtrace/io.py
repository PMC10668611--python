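"""Readers, writers, and configuration for the pipeline's file formats.

Images are grayscale PNG/TIFF; traces, measurements, pairs, and cohort
tables are CSV with a ``#``-prefixed header block recording the software
version, seed, and config hash; reports are JSON. Configuration files are
flat ``key=value`` text.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import BoundaryTrace, BScan, InvalidParameterError, MetadataError

__version__ = "0.1.0"


def load_bscan(path, metadata: dict) -> BScan:
    """Load a grayscale PNG/TIFF as a BScan with intensities in [0, 1].

    ``metadata`` must provide ``lateral_scale``, ``axial_scale`` and
    ``fovea_column``; remaining keys are attached as acquisition metadata.
    """
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        if not np.all(img[..., 0] == img[..., 1]):
            raise InvalidParameterError(f"{path}: not a grayscale image")
        img = img[..., 0]
    if img.ndim != 2:
        raise InvalidParameterError(f"{path}: expected a 2-D grayscale image")
    for key in ("lateral_scale", "axial_scale", "fovea_column"):
        if key not in metadata:
            raise MetadataError(f"missing required metadata key {key!r}")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(img.dtype).max
    else:
        img = img.astype(float)
    meta = {k: v for k, v in metadata.items()
            if k not in ("lateral_scale", "axial_scale", "fovea_column")}
    return BScan(
        pixels=img,
        lateral_scale=float(metadata["lateral_scale"]),
        axial_scale=float(metadata["axial_scale"]),
        fovea_column=int(metadata["fovea_column"]),
        meta=meta,
    )


def save_bscan(scan: BScan, path) -> None:
    """Write a BScan as 8-bit PNG or 16-bit TIFF depending on the suffix."""
    path = Path(path)
    img = np.clip(scan.pixels, 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, (img * 65535).round().astype(np.uint16))
    else:
        iio.imwrite(path, (img * 255).round().astype(np.uint8))


def _header_lines(seed=None, config: dict | None = None) -> list[str]:
    lines = [f"# choroidtrace={__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_sha={digest}")
    return lines


def write_table(df: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """Write a CSV with the standard comment-header block."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_trace(trace: BoundaryTrace, path, seed=None, config: dict | None = None) -> None:
    df = pd.DataFrame(
        {"column": trace.columns, "row_subpixel": trace.rows, "sd_px": trace.sd}
    )
    write_table(df, path, seed=seed, config=config)


def read_trace(path) -> BoundaryTrace:
    df = read_table(path)
    return BoundaryTrace(
        columns=df["column"].to_numpy(),
        rows=df["row_subpixel"].to_numpy(),
        sd=df["sd_px"].to_numpy(),
    )


def write_report(report: dict, path, seed=None) -> None:
    """Write a JSON report with version and seed recorded."""
    payload = {"choroidtrace": __version__}
    if seed is not None:
        payload["seed"] = seed
    payload.update(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    if "," in value:
        return [_coerce(v.strip()) for v in value.split(",")]
    return value


def load_config(path) -> dict:
    """Parse a flat key=value config file; ``#`` starts a comment."""
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidParameterError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = _coerce(value.strip())
    return out
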