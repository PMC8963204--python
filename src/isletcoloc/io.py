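"""Reading and writing the pipeline's on-disk formats.

Images are OME-TIFF (written by tifffile with channel names in the OME
metadata) holding a (C, H, W) uint16 stack in the fixed channel order
DAPI, INS, GCG, SST, CHGA, MDA5.  ROI label masks are single-page uint16
TIFFs with 0 = background.  Ground-truth and result tables are CSV with
full-precision floats, so write/read round-trips are bit-exact.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import CHANNELS, ChannelStack, GroundTruth

FLOAT_FORMAT = "%.17g"  # round-trips float64 exactly


class FixtureIOError(IOError):
    pass


def write_stack(path: str | Path, stack: ChannelStack) -> Path:
    path = Path(path)
    try:
        tifffile.imwrite(
            path,
            stack.data,
            ome=True,
            photometric="minisblack",
            metadata={
                "axes": "CYX",
                "Channel": {"Name": list(stack.names)},
                "PhysicalSizeX": stack.pixel_size,
                "PhysicalSizeY": stack.pixel_size,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeYUnit": "µm",
            },
        )
    except OSError as exc:
        raise FixtureIOError(f"cannot write image {path}: {exc}") from exc
    return path


def _channel_names_from_ome(xml_text: str) -> tuple[str, ...] | None:
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    names = [
        ch.get("Name")
        for ch in root.iter()
        if ch.tag.endswith("}Channel") or ch.tag == "Channel"
    ]
    if names and all(n for n in names):
        return tuple(names)
    return None


def read_stack(path: str | Path) -> ChannelStack:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            names = None
            pixel_size = 0.5
            if tf.ome_metadata:
                names = _channel_names_from_ome(tf.ome_metadata)
                try:
                    root = ET.fromstring(tf.ome_metadata)
                    for px in root.iter():
                        if px.tag.endswith("}Pixels"):
                            pixel_size = float(px.get("PhysicalSizeX", pixel_size))
                            break
                except ET.ParseError:
                    pass
    except (OSError, ValueError) as exc:
        raise FixtureIOError(f"cannot read image {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if names is None:
        if data.shape[0] != len(CHANNELS):
            raise FixtureIOError(
                f"{path}: no channel names in metadata and {data.shape[0]} pages "
                f"!= the default {len(CHANNELS)}-channel layout"
            )
        names = CHANNELS
    return ChannelStack(data=np.ascontiguousarray(data), names=tuple(names), pixel_size=pixel_size)


def write_labels(path: str | Path, labels: np.ndarray) -> Path:
    path = Path(path)
    try:
        tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")
    except OSError as exc:
        raise FixtureIOError(f"cannot write label mask {path}: {exc}") from exc
    return path


def read_labels(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        return tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise FixtureIOError(f"cannot read label mask {path}: {exc}") from exc


def write_csv(path: str | Path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    """Counterpart of :func:`write_csv`: lossless float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def write_fixture(stack: ChannelStack, truth: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write one donor fixture: image + ROI label mask + ground-truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "image": write_stack(out_dir / "image.ome.tif", stack),
        "roi_labels": write_labels(out_dir / "roi_labels.tif", truth.roi_labels),
        "truth": write_csv(out_dir / "truth.csv", truth.to_frame()),
    }
    return files


def read_fixture(in_dir: str | Path) -> tuple[ChannelStack, np.ndarray, pd.DataFrame]:
    in_dir = Path(in_dir)
    stack = read_stack(in_dir / "image.ome.tif")
    labels = read_labels(in_dir / "roi_labels.tif")
    truth = pd.read_csv(in_dir / "truth.csv", float_precision="round_trip")
    return stack, labels, truth
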