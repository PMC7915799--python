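"""Volumetric containers and slice-stack / DICOM input-output.

A scan is held as a plain 3-D numpy grid indexed ``(k, y, x)`` — slice,
row, column — together with its voxel spacing and an intensity-unit tag.
Two units exist: calibrated Hounsfield values (``"hu"``) and windowed
8-bit display values (``"8bit"``).  Quantitative measurements (fluid
density) require Hu; profile plotting and signature detection work in
either unit given matching thresholds.

On disk a volume is a directory of equally sized PNG slices
(``slice_0000.png``, ...) plus a ``volume.json`` sidecar recording
spacing, unit and, where applicable, the display window.  8-bit volumes
round-trip bit-identically.  Hu volumes are stored as 16-bit PNGs with a
fixed intercept of −1024 (recorded in the sidecar), exact for integer Hu
in [−1024, 64511].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "Tissue",
    "DEFAULT_HU",
    "SINUS_INTERIOR",
    "Volume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_dicom_series",
]

#: Intercept used when persisting Hu volumes as unsigned 16-bit PNGs.
HU_PNG_INTERCEPT = -1024

SIDECAR_NAME = "volume.json"


class Tissue(IntEnum):
    """Voxel classes of a labelled sinus volume."""

    BACKGROUND = 0
    BONE = 1
    AIR = 2
    FLUID = 3
    MUCOSA = 4
    CYST = 5
    FOREIGN_BODY = 6


#: Default Hounsfield value per tissue class.  Air/serous/purulent fluid
#: follow CT convention and the diagnostic reference values (serous ≈ 19 Hu,
#: purulent ≈ 37 Hu); mucosa, bone and metallic foreign bodies are generic
#: soft-tissue / cortical / metal densities.
DEFAULT_HU: dict[Tissue, float] = {
    Tissue.BACKGROUND: 40.0,
    Tissue.BONE: 700.0,
    Tissue.AIR: -1000.0,
    Tissue.FLUID: 19.0,
    Tissue.MUCOSA: 45.0,
    Tissue.CYST: 45.0,
    Tissue.FOREIGN_BODY: 2000.0,
}

#: Classes counted as sinus interior (cavity content) for centroids and
#: relative volume indicators.
SINUS_INTERIOR: tuple[Tissue, ...] = (
    Tissue.AIR,
    Tissue.FLUID,
    Tissue.MUCOSA,
    Tissue.CYST,
    Tissue.FOREIGN_BODY,
)


@dataclass
class Volume:
    """3-D intensity grid with spacing and unit metadata.

    Parameters
    ----------
    data
        Intensity grid indexed ``(k, y, x)``; 0-based, x = column.
    spacing_mm
        Voxel size as ``(slice step, row, column)`` in millimetres.
    unit
        ``"hu"`` for calibrated Hounsfield values, ``"8bit"`` for
        windowed display values in [0, 255].
    window
        Optional ``(center, width)`` in Hu recording the display window
        that produced an 8-bit volume.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    unit: str = "hu"
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume grid must be 3-D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")
        if self.unit not in ("hu", "8bit"):
            raise ValueError(f"unit must be 'hu' or '8bit', got {self.unit!r}")
        if self.unit == "8bit":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < 0 or hi > 255:
                raise ValueError(f"8bit volume values out of [0, 255]: [{lo}, {hi}]")
        if self.window is not None:
            self.window = (float(self.window[0]), float(self.window[1]))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing_mm, self.unit, self.window)


@dataclass
class LabelVolume:
    """Per-voxel tissue classes aligned with a :class:`Volume`."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError(f"label grid must be 3-D, got shape {self.labels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, *classes: Tissue) -> np.ndarray:
        """Boolean mask of voxels belonging to any of the given classes."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for c in classes:
            out |= self.labels == int(c)
        return out

    def counts(self) -> dict[Tissue, int]:
        """Voxel count per tissue class present in the volume."""
        vals, cnts = np.unique(self.labels, return_counts=True)
        return {Tissue(int(v)): int(c) for v, c in zip(vals, cnts)}


# ---------------------------------------------------------------------------
# slice-stack I/O


def _slice_name(i: int) -> str:
    return f"slice_{i:04d}.png"


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as a PNG slice stack plus JSON sidecar.

    Returns the directory written.  8-bit volumes are stored losslessly
    as 8-bit PNG; Hu volumes as 16-bit PNG with intercept −1024.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {
        "spacing_mm": list(volume.spacing_mm),
        "intensity_unit": volume.unit,
        "window": list(volume.window) if volume.window else None,
        "n_slices": volume.n_slices,
    }
    if volume.unit == "8bit":
        stack = np.rint(volume.data).astype(np.uint8)
    else:
        shifted = np.rint(volume.data).astype(np.int64) - HU_PNG_INTERCEPT
        if shifted.min() < 0 or shifted.max() > 65535:
            raise ValueError(
                "Hu volume outside persistable range "
                f"[{HU_PNG_INTERCEPT}, {HU_PNG_INTERCEPT + 65535}]"
            )
        stack = shifted.astype(np.uint16)
        sidecar["rescale_intercept"] = HU_PNG_INTERCEPT
    for i in range(volume.n_slices):
        Image.fromarray(stack[i]).save(path / _slice_name(i))
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> Volume:
    """Read a PNG slice stack written by :func:`write_volume`."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("spacing_mm", "intensity_unit", "n_slices"):
        if key not in sidecar:
            raise ValueError(f"sidecar missing required field {key!r}")
    n = int(sidecar["n_slices"])
    slices = []
    shape0: tuple[int, int] | None = None
    for i in range(n):
        arr = np.asarray(Image.open(path / _slice_name(i)))
        if shape0 is None:
            shape0 = arr.shape
        elif arr.shape != shape0:
            raise ValueError(
                f"slice {i} has shape {arr.shape}, expected {shape0}"
            )
        slices.append(arr)
    data = np.stack(slices, axis=0)
    unit = sidecar["intensity_unit"]
    if unit == "hu":
        data = data.astype(np.float64) + float(sidecar.get("rescale_intercept", HU_PNG_INTERCEPT))
    window = tuple(sidecar["window"]) if sidecar.get("window") else None
    return Volume(data, tuple(sidecar["spacing_mm"]), unit, window)


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as 8-bit PNG class-id slices plus sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i in range(labels.shape[0]):
        Image.fromarray(labels.labels[i]).save(path / _slice_name(i))
    sidecar = {
        "spacing_mm": list(labels.spacing_mm),
        "intensity_unit": "label",
        "n_slices": labels.shape[0],
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    sidecar = json.loads((path / SIDECAR_NAME).read_text())
    if sidecar.get("intensity_unit") != "label":
        raise ValueError(f"{path} is not a label stack")
    n = int(sidecar["n_slices"])
    data = np.stack(
        [np.asarray(Image.open(path / _slice_name(i))) for i in range(n)], axis=0
    )
    return LabelVolume(data, tuple(sidecar["spacing_mm"]))


# ---------------------------------------------------------------------------
# DICOM


def read_dicom_series(path: str | Path, files: Sequence[str | Path] | None = None) -> Volume:
    """Read a directory of single-frame DICOM slices into an Hu volume.

    Stored values are mapped to Hounsfield units through the rescale
    slope/intercept of each slice.  Slices are ordered by
    ``InstanceNumber`` when present, else by filename.
    """
    import pydicom

    path = Path(path)
    if files is None:
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
        if not files:
            files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = [pydicom.dcmread(str(f)) for f in files]
    if not datasets:
        raise ValueError(f"no DICOM slices found under {path}")
    datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    ds0 = datasets[0]
    row_mm, col_mm = (float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0]))
    step_mm = float(getattr(ds0, "SliceThickness", 1.0))
    return Volume(np.stack(slices, axis=0), (step_mm, row_mm, col_mm), unit="hu")
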