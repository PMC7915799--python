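"""The five diagnostic indicators measured on a labelled sinus volume.

x1  mean density of the fluid content, Hu;
x2  free (air) share of the anastomosis opening, %;
x3  soft-tissue content of the cavity (mucosa, polyp, cyst), % of cavity
    volume;
x4  fluid content of the cavity, % of cavity volume;
x5  aerodynamic nasal drag coefficient A, kPa/(L/s).

x2–x4 are relative quantities on purpose: ratios of voxel counts cancel
individual anatomical size so the indicators compare across patients
(and across phantom resolutions).  x1 demands calibrated Hu input —
windowed 8-bit values are refused rather than guessed back.  x5 comes
from the hydraulic model (channel geometry route) or directly from a
measured rhinomanometric (Δp, Q) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import aerodynamics
from .volume import SINUS_INTERIOR, LabelVolume, Tissue, Volume

__all__ = [
    "IndicatorVector",
    "fluid_density",
    "anastomosis_opening",
    "mucosa_volume_fraction",
    "fluid_volume_fraction",
    "extract_indicators",
]

INDICATOR_NAMES = ("x1", "x2", "x3", "x4", "x5")


@dataclass
class IndicatorVector:
    """The five indicators; ``x1`` is None when the sinus holds no fluid."""

    x1: float | None  # Hu
    x2: float  # %
    x3: float  # %
    x4: float  # %
    x5: float  # kPa/(L/s)

    def __post_init__(self) -> None:
        for name in ("x2", "x3", "x4"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
        if self.x3 + self.x4 > 100.0 + 1e-9:
            raise ValueError(f"x3 + x4 exceed 100% ({self.x3} + {self.x4})")
        if self.x5 < 0:
            raise ValueError(f"x5 must be non-negative, got {self.x5}")

    def as_dict(self) -> dict:
        return {"x1": self.x1, "x2": self.x2, "x3": self.x3, "x4": self.x4, "x5": self.x5}

    def values(self, features=INDICATOR_NAMES) -> dict:
        return {f: getattr(self, f) for f in features}


def fluid_density(volume: Volume, labels: LabelVolume) -> float | None:
    """x1: mean Hu over fluid-labelled voxels; None when no fluid exists.

    Requires a calibrated Hu volume — display-windowed 8-bit intensities
    cannot be averaged into a density.
    """
    if volume.unit != "hu":
        raise ValueError("fluid density needs Hu-calibrated intensities, got unit "
                         f"{volume.unit!r}")
    if volume.shape != labels.shape:
        raise ValueError("volume and labels are not aligned")
    mask = labels.mask(Tissue.FLUID)
    if not mask.any():
        return None
    return float(volume.data[mask].mean())


def anastomosis_opening(labels: LabelVolume, region: np.ndarray) -> float:
    """x2: percentage of the anastomosis region voxels that are air."""
    region = np.asarray(region, dtype=bool)
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty anastomosis region")
    n_air = int((labels.labels[region] == int(Tissue.AIR)).sum())
    return 100.0 * n_air / n


def _cavity_mask(labels: LabelVolume, exclude: np.ndarray | None = None) -> np.ndarray:
    mask = labels.mask(*SINUS_INTERIOR)
    if exclude is not None:
        mask &= ~np.asarray(exclude, dtype=bool)
    if not mask.any():
        raise ValueError("empty sinus cavity: no interior-class voxels")
    return mask


def mucosa_volume_fraction(labels: LabelVolume,
                           exclude: np.ndarray | None = None) -> float:
    """x3: mucosa + polyp + cyst share of the cavity volume, %.

    ``exclude`` masks voxels outside the cavity proper (e.g. the ostium
    canal) from the denominator.
    """
    cavity = _cavity_mask(labels, exclude)
    soft = labels.mask(Tissue.MUCOSA, Tissue.CYST) & cavity
    return 100.0 * int(soft.sum()) / int(cavity.sum())


def fluid_volume_fraction(labels: LabelVolume,
                          exclude: np.ndarray | None = None) -> float:
    """x4: fluid share of the cavity volume, %."""
    cavity = _cavity_mask(labels, exclude)
    fluid = labels.mask(Tissue.FLUID) & cavity
    return 100.0 * int(fluid.sum()) / int(cavity.sum())


def extract_indicators(volume: Volume, labels: LabelVolume,
                       anastomosis_region: np.ndarray,
                       *,
                       dp_kpa: float | None = None,
                       q_lps: float | None = None,
                       channels: tuple | None = None,
                       q_total: float | None = None) -> IndicatorVector:
    """Assemble the full indicator vector.

    x5 comes from a measured rhinomanometric pair (``dp_kpa``,
    ``q_lps``) or from two channel models plus a total flow
    (``channels=(left, right)``, ``q_total`` in m³/s) through the
    hydraulic model.
    """
    region = np.asarray(anastomosis_region, dtype=bool)
    if dp_kpa is not None and q_lps is not None:
        x5 = aerodynamics.drag_coefficient(dp_kpa, q_lps)
    elif channels is not None and q_total is not None:
        result = aerodynamics.split_flow(channels[0], channels[1], q_total)
        x5 = result.drag_total_kpa_per_lps
    else:
        raise ValueError("supply either (dp_kpa, q_lps) or (channels, q_total) for x5")
    return IndicatorVector(
        x1=fluid_density(volume, labels),
        x2=anastomosis_opening(labels, region),
        x3=mucosa_volume_fraction(labels, exclude=region),
        x4=fluid_volume_fraction(labels, exclude=region),
        x5=x5,
    )
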