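"""Brightness profiles (densitograms) along line trajectories and
rule-based classification of their shape.

A trajectory between pixel points Ts = (xs, ys) and Te = (xe, ye) on
slice k is parameterised as

    x(t) = xs + (xe − xs)·t,   y(t) = ys + (ye − ys)·t,   t ∈ [0, 1]

sampled at steps Δt = 1/d where d = |Te − Ts| is the Euclidean pixel
distance, so that consecutive samples advance by about one pixel.  The
intensity sequence along the trajectory is the densitogram.

A fan of such trajectories is cast from the sinus centre over the
downward semicircle ("lower hemisphere" of the cavity as seen on a
coronal section).  Each profile is classified into one of five
signatures by threshold rules:

NORMAL         air-level plateau through the cavity ending in a
               pronounced bone peak;
TISSUE_CONTENT tissue-density interior with a single terminal bone peak
               (fluid or polypous filling);
CYST           an extra tissue border inside the cavity before the bone
               peak (two upward tissue crossings);
PERFORATION    tissue-density interior with no bone peak at the far
               border;
FOREIGN_BODY   an interior sample at metal-level intensity, overriding
               all other evidence.

The rules are applied in fixed priority order (most specific evidence
first): FOREIGN_BODY > PERFORATION > CYST > TISSUE_CONTENT > NORMAL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

from .volume import SINUS_INTERIOR, LabelVolume, Volume

__all__ = [
    "Trajectory",
    "Densitogram",
    "Signature",
    "ProfileSignature",
    "Thresholds",
    "line_trajectory",
    "sample_profile",
    "sinus_center",
    "radial_fan",
    "classify_profile",
    "aggregate_signatures",
]


@dataclass(frozen=True)
class Trajectory:
    """Parametric line on one slice, sampled at Δt = 1/d."""

    start: tuple[float, float]  # (x, y) pixels
    end: tuple[float, float]
    slice_index: int
    d: float  # Euclidean length, pixels
    dt: float
    t_samples: np.ndarray

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample coordinates (x(t), y(t)) along the line."""
        xs, ys = self.start
        xe, ye = self.end
        t = self.t_samples
        return xs + (xe - xs) * t, ys + (ye - ys) * t

    def reversed(self) -> "Trajectory":
        return line_trajectory(self.end, self.start, self.slice_index)


@dataclass
class Densitogram:
    """Sampled intensities along a trajectory."""

    positions_px: np.ndarray  # distance from the start, pixels
    positions_mm: np.ndarray
    values: np.ndarray
    unit: str
    trajectory: Trajectory


class Signature(str, Enum):
    NORMAL = "NORMAL"
    CYST = "CYST"
    PERFORATION = "PERFORATION"
    FOREIGN_BODY = "FOREIGN_BODY"
    TISSUE_CONTENT = "TISSUE_CONTENT"


#: Aggregation priority — the most specific evidence wins.
PRIORITY = (
    Signature.FOREIGN_BODY,
    Signature.PERFORATION,
    Signature.CYST,
    Signature.TISSUE_CONTENT,
    Signature.NORMAL,
)


@dataclass
class ProfileSignature:
    label: Signature
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Thresholds:
    """Intensity cut-offs for signature detection.

    Defaults are Hounsfield-scale values; profiles sampled from windowed
    8-bit volumes need thresholds restated on that scale.  ``prominence``
    is how far the terminal peak must rise above the interior median to
    count as a bone border; ``plateau_len`` the minimum run of
    consecutive tissue-level samples treated as content rather than a
    border artefact.
    """

    t_air: float = -500.0
    t_tissue: float = 0.0
    t_bone: float = 300.0
    t_foreign: float = 1500.0
    prominence: float = 200.0
    plateau_len: int = 3

    def __post_init__(self) -> None:
        if not (self.t_air < self.t_tissue < self.t_bone <= self.t_foreign):
            raise ValueError(
                "thresholds must satisfy t_air < t_tissue < t_bone <= t_foreign, got "
                f"{self.t_air}, {self.t_tissue}, {self.t_bone}, {self.t_foreign}"
            )


# ---------------------------------------------------------------------------
# trajectories and sampling


def line_trajectory(ts: tuple[float, float], te: tuple[float, float],
                    slice_index: int = 0,
                    slice_shape: tuple[int, int] | None = None) -> Trajectory:
    """Build the sampled line from Ts to Te on slice k.

    ``slice_shape`` (ny, nx), when given, rejects endpoints outside the
    slice bounds.
    """
    xs, ys = float(ts[0]), float(ts[1])
    xe, ye = float(te[0]), float(te[1])
    d = math.hypot(xe - xs, ye - ys)
    if d == 0:
        raise ValueError("trajectory endpoints coincide")
    if slice_shape is not None:
        ny, nx = slice_shape
        for name, (x, y) in (("start", (xs, ys)), ("end", (xe, ye))):
            if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
                raise ValueError(f"{name} point ({x}, {y}) outside slice bounds {slice_shape}")
    dt = 1.0 / d
    t = np.arange(0.0, 1.0, dt)
    if t[-1] < 1.0:
        t = np.append(t, 1.0)
    return Trajectory(start=(xs, ys), end=(xe, ye), slice_index=int(slice_index),
                      d=d, dt=dt, t_samples=t)


def sample_profile(volume: Volume, trajectory: Trajectory,
                   interpolation: str = "nearest") -> Densitogram:
    """Sample the volume along a trajectory on its slice.

    ``nearest`` picks the closest voxel centre (half-up rounding);
    ``linear`` interpolates bilinearly within the slice.
    """
    k = trajectory.slice_index
    if not 0 <= k < volume.n_slices:
        raise ValueError(f"slice index {k} outside volume with {volume.n_slices} slices")
    sl = volume.data[k]
    ny, nx = sl.shape
    x, y = trajectory.coordinates()
    if x.min() < -0.5 or x.max() > nx - 0.5 or y.min() < -0.5 or y.max() > ny - 0.5:
        raise ValueError("trajectory leaves the slice")
    if interpolation == "nearest":
        xi = np.clip(np.floor(x + 0.5).astype(int), 0, nx - 1)
        yi = np.clip(np.floor(y + 0.5).astype(int), 0, ny - 1)
        values = sl[yi, xi].astype(np.float64)
    elif interpolation == "linear":
        values = ndimage.map_coordinates(sl.astype(np.float64), [y, x], order=1,
                                         mode="nearest")
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    t = trajectory.t_samples
    pos_px = t * trajectory.d
    _, sy, sx = volume.spacing_mm
    dx_mm = (trajectory.end[0] - trajectory.start[0]) * sx
    dy_mm = (trajectory.end[1] - trajectory.start[1]) * sy
    pos_mm = t * math.hypot(dx_mm, dy_mm)
    return Densitogram(positions_px=pos_px, positions_mm=pos_mm, values=values,
                       unit=volume.unit, trajectory=trajectory)


def sinus_center(labels: LabelVolume, slice_index: int) -> tuple[int, int]:
    """Centroid (x, y) of sinus-interior voxels on one slice, rounded.

    All content classes count (air, fluid, mucosa, cyst, foreign body),
    so the centre does not move when the sinus fills.
    """
    if not 0 <= slice_index < labels.shape[0]:
        raise ValueError(f"slice index {slice_index} out of range")
    mask = labels.mask(*SINUS_INTERIOR)[slice_index]
    if not mask.any():
        raise ValueError(
            f"center undeterminable: no sinus-interior voxels on slice {slice_index}"
        )
    ys, xs = np.nonzero(mask)
    return int(round(xs.mean())), int(round(ys.mean()))


def radial_fan(center: tuple[float, float], radius: float, n_rays: int = 13,
               sector: str = "lower_hemisphere", slice_index: int = 0,
               slice_shape: tuple[int, int] | None = None) -> list[Trajectory]:
    """Equally spaced rays from the centre over the downward semicircle.

    Angles run from 0° (horizontal left) through 90° (straight down) to
    180° (horizontal right) inclusive; ``sector="full"`` covers the full
    circle (end angle excluded to avoid a duplicate ray).  Rays are
    clipped to the slice bounds, so every returned trajectory has
    d ≤ radius.
    """
    if n_rays < 3:
        raise ValueError(f"n_rays must be >= 3, got {n_rays}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    cx, cy = float(center[0]), float(center[1])
    if slice_shape is not None:
        ny, nx = slice_shape
        if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
            raise ValueError(f"center ({cx}, {cy}) outside slice bounds {slice_shape}")
    if sector == "lower_hemisphere":
        angles = np.linspace(0.0, 180.0, n_rays)
    elif sector == "full":
        angles = np.linspace(0.0, 360.0, n_rays, endpoint=False)
    else:
        raise ValueError(f"unknown sector {sector!r}")
    rays = []
    for deg in angles:
        th = math.radians(deg)
        # 0 deg -> left, 90 deg -> down (+y, rows grow downward), 180 deg -> right
        dx, dy = -math.cos(th), math.sin(th)
        ex, ey = cx + radius * dx, cy + radius * dy
        if slice_shape is not None:
            ny, nx = slice_shape
            scale = 1.0
            if dx != 0:
                lim = (nx - 1 - cx) / (radius * dx) if dx > 0 else (0 - cx) / (radius * dx)
                scale = min(scale, lim)
            if dy != 0:
                lim = (ny - 1 - cy) / (radius * dy) if dy > 0 else (0 - cy) / (radius * dy)
                scale = min(scale, lim)
            ex, ey = cx + radius * scale * dx, cy + radius * scale * dy
        rays.append(line_trajectory((cx, cy), (ex, ey), slice_index))
    return rays


# ---------------------------------------------------------------------------
# signature classification


def _upward_crossings(values: np.ndarray, level: float) -> int:
    above = values >= level
    return int(np.count_nonzero(~above[:-1] & above[1:])) + int(above[0])


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def classify_profile(profile: Densitogram,
                     thresholds: Thresholds | None = None) -> ProfileSignature:
    """Classify one densitogram into a pathology signature.

    The interior is everything before the first bone-level sample (the
    whole profile when none exists).  Evidence collected: the bone-peak
    position/height, the tissue-plateau extent, the number of upward
    tissue crossings (extra borders) and any metal-level inclusion.
    Rules in priority order:

    1. FOREIGN_BODY — any sample at or above ``t_foreign``;
    2. PERFORATION — a tissue plateau in the interior and no bone peak;
    3. CYST — ≥ 2 upward tissue crossings and a bone peak;
    4. TISSUE_CONTENT — tissue-level interior and a bone peak;
    5. NORMAL — otherwise (air-level cavity ending at the bone border).
    """
    thr = thresholds or Thresholds()
    v = np.asarray(profile.values, dtype=np.float64)
    if v.size < 5:
        raise ValueError(f"profile too short for classification ({v.size} samples)")

    bone_idx_arr = np.nonzero(v >= thr.t_bone)[0]
    first_bone = int(bone_idx_arr[0]) if bone_idx_arr.size else None
    interior = v[:first_bone] if first_bone is not None else v
    if interior.size == 0:
        interior = v[:1]
    interior_median = float(np.median(interior))
    has_bone_peak = (
        first_bone is not None
        and float(v[first_bone:].max()) >= interior_median + thr.prominence
    )
    plateau = _longest_run(interior >= thr.t_tissue)
    crossings = _upward_crossings(v, thr.t_tissue)
    foreign_idx = np.nonzero(v >= thr.t_foreign)[0]

    evidence = {
        "interior_median": interior_median,
        "bone_peak_index": first_bone,
        "bone_peak_value": float(v[first_bone:].max()) if first_bone is not None else None,
        "has_bone_peak": has_bone_peak,
        "tissue_plateau_len": plateau,
        "tissue_upward_crossings": crossings,
        "foreign_index": int(foreign_idx[0]) if foreign_idx.size else None,
    }

    if foreign_idx.size:
        label = Signature.FOREIGN_BODY
    elif plateau >= thr.plateau_len and not has_bone_peak:
        label = Signature.PERFORATION
    elif has_bone_peak and crossings >= 2:
        label = Signature.CYST
    elif has_bone_peak and bool((interior >= thr.t_tissue).any()):
        label = Signature.TISSUE_CONTENT
    elif has_bone_peak and bool((interior <= thr.t_air).all()):
        label = Signature.NORMAL
    elif not has_bone_peak:
        # no tissue content either: an open border over an aerated cavity
        label = Signature.PERFORATION
    else:
        label = Signature.NORMAL
    return ProfileSignature(label=label, evidence=evidence)


def aggregate_signatures(signatures: list[ProfileSignature],
                         min_support: int = 1) -> tuple[Signature, int, dict]:
    """Sinus-level finding from a fan of per-ray signatures.

    The highest-priority label supported by at least ``min_support``
    rays wins; when none reaches the support floor, the most frequent
    label is returned.  Returns (label, supporting rays, counts).
    """
    if not signatures:
        raise ValueError("no signatures to aggregate")
    counts: dict[Signature, int] = {}
    for s in signatures:
        counts[s.label] = counts.get(s.label, 0) + 1
    for label in PRIORITY:
        if counts.get(label, 0) >= min_support:
            return label, counts[label], {k.value: c for k, c in counts.items()}
    label = max(counts, key=lambda k: counts[k])
    return label, counts[label], {k.value: c for k, c in counts.items()}
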