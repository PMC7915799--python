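"""Synthetic maxillary-sinus phantoms with known ground truth.

The cavity is a sphere embedded in a bone shell inside a soft-tissue
background.  Gravity points along +y (rows increase downward), so fluid
occupies the voxels below a horizontal plane whose height is chosen to
match a requested fill fraction; polypous soft tissue fills a band above
the fluid.  Optional lesions reproduce the archetypal densitographic
pictures: a cyst (tissue sphere inside the air cavity), a perforation
(bone removed in a cone around the cavity floor, exposing the cavity to
background tissue), and a metallic foreign body.  A cylindrical ostium
(anastomosis) is carved through the bone roof; its open fraction is the
air share of the carved cross-section.

Everything the generator emits is recomputable by brute-force voxel
counting on the returned label volume, which is what the ground-truth
record carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .aerodynamics import ChannelModel, ChannelSection, circular_tube
from .volume import DEFAULT_HU, SINUS_INTERIOR, LabelVolume, Tissue, Volume

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "SphereSpec",
    "PerforationSpec",
    "NoiseSpec",
    "make_sinus_phantom",
    "add_impulse_noise",
    "make_channel_geometry",
    "preset_config",
    "PRESETS",
]


@dataclass(frozen=True)
class SphereSpec:
    """A spherical insert: centre offset from the cavity centre (mm) and radius."""

    offset_mm: tuple[float, float, float]  # (k, y, x) offsets
    radius_mm: float
    hu: float | None = None  # override intensity (foreign bodies)


@dataclass(frozen=True)
class PerforationSpec:
    """Cone of removed floor bone, half-angle around straight-down (+y)."""

    half_angle_deg: float = 30.0


@dataclass(frozen=True)
class NoiseSpec:
    probability: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity recipe for one synthetic sinus volume.

    Defaults give a 64³ isotropic 0.5 mm grid (32 mm field of view)
    holding a 12 mm cavity in a 2.5 mm bone shell, with a 2 mm-radius
    ostium carved through the roof.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    sinus_radius_mm: float = 12.0
    bone_thickness_mm: float = 2.5
    fluid_fraction: float = 0.0
    polyp_fraction: float = 0.0  # polypous (mucosa-class) fill above the fluid
    mucosa_thickness_mm: float = 0.0
    cyst: SphereSpec | None = None
    foreign_body: SphereSpec | None = None
    perforation: PerforationSpec | None = None
    anastomosis_open_fraction: float = 1.0
    anastomosis_radius_mm: float = 2.0
    noise: NoiseSpec | None = None
    hu_values: dict = field(default_factory=lambda: dict(DEFAULT_HU))

    def __post_init__(self) -> None:
        for name in ("fluid_fraction", "polyp_fraction", "anastomosis_open_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fluid_fraction + self.polyp_fraction > 1.0 + 1e-12:
            raise ValueError("fluid_fraction + polyp_fraction exceeds 1")
        if self.sinus_radius_mm <= 0:
            raise ValueError("sinus_radius_mm must be positive")
        if self.mucosa_thickness_mm < 0 or self.bone_thickness_mm <= 0:
            raise ValueError("thicknesses must be non-negative (bone positive)")


@dataclass
class GroundTruth:
    """Brute-force recomputable expectations for a generated phantom."""

    expected_x1: float | None  # mean fluid Hu (None when no fluid)
    expected_x2: float  # % of ostium voxels that are air
    expected_x3: float  # % of cavity voxels that are mucosa/cyst
    expected_x4: float  # % of cavity voxels that are fluid
    class_counts: dict
    ostium_mask: np.ndarray  # boolean, aligned with the label grid
    cavity_voxels: int


def _radius_grid(config: PhantomConfig) -> tuple[np.ndarray, ...]:
    nk, ny, nx = config.grid_shape
    sk, sy, sx = config.spacing_mm
    ck, cy, cx = (nk - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    kk, yy, xx = np.meshgrid(
        (np.arange(nk) - ck) * sk,
        (np.arange(ny) - cy) * sy,
        (np.arange(nx) - cx) * sx,
        indexing="ij",
    )
    return kk, yy, xx, np.sqrt(kk * kk + yy * yy + xx * xx)


def _fill_fraction_plane(y_mm: np.ndarray, region: np.ndarray,
                         fraction: float) -> tuple[np.ndarray, float]:
    """Mask of region voxels below a horizontal plane holding ``fraction``.

    Scans candidate plane heights at the voxel rows and picks the one
    whose below-plane voxel share of ``region`` is closest to
    ``fraction`` (fluid levels are gravity-horizontal, so the boundary
    is planar).  Callers stack bands by subtracting lower masks.
    """
    n_total = int(region.sum())
    if n_total == 0:
        raise ValueError("empty region for fluid-level search")
    target = fraction * n_total
    ys = y_mm[region]
    levels = np.unique(ys)
    # counts of voxels with y >= level, per candidate level (descending plane)
    best_level, best_err = None, np.inf
    counts = [(lv, int((ys >= lv).sum())) for lv in levels]
    counts.append((np.inf, 0))
    for lv, cnt in counts:
        err = abs(cnt - target)
        if err < best_err:
            best_err, best_level = err, lv
    mask = region & (y_mm >= best_level)
    return mask, float(best_level)


def make_sinus_phantom(config: PhantomConfig) -> tuple[Volume, LabelVolume, GroundTruth]:
    """Generate a sinus phantom; deterministic given the config.

    Returns the intensity volume (Hu), the label volume, and a ground
    truth computed by counting voxels on the emitted labels.
    """
    nk, ny, nx = config.grid_shape
    sk, sy, sx = config.spacing_mm
    R = config.sinus_radius_mm
    outer = R + config.bone_thickness_mm
    half_extent = (
        (nk - 1) / 2.0 * sk,
        (ny - 1) / 2.0 * sy,
        (nx - 1) / 2.0 * sx,
    )
    axis_names = ("slice (k)", "row (y)", "column (x)")
    for name, ext in zip(axis_names, half_extent):
        if outer >= ext:
            raise ValueError(
                f"cavity radius + bone wall ({outer:.1f} mm) does not fit the "
                f"{name} half-extent ({ext:.1f} mm)"
            )

    kk, yy, xx, r = _radius_grid(config)
    labels = np.full(config.grid_shape, int(Tissue.BACKGROUND), dtype=np.uint8)
    labels[r <= outer] = int(Tissue.BONE)
    cavity = r <= R
    labels[cavity] = int(Tissue.AIR)

    # mucosal lining on the cavity wall
    if config.mucosa_thickness_mm > 0:
        lining = cavity & (r > R - config.mucosa_thickness_mm)
        labels[lining] = int(Tissue.MUCOSA)
        interior = cavity & ~lining
    else:
        interior = cavity

    # gravity-dependent fluid, then a polypous band directly above it
    fluid_mask = np.zeros_like(interior)
    if config.fluid_fraction > 0:
        fluid_mask, _ = _fill_fraction_plane(yy, interior, config.fluid_fraction)
        labels[fluid_mask] = int(Tissue.FLUID)
    if config.polyp_fraction > 0:
        combined, _ = _fill_fraction_plane(
            yy, interior, config.fluid_fraction + config.polyp_fraction)
        polyp_mask = combined & ~fluid_mask
        labels[polyp_mask] = int(Tissue.MUCOSA)

    # lesions
    if config.cyst is not None:
        _insert_sphere(labels, config, kk, yy, xx, config.cyst, Tissue.CYST,
                       limit=interior)
    if config.foreign_body is not None:
        _insert_sphere(labels, config, kk, yy, xx, config.foreign_body,
                       Tissue.FOREIGN_BODY, limit=cavity)
    if config.perforation is not None:
        half = np.deg2rad(config.perforation.half_angle_deg)
        with np.errstate(invalid="ignore", divide="ignore"):
            angle_from_down = np.arccos(np.clip(yy / np.maximum(r, 1e-9), -1, 1))
        cone = (labels == int(Tissue.BONE)) & (angle_from_down <= half)
        labels[cone] = int(Tissue.BACKGROUND)

    # ostium: vertical cylinder through the bone roof
    axial_dist = np.sqrt(kk * kk + xx * xx)
    in_cyl = (axial_dist <= config.anastomosis_radius_mm) & (yy < 0)
    ostium_mask = in_cyl & (labels == int(Tissue.BONE))
    if ostium_mask.any():
        open_r = config.anastomosis_radius_mm * np.sqrt(config.anastomosis_open_fraction)
        open_mask = ostium_mask & (axial_dist <= open_r)
        labels[ostium_mask] = int(Tissue.MUCOSA)
        labels[open_mask] = int(Tissue.AIR)
    else:
        open_mask = np.zeros_like(ostium_mask)

    # intensities from the Hu map
    hu_map = {int(k): float(v) for k, v in config.hu_values.items()}
    present = set(np.unique(labels).tolist())
    missing = present - set(hu_map)
    if missing:
        raise ValueError(f"hu_values missing entries for classes {sorted(missing)}")
    lut = np.zeros(max(hu_map) + 1, dtype=np.float64)
    for cls, hu in hu_map.items():
        lut[cls] = hu
    volume = Volume(lut[labels], config.spacing_mm, unit="hu")
    if config.noise is not None and config.noise.probability > 0:
        volume = add_impulse_noise(volume, config.noise.probability, config.noise.seed)

    label_volume = LabelVolume(labels, config.spacing_mm)
    gt = _ground_truth(label_volume, ostium_mask, hu_map)
    return volume, label_volume, gt


def _insert_sphere(labels, config, kk, yy, xx, spec: SphereSpec, tissue: Tissue,
                   limit: np.ndarray) -> None:
    ok, oy, ox = spec.offset_mm
    d = np.sqrt((kk - ok) ** 2 + (yy - oy) ** 2 + (xx - ox) ** 2)
    inside = (d <= spec.radius_mm) & limit
    if not inside.any():
        raise ValueError(
            f"{tissue.name.lower()} sphere (radius {spec.radius_mm} mm at offset "
            f"{spec.offset_mm}) lies outside the cavity"
        )
    labels[inside] = int(tissue)


def _ground_truth(labels: LabelVolume, ostium_mask: np.ndarray, hu_map: dict) -> GroundTruth:
    counts = labels.counts()
    cavity_mask = labels.mask(*SINUS_INTERIOR) & ~ostium_mask
    n_cavity = int(cavity_mask.sum())
    lab = labels.labels
    n_fluid = int(((lab == int(Tissue.FLUID)) & cavity_mask).sum())
    n_soft = int((((lab == int(Tissue.MUCOSA)) | (lab == int(Tissue.CYST))) & cavity_mask).sum())
    n_ostium = int(ostium_mask.sum())
    n_ostium_air = int((lab[ostium_mask] == int(Tissue.AIR)).sum()) if n_ostium else 0
    return GroundTruth(
        expected_x1=hu_map[int(Tissue.FLUID)] if n_fluid else None,
        expected_x2=100.0 * n_ostium_air / n_ostium if n_ostium else 100.0,
        expected_x3=100.0 * n_soft / n_cavity,
        expected_x4=100.0 * n_fluid / n_cavity,
        class_counts={t.name: c for t, c in counts.items()},
        ostium_mask=ostium_mask,
        cavity_voxels=n_cavity,
    )


def add_impulse_noise(volume: Volume, probability: float, seed: int) -> Volume:
    """Salt-and-pepper corruption: each voxel is independently replaced
    by the volume's minimum or maximum intensity with the stated
    probability (half salt, half pepper).  Reproducible per seed."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {probability}")
    if probability == 0.0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    data = volume.data.copy()
    lo, hi = data.min(), data.max()
    hit = rng.random(data.shape) < probability
    salt = rng.random(data.shape) < 0.5
    data[hit & salt] = hi
    data[hit & ~salt] = lo
    return Volume(data, volume.spacing_mm, volume.unit, volume.window)


# ---------------------------------------------------------------------------
# channel geometry


def make_channel_geometry(profile: str | Sequence[tuple[float, float, float, float]],
                          **kwargs) -> ChannelModel | tuple[ChannelModel, ChannelModel]:
    """Build channel models from a named preset or an explicit series.

    Presets:

    - ``"circular_tube"`` (kwargs ``diameter_m``, ``length_m``) — one
      circular section with dh = d;
    - ``"two_identical_passages"`` (same kwargs, default 8 mm × 0.1 m) —
      a pair of equal tubes, the symmetric parallel-passage case.

    An explicit series is a sequence of ``(S_m2, P_m, dl_m, xi)`` rows.
    """
    if isinstance(profile, str):
        if profile == "circular_tube":
            return circular_tube(kwargs.pop("diameter_m"), kwargs.pop("length_m"), **kwargs)
        if profile == "two_identical_passages":
            d = kwargs.pop("diameter_m", 0.008)
            L = kwargs.pop("length_m", 0.1)
            return (circular_tube(d, L, **kwargs), circular_tube(d, L, **kwargs))
        raise ValueError(f"unknown channel preset {profile!r}")
    sections = [ChannelSection.from_area_perimeter(S, P, dl, xi)
                for (S, P, dl, xi) in profile]
    return ChannelModel(tuple(sections), **kwargs)


# ---------------------------------------------------------------------------
# presets reproducing the four schematic sinus configurations plus lesions


PRESETS: dict[str, PhantomConfig] = {
    # empty, clean cavity (conditional norm)
    "conditional_norm": PhantomConfig(),
    # 60% polypous fill, the chronic picture
    "polyposis_60": PhantomConfig(polyp_fraction=0.60),
    # 40% serous fluid, the acute serous picture
    "serous_40": PhantomConfig(fluid_fraction=0.40),
    # 40% purulent fluid (fluid Hu overridden to the purulent density)
    "purulent_40": PhantomConfig(
        fluid_fraction=0.40,
        hu_values={**DEFAULT_HU, Tissue.FLUID: 37.0},
    ),
    # 30% polypous + 20% fluid, the exacerbated chronic picture
    "mixed_30_20": PhantomConfig(fluid_fraction=0.20, polyp_fraction=0.30),
    # lesion archetypes for densitographic signatures
    "cyst": PhantomConfig(cyst=SphereSpec(offset_mm=(0.0, 6.0, 0.0), radius_mm=4.0)),
    "perforation": PhantomConfig(
        fluid_fraction=0.40, perforation=PerforationSpec(half_angle_deg=30.0)),
    "foreign_body": PhantomConfig(
        fluid_fraction=0.40,
        foreign_body=SphereSpec(offset_mm=(0.0, 6.0, 0.0), radius_mm=2.5, hu=2000.0)),
}

#: The four schematic fill configurations, in presentation order.
SCHEMATIC_PRESETS = ("conditional_norm", "polyposis_60", "serous_40", "mixed_30_20")


def preset_config(name: str, **overrides) -> PhantomConfig:
    """Named phantom preset, optionally with field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg
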