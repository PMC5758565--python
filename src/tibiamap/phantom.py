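"""Synthetic ovine tibial-plateau phantoms with analytic ground truth.

The phantom emulates the bony features that define the five reference
points on coronal micro-CT stacks of the ovine proximal tibia:

* two condylar plateau footprints (irregular ovals with a posterior
  slope), the medial one beginning most posteriorly (RP1) and the lateral
  one ending anteriorly at the groove of the extensor digitorum longus
  tendon (RP5);
* medial and lateral tibial spines modelled as Gaussian ridges, the
  lateral one arising more posteriorly; the medial spine's emergence
  above the detection threshold defines RP2;
* a saddle between the spines whose trough depth shrinks until the two
  spines fuse (RP3);
* the area intercondylaris anterior (AIA), a central prominence that
  grows above the spines (RP4);
* a tibial tuberosity continuing anterior to RP5, so RP5 is *not* the
  last bony slice;
* an articular cartilage layer and a subchondral bone plate whose
  thickness rises linearly from the peripheral (submeniscal) margin to
  the central (spine-side) margin of each plateau.

The surface is built analytically as a height field and then voxelized,
so every feature has exact ground truth: reference-point slices, spine
ridgelines, halving lines, subregion map, thickness fields and pathology
masks.  Pathology (marginal osteophytes, cartilage lesions) is placed via
the ground-truth subregion map, keeping the downstream detectors
independent of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import BONE, CARTILAGE, VolumeStack
from .geometry import SUBREGION_CODES, SUBREGIONS

__all__ = [
    "PlateauShapeParams",
    "OsteochondralFieldParams",
    "OsteophyteSpec",
    "LesionSpec",
    "PathologyParams",
    "GroundTruth",
    "generate_phantom",
    "add_pathology",
]


@dataclass
class PlateauShapeParams:
    """Geometry of the canonical (mean-shape) phantom.

    Lengths in mm.  ``rp_rel`` are the relative posterior-anterior
    positions of RP1..RP5 in percent of the RP1-RP5 span; the defaults are
    the mean positions reported for healthy adult sheep, together with the
    mean plateau length of 32.7 mm.  Spine and AIA heights are free
    parameters of the model (no quantitative heights are published); the
    defaults are chosen so the slice criteria cross sharply at one-voxel
    scale.
    """

    length_mm: float = 32.7
    rp_rel: tuple[float, ...] = (0.0, 29.9, 40.8, 74.2, 100.0)
    width_mm: float = 30.0
    height_mm: float = 16.5
    voxel_mm: float = 0.15
    blank_posterior_slices: int = 5

    # condyle footprints
    condyle_halfwidth_mm: float = 5.5
    medial_centerline_mm: tuple[float, float, float] = (11.5, 8.0, 9.5)
    lateral_centerline_mm: tuple[float, float, float] = (20.5, 22.5, 19.0)
    lateral_posterior_offset_mm: float = 1.0
    lateral_tip_overshoot_mm: float = 3.0

    # base surface
    base_height_mm: float = 3.0
    posterior_slope_deg: float = 6.0
    shell_mm: float = 1.5  # bone shell under non-articular surface

    # spines / saddle / AIA
    spine_x_mm: tuple[float, float] = (13.2, 16.8)  # medial, lateral
    spine_height_mm: tuple[float, float] = (4.0, 4.0)
    spine_sigma_mm: float = 0.8
    lateral_spine_origin_mm: float = 5.0  # posterior to the medial spine origin
    emergence_mm: float = 0.5  # prominence at which a spine counts as emerged
    saddle_depth_mm: float = 1.2  # inter-spine trough before fusion
    fusion_trough_mm: float = 0.3  # trough depth at which the spines fuse
    residual_trough_mm: float = 0.25
    aia_x_mm: float = 15.0
    aia_height_mm: float = 5.5
    aia_sigma_mm: float = 0.8
    aia_cross_slope_mm_per_mm: float = 8.0

    # anterior structures
    edl_groove_depth_mm: float = 0.8
    edl_groove_width_mm: float = 3.0
    edl_groove_x_mm: float = 20.5
    tuberosity_offset_mm: float = 3.0  # center anterior to RP5
    tuberosity_semi_mm: tuple[float, float] = (5.0, 3.0)  # (z, x)
    tuberosity_x_mm: float = 13.0
    tuberosity_height_mm: float = 5.0

    surface_noise_mm: float = 0.0

    def __post_init__(self):
        rel = np.asarray(self.rp_rel, float)
        if len(rel) != 5 or rel[0] != 0.0 or rel[-1] != 100.0 or np.any(np.diff(rel) <= 0):
            raise ValueError("rp_rel must be 5 strictly increasing values from 0 to 100")
        if self.length_mm <= 0 or self.voxel_mm <= 0:
            raise ValueError("length_mm and voxel_mm must be positive")
        min_feature = min(2 * self.spine_sigma_mm, 2 * self.aia_sigma_mm, self.edl_groove_width_mm)
        if self.voxel_mm > min_feature / 3.0:
            raise ValueError(
                f"voxel size {self.voxel_mm} mm too coarse to resolve the saddle/AIA "
                f"features (must be <= {min_feature / 3.0:.3f} mm)"
            )
        if self.lateral_spine_origin_mm >= self.rp_rel[1] / 100.0 * self.length_mm:
            raise ValueError("lateral spine origin must lie posterior to the medial spine origin (RP2)")


@dataclass
class OsteochondralFieldParams:
    """Cartilage and subchondral-bone-plate thickness fields (mm).

    Both tissues thin from the central (spine-side) margin to the
    peripheral (submeniscal) margin of each plateau; the default range is
    0.2-2.2 mm with a linear profile across the footprint.
    """

    cartilage_central_mm: float = 2.2
    cartilage_peripheral_mm: float = 0.2
    plate_central_mm: float = 2.2
    plate_peripheral_mm: float = 0.2

    def __post_init__(self):
        for lo, hi in (
            (self.cartilage_peripheral_mm, self.cartilage_central_mm),
            (self.plate_peripheral_mm, self.plate_central_mm),
        ):
            if not 0 <= lo < hi:
                raise ValueError("thickness fields need 0 <= peripheral < central")


@dataclass
class OsteophyteSpec:
    """A marginal bony outgrowth at the peripheral edge of named subregions."""

    subregions: tuple[str, ...] = ("medial_intermediate_peripheral", "medial_anterior_peripheral")
    protrusion_mm: float = 2.0
    extent_mm: float = 6.0


@dataclass
class LesionSpec:
    """Cartilage loss covering a fraction of one subregion's area."""

    subregion: str = "medial_intermediate_central"
    area_fraction: float = 0.6
    thinning: float = 1.0  # 1.0 = full-thickness loss

    def __post_init__(self):
        if not 0 <= self.area_fraction <= 1 or not 0 < self.thinning <= 1:
            raise ValueError("area_fraction in [0,1] and thinning in (0,1] required")


@dataclass
class PathologyParams:
    """The default pathology emulates the reported post-OA pattern: one
    large osteophyte spanning the medial intermediate+anterior peripheral
    margins, and cartilage lesions dominated by the medial intermediate
    central subregion (50-75% of its area)."""

    osteophytes: list = field(default_factory=lambda: [OsteophyteSpec()])
    lesions: list = field(
        default_factory=lambda: [
            LesionSpec("medial_intermediate_central", 0.6),
            LesionSpec("medial_anterior_central", 0.375),
            LesionSpec("lateral_intermediate_central", 0.375),
        ]
    )
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the generator knows about the phantom it built."""

    rp_image_numbers: np.ndarray  # (5,) 1-based
    rp_rel: np.ndarray  # (5,) percent, voxel-quantized
    rp_coords_mm: np.ndarray  # (5, 3) (z, y, x) of the defining feature
    length_mm: float
    spacing: tuple[float, float, float]
    footprints: dict  # {"medial","lateral"}: (nz, nx) bool
    ridgelines: dict  # {"medial","lateral"}: (nz,) x mm, NaN where absent
    rl6: tuple  # ((z_mm, x_mm), (z_mm, x_mm))
    rl7: tuple
    subregion_map: np.ndarray  # (nz, nx) int8, codes as geometry.SUBREGIONS
    cartilage_mm: np.ndarray  # (nz, nx) analytic field, NaN off-footprint
    plate_mm: np.ndarray
    surface_mm: np.ndarray  # bone surface height field (nz, nx), NaN off-support
    osteophyte_mask: np.ndarray | None = None  # 3-D bool
    lesion_mask: np.ndarray | None = None  # (nz, nx) bool columns
    shape_params: PlateauShapeParams | None = None
    field_params: OsteochondralFieldParams | None = None

    @property
    def rp_indices(self) -> np.ndarray:
        return self.rp_image_numbers - 1


def _quad_through(z0, z1, z2, v0, v1, v2):
    """Quadratic Lagrange interpolant through three (z, value) points."""

    def f(z):
        z = np.asarray(z, float)
        return (
            v0 * (z - z1) * (z - z2) / ((z0 - z1) * (z0 - z2))
            + v1 * (z - z0) * (z - z2) / ((z1 - z0) * (z1 - z2))
            + v2 * (z - z0) * (z - z1) / ((z2 - z0) * (z2 - z1))
        )

    return f


def _smoothstep(t):
    return 0.5 - 0.5 * np.cos(np.pi * np.clip(t, 0.0, 1.0))


def _fill_between(support: np.ndarray) -> np.ndarray:
    """Per-slice fill between the left- and right-most support columns."""
    out = support.copy()
    for i in range(support.shape[0]):
        idx = np.flatnonzero(support[i])
        if idx.size:
            out[i, idx[0] : idx[-1] + 1] = True
    return out


def generate_phantom(
    shape: PlateauShapeParams | None = None,
    fields: OsteochondralFieldParams | None = None,
    seed: int = 0,
) -> tuple[VolumeStack, GroundTruth]:
    """Build a canonical-frame label phantom and its ground truth.

    Deterministic given ``seed`` (randomness only enters through the
    optional surface noise).
    """
    shp = shape or PlateauShapeParams()
    fld = fields or OsteochondralFieldParams()
    rng = np.random.default_rng(seed)

    v = shp.voxel_mm
    dz = dy = dx = v
    L = shp.length_mm
    span = int(round(L / v))
    z1 = shp.blank_posterior_slices  # 0-based index of RP1
    rel = np.asarray(shp.rp_rel, float)
    rp_off = np.round(span * rel / 100.0).astype(int)  # slice offsets from RP1
    zeta_rp = rp_off * v  # feature positions in mm anterior of RP1
    z2m, z3m, z4m, z5m = zeta_rp[1], zeta_rp[2], zeta_rp[3], zeta_rp[4]

    tub_zc = L + shp.tuberosity_offset_mm
    tub_az, tub_bx = shp.tuberosity_semi_mm
    nz = z1 + span + int(np.ceil((shp.tuberosity_offset_mm + tub_az) / v)) + 3
    nx = int(round(shp.width_mm / v))
    ny = int(round(shp.height_mm / v))

    zeta = (np.arange(nz) - z1) * v  # mm anterior of the RP1 plane
    x = np.arange(nx) * v

    # ---- footprints -----------------------------------------------------
    b = shp.condyle_halfwidth_mm
    m0, m1, m2 = shp.medial_centerline_mm
    cl_med = _quad_through(0.0, L / 2, L, m0, m1, m2)(zeta)
    s_med = np.clip((zeta - L / 2) / (L / 2), -1.0, 1.0)
    hw_med = np.where((zeta >= -1e-9) & (zeta <= L + 1e-9), b * np.sqrt(np.clip(1 - s_med**2, 0, 1)), -1.0)
    hw_med = np.where(hw_med >= 0, np.maximum(hw_med, 1.5 * dx), -1.0)

    lat0 = shp.lateral_posterior_offset_mm
    lat_virtual_tip = L + shp.lateral_tip_overshoot_mm
    lat_c = (lat0 + lat_virtual_tip) / 2
    lat_a = (lat_virtual_tip - lat0) / 2
    l0, l1, l2 = shp.lateral_centerline_mm
    cl_lat = _quad_through(lat0, lat_c, L, l0, l1, l2)(zeta)
    s_lat = np.clip((zeta - lat_c) / lat_a, -1.0, 1.0)
    hw_lat = np.where(
        (zeta >= lat0 - 1e-9) & (zeta <= L + 1e-9), b * np.sqrt(np.clip(1 - s_lat**2, 0, 1)), -1.0
    )
    hw_lat = np.where(hw_lat >= 0, np.maximum(hw_lat, 1.5 * dx), -1.0)

    x_ms, x_ls = shp.spine_x_mm
    med_fp = (
        (np.abs(x[None, :] - cl_med[:, None]) <= hw_med[:, None])
        & (hw_med[:, None] >= 0)
        & (x[None, :] <= x_ms)
    )
    lat_fp = (
        (np.abs(x[None, :] - cl_lat[:, None]) <= hw_lat[:, None])
        & (hw_lat[:, None] >= 0)
        & (x[None, :] >= x_ls)
    )

    # ---- tuberosity -----------------------------------------------------
    q2 = ((zeta[:, None] - tub_zc) / tub_az) ** 2 + ((x[None, :] - shp.tuberosity_x_mm) / tub_bx) ** 2
    tub_fp = q2 <= 1.0
    tub_dome = shp.tuberosity_height_mm * np.clip(1.0 - q2, 0.0, None)

    support = _fill_between(med_fp | lat_fp | tub_fp)

    # ---- spine / saddle / AIA envelopes ---------------------------------
    Am_max, Al_max = shp.spine_height_mm
    emergence = shp.emergence_mm
    # medial spine: crosses the emergence threshold exactly at RP2; the
    # ramp is steep so surface quantization (half a voxel) cannot move the
    # crossing slice
    a_med = np.interp(
        zeta,
        [z2m - 0.25, z2m, z3m - 1.5, z4m + 1.0, z4m + 4.0],
        [0.0, 2.2 * emergence, Am_max, Am_max, 0.0],
        left=0.0,
        right=0.0,
    )
    a_lat = np.interp(
        zeta,
        [shp.lateral_spine_origin_mm, shp.lateral_spine_origin_mm + 3.0, z4m + 1.0, z4m + 4.0],
        [0.0, Al_max, Al_max, 0.0],
        left=0.0,
        right=0.0,
    )
    sig2 = 2 * shp.spine_sigma_mm**2
    g_med = a_med[:, None] * np.exp(-((x[None, :] - x_ms) ** 2) / sig2)
    g_lat = a_lat[:, None] * np.exp(-((x[None, :] - x_ls) ** 2) / sig2)

    # saddle bridge: trough depth crosses the fusion threshold exactly at RP3
    trough = np.interp(
        zeta,
        [z3m - 1.5, z3m - 0.2, z3m, z3m + 0.5],
        [shp.saddle_depth_mm, 2.2 * shp.fusion_trough_mm, 0.65 * shp.fusion_trough_mm, shp.residual_trough_mm],
        left=shp.saddle_depth_mm,
        right=shp.residual_trough_mm,
    )
    bridge_level = np.clip(np.minimum(a_med, a_lat) - trough, 0.0, None)
    wx = _smoothstep((x - (x_ms - 0.3)) / 0.3) * _smoothstep(((x_ls + 0.3) - x) / 0.3)
    bridge = bridge_level[:, None] * wx[None, :]

    # AIA: crosses the spine height exactly at RP4
    slope = shp.aia_cross_slope_mm_per_mm
    cross = 1.25 * max(Am_max, Al_max)
    a_aia = np.interp(
        zeta,
        [z4m - cross / slope, z4m, z4m + (shp.aia_height_mm - cross) / slope, z4m + 5.0, z4m + 7.0],
        [0.0, cross, shp.aia_height_mm, shp.aia_height_mm, 0.0],
        left=0.0,
        right=0.0,
    )
    g_aia = a_aia[:, None] * np.exp(-((x[None, :] - shp.aia_x_mm) ** 2) / (2 * shp.aia_sigma_mm**2))

    # ---- EDL groove ------------------------------------------------------
    gw = shp.edl_groove_width_mm / 2
    groove = (
        shp.edl_groove_depth_mm
        * _smoothstep((zeta[:, None] - (L - 1.5)) / 1.5)
        * _smoothstep(1.0 - np.abs(x[None, :] - shp.edl_groove_x_mm) / gw)
    )

    # ---- surface height field -------------------------------------------
    base = shp.base_height_mm + np.tan(np.deg2rad(shp.posterior_slope_deg)) * np.clip(zeta, 0, None)
    bumps = np.maximum.reduce([g_med, g_lat, bridge, g_aia, tub_dome])
    H = base[:, None] + bumps - groove
    if shp.surface_noise_mm > 0:
        H = H + rng.normal(0.0, shp.surface_noise_mm, H.shape)
    H = np.where(support, H, np.nan)

    # ---- thickness fields -----------------------------------------------
    cart = np.full((nz, nx), np.nan)
    plate = np.full((nz, nx), np.nan)

    def across(u, lo, hi):
        return lo + (hi - lo) * u

    # medial: central margin at the spine side (high x)
    outer_m = np.clip(cl_med - hw_med, 0.0, None)
    central_m = np.minimum(x_ms, cl_med + hw_med)
    width_m = np.maximum(central_m - outer_m, 1e-9)
    u_m = np.clip((x[None, :] - outer_m[:, None]) / width_m[:, None], 0.0, 1.0)
    u_m = np.where(width_m[:, None] < dx, 0.5, u_m)
    cart = np.where(med_fp, across(u_m, fld.cartilage_peripheral_mm, fld.cartilage_central_mm), cart)
    plate = np.where(med_fp, across(u_m, fld.plate_peripheral_mm, fld.plate_central_mm), plate)

    # lateral: central margin at the spine side (low x)
    outer_l = cl_lat + hw_lat
    central_l = np.maximum(x_ls, cl_lat - hw_lat)
    width_l = np.maximum(outer_l - central_l, 1e-9)
    u_l = np.clip((outer_l[:, None] - x[None, :]) / width_l[:, None], 0.0, 1.0)
    u_l = np.where(width_l[:, None] < dx, 0.5, u_l)
    cart = np.where(lat_fp, across(u_l, fld.cartilage_peripheral_mm, fld.cartilage_central_mm), cart)
    plate = np.where(lat_fp, across(u_l, fld.plate_peripheral_mm, fld.plate_central_mm), plate)

    footprint = med_fp | lat_fp
    plate_render = np.where(footprint, plate, shp.shell_mm)

    # ---- voxelization ----------------------------------------------------
    y_base_row = ny - 3
    surf_row = np.where(support, np.round(y_base_row - H / dy), ny)  # (nz, nx)
    cart_vox = np.where(footprint, np.maximum(np.round(cart / dy), 1), 0)
    plate_vox = np.where(support, np.maximum(np.round(plate_render / dy), 1), 0)

    rows = np.arange(ny)[None, :, None]
    ys = surf_row[:, None, :]
    bone3 = support[:, None, :] & (rows >= ys) & (rows < ys + plate_vox[:, None, :])
    cart3 = footprint[:, None, :] & (rows >= ys - cart_vox[:, None, :]) & (rows < ys)
    vox = np.zeros((nz, ny, nx), dtype=np.uint8)
    vox[bone3] = BONE
    vox[cart3] = CARTILAGE
    vol = VolumeStack(vox, (dz, dy, dx), side="canonical", kind="label")

    # ---- ground truth ----------------------------------------------------
    ridge_med = np.where(a_med > 0, x_ms, np.nan)
    ridge_lat = np.where(a_lat > 0, x_ls, np.nan)

    # analytic halving lines from the true geometry
    def edge_lat_at(zm):
        s = (zm - lat_c) / lat_a
        return float(_quad_through(lat0, lat_c, L, l0, l1, l2)(zm) + b * np.sqrt(max(0.0, 1 - s**2)))

    def edge_med_at(zm):
        s = (zm - L / 2) / (L / 2)
        return float(_quad_through(0.0, L / 2, L, m0, m1, m2)(zm) - b * np.sqrt(max(0.0, 1 - s**2)))

    z_abs = lambda off: (z1 + off) * dz  # noqa: E731  absolute z in mm
    rl6 = (
        (z_abs(rp_off[2]), (x_ls + edge_lat_at(z3m)) / 2),
        (z_abs(rp_off[3]), (x_ls + edge_lat_at(z4m)) / 2),
    )
    rl7 = (
        (z_abs(rp_off[2]), (x_ms + edge_med_at(z3m)) / 2),
        (z_abs(rp_off[4]), m2),
    )

    submap = _ground_truth_submap(nz, nx, dz, dx, z1, rp_off, med_fp, lat_fp, rl6, rl7)

    base_at = lambda zm: shp.base_height_mm + np.tan(np.deg2rad(shp.posterior_slope_deg)) * zm  # noqa: E731
    y_of = lambda h: y_base_row * dy - h  # noqa: E731
    # RP5: centroid of the lateral footprint columns in the lateral outer region
    i5 = z1 + rp_off[4]
    lat_cols5 = np.flatnonzero(lat_fp[i5] & (x >= 0.6 * shp.width_mm))
    x5 = float(x[lat_cols5].mean()) if lat_cols5.size else float(cl_lat[i5])
    tip_plate = across(0.5, fld.plate_peripheral_mm, fld.plate_central_mm)
    rp_coords = np.array(
        [
            [z_abs(rp_off[0]), y_of(base_at(0.0)) + tip_plate / 2, m0],
            [z_abs(rp_off[1]), y_of(base_at(z2m) + 2.2 * emergence), x_ms],
            [z_abs(rp_off[2]), y_of(base_at(z3m) + Am_max - 0.65 * shp.fusion_trough_mm), shp.aia_x_mm],
            [z_abs(rp_off[3]), y_of(base_at(z4m) + Am_max + shp.fusion_trough_mm), shp.aia_x_mm],
            [z_abs(rp_off[4]), y_of(base_at(z5m)) + tip_plate / 2, x5],
        ]
    )

    gt = GroundTruth(
        rp_image_numbers=z1 + 1 + rp_off,
        rp_rel=100.0 * rp_off / rp_off[-1],
        rp_coords_mm=rp_coords,
        length_mm=rp_off[-1] * dz,
        spacing=(dz, dy, dx),
        footprints={"medial": med_fp, "lateral": lat_fp},
        ridgelines={"medial": ridge_med, "lateral": ridge_lat},
        rl6=rl6,
        rl7=rl7,
        subregion_map=submap,
        cartilage_mm=cart,
        plate_mm=plate,
        surface_mm=H,
        shape_params=shp,
        field_params=fld,
    )
    return vol, gt


def _ground_truth_submap(nz, nx, dz, dx, z1, rp_off, med_fp, lat_fp, rl6, rl7) -> np.ndarray:
    """Subregion labels from the generator's own geometry (test oracle)."""
    z_idx = np.arange(nz)
    x_mm = np.arange(nx) * dx
    i1, i3, i4, i5 = z1 + rp_off[0], z1 + rp_off[2], z1 + rp_off[3], z1 + rp_off[4]
    band = np.zeros(nz, dtype=np.int8)
    band[(z_idx >= i1) & (z_idx < i3)] = 1
    band[(z_idx >= i3) & (z_idx < i4)] = 2
    band[(z_idx >= i4) & (z_idx <= i5)] = 3

    def line_x(anchors):
        (za, xa), (zb, xb) = anchors
        t = (z_idx * dz - za) / (zb - za)
        return xa + t * (xb - xa)

    rl6x = line_x(rl6)[:, None]
    rl7x = line_x(rl7)[:, None]
    labels = np.zeros((nz, nx), dtype=np.int8)
    in_band = band[:, None] > 0
    base_m = np.broadcast_to((band[:, None] - 1) * 2, (nz, nx))
    cen_m = np.broadcast_to(x_mm[None, :] >= rl7x, (nz, nx))
    labels[med_fp & in_band & cen_m] = (1 + base_m)[med_fp & in_band & cen_m]
    labels[med_fp & in_band & ~cen_m] = (2 + base_m)[med_fp & in_band & ~cen_m]
    base_l = np.broadcast_to(6 + (band[:, None] - 1) * 2, (nz, nx))
    cen_l = np.broadcast_to(x_mm[None, :] <= rl6x, (nz, nx))
    labels[lat_fp & in_band & cen_l] = (1 + base_l)[lat_fp & in_band & cen_l]
    labels[lat_fp & in_band & ~cen_l] = (2 + base_l)[lat_fp & in_band & ~cen_l]
    return labels


# ---------------------------------------------------------------------------
# pathology
# ---------------------------------------------------------------------------

def add_pathology(
    vol: VolumeStack, gt: GroundTruth, path: PathologyParams | None = None
) -> tuple[VolumeStack, GroundTruth]:
    """Add marginal osteophytes and cartilage lesions to a control phantom.

    Placement uses the ground-truth subregion map, not any detected one.
    Returns a new volume and ground truth; the inputs are not modified.
    """
    path = path or PathologyParams()
    shp = gt.shape_params
    dz, dy, dx = gt.spacing
    vox = vol.voxels.copy()
    nz, ny, nx = vox.shape
    x = np.arange(nx) * dx
    y_base_row = ny - 3

    osteo_mask = np.zeros_like(vox, dtype=bool)
    for spec in path.osteophytes:
        codes = [SUBREGION_CODES[s] for s in spec.subregions]
        sides = {SUBREGIONS[c][0].split("_")[0] for c in codes}
        if len(sides) != 1:
            raise ValueError("an osteophyte spec must target subregions of one plateau")
        side = sides.pop()
        fp = gt.footprints["medial" if side == "medial" else "lateral"]
        # z range: union of the targeted subregions, centered on the shared
        # boundary when two adjacent bands are given
        zsel = np.flatnonzero(np.isin(gt.subregion_map, codes).any(axis=1))
        if zsel.size == 0:
            raise ValueError(f"target subregions {spec.subregions} are empty")
        zc = 0.5 * (zsel[0] + zsel[-1])
        if len(codes) == 2:
            za = np.flatnonzero((gt.subregion_map == codes[0]).any(axis=1))
            zb = np.flatnonzero((gt.subregion_map == codes[1]).any(axis=1))
            zc = 0.5 * (max(za[0], zb[0]) + min(za[-1], zb[-1]))
        half = spec.extent_mm / 2 / dz
        z_lo, z_hi = int(np.ceil(zc - half)), int(np.floor(zc + half))
        shell_vox = max(1, int(round(shp.shell_mm / dy)))
        for i in range(max(z_lo, 0), min(z_hi, nz - 1) + 1):
            cols = np.flatnonzero(fp[i])
            if cols.size == 0:
                continue
            edge = cols[0] if side == "medial" else cols[-1]
            prot = spec.protrusion_mm * np.sin(np.pi * (i - z_lo) / max(z_hi - z_lo, 1))
            n_new = int(round(prot / dx))
            if n_new == 0:
                continue
            new_cols = (
                np.arange(edge - n_new, edge) if side == "medial" else np.arange(edge + 1, edge + 1 + n_new)
            )
            new_cols = new_cols[(new_cols >= 0) & (new_cols < nx)]
            h_edge = gt.surface_mm[i, edge]
            for c in new_cols:
                droop = 0.3 * abs(c - edge) * dx
                r0 = int(round(y_base_row - (h_edge - droop) / dy))
                r1 = min(r0 + shell_vox + 2, ny)
                sl = vox[i, r0:r1, c]
                newly = sl == 0
                vox[i, r0:r1, c][newly] = BONE
                osteo_mask[i, r0:r1, c] = newly

    lesion_cols = np.zeros((nz, nx), dtype=bool)
    cart_field = gt.cartilage_mm.copy()
    for spec in path.lesions:
        code = SUBREGION_CODES[spec.subregion]
        cols = np.argwhere(gt.subregion_map == code)
        n_total = len(cols)
        if n_total == 0:
            raise ValueError(f"subregion {spec.subregion} has no columns")
        n_sel = int(round(spec.area_fraction * n_total))
        if spec.area_fraction > 0 and n_sel == 0:
            raise ValueError(
                f"requested fraction {spec.area_fraction} unreachable at this resolution; "
                f"smallest nonzero fraction is {1.0 / n_total:.4f}"
            )
        centroid = cols.mean(axis=0)
        order = np.argsort(((cols - centroid) ** 2).sum(axis=1), kind="stable")
        chosen = cols[order[:n_sel]]
        for i, c in chosen:
            col = vox[:, :, :][i, :, c]
            cart_rows = np.flatnonzero(col == CARTILAGE)
            if cart_rows.size == 0:
                continue
            keep = int(round((1 - spec.thinning) * cart_rows.size))
            # cartilage erodes from the articular surface (top of the run)
            remove = cart_rows[: cart_rows.size - keep] if keep > 0 else cart_rows
            vox[i, remove, c] = 0
            lesion_cols[i, c] = True
            cart_field[i, c] *= 1 - spec.thinning

    new_vol = VolumeStack(vox, vol.spacing, side=vol.side, kind="label")
    new_gt = GroundTruth(
        rp_image_numbers=gt.rp_image_numbers.copy(),
        rp_rel=gt.rp_rel.copy(),
        rp_coords_mm=gt.rp_coords_mm.copy(),
        length_mm=gt.length_mm,
        spacing=gt.spacing,
        footprints={k: v.copy() for k, v in gt.footprints.items()},
        ridgelines={k: v.copy() for k, v in gt.ridgelines.items()},
        rl6=gt.rl6,
        rl7=gt.rl7,
        subregion_map=gt.subregion_map.copy(),
        cartilage_mm=cart_field,
        plate_mm=gt.plate_mm.copy(),
        surface_mm=gt.surface_mm.copy(),
        osteophyte_mask=osteo_mask,
        lesion_mask=lesion_cols,
        shape_params=gt.shape_params,
        field_params=gt.field_params,
    )
    return new_vol, new_gt
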