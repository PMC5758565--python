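"""Osteochondral thickness mapping, measurement-point sampling,
osteophyte detection and OA-lesion area mapping.

Thickness is measured along the image column (y) direction of the
coronal sections, a deliberate simplification of surface-normal
thickness that matches per-slice measurement practice: per surface
column, the cartilage thickness is the contiguous cartilage run at the
proximal surface, and the subchondral bone plate thickness is the
contiguous bone run immediately beneath it (or beneath the bone surface
where cartilage is absent), both in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import BONE, CARTILAGE, VolumeStack
from .geometry import SUBREGIONS, SubregionMap

__all__ = [
    "ThicknessMap",
    "OsteophyteRecord",
    "LesionReport",
    "thickness_maps",
    "sample_thickness_points",
    "detect_osteophytes",
    "lesion_fractions",
    "SAMPLING_PRESETS",
]

#: per-subregion measurement-point totals over the 3 sampling slices.
#: "points96" spreads 8 points over each of the 12 subregions;
#: "points98" redistributes them 52 medial / 46 lateral.
SAMPLING_PRESETS: dict[str, dict[str, int]] = {
    "points96": {name: 8 for _, (name, _) in SUBREGIONS.items()},
    "points98": {
        "medial_posterior_central": 9,
        "medial_intermediate_central": 9,
        "medial_anterior_central": 9,
        "medial_posterior_peripheral": 8,
        "medial_intermediate_peripheral": 8,
        "medial_anterior_peripheral": 9,
        "lateral_posterior_central": 8,
        "lateral_intermediate_central": 8,
        "lateral_anterior_central": 8,
        "lateral_posterior_peripheral": 8,
        "lateral_intermediate_peripheral": 7,
        "lateral_anterior_peripheral": 7,
    },
}


@dataclass
class ThicknessMap:
    """Per-surface-column cartilage and bone-plate thickness in mm."""

    cartilage_mm: np.ndarray  # (n_slices, n_cols), NaN where invalid
    plate_mm: np.ndarray
    valid: np.ndarray  # bool: column contains bone
    spacing: tuple[float, float, float]

    def summarize(self, submap: SubregionMap) -> pd.DataFrame:
        """Per-subregion n / mean / min / max for both tissues."""
        rows = []
        for code in submap.present_codes():
            mask = submap.mask(code) & self.valid
            for tissue, arr in (("cartilage", self.cartilage_mm), ("plate", self.plate_mm)):
                vals = arr[mask]
                vals = vals[np.isfinite(vals)]
                rows.append(
                    {
                        "subregion": submap.legend[code][0],
                        "abbrev": submap.legend[code][1],
                        "tissue": tissue,
                        "n": len(vals),
                        "mean_mm": float(np.mean(vals)) if len(vals) else np.nan,
                        "min_mm": float(np.min(vals)) if len(vals) else np.nan,
                        "max_mm": float(np.max(vals)) if len(vals) else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def thickness_maps(vol: VolumeStack) -> ThicknessMap:
    """Column-wise cartilage and subchondral-bone-plate thickness.

    Cartilage thickness is NaN on bone columns without a cartilage cap;
    a volume without any cartilage voxels yields an all-invalid cartilage
    map with a warning.
    """
    if vol.kind != "label":
        raise ValueError("thickness mapping needs a label volume (bone=1, cartilage=2)")
    vox = vol.voxels
    nz, ny, nx = vox.shape
    dy = vol.dy
    cart = np.full((nz, nx), np.nan)
    plate = np.full((nz, nx), np.nan)
    valid = np.zeros((nz, nx), dtype=bool)
    if not (vox == CARTILAGE).any():
        warnings.warn("volume contains no cartilage voxels; cartilage map is all-invalid")

    pad = np.zeros((1, nx), dtype=vox.dtype)
    rows = np.arange(ny + 1)[:, None]
    for i in range(nz):
        sl = np.vstack([vox[i], pad])  # sentinel row so runs always terminate
        has = sl.any(axis=0)
        if not has.any():
            continue
        top = np.argmax(sl > 0, axis=0)
        # cartilage run from the surface down
        non_cart_below = (sl != CARTILAGE) & (rows >= top[None, :])
        cart_end = np.argmax(non_cart_below, axis=0)
        cart_len = np.where(sl[top, np.arange(nx)] == CARTILAGE, cart_end - top, 0)
        # plate = bone run immediately beneath
        p0 = top + cart_len
        non_bone_below = (sl != BONE) & (rows >= p0[None, :])
        plate_end = np.argmax(non_bone_below, axis=0)
        plate_len = np.where(sl[np.minimum(p0, ny), np.arange(nx)] == BONE, plate_end - p0, 0)

        bone_col = (sl == BONE).any(axis=0)
        valid[i] = bone_col
        cart[i, bone_col & (cart_len > 0)] = cart_len[bone_col & (cart_len > 0)] * dy
        plate[i, bone_col] = plate_len[bone_col] * dy
    return ThicknessMap(cart, plate, valid, vol.spacing)


def sample_thickness_points(
    tmap: ThicknessMap,
    submap: SubregionMap,
    k_slices: int = 3,
    points: str | dict[str, int] = "points96",
) -> pd.DataFrame:
    """Standardized measurement points: ``k_slices`` equidistant coronal
    slices per subregion, with the subregion's point budget spread evenly
    over them and, within each slice, over equally spaced valid columns.

    ``points`` is a preset name (:data:`SAMPLING_PRESETS`) or a mapping
    subregion name -> total points.
    """
    budget = SAMPLING_PRESETS[points] if isinstance(points, str) else dict(points)
    rows = []
    for code in submap.present_codes():
        name = submap.legend[code][0]
        total = int(budget.get(name, 0))
        if total <= 0:
            continue
        mask = submap.mask(code)
        z_present = np.flatnonzero(mask.any(axis=1))
        k = min(k_slices, len(z_present))
        if k < k_slices:
            warnings.warn(f"subregion {name} narrower than {k_slices} slices; using {k}")
        z_sel = np.unique(np.linspace(z_present[0], z_present[-1], k + 2)[1:-1].round().astype(int))
        # snap to slices where the subregion is present
        z_sel = np.array([z_present[np.argmin(np.abs(z_present - z))] for z in z_sel])
        per = np.full(len(z_sel), total // len(z_sel))
        per[: total % len(z_sel)] += 1
        for z, n_pts in zip(z_sel, per):
            cols = np.flatnonzero(mask[z] & tmap.valid[z])
            if cols.size == 0:
                continue
            picks = cols[np.unique(np.linspace(0, cols.size - 1, min(n_pts, cols.size)).round().astype(int))]
            for c in picks:
                rows.append(
                    {
                        "subregion": name,
                        "abbrev": submap.legend[code][1],
                        "slice_index": int(z) + 1,
                        "col": int(c),
                        "cartilage_mm": float(tmap.cartilage_mm[z, c]),
                        "plate_mm": float(tmap.plate_mm[z, c]),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class OsteophyteRecord:
    """One connected marginal bone outgrowth."""

    component_id: int
    volume_mm3: float
    n_voxels: int
    subregions: tuple[str, ...]
    centroid_zyx_mm: tuple[float, float, float]


def detect_osteophytes(
    oa_vol: VolumeStack,
    control: VolumeStack | np.ndarray,
    submap: SubregionMap,
    v_min_mm3: float = 1.0,
    max_assign_dist_mm: float = 5.0,
) -> tuple[list[OsteophyteRecord], np.ndarray]:
    """Marginal bone outside the control bone footprint, as components.

    ``control`` is either the registered control volume or a boolean
    (n_slices, n_cols) column footprint of its bone.  Components smaller
    than ``v_min_mm3`` are dropped.  Each osteophyte is mapped to the
    subregions of the nearest footprint columns within
    ``max_assign_dist_mm``.  Returns the records and the 3-D osteophyte
    mask.
    """
    if isinstance(control, VolumeStack):
        ref_support = (control.voxels > 0).any(axis=1)
    else:
        ref_support = np.asarray(control, bool)
    if ref_support.shape != (oa_vol.n_slices, oa_vol.shape[2]):
        raise ValueError("control footprint shape does not match the OA volume grid")
    dz, dy, dx = oa_vol.spacing
    outside_cols = ~ref_support
    bone3 = oa_vol.voxels == BONE
    cand = bone3 & outside_cols[:, None, :]
    lab, n = ndimage.label(cand, structure=np.ones((3, 3, 3), bool))
    vox_mm3 = dz * dy * dx

    # nearest labeled subregion column for assignment
    dist, (iz, ix) = ndimage.distance_transform_edt(
        submap.labels == 0, sampling=(dz, dx), return_indices=True
    )
    records: list[OsteophyteRecord] = []
    mask = np.zeros_like(cand)
    for comp in range(1, n + 1):
        comp_mask = lab == comp
        nvox = int(comp_mask.sum())
        if nvox * vox_mm3 < v_min_mm3:
            continue
        cols = np.argwhere(comp_mask.any(axis=1))  # (z, x) columns
        touched = set()
        for z, x in cols:
            if dist[z, x] <= max_assign_dist_mm:
                touched.add(int(submap.labels[iz[z, x], ix[z, x]]))
        touched.discard(0)
        cz, cy, cx = ndimage.center_of_mass(comp_mask)
        records.append(
            OsteophyteRecord(
                component_id=comp,
                volume_mm3=nvox * vox_mm3,
                n_voxels=nvox,
                subregions=tuple(sorted(SUBREGIONS[c][0] for c in touched)),
                centroid_zyx_mm=(cz * dz, cy * dy, cx * dx),
            )
        )
        mask |= comp_mask
    return records, mask


_CATEGORIES = ("0-25%", "25-50%", "50-75%", "75-100%")


def _categorize(fraction: float) -> str:
    """Half-open bins; a fraction of exactly 1.0 falls in the top bin."""
    pct = fraction * 100.0
    if pct < 25:
        return _CATEGORIES[0]
    if pct < 50:
        return _CATEGORIES[1]
    if pct < 75:
        return _CATEGORIES[2]
    return _CATEGORIES[3]


@dataclass
class LesionReport:
    """Per-subregion OA-lesion coverage."""

    fractions: dict[str, float]
    categories: dict[str, str]
    table: pd.DataFrame = field(repr=False, default=None)


def lesion_fractions(lesion_mask: np.ndarray, submap: SubregionMap) -> LesionReport:
    """Affected-area fraction and 4-bin category per subregion.

    ``lesion_mask`` is a boolean (n_slices, n_cols) column mask; columns
    outside both footprints are ignored with a warning.
    """
    lesion = np.asarray(lesion_mask, bool)
    if lesion.shape != submap.labels.shape:
        raise ValueError("lesion mask shape does not match the subregion map")
    outside = lesion & (submap.labels == 0)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} lesion columns outside the footprints were ignored")
    fractions, categories, rows = {}, {}, []
    for code in submap.present_codes():
        name = submap.legend[code][0]
        region = submap.mask(code)
        n_region = int(region.sum())
        frac = float((lesion & region).sum()) / n_region if n_region else 0.0
        fractions[name] = frac
        categories[name] = _categorize(frac)
        rows.append(
            {
                "subregion": name,
                "abbrev": submap.legend[code][1],
                "columns": n_region,
                "lesion_columns": int((lesion & region).sum()),
                "fraction": frac,
                "category": categories[name],
            }
        )
    return LesionReport(fractions, categories, pd.DataFrame(rows))
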