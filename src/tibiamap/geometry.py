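"""Reference lines RL1-RL11 and the 12-subregion parcellation.

The five coronal reference planes (RL1-RL5) pass through the reference
points RP1-RP5.  RL6/RL7 are straight axial-plane lines through halving
points between each tibial spine and the outer plateau edge; RL8/RL9 are
the peripheral footprint margins and RL10/RL11 the spine ridgelines.
Together they split each plateau into posterior/intermediate/anterior x
central/peripheral subregions (12 labels over both plateaus; RP2/RL2 is
not used for the regions).

Longitudinal bands use half-open intervals with the boundary slice
assigned anterior-ward: posterior = [RL1, RL3), intermediate = [RL3, RL4),
anterior = [RL4, RL5].  Points exactly on RL6/RL7 count as central.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import image_number_to_index

__all__ = [
    "SUBREGIONS",
    "SUBREGION_CODES",
    "ReferenceLines",
    "SubregionMap",
    "percent_slice",
    "build_reference_lines",
    "partition_subregions",
    "assign_point",
    "thirds_quarters_grid",
    "footprints_from_volume",
]

#: code -> (full name, abbreviation); codes 1-6 medial, 7-12 lateral.
SUBREGIONS: dict[int, tuple[str, str]] = {
    1: ("medial_posterior_central", "MPC"),
    2: ("medial_posterior_peripheral", "MPP"),
    3: ("medial_intermediate_central", "MIC"),
    4: ("medial_intermediate_peripheral", "MIP"),
    5: ("medial_anterior_central", "MAC"),
    6: ("medial_anterior_peripheral", "MAP"),
    7: ("lateral_posterior_central", "LPC"),
    8: ("lateral_posterior_peripheral", "LPP"),
    9: ("lateral_intermediate_central", "LIC"),
    10: ("lateral_intermediate_peripheral", "LIP"),
    11: ("lateral_anterior_central", "LAC"),
    12: ("lateral_anterior_peripheral", "LAP"),
}

SUBREGION_CODES: dict[str, int] = {name: code for code, (name, _) in SUBREGIONS.items()}
SUBREGION_CODES.update({abbr: code for code, (_, abbr) in SUBREGIONS.items()})


def percent_slice(n_rp1: int, n_rp5: int, p: float) -> int:
    """Image number at ``p`` percent of the RP1-RP5 span.

    ``N_p = N_RP1 + round((N_RP5 - N_RP1) * p / 100)`` with round-half-even
    rounding to an integer image number.
    """
    if n_rp5 <= n_rp1:
        raise ValueError(f"degenerate span: N_RP5 ({n_rp5}) must exceed N_RP1 ({n_rp1})")
    if not 0 <= p <= 100:
        raise ValueError(f"percentage must lie in [0, 100], got {p}")
    return int(n_rp1) + round((int(n_rp5) - int(n_rp1)) * p / 100)


def thirds_quarters_grid(rps, scheme: str = "thirds", include_bounds: bool = True) -> list[int]:
    """Image numbers at thirds (33%, 66%) or quarters (25/50/75%) of the span.

    RL1 and RL5 bound the grid and are included by default.
    """
    n1, n5 = int(rps.image_numbers[0]), int(rps.image_numbers[4])
    pcts = {"thirds": (33, 66), "quarters": (25, 50, 75)}[scheme]
    interior = [percent_slice(n1, n5, p) for p in pcts]
    return [n1, *interior, n5] if include_bounds else interior


@dataclass
class ReferenceLines:
    """RL1-RL11 for one stack.

    ``rp_indices`` are 0-based slice indices of RP1-RP5 (RL1-RL5 planes).
    ``rl6``/``rl7`` are ((z_mm, x_mm), (z_mm, x_mm)) anchor pairs of the
    halving lines, extended as straight lines over the full stack.
    ``rl8``/``rl9`` are the per-slice outer-edge x positions (mm) of the
    lateral/medial footprint, NaN where the footprint is absent;
    ``rl10``/``rl11`` the lateral/medial spine ridgelines, inter- and
    extrapolated over the whole RP1-RP5 span.
    """

    rp_indices: np.ndarray
    spacing: tuple[float, float, float]
    rl6: tuple[tuple[float, float], tuple[float, float]]
    rl7: tuple[tuple[float, float], tuple[float, float]]
    rl8: np.ndarray
    rl9: np.ndarray
    rl10: np.ndarray
    rl11: np.ndarray

    @property
    def image_numbers(self) -> np.ndarray:
        return self.rp_indices + 1

    def _x_at(self, anchors, z_mm):
        (za, xa), (zb, xb) = anchors
        if zb == za:
            return np.full_like(np.asarray(z_mm, dtype=float), (xa + xb) / 2.0)
        t = (np.asarray(z_mm, dtype=float) - za) / (zb - za)
        return xa + t * (xb - xa)

    def rl6_x_at(self, z_mm):
        """x (mm) of the lateral halving line at coronal position z (mm)."""
        return self._x_at(self.rl6, z_mm)

    def rl7_x_at(self, z_mm):
        """x (mm) of the medial halving line at coronal position z (mm)."""
        return self._x_at(self.rl7, z_mm)


@dataclass
class SubregionMap:
    """Per-surface-column subregion labels (0 = outside both plateaus)."""

    labels: np.ndarray  # (n_slices, n_cols) int8
    spacing: tuple[float, float, float]
    legend: dict[int, tuple[str, str]] = None

    def __post_init__(self):
        if self.legend is None:
            self.legend = dict(SUBREGIONS)

    def mask(self, region) -> np.ndarray:
        code = region if isinstance(region, int) else SUBREGION_CODES[region]
        return self.labels == code

    def present_codes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels) if c != 0)

    def area_mm2(self, region) -> float:
        return float(self.mask(region).sum()) * self.spacing[0] * self.spacing[2]


def _interp_ridgeline(xs: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Linear inter/extrapolation of a per-slice ridgeline over [lo, hi]."""
    out = np.full_like(xs, np.nan, dtype=float)
    idx = np.flatnonzero(np.isfinite(xs))
    if idx.size == 0:
        return out
    span = np.arange(lo, hi + 1)
    if idx.size == 1:
        out[lo : hi + 1] = xs[idx[0]]
        return out
    out[lo : hi + 1] = np.interp(span, idx, xs[idx])
    # linear extrapolation beyond the defined span
    k0 = (xs[idx[1]] - xs[idx[0]]) / (idx[1] - idx[0])
    k1 = (xs[idx[-1]] - xs[idx[-2]]) / (idx[-1] - idx[-2])
    before = span < idx[0]
    after = span > idx[-1]
    out[lo : hi + 1][before] = xs[idx[0]] + k0 * (span[before] - idx[0])
    out[lo : hi + 1][after] = xs[idx[-1]] + k1 * (span[after] - idx[-1])
    return out


def footprints_from_volume(vol, ridgelines: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Plateau footprints as cartilage-bearing surface columns.

    Articular cartilage covers only the two condylar surfaces, so a column
    belongs to a plateau footprint iff it contains cartilage.  The
    medial/lateral split follows the valley midway between the two spine
    ridgelines.
    """
    if vol.kind != "label":
        raise ValueError("footprints_from_volume needs a label volume")
    cart_cols = (vol.voxels == 2).any(axis=1)  # (nz, nx)
    nz, nx = cart_cols.shape
    x_mm = np.arange(nx) * vol.dx
    split = (np.asarray(ridgelines["medial"], dtype=float) + np.asarray(ridgelines["lateral"], dtype=float)) / 2.0
    split = np.where(np.isfinite(split), split, np.nanmean(split))
    medial = cart_cols & (x_mm[None, :] < split[:, None])
    lateral = cart_cols & ~medial
    return {"medial": medial, "lateral": lateral}


def build_reference_lines(
    rps,
    footprints: dict[str, np.ndarray],
    ridgelines: dict[str, np.ndarray],
    spacing: tuple[float, float, float],
) -> ReferenceLines:
    """Construct RL1-RL11 from detected reference points.

    ``footprints`` maps ``"medial"``/``"lateral"`` to boolean (n_slices,
    n_cols) column masks; ``ridgelines`` maps the same keys to per-slice
    spine-peak x positions in mm (NaN where the spine is absent).
    """
    rp_idx = np.asarray([image_number_to_index(n) for n in rps.image_numbers])
    dz, _, dx = spacing
    med = np.asarray(footprints["medial"], bool)
    lat = np.asarray(footprints["lateral"], bool)
    nz, nx = med.shape
    x_mm = np.arange(nx) * dx

    i1, i3, i4, i5 = rp_idx[0], rp_idx[2], rp_idx[3], rp_idx[4]

    for name, fp, i in (("lateral", lat, i3), ("lateral", lat, i4)):
        if not fp[i].any():
            raise ValueError(f"{name} footprint empty at RL{3 if i == i3 else 4} (slice {i + 1})")
    if not med[i3].any():
        raise ValueError(f"medial footprint empty at RL3 (slice {i3 + 1})")

    ridge_m = _interp_ridgeline(np.asarray(ridgelines["medial"], float), i1, i5)
    ridge_l = _interp_ridgeline(np.asarray(ridgelines["lateral"], float), i1, i5)
    span = i5 - i1
    for nm, r in (("medial", ridgelines["medial"]), ("lateral", ridgelines["lateral"])):
        defined = np.isfinite(np.asarray(r, float)[i1 : i5 + 1]).sum()
        if defined < 0.5 * span:
            raise ValueError(f"{nm} ridgeline undefined over more than half of the RP1-RP5 span")

    # RL6: halving points between the lateral spine and the lateral outer edge
    # at RL3 and RL4.
    def lat_halving(i):
        edge = x_mm[np.flatnonzero(lat[i])].max()
        return (i * dz, (ridge_l[i] + edge) / 2.0)

    rl6 = (lat_halving(i3), lat_halving(i4))

    # RL7: medial halving point at RL3, and the medial footprint edge at RL5.
    med_edge_3 = x_mm[np.flatnonzero(med[i3])].min()
    a7 = (i3 * dz, (ridge_m[i3] + med_edge_3) / 2.0)
    j = i5
    while j > i1 and not med[j].any():
        j -= 1
    if not med[j].any():
        raise ValueError("medial footprint vanishes before RL5; cannot anchor RL7")
    b7 = (j * dz, float(x_mm[np.flatnonzero(med[j])].mean()))
    rl7 = (a7, b7)

    rl8 = np.full(nz, np.nan)
    rl9 = np.full(nz, np.nan)
    for i in range(nz):
        if lat[i].any():
            rl8[i] = x_mm[np.flatnonzero(lat[i])].max()
        if med[i].any():
            rl9[i] = x_mm[np.flatnonzero(med[i])].min()

    return ReferenceLines(rp_idx, tuple(spacing), rl6, rl7, rl8, rl9, ridge_l, ridge_m)


def partition_subregions(rls: ReferenceLines, footprints: dict[str, np.ndarray]) -> SubregionMap:
    """Assign every plateau footprint column to one of the 12 subregions.

    Longitudinal bands follow the half-open convention (boundary slice goes
    anterior-ward); the central/peripheral split is the signed side of RL6
    (lateral plateau) or RL7 (medial plateau), spine side = central.
    """
    med = np.asarray(footprints["medial"], bool)
    lat = np.asarray(footprints["lateral"], bool)
    if (med & lat).any():
        raise ValueError("medial and lateral footprints overlap")
    nz, nx = med.shape
    dz, _, dx = rls.spacing
    i1, _, i3, i4, i5 = rls.rp_indices
    z_idx = np.arange(nz)
    x_mm = np.arange(nx) * dx
    z_mm = z_idx * dz

    band = np.zeros(nz, dtype=np.int8)  # 0 outside, 1 posterior, 2 intermediate, 3 anterior
    band[(z_idx >= i1) & (z_idx < i3)] = 1
    band[(z_idx >= i3) & (z_idx < i4)] = 2
    band[(z_idx >= i4) & (z_idx <= i5)] = 3

    rl6x = rls.rl6_x_at(z_mm)[:, None]
    rl7x = rls.rl7_x_at(z_mm)[:, None]
    central_med = x_mm[None, :] >= rl7x  # spine side of the medial plateau
    central_lat = x_mm[None, :] <= rl6x  # spine side of the lateral plateau

    labels = np.zeros((nz, nx), dtype=np.int8)
    in_band = band[:, None] > 0
    base_med = np.broadcast_to((band[:, None] - 1) * 2, (nz, nx))  # 0/2/4
    central_med = np.broadcast_to(central_med, (nz, nx))
    central_lat = np.broadcast_to(central_lat, (nz, nx))
    labels[med & in_band & central_med] = (1 + base_med)[med & in_band & central_med]
    labels[med & in_band & ~central_med] = (2 + base_med)[med & in_band & ~central_med]
    base_lat = np.broadcast_to(6 + (band[:, None] - 1) * 2, (nz, nx))
    labels[lat & in_band & central_lat] = (1 + base_lat)[lat & in_band & central_lat]
    labels[lat & in_band & ~central_lat] = (2 + base_lat)[lat & in_band & ~central_lat]
    return SubregionMap(labels, rls.spacing)


def assign_point(z: int, x: int, submap: SubregionMap) -> str | None:
    """Subregion name of the surface column at slice index z, column x.

    Returns None outside both plateau footprints; raises on out-of-bounds
    coordinates.
    """
    nz, nx = submap.labels.shape
    if not (0 <= z < nz and 0 <= x < nx):
        raise IndexError(f"point (z={z}, x={x}) outside the {nz}x{nx} column grid")
    code = int(submap.labels[z, x])
    return None if code == 0 else submap.legend[code][0]
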