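"""Detection of the five bony reference points RP1-RP5.

Each coronal slice is reduced to a bone-surface profile h(x) (height of
the proximal-most bone voxel per column, in mm above the image bottom).
A rolling-minimum (grey-opening) baseline is subtracted so that peak
measurements are invariant to in-plane tilt, and peaks closer than an
edge margin to the slice's bone support boundary are discarded (a tilted
condylar margin produces a corner there, not an anatomical prominence).
Peaks of the remaining elevation are the tibial spines and the AIA
prominence.  All medio-lateral bands are fractions of the stack's bone
extent, not of the image width, so padding and rotation do not move
them.  Scanning the profiles posterior -> anterior:

RP1  first slice whose bone area reaches the noise floor ``a_min``;
RP2  first slice with *two* spine-scale peaks (prominence >= ``delta``)
     in the central band: the lateral spine arises more posteriorly, so
     the medial spine's emergence is the appearance of the second,
     more medial ridge;
RP3  first slice where the trough between the two spine-scale central
     peaks becomes shallower than ``tau`` (the saddle where the spines
     fuse);
RP4  first slice where a central peak *between* the two spine peaks
     reaches the height of both (the AIA prominence overtaking the
     spines);
RP5  last slice where the lateral plateau's articular footprint
     (cartilage-bearing columns lateral of the intercondylar midline on
     label volumes; lateral bone columns otherwise) persists —
     explicitly not the last bony slice, because the tibial tuberosity
     continues anteriorly.

Ties resolve to the earliest slice ("first image" convention); the
ordering RP1 < RP2 < RP3 < RP4 < RP5 is enforced on return.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .core_io import LandmarkSet, VolumeStack, index_to_image_number

__all__ = [
    "DetectionConfig",
    "SliceProfile",
    "ReferencePoints",
    "LandmarkDetectionError",
    "compute_slice_profiles",
    "detect",
    "detect_reference_points",
    "extract_ridgelines",
    "relative_positions",
    "plateau_length_mm",
]

RP_NAMES = ("RP1", "RP2", "RP3", "RP4", "RP5")


class LandmarkDetectionError(RuntimeError):
    """A reference-point criterion was never satisfied on the stack."""


@dataclass
class DetectionConfig:
    """Thresholds of the slice criteria (lengths in mm).

    The published criteria are visual; these defaults formalize them and
    are exposed because the AIA criterion (RP4) is the least sharp one.
    Band limits are fractions of the stack-wide medio-lateral bone
    extent (medial edge = 0, lateral edge = 1).
    """

    a_min_voxels: int = 10  # bone-area noise floor for RP1
    delta_mm: float = 0.5  # peak prominence for spine emergence (RP2)
    tau_mm: float = 0.3  # saddle trough depth for spine fusion (RP3)
    a_lat_frac: float = 0.05  # RP5: fraction of the max lateral footprint
    central_band: tuple[float, float] = (0.3, 0.7)  # spines + AIA
    lateral_region: float = 0.5  # x threshold for the RP5 footprint count
    baseline_window_mm: float = 10.0  # must exceed the spine-complex width
    min_peak_prominence_mm: float = 0.05
    min_peak_separation_mm: float = 1.2  # merge resampling-jitter twin peaks
    saddle_peak_min_mm: float = 1.0  # spines must be this tall to carry a saddle
    edge_margin_mm: float = 1.0  # ignore peaks this close to the support edge
    bone_threshold: float | None = None  # required for intensity volumes


@dataclass
class SliceProfile:
    """Bone-surface summary of one coronal slice."""

    slice_index: int  # 1-based image number
    bone_area: int
    heights_mm: np.ndarray  # h(x), NaN where no bone
    elevation_mm: np.ndarray  # h minus rolling-minimum baseline
    peaks: list  # interior peaks [(x_mm, elevation_mm, prominence_mm)], by x
    trough_depth_mm: float  # between the two highest spine-scale central peaks
    lateral_cols: int  # bone columns in the lateral outer region
    n_rows: int = 0  # in-plane row count of the source slice
    x_bounds_mm: tuple[float, float] = (0.0, 0.0)  # stack-wide bone x extent


def _cluster_peaks(peaks: list, sep_mm: float) -> list:
    """Merge peaks closer than ``sep_mm``, keeping the highest of each run.

    Nearest-neighbour resampling can split one narrow ridge top into twin
    local maxima one voxel apart; anatomical prominences (spines, AIA) are
    farther apart than the merge distance.
    """
    merged: list = []
    for p in peaks:  # peaks arrive sorted by x
        if merged and p[0] - merged[-1][0] < sep_mm:
            if p[1] > merged[-1][1]:
                merged[-1] = (p[0], p[1], max(p[2], merged[-1][2]))
            else:
                merged[-1] = (merged[-1][0], merged[-1][1], max(p[2], merged[-1][2]))
        else:
            merged.append(p)
    return merged


def _surface_heights(bone2d: np.ndarray, dy: float) -> np.ndarray:
    """Height (mm above the image bottom) of the top bone voxel per column."""
    ny = bone2d.shape[0]
    has = bone2d.any(axis=0)
    top = np.argmax(bone2d, axis=0)
    h = (ny - 1 - top) * dy
    return np.where(has, h, np.nan)


def compute_slice_profiles(vol: VolumeStack, config: DetectionConfig | None = None) -> list[SliceProfile]:
    """One :class:`SliceProfile` per coronal slice, posterior -> anterior."""
    cfg = config or DetectionConfig()
    if vol.kind != "label" and cfg.bone_threshold is None:
        raise ValueError("intensity volume: set DetectionConfig.bone_threshold")
    bone = vol.bone_mask(cfg.bone_threshold)
    nz, ny, nx = bone.shape
    dy, dx = vol.dy, vol.dx
    win = max(3, int(round(cfg.baseline_window_mm / dx)) | 1)
    x_mm = np.arange(nx) * dx

    bone_cols = bone.any(axis=1).any(axis=0)  # (nx,)
    if bone_cols.any():
        ci = np.flatnonzero(bone_cols)
        x_lo, x_hi = float(x_mm[ci[0]]), float(x_mm[ci[-1]])
    else:
        x_lo, x_hi = 0.0, float(x_mm[-1])
    width = max(x_hi - x_lo, dx)
    c_lo = x_lo + cfg.central_band[0] * width
    c_hi = x_lo + cfg.central_band[1] * width
    lat_x = x_lo + cfg.lateral_region * width

    profiles = []
    for i in range(nz):
        sl = bone[i]
        area = int(sl.sum())
        h = _surface_heights(sl, dy)
        valid = np.isfinite(h)
        e = np.zeros(nx)
        peaks: list[tuple[float, float, float]] = []
        trough = np.nan
        if valid.any():
            hf = h.copy()
            idx = np.flatnonzero(valid)
            hf[: idx[0]] = h[idx[0]]
            hf[idx[-1] + 1 :] = h[idx[-1]]
            if idx.size > 1 and (~valid[idx[0] : idx[-1] + 1]).any():
                inner = np.arange(idx[0], idx[-1] + 1)
                hf[inner] = np.interp(inner, idx, h[idx])
            baseline = ndimage.grey_dilation(ndimage.grey_erosion(hf, size=win), size=win)
            e = np.where(valid, hf - baseline, 0.0)
            pk, props = find_peaks(e, prominence=cfg.min_peak_prominence_mm)
            margin = cfg.edge_margin_mm / dx
            interior = (pk >= idx[0] + margin) & (pk <= idx[-1] - margin)
            peaks = _cluster_peaks(
                [
                    (float(x_mm[p]), float(e[p]), float(pr))
                    for p, pr in zip(pk[interior], props["prominences"][interior])
                ],
                cfg.min_peak_separation_mm,
            )
            spine_scale = [
                (px, pe, pp)
                for px, pe, pp in peaks
                if c_lo <= px <= c_hi and pe >= cfg.saddle_peak_min_mm
            ]
            if len(spine_scale) >= 2:
                two = sorted(spine_scale, key=lambda t: t[1])[-2:]
                xa, xb = sorted((two[0][0], two[1][0]))
                ia, ib = int(round(xa / dx)), int(round(xb / dx))
                trough = float(min(two[0][1], two[1][1]) - e[ia : ib + 1].min())
        if vol.kind == "label":
            lat_cols = int(((vol.voxels[i] == 2).any(axis=0) & (x_mm >= lat_x)).sum())
        else:
            lat_cols = int((sl.any(axis=0) & (x_mm >= lat_x)).sum())
        profiles.append(
            SliceProfile(
                index_to_image_number(i), area, h, e, peaks, trough, lat_cols, ny, (x_lo, x_hi)
            )
        )
    return profiles


@dataclass
class ReferencePoints:
    """RP1-RP5 as 1-based image numbers with mm and relative positions."""

    image_numbers: np.ndarray  # (5,)
    spacing: tuple[float, float, float]
    in_plane: np.ndarray | None = None  # (5, 2) (row, col), optional

    def __post_init__(self):
        self.image_numbers = np.asarray(self.image_numbers, dtype=int)
        if self.image_numbers.shape != (5,):
            raise ValueError("exactly five reference points are required")
        if np.any(np.diff(self.image_numbers) < 0):
            raise ValueError(f"reference points must be ordered, got {self.image_numbers}")

    @property
    def mm(self) -> np.ndarray:
        """Posterior-anterior positions in mm (slice 1 = 0 mm)."""
        return (self.image_numbers - 1) * self.spacing[0]

    @property
    def relative(self) -> np.ndarray:
        return relative_positions(self)

    def to_landmark_set(self) -> LandmarkSet:
        ip = self.in_plane if self.in_plane is not None else np.zeros((5, 2))
        return LandmarkSet(
            list(RP_NAMES), self.image_numbers.astype(float), ip[:, 0], ip[:, 1], self.spacing
        )


def relative_positions(rps: ReferencePoints) -> np.ndarray:
    """Relative positions in % of the RP1-RP5 span: 100*(N_i - N_1)/(N_5 - N_1)."""
    n = rps.image_numbers
    span = n[4] - n[0]
    if span == 0:
        raise ValueError("degenerate span: RP5 and RP1 coincide")
    return 100.0 * (n - n[0]) / span


def plateau_length_mm(rps: ReferencePoints, vol: VolumeStack | None = None) -> float:
    """Posterior-anterior RP1-RP5 length: slice span times slice spacing."""
    dz = vol.dz if vol is not None else rps.spacing[0]
    span = int(rps.image_numbers[4] - rps.image_numbers[0])
    if span == 0:
        raise ValueError("degenerate span: RP5 and RP1 coincide")
    return span * dz


def detect_reference_points(
    profiles: list[SliceProfile],
    config: DetectionConfig | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> ReferencePoints:
    """Scan slice profiles posterior -> anterior and locate RP1-RP5."""
    cfg = config or DetectionConfig()
    if spacing is None:
        raise ValueError("pass the volume spacing (or use detect() on a volume)")
    if not profiles:
        raise LandmarkDetectionError("empty stack")
    x_lo, x_hi = profiles[0].x_bounds_mm
    width = max(x_hi - x_lo, 1e-9)
    c_lo, c_hi = (x_lo + cfg.central_band[0] * width, x_lo + cfg.central_band[1] * width)

    def spine_peaks(p):
        return [(px, pe) for px, pe, pp in p.peaks if c_lo <= px <= c_hi and pp >= cfg.delta_mm]

    def first(pred, start, label):
        for p in profiles[start:]:
            if pred(p):
                return p.slice_index
        raise LandmarkDetectionError(f"criterion for {label} never satisfied")

    rp1 = first(lambda p: p.bone_area >= cfg.a_min_voxels, 0, "RP1")

    rp2 = first(lambda p: len(spine_peaks(p)) >= 2, rp1 - 1, "RP2")

    def fused(p):
        return np.isfinite(p.trough_depth_mm) and p.trough_depth_mm < cfg.tau_mm

    rp3 = first(fused, rp2, "RP3")

    # RP4: the AIA prominence overtakes the spines.  The two spine ridges
    # are tracked anterior-ward from the fusion slice (their x drifts under
    # axial rotation); the AIA counts as emerged once a peak strictly
    # between the ridges exceeds both spine heights *of the same slice* by
    # a saddle-scale margin (tau) — a within-slice comparison, so uniform
    # resampling attenuation cancels.
    p3 = profiles[rp3 - 1]
    sp3 = sorted(
        px for px, pe, _ in p3.peaks if c_lo <= px <= c_hi and pe >= cfg.saddle_peak_min_mm
    )
    if len(sp3) < 2:
        raise LandmarkDetectionError("criterion for RP4 never satisfied (spine ridges lost at RP3)")
    xm, xl = sp3[0], sp3[-1]
    dx = spacing[2]
    rp4 = None
    for p in profiles[rp3:]:
        # follow each ridge to the nearest peak of this slice
        near_m = [(abs(px - xm), px, pe) for px, pe, _ in p.peaks if abs(px - xm) <= 1.0]
        near_l = [(abs(px - xl), px, pe) for px, pe, _ in p.peaks if abs(px - xl) <= 1.0]
        nxc = len(p.elevation_mm) - 1
        em = min(near_m)[2] if near_m else p.elevation_mm[min(max(int(round(xm / dx)), 0), nxc)]
        el = min(near_l)[2] if near_l else p.elevation_mm[min(max(int(round(xl / dx)), 0), nxc)]
        if near_m:
            xm = min(near_m)[1]
        if near_l:
            xl = min(near_l)[1]
        if xl - xm > 1.8:
            middles = [pe for px, pe, _ in p.peaks if xm + 0.8 < px < xl - 0.8]
            if middles and max(middles) >= max(em, el) + cfg.tau_mm:
                rp4 = p.slice_index
                break
    if rp4 is None:
        raise LandmarkDetectionError("criterion for RP4 never satisfied")

    lat_max = max(p.lateral_cols for p in profiles)
    if lat_max == 0:
        raise LandmarkDetectionError("criterion for RP5 never satisfied (no lateral footprint)")
    a_lat = max(3.0, cfg.a_lat_frac * lat_max)
    rp5 = None
    for p in profiles:
        if p.lateral_cols >= a_lat:
            rp5 = p.slice_index
    if rp5 is None:
        raise LandmarkDetectionError("criterion for RP5 never satisfied")

    numbers = np.array([rp1, rp2, rp3, rp4, rp5])
    if np.any(np.diff(numbers) <= 0):
        raise LandmarkDetectionError(f"detected reference points violate ordering: {numbers}")
    in_plane = _in_plane_coords(profiles, numbers, cfg, spacing)
    return ReferencePoints(numbers, spacing, in_plane=in_plane)


def detect(vol: VolumeStack, config: DetectionConfig | None = None) -> ReferencePoints:
    """Convenience: profiles + detection on a volume."""
    cfg = config or DetectionConfig()
    return detect_reference_points(compute_slice_profiles(vol, cfg), cfg, spacing=vol.spacing)


def _row_of(p: SliceProfile, col: int, dy: float) -> float:
    """Recover the surface row index from the stored height h = (ny-1-row)*dy."""
    h = p.heights_mm[col]
    if not np.isfinite(h):
        fin = np.flatnonzero(np.isfinite(p.heights_mm))
        col = int(fin[np.argmin(np.abs(fin - col))])
        h = p.heights_mm[col]
    return float(p.n_rows - 1 - h / dy)


def _in_plane_coords(profiles, numbers, cfg, spacing):
    """Representative (row, col) of each RP's defining feature."""
    dy, dx = spacing[1], spacing[2]
    x_lo, x_hi = profiles[0].x_bounds_mm
    width = max(x_hi - x_lo, 1e-9)
    c_lo, c_hi = (x_lo + cfg.central_band[0] * width, x_lo + cfg.central_band[1] * width)
    out = np.zeros((5, 2))

    # RP1: bone-surface centroid column of the first bony slice
    p1 = profiles[numbers[0] - 1]
    fin = np.flatnonzero(np.isfinite(p1.heights_mm))
    c1 = int(round(fin.mean()))
    out[0] = (_row_of(p1, c1, dy), c1)
    # RP2: the emerging (medial-most) spine-scale peak
    p2 = profiles[numbers[1] - 1]
    cands = [px for px, pe, pp in p2.peaks if c_lo <= px <= c_hi and pp >= cfg.delta_mm]
    c2 = int(round(min(cands) / dx)) if cands else c1
    out[1] = (_row_of(p2, c2, dy), c2)
    # RP3: the saddle point between the two highest spine-scale peaks
    p3 = profiles[numbers[2] - 1]
    central = sorted(
        [(px, pe) for px, pe, _ in p3.peaks if c_lo <= px <= c_hi and pe >= cfg.saddle_peak_min_mm],
        key=lambda t: t[1],
    )[-2:]
    if len(central) == 2:
        ia, ib = sorted(int(round(px / dx)) for px, _ in central)
        c3 = ia + int(np.argmin(p3.elevation_mm[ia : ib + 1]))
    else:
        c3 = c2
    out[2] = (_row_of(p3, c3, dy), c3)
    # RP4: the AIA prominence = tallest central peak at the RP4 slice
    p4 = profiles[numbers[3] - 1]
    central = [(pe, px) for px, pe, _ in p4.peaks if c_lo <= px <= c_hi]
    c4 = int(round(max(central)[1] / dx)) if central else c3
    out[3] = (_row_of(p4, c4, dy), c4)
    # RP5: centroid of the lateral-region bone columns of the edge slice
    p5 = profiles[numbers[4] - 1]
    lat_start = int(round((x_lo + cfg.lateral_region * width) / dx))
    cols = np.flatnonzero(np.isfinite(p5.heights_mm[lat_start:])) + lat_start
    c5 = int(round(cols.mean())) if cols.size else c1
    out[4] = (_row_of(p5, c5, dy), c5)
    return out


def extract_ridgelines(
    vol: VolumeStack,
    profiles: list[SliceProfile] | None = None,
    config: DetectionConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-slice x (mm) of the medial and lateral spine peaks (RL10/RL11).

    The two spine ridgelines are tracked as the most prominent interior
    peak in the medial and lateral halves of the central band; NaN where
    the spine is absent.
    """
    cfg = config or DetectionConfig()
    profiles = profiles or compute_slice_profiles(vol, cfg)
    x_lo, x_hi = profiles[0].x_bounds_mm
    width = max(x_hi - x_lo, 1e-9)
    c_lo, c_hi = (x_lo + cfg.central_band[0] * width, x_lo + cfg.central_band[1] * width)
    mid = (c_lo + c_hi) / 2
    med = np.full(len(profiles), np.nan)
    lat = np.full(len(profiles), np.nan)
    for i, p in enumerate(profiles):
        mcand = [(pp, px) for px, pe, pp in p.peaks if c_lo <= px < mid and pp >= cfg.delta_mm]
        lcand = [(pp, px) for px, pe, pp in p.peaks if mid <= px <= c_hi and pp >= cfg.delta_mm]
        if mcand:
            med[i] = max(mcand)[1]
        if lcand:
            lat[i] = max(lcand)[1]
    return {"medial": med, "lateral": lat}
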