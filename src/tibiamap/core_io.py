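"""Volumes, landmark sets and the canonical anatomical frame.

Conventions
-----------
Voxel arrays are ordered ``(z, y, x)``:

* ``z`` — coronal slice index, posterior -> anterior (slice 1 = most
  posterior; slices are reported as 1-based *image numbers*, the micro-CT
  convention, while all internal indices are 0-based);
* ``y`` — in-plane row, proximal -> distal (row 0 is the top of the image;
  the in-plane origin is the top-left pixel);
* ``x`` — in-plane column; in the *canonical frame* (a LEFT tibia) ``x``
  increases medial -> lateral.  Right-sided specimens are mirrored along
  ``x`` on canonicalization.

Label volumes use 0 = background, 1 = bone, 2 = articular cartilage.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "BACKGROUND",
    "BONE",
    "CARTILAGE",
    "VolumeStack",
    "LandmarkSet",
    "image_number_to_index",
    "index_to_image_number",
    "read_volume",
    "write_volume",
    "to_canonical_frame",
    "read_landmarks",
    "write_landmarks",
]

BACKGROUND = 0
BONE = 1
CARTILAGE = 2

_LABELS = frozenset({BACKGROUND, BONE, CARTILAGE})


def image_number_to_index(n: int) -> int:
    """Convert a 1-based micro-CT image number to a 0-based slice index."""
    return int(n) - 1


def index_to_image_number(i: int) -> int:
    """Convert a 0-based slice index to a 1-based micro-CT image number."""
    return int(i) + 1


@dataclass
class VolumeStack:
    """A coronal image stack with voxel spacing and anatomical tags.

    Parameters
    ----------
    voxels
        3-D array ordered ``(z, y, x)``.  Small-integer labels
        ({0, 1, 2}) when ``kind == "label"``, grayscale otherwise.
    spacing
        ``(dz, dy, dx)`` in mm per voxel; all components must be positive.
    side
        ``"left"``, ``"right"`` or ``"canonical"`` (left-equivalent).
    kind
        ``"label"`` or ``"intensity"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    side: str = "canonical"
    kind: str = "label"
    frame: str = "zyx-coronal"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D (z, y, x), got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm/voxel values, got {self.spacing}")
        if self.side not in ("left", "right", "canonical", "unknown"):
            raise ValueError(f"side must be left/right/canonical, got {self.side!r}")
        if self.kind not in ("label", "intensity"):
            raise ValueError(f"kind must be 'label' or 'intensity', got {self.kind!r}")
        if self.kind == "label":
            values = np.unique(self.voxels)
            if not set(int(v) for v in values) <= _LABELS:
                raise ValueError(f"label volume contains labels outside {sorted(_LABELS)}: {values}")

    # -- geometry helpers -------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)

    @property
    def dz(self) -> float:
        return self.spacing[0]

    @property
    def dy(self) -> float:
        return self.spacing[1]

    @property
    def dx(self) -> float:
        return self.spacing[2]

    @property
    def width_mm(self) -> float:
        return self.voxels.shape[2] * self.dx

    def bone_mask(self, threshold: float | None = None) -> np.ndarray:
        """Boolean bone mask; intensity volumes need an explicit threshold."""
        if self.kind == "label":
            return self.voxels == BONE
        if threshold is None:
            raise ValueError("intensity volume: a bone threshold is required")
        return self.voxels >= threshold

    def copy(self, **changes) -> "VolumeStack":
        out = replace(self, **changes)
        if "voxels" not in changes:
            out.voxels = self.voxels.copy()
        return out


@dataclass
class LandmarkSet:
    """Named points on a coronal stack (1-based image number, row, col).

    ``mm`` coordinates are derived from indices and spacing:
    ``z = (image_number - 1) * dz``, ``y = row * dy``, ``x = col * dx``.
    """

    names: list[str]
    image_numbers: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    spacing: tuple[float, float, float]
    frame: str = "zyx-coronal"

    def __post_init__(self) -> None:
        self.names = list(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        self.image_numbers = np.asarray(self.image_numbers, dtype=float)
        self.rows = np.asarray(self.rows, dtype=float)
        self.cols = np.asarray(self.cols, dtype=float)
        n = len(self.names)
        if not (self.image_numbers.shape == self.rows.shape == self.cols.shape == (n,)):
            raise ValueError("names, image_numbers, rows, cols must have equal length")
        if np.any(self.image_numbers < 1):
            raise ValueError("image numbers are 1-based and must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def mm(self) -> np.ndarray:
        """(n, 3) array of (z, y, x) positions in mm."""
        dz, dy, dx = self.spacing
        return np.column_stack(
            [(self.image_numbers - 1) * dz, self.rows * dy, self.cols * dx]
        )

    def subset(self, names: list[str]) -> "LandmarkSet":
        idx = [self.names.index(n) for n in names]
        return LandmarkSet(
            [self.names[i] for i in idx],
            self.image_numbers[idx],
            self.rows[idx],
            self.cols[idx],
            self.spacing,
            self.frame,
        )


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

_SLICE_RE = re.compile(r"(\d+)\D*$")


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "metadata.json"
    return path.with_name(path.name + ".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            return json.load(fh)
    return {}


def _numbered_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF slices found in {directory}")
    numbered = []
    for p in files:
        m = _SLICE_RE.search(p.stem)
        if m is None:
            raise ValueError(f"cannot parse slice number from file name {p.name!r}")
        numbered.append((int(m.group(1)), p))
    numbered.sort(key=lambda t: t[0])
    nums = [n for n, _ in numbered]
    if len(set(nums)) != len(nums):
        raise ValueError(f"duplicate slice numbers in {directory}")
    for prev, cur in zip(nums, nums[1:]):
        if cur != prev + 1:
            raise ValueError(f"slice numbering gap at index {prev + 1}")
    return [p for _, p in numbered]


def read_volume(
    path,
    spacing_override: tuple[float, float, float] | None = None,
    side: str | None = None,
    kind: str | None = None,
) -> VolumeStack:
    """Read a NIfTI/MetaImage volume or a numbered PNG/TIFF slice series.

    Slice files are stacked in ascending file-number order, which is the
    posterior -> anterior direction.  Spacing comes from the file header or
    a JSON sidecar and can be overridden.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    spacing = spacing_override or meta.get("spacing")
    side = side or meta.get("side", "canonical")
    kind = kind or meta.get("kind")

    if path.is_dir():
        import imageio.v3 as iio

        files = _numbered_files(path)
        arr = np.stack([np.asarray(iio.imread(f)) for f in files], axis=0)
        if spacing is None:
            raise ValueError("slice series carries no spacing; pass spacing_override")
    elif path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        # stored as (x, y, z); bring back to (z, y, x)
        arr = np.asarray(img.dataobj).T
        if spacing is None:
            zooms = img.header.get_zooms()[:3]
            spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    elif path.suffix == ".mha":
        try:
            import SimpleITK as sitk
        except ImportError as exc:  # pragma: no cover
            raise ValueError("MetaImage support requires SimpleITK") from exc
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        if spacing is None:
            sx, sy, sz = img.GetSpacing()
            spacing = (float(sz), float(sy), float(sx))
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            arr = arr[None]
        if spacing is None:
            raise ValueError("TIFF carries no reliable spacing; pass spacing_override")
    else:
        raise ValueError(f"unsupported volume path {path}")

    if spacing is None:
        raise ValueError("no spacing in header or sidecar; pass spacing_override")
    if kind is None:
        kind = "label" if arr.dtype.kind in "biu" and arr.max(initial=0) <= 2 else "intensity"
    return VolumeStack(arr, tuple(spacing), side=side, kind=kind)


def write_volume(vol: VolumeStack, path) -> None:
    """Write a volume losslessly with a JSON sidecar (spacing, side, kind)."""
    path = Path(path)
    arr = vol.voxels
    if path.name.endswith(".nii.gz") or path.suffix == ".nii":
        import nibabel as nib

        dz, dy, dx = vol.spacing
        affine = np.diag([dx, dy, dz, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(arr.T), affine), str(path))
    elif path.suffix == ".mha":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(arr)
        dz, dy, dx = vol.spacing
        img.SetSpacing((dx, dy, dz))
        sitk.WriteImage(img, str(path))
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
    elif path.suffix == "":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        data = arr.astype(np.uint8) if vol.kind == "label" else arr
        for i in range(vol.n_slices):
            iio.imwrite(path / f"slice_{i + 1:04d}.png", data[i])
    else:
        raise ValueError(f"unsupported output path {path}")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {"spacing": list(vol.spacing), "side": vol.side, "kind": vol.kind, "frame": vol.frame},
            fh,
            indent=1,
        )


def to_canonical_frame(vol: VolumeStack) -> VolumeStack:
    """Mirror right-sided volumes along x so medial/lateral match a left tibia.

    Left volumes are returned with only the tag changed; applying the mirror
    twice restores the original voxels.
    """
    if vol.side == "canonical":
        return vol
    if vol.side == "left":
        return vol.copy(side="canonical")
    if vol.side == "right":
        return vol.copy(voxels=vol.voxels[:, :, ::-1].copy(), side="canonical")
    raise ValueError(f"cannot canonicalize volume with side {vol.side!r}")


# ---------------------------------------------------------------------------
# landmark I/O
# ---------------------------------------------------------------------------

def read_landmarks(path, spacing: tuple[float, float, float] | None = None) -> LandmarkSet:
    """Read a landmark JSON file ({name, image_number, row, col} entries)."""
    with open(path) as fh:
        doc = json.load(fh)
    entries = doc["landmarks"]
    spacing = spacing or tuple(doc.get("spacing", ()))
    if not spacing:
        raise ValueError("landmark file carries no spacing; pass spacing=")
    return LandmarkSet(
        [e["name"] for e in entries],
        np.array([e["image_number"] for e in entries], dtype=float),
        np.array([e.get("row", 0.0) for e in entries], dtype=float),
        np.array([e.get("col", 0.0) for e in entries], dtype=float),
        tuple(spacing),
        frame=doc.get("frame", "zyx-coronal"),
    )


def write_landmarks(lms: LandmarkSet, path) -> None:
    doc = {
        "frame": lms.frame,
        "spacing": list(lms.spacing),
        "landmarks": [
            {
                "name": n,
                "image_number": float(num),
                "row": float(r),
                "col": float(c),
            }
            for n, num, r, c in zip(lms.names, lms.image_numbers, lms.rows, lms.cols)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
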