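import numpy as np
import pytest

from tibiamap import generate_phantom
from tibiamap.geometry import (
    build_reference_lines,
    footprints_from_volume,
    partition_subregions,
)
from tibiamap.landmarks import (
    DetectionConfig,
    compute_slice_profiles,
    detect_reference_points,
    extract_ridgelines,
)
from tibiamap.phantom import PathologyParams, add_pathology

PAPER_REL = np.array([0.0, 29.9, 40.8, 74.2, 100.0])
PAPER_LENGTH_MM = 32.7


@pytest.fixture(scope="session")
def phantom():
    """Canonical mean-shape phantom and its ground truth."""
    return generate_phantom(seed=1)


@pytest.fixture(scope="session")
def oa_phantom(phantom):
    vol, gt = phantom
    return add_pathology(vol, gt, PathologyParams(seed=1))


@pytest.fixture(scope="session")
def pipeline(phantom):
    """Detection -> reference lines -> subregion map on the phantom."""
    vol, gt = phantom
    cfg = DetectionConfig()
    profiles = compute_slice_profiles(vol, cfg)
    rps = detect_reference_points(profiles, cfg, spacing=vol.spacing)
    ridgelines = extract_ridgelines(vol, profiles, cfg)
    footprints = footprints_from_volume(vol, ridgelines)
    rls = build_reference_lines(rps, footprints, ridgelines, vol.spacing)
    submap = partition_subregions(rls, footprints)
    return {
        "config": cfg,
        "profiles": profiles,
        "rps": rps,
        "ridgelines": ridgelines,
        "footprints": footprints,
        "lines": rls,
        "submap": submap,
    }


@pytest.fixture(scope="session")
def rotation_results(phantom):
    """Detected reference points after +/-10 deg rotations in each plane."""
    from tibiamap.landmarks import detect
    from tibiamap.transforms import RotationSpec, rotate_volume

    vol, _ = phantom
    out = {}
    for plane in ("coronal", "axial", "sagittal"):
        for angle in (-10.0, 10.0):
            rv = rotate_volume(vol, RotationSpec(plane, angle))
            out[(plane, angle)] = detect(rv)
    return out


@pytest.fixture(scope="session")
def registration_roundtrip(phantom):
    """Sagittal +10 deg rotation registered back via RP landmarks + SSD."""
    from tibiamap.landmarks import detect
    from tibiamap.transforms import (
        RotationSpec,
        apply_transform,
        fit_rigid_landmarks,
        refine_rigid_ssd,
        rotate_volume,
    )

    vol, _ = phantom
    r0 = detect(vol)
    rotated = rotate_volume(vol, RotationSpec("sagittal", 10.0))
    r_rot = detect(rotated)
    t_lm = fit_rigid_landmarks(r0.to_landmark_set(), r_rot.to_landmark_set())
    t = refine_rigid_ssd(vol, rotated, init=t_lm, levels=(6, 3))
    back = apply_transform(rotated, t, reference=vol)
    return {"baseline": r0, "rotated": rotated, "transform": t, "back": back}
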