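import numpy as np
import pytest

import meniscoq as mq


@pytest.fixture(scope="session")
def patient_truth():
    """Noise-free ground-truth scene with patient-group regional T2* values."""
    return mq.generate_phantom(mq.patient_spec(extrusion_mm=0.0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def noiseless_vol(patient_truth):
    return mq.simulate_multiecho(patient_truth, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_maps(patient_truth, noiseless_vol):
    return mq.fit_monoexponential(noiseless_vol, patient_truth.combined_mask())


@pytest.fixture(scope="session")
def medial_partition(patient_truth):
    lm = patient_truth.landmarks
    return mq.partition_regions(
        patient_truth.mask("medial"),
        lm.anterior_horn_mm["medial"],
        lm.posterior_horn_mm["medial"],
        patient_truth.affine,
    )


def brute_force_angle_labels(mask, anterior_mm, posterior_mm, affine):
    """Independent per-voxel oracle: explicit loop, scalar atan2, explicit bins.

    Vertex at the horn midpoint; sweep side chosen by the mask centroid;
    far-side voxels clamped to the nearest terminal bin; bins half-open with
    180 degrees closed.
    """
    import math

    mask = np.asarray(mask).astype(bool)
    A = np.asarray(anterior_mm, float)
    P = np.asarray(posterior_mm, float)
    O = (A + P) / 2.0
    ax, ay = A[0] - O[0], A[1] - O[1]
    na = math.hypot(ax, ay)
    ax, ay = ax / na, ay / na
    nx, ny = -ay, ax
    idx = np.argwhere(mask)
    pts = idx @ affine[:3, :3].T + affine[:3, 3]
    cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
    if (cx - O[0]) * nx + (cy - O[1]) * ny < 0:
        nx, ny = -nx, -ny
    labels = np.zeros(mask.shape, dtype=np.int8)
    for (i, j, k), p in zip(idx, pts):
        vx, vy = p[0] - O[0], p[1] - O[1]
        theta = math.degrees(math.atan2(vx * nx + vy * ny, vx * ax + vy * ay))
        if theta < 0:
            theta = 0.0 if theta > -90.0 else 180.0
        if theta < 45.0:
            lab = 1
        elif theta < 90.0:
            lab = 2
        elif theta < 135.0:
            lab = 3
        else:
            lab = 4
        labels[i, j, k] = lab
    return labels
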