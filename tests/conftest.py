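import numpy as np
import pytest

from bmquant import (LesionSpec, PhantomConfig, generate_phantom, masks_from_labels)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Noise-free phantom with two medullary lesions (axial + extremity) and
    one extramedullary soft-tissue lesion, all with known planted volumes."""
    config = PhantomConfig(
        noise_sd=0.0,
        infiltration_fraction=0.1,
        lesion_specs=(
            LesionSpec((24, 24, 40), 5.0, 5.0, "axial"),
            LesionSpec((6, 24, 20), 4.0, 4.5, "extremity"),
            LesionSpec((10, 36, 10), 5.0, 4.0, "extramedullary"),
        ),
    )
    ct, suv, truth = generate_phantom(config)
    return config, ct, suv, truth


@pytest.fixture(scope="session")
def lesion_masks(lesion_phantom):
    _, _, _, truth = lesion_phantom
    return masks_from_labels(truth.label_map)


def brute_force_mtv_tlg(segmented, suv_values, spacing_mm):
    """Independent voxel-loop oracle for MTV/TLG (kept free of the package's
    vectorized path)."""
    vox_ml = (spacing_mm[0] * spacing_mm[1] * spacing_mm[2]) / 1000.0
    count = 0
    total = 0.0
    nx, ny, nz = segmented.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if segmented[i, j, k]:
                    count += 1
                    total += suv_values[i, j, k]
    mtv = count * vox_ml
    suv_mean = total / count if count else 0.0
    return mtv, suv_mean * mtv, suv_mean, count
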