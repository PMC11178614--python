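"""Automated IMPeTUs reading of the focal-lesion phantom.

Regenerates the focal phantom from 01 and emits the structured report:
diffuse Deauville score, focal count with F bin, hottest-lesion score, lytic
count with L bin, and the PMD/EMD flags.
"""

import json
from pathlib import Path

import numpy as np

from bmquant import (LesionSpec, PhantomConfig, assemble_impetus_report,
                     generate_phantom, masks_from_labels)

RESULTS = Path("results")
SEED = 20260928


def main() -> None:
    rng = np.random.default_rng(SEED)
    rng.integers(2 ** 31, size=12)  # skip the diffuse-series seeds
    cfg = PhantomConfig(
        noise_sd=0.05, seed=int(rng.integers(2 ** 31)), infiltration_fraction=0.1,
        lesion_specs=(LesionSpec((24, 24, 35), 4.0, 5.0, "axial"),
                      LesionSpec((24, 24, 50), 4.0, 4.5, "axial"),
                      LesionSpec((6, 24, 20), 4.0, 4.5, "extremity"),
                      LesionSpec((10, 36, 10), 5.0, 4.0, "extramedullary")),
        lytic_specs=(((24, 24, 30), 4.0),))
    ct, suv, truth = generate_phantom(cfg)
    report = assemble_impetus_report(suv, ct, masks_from_labels(truth.label_map),
                                     truth.label_map)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "impetus_focal_phantom.json").write_text(
        json.dumps(report.to_dict(), indent=2))
    print(f"focal lesions: {report.focal_count} (F{report.f_score}), "
          f"hottest Deauville {report.hottest_ds}, diffuse Deauville "
          f"{report.diffuse_ds}, lytic {report.lytic_count} (L{report.l_score}), "
          f"PMD={report.pmd_flag}, EMD={report.emd_flag}")


if __name__ == "__main__":
    main()
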