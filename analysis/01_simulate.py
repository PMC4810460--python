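"""Generate the default synthetic two-group cohort and write it to disk.

Twenty subjects (10 controls, 10 patients), six spatially independent
networks on a 12 x 12 x 8 grid, a 126-volume alternating 0-back/1-back
block design at TR = 2 s, patient-specific changes planted in the ground
truth: higher task activation gain (1.3x), reduced coupling inside a
30-voxel region of one network (scale 0.4), and a decoupled network pair
(timecourse correlation 0.5 -> 0.15).
"""

import sys
from pathlib import Path

import numpy as np

from gicafc import io as pio
from gicafc.synthetic import CohortConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 3) -> None:
    cfg = CohortConfig(seed=seed)
    cohort = generate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    pio.write_mask(OUT / "mask.nii", cohort.mask)
    for run in cohort.runs:
        pio.write_run(OUT / f"{run.subject}_bold.nii", run, cohort.mask)
    pio.write_table(OUT / "behavior.tsv", cohort.behavior)
    pio.write_table(OUT / "covariates.tsv", cohort.covariates)
    np.save(OUT / "truth_maps.npy", cohort.truth.spatial_maps)

    t = cohort.truth
    print(f"cohort: {len(cohort.runs)} subjects, grid {cfg.shape}, "
          f"{cohort.runs[0].n_volumes} volumes, {cfg.n_components} networks")
    print(f"task components: {t.task_components}; FC pair: {t.fc_pair}; "
          f"deficit component: {t.deficit_component} "
          f"({t.deficit_region.size} voxels)")
    print(f"wrote runs, mask, behavior and covariates under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 3)
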