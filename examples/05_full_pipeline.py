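"""The full pipeline from displacement fields to statistics tables.

Builds a small synthetic longitudinal cohort (4 subjects x 4 intervals of
Gaussian-expansion deformations whose amplitude decays with age), writes
the NIfTI inputs and cohort CSV, and runs strain -> 90-day adjustment ->
smoothing -> voxel-wise tests -> mixed model -> ROI classification.
"""

import tempfile
from pathlib import Path

import pandas as pd

from strainmorph import AnalyticDeformation, PipelineConfig, default_grid, run_pipeline, sample_field
from strainmorph import io_volumes as iov
from strainmorph.synthetic import (
    DEFAULT_INTERVAL_DAYS,
    DEFAULT_INTERVAL_IDS,
    DEFAULT_MIDPOINT_AGES,
    make_phantom_atlas,
)

root = Path(tempfile.mkdtemp(prefix="strainmorph_demo_"))
grid = default_grid(8, spacing=2.0)

rows = []
for s in range(4):
    for k in range(4):
        age = DEFAULT_MIDPOINT_AGES[k]
        alpha = 0.8 - 0.0015 * age + 0.05 * s  # growth decelerates with age
        field, _ = sample_field(AnalyticDeformation.gaussian_expansion(alpha, sigma=8.0), grid)
        path = root / f"field_s{s}_k{k}.nii.gz"
        iov.write_displacement_field(path, field)
        rows.append({
            "subject_id": f"sub-{s:02d}",
            "interval_id": DEFAULT_INTERVAL_IDS[k],
            "days_between_scans": DEFAULT_INTERVAL_DAYS[k],
            "midpoint_age_days": age,
            "field_path": str(path),
        })
pd.DataFrame(rows).to_csv(root / "cohort.csv", index=False)
atlas, _ = make_phantom_atlas(grid, 3)
iov.write_label_atlas(root / "atlas.nii.gz", root / "atlas_names.csv", atlas)

cfg = PipelineConfig(
    cohort=str(root / "cohort.csv"),
    output_dir=str(root / "out"),
    atlas=str(root / "atlas.nii.gz"),
    atlas_names=str(root / "atlas_names.csv"),
)
result = run_pipeline(cfg)

lme = pd.read_csv(result.tables["lme_age_effects"])
print(lme.to_string(index=False))
print("\noutputs under:", result.output_dir)

# The JD row shows FDR-significant voxels with a negative mean slope: the
# deliberately built-in deceleration of growth with age is recovered.  Note
# these demo fields are noise-free, so residual variance is near zero and
# even the numerically-zero shear slopes reach formal significance; with
# realistic noise (see example 03) only genuine effects survive the FDR.
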