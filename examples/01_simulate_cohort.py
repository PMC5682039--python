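"""Simulate a synthetic PET cohort and write it to disk.

Builds the default two-group (13 nonSAD + 6 SAD), two-season phantom
cohort: 38 parametric volumes with a planted winter-selective group
pattern, subject intercepts and voxel noise, plus the gray-matter/CSF
probability volumes used for masking.
"""

import numpy as np

from npairspls import (
    PhantomSpec,
    brain_ellipsoid_probabilities,
    build_phantom,
    simulate_cohort,
    write_cohort,
)

spec = PhantomSpec(seed=42)
volumes, design = simulate_cohort(spec)
gm, csf = brain_ellipsoid_probabilities(spec)
baseline, effect = build_phantom(spec)

csv_path = write_cohort(volumes, design, "scratch/example_cohort", gm=gm, csf=csf)

print(f"scans written: {design.n_scans} (subjects: {len(design.subjects)})")
print(f"design table:  {csv_path}")
print(f"grid {spec.grid_shape} @ {spec.voxel_size_mm} mm, baseline {spec.baseline_level} BP_ND")
print(f"planted voxels: {int(np.sum(effect.values != 0))} "
      f"(|effect| = {spec.regions[0].effect_size} BP_ND)")
# The planted pattern is expressed with coefficient +1 by nonSAD winter
# scans and -1 by SAD winter scans; summer scans carry no effect. That is
# the group-by-season dissociation the downstream PLS analysis should find.
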