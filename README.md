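# isps

Inter-subject phase synchronization (ISPS) analysis for blocked-design
fMRI, with a fully synthetic benchmark.

When a group of participants experiences the same stimulus sequence,
task-engaged brain regions do not merely activate — their BOLD signals
align *in time* across people.  ISPS quantifies that alignment voxel by
voxel and TR by TR: each subject's prepared voxel time series is turned
into an analytic signal via the Hilbert transform, its angle θ_s(t) is the
instantaneous phase, and the group synchronization is the mean resultant
length

    R(t) = | (1/N) Σ_s exp(i·θ_s(t)) |  =  1 − circular variance,

ranging from 0 (complete phase dispersion) to 1 (identical phases).  The
voxels × time synchronization matrix is then decomposed by spatial ICA into
synchronization networks, whose time courses (the degree of group phase
alignment per TR) are correlated against HRF-convolved condition reference
functions — Pearson r with Bonferroni correction, and Fisher r-to-z
contrasts (Z statistic, Cohen's q) for condition specificity.  A minimal
mass-univariate GLM is included for method comparison, along with
percent-overlap reporting against a labelled parcellation (e.g. Yeo-7).

The package is aimed at researchers who want a tested, reproducible
reference implementation of the ISPS pipeline — and at methodologists who
want to probe when synchronization analyses diverge from conventional GLM
subtraction, using the built-in generator that plants condition-locked
networks with controllable inter-subject heterogeneity.

## Worked example

Simulate a 24-subject group with three planted networks, run the pipeline,
and inspect the association table:

```python
import numpy as np
from isps import (build_default_design, build_references, default_spec,
                  simulate_group, prepare, analytic_phase, sync_map,
                  sync_ica, component_condition_correlations)
from isps.io import apply_mask

design = build_default_design()
spec = default_spec(seed=1)                      # 12x12x12, 24 subjects
series, truth = simulate_group(spec, design)

mask = np.ones(spec.grid_dims, dtype=bool)
prepared = [prepare(apply_mask(s, mask), tr_s=2.0).data for s in series]
phases = [analytic_phase(p) for p in prepared]
smap = sync_map(phases)                          # voxels x TRs, in [0, 1]

result = sync_ica(smap, order=10, seed=0)
table = component_condition_correlations(
    result.time_courses, build_references(design))
print(table.sort_values("r", ascending=False).head(3).to_string(index=False))
```

```
 component        condition        r        p_raw  p_bonferroni   n
         0 physical_control 0.813110 2.656906e-50  2.125525e-48 208
         1   affective_pain 0.756059 8.754727e-40  7.003781e-38 208
         2    physical_pain 0.744573 5.169153e-38  4.135322e-36 208
```

The three strongest associations are exactly the three planted networks:
each recovered component's synchronization time course correlates at
r ≈ 0.74–0.81 with the reference function of its own condition, surviving
Bonferroni correction over 8 conditions × 10 components.  Condition
specificity can then be tested with
`isps.compare_correlations(r1, r2, 208, 208)`, which returns the Fisher Z
statistic, its p-value and Cohen's q.

The same stages are available from the shell:

```bash
isps simulate --out ds --seed 1
isps sync --in ds --mask ds/mask.nii --out sync.nii
isps ica --sync sync.nii --mask ds/mask.nii --order 10 --out ica_out
isps associate --timecourses ica_out/time_courses.tsv --events ds/events.tsv --out assoc.tsv
```

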