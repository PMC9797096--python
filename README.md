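# seednets

Seed-region restricted group ICA for resting-state fMRI, with dual
regression, reference-network matching, and mixed-model statistics on
subregion co-activity.

## The problem

The amygdala is a small structure built from interconnected nuclei, and
conventional whole-brain functional-connectivity analyses treat it (or its
three large-scale divisions) as a unit, blurring over which nuclei drive
which resting-state networks.  `seednets` implements the data-driven
alternative: restrict a group spatial ICA to the voxels of the seed
structure, let the data reveal co-activity clusters that need not respect
nucleus boundaries, map each cluster to the whole brain, and only then ask
which nuclei carry each network and whether a behavioural covariate (here
self-reported fear) modulates nucleus co-activity.  The package is written
for researchers who want that analysis as a tested, reusable library rather
than a chain of shell tools, and it ships a synthetic-data generator with
full ground truth so every stage can be validated by parameter recovery.

## The method

1. **Preprocess** each session: hard DFT highpass (2000 s cutoff) and
   regression of CSF/WM mean time-courses.
2. **srICA**: concatenate the per-session seed matrices over time
   (each block demeaned, unit column SD) and factor `X = A S` by PCA
   whitening to `d` components plus fixed-point (log-cosh) ICA on the voxel
   dimension, so the rows of `S` are spatial maps over seed voxels.  Maps
   are z-scored and oriented to nonnegative skewness.
3. **Dual regression**: per session, regress each time point's seed pattern
   jointly on the maps (stage 1 time-courses), then each brain voxel on the
   time-courses (stage 2), giving per-subject beta/t/Z maps; a voxelwise
   one-sample test across subjects (sessions averaged) gives group Z maps,
   with optional sign-flip permutation p-values.
4. **Network matching**: Pearson-correlate each group Z map with binary
   reference templates over the brain mask; a component uniquely detects
   network n iff r(c,n) >= r* (default 0.4), all other r(c,m) < r*, and no
   other component beats it on n.  Sweep d and select the smallest order
   maximising the number of uniquely detected networks.
5. **Parcel statistics**: mean Z per region and hemisphere per subject is
   fitted with the mixed model
   `Z ~ hemisphere + FC_map * region + (1 | participant)` (REML, sum-to-zero
   coding, Type-III F with Satterthwaite df).  Effect contrasts (each map
   vs the mean of the others) list the regions of each network; summed
   pairwise subregion z-ratios, thresholded at > 0, rank the nuclei inside
   each network; a median split of fear scores with a
   Group x map x region model and Bonferroni post-hocs tests covariate
   effects; a session split replicates the maps in held-out data.

Details, assumptions and limitations are in `docs/methods.md`.

## Worked example

Run the whole pipeline on a synthetic cohort (12 subjects, 2 sessions,
3 embedded networks) and print the key results:

```python
import json
import seednets as sn
from seednets.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    output_dir="demo-out", d_min=1, d_max=8, rng_seed=0,
    synthetic=sn.SyntheticConfig(n_subjects=12, n_timepoints=150,
                                 rng_seed=42),
)
results = run_pipeline(cfg)
print(json.dumps({k: results[k] for k in
                  ("chosen_dimension", "n_unique_networks", "assignment",
                   "truth_assignment", "fear_significant_nuclei")}, indent=2))
```

prints

```json
{
  "chosen_dimension": 3,
  "n_unique_networks": 3,
  "assignment": {"0": 1, "1": 4, "2": 2},
  "truth_assignment": [1, 2, 4],
  "fear_significant_nuclei": ["Co"]
}
```

The sweep selected order 3 (the true number of embedded networks), all
three components were uniquely matched — component 0 to template 1,
component 1 to template 4, component 2 to template 2, exactly the set the
generator embedded — and the fear analysis flagged the cortical nucleus
(Co), the subregion whose coupling the generator boosted with the fear
score.  The ranking table (`demo-out/nucleus_ranking.tsv`) recovers the
generative loading order of every network:

```
fc_map subregion  summed_z_ratio  rank
   IC0       CAT      229.772512     1
   IC0        PL      187.944694     2
   IC0        Ba       96.153931     3
   IC1        Me      262.408222     1
   IC1        AB      186.375245     2
   IC2        Co      232.776774     1
   IC2       AAA      154.796675     2
   IC2        Ce       62.823681     3
```

Positive summed z-ratios mean a nucleus dominates the others within that
map; nuclei with non-positive sums are not listed.  `demo-out/` also holds
the full sweep table, match tables, region/nucleus ANOVA and contrast
tables, the split-session validation correlations and a run manifest with
seeds and the configuration hash.

The same stages are exposed on the command line
(`seednets simulate|preprocess|ica-sweep|dualreg|match|stats|fear|validate|all`
plus `seednets qc-filter`), configured by a YAML file with flag overrides.

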