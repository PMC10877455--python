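# depstrat

**Exact-k depression-criteria stratification of voxel-wise brain-imaging
group effects.**

Large cohort studies can define "lifetime depression" in many ways — help
seeking, self-report, antidepressant use, a symptom-based definition,
hospital ICD-10 F32/F33 codes, or a CIDI-SF screen — and imaging findings
vary with the choice. `depstrat` implements, as a reusable and fully
tested pipeline, a two-stage analysis that makes this variation
measurable:

1. **Stage 1 — voxel-wise inference.** Cases are split into six *disjoint*
   strata by the exact number k of criteria met. For each stratum,
   modality (fALFF, LCOR, GCOR, gray-matter volume) and direction, a
   covariate-adjusted (age, age², sex, TIV) Welch t map is thresholded at
   voxel p < .001 and cluster-level family-wise error is controlled at
   p < .05 with a max-cluster-extent permutation null — 48 tests per
   control strategy (pooled controls, or 1:1 matched on age/sex/education).
2. **Stage 2 — effect sizes and attribution.** Surviving clusters become
   binary masks (up to 12 per measure). For every criteria constellation
   (63 subsets; those with < 10 cases excluded), Cohen's
   d = (x̄_dep − x̄_ctrl)/s_pooled of the per-subject mask means is
   computed against the pooled controls. Each criterion's association is
   its **difference in effect size**: the unweighted mean d of
   constellations containing the criterion minus the mean of those lacking
   it, summarized per mask family as median [IQR].

Because per-subject cohort data of this kind are access-restricted, the
package ships a first-class synthetic cohort generator: six correlated
binary criteria from a latent-severity probit model (marginals patterned
on published biobank group counts), realistic demographics, and small 4D/3D
NIfTI volumes with planted, criterion-linked effects per modality — so the
whole chain is testable end to end against known ground truth.

## Worked example

Run the full pipeline on a synthetic cohort where a fALFF decrease is
planted on the antidepressant-use and ICD-10 criteria only (the packaged
recovery preset: 600 cases / 150 controls on a 24³ grid, ~30 s on one CPU):

```python
from depstrat.experiments import run_recovery_replicate
from depstrat.attribution import summarize_attribution

out = run_recovery_replicate(seed=7)
print("masks:", out.n_masks, "dice(union) = %.2f" % out.dice_union)
print(out.strata_table.query("mask_id == 'falff_decrease_k3'")
      [["group", "n_case", "cohens_d", "ci_low", "ci_high"]].to_string(index=False))
print(summarize_attribution(out.attribution).to_string(index=False))
```

which prints (exactly, for this seed):

```text
masks: 6 dice(union) = 0.61
group  n_case  cohens_d    ci_low   ci_high
   k1     123 -0.878081 -1.107818 -0.654626
   k2     138 -1.632932 -1.998797 -1.353418
   k3     155 -2.143202 -2.541730 -1.823422
   k4      95 -3.905878 -4.747994 -3.247140
   k5      64 -5.768397 -6.590288 -5.176556
   k6      25 -7.561136 -8.517708 -6.799501

criterion    median        q1        q3  n_masks
 helpseek -0.188535 -0.192717 -0.185799        6
  selfrep -1.266064 -1.353933 -1.230181        6
  antidep -3.869985 -4.154162 -3.762934        6
    smith -1.712191 -1.821784 -1.672742        6
    icd10 -4.007093 -4.287789 -3.898923        6
   cidisf -0.557628 -0.589145 -0.547981        6
```

Reading the output: all six stage-1 decrease masks survived FWE correction
and together overlap the planted sphere (Dice 0.61); Cohen's d for the
exact-k strata grows from −0.9 (one criterion met) to −7.6 (all six) —
more restrictive definitions mean stronger observed alterations; and the
per-criterion difference in effect size (median [IQR] over the six masks)
singles out the two loaded criteria, `icd10` (−4.01) and `antidep`
(−3.87), as carrying the effect, while criteria that merely co-occur with
them stay far behind.

Full runs — simulate → measures → stratify → stage 1 → stage 2 →
attribution, with TSV/NIfTI outputs and a checksummed manifest — go
through `run_all(RunConfig(...), out_dir)` or the shell:

```bash
depstrat simulate --config cfg.yaml --out cohort/   # TSV + NIfTI cohort
depstrat run-all  --config cfg.yaml --seed 21 --out run/
depstrat attribute --config cfg.yaml --out run/     # prints the summary
```

## Layout

| module | contents |
| --- | --- |
| `depstrat.cohort` | criteria/demographics/volume simulation (`SimulationConfig`, `generate_cohort`) |
| `depstrat.measures` | fALFF, LCOR, GCOR, relative GMV, mask-aware smoothing |
| `depstrat.stratify` | constellation lattice, exact-k strata, 1:1 matching |
| `depstrat.voxelstats` | residualization, Welch t maps, clusters, permutation FWE |
| `depstrat.effects` | mask means, Cohen's d with bootstrap CI, effect tables |
| `depstrat.attribution` | difference-in-effect-size per criterion, median [IQR] summaries |
| `depstrat.pipeline` / `depstrat.cli` | `RunConfig`, `run_all`, the `depstrat` command |
| `depstrat.experiments` | null-calibration and planted-recovery reference studies |

Methodological details and the reasoning behind every default live in
[`docs/methods.md`](docs/methods.md).
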