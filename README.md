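# melif

Automated MRI liver-function scoring: from multi-flip-angle spoiled
gradient-echo (SPGR) volumes to voxel-wise T1 reduction-rate maps and two
whole-liver function scores — the mean reduction rate `rrT1_liver (%)` and
the personalized `MELIF` score — together with the laboratory MELD
reference score and cohort-level diagnostic statistics (group summaries,
t-tests, Pearson/regression, ROC with DeLong CIs and Youden cutoffs).

Because no clinical data ship with this package, a first-class synthetic
phantom module generates paired pre/post-contrast liver T1 maps with
regional uptake heterogeneity, inter-phase deformation, Rician noise and
cohort-level group structure, so the entire pipeline is testable end to
end.

## Pipeline

1. **t1map** — linearized DESPOT1 fit of T1/proton-density maps from
   variable-flip-angle SPGR series, with optional relative-B1 correction.
2. **segmentation** — external liver-mask ingestion and validation, plus a
   classical Otsu-based segmenter adequate for phantoms (clinical
   segmentation is explicitly out of scope).
3. **register** — multi-resolution rigid (Powell on mutual information)
   plus a free-form deformable stage, aligning the post-contrast T1 map
   onto the pre-contrast grid.
4. **scoring** — voxel reduction rate `rr = (T1pre - T1postReg)/T1pre x 100`,
   whole-liver aggregation (`mean_pct` and a resolution-stable `integrated`
   convention on a 3.6 mm standard grid), the patient factor
   `f_p = h^0.6 / (w^0.3 V^0.6)` (m/kg/mL), `MELIF = 0.694 f_p rrT1_liver`,
   and a UNOS-style MELD calculator with the <=10 / 11-18 / >18 grouping.
5. **cohortstats** — descriptive summaries, D'Agostino-Pearson normality,
   unpaired t-tests, Pearson r with Fisher-z CIs, ROC/AUC with DeLong CIs
   and Youden-index cutoffs, assembled into a cohort report bundle.
6. **phantom / pipeline** — synthetic-data generation and the orchestrated,
   provenance-tracked per-patient and cohort runs.

All volumes are NIfTI; patient records are CSV; score reports and
provenance are JSON.

## CLI

```bash
melif simulate --out cohort/ --seed 1 --normal 2 --impaired 1 --severe 0
melif t1fit --series vfa.nii.gz --angles 2,15 --tr 5 --out t1.nii.gz
melif mask --image hbp.nii.gz --phantom-segment --out mask.nii.gz
melif register --fixed t1_pre.nii.gz --moving t1_post.nii.gz --out field.nii.gz
melif score --t1pre t1_pre.nii.gz --t1post t1_post.nii.gz \
            --mask mask.nii.gz --patient-csv cohort.csv --patient-id nor-0000
melif cohort-stats --table cohort_table.csv --out report/
melif run --config run.yaml        # full patient or cohort pipeline
```

`melif run` consumes a strict YAML/JSON config (`RunConfig`); pass
`manifest_path` for cohort mode.

## Conventions and caveats

- The `integrated` aggregation deliberately resamples fractional reduction
  rates onto a fixed 3.6 mm isotropic grid before summing; this makes the
  score resolution-independent and places MELIF on its conventional 20-80
  scale for typical adult livers.  The spacing is configurable
  (`--grid-mm`); the default is a documented reconstruction.
- The built-in segmenter is phantom-only.  Clinical masks are used exactly
  as supplied (no vessel/lesion handling).
- Registration is a classical scipy-based implementation (no external
  registration toolkit); the deformable stage is a demons-style free-form
  field driven by normalized gradient-magnitude images, robust to the
  contrast change between phases.
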