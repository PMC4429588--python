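# nucleimap

Morphometry, probabilistic atlasing and meta-analytic connectivity
modeling of the human deep cerebellar nuclei — the dentate (with its
dorsal/ventral parts), emboliform, globose and fastigial nuclei — as a
tested, end-to-end Python pipeline exercised on synthetic data.

The deep cerebellar nuclei are the cerebellum's output stage; mapping them
requires chaining several quantitative methods that are usually scattered
across histology and neuroimaging toolchains.  `nucleimap` implements that
chain for anatomists and neuroimagers who want each step reproducible and
testable:

* **Cell density** via the Grey Level Index,
  GLI = (segmented cell area)/(structure area), with Otsu segmentation and
  exact Wilcoxon signed-rank comparison of paired parts (dorsal vs ventral
  dentate);
* **Folding** via the Folding Index,
  FI = (contour perimeter)/(convex-hull perimeter) ≥ 1, equal to 1 exactly
  for convex outlines;
* **Volumetry** via the Cavalieri estimator
  V = Σ areaᵢ × (thickness × interval), shrinkage-corrected and
  brain-volume-normalised, with permutation tests (sex, hemisphere,
  interaction) under Benjamini–Hochberg FDR;
* **Atlas construction**: voxelwise probability maps
  p(v) = (subjects labelled at v)/N on a 1 mm reference grid, and
  maximum-probability-map (MPM) parcellations with audited tie-breaking;
* **MACM**: seed-filtered Activation Likelihood Estimation,
  ALE(v) = 1 − Πₑ(1 − MAₑ(v)) over per-experiment Gaussian modelled
  activation maps with sample-size-dependent FWHM, Monte-Carlo voxel nulls,
  cluster-level FWE correction, and seed-vs-seed contrasts;
* **Functional decoding**: exact binomial enrichment of behavioural-domain
  and paradigm-class labels against database base rates, FDR-corrected,
  with Fisher-exact profile contrasts.

A synthetic-data module generates every input with ground truth —
micrographs with planted cell-area fractions, denticulated contours,
ten-subject jittered label volumes, and coordinate databases with planted
co-activation links and label enrichments — so the full chain runs and is
verified without any external data.

## Worked example

```bash
nucleimap run --out demo_out
```

runs the whole synthetic study (simulate → morphometry → volumetry → atlas
→ MACM → decoding) and writes tables, NIfTI volumes, a report and a
reproducibility manifest.  The demo's `report.md` reads:

```
Simulated 400 experiments, 10 subjects, 6 micrographs.
Density: mean GLI dorsal 4.10%, ventral 3.40%; dorsal-vs-ventral adjusted p = 0.007812.
Folding Index: dorsal 1.70, ventral 1.71.
Volumetry: 4 nuclei; 0 significant group contrasts at FDR.
Atlas: max probability dentate 1.0, emboliform 0.7, globose 0.3, fastigial 0.7; MPM assigns 1644 voxels.
MACM dentate: 43 seed experiments, 2 FWE-significant clusters.
MACM interposed: 14 seed experiments, 2 FWE-significant clusters.
Decoding dentate: enriched domains ['action'].
Decoding interposed: enriched domains none.
```

Reading the numbers: the planted cell-area fractions (4.1% dorsal, 3.4%
ventral) are recovered by segmentation and the paired signed-rank test
flags the dorsal/ventral density difference (adjusted p < 0.05); the two
folding fixtures land at FI ≈ 1.7 despite different fold geometry; with
only ten subjects the volumes show no sex or hemisphere effect after FDR;
superimposing the jittered subjects gives full (probability 1.0) overlap
in the dentate core; the dentate-seeded ALE analysis finds two
FWE-significant clusters — the seed region itself (convergence by
construction) and the planted co-activation target — and decoding
recovers the domain planted at three times its base rate among the
seed-associated experiments.

The same steps are available as library calls (`nucleimap.synthdata`,
`.histomorph`, `.volumetry`, `.atlas`, `.macm`, `.decoding`,
`.pipeline`) and as individual CLI commands (`nucleimap simulate`, `gli`,
`fi`, `compare-density`, `volumes`, `volstats`, `probmap`, `mpm`,
`overlap`, `macm`, `decode`).

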