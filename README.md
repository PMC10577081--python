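# varmap

A variant-effect-map pipeline: from simulated saturation-mutagenesis
selection data, through tiled duplex variant counting and enrichment-ratio
functional scoring, to calibration of scores into ACMG/AMP clinical
evidence strengths and map-performance evaluation.

## The problem

Multiplexed assays of variant effect (MAVEs) measure the functional impact
of (nearly) every amino-acid substitution in a protein at once — for
example, by expressing a codon-randomized library of a human enzyme such as
HMBS (hydroxymethylbilane synthase, deficient in acute intermittent
porphyria) in a yeast strain whose growth depends on the human protein's
activity, growing the pool under selection, and sequencing short amplicon
tiles on both strands before and after selection.  The resulting *variant
effect map* can provide functional evidence for classifying clinical
missense variants, including variants that have never been observed in a
patient.

`varmap` implements the full analysis stack for this design, plus an
in-silico stand-in for the wet-lab experiment so that every stage is
testable end to end:

* **`varmap.synthetic`** — ground-truth fitness maps (bimodal missense
  scores, null nonsense, neutral synonymous, a small hyper-complementing
  fraction), Poisson clone libraries (mean 1.7 amino-acid changes per
  clone, two mutagenesis regions), exponential-growth selection, and tiled
  duplex sequencing with per-base errors.
* **`varmap.counting`** — duplex variant calling: a substitution is trusted
  only where both reads of a pair agree, with posterior
  `(1-e1)(1-e2) / [(1-e1)(1-e2) + e1*e2/3] > 0.9`; calls are translated
  per codon and tabulated into depth-normalised count tables.
* **`varmap.scoring`** — count filters (min count 10; 90th percentile of
  wild-type-control frequencies), wild-type background subtraction, the
  enrichment ratio `Φ = f_sel_adj / f_nonsel_adj`, and the functional
  impact score

  `FS = ln(Φ/Φ_STOP) / ln(Φ_SYN/Φ_STOP)`

  anchored per mutagenesis region so nonsense medians score 0 and
  synonymous medians score 1 (nonsense variants in the last 14 residues
  are excluded from `Φ_STOP`).  Replicate errors are regularised against a
  running-quantile trend; scores with σ > 0.3 or a pre-selection frequency
  below 0.005% are flagged out; isoform maps are rescaled (affine least
  squares) and combined by inverse-variance weighting, with a delta score
  per variant.
* **`varmap.calibration`** — positive/negative reference sets (including
  "proxy-benign" population variants: MAF < 0.0005, at least one
  homozygote, no annotations), Gaussian-KDE score densities, the log10
  likelihood ratio of pathogenicity `LLRp(s) = log10(π+(s)/π−(s))`, and a
  Tavtigian-style Bayesian point-system solver that maps LLRp to ACMG/AMP
  evidence strengths at a global prior of 0.1.
* **`varmap.evaluation`** — ROC/AUROC with a DeLong paired test, balanced
  precision-recall (`balanced precision = TPR/(TPR+FPR)`) with AUBPRC and
  R90BP, Mann-Whitney set comparisons, moving-window positional profiles,
  solvent-accessibility classes, predictor normalisation, and
  allele-depletion odds ratios.

## Worked example

```python
import numpy as np
import varmap as vm

# 1. simulate a full experiment and recover the map
res = vm.run_recovery(seed=1, depth_per_tile=500_000)
print(f"Spearman vs truth: {res.spearman:.3f}   RMSE: {res.rmse:.3f}")
print(f"nonsense median: {res.nonsense_median:.3f}   "
      f"synonymous median: {res.synonymous_median:.3f}")

# 2. calibrate scores against reference sets and derive evidence cuts
rng = np.random.default_rng(1)
pathogenic = rng.normal(0.15, 0.15, 53)   # low scores = damaging
benign = rng.normal(0.95, 0.15, 13)
calib = vm.estimate_densities(pathogenic, benign)
cuts = vm.solve_acmg_thresholds(prior=0.1)
print({k: round(v, 2) for k, v in cuts.llr_cuts.items()})
print(vm.assign_evidence(0.05, calib, cuts))
```

prints

```
Spearman vs truth: 0.969   RMSE: 0.029
nonsense median: 0.003   synonymous median: 1.001
{'PVSt': 2.54, 'PSt': 1.27, 'PM': 0.64, 'PSu': 0.32, 'BSu': -0.32, 'BSt': -1.27}
('pathogenic_very_strong', 5.85..., False)
```

The recovery run simulates two mutagenesis regions x two replicates x two
isoforms at 5x10^5 read pairs per tile and 10^6 clones per regional pool,
scores each isoform map, rescales and combines them, and compares the
combined map with the generating truth.  The evidence cuts say, e.g., that
an LLRp above 0.64 is moderate evidence of pathogenicity and an LLRp below
-0.32 is supporting evidence of benignity.

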