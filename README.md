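# rubiscope

Analysis toolkit for large-scale enzyme kinetic surveys of rubisco
(ribulose-1,5-bisphosphate carboxylase/oxygenase), built around the
question of whether fast-carboxylating variants exist anywhere in the
enzyme's natural sequence diversity.  The package implements, as a
tested reusable library, the computational chain such a survey needs:

1. **Sequence space** (`rubiscope.seqspace`) — aligned-sequence data
   model, Hamming identity on alignments (shared-gap columns excluded,
   gap-vs-residue mismatching), >95%-gap column trimming, greedy
   centroid clustering at an identity threshold, and the
   *diversity-coverage* metric: the fraction of 90%-identity cluster
   representatives that share at least X identity with any kinetically
   characterized variant.
2. **Kinetics harmonization** (`rubiscope.kinetics`) — carboxylation
   rates (k<sub>cat,C</sub>, s⁻¹) from heterogeneous assays brought to a
   common scale: Q₁₀ temperature correction to 30 °C
   (k′ = k·Q₁₀^((30−T)/10), Q₁₀ = 2.2), per-batch normalization to a
   control variant (geometric mean), and a coupled-to-direct assay
   correction fitted as a log–log comparison with the slope fixed to 1 —
   i.e. the geometric-mean ratio exp(mean(ln k_direct − ln k_coupled))
   with a t-interval on the log-ratios.
3. **Rate prediction** (`rubiscope.predict`) — nearest-neighbour,
   unweighted-mean, identity-weighted-mean
   (w = exp(−λ(1−identity))) and RBF-kernel SVR models on one-hot
   encoded alignment columns, all in natural-log rate space; an
   identity-thresholded leave-one-out benchmark (training restricted to
   variants with identity ≥ X to the target) reporting ln-space RMSE and
   its fold-change equivalent exp(RMSE); per-form prediction of
   uncharacterized variants.
4. **Position association** (`rubiscope.association` +
   `rubiscope.shapley`) — 100 random 75/25 splits, a depth-3 regression
   tree per split, **exact** Shapley attribution of each held-out
   prediction (conditional-expectation tree traversal with full
   coalition enumeration, so attributions + base value reproduce the
   tree output to machine precision), aggregated per alignment position
   and mapped to reference-sequence residue numbering; Kruskal–Wallis +
   Dunn statistics for rate-by-residue comparisons.
5. **Synthetic surveys** (`rubiscope.synthetic`) — a seeded generator of
   survey-shaped data: a form-structured coalescent forest, sequences
   under a uniform 20-state substitution model, a latent ln-rate
   evolving as Brownian motion (phylogenetic signal: similar sequences,
   similar rates), optional planted causal residues, and a realistic
   observation model (assay bias β, batch scaling, log-normal noise,
   off-target temperatures).  Every analysis above is validated by
   recovering what the generator injected.
6. **Orchestration** (`rubiscope.pipeline`, CLI `rubiscope`) — the full
   chain on files, each output stamped with a config hash and seed.

## Worked example

Harmonizing a simulated survey and checking the recovered assay bias
(`python examples/02_rate_harmonization.py`):

```
33 raw coupled-assay observations, temperatures 17.2-32.6 degC

assay correction: x2.19 (95% CI 1.93-2.48, n = 11); injected bias was x2.1
  form I       n=  9 median   3.8 s^-1 [3.5, 5.2]
  form II      n=  6 median   6.5 s^-1 [4.4, 10.1]
  form II/III  n=  5 median  15.0 s^-1 [14.0, 17.8]
  form III     n=  5 median   2.7 s^-1 [2.5, 4.8]

recovered vs true ln-rates: RMSE = 0.283 (observation noise was 0.2)
```

The correction factor fitted from 11 variants measured by both assay
routes (×2.19) recovers the injected 2.1-fold coupled-assay
underestimation within its confidence interval, and the harmonized
per-variant rates sit within measurement noise of the simulated truth.
The remaining examples cover clustering/coverage
(`01_sequence_space.py`), the identity-thresholded prediction benchmark
(`03_rate_prediction.py`), planted-position recovery with exact Shapley
attribution (`04_position_association.py`), and the end-to-end pipeline
on files (`05_full_pipeline.py`).

## Command-line interface

```bash
rubiscope simulate --out survey/ --seed 7        # write a synthetic survey
rubiscope cluster survey/alignment.fasta --threshold 0.9
rubiscope coverage reps.fasta characterized.fasta --thresholds 0.5:1.0:0.05
rubiscope fit-correction survey/pairs.csv
rubiscope normalize survey/rates.csv --control-id control --control-reference 2.4 --out norm.csv
rubiscope summarize norm.csv --metadata survey/metadata.tsv
rubiscope run-full --config pipeline.json
```

The CLI is a thin layer; the library functions are the primary
interface.
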