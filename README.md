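# chmcs — compact hybrid multi-color-space texture classification

`chmcs` classifies color textures — tree bark species, wood grades, surface
materials — without requiring the user to pre-commit to a color space, a
texture descriptor or a parameter setting. Those prior choices strongly
affect accuracy and the right one varies from task to task. Instead, the
package extracts features from **many configurations at once** and lets a
selection stage find the compact subset that discriminates the classes at
hand.

## The method

Two classical descriptor families are computed in five device-dependent
color spaces (RGB, HSV, YCbCr, Ohta I1I2I3, normalized RnGnBn):

* **RSCCM** — reduced-size chromatic cooccurrence matrices: Q×Q normalized
  histograms of quantized value pairs between a pixel in channel `Cg` and
  its 8 isotropic neighbors at distance δ in channel `Cg'`, for the 6
  unordered channel pairs and 25 settings `(δ, Q) ∈ {1,2,3,5,10} ×
  {16,32,64,128,256}`. Each matrix yields 13 Haralick statistics.
* **EOCLBP** — extended opponent-color local binary patterns: P-bit codes
  thresholding a pre-sampled circle of radius δ in channel `Cg'` against the
  center in `Cg`, for all 9 ordered channel pairs and 13 settings `(P, δ)`.
  Each code histogram yields 17 statistics (6 first-order, 11 Haralick-style
  second-order).

The full hybrid bank has

    D = Nspac × Σ_p Npair_p × Npara_p × Nfeat_p
      = 5 × (6×25×13 + 9×13×17) = 19,695

features. **CEFS** (clustering-based embedded feature selection) then
reduces it: features are clustered as connected components of the
`|Pearson ρ| > t` dependency graph (t chosen automatically by maximizing a
cluster separability/compactness criterion `Tr = trace((W+B)⁻¹B)`); a
sequential forward search adds, at each step, the candidate maximizing the
class-separability trace of the growing subset and removes the whole cluster
of the added feature; the final dimension `d̂` maximizes the mean validation
accuracy `R̄_d` of a 1-NN/L1 classifier over repeated stratified K folds.

## Worked example

Generate a synthetic 4-class texture dataset (64×64 images; classes differ
subtly in spatial frequency, orientation and channel correlation, with heavy
within-class variation), extract a reduced hybrid bank (2 spaces × 4 RSCCM
settings × 4 EOCLBP settings), select and evaluate:

```sh
chmcs synth --out demo/images
chmcs extract --manifest demo/images/manifest.csv --config demo/config.json --out features.csv
chmcs select  --features features.csv --config demo/config.json --out selection.json
chmcs eval    --features features.csv --selection selection.json --out eval.json
```

With the configuration above (seed 1) this prints:

```
INFO chmcs: extracted 80 images x 1848 features in 4.00 s
INFO chmcs: selected 30 features (d_hat=7, t_hat=0.95, 727 clusters); report in selection.json
INFO chmcs: test accuracy 85.00% on 40 images; report in eval.json
```

The 1848 extracted features collapse into 727 correlation clusters at the
automatically chosen threshold 0.95; the greedy search keeps 7 of them
(`d_hat=7`, where the validation curve `R̄_d` peaks), and that 7-feature
compact descriptor classifies 85% of the held-out images. For comparison,
the best *single* predetermined configuration (one space, one descriptor,
one setting) reaches 75% on the same split and the average one 48% — the
gain from combining configurations is exactly what the selection stage is
for. The report lists the selected features with full provenance, e.g.
`RSCCM|RGB|C2C3|d1q32|correlation` (correlation of the fine-scale G/B
cooccurrence matrix in RGB).

The same pipeline is available as library calls: `extract_dataset` /
`extract_image`, `run_cefs`, `evaluate_split` (see the module docstrings).

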