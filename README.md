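# endocoloc

Quantitative triple-channel colocalization analysis of endosomal
integrin signaling platforms in fluorescence micrographs.

## The problem

Detached, anoikis-resistant cancer cells keep integrin survival signaling
alive on endosomes: activated integrin clusters are endocytosed and, on
Rab5-positive early endosomes, recruit phosphorylated focal adhesion
kinase (pFAK). In three-channel confocal images — an integrin-targeting
AIE–cRGD probe, a pFAK immunostain and a Rab5 marker — these platforms
show up as puncta that are positive in all three channels at once.
`endocoloc` quantifies them:

- **Effective pixels** — pixels whose intensity exceeds a threshold
  (strictly `> 0` by default) in *all three* channels; their count is N₀.
- **Colocalization rate indices** — N₀/N_R, N₀/N_G, N₀/N_B, where N_R,
  N_G, N_B count pixels above threshold in the pFAK, Rab5 and probe
  channels respectively (red/green/blue pseudo-color convention).
- **Colocation islands** — maximal connected components of effective
  pixels (8-connectivity by default), each interpreted as one endosomal
  signaling platform, with per-island intensity statistics and
  bounding-box patches for 3-D surface plots.
- **Intensity model** — pooled over images, the pFAK intensity at
  effective pixels is regressed on the probe intensity with the quadratic

  N_pFAK = a₀ + a₁·N_AIE-cRGD + a₂·N²_AIE-cRGD ,

  reference coefficients (a₀, a₁, a₂) = (125.86, 0.346, −2.99×10⁻⁵),
  with bootstrap standard errors and a seeded permutation test of the
  positive correlation. The fitted curve lets the probe signal alone
  quantify endosomal pFAK recruitment.
- **Pairwise Pearson/Manders coefficients**, Bresenham line profiles,
  group comparison of rate indices (e.g. detached "model" cells vs
  attached controls) with a permutation test, and a fold-change utility.

Because no real image data are distributed, a synthetic micrograph
generator renders 512×512 px, 12-bit three-channel images of Gaussian
puncta with known ground truth — channel memberships, peak intensities
and the quadratic probe→pFAK coupling — so every stage is testable end
to end.

## Worked example

Simulate 22 images under the default conditions and run the full
pipeline (simulate → mask → counts → islands → pairs → fit → report):

```sh
cat > run.yaml <<EOF
simulation: {n_puncta: 40.0}
n_images: 22
seed: 1
permutations: 999
out_dir: run_out
EOF
coloc run --config run.yaml
```

which prints (numbers exactly reproducible from the seed):

```json
{
 "images": 22,
 "fit": {
  "a0": 181.02107593633536,
  "a1": 0.30640423819450036,
  "a2": -2.2977909471743677e-05,
  "degree": 2,
  "n_points": 516,
  "r2": 0.6981400747859838,
  "pearson_r": 0.8305431145313119,
  "residual_sd": 150.73524959658846
 }
}
```

516 colocation islands were found across the 22 images; fitting their
peak (probe, pFAK) intensity pairs recovers the generating coupling
(125.86, 0.346, −2.99×10⁻⁵) well within its bootstrap uncertainty — the
scatter (residual sd ≈ 151) comes from overlapping puncta merging into
single islands, not from the fit. The strong positive correlation
(Pearson r ≈ 0.83) is what makes the probe channel a usable proxy for
endosomal pFAK. `run_out/` contains `counts.csv` (per-image N₀, N_R,
N_G, N_B and rate indices), `islands.csv`, `pairs.csv`, `fit.json` and
`report.json`; the first rows of `counts.csv`:

```
source_id,n0,n_r,n_g,n_b,rate_r,rate_g,rate_b,threshold
sim_000,2771,3400,3361,3184,0.815,0.8244570068432014,0.8702889447236181,0.0
sim_001,2172,3461,3352,3276,0.6275642877780988,0.6479713603818615,0.663003663003663,0.0
```

Other subcommands: `coloc simulate` (dataset + ground truth + manifest),
`coloc stats`, `coloc islands`, `coloc fit`, `coloc compare`. The same
functionality is available as a library (`import endocoloc`).

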