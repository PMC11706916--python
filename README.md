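# cropsift

Classify archaeobotanical samples by crop-processing stage from weed-seed
attributes.

Harvested cereals and pulses pass through winnowing, coarse sieving and fine
sieving; each step leaves a characteristic fingerprint in the weed seeds that
accompany the crop, summarised by six attribute combinations of seed size
(Big/Small), tendency to remain in heads (Headed/Free) and aerodynamics
(Heavy/Light): **BHH, BFH, SHH, SHL, SFH, SFL**. `cropsift` implements the
complete workflow:

- **I/O and screening** (`cropsift.io`): read taxon × sample count CSVs,
  apply minimum-item filters, label samples by crop dominance (80 %
  threshold for barley / free-threshing cereal / pulses / mixed), write
  results.
- **Attribute transform** (`cropsift.transform`): per sample, each
  classifiable weed taxon contributes the square root of its percentage of
  classifiable weed seeds; contributions are summed per attribute code
  (sum-of-roots, *not* root-of-sum).
- **Discriminant engine** (`cropsift.lda`): from-scratch LDA — group means,
  unbiased pooled within-group covariance (divisor *n − G*), sphered
  between/within eigenproblem, unit within-group variance scalings,
  shared-covariance Gaussian posteriors with a log-sum-exp guard.
  Discriminant signs are oriented deterministically (largest loading
  positive) since signs are arbitrary across statistical software.
- **Classification** (`cropsift.classify`): the four-group procedure
  (model fitted on the ethnographic reference; samples classified as
  winnowing by-product / coarse sieve by-product / fine sieve by-product /
  fine sieve product) and the five-group procedure (archaeological samples
  included as a fifth group at the discrimination stage, then reclassified,
  to probe non-crop-processing origins such as dung burning). Includes
  classification tables and taxon-removal re-runs with change reports.
- **Ternary plots** (`cropsift.triplot`): grain : rachis : weed-seed
  proportions, side-by-side with the ethnographic proportions.
- **Score plots** (`cropsift.viz`): 2D and 3D discriminant-score plots; the
  five-group method gets its own reference coordinates by construction.
- **Synthetic fixtures** (`cropsift.synthetic`): compound-multinomial
  generators for ethnographic-like reference sets and archaeological
  assemblages (with an optional contamination component), so everything is
  testable without the published data files.

## CLI

```sh
# generate synthetic fixtures
cropsift simulate --seed 3 --out-dir fixtures/

# counts -> six-attribute scores
cropsift transform --counts fixtures/arch_counts.csv \
    --first-sample-column arch_1 --min-seeds 10 --out scores.csv

# classify (four-group "jones" or five-group "charles" method)
cropsift classify --counts fixtures/arch_counts.csv \
    --first-sample-column arch_1 \
    --reference fixtures/reference_attributes.csv \
    --method jones --min-seeds 10 --out-dir results/

# ternary plot with a highlighted sample
cropsift triplot --table triplot_totals.csv --min-items 30 \
    --highlight 478 --out triplot.png

# discriminant-score plot from saved results
cropsift plot --results-dir results/ --axes 1,2 --out scores.png
```

All flags can also come from a YAML file via `--config`; explicit flags win.
Each run writes a `manifest.json` (version, seed, resolved options, config
hash) next to its outputs.

## Published data

The ethnographic reference table and the two worked-example site datasets
are journal supplements and are not redistributable here. If you download
them, convert them to CSV and place them under `data/supplements/` with the
names documented in `cropsift.supplements`; the reproduction tests and the
full acceptance report will then run against the real data.

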