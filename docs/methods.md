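# Methods

## Counting model and exclusion rules

The unit of analysis is one tracer deposit (an *injection case*). Charted
labeling is reduced to per-(hemisphere, area) counts, with two exclusion
rules applied consistently throughout:

- **Ipsilaterally**, neurons inside the injected area are excluded from all
  counts and distributions (they reflect local/intrinsic labeling, not
  afferents from other areas). They are tallied and reported
  (`n_excluded_injected`), never silently dropped.
- **Contralaterally**, nothing is excluded from the aggregate counts — the
  same-named area is the *homotopic* area and its neurons are CPNs like any
  others — but the homotopic area is excluded from the contralateral
  percentage distribution, so that distribution describes the *heterotopic*
  spread only.

%CPN is `100·contra/(ipsi+contra)` and the homotopic fraction
`100·homotopic/contra`. A case with `contra = 0` has an *undefined*
homotopic fraction, surfaced as NaN (empty CSV cell / JSON null): absence
of callosal labeling is not evidence of 0% homotopy.

### Homotopy and injection subfields

Homotopy is the identity on area names (an involution). Injections are
sometimes recorded at subfield grain (e.g. `46d (r)`, rostral 46d) while
labeling is charted at area grain. Subfield units therefore carry a
`parent` pointing at their area-level unit, and aggregation counts the
whole contralateral parent area (`46d`) as homotopic. This is a convention:
whether published homotopic counts for subfield injections cover the whole
mirror area or only the mirror subfield is not documented; counting the
whole area is the only option available when records are area-level.

### Laterality index

For each area holding strictly more than `min_ipsi_pct` (default 1%) of the
ipsilateral distribution (computed after the injected-area exclusion), the
index is `contra_count/ipsi_count`. The filter is applied strictly (an
area at exactly 1% is out) and areas labeled only contralaterally can never
pass it; those are reported separately (`contra_only_areas`) so no labeling
is lost from view. Values above 1 are legitimate (contralateral-dominant
input) and do occur.

## Laminar classification

Each projection's laminar origin is summarized by the superficial fraction
s/(s+d), where s counts labeled neurons in layers II–III and d in layers
V–VI, on sections taken every `sampling_um` (default 300 µm, configurable
phase) — one section per repeating series, as cut. Neurons without a layer
assignment are tallied and excluded from the fraction.

The hierarchical classes are defined qualitatively in the source
literature ("mainly superficial", "more equally distributed"); the numeric
boundaries here are a symmetric convention, exposed as parameters and
echoed in every output:

| parameter | default | meaning |
|---|---|---|
| `ff_threshold` | 0.70 | s-fraction ≥ this ⇒ feedforward (closed bound) |
| `fb_threshold` | 0.30 | s-fraction ≤ this ⇒ feedback (closed bound) |
| `min_neurons` | 20 | fewer assigned neurons ⇒ indeterminate |

`min_neurons` guards against classifying sampling noise; classification is
monotone in the s-fraction by construction. Contralateral connections whose
class differs from the determinate ipsilateral class of the same source
area are flagged (`differs_from_ipsi`). Published per-connection class
tables cannot be regenerated without the raw charts, so laminar validation
is property-based on synthetic data (≥95% recovery of designed classes at
s-fractions 0.85/0.50/0.15 with ≥200 neurons per connection).

## Group statistics

- **Correlations** are plain product-moment r with the two-sided t test
  (n−2 df). %CPN values entering correlations are recomputed at full
  precision from counts, never read back from rounded report columns.
- **Region summaries** are mean/min/max %CPN per region; presentation
  rounds the mean to the nearest integer. The premotor region excludes F1
  by construction (F1 is its own region class), and the parietal summary is
  also reported with the two weakly-callosal PF cases excluded. On the
  bundled counts, the premotor mean is 13.84 → 14 (range 7.7–18.1) and the
  PF-excluded parietal mean 8.79 → 9 (range 4.6–15.1). The prefrontal mean
  computes to 16.3 (range 6.4–25.8); the source report gives 17 for this
  group, a value we cannot reproduce from the printed counts under any
  rounding path, so it is documented here rather than asserted.
- **Rate-ratio regression.** Contralateral counts are modeled as
  NB2: `contra_i ~ NB(mu_i, alpha)`, `log mu_i = log(total_i) + beta_g(i)`,
  variance `mu + alpha·mu²`, with alpha estimated by maximum likelihood
  (Newton, tolerance 1e-8, ≤100 iterations; fit via statsmodels). Group
  membership follows the region class of the injected area: prefrontal
  (9 cases), premotor (10, F1 excluded), parietal (12, including PF); F1
  and frontal opercular cases are excluded. All three pairwise contrasts
  are exponentiated into rate ratios with Wald p-values,
  Benjamini–Hochberg-adjusted across exactly those three. On the bundled
  counts: parietal-vs-prefrontal 0.4605, parietal-vs-premotor 0.5419,
  alpha ≈ 0.264. The source's p-values are not reproducible (its dispersion
  estimator and contrast scheme are unspecified) and are not asserted; the
  ratios are. When ML drives alpha to the zero boundary (equidispersed
  data) with a vanishing gradient, the fit falls back to the Poisson limit,
  which is the NB2 model at alpha = 0.
- `dispersion=0` selects a Poisson GLM and a fixed positive value a
  NB-family GLM, used for oracle checks and for fitting with known alpha.

## Synthetic data generator

The generator emulates the *structure* of charted bilateral labeling, not
its anatomy:

- case total ~ gamma-Poisson (NB2, default dispersion 0.2 — of the order
  estimated from the bundled counts);
- total → contra split binomially by the true %CPN; contra → homotopic
  split binomially by the true homotopic share;
- heterotopic and ipsilateral neurons scatter multinomially over
  configurable area weights (the 36-case suite uses harmonically decaying
  weights over same-region areas plus a cingulate term, echoing the
  adjacency-dominated spread of real labeling);
- sections uniform on a regular grid (default 300 µm spacing); layers
  Bernoulli per (hemisphere, area) s-fraction with a 5% unknown-layer rate
  to exercise exclusion paths.

Per-case generators derive from `(master_seed, case_index)`, so any case is
independently reproducible. The generator has no spatial structure within
areas, no per-area extra-dispersion, no tracer-chemistry effects, and its
laminar fractions are exchangeable across sections; passing recovery tests
therefore validates the *pipeline arithmetic and estimator behavior*, not
anatomical claims about real charts.

Test and acceptance problem sizes: 200 replicates at mean_total 10 000 for
%CPN bias (binomial SE ≈ 0.03 points, well inside the ±0.5 bound), 200
connections for laminar recovery, 200 replicates of n=12-per-group NB fits
for rate-ratio recovery.

## Numerical conventions

- Report columns round half-up (ties away from zero) to 1 decimal, as the
  reference tables print; all internal computation is full precision.
- Missing values are empty CSV cells and JSON nulls, never sentinels.
- CSV dialect: UTF-8, comma-separated, header row, decimal point, no
  thousands separators.
- CLI exit codes: 2 schema errors, 3 referential errors, 4 numeric errors;
  every report directory gets a `params.json` sidecar recording the
  thresholds and exclusion rules used.

## Known limitations

- Region assignment of a case rests entirely on the input parcellation
  labels; no architectonic inference is attempted.
- Whether the 600-µm areal-count series and the 300-µm laminar series share
  neurons is dataset-specific; records store raw section positions and each
  analysis selects its own grid, with no merging policy imposed.
- The laterality index is undefined for areas below the ipsilateral filter,
  so heatmaps are sparse by design; homotopic cells are masked, not zero.
- Tracer-efficiency differences across tracers are not modeled; the
  total-vs-%CPN correlation is the only guard against them, as in the
  source analysis.
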