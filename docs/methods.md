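# Methods

## Model and procedure

The pipeline estimates where marker-gene-expressing cells are located
anatomically by combining two measurements of the same tissue made at
different resolutions. The single-cell RNA-seq table measures the
marker directly but localises cells only to a coarse dissection region;
the spatial table localises cells to CCF structures but does not
measure the marker. The bridge is the shared cell-type taxonomy: both
datasets label every cell with a cluster id.

Stage 1 treats marker detection within cluster *k* as Bernoulli with
probability f_k, estimated as the observed positive fraction
n_pos,k / n_total,k among region cells at threshold τ. Stage 2 assumes
cluster-conditional exchangeability across modalities: a spatial cell of
cluster *k* is marker-positive with the same probability f_k, so the
expected positive count in structure *s* is the linear form
E[s] = Σ_k n[s,k]·f_k. This assumption — that detection probability
depends on cell type but not on modality or location within the region —
is the method's substantive leap and is not itself testable inside the
pipeline.

## Parameters

- **τ (positivity threshold)**, integer ≥ 1, default 1. Applied to raw
  counts, never normalised values: the criterion is "any non-zero
  expression", and a detection threshold on raw counts keeps the
  definition identical across clusters of different sequencing depth.
- **Region**, default `OLF`. Prevalence denominators are restricted to
  the region by default so that detection conditions in numerator and
  denominator match; `region_restricted_denominator=False` switches to
  whole-table denominators for sensitivity analysis.
- **ci_level**, default 0.95. The Jeffreys interval is an artifact
  addition used for uncertainty reporting and the recovery tests; the
  imputation consumes only the point estimate f_k.
- **min_n_pos**, default 1. A cluster is carried into the spatial
  cross-reference when it has at least this many positive single-cell
  cells; prior detection is the only relevance criterion applied.
- **sections / structures**: the spatial reader keeps only configured
  section ids (empty = all) and rolls raw structure acronyms onto the
  target set.

## Numerical choices

- Jeffreys interval: equal-tailed Beta(x+½, n−x+½) quantiles with the
  standard boundary modification (lower limit 0 when x = 0, upper limit
  1 when x = n), so the interval always contains the point estimate.
- Structure roll-up: an explicit acronym map takes precedence; otherwise
  the longest configured target that is a prefix of the raw acronym
  wins (layer acronyms such as `MOB-gl` or `AONd` resolve to their
  parent). The map is idempotent by construction. Real atlas runs
  should supply the release's parcellation-term table instead of
  relying on prefixes.
- Unknown cluster ids are an error in strict mode (the default) and
  resolve to the `unassigned` class with a warning in lenient mode.
  Spatial clusters absent from the prevalence table are never silently
  imputed at f = 0: strict mode aborts, lenient mode excludes with a
  warning.
- Expected counts are reported unrounded; `--round` applies half-even
  rounding for display only. Fractions are serialised with 12
  significant digits; integer and string columns round-trip
  bit-identically.
- Degenerate inputs (no cells in region, no positives, no retained
  spatial rows, no relevant clusters) raise dedicated empty-result
  errors rather than returning empty tables, because every downstream
  quantity would be undefined.

## Synthetic data

The generator emulates exactly what the analysis assumes: per-cluster
Bernoulli positivity p_k with positive counts drawn as
1 + Poisson(λ) (λ = 1 by default — the analysis only thresholds counts,
and the +1 keeps τ > 1 experiments meaningful), per-structure cluster
mixtures θ_{s,·}, and independent section assignment. Two RNG
substreams are spawned from the one seed so resizing one table never
perturbs the other. It does **not** emulate full transcriptomes,
batch or section effects, segmentation errors, doublets, or spatial
autocorrelation — so passing recovery tests show the estimator is
correct under the model's own assumptions, not that the assumptions
hold in real tissue.

Two reference specs ship with the package. `toy_spec`/`toy_tables` is
the deterministic 11-cell / 29-cell worked example used throughout the
tests and docs. `study_spec` is the study-scale default: six clusters
(two glutamatergic, two GABAergic, one dopaminergic, one unassigned)
sized and parameterised so the expected marker-positive population is
133 cells split 76/20/2/2 percent across classes, with structure
mixtures placing roughly equal expected glutamatergic and GABAergic
positives in the MOB (GABAergic granule-type clusters dominate its cell
count at about a tenth of the glutamatergic positivity rate) and
predominantly glutamatergic positives in the AOB and AON, over five
equally weighted sections. Sizes (7,500 single-cell and 5,800 spatial
cells) keep a full run under a couple of seconds while leaving relative
sampling error on per-structure expectations near ten percent.

## Testing strategy

Exact results (counts, fractions, expected counts) are checked against
naive per-cell Python loops on both the hand-derived fixture and fifty
seeded random simulations. The Jeffreys implementation is
cross-checked against statsmodels on interior cases. Statistical
behaviour is checked by recovery: over 100 seeds at 2,000 cells per
cluster the true p_k must fall inside the 99% interval in at least 97
seeds per cluster, and the mean imputation error must sit within three
standard errors of zero.

## Known limitations

- Cross-modal exchangeability is assumed, not tested; platform
  sensitivity differences between scRNA-seq and MERFISH would bias E[s]
  multiplicatively per cluster.
- E[s] treats f_k as known; its sampling error from Stage 1 is not
  propagated into an interval for E[s].
- Single marker per run; no co-expression logic, spatial smoothing, or
  per-layer breakdown within a target structure.
- The real-data adapter reads a local h5ad and metadata tables; atlas
  version pinning and downloading are the caller's responsibility.
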