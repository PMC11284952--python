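# Methods

This note records the models implemented by `timetopo`, the assumptions
behind them, the defaults and why they were chosen, and the places where
the design was genuinely open.

## Tissue geometry

Coordinates are micrometres in a planar slide frame (y increasing
downward, the convention of common cell-detection exports; only distances
and areas are used, so orientation never matters). All polygon work is
done with shapely; areas are reported in mm² (1 mm² = 10⁶ µm²).

**Tumor area.** Union of the tumor-field polygons, interior rings filled
(stroma completely enclosed by tumor belongs to the tumor area), then
buffered outward by `tumor_area_buffer` (default 250 µm — the stromal
collar beyond the outer tumor cells). Fields farther apart than twice the
buffer stay separate components. Buffering uses ≥ 16 segments per quarter
circle; the 1% tolerances quoted for the circle closed forms cover this
discretization (at `quad_segs=16` a buffered circle's area is within
≈ 0.1% of πr²).

**Invasive margin.** The margin is a band of total width
2 × `margin_halfwidth` (default 2 × 250 = 500 µm) straddling the outer
tumor-field contour: all points within 250 µm of the boundary of the
filled field union, clipped to the tumor area. Two readings of the margin
are defensible — a band centred on the tumor-field contour, or the outer
500 µm layer of the tumor area itself. The constructive contour reading is
the default (`margin_mode="contour"`) because the band is drawn from the
outlined tumor front; `margin_mode="area_boundary"` implements the
alternative. For a circular field of radius r with a 250 µm collar, the
contour reading gives margin = annulus (r − 250, r + 250), so the two
coincide on convex landscapes. Interior holes are filled *before* taking
the contour so that stroma islands fully inside the tumor do not spawn
margin bands: the margin is the invasion front, not internal texture.

**Tumor center.** Tumor area minus invasive margin. If the band consumes
the whole tumor area (fields smaller than the halfwidth), the margin is
the tumor area, the center is empty, and this is logged; center densities
become missing rather than zero.

**Cell assignment.** Point-in-polygon includes the boundary
(`shapely.covers`). Zones have disjoint interiors, so ties are
measure-zero; they resolve by the deterministic precedence margin > center
and field > stroma. Cells outside the tumor area are labelled `outside`
and excluded from all tumor-area metrics.

**Biopsies** sample the tumor center only: no margin is constructed, only
whole-tissue and field/stroma metrics are computed, and immunotyping is
refused rather than guessed.

## Immunotype decision tree

The label is a total function of three CD8 densities (cells/mm²): tumor
center (TC), tumor fields across the whole tumor area (TF), invasive
margin (IM). Thresholds default to TC > 100, TF > 82.8, IM > 200, all
strict — the published wording is "more than" / "higher than", so equality
falls to the lower branch. The TF threshold is a *cohort median*, not a
universal constant; `tf_cd8_threshold_mode="cohort_median"` recomputes it
as the median TF CD8 density over the cohort's resections, while the
default `"fixed"` mode uses the printed 82.8. The decision path is
recorded on every call so a label can be audited and re-derived.

## Distance statistics

AMD(reference → target) is the mean over reference cells of the Euclidean
centroid-to-centroid distance to the nearest target cell; it is asymmetric
by construction. When reference and target phenotypes coincide each cell's
own entry is excluded. An empty target set yields a missing value, never
infinity. No edge correction is applied — references near the tissue
boundary have upward-biased minima; the Poisson validation below therefore
restricts reference points to an interior window. The radius fraction is
the share of a counted population with ≥ 1 probe cell at distance ≤ r
(boundary inclusive), r = 10 µm by default; an empty probe set gives 0,
an empty counted set a missing value. Queries use a k-d tree and are
tested to agree bit-for-bit with the O(n²) definition.

Validation anchor: for a homogeneous Poisson process of intensity λ the
mean nearest-neighbor distance is 1/(2√λ); at λ = 100 cells/mm² this is
50 µm, and the interior-window simulation reproduces it to ± 2 µm averaged
over 200 seeds.

## Cellular neighborhoods

For each immune cell the neighbors within `neighborhood_radius` (50 µm)
are counted per immune phenotype (five counts; tumor and `other` cells
enter neither the centers nor the counts, and the index cell is excluded
from its own vector). K-means with k-means++ initialization, 10 restarts
and a fixed seed clusters the raw count vectors into
`neighborhood_k` = 4 neighborhoods per specimen. Features are deliberately
*not* scaled by default — the counts share a unit and scaling would
up-weight rare phenotypes — and the index cell's own phenotype is not a
feature; both choices are switchable (`scale_neighborhood_features`,
`include_index_cell_feature`) since upstream tools differ here. Labels are
canonicalized by descending cluster size. A phenotype making up
≥ `dominance_fraction` (0.40) of a cluster is flagged dominant. Specimens
with fewer immune cells than k are skipped with a log entry, and when
there are fewer distinct count vectors than k the distinct vectors define
the effective clusters and the remaining labels stay empty.

## Secretome (NPX)

NPX values are log2-scale relative abundances. A protein is discarded when
non-missing in *less than* `protein_presence_min` (85%) of samples —
exactly 85% is retained. "Present" is read as non-missing in the mask;
whether missingness means below-LOD or unmeasured is upstream information
the matrix does not carry. Intensity normalization shifts each protein on
each plate by (overall median − plate median); afterwards every per-plate
per-protein median equals the pre-normalization overall median (machine
precision; tested at 1e-9). Plates with no non-missing value for a protein
keep a zero shift with a warning. Missing values stay missing — no
imputation; density–protein associations use Spearman's ρ on
pairwise-complete observations and are refused below 4 pairs.
Hierarchical clustering of samples and proteins defaults to Ward linkage
on Euclidean distance (the published figure does not state its linkage;
both are configurable); for the distance computation only, missing entries
are filled with the per-protein median. Interplate-control normalization
(three control wells per plate) has no published formula; a
median-alignment variant applied to control rows exists behind a flag but
is excluded from any validation claims.

## Statistical layer

Two-group comparisons use the two-sided Wilcoxon signed-rank (paired) or
rank-sum / Mann-Whitney (unpaired) test; multi-group comparisons the
Friedman (paired) or Kruskal-Wallis (unpaired) test, all via scipy with
midrank tie handling and the usual large-sample approximations (exact
small-sample enumeration is not attempted; group sizes here are ≥ 29
where calibration matters). Dunn's uncorrected post-hoc tests are
implemented from the mean-rank formulas: after Kruskal-Wallis,
z = (R̄ᵢ − R̄ⱼ) / √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)] on pooled
midranks; after Friedman, z = (Rᵢ − Rⱼ) / √(nk(k+1)/6) on within-block
rank sums. No multiplicity adjustment is applied, matching the analysis
convention the pipeline reproduces. Contingency tables use Pearson's
chi-square *without* continuity correction: the published 2×2 worked
example (4/14 vs 10/15, p = 0.04) is reproduced only without Yates'
correction, which is therefore the default, with the corrected variant
behind a flag. Correlation matrices (Pearson or Spearman) use
complete-case rows and refuse fewer than 4 cases. Under null simulation
(three normal groups of n = 29, 2,000 replicates) the rank tests and
Dunn's tests reject at 5% ± 2% at α = 0.05.

## Synthetic generator

The generator exists to make every downstream stage testable; it emulates
the *structure* of real specimens, not their imagery.

- **Landscape.** Six perturbed-circle tumor-field blobs (radius 350 µm,
  low-order Fourier boundary roughness 0.10) on a 900 µm ring with ± 80 µm
  jitter. The ring layout guarantees, robustly under jitter, that the
  tumor center contains both field cores and a central enclosed-stroma
  pocket ≥ 250 µm from any field boundary — without which the
  stroma-restricted archetype would have nowhere to put its stromal CD8s.
- **Cells.** Homogeneous Poisson per (zone, phenotype): count ~
  Poisson(density × area), positions uniform by rejection sampling
  (bounding-box proposals). Nothing in the published work specifies a
  generative model, so the simplest process consistent with zone densities
  is used.
- **Archetypes.** Zone-wise CD8 densities are placed ≥ 2× above or ≤ 0.5×
  below every threshold on the branch they must clear or miss (e.g.
  fully-infiltrated: center stroma 500, fields 300, margin stroma 600
  cells/mm²; immune-desert: 2–30 cells/mm² everywhere). With zone areas of
  a few mm² the Poisson coefficient of variation is a few percent, so the
  intended label is recovered in effectively 100% of seeds (acceptance
  demands ≥ 95%). Background phenotype densities (tumor 800/mm² in
  fields; macrophages, T-helper and Tregs concentrated in stroma and
  margin) reproduce the qualitative density gradients of resections.
- **B-cell aggregates.** A Thomas cluster process (Poisson parents at
  1.5/mm², Poisson(25) offspring, 30 µm Gaussian dispersion, clipped to
  the stromal zones). Real aggregate sizes are not quantified anywhere the
  pipeline can cite; these defaults are an order-of-magnitude choice,
  flagged as such, and only the *clustering property* (stochastically
  smaller nearest-neighbor distances than Poisson at equal intensity) is
  asserted.
- **NPX.** value = protein baseline N(5, 2) + sample effect N(0, 0.5) +
  plate shift + noise N(0, 0.3), missing i.i.d. This supports exact
  recovery tests for the normalization and presence filter; it does not
  model LOD-censoring (missingness correlated with level) or
  protein–protein correlation.
- **Determinism.** All randomness flows from one integer seed through
  named substreams (`substream(seed, name)`), so identical seed + spec
  gives bit-identical specimens.

What passing tests on synthetic data do **not** show: robustness to
segmentation/phenotyping error, irregular real tumor-front geometry,
tissue folds and staining artefacts, or biologically realistic covariance
between phenotype densities. The geometry, metric and statistical layers
are validated against closed forms and brute-force oracles, which do
transfer; the archetype recovery rates are statements about the generator's
safety margins, not about classifier performance on patient slides.

## Problem sizes

Defaults keep the full test suite and the acceptance script each within a
few minutes on one CPU: archetype specimens carry ~6,000–9,500 cells,
recovery sweeps use 4 × 20 seeds, the Poisson closed form 200 seeds,
oracle equivalence 50 × 1,000 cells, and calibration 2,000 null
replicates of n = 29 — the cohort size whose calibration matters.

## Known limitations

- Membrane-to-membrane distances are out of reach (tables carry centroids
  only).
- No spatial null models (Ripley's K, permutation envelopes) — deliberate
  scope restriction, not an oversight.
- Neighborhoods are per-specimen; no cohort-level harmonization of cluster
  identities is attempted.
- Tertiary lymphoid structures cannot be called from this phenotype panel;
  B-cell aggregates are as far as the data go.
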