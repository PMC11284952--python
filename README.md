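# timetopo

Spatial **t**umor-**im**mune-micro**e**nvironment **topo**graphy for multiplex
immunohistochemistry of head and neck squamous cell carcinoma (and similar
solid-tumor panels).

Pathology labs that phenotype cells on whole-slide multiplex-IHC images
(e.g. in QuPath) export, per specimen, a table of cell centroids with
phenotype labels and a set of tumor-field polygons. `timetopo` turns those
exports into the standard spatial read-outs of the tumor immune
microenvironment (TIME):

- **Tissue zones.** The *tumor area* is the union of tumor fields with
  enclosed stroma filled plus a 250 µm stromal collar; the *invasive
  margin* is the 500 µm band straddling the outer tumor-field contour
  (250 µm to each side); the *tumor center* is the remainder. Each zone is
  split into tumor-*field* and tumor-*stroma* compartments.
- **Immunotype.** A four-way classification from CD8+ T-cell densities
  (cells/mm², strict inequalities):

  ```
  if   TC  > 100   and TF > 82.8  ->  fully infiltrated
  elif TC  > 100                  ->  stroma-restricted
  elif IM  > 200                  ->  immune-excluded
  else                            ->  immune-desert
  ```

  where TC, TF, IM are the CD8 densities in the tumor center, tumor
  fields, and invasive margin. The TF cut-off is a cohort median (82.8
  cells/mm² in the published cohort) and can be recomputed per cohort.
- **Distance statistics.** The average minimum distance (AMD) from each
  reference phenotype to its nearest target-phenotype cell, and the
  fraction of cells of one type with at least one cell of another type
  within 10 µm.
- **Cellular neighborhoods.** Per immune cell, neighbor counts within
  50 µm over the five immune phenotypes (CD163+ macrophage, CD19+ B cell,
  CD8+ T cell, CD4+ T helper, FoxP3+ Treg), clustered by k-means (k = 4
  per specimen) with composition summaries and ≥ 40% dominance flags.
- **Secretome.** NPX (log2) protein matrices: 85%-presence filtering,
  plate intensity normalization (per-protein per-plate median aligned to
  the overall median), hierarchical clustering, and Spearman correlation
  of protein levels with immune densities.
- **Cohort statistics.** Signed-rank / rank-sum / Friedman /
  Kruskal-Wallis dispatch, uncorrected Dunn's post-hoc tests, Pearson
  chi-square on contingency tables, and Pearson/Spearman correlation
  matrices — all two-sided.

A synthetic tissue generator produces fully specified specimens (Poisson
cells per zone, Thomas-process B-cell aggregates, four immunotype
archetypes) and NPX matrices with plate shifts, so the entire pipeline is
testable without any patient data.

## Worked example

Simulate a two-specimen cohort and run the full pipeline:

```bash
timetopo simulate --archetype fully_infiltrated --seed 7 --out cohort/P01
timetopo simulate --archetype immune_excluded  --seed 8 --out cohort/P02
timetopo run --cohort cohort --out report
```

```
wrote specimen fully_infiltrated_s7 (9211 cells) to cohort/P01
wrote specimen immune_excluded_s8 (8992 cells) to cohort/P02
processed 2/2 specimens -> report
```

`report/summary.txt` then contains:

```
immunotype distribution:
  fully_infiltrated: 1 (50%)
  immune_excluded: 1 (50%)
  tumor-field CD8 threshold used: 82.8 cells/mm²
```

Both synthetic specimens are classified to the archetype they were
generated from. `report/densities.csv` holds the per-zone counts, areas
(mm²) and densities (cells/mm²); `report/amd.csv` the reference × target
AMD matrix in µm (e.g. B cells typically sit farther from tumor cells than
macrophages do, mirroring their aggregated, stroma-restricted layout);
`report/radius_fractions.csv` the 10 µm contact fractions; and
`report/neighborhoods_*.csv` plus the PNG maps the per-specimen cellular
neighborhoods.

The same steps are available as library calls:

```python
from timetopo import generate_archetype, build_zones, compute_densities, immunotype_specimen

specimen = generate_archetype("stroma_restricted", seed=1)
zones = build_zones(specimen.tumor_fields)
table = compute_densities(specimen, zones)
call = immunotype_specimen(specimen, table)
print(call.label, call.decision_path)
# stroma_restricted ['tc_cd8 585.7 > 100', 'tf_cd8 24.7 <= 82.8']
```

## Limitations

Cell segmentation, phenotyping, and tissue pixel classification are
upstream concerns: the package consumes their exports. Distances are
centroid-to-centroid and uncorrected for slide edges. See
`docs/methods.md` for the model assumptions, parameter defaults, and what
the synthetic generator does and does not emulate.
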