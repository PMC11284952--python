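"""Cohort pipeline orchestration and reporting.

Runs the full analysis — zone construction, densities, immunotype calls,
distance metrics, cellular neighborhoods, cohort statistics — over a
directory of specimen subfolders and renders CSV tables, figures and a
text summary.  Biopsy specimens route only through density, fraction and
radius analyses; immunotyping requires a resection.  Failures are isolated
per specimen: an unreadable specimen is skipped with a recorded reason and
the pipeline continues.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_model import (
    IMMUNE_PHENOTYPES,
    NPXMatrix,
    PipelineConfig,
    Specimen,
    TimetopoError,
    read_annotations,
    read_cell_table,
    read_metadata,
    read_npx,
)
from .cohort_stats import chi2_2x2, rank_tests
from .neighborhoods import (
    cluster_neighborhoods,
    count_neighbors,
    neighborhood_composition,
    neighborhood_map,
)
from .quantification import (
    cohort_tf_threshold,
    compute_densities,
    get_density,
    immunotype_specimen,
)
from .secretome import correlate_densities, filter_proteins, hierarchical_cluster, intensity_normalize
from .spatial import amd_matrix, radius_fraction
from .zoning import assign_cells_to_zones, build_zones

log = logging.getLogger("timetopo.pipeline")


@dataclass
class SpecimenResult:
    specimen_id: str
    status: str  # processed | skipped
    reason: str = ""
    densities: pd.DataFrame | None = None
    immunotype: str | None = None
    amd: pd.DataFrame | None = None
    radius_fractions: pd.DataFrame | None = None
    neighborhood_composition: pd.DataFrame | None = None
    neighborhood_table: pd.DataFrame | None = None


@dataclass
class CohortResult:
    specimens: dict = field(default_factory=dict)  # specimen_id -> SpecimenResult
    immunotypes: pd.DataFrame | None = None
    densities: pd.DataFrame | None = None
    tf_threshold: float | None = None
    stats: dict = field(default_factory=dict)
    secretome: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_processed(self) -> int:
        return sum(1 for r in self.specimens.values() if r.status == "processed")


def load_specimen(folder: Path, config: PipelineConfig) -> Specimen:
    """Load one specimen subfolder (cells.csv, fields.geojson, metadata.csv)."""
    cells = read_cell_table(folder / "cells.csv", aliases=config.phenotype_aliases)
    fields = read_annotations(folder / "fields.geojson", repair=config.repair_geometries)
    meta_path = folder / "metadata.csv"
    meta: dict = {}
    if meta_path.exists():
        row = read_metadata(meta_path).iloc[0].to_dict()
        meta = {k: v for k, v in row.items() if pd.notna(v)}
    return Specimen(
        specimen_id=str(meta.get("specimen_id", folder.name)),
        kind=meta.get("kind", "resection"),
        site=meta.get("site", "oral_cavity"),
        hpv_status=meta.get("hpv_status", "unknown"),
        cells=cells.frame,
        tumor_fields=fields,
        covariates={k: v for k, v in meta.items()
                    if k not in ("specimen_id", "kind", "site", "hpv_status")},
    )


def analyze_specimen(specimen: Specimen, config: PipelineConfig,
                     tf_threshold: float | None = None) -> SpecimenResult:
    """Run the per-specimen analyses (zones → densities → immunotype →
    AMD → radius fractions → neighborhoods)."""
    zones = build_zones(specimen.tumor_fields, config)
    labels = assign_cells_to_zones(specimen.cells, zones)
    densities = compute_densities(specimen, zones, labels)
    result = SpecimenResult(specimen_id=specimen.specimen_id, status="processed",
                            densities=densities)

    if specimen.kind == "resection":
        call = immunotype_specimen(specimen, densities, config, tf_threshold)
        result.immunotype = call.label

    in_area = specimen.cells[labels["region"].to_numpy() != "outside"]
    result.amd = amd_matrix(in_area)

    rf_rows = []
    pairs = [("tumor", p) for p in IMMUNE_PHENOTYPES]
    pairs += [("t_cd8", p) for p in ("macrophage_cd163", "t_cd4_helper", "treg")]
    for counted, probe in pairs:
        rf = radius_fraction(in_area, counted, probe, config.radius_fraction_r)
        rf_rows.append((specimen.specimen_id, counted, probe, rf.radius,
                        rf.fraction, rf.n_counted))
    result.radius_fractions = pd.DataFrame(
        rf_rows, columns=["specimen_id", "counted", "probe", "radius_um",
                          "fraction", "n_counted"])

    if specimen.kind == "resection":
        counts = count_neighbors(in_area, config.neighborhood_radius)
        if len(counts) >= config.neighborhood_k:
            nb_labels = cluster_neighborhoods(
                counts, config.neighborhood_k, seed=config.random_seed,
                scale=config.scale_neighborhood_features)
            result.neighborhood_composition = neighborhood_composition(
                nb_labels, counts["phenotype"].to_numpy(), config.neighborhood_k,
                config.dominance_fraction)
            result.neighborhood_table = neighborhood_map(in_area, nb_labels)
        else:
            log.warning("specimen %s: too few immune cells for neighborhoods",
                        specimen.specimen_id)
    return result


def run_pipeline(cohort_dir: str | Path, config: PipelineConfig | None = None
                 ) -> CohortResult:
    """Run the full pipeline over a cohort directory.

    Each subfolder is one specimen; an optional top-level ``npx.csv``
    triggers the secretome analysis against the cohort density table.
    """
    config = config or PipelineConfig()
    cohort_dir = Path(cohort_dir)
    folders = sorted(p for p in cohort_dir.iterdir() if p.is_dir())
    if not folders:
        raise TimetopoError(f"no specimen subfolders in {cohort_dir}")

    result = CohortResult()
    specimens: dict[str, Specimen] = {}
    for folder in folders:
        try:
            specimens[folder.name] = load_specimen(folder, config)
        except (TimetopoError, OSError, KeyError) as exc:
            log.warning("skipping specimen %s: %s", folder.name, exc)
            result.specimens[folder.name] = SpecimenResult(
                specimen_id=folder.name, status="skipped", reason=str(exc))

    # two passes when the TF threshold is the cohort median: densities first
    tf_threshold = config.tf_cd8_threshold_fixed
    density_tables = {}
    analyzed: dict[str, SpecimenResult] = {}
    for sid, spec in specimens.items():
        try:
            analyzed[sid] = analyze_specimen(spec, config, tf_threshold=None
                                             if config.tf_cd8_threshold_mode == "cohort_median"
                                             else tf_threshold)
        except TimetopoError as exc:
            log.warning("skipping specimen %s: %s", sid, exc)
            result.specimens[sid] = SpecimenResult(specimen_id=sid, status="skipped",
                                                   reason=str(exc))
            continue
        density_tables[sid] = analyzed[sid].densities

    if density_tables:
        all_densities = pd.concat(density_tables.values(), ignore_index=True)
        result.densities = all_densities
        if config.tf_cd8_threshold_mode == "cohort_median":
            resection_ids = [sid for sid in analyzed if specimens[sid].kind == "resection"]
            tf_threshold = cohort_tf_threshold(
                all_densities[all_densities["specimen_id"].isin(resection_ids)])
            for sid in analyzed:  # re-call with the cohort threshold
                spec = specimens[sid]
                if spec.kind == "resection":
                    call = immunotype_specimen(spec, analyzed[sid].densities,
                                               config, tf_threshold)
                    analyzed[sid].immunotype = call.label
        result.tf_threshold = tf_threshold

    result.specimens.update(analyzed)

    calls = [(r.specimen_id, r.immunotype) for r in analyzed.values()
             if r.immunotype is not None]
    if calls:
        result.immunotypes = pd.DataFrame(calls, columns=["specimen_id", "immunotype"])

    result.stats = _cohort_stats(result, specimens, config)

    npx_path = cohort_dir / "npx.csv"
    if npx_path.exists() and result.densities is not None:
        result.secretome = _secretome_analysis(read_npx(npx_path), result, config)

    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    result.provenance = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": config.random_seed,
        "version": __version__,
        "n_specimens": len(folders),
        "n_processed": result.n_processed,
    }
    return result


def _cohort_stats(result: CohortResult, specimens: dict, config: PipelineConfig) -> dict:
    """Cohort tests: Friedman over immune densities, TC-vs-IM signed-rank,
    and (when an LVI covariate exists) the immunotype × LVI chi-square."""
    out: dict = {}
    if result.densities is None:
        return out
    d = result.densities
    wide = {}
    for phen in IMMUNE_PHENOTYPES:
        m = ((d["region"] == "tumor_area") & (d["compartment"] == "all")
             & (d["phenotype"] == phen))
        wide[phen] = d[m].set_index("specimen_id")["density"]
    wide_df = pd.DataFrame(wide).dropna()
    if len(wide_df) >= 3:
        out["friedman_densities"] = rank_tests(
            [wide_df[p].to_numpy() for p in IMMUNE_PHENOTYPES], design="paired")
    tc, im = [], []
    for sid in d["specimen_id"].unique():
        tc.append(get_density(d, "center", "all", "all_immune", sid))
        im.append(get_density(d, "margin", "all", "all_immune", sid))
    tc, im = np.asarray(tc), np.asarray(im)
    ok = np.isfinite(tc) & np.isfinite(im)
    if ok.sum() >= 3 and np.any(tc[ok] != im[ok]):
        out["tc_vs_im_signed_rank"] = rank_tests([tc[ok], im[ok]], design="paired")

    if result.immunotypes is not None:
        lvi = {sid: str(specimens[sid].covariates.get("lymphovascular_invasion", "")).lower()
               for sid in specimens if sid in set(result.immunotypes["specimen_id"])}
        if any(v in ("yes", "no") for v in lvi.values()):
            tab = np.zeros((2, 2), dtype=int)
            for _, row in result.immunotypes.iterrows():
                v = lvi.get(row["specimen_id"], "")
                if v not in ("yes", "no"):
                    continue
                i = 0 if row["immunotype"] == "fully_infiltrated" else 1
                j = 0 if v == "yes" else 1
                tab[i, j] += 1
            if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
                out["lvi_chi2"] = chi2_2x2(tab, continuity=config.chi2_continuity_correction)
    return out


def _secretome_analysis(npx: NPXMatrix, result: CohortResult,
                        config: PipelineConfig) -> dict:
    filtered, discarded = filter_proteins(npx, config.protein_presence_min)
    normalized, report = intensity_normalize(filtered)
    clustering = hierarchical_cluster(normalized, config.linkage_method,
                                      config.linkage_metric)
    out = {"filtered": normalized, "discarded": discarded,
           "normalization_report": report, "clustering": clustering}
    try:
        out["treg_correlations"] = correlate_densities(
            normalized, result.densities, "treg", "tumor_area", "all")
    except TimetopoError as exc:
        log.warning("secretome correlation skipped: %s", exc)
    return out


def _plot_neighborhood_map(table: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for cluster in sorted(table["cluster"].unique()):
        sub = table[table["cluster"] == cluster]
        ax.scatter(sub["x"], sub["y"], s=4, label=f"neighborhood {cluster}")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.legend(markerscale=3, fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(result: CohortResult, out_dir: str | Path) -> list[Path]:
    """Write CSV tables, figures and a text summary; returns files written.

    Nothing is recomputed at render time, so regeneration is idempotent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str, **kw) -> None:
        path = out_dir / name
        df.to_csv(path, **kw)
        written.append(path)

    if result.densities is not None:
        _write_csv(result.densities, "densities.csv", index=False)
    if result.immunotypes is not None:
        _write_csv(result.immunotypes, "immunotypes.csv", index=False)

    amd_frames, rf_frames = [], []
    for sid, sr in sorted(result.specimens.items()):
        if sr.status != "processed":
            continue
        if sr.amd is not None:
            long = sr.amd.stack().rename("amd_um").reset_index()
            long.columns = ["reference", "target", "amd_um"]
            long.insert(0, "specimen_id", sid)
            amd_frames.append(long)
        if sr.radius_fractions is not None:
            rf_frames.append(sr.radius_fractions)
        if sr.neighborhood_composition is not None:
            _write_csv(sr.neighborhood_composition, f"neighborhoods_{sid}.csv")
        if sr.neighborhood_table is not None:
            fig_path = out_dir / f"neighborhood_map_{sid}.png"
            _plot_neighborhood_map(sr.neighborhood_table, fig_path)
            written.append(fig_path)
    if amd_frames:
        _write_csv(pd.concat(amd_frames, ignore_index=True), "amd.csv", index=False)
    if rf_frames:
        _write_csv(pd.concat(rf_frames, ignore_index=True),
                   "radius_fractions.csv", index=False)

    if "treg_correlations" in result.secretome:
        _write_csv(result.secretome["treg_correlations"],
                   "secretome_treg_correlations.csv", index=False)

    lines = ["cohort summary", "==============", ""]
    lines.append(f"specimens: {len(result.specimens)} "
                 f"({result.n_processed} processed)")
    for sid, sr in sorted(result.specimens.items()):
        if sr.status == "skipped":
            lines.append(f"  {sid}: skipped ({sr.reason})")
    if result.immunotypes is not None:
        lines += ["", "immunotype distribution:"]
        dist = result.immunotypes["immunotype"].value_counts()
        total = int(dist.sum())
        for label, count in dist.items():
            lines.append(f"  {label}: {count} ({100 * count / total:.0f}%)")
        if result.tf_threshold is not None:
            lines.append(f"  tumor-field CD8 threshold used: "
                         f"{result.tf_threshold:.1f} cells/mm²")
    for name, tr in result.stats.items():
        lines.append(f"stat {name}: {tr.test} statistic={tr.statistic:.3g} "
                     f"p={tr.p_value:.3g}")
    for path in written:
        lines.append(f"file: {path.name}")
    summary = out_dir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
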