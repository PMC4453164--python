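"""End-to-end screen analysis: images or tables in, scored screen out.

``run_screen`` composes the stages — (optional) per-field image analysis →
per-well summaries → replicate correlation → Z / dZ scores → hit calls and
rate summary → dZ clustering — and writes every intermediate table plus a
run manifest.  Feeding the imaging mode's well table back through
tables-only mode reproduces identical downstream statistics.
"""

from __future__ import annotations

import logging
import sys
import warnings
from pathlib import Path

import pandas as pd

from . import clustering, image_pipeline, io_utils, screen_statistics
from .image_pipeline import PipelineParams

log = logging.getLogger("spindlescreen")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input context."""


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def summarize_image_dir(images_dir: str | Path, layout: pd.DataFrame,
                        params: PipelineParams,
                        channel_map: dict[str, int] | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse every field TIFF under ``images_dir``; returns (cells, wells).

    Files are expected to be named ``<background>_r<replicate>_<well>_f<k>.tif``
    (the layout of :func:`simulate_plate_images`); the layout table supplies
    gene/role metadata per well.
    """
    images_dir = Path(images_dir)
    paths = sorted(images_dir.glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no .tif fields under {images_dir}")
    meta = layout.set_index(["background", "replicate", "well"])
    cell_tables = []
    for path in paths:
        stem = path.stem
        try:
            bg, rep_s, well, _field = stem.split("_")
            rep = int(rep_s.lstrip("r"))
        except ValueError as exc:
            raise ValueError(f"unparseable field filename {path.name}") from exc
        image = io_utils.read_field_tiff(path, channel_map)
        cells = image_pipeline.process_field(image, params)
        cells.insert(0, "background", bg)
        cells.insert(1, "replicate", rep)
        cells["well"] = well
        cell_tables.append(cells)
    cells = pd.concat(cell_tables, ignore_index=True)
    well_rows = []
    for (bg, rep, well), sub in cells.groupby(["background", "replicate", "well"]):
        summary = image_pipeline.summarize_well(sub, well=well)
        info = meta.loc[(bg, rep, well)]
        if isinstance(info, pd.DataFrame):
            info = info.iloc[0]
        summary.update({"background": bg, "replicate": rep,
                        "gene": info["gene"], "sirna_id": info["sirna_id"],
                        "role": info["role"]})
        well_rows.append(summary)
    wells = pd.DataFrame(well_rows)
    return cells, wells


def score_wells(wells: pd.DataFrame, k: float = 1.5, library_size: int | None = None,
                robust: bool = False, seed: int = 0) -> dict:
    """Statistics stages shared by both modes; returns a dict of tables."""
    correlations = []
    for bg, sub in wells.groupby("background"):
        reps = sorted(sub["replicate"].unique())
        if len(reps) >= 2:
            a = sub[sub["replicate"] == reps[0]]
            b = sub[sub["replicate"] == reps[1]]
            for feat in screen_statistics.FEATURES:
                try:
                    res = _stage("replicate_correlation",
                                 screen_statistics.replicate_correlation, a, b,
                                 feature=feat, seed=seed)
                except StageError as exc:
                    log.warning("skipping correlation for %s/%s: %s", bg, feat, exc)
                    continue
                correlations.append({"background": bg, "feature": res.feature,
                                     "rho": res.rho, "p": res.p, "n": res.n})
    corr = pd.DataFrame(correlations)
    scores = _stage("compute_zscores", screen_statistics.compute_zscores, wells,
                    robust=robust)
    hits = _stage("call_hits", screen_statistics.call_hits, wells, k=k)
    n_library = library_size or wells.loc[wells["role"] == "sample", "gene"].nunique()
    hit_summary = _stage("summarize_hits", screen_statistics.summarize_hits,
                         hits, n_library)
    return {"correlations": corr, "gene_scores": scores, "hits": hits,
            "hit_summary": hit_summary}


def cluster_scores(scores: pd.DataFrame, cut: float = 0.7,
                   metric: str = "uncentred_pearson") -> tuple[pd.DataFrame, object, pd.DataFrame]:
    """Filter → distance → complete linkage → cut; returns
    (cluster table, ClusterResult, dZ matrix)."""
    matrix = clustering.filter_genes(scores)
    D = clustering.pairwise_distance(matrix, metric=metric)
    merges = clustering.cluster_complete(D)
    result = clustering.cut_clusters(merges, list(matrix.index),
                                     similarity_cut=cut, metric=metric)
    table = result.labels.rename_axis("gene").reset_index()
    return table, result, matrix


def run_screen(out_dir: str | Path, layout: pd.DataFrame,
               wells: pd.DataFrame | None = None,
               images_dir: str | Path | None = None,
               params: PipelineParams | None = None,
               channel_map: dict[str, int] | None = None,
               k: float = 1.5, cluster_cut: float = 0.7,
               cluster_metric: str = "uncentred_pearson", robust: bool = False,
               seed: int = 0) -> dict:
    """Execute the full screen analysis and write the output bundle.

    Exactly one of ``wells`` (tables mode) or ``images_dir`` (imaging mode)
    must be given.  Writes per-cell (imaging mode), per-well, correlation,
    gene-score, hit, hit-summary and cluster CSVs plus CDT/GTR/Newick trees
    and a run-manifest JSON into ``out_dir``; every table carries the
    manifest hash.  Returns the tables keyed by name.
    """
    if (wells is None) == (images_dir is None):
        raise ValueError("provide exactly one of wells= or images_dir=")
    params = params or PipelineParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = io_utils.make_manifest(
        mode="images" if images_dir else "tables",
        pipeline_params=params.asdict(), hit_k=k, cluster_cut=cluster_cut,
        cluster_metric=cluster_metric, robust_z=robust, seed=seed,
        n_layout_wells=int(len(layout)))
    io_utils.write_manifest(manifest, out_dir / "run_manifest.json")

    tables: dict[str, pd.DataFrame] = {}
    if images_dir is not None:
        cells, wells = _stage("segment", summarize_image_dir, images_dir, layout,
                              params, channel_map)
        tables["cells"] = cells
        io_utils.write_table(cells, out_dir / "cells.csv", manifest)
    tables["wells"] = wells
    io_utils.write_table(wells, out_dir / "wells.csv", manifest)

    stats = score_wells(wells, k=k, robust=robust, seed=seed)
    tables.update(stats)
    io_utils.write_table(stats["correlations"], out_dir / "replicate_correlations.csv", manifest)
    io_utils.write_table(stats["gene_scores"], out_dir / "gene_scores.csv", manifest)
    io_utils.write_table(stats["hits"], out_dir / "hits.csv", manifest)
    io_utils.write_table(stats["hit_summary"], out_dir / "hit_summary.csv", manifest)

    try:
        table, result, matrix = _stage("cluster", cluster_scores, stats["gene_scores"],
                                       cut=cluster_cut, metric=cluster_metric)
        if len(matrix) >= 2:
            clustering.export_tree(result, matrix, out_dir, basename="dz_clusters")
        tables["clusters"] = table
    except StageError as exc:
        warnings.warn(f"clustering skipped: {exc}")
        tables["clusters"] = pd.DataFrame(columns=["gene", "cluster"])
    io_utils.write_table(tables["clusters"], out_dir / "clusters.csv", manifest)
    return tables


def simulate_plate_images(out_dir: str | Path, layout: pd.DataFrame,
                          model, seed: int, n_fields: int = 2,
                          mitotic_per_field: int = 6, interphase_per_field: int = 8,
                          eight_bit: bool = True) -> dict:
    """Render TIFF fields (plus ground truth) for every well of a layout.

    Per-well multipolar penetrance and multinucleate fraction come from the
    :class:`~spindlescreen.synthetic_data.GeneEffectModel`.  Field files are
    named ``<background>_r<rep>_<well>_f<k>.tif``; per-cell truth goes to
    ``truth_cells.csv`` and per-well truth features to ``truth_wells.json``.
    Intended for mini-plates: rendering a full 384-well plate this way is
    possible but slow.
    """
    import json

    import numpy as np

    from . import synthetic_data as synth

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth_rows = []
    well_truth = {}
    lay = layout[layout["role"] != "empty"].sort_values(
        ["background", "replicate", "well"])
    for rec in lay.itertuples(index=False):
        eff = model.effect(rec.gene, rec.background)
        gain = model.replicate_gain.get(int(rec.replicate), 1.0)
        pen = float(np.clip(eff.multipolar_penetrance * gain, 0.0, 1.0))
        # per-well cell-count variation (viability differences between wells)
        n_inter = max(int(rng.poisson(interphase_per_field)), 1)
        fields = synth.simulate_well_fields(
            seed=int(rng.integers(0, 2**31 - 1)), n_fields=n_fields,
            mitotic_per_field=mitotic_per_field,
            interphase_per_field=n_inter,
            multipolar_penetrance=pen,
            multipolar_pole_mean=eff.mean_pole_count,
            binucleate_fraction=eff.multinucleate_fraction,
            well=rec.well, eight_bit=eight_bit)
        n_mit = n_multi = poles = n_inter = n_multinuc = n_nuclei_inter = 0
        for f, (image, truth) in enumerate(fields):
            name = f"{rec.background}_r{int(rec.replicate)}_{rec.well}_f{f}.tif"
            io_utils.write_field_tiff(out_dir / name, image)
            truth = truth.assign(background=rec.background, replicate=int(rec.replicate),
                                 well=rec.well, field=f, gene=rec.gene)
            truth_rows.append(truth)
            mit = truth[truth["kind"] == "mitotic"]
            inter = truth[truth["kind"] == "interphase"]
            n_mit += len(mit)
            n_multi += int(mit["is_multipolar"].sum())
            poles += int(mit["n_poles"].sum())
            n_inter += len(inter)
            n_nuclei_inter += int(inter["n_nuclei"].sum())
            n_multinuc += int((inter["n_nuclei"] >= 2).sum())
        well_truth[f"{rec.background}_r{int(rec.replicate)}_{rec.well}"] = {
            "n_cells": n_mit + n_nuclei_inter,
            "mitotic_index": n_mit / max(n_mit + n_inter, 1),
            "pct_multipolar": 100.0 * n_multi / n_mit if n_mit else None,
            "mean_poles": poles / n_mit if n_mit else None,
            "pct_multinucleate": 100.0 * n_multinuc / n_inter if n_inter else None,
        }
    cells = pd.concat(truth_rows, ignore_index=True)
    io_utils.write_table(cells, out_dir / "truth_cells.csv")
    (out_dir / "truth_wells.json").write_text(json.dumps(well_truth, indent=2))
    return {"cells": cells, "wells": well_truth, "dir": out_dir}


def configure_logging(json_lines: bool = False, level: int = logging.INFO) -> None:
    """Stderr logging; machine-readable JSON-lines optional."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        handler.setFormatter(logging.Formatter(
            '{"level": "%(levelname)s", "stage": "%(name)s", "msg": "%(message)s"}'))
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
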