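"""Recovery benchmarks: run the pipeline on synthetic data with known truth.

These routines power the package's self-validation: they generate plates or
fields under the default study conditions, run the actual analysis code, and
score it against the simulator's ground truth.  They are used by the test
suite and the reproduction script, and are public so users can rerun them at
other settings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import image_pipeline, io_utils, screen_statistics, synthetic_data
from .image_pipeline import PipelineParams


def _match_mitotic_records(records: pd.DataFrame, truth: pd.DataFrame,
                           max_dist: float = 13.0) -> pd.DataFrame:
    """Match detected mitotic cells to true mitotic cells by nearest centroid.

    Returns the truth rows with columns ``detected`` (bool) and
    ``n_poles_detected`` (NaN when undetected or QC-excluded).
    """
    det = records[records["kind"] == "mitotic"].copy()
    out = truth[truth["kind"] == "mitotic"].copy()
    detected = []
    n_poles = []
    for t in out.itertuples(index=False):
        if len(det):
            d2 = (det["centroid_r"] - t.row) ** 2 + (det["centroid_c"] - t.col) ** 2
            i = d2.idxmin()
            if d2.loc[i] <= max_dist**2:
                rec = det.loc[i]
                detected.append(True)
                n_poles.append(rec["n_poles"] if rec["exclusion_reason"] == "none"
                               else np.nan)
                det = det.drop(index=i)
                continue
        detected.append(False)
        n_poles.append(np.nan)
    out["detected"] = detected
    out["n_poles_detected"] = n_poles
    return out


def pole_count_recovery(seed: int, n_cells_per_condition: int = 200,
                        conditions: tuple[int, ...] = (1, 2, 3, 4),
                        mitotic_per_field: int = 8, interphase_per_field: int = 4,
                        params: PipelineParams | None = None) -> dict:
    """Exact pole-count agreement between pipeline and truth, per condition.

    Each condition is a pure population of mitotic cells with a fixed true
    pole count, rendered at the default signal-to-noise settings and analysed
    with the full per-cell pipeline.  A cell counts as correct only when it
    is detected, passes QC and receives exactly its true pole count.
    """
    params = params or PipelineParams()
    rng = np.random.default_rng(seed)
    per_condition = {}
    total_correct = 0
    total_cells = 0
    for k in conditions:
        n_done = 0
        correct = 0
        while n_done < n_cells_per_condition:
            n_mit = min(mitotic_per_field, n_cells_per_condition - n_done)
            cells = synthetic_data.random_cell_layout(
                rng, (448, 448), interphase_per_field, [k] * n_mit)
            cfg = synthetic_data.FieldSimConfig(
                field_size=(448, 448), cells=cells,
                seed=int(rng.integers(0, 2**31 - 1)), eight_bit=True)
            image, truth = synthetic_data.simulate_field(cfg)
            records = image_pipeline.process_field(image, params)
            matched = _match_mitotic_records(records, truth)
            correct += int((matched["n_poles_detected"] == matched["n_poles"]).sum())
            n_done += n_mit
        per_condition[k] = 100.0 * correct / n_done
        total_correct += correct
        total_cells += n_done
    return {"accuracy_pct": 100.0 * total_correct / total_cells,
            "per_condition_pct": per_condition, "n_cells": total_cells}


def multipolar_well_recovery(seed: int, n_wells: int = 2, mitotic_per_well: int = 100,
                             penetrance: float = 0.25,
                             params: PipelineParams | None = None) -> dict:
    """Per-well % multipolar measured by the pipeline vs simulator truth.

    Wells mix bipolar and multipolar mitotic cells at the given penetrance
    (the sensitized-background regime); reported is the largest absolute
    per-well error in percentage points.
    """
    params = params or PipelineParams()
    rng = np.random.default_rng(seed)
    errors = []
    for w in range(n_wells):
        n_fields = int(np.ceil(mitotic_per_well / 8))
        fields = synthetic_data.simulate_well_fields(
            seed=int(rng.integers(0, 2**31 - 1)), n_fields=n_fields,
            mitotic_per_field=8, interphase_per_field=4,
            multipolar_penetrance=penetrance, eight_bit=True,
            well=f"W{w:02d}")
        rec_tables = []
        true_multi = 0
        true_mit = 0
        for image, truth in fields:
            rec_tables.append(image_pipeline.process_field(image, params))
            mit = truth[truth["kind"] == "mitotic"]
            true_mit += len(mit)
            true_multi += int(mit["is_multipolar"].sum())
        records = pd.concat(rec_tables, ignore_index=True)
        summary = image_pipeline.summarize_well(records, well=f"W{w:02d}")
        truth_pct = 100.0 * true_multi / true_mit
        errors.append(abs(summary["pct_multipolar"] - truth_pct))
    return {"max_abs_error_points": float(max(errors)),
            "per_well_errors": [float(e) for e in errors],
            "n_wells": n_wells, "mitotic_per_well": mitotic_per_well}


def hit_recovery(seed: int, n_genes: int = 240, n_enhancers: int = 20,
                 n_suppressors: int = 10, k: float = 1.5,
                 background: str = "chTOG") -> dict:
    """Hit-call recall and false-positive rate on a simulated duplicate screen.

    ``n_enhancers``/``n_suppressors`` library genes carry ±3σ multipolar
    effects in the sensitized background (σ = the analytically expected
    control-well SD); the rest are null.  Recall is the fraction of effect
    genes called (in the correct direction counts as called); the
    false-positive rate is the fraction of null genes called at all.
    """
    genes = [f"G{i:03d}" for i in range(n_genes)]
    layout = io_utils.make_default_layout(genes)
    model = synthetic_data.add_designated_hits(
        synthetic_data.GeneEffectModel(), enhancers=genes[:n_enhancers],
        suppressors=genes[n_enhancers:n_enhancers + n_suppressors],
        background=background, sd_units=3.0)
    wells, _ = synthetic_data.simulate_screen_tables(layout, model, seed=seed)
    hits = screen_statistics.call_hits(wells, k=k)
    sub = hits[hits["background"] == background]
    called = set(sub.loc[sub["class"] != "none", "gene"])
    true_hits = set(genes[:n_enhancers + n_suppressors])
    nulls = set(genes) - true_hits
    recall = 100.0 * len(called & true_hits) / len(true_hits)
    fp_rate = 100.0 * len(called & nulls) / len(nulls)
    return {"recall_pct": recall, "false_positive_pct": fp_rate,
            "n_true_hits": len(true_hits), "n_null_genes": len(nulls),
            "wells": wells, "hits": hits}


def null_hit_rate(seed: int, n_genes: int = 280, k: float = 1.5,
                  n_control_wells: int = 96) -> dict:
    """Flagged fraction on a single-replicate null screen (no effects, no
    batch drift): expectation 2·Φ(−k) ≈ 13.4% at k = 1.5.  The expectation
    is exact in the many-control-well limit; the default uses a large control
    block so that control-SD estimation noise does not dominate."""
    genes = [f"N{i:03d}" for i in range(n_genes)]
    layout = io_utils.make_default_layout(genes, replicates=(1,),
                                          n_control_wells=n_control_wells)
    model = synthetic_data.GeneEffectModel(replicate_gain={1: 1.0})
    wells, _ = synthetic_data.simulate_screen_tables(layout, model, seed=seed)
    hits = screen_statistics.call_hits(wells, k=k)
    sub = hits[hits["background"] == "chTOG"]
    rate = 100.0 * (sub["class"] != "none").mean()
    return {"flagged_pct": float(rate), "n_genes": n_genes}
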