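"""Per-cell mitotic image analysis.

Stages, mirroring a high-content screen protocol: segment all nuclei from the
DNA channel (total cell number); gate mitotic nuclei on PHH3; grow mitotic
cytoplasm masks from the RFP channel; apply QC (edge / roundness / low
tubulin); count spindle poles as quality-filtered local tubulin maxima;
classify multipolar cells (>2 poles); count nuclei per interphase RFP body
for the multinucleate fraction; and summarize the five per-well features.

The spot detector is this package's concrete, scale-invariant stand-in for
proprietary "relative spot intensity" / "splitting coefficient" spot-finder
parameters: a candidate local maximum is kept when its background-and-max
normalized contrast exceeds ``rel_spot_intensity_min``, and two surviving
maxima are merged (keeping the brighter) when the minimum smoothed intensity
along the straight path between them exceeds ``splitting_coefficient`` times
the dimmer peak — i.e. when no sufficient valley separates them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import perimeter_crofton as _perimeter
from skimage.segmentation import watershed

from .synthetic_data import FieldImage

EXCLUSION_REASONS = ("none", "edge", "roundness", "low_tubulin")


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds of the image pipeline.

    Defaults follow the screen protocol: roundness (4πA/P²) ≥ 0.8, mean
    tubulin ≥ 30 (8-bit scale), relative spot intensity > 0.095, splitting
    coefficient 0.56, multipolar ⇔ more than two poles.  All inequalities at
    thresholds are strict.  ``phh3_threshold="auto"`` estimates the mitotic
    gate as mean + 3·SD of the lower mode of per-nucleus PHH3 means.
    """

    phh3_threshold: float | str = "auto"
    roundness_min: float = 0.8
    tubulin_mean_min: float = 30.0
    rel_spot_intensity_min: float = 0.095
    splitting_coefficient: float = 0.56
    smoothing_sigma: float = 2.0
    multipolar_pole_count_min: int = 3
    nucleus_smooth_sigma: float = 2.0
    min_nucleus_area: int = 40
    nucleus_split_min_distance: int = 7

    def __post_init__(self) -> None:
        if not 0.0 < self.roundness_min <= 1.0:
            raise ValueError("roundness_min must be in (0, 1]")
        if not 0.0 < self.rel_spot_intensity_min < 1.0:
            raise ValueError("rel_spot_intensity_min must be in (0, 1)")
        if not 0.0 <= self.splitting_coefficient <= 1.0:
            raise ValueError("splitting_coefficient must be in [0, 1]")

    def asdict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class SpindlePole:
    """One accepted tubulin focus."""

    position: tuple[int, int]
    peak_intensity: float
    relative_intensity: float


# ---------------------------------------------------------------------------
# Nucleus segmentation and mitotic gating
# ---------------------------------------------------------------------------

def segment_nuclei(dna: np.ndarray, params: PipelineParams | None = None
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment all nuclei from the DNA channel.

    Smooth → Otsu threshold → remove specks → split touching nuclei by
    seeded watershed on the distance transform.  Returns ``(labels, records)``
    with one record per nucleus (label, centroid, area, mean_dna).  A blank
    or constant image yields zero nuclei.
    """
    params = params or PipelineParams()
    dna = np.asarray(dna, dtype=float)
    if dna.size == 0:
        raise ValueError("empty image")
    sm = ndi.gaussian_filter(dna, params.nucleus_smooth_sigma)
    if np.ptp(sm) <= 1e-12:
        return np.zeros(dna.shape, dtype=np.int32), _nucleus_records(
            np.zeros(dna.shape, np.int32), dna, np.zeros(dna.shape))
    thr = threshold_otsu(sm)
    mask = sm > thr
    lab, n_obj = ndi.label(mask)
    if n_obj:
        sizes = np.bincount(lab.ravel())
        mask = (sizes[lab] >= params.min_nucleus_area) & (lab > 0)
    if not mask.any():
        return np.zeros(dna.shape, dtype=np.int32), _nucleus_records(
            np.zeros(dna.shape, np.int32), dna, sm)
    # seeded watershed split of touching nuclei: one seed per distance peak
    dist = ndi.distance_transform_edt(mask)
    seeds_idx = peak_local_max(dist, min_distance=params.nucleus_split_min_distance,
                               labels=mask, exclude_border=False)
    seed_img = np.zeros(dna.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds_idx, start=1):
        seed_img[r, c] = i
    if seed_img.max() == 0:
        labels, _ = ndi.label(mask)
        labels = labels.astype(np.int32)
    else:
        labels = watershed(-dist, markers=seed_img, mask=mask).astype(np.int32)
    labels = _relabel_sequential(labels)
    return labels, _nucleus_records(labels, dna, sm)


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def _nucleus_records(labels: np.ndarray, dna: np.ndarray, sm: np.ndarray) -> pd.DataFrame:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return pd.DataFrame(columns=["label", "centroid_r", "centroid_c", "area", "mean_dna"])
    coms = ndi.center_of_mass(sm, labels, ids)
    areas = ndi.sum_labels(np.ones_like(labels), labels, ids)
    means = ndi.mean(dna, labels, ids)
    return pd.DataFrame({
        "label": ids.astype(int),
        "centroid_r": [c[0] for c in coms],
        "centroid_c": [c[1] for c in coms],
        "area": areas.astype(float),
        "mean_dna": np.atleast_1d(means).astype(float),
    })


def auto_phh3_threshold(phh3_means: np.ndarray) -> float:
    """Mitotic gate: mean + 3·SD of the lower mode of per-nucleus PHH3 means.

    The lower (interphase) mode is isolated with an Otsu split of the
    per-nucleus means; if the means are effectively unimodal the whole
    population is treated as the lower mode.  Requires >= 10 nuclei.
    """
    x = np.asarray(phh3_means, dtype=float)
    if x.size < 10:
        raise ValueError("auto PHH3 threshold needs at least 10 nuclei")
    if np.ptp(x) <= 1e-12:
        return float(x[0])  # all identical: nothing exceeds the gate (strict >)
    split = threshold_otsu(x)
    lower = x[x <= split]
    if lower.size < 2:
        lower = x
    return float(lower.mean() + 3.0 * lower.std())


def classify_mitotic(nuclei: pd.DataFrame, labels: np.ndarray, phh3: np.ndarray,
                     params: PipelineParams | None = None) -> pd.DataFrame:
    """Flag mitotic nuclei: mean PHH3 over the nucleus mask > threshold."""
    params = params or PipelineParams()
    nuclei = nuclei.copy()
    if nuclei.empty:
        nuclei["mean_phh3"] = pd.Series(dtype=float)
        nuclei["is_mitotic"] = pd.Series(dtype=bool)
        return nuclei
    ids = nuclei["label"].to_numpy()
    means = np.atleast_1d(ndi.mean(np.asarray(phh3, dtype=float), labels, ids))
    if params.phh3_threshold == "auto":
        thr = auto_phh3_threshold(means)
    else:
        thr = float(params.phh3_threshold)
    nuclei["mean_phh3"] = means
    nuclei["is_mitotic"] = means > thr
    return nuclei


# ---------------------------------------------------------------------------
# Cytoplasm segmentation
# ---------------------------------------------------------------------------

def _rfp_mask(rfp: np.ndarray, params: PipelineParams) -> np.ndarray:
    sm = ndi.gaussian_filter(np.asarray(rfp, dtype=float), params.nucleus_smooth_sigma)
    if np.ptp(sm) <= 1e-12:
        return np.zeros(sm.shape, dtype=bool)
    return sm > threshold_otsu(sm)


def segment_mitotic_cells(rfp: np.ndarray, nuclei: pd.DataFrame, labels: np.ndarray,
                          params: PipelineParams | None = None
                          ) -> dict[int, dict]:
    """Grow one cytoplasm mask per mitotic nucleus over RFP-positive pixels.

    All nuclei seed the watershed so neighbouring cells constrain each other;
    masks are therefore disjoint.  A mitotic nucleus with no surrounding RFP
    signal falls back to its own nucleus mask.  Returns
    ``{nucleus label: {"mask": bool array, "touches_edge": bool}}``.
    """
    params = params or PipelineParams()
    mask = _rfp_mask(rfp, params)
    sm = ndi.gaussian_filter(np.asarray(rfp, dtype=float), params.nucleus_smooth_sigma)
    region = mask | (labels > 0)
    ws = watershed(-sm, markers=labels, mask=region)
    out: dict[int, dict] = {}
    mitotic_ids = nuclei.loc[nuclei["is_mitotic"], "label"].astype(int)
    for lab in mitotic_ids:
        cell = ws == lab
        if not cell.any():
            cell = labels == lab
        touches = bool(cell[0, :].any() or cell[-1, :].any()
                       or cell[:, 0].any() or cell[:, -1].any())
        out[int(lab)] = {"mask": cell, "touches_edge": touches}
    return out


def roundness(mask: np.ndarray) -> float:
    """Isoperimetric roundness 4πA/P² of a binary mask (1.0 = perfect disc).

    The perimeter is the 4-direction Crofton estimate, which is close to the
    true contour length for smooth shapes and heavily penalizes 1-px-thin
    structures — the regime the roundness QC is meant to reject.
    """
    area = float(mask.sum())
    if area == 0:
        return 0.0
    per = float(_perimeter(mask, directions=4))
    if per <= 0:
        return 1.0
    return min(4.0 * math.pi * area / per**2, 1.0)


def qc_filter(cells: dict[int, dict], tubulin: np.ndarray,
              params: PipelineParams | None = None) -> dict[int, dict]:
    """Set each mitotic cell's exclusion reason, in order edge → roundness →
    low_tubulin (strict inequalities); kept cells get reason ``"none"``."""
    params = params or PipelineParams()
    tub = np.asarray(tubulin, dtype=float)
    for lab, cell in cells.items():
        mask = cell["mask"]
        cell["roundness"] = roundness(mask)
        cell["tubulin_mean"] = float(tub[mask].mean()) if mask.any() else 0.0
        if cell["touches_edge"]:
            cell["exclusion_reason"] = "edge"
        elif cell["roundness"] < params.roundness_min:
            cell["exclusion_reason"] = "roundness"
        elif cell["tubulin_mean"] < params.tubulin_mean_min:
            cell["exclusion_reason"] = "low_tubulin"
        else:
            cell["exclusion_reason"] = "none"
    return cells


# ---------------------------------------------------------------------------
# Spindle-pole detection
# ---------------------------------------------------------------------------

def masked_smooth(img: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing normalized to the mask, so that signal outside the
    cell does not bleed in.  Pixels outside the mask hold the extrapolated
    in-mask estimate (used only for path sampling between peaks)."""
    img = np.asarray(img, dtype=float)
    m = mask.astype(float)
    if sigma <= 0:
        return img.copy()
    num = ndi.gaussian_filter(img * m, sigma)
    den = ndi.gaussian_filter(m, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), 0.0)
    return out


def _local_maxima(sm: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """8-connected local maxima of ``sm`` restricted to ``mask``.

    A pixel is a candidate when its value is >= all in-mask 8-neighbours
    (out-of-mask neighbours are ignored); connected plateaus of equal value
    contribute their lexicographically smallest pixel.
    """
    work = np.where(mask, sm, -np.inf)
    padded = np.pad(work, 1, constant_values=-np.inf)
    center = padded[1:-1, 1:-1]
    is_max = np.ones_like(center, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr:padded.shape[0] - 1 + dr, 1 + dc:padded.shape[1] - 1 + dc]
            is_max &= center >= nb
    is_max &= mask
    if not is_max.any():
        return []
    # dedupe connected plateaus (adjacent candidates necessarily share a value)
    lab, n = ndi.label(is_max, structure=np.ones((3, 3), dtype=int))
    peaks = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(lab == i)
        order = np.lexsort((cc, rr))
        peaks.append((int(rr[order[0]]), int(cc[order[0]])))
    return peaks


def path_min(sm: np.ndarray, a: tuple[int, int], b: tuple[int, int]) -> float:
    """Minimum of bilinear-interpolated samples along the straight segment
    a→b, at ``ceil(2·distance)+1`` evenly spaced points (inclusive)."""
    dist = math.hypot(a[0] - b[0], a[1] - b[1])
    n = max(int(math.ceil(2 * dist)) + 1, 2)
    rows = np.linspace(a[0], b[0], n)
    cols = np.linspace(a[1], b[1], n)
    vals = ndi.map_coordinates(sm, np.vstack([rows, cols]), order=1, mode="nearest")
    return float(vals.min())


def detect_spindle_poles(tubulin: np.ndarray, mask: np.ndarray,
                         params: PipelineParams | None = None) -> list[SpindlePole]:
    """Count spindle poles inside a cytoplasm mask.

    1. smooth the tubulin channel with a mask-normalized Gaussian;
    2. find 8-connected local maxima inside the mask;
    3. keep maxima with relative spot intensity
       ``r = (I_peak − bg) / (I_max − bg) > rel_spot_intensity_min`` where
       ``bg`` is the median smoothed intensity over the mask;
    4. iteratively merge pairs lacking a sufficient valley: while any
       surviving pair has ``path_min > splitting_coefficient · I_dimmer``,
       delete the dimmest such dim member (ties broken by position).

    Raises ``ValueError`` on an empty mask; warns and returns no poles when
    the mask is smaller than the smoothing kernel footprint.
    """
    params = params or PipelineParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cytoplasm mask")
    kernel_area = (2 * int(math.ceil(2 * params.smoothing_sigma)) + 1) ** 2
    if mask.sum() < kernel_area:
        warnings.warn("mask smaller than the smoothing kernel; reporting 0 poles")
        return []
    sm = masked_smooth(tubulin, mask, params.smoothing_sigma)
    inmask = sm[mask]
    bg = float(np.median(inmask))
    vmax = float(inmask.max())
    if vmax - bg <= 1e-12:
        return []
    peaks = []
    for pos in _local_maxima(sm, mask):
        v = float(sm[pos])
        r = (v - bg) / (vmax - bg)
        if r > params.rel_spot_intensity_min:
            peaks.append(SpindlePole(position=pos, peak_intensity=v, relative_intensity=r))
    # merge step: while any pair lacks a sufficient valley, delete the
    # dimmest dim member of such a pair (deterministic tie-break by position)
    def rank(p: SpindlePole):
        return (p.peak_intensity, -p.position[0], -p.position[1])

    while len(peaks) > 1:
        removable = []
        for i in range(len(peaks)):
            for j in range(i + 1, len(peaks)):
                hi, lo = peaks[i], peaks[j]
                if rank(hi) < rank(lo):
                    hi, lo = lo, hi
                valley = path_min(sm, hi.position, lo.position)
                if valley > params.splitting_coefficient * lo.peak_intensity:
                    removable.append(lo)
        if not removable:
            break
        victim = min(removable, key=rank)
        peaks = [p for p in peaks if p is not victim]
    return sorted(peaks, key=lambda p: p.position)


def classify_multipolar(n_poles: int, params: PipelineParams | None = None) -> bool:
    """Multipolar ⇔ pole count strictly greater than two (>= the minimum)."""
    params = params or PipelineParams()
    return n_poles >= params.multipolar_pole_count_min


# ---------------------------------------------------------------------------
# Multinucleate detection (interphase)
# ---------------------------------------------------------------------------

def detect_multinucleate(rfp: np.ndarray, nuclei: pd.DataFrame, labels: np.ndarray,
                         params: PipelineParams | None = None) -> pd.DataFrame:
    """Count nuclei per interphase RFP body.

    Mitotic nuclei are excluded first; RFP bodies are connected components of
    the RFP-positive mask united with the nucleus masks (so every nucleus
    belongs to a body).  A body containing a mitotic nucleus is dropped from
    the interphase analysis; bodies touching the field edge are flagged and
    excluded from the multinucleate denominator.  Returns one row per
    interphase body: ``body_id, n_nuclei, is_multinucleate, touches_edge,
    centroid_r, centroid_c``.
    """
    params = params or PipelineParams()
    mask = _rfp_mask(rfp, params) | (labels > 0)
    bodies, n_bodies = ndi.label(mask)
    rows = []
    if n_bodies == 0 or nuclei.empty:
        return pd.DataFrame(columns=["body_id", "n_nuclei", "is_multinucleate",
                                     "touches_edge", "centroid_r", "centroid_c"])
    mitotic = set(nuclei.loc[nuclei["is_mitotic"], "label"].astype(int))
    # body id of each nucleus, read at its centroid (nuclei lie inside bodies)
    nuc_body: dict[int, int] = {}
    for rec in nuclei.itertuples(index=False):
        r, c = int(round(rec.centroid_r)), int(round(rec.centroid_c))
        r = np.clip(r, 0, bodies.shape[0] - 1)
        c = np.clip(c, 0, bodies.shape[1] - 1)
        b = int(bodies[r, c])
        if b == 0:  # centroid off-body (concave nucleus): use the label mask
            bb = bodies[labels == rec.label]
            bb = bb[bb > 0]
            b = int(bb[0]) if bb.size else 0
        nuc_body[int(rec.label)] = b
    for b in range(1, n_bodies + 1):
        nucs = [lab for lab, bb in nuc_body.items() if bb == b]
        if not nucs or any(lab in mitotic for lab in nucs):
            continue
        body = bodies == b
        touches = bool(body[0, :].any() or body[-1, :].any()
                       or body[:, 0].any() or body[:, -1].any())
        com = ndi.center_of_mass(body)
        rows.append({"body_id": b, "n_nuclei": len(nucs),
                     "is_multinucleate": len(nucs) >= 2, "touches_edge": touches,
                     "centroid_r": com[0], "centroid_c": com[1]})
    return pd.DataFrame(rows, columns=["body_id", "n_nuclei", "is_multinucleate",
                                       "touches_edge", "centroid_r", "centroid_c"])


# ---------------------------------------------------------------------------
# Spindle marker intensity (e.g. HSET)
# ---------------------------------------------------------------------------

def measure_spindle_intensity(marker: np.ndarray, dna: np.ndarray,
                              dna_mitotic_threshold: float,
                              params: PipelineParams | None = None,
                              window_radius: int = 40,
                              marker_threshold: float | None = None) -> pd.DataFrame:
    """Measure a spindle-bound marker in mitotic cells.

    Mitotic nuclei are identified by a DNA-intensity threshold (condensed
    mitotic chromatin is brighter); the spindle region is segmented by
    thresholding the marker channel in a window around each mitotic nucleus
    (Otsu unless ``marker_threshold`` is given).  Returns per-cell mean and
    integrated marker intensity; cells with no supra-threshold marker signal
    are recorded as missing (NaN), not zero.
    """
    params = params or PipelineParams()
    labels, nuclei = segment_nuclei(dna, params)
    marker = np.asarray(marker, dtype=float)
    rows = []
    for rec in nuclei.itertuples(index=False):
        if rec.mean_dna <= dna_mitotic_threshold:
            continue
        r, c = int(round(rec.centroid_r)), int(round(rec.centroid_c))
        r0, r1 = max(0, r - window_radius), min(marker.shape[0], r + window_radius + 1)
        c0, c1 = max(0, c - window_radius), min(marker.shape[1], c + window_radius + 1)
        win = marker[r0:r1, c0:c1]
        thr = marker_threshold if marker_threshold is not None else (
            threshold_otsu(win) if np.ptp(win) > 1e-12 else np.inf)
        region = win > thr
        if not region.any():
            rows.append({"label": int(rec.label), "mean_intensity": np.nan,
                         "integrated_intensity": np.nan, "spindle_area": 0})
            continue
        vals = win[region]
        rows.append({"label": int(rec.label), "mean_intensity": float(vals.mean()),
                     "integrated_intensity": float(vals.sum()),
                     "spindle_area": int(region.sum())})
    return pd.DataFrame(rows, columns=["label", "mean_intensity",
                                       "integrated_intensity", "spindle_area"])


# ---------------------------------------------------------------------------
# Field orchestration and well summaries
# ---------------------------------------------------------------------------

def process_field(image: FieldImage, params: PipelineParams | None = None) -> pd.DataFrame:
    """Run the full per-cell analysis on one field.

    Returns one row per analysed cell: mitotic cells (one per mitotic
    nucleus, with QC reason and pole count) and interphase RFP bodies (with
    nucleus counts).  Column ``kind`` is ``"mitotic"`` or ``"interphase"``.
    """
    params = params or PipelineParams()
    labels, nuclei = segment_nuclei(image["dna"], params)
    nuclei = classify_mitotic(nuclei, labels, image["phh3"], params)
    rows = []
    cells = segment_mitotic_cells(image["rfp"], nuclei, labels, params)
    cells = qc_filter(cells, image["tubulin"], params)
    nuc_by_label = nuclei.set_index("label")
    for lab, cell in sorted(cells.items()):
        n_poles = 0
        if cell["exclusion_reason"] == "none":
            poles = detect_spindle_poles(image["tubulin"], cell["mask"], params)
            n_poles = len(poles)
        rows.append({
            "well": image.well, "field": image.field_id, "cell_id": int(lab),
            "kind": "mitotic", "centroid_r": float(nuc_by_label.loc[lab, "centroid_r"]),
            "centroid_c": float(nuc_by_label.loc[lab, "centroid_c"]),
            "touches_edge": cell["touches_edge"], "roundness": cell["roundness"],
            "tubulin_mean": cell["tubulin_mean"],
            "exclusion_reason": cell["exclusion_reason"],
            "n_poles": n_poles,
            "is_multipolar": (cell["exclusion_reason"] == "none"
                              and classify_multipolar(n_poles, params)),
            "n_nuclei": 1, "is_multinucleate": False,
        })
    bodies = detect_multinucleate(image["rfp"], nuclei, labels, params)
    for rec in bodies.itertuples(index=False):
        rows.append({
            "well": image.well, "field": image.field_id, "cell_id": -int(rec.body_id),
            "kind": "interphase", "centroid_r": float(rec.centroid_r),
            "centroid_c": float(rec.centroid_c), "touches_edge": bool(rec.touches_edge),
            "roundness": np.nan, "tubulin_mean": np.nan, "exclusion_reason": "none",
            "n_poles": 0, "is_multipolar": False,
            "n_nuclei": int(rec.n_nuclei), "is_multinucleate": bool(rec.is_multinucleate),
        })
    return pd.DataFrame(rows, columns=["well", "field", "cell_id", "kind", "centroid_r",
                                       "centroid_c", "touches_edge", "roundness",
                                       "tubulin_mean", "exclusion_reason", "n_poles",
                                       "is_multipolar", "n_nuclei", "is_multinucleate"])


def summarize_well(records: pd.DataFrame, well: str | None = None) -> dict:
    """Reduce one well's cell records to the five screen features.

    ``n_cells`` counts all detected nuclei; ``mitotic_index`` is mitotic /
    total nuclei; ``pct_multipolar`` and ``mean_poles`` are computed over
    QC-kept mitotic cells (cells with zero detected poles are retained and
    contribute zero); ``pct_multinucleate`` is over non-edge interphase
    bodies.  Empty denominators yield NaN (recorded as missing).
    """
    mit = records[records["kind"] == "mitotic"]
    inter = records[records["kind"] == "interphase"]
    kept = mit[mit["exclusion_reason"] == "none"]
    inter_ok = inter[~inter["touches_edge"]]
    n_nuclei = int(mit.shape[0] + inter["n_nuclei"].sum())
    n_mitotic = int(mit.shape[0])
    out = {
        "well": well if well is not None else (records["well"].iloc[0] if len(records) else ""),
        "n_cells": n_nuclei,
        "mitotic_index": n_mitotic / n_nuclei if n_nuclei else np.nan,
        "pct_multipolar": 100.0 * kept["is_multipolar"].mean() if len(kept) else np.nan,
        "mean_poles": float(kept["n_poles"].mean()) if len(kept) else np.nan,
        "pct_multinucleate": (100.0 * inter_ok["is_multinucleate"].mean()
                              if len(inter_ok) else np.nan),
    }
    return out
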