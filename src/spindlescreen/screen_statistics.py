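"""Gene-level screen statistics.

Turns per-well feature tables into replicate-agreement correlations,
plate-normalized Z-scores, differential Z-scores (dZ = Z_NS − Z_chTOG), hit
calls against control-well spread, hit-rate summaries, and multiplicative
genetic-interaction (epistasis) scores.

Conventions
-----------
* Z-scores are computed per plate (background × replicate) per feature
  against all library *sample* wells of that plate, then averaged across the
  duplicate plates; a robust median/MAD variant is available.
* Hit calling operates on raw ``pct_multipolar``: a gene's replicate-mean
  must lie strictly more than ``k`` control-well standard deviations from
  the control-well mean (controls pooled across the replicate plates).
* The interaction score normalizes phenotypes to the reference perturbation
  (``w = p / p_ref``, control = 1) and measures the deviation of the double
  from the multiplicative expectation, ``epsilon = w_AB − w_A · w_B``.
  Severity here is the % multipolar phenotype, so a double *less* severe
  than expected (alleviating) has negative epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: The five per-well screen features.
FEATURES = ("n_cells", "mitotic_index", "pct_multipolar", "mean_poles", "pct_multinucleate")

BACKGROUNDS = ("NS", "chTOG")


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class InteractionResult:
    w_a: float
    w_b: float
    w_ab: float
    expected: float
    epsilon: float
    classification: str  # alleviating | aggravating | none


def replicate_correlation(plate_a: pd.DataFrame, plate_b: pd.DataFrame,
                          feature: str = "pct_multipolar", method: str = "auto",
                          n_permutations: int = 10000, seed: int = 0) -> CorrelationResult:
    """Spearman rank correlation of one feature between replica plates.

    Wells are paired on the ``well`` column; both plates must share the same
    well→gene map.  ``method="t"`` uses the t-approximation for the p-value,
    ``"permutation"`` a permutation null; ``"auto"`` permutes when n < 20.
    Requires at least 3 paired wells with finite values.
    """
    merged = plate_a[["well", feature]].merge(plate_b[["well", feature]],
                                              on="well", suffixes=("_a", "_b"))
    merged = merged.dropna()
    n = len(merged)
    if n < 3:
        raise ValueError(f"need at least 3 paired wells, got {n}")
    x = merged[f"{feature}_a"].to_numpy(float)
    y = merged[f"{feature}_b"].to_numpy(float)
    rho, p_t = stats.spearmanr(x, y)
    if method == "auto":
        method = "permutation" if n < 20 else "t"
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            r_perm, _ = stats.spearmanr(x, rng.permutation(y))
            if abs(r_perm) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        p = p_t
    return CorrelationResult(feature=feature, rho=float(rho), p=float(p), n=n)


def _plate_reference(values: np.ndarray, robust: bool) -> tuple[float, float]:
    if robust:
        mu = float(np.median(values))
        sigma = float(stats.median_abs_deviation(values, scale="normal"))
    else:
        mu = float(values.mean())
        sigma = float(values.std(ddof=1))
    return mu, sigma


def compute_zscores(wells: pd.DataFrame, features: tuple[str, ...] = FEATURES,
                    robust: bool = False) -> pd.DataFrame:
    """Per-gene Z, per background, averaged over replicate plates, plus dZ.

    For each plate (background × replicate) and feature, Z = (x − μ)/σ with
    μ, σ taken over that plate's library sample wells; the two replicate Z
    values are then averaged per gene.  Output: one row per (gene, feature)
    with columns ``Z_NS, Z_chTOG, dZ`` where ``dZ = Z_NS − Z_chTOG``.

    Raises ``ValueError`` naming the feature if a plate's reference σ is 0.
    Genes with missing feature values are dropped from that feature's table
    with a warning.
    """
    rows = []
    for (bg, rep), plate in wells.groupby(["background", "replicate"]):
        samples = plate[plate["role"] == "sample"]
        for feat in features:
            vals = samples[feat].to_numpy(float)
            ok = np.isfinite(vals)
            if ok.sum() < 2:
                raise ValueError(f"not enough sample wells to normalize {feat!r} "
                                 f"on plate {bg}/rep{rep}")
            mu, sigma = _plate_reference(vals[ok], robust)
            if sigma <= 0:
                raise ValueError(f"degenerate feature {feat!r}: zero spread on "
                                 f"plate {bg}/rep{rep}")
            z = (samples[feat].to_numpy(float) - mu) / sigma
            for gene, zi in zip(samples["gene"], z):
                rows.append({"gene": gene, "background": bg, "replicate": rep,
                             "feature": feat, "Z": zi})
    per_plate = pd.DataFrame(rows)
    dropped = per_plate[~np.isfinite(per_plate["Z"])]
    if len(dropped):
        genes = sorted(dropped["gene"].unique())
        warnings.warn(f"dropping genes with missing feature values: {genes}")
        per_plate = per_plate[np.isfinite(per_plate["Z"])]
    avg = (per_plate.groupby(["gene", "feature", "background"])["Z"]
           .mean().unstack("background"))
    avg.columns = [f"Z_{c}" for c in avg.columns]
    out = avg.reset_index()
    if "Z_NS" in out and "Z_chTOG" in out:
        out["dZ"] = out["Z_NS"] - out["Z_chTOG"]
    out = out.dropna().reset_index(drop=True)
    return out


def call_hits(wells: pd.DataFrame, k: float = 1.5,
              feature: str = "pct_multipolar") -> pd.DataFrame:
    """Classify each gene as suppressor / enhancer / none per background.

    A gene's mean ``feature`` across replicate plates is compared against the
    mean and SD of the individual control-siRNA wells (role ``"control"``)
    pooled across both plates of the same background: enhancer if strictly
    above μ + k·σ, suppressor if strictly below μ − k·σ.

    Requires at least 2 control wells per background.
    """
    rows = []
    for bg, sub in wells.groupby("background"):
        ctrl = sub.loc[sub["role"] == "control", feature].dropna()
        if len(ctrl) < 2:
            raise ValueError(f"background {bg!r}: need >= 2 control wells, got {len(ctrl)}")
        mu_c = float(ctrl.mean())
        sd_c = float(ctrl.std(ddof=1))
        samples = sub[sub["role"] == "sample"]
        means = samples.groupby("gene")[feature].mean()
        for gene, m in means.items():
            if not np.isfinite(m):
                cls = "none"
            elif m > mu_c + k * sd_c:
                cls = "enhancer"
            elif m < mu_c - k * sd_c:
                cls = "suppressor"
            else:
                cls = "none"
            rows.append({"gene": gene, "background": bg, "mean_value": float(m),
                         "control_mean": mu_c, "control_sd": sd_c, "k": k,
                         "class": cls})
    return pd.DataFrame(rows)


def summarize_hits(hitcalls: pd.DataFrame | None, library_size: int,
                   n_suppressors: int | None = None,
                   n_enhancers: int | None = None) -> pd.DataFrame:
    """Per-background hit counts and the percentage of the library hit.

    Either pass a ``call_hits`` table, or (for echoing printed summaries)
    explicit counts with ``hitcalls=None``.  ``pct_hits`` is reported to one
    decimal place: 100 · (suppressors + enhancers) / library size.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    rows = []
    if hitcalls is None:
        ns, ne = int(n_suppressors or 0), int(n_enhancers or 0)
        rows.append({"background": "", "n_suppressors": ns, "n_enhancers": ne,
                     "pct_hits": round(100.0 * (ns + ne) / library_size, 1)})
    else:
        for bg, sub in hitcalls.groupby("background"):
            ns = int((sub["class"] == "suppressor").sum())
            ne = int((sub["class"] == "enhancer").sum())
            rows.append({"background": bg, "n_suppressors": ns, "n_enhancers": ne,
                         "pct_hits": round(100.0 * (ns + ne) / library_size, 1)})
    return pd.DataFrame(rows, columns=["background", "n_suppressors", "n_enhancers",
                                       "pct_hits"])


def proportion(numerator: int, denominator: int, digits: int | None = None) -> float:
    """Percentage ``100 · numerator / denominator``; optionally rounded
    (report-style summaries round to the nearest integer, ``digits=0``)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    pct = 100.0 * numerator / denominator
    return round(pct, digits) if digits is not None else pct


def interaction_score(p_ref: float, p_a: float, p_b: float, p_ab: float,
                      epsilon_threshold: float = 0.25) -> InteractionResult:
    """Multiplicative genetic-interaction score on normalized phenotypes.

    Phenotypes (e.g. % multipolar) are normalized to the reference
    perturbation: ``w_X = p_X / p_ref`` so the reference itself scores 1.
    The multiplicative expectation for the double is ``w_A · w_B`` and
    ``epsilon = w_AB − w_A · w_B``.  With severity-scaled phenotypes,
    ``epsilon < −threshold`` classifies as alleviating (double less severe
    than expected) and ``epsilon > +threshold`` as aggravating.

    The score is invariant to rescaling all four phenotypes by a common
    factor.  Requires ``p_ref > 0`` and all inputs in [0, 100].
    """
    for name, v in (("p_ref", p_ref), ("p_a", p_a), ("p_b", p_b), ("p_ab", p_ab)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    if p_ref <= 0:
        raise ValueError("p_ref must be > 0")
    w_a = p_a / p_ref
    w_b = p_b / p_ref
    w_ab = p_ab / p_ref
    expected = w_a * w_b
    epsilon = w_ab - expected
    if epsilon < -epsilon_threshold:
        cls = "alleviating"
    elif epsilon > epsilon_threshold:
        cls = "aggravating"
    else:
        cls = "none"
    return InteractionResult(w_a=w_a, w_b=w_b, w_ab=w_ab, expected=expected,
                             epsilon=epsilon, classification=cls)
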