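"""Synthetic fluorescence fields and screen tables with known ground truth.

Two generators stand in for the data a sensitized double-RNAi spindle screen
would produce:

* :func:`simulate_field` renders one four-channel field (DNA / PHH3 / RFP /
  alpha-tubulin) containing interphase cells (1-2+ nuclei per RFP body) and
  mitotic cells with a configurable number of tubulin pole foci, plus
  Poisson + Gaussian imaging noise, and returns per-cell ground truth.
* :func:`simulate_screen_tables` skips imaging altogether and draws the five
  per-well screen features (cell count, mitotic index, % multipolar,
  mean poles/cell, % multinucleate) from an explicit per-gene effect model,
  for a duplicate two-background (NS vs ch-TOG shRNA) plate layout.

Both are deterministic under a fixed seed.  Intensities live on a continuous
8-bit-like scale (0-255); ``eight_bit=True`` quantizes to integers so that
absolute intensity thresholds (e.g. the mean-tubulin QC cut of 30) operate on
their native scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

CHANNELS = ("dna", "phh3", "rfp", "tubulin")

#: Per-well screen features, in fixed column order.
FEATURES = ("n_cells", "mitotic_index", "pct_multipolar", "mean_poles", "pct_multinucleate")

# Default rendering intensities (8-bit-like scale).  Peak tubulin focus over
# background is ~8x, the regime where local-maxima pole counting is reliable
# but not trivial.
DEFAULT_BACKGROUND = {"dna": 8.0, "phh3": 4.0, "rfp": 5.0, "tubulin": 24.0}
DEFAULT_POLE_AMPLITUDE = 200.0
DEFAULT_PHH3_LEVEL = 90.0
DNA_AMP_INTERPHASE = 100.0
DNA_AMP_MITOTIC = 170.0
RFP_AMP = 70.0
TUBULIN_HAZE_AMP = 12.0
TUBULIN_CYTO_AMP = 8.0
POLE_SIGMA = 2.5
NUCLEUS_SIGMA_FRAC = 0.28   # interphase nucleus sigma as a fraction of cell radius
MITOTIC_SIGMA_FRAC = 0.20   # condensed mitotic chromatin is tighter and brighter
POLE_RING_FRAC = 0.60       # pole foci sit on a ring at this fraction of the radius


class FieldOverlapError(ValueError):
    """Cell bodies overlap beyond tolerance; segmentation truth is ill-defined."""


@dataclass(frozen=True)
class CellSpec:
    """Geometry and intensity of one simulated cell.

    ``kind`` is ``"interphase"`` or ``"mitotic"``.  Mitotic cells have exactly
    one (condensed) nucleus and ``n_poles`` tubulin foci at
    ``pole_positions``; interphase cells have ``n_nuclei`` nuclei and no
    poles.  Positions are ``(row, col)`` pixel coordinates, 0-based.
    """

    center: tuple[float, float]
    kind: str
    cell_radius: float = 26.0
    n_nuclei: int = 1
    n_poles: int = 0
    pole_positions: tuple[tuple[float, float], ...] = ()
    pole_amplitude: float = DEFAULT_POLE_AMPLITUDE
    phh3_level: float = DEFAULT_PHH3_LEVEL

    def __post_init__(self) -> None:
        if self.kind not in ("interphase", "mitotic"):
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")
        if self.kind == "mitotic":
            if self.n_nuclei != 1:
                raise ValueError("mitotic cells have exactly one nucleus")
            if len(self.pole_positions) != self.n_poles:
                raise ValueError("len(pole_positions) must equal n_poles")
            for p in self.pole_positions:
                d = math.hypot(p[0] - self.center[0], p[1] - self.center[1])
                if d > self.cell_radius:
                    raise ValueError("pole positions must lie inside the cell radius")
        else:
            if self.n_nuclei < 1:
                raise ValueError("interphase cells need n_nuclei >= 1")
            if self.n_poles or self.pole_positions:
                raise ValueError("interphase cells have no spindle poles")

    @property
    def is_multipolar(self) -> bool:
        return self.kind == "mitotic" and self.n_poles > 2


@dataclass(frozen=True)
class FieldSimConfig:
    """Everything needed to render one field deterministically."""

    field_size: tuple[int, int] = (448, 448)
    cells: tuple[CellSpec, ...] = ()
    background: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    poisson_scale: float = 0.8   # photons per intensity unit; 0 disables shot noise
    gaussian_sd: float = 2.5     # additive read noise, intensity units
    psf_sigma: float = 1.2       # in-plane PSF approximation, px
    seed: int = 0
    overlap_tolerance: float = 0.1  # allowed fractional overlap of radii
    eight_bit: bool = False

    def __post_init__(self) -> None:
        h, w = self.field_size
        if h <= 0 or w <= 0:
            raise ValueError("field_size must be positive")
        for name, level in self.background.items():
            if level < 0:
                raise ValueError(f"background[{name!r}] must be >= 0")
        if self.poisson_scale < 0 or self.gaussian_sd < 0 or self.psf_sigma < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class FieldImage:
    """One imaged field: co-registered 2-D channels plus metadata."""

    channels: dict[str, np.ndarray]
    well: str = ""
    field_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def _add_blob(img: np.ndarray, center: tuple[float, float], sigma_r: float,
              sigma_c: float, amplitude: float, theta: float = 0.0) -> None:
    """Add an (optionally rotated anisotropic) Gaussian blob in place."""
    h, w = img.shape
    extent = 4.0 * max(sigma_r, sigma_c)
    r0 = max(0, int(center[0] - extent))
    r1 = min(h, int(center[0] + extent) + 1)
    c0 = max(0, int(center[1] - extent))
    c1 = min(w, int(center[1] + extent) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    if theta:
        u = dr * math.cos(theta) + dc * math.sin(theta)
        v = -dr * math.sin(theta) + dc * math.cos(theta)
    else:
        u, v = dr, dc
    img[r0:r1, c0:c1] += amplitude * np.exp(-0.5 * ((u / sigma_r) ** 2 + (v / sigma_c) ** 2))


def _add_disc(img: np.ndarray, center: tuple[float, float], radius: float,
              amplitude: float) -> None:
    h, w = img.shape
    r0 = max(0, int(center[0] - radius) - 1)
    r1 = min(h, int(center[0] + radius) + 2)
    c0 = max(0, int(center[1] - radius) - 1)
    c1 = min(w, int(center[1] + radius) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    img[r0:r1, c0:c1] += amplitude * inside


def _nucleus_centers(cell: CellSpec) -> list[tuple[float, float]]:
    """Deterministic nucleus placement: 1 at the center, >=2 on a small ring."""
    if cell.n_nuclei == 1:
        return [cell.center]
    off = 0.45 * cell.cell_radius
    out = []
    for i in range(cell.n_nuclei):
        ang = 2 * math.pi * i / cell.n_nuclei
        out.append((cell.center[0] + off * math.sin(ang), cell.center[1] + off * math.cos(ang)))
    return out


def _check_overlaps(cells: tuple[CellSpec, ...], tolerance: float) -> None:
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < (a.cell_radius + b.cell_radius) * (1.0 - tolerance):
                raise FieldOverlapError(
                    f"cells {i} and {j} overlap beyond tolerance "
                    f"(distance {d:.1f} px, radii {a.cell_radius:.1f}+{b.cell_radius:.1f})"
                )


def render_clean_field(config: FieldSimConfig) -> dict[str, np.ndarray]:
    """Render noise-free, background-free channels (before PSF and noise)."""
    shape = config.field_size
    chans = {name: np.zeros(shape, dtype=float) for name in CHANNELS}
    for cell in config.cells:
        r = cell.cell_radius
        _add_disc(chans["rfp"], cell.center, r, RFP_AMP)
        _add_disc(chans["tubulin"], cell.center, r, TUBULIN_CYTO_AMP)
        if cell.kind == "interphase":
            sig = NUCLEUS_SIGMA_FRAC * r
            for nc in _nucleus_centers(cell):
                _add_blob(chans["dna"], nc, sig, sig, DNA_AMP_INTERPHASE)
        else:
            sig = MITOTIC_SIGMA_FRAC * r
            _add_blob(chans["dna"], cell.center, sig, sig, DNA_AMP_MITOTIC)
            _add_blob(chans["phh3"], cell.center, sig, sig, cell.phh3_level)
            if cell.n_poles:
                poles = np.asarray(cell.pole_positions, dtype=float)
                centroid = poles.mean(axis=0)
                if cell.n_poles >= 2:
                    # diffuse spindle body: an anisotropic Gaussian spanning the poles
                    d = poles - centroid
                    spread = math.sqrt(float((d**2).sum(axis=1).max()))
                    along = max(0.35 * r, spread / 1.6)
                    across = 0.30 * r
                    # theta chosen so the first sigma acts along the pole axis
                    theta = math.atan2(d[0, 1], d[0, 0]) if spread > 0 else 0.0
                    _add_blob(chans["tubulin"], tuple(centroid), along, across,
                              TUBULIN_HAZE_AMP, theta=theta)
                else:
                    s = 0.30 * r
                    _add_blob(chans["tubulin"], tuple(centroid), s, s, TUBULIN_HAZE_AMP)
                for p in cell.pole_positions:
                    _add_blob(chans["tubulin"], p, POLE_SIGMA, POLE_SIGMA, cell.pole_amplitude)
    return chans


def simulate_field(config: FieldSimConfig, well: str = "", field_id: int = 0
                   ) -> tuple[FieldImage, pd.DataFrame]:
    """Render a field and its per-cell ground-truth table.

    Returns ``(FieldImage, truth)`` where ``truth`` has one row per cell:
    ``cell_index, row, col, kind, cell_radius, n_nuclei, n_poles,
    is_multipolar``.

    Raises
    ------
    FieldOverlapError
        If any two cell bodies overlap beyond ``config.overlap_tolerance``.
    """
    _check_overlaps(config.cells, config.overlap_tolerance)
    rng = np.random.default_rng(config.seed)
    chans = render_clean_field(config)
    for name in CHANNELS:
        img = chans[name]
        if config.psf_sigma > 0:
            img = gaussian_filter(img, config.psf_sigma)
        img = img + config.background.get(name, 0.0)
        if config.poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * config.poisson_scale) / config.poisson_scale
        if config.gaussian_sd > 0:
            img = img + rng.normal(0.0, config.gaussian_sd, size=img.shape)
        if config.eight_bit:
            img = np.clip(np.rint(img), 0, 255)
        chans[name] = img.astype(float)

    rows = []
    for i, cell in enumerate(config.cells):
        rows.append({
            "cell_index": i,
            "row": cell.center[0],
            "col": cell.center[1],
            "kind": cell.kind,
            "cell_radius": cell.cell_radius,
            "n_nuclei": cell.n_nuclei if cell.kind == "interphase" else 1,
            "n_poles": cell.n_poles if cell.kind == "mitotic" else 0,
            "is_multipolar": cell.is_multipolar,
        })
    truth = pd.DataFrame(rows, columns=["cell_index", "row", "col", "kind", "cell_radius",
                                        "n_nuclei", "n_poles", "is_multipolar"])
    image = FieldImage(channels=chans, well=well, field_id=field_id,
                       metadata={"seed": config.seed, "field_size": config.field_size})
    return image, truth


def ring_poles(center: tuple[float, float], radius: float, n_poles: int,
               rng: np.random.Generator | None = None) -> tuple[tuple[float, float], ...]:
    """Place ``n_poles`` foci on a ring inside a cell of the given radius.

    Bipolar cells get two opposed poles; higher counts are evenly spaced with
    a small angular jitter so fields are not artificially symmetric.
    """
    if n_poles == 0:
        return ()
    ring = POLE_RING_FRAC * radius
    if n_poles == 1:
        return ((center[0], center[1] + 0.2 * radius),)
    rot = float(rng.uniform(0, 2 * math.pi)) if rng is not None else 0.0
    out = []
    for i in range(n_poles):
        ang = rot + 2 * math.pi * i / n_poles
        if rng is not None and n_poles > 2:
            # jitter bounded to a fraction of the angular slot so that even
            # six-pole rings keep pairwise separations above the merge
            # resolution of the default detector settings
            ang += float(rng.uniform(-0.06, 0.06)) * 2 * math.pi / n_poles
        out.append((center[0] + ring * math.sin(ang), center[1] + ring * math.cos(ang)))
    return tuple(out)


def random_cell_layout(rng: np.random.Generator, field_size: tuple[int, int],
                       n_interphase: int, mitotic_pole_counts: list[int],
                       binucleate_fraction: float = 0.0, cell_radius: float = 26.0,
                       min_gap: float = 6.0, max_attempts: int = 500) -> tuple[CellSpec, ...]:
    """Dart-throwing placement of non-overlapping cells, fully inside the field.

    ``mitotic_pole_counts`` gives one entry per mitotic cell (its true pole
    count).  Raises ``RuntimeError`` if the field cannot accommodate the
    requested cells.
    """
    h, w = field_size
    margin = cell_radius + min_gap
    placed: list[tuple[float, float]] = []
    specs: list[CellSpec] = []

    def place() -> tuple[float, float]:
        for _ in range(max_attempts):
            r = float(rng.uniform(margin, h - margin))
            c = float(rng.uniform(margin, w - margin))
            if all((r - pr) ** 2 + (c - pc) ** 2 >= (2 * cell_radius + min_gap) ** 2
                   for pr, pc in placed):
                placed.append((r, c))
                return r, c
        raise RuntimeError("could not place all cells without overlap; "
                           "reduce cell count or enlarge the field")

    for k in mitotic_pole_counts:
        center = place()
        specs.append(CellSpec(center=center, kind="mitotic", cell_radius=cell_radius,
                              n_poles=k, pole_positions=ring_poles(center, cell_radius, k, rng)))
    for i in range(n_interphase):
        center = place()
        n_nuc = 2 if rng.uniform() < binucleate_fraction else 1
        specs.append(CellSpec(center=center, kind="interphase", cell_radius=cell_radius,
                              n_nuclei=n_nuc))
    return tuple(specs)


def simulate_well_fields(seed: int, n_fields: int = 4, mitotic_per_field: int = 6,
                         interphase_per_field: int = 8, multipolar_penetrance: float = 0.0,
                         multipolar_pole_mean: float = 3.6, binucleate_fraction: float = 0.05,
                         field_size: tuple[int, int] = (448, 448), well: str = "A01",
                         eight_bit: bool = False, **config_kwargs
                         ) -> list[tuple[FieldImage, pd.DataFrame]]:
    """Simulate all fields of one well under a multipolar-penetrance model.

    Each mitotic cell is multipolar with probability ``multipolar_penetrance``;
    multipolar cells draw their pole count as ``3 + Poisson(mean - 3)``
    (clipped at 6), others are bipolar.
    """
    rng = np.random.default_rng(seed)
    out = []
    for f in range(n_fields):
        pole_counts = []
        for _ in range(mitotic_per_field):
            if rng.uniform() < multipolar_penetrance:
                k = 3 + int(rng.poisson(max(multipolar_pole_mean - 3.0, 0.0)))
                pole_counts.append(min(k, 6))
            else:
                pole_counts.append(2)
        cells = random_cell_layout(rng, field_size, interphase_per_field, pole_counts,
                                   binucleate_fraction=binucleate_fraction)
        cfg = FieldSimConfig(field_size=field_size, cells=cells,
                             seed=int(rng.integers(0, 2**31 - 1)),
                             eight_bit=eight_bit, **config_kwargs)
        img, truth = simulate_field(cfg, well=well, field_id=f)
        out.append((img, truth))
    return out


# ---------------------------------------------------------------------------
# Tabular screen simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneEffect:
    """Per-gene, per-background generative parameters for one well."""

    multipolar_penetrance: float
    mean_pole_count: float = 3.6        # mean poles among multipolar cells (>=3)
    mitotic_fraction: float = 0.1
    multinucleate_fraction: float = 0.03
    cell_count_mean: float = 1200.0

    def __post_init__(self) -> None:
        for name in ("multipolar_penetrance", "mitotic_fraction", "multinucleate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_pole_count < 3.0:
            raise ValueError("mean_pole_count (given multipolar) must be >= 3")
        if self.cell_count_mean <= 0:
            raise ValueError("cell_count_mean must be > 0")


# Baseline conditions per shRNA background. The sensitized (ch-TOG) background
# runs at ~20% multipolar penetrance and a raised mitotic index; with ~1200
# cells/well this yields ~36 NS and ~260 ch-TOG mitotic cells per well.
DEFAULT_BASELINES = {
    "NS": GeneEffect(multipolar_penetrance=0.03, mitotic_fraction=0.03,
                     multinucleate_fraction=0.03, cell_count_mean=1200.0),
    "chTOG": GeneEffect(multipolar_penetrance=0.20, mitotic_fraction=0.22,
                        multinucleate_fraction=0.04, cell_count_mean=1200.0),
}


@dataclass
class GeneEffectModel:
    """Generative model of a duplicate two-background screen.

    ``overrides[(gene, background)]`` replaces the baseline :class:`GeneEffect`
    for that gene/background; the control gene defines the null.  Replicate
    plates carry a multiplicative batch factor on multipolar penetrance
    (``replicate_gain``), emulating day-to-day staining/imaging drift between
    the duplicate plates.
    """

    control_gene: str = "CTRL"
    baselines: dict[str, GeneEffect] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    overrides: dict[tuple[str, str], GeneEffect] = field(default_factory=dict)
    well_noise_sd: float = 0.03
    replicate_gain: dict[int, float] = field(default_factory=lambda: {1: 1.0, 2: 1.4})

    def __post_init__(self) -> None:
        if self.well_noise_sd < 0:
            raise ValueError("well_noise_sd must be >= 0")

    def effect(self, gene: str, background: str) -> GeneEffect:
        if background not in self.baselines:
            raise KeyError(f"unknown background {background!r}")
        return self.overrides.get((gene, background), self.baselines[background])

    def genes_with_effects(self) -> set[str]:
        return {g for g, _ in self.overrides}

    def expected_control_sd(self, background: str) -> float:
        """Analytic SD (percentage points) of control-well pct_multipolar.

        Pools the per-plate variance (well noise x batch gain, plus binomial
        counting error at the expected number of mitotic cells) with the
        between-replicate batch spread — the quantity the ±k·SD hit rule
        measures from its control wells.
        """
        base = self.baselines[background]
        gains = [self.replicate_gain.get(r, 1.0) for r in sorted(self.replicate_gain)]
        n_mit = base.cell_count_mean * base.mitotic_fraction
        per_plate_var = []
        means = []
        for g in gains:
            p = min(base.multipolar_penetrance * g, 1.0)
            binom = p * (1 - p) / max(n_mit, 1.0)
            per_plate_var.append((self.well_noise_sd * g) ** 2 + binom)
            means.append(p)
        within = float(np.mean(per_plate_var))
        between = float(np.var(means))  # population variance of plate means
        return 100.0 * math.sqrt(within + between)


def add_designated_hits(model: GeneEffectModel, enhancers: list[str], suppressors: list[str],
                        background: str = "chTOG", sd_units: float = 3.0) -> GeneEffectModel:
    """Return a copy of ``model`` with enhancer/suppressor genes planted.

    Effect sizes are ``±sd_units`` times the analytically expected control-well
    SD of pct_multipolar, converted back to penetrance units (accounting for
    the average replicate batch gain), i.e. designated hits sit at exactly
    ``±sd_units``·σ of the statistic the hit rule thresholds.
    """
    sd_pct = model.expected_control_sd(background)
    gains = [model.replicate_gain.get(r, 1.0) for r in sorted(model.replicate_gain)]
    mean_gain = float(np.mean(gains))
    delta = sd_units * sd_pct / 100.0 / mean_gain
    base = model.baselines[background]
    overrides = dict(model.overrides)
    for g in enhancers:
        p = min(base.multipolar_penetrance + delta, 1.0)
        overrides[(g, background)] = replace(base, multipolar_penetrance=p,
                                             mean_pole_count=max(base.mean_pole_count, 3.8))
    for g in suppressors:
        p = max(base.multipolar_penetrance - delta, 0.0)
        overrides[(g, background)] = replace(base, multipolar_penetrance=p)
    return GeneEffectModel(control_gene=model.control_gene, baselines=dict(model.baselines),
                           overrides=overrides, well_noise_sd=model.well_noise_sd,
                           replicate_gain=dict(model.replicate_gain))


def simulate_screen_tables(layout: pd.DataFrame, model: GeneEffectModel,
                           seed: int, cells_per_well: float | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-well screen features for every non-empty well of ``layout``.

    ``layout`` columns: well, gene, sirna_id, background, replicate, role
    (see :func:`spindlescreen.io_utils.read_layout`).  Returns
    ``(wells, truth)``: ``wells`` holds the five features per well plus layout
    metadata; ``truth`` holds the generative parameters and realized counts,
    from which the emitted features are exactly recomputable.

    Raises ``KeyError`` listing genes whose background is missing from the
    model's baselines.
    """
    missing = sorted({b for b in layout["background"].unique() if b not in model.baselines})
    if missing:
        raise KeyError(f"layout backgrounds missing from model: {missing}")
    rng = np.random.default_rng(seed)
    well_rows = []
    truth_rows = []
    lay = layout[layout["role"] != "empty"].sort_values(
        ["background", "replicate", "well"]).reset_index(drop=True)
    for rec in lay.itertuples(index=False):
        eff = model.effect(rec.gene, rec.background)
        if cells_per_well is not None:
            eff = replace(eff, cell_count_mean=float(cells_per_well))
        gain = model.replicate_gain.get(int(rec.replicate), 1.0)
        n_cells = int(rng.poisson(eff.cell_count_mean))
        n_mitotic = int(rng.binomial(n_cells, eff.mitotic_fraction)) if n_cells else 0
        p_true = min(eff.multipolar_penetrance * gain, 1.0)
        p_well = float(np.clip((eff.multipolar_penetrance
                                + rng.normal(0.0, model.well_noise_sd)) * gain, 0.0, 1.0)) \
            if model.well_noise_sd > 0 else p_true
        n_multi = int(rng.binomial(n_mitotic, p_well)) if n_mitotic else 0
        if n_multi:
            extra = rng.poisson(max(eff.mean_pole_count - 3.0, 0.0), size=n_multi)
            poles_multi = int((3 + extra).sum())
        else:
            poles_multi = 0
        n_interphase = n_cells - n_mitotic
        n_multinuc = int(rng.binomial(n_interphase, eff.multinucleate_fraction)) \
            if n_interphase else 0

        mitotic_index = n_mitotic / n_cells if n_cells else np.nan
        pct_multipolar = 100.0 * n_multi / n_mitotic if n_mitotic else np.nan
        mean_poles = (2.0 * (n_mitotic - n_multi) + poles_multi) / n_mitotic \
            if n_mitotic else np.nan
        pct_multinucleate = 100.0 * n_multinuc / n_interphase if n_interphase else np.nan

        meta = dict(well=rec.well, gene=rec.gene, sirna_id=rec.sirna_id,
                    background=rec.background, replicate=int(rec.replicate), role=rec.role)
        well_rows.append({**meta, "n_cells": n_cells, "mitotic_index": mitotic_index,
                          "pct_multipolar": pct_multipolar, "mean_poles": mean_poles,
                          "pct_multinucleate": pct_multinucleate})
        truth_rows.append({**meta, "true_penetrance": eff.multipolar_penetrance,
                           "plate_gain": gain, "realized_penetrance": p_well,
                           "n_cells": n_cells, "n_mitotic": n_mitotic,
                           "n_multipolar": n_multi, "poles_in_multipolar": poles_multi,
                           "n_interphase": n_interphase, "n_multinucleate": n_multinuc})
    wells = pd.DataFrame(well_rows)
    truth = pd.DataFrame(truth_rows)
    if wells.empty:
        warnings.warn("layout contained no non-empty wells")
    return wells, truth
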