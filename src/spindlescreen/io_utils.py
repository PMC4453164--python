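"""Formats and configuration: plate layouts, multi-page TIFFs, run manifests.

Layouts are CSV tables with one row per well (columns: well, gene, sirna_id,
background, replicate, role).  Field images travel as multi-page TIFFs with
one page per channel and the channel names in the TIFF metadata.  Every run
writes a manifest JSON recording all parameters and seeds; its SHA-256 hash
is stamped as a comment line on every output table so outputs can be traced
to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic_data import CHANNELS, FieldImage

LAYOUT_COLUMNS = ("well", "gene", "sirna_id", "background", "replicate", "role")
VALID_BACKGROUNDS = ("NS", "chTOG")
VALID_ROLES = ("sample", "control", "positive_control", "empty")
_WELL_RE = re.compile(r"^[A-P](0[1-9]|1[0-9]|2[0-4])$")


class LayoutError(ValueError):
    """A plate-layout table failed validation."""


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate-layout CSV.

    Checks: required columns; well ids in 384-well format ("A01".."P24"),
    unique within each (background, replicate) plate; known background and
    role tokens.  Sample genes present in only one replicate of a background
    raise a warning listing the genes.  Errors name the offending rows.
    """
    df = pd.read_csv(path, dtype={"well": str, "gene": str, "sirna_id": str,
                                  "background": str, "role": str})
    return validate_layout(df)


def validate_layout(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"layout is missing columns: {missing}")
    bad_wells = df.loc[~df["well"].astype(str).str.match(_WELL_RE), "well"]
    if len(bad_wells):
        raise LayoutError(f"malformed well ids: {sorted(bad_wells.unique())}")
    bad_bg = df.loc[~df["background"].isin(VALID_BACKGROUNDS), "background"]
    if len(bad_bg):
        raise LayoutError(f"unknown background tokens: {sorted(bad_bg.unique())} "
                          f"(expected {VALID_BACKGROUNDS})")
    bad_role = df.loc[~df["role"].isin(VALID_ROLES), "role"]
    if len(bad_role):
        raise LayoutError(f"unknown role tokens: {sorted(bad_role.unique())}")
    dup = df.duplicated(subset=["background", "replicate", "well"], keep=False)
    if dup.any():
        dups = df.loc[dup, ["background", "replicate", "well"]].drop_duplicates()
        raise LayoutError(f"duplicated well ids per plate:\n{dups.to_string(index=False)}")
    samples = df[df["role"] == "sample"]
    lonely = []
    for bg, sub in samples.groupby("background"):
        reps = set(sub["replicate"].unique())
        if len(reps) > 1:
            counts = sub.groupby("gene")["replicate"].nunique()
            lonely.extend(f"{g} ({bg})" for g in counts[counts < len(reps)].index)
    if lonely:
        warnings.warn(f"sample genes present in only one replicate: {sorted(lonely)}")
    out = df.copy()
    out["replicate"] = out["replicate"].astype(int)
    return out


def well_name(index: int) -> str:
    """0-based well index -> 384-well name, row-major ("A01".."P24")."""
    if not 0 <= index < 384:
        raise ValueError("384-well plates have wells 0..383")
    return f"{chr(ord('A') + index // 24)}{index % 24 + 1:02d}"


def make_default_layout(genes: list[str], n_control_wells: int = 24,
                        positive_controls: list[str] | None = None,
                        control_gene: str = "CTRL",
                        backgrounds: tuple[str, ...] = VALID_BACKGROUNDS,
                        replicates: tuple[int, ...] = (1, 2)) -> pd.DataFrame:
    """Duplicate two-background layout: one well per library gene, a block of
    control-siRNA wells, optional positive controls, remainder empty."""
    positive_controls = positive_controls or []
    rows = []
    for bg in backgrounds:
        for rep in replicates:
            idx = 0
            for g in genes:
                rows.append({"well": well_name(idx), "gene": g, "sirna_id": f"si_{g}",
                             "background": bg, "replicate": rep, "role": "sample"})
                idx += 1
            for i in range(n_control_wells):
                rows.append({"well": well_name(idx), "gene": control_gene,
                             "sirna_id": f"si_ctrl_{i}", "background": bg,
                             "replicate": rep, "role": "control"})
                idx += 1
            for g in positive_controls:
                rows.append({"well": well_name(idx), "gene": g, "sirna_id": f"si_{g}",
                             "background": bg, "replicate": rep, "role": "positive_control"})
                idx += 1
    return validate_layout(pd.DataFrame(rows, columns=list(LAYOUT_COLUMNS)))


# ---------------------------------------------------------------------------
# TIFF field images
# ---------------------------------------------------------------------------

def write_field_tiff(path: str | Path, image: FieldImage,
                     channel_order: tuple[str, ...] = CHANNELS) -> Path:
    """Write one field as a multi-page TIFF, one page per channel, with the
    channel names recorded in the image description metadata."""
    path = Path(path)
    stack = np.stack([np.asarray(image[c], dtype=np.float32) for c in channel_order])
    meta = {"channels": list(channel_order), "well": image.well,
            "field_id": int(image.field_id)}
    tifffile.imwrite(path, stack, photometric="minisblack", metadata=meta)
    return path


def read_field_tiff(path: str | Path,
                    channel_map: dict[str, int] | None = None) -> FieldImage:
    """Read a multi-page TIFF back into a FieldImage.

    ``channel_map`` (channel name -> page index) overrides the embedded
    metadata, for files produced elsewhere.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    if channel_map is None:
        names = meta.get("channels")
        if names is None:
            raise ValueError(f"{path}: no channel metadata; provide channel_map")
        channel_map = {name: i for i, name in enumerate(names)}
    channels = {name: np.asarray(stack[i], dtype=float) for name, i in channel_map.items()}
    return FieldImage(channels=channels, well=str(meta.get("well", "")),
                      field_id=int(meta.get("field_id", 0)))


def load_channel_map(config_path: str | Path) -> dict[str, int]:
    """Channel name -> TIFF page mapping from a YAML run config."""
    cfg = yaml.safe_load(Path(config_path).read_text())
    cmap = cfg.get("channel_map", cfg)
    missing = [c for c in CHANNELS if c not in cmap]
    if missing:
        raise ValueError(f"channel map missing required channels: {missing}")
    return {str(k): int(v) for k, v in cmap.items()}


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def make_manifest(**entries) -> dict:
    """Run manifest: every parameter, threshold and seed used by a run."""
    from . import __version__
    manifest = {"spindlescreen_version": __version__}
    manifest.update(entries)
    manifest["manifest_hash"] = manifest_hash(manifest)
    return manifest


def manifest_hash(manifest: dict) -> str:
    clean = {k: v for k, v in manifest.items() if k != "manifest_hash"}
    blob = json.dumps(clean, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def write_table(df: pd.DataFrame, path: str | Path, manifest: dict | None = None) -> Path:
    """Write a CSV stamped with the run-manifest hash as a comment line."""
    path = Path(path)
    with path.open("w") as fh:
        if manifest is not None:
            fh.write(f"# manifest={manifest['manifest_hash']}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
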