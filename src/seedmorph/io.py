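"""File formats: trait-table CSV, silhouette PNG + JSON sidecar, Newick.

Trait tables are comma-separated UTF-8 with "." decimals and fixed headers
(units in the column names): seed_id, species, population, surface_um2,
profile_um, rectangle_a_um, rectangle_b_um, angle_deg, pits. Silhouettes are
stored as a binary PNG mask plus a JSON sidecar carrying the physical pixel
size, the contour and pit lattice in µm, and the generative provenance when
synthetic.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import EmptyTableError, TraitTableError
from .silhouette import SeedShapeParams, SeedSilhouette
from .synthetic import TABLE_COLUMNS, TRAIT_COLUMNS


def write_trait_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise TraitTableError(f"table is missing columns: {missing}")
    table[TABLE_COLUMNS].to_csv(path, index=False)


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate a trait-table CSV (malformed rows named by line)."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path}: no columns or rows") from None
    if len(table) == 0:
        raise EmptyTableError(f"{path}: header only, no data rows")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise TraitTableError(f"{path}: missing columns {missing}")
    offenders = []
    for col in TRAIT_COLUMNS:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[numeric.isna()]
        # +2: one for the header line, one for 0- vs 1-based indexing
        offenders.extend(f"line {i + 2}: bad {col}={table.loc[i, col]!r}" for i in bad)
        table[col] = numeric
    if offenders:
        raise TraitTableError(f"{path}: " + "; ".join(offenders[:10]))
    return table[TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# silhouettes
# ---------------------------------------------------------------------------


def write_silhouette(sil: SeedSilhouette, png_path) -> None:
    png_path = Path(png_path)
    Image.fromarray((sil.mask * np.uint8(255))).save(png_path)
    sidecar = {
        "pixel_size_um": sil.pixel_size,
        "contour_um": sil.contour.tolist(),
        "pit_lattice_um": (
            None
            if sil.pit_lattice is None
            else [np.asarray(p).tolist() for p in sil.pit_lattice]
        ),
        "provenance": None if sil.provenance is None else asdict(sil.provenance),
        "meta": {k: v for k, v in sil.meta.items() if not k.startswith("_")},
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_silhouette(png_path, pixel_size: float | None = None) -> SeedSilhouette:
    """Read a PNG + sidecar silhouette; `pixel_size` overrides the sidecar."""
    png_path = Path(png_path)
    mask = np.asarray(Image.open(png_path).convert("L")) > 127
    sidecar = json.loads(png_path.with_suffix(".json").read_text())
    prov = sidecar.get("provenance")
    return SeedSilhouette(
        mask=mask,
        pixel_size=float(pixel_size or sidecar["pixel_size_um"]),
        contour=np.asarray(sidecar["contour_um"], dtype=float),
        pit_lattice=(
            None
            if sidecar.get("pit_lattice_um") is None
            else [np.asarray(p, dtype=float) for p in sidecar["pit_lattice_um"]]
        ),
        provenance=None if prov is None else SeedShapeParams(**prov),
        meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# population metadata and trees
# ---------------------------------------------------------------------------

POPULATION_COLUMNS = ["acronym", "species", "latitude", "longitude", "n_seeds"]


def read_population_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in POPULATION_COLUMNS if c not in table.columns]
    if missing:
        raise TraitTableError(f"{path}: missing columns {missing}")
    lat, lon = table["latitude"], table["longitude"]
    if ((lat < -90) | (lat > 90)).any() or ((lon < -180) | (lon > 180)).any():
        raise ValueError(f"{path}: coordinates outside valid ranges")
    if (table["n_seeds"] < 1).any():
        raise ValueError(f"{path}: n_seeds must be >= 1")
    return table


def write_newick(tree, path) -> None:
    Path(path).write_text(tree.newick() + "\n")
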