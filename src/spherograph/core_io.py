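"""Data model and I/O for two-channel spheroid slices and per-cell tables.

A :class:`ChannelSlice` holds one confocal plane with a nuclear-stain channel
(e.g. DAPI) and a stemness-marker channel (e.g. SOX2) on the same pixel grid,
plus the physical pixel metadata needed to report distances in micrometres.
A :class:`CellTable` holds one record per segmented cell and travels through
the whole pipeline, accumulating marker sums and phenotype labels.

Coordinate convention: images are row-major and 0-based; centroids are
``(x, y) = (column, row)`` in pixel units. Physical coordinates are obtained
by multiplying by ``pixel_size_xy``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelSlice",
    "CellRecord",
    "CellTable",
    "read_slice",
    "write_slice",
    "read_cell_table",
    "write_cell_table",
    "PHENOTYPES",
]

#: Allowed phenotype labels. "stem" marks marker-high cells (CSC),
#: "differentiated" marker-low cells (DCC); "unassigned" is the pre-threshold
#: state.
PHENOTYPES = ("stem", "differentiated", "unassigned")

TABLE_COLUMNS = ["cell_id", "x", "y", "area_px", "marker_sum", "phenotype"]


@dataclass(frozen=True)
class ChannelSlice:
    """One confocal plane: nuclei + marker channels with pixel metadata."""

    nuclei: np.ndarray
    marker: np.ndarray
    pixel_size_xy: float = 0.12  # µm per pixel in the x-y plane
    slice_thickness: float = 2.0  # µm per optical slice
    slice_index: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        nuclei = np.asarray(self.nuclei, dtype=float)
        marker = np.asarray(self.marker, dtype=float)
        if nuclei.ndim != 2 or marker.ndim != 2:
            raise ValueError("channels must be 2-D intensity grids")
        if nuclei.shape != marker.shape:
            raise ValueError(
                f"nuclei shape {nuclei.shape} != marker shape {marker.shape}"
            )
        if np.any(nuclei < 0) or np.any(marker < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_xy > 0:
            raise ValueError("pixel_size_xy must be positive")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        object.__setattr__(self, "nuclei", nuclei)
        object.__setattr__(self, "marker", marker)

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei.shape

    def meta_dict(self) -> dict:
        return {
            "pixel_size_xy": self.pixel_size_xy,
            "slice_thickness": self.slice_thickness,
            "slice_index": self.slice_index,
            "provenance": self.provenance,
        }


class CellRecord(NamedTuple):
    """One segmented cell: identity, geometry, marker content, phenotype."""

    cell_id: int
    x: float
    y: float
    area_px: int
    marker_sum: float
    phenotype: str


@dataclass
class CellTable:
    """Ordered collection of :class:`CellRecord` plus slice metadata.

    Internally backed by a :class:`pandas.DataFrame` with the canonical
    columns ``cell_id, x, y, area_px, marker_sum, phenotype``.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in TABLE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"cell table missing column {col!r}")
        df = df[TABLE_COLUMNS].reset_index(drop=True)
        df["cell_id"] = df["cell_id"].astype(int)
        df["area_px"] = df["area_px"].astype(int)
        df["marker_sum"] = df["marker_sum"].astype(float)
        df["phenotype"] = df["phenotype"].astype(str)
        if len(df):
            if df["cell_id"].duplicated().any():
                raise ValueError("cell_id values must be unique")
            if (df["cell_id"] <= 0).any():
                raise ValueError("cell_id values must be positive")
            if (df["area_px"] < 1).any():
                raise ValueError("area_px must be >= 1")
            if (df["marker_sum"] < 0).any():
                raise ValueError("marker_sum must be non-negative")
            bad = set(df["phenotype"]) - set(PHENOTYPES)
            if bad:
                raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        self.df = df

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Sequence[CellRecord], meta: dict | None = None
    ) -> "CellTable":
        df = pd.DataFrame(list(records), columns=TABLE_COLUMNS)
        return cls(df, dict(meta or {}))

    @classmethod
    def empty(cls, meta: dict | None = None) -> "CellTable":
        return cls(pd.DataFrame(columns=TABLE_COLUMNS), dict(meta or {}))

    # -- views ----------------------------------------------------------------
    @property
    def records(self) -> list[CellRecord]:
        return [CellRecord(*row) for row in self.df.itertuples(index=False)]

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[CellRecord]:
        return iter(self.records)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in pixel units."""
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def counts(self) -> dict:
        """Total / per-phenotype counts; always satisfies the partition
        ``n_stem + n_differentiated + n_unassigned == n_total``."""
        ph = self.df["phenotype"]
        return {
            "n_total": len(self.df),
            "n_stem": int((ph == "stem").sum()),
            "n_differentiated": int((ph == "differentiated").sum()),
            "n_unassigned": int((ph == "unassigned").sum()),
        }

    def with_df(self, df: pd.DataFrame) -> "CellTable":
        return CellTable(df, dict(self.meta))


# -- slice I/O ----------------------------------------------------------------

def read_slice(
    path: str | Path,
    nuclei_channel: int = 0,
    marker_channel: int = 1,
    **meta,
) -> ChannelSlice:
    """Read a two-channel slice from a multi-page TIFF or an ``.npz`` bundle.

    For TIFF, each page (or each element of the leading axis) is one channel;
    ``nuclei_channel`` and ``marker_channel`` are page indices. ``.npz``
    bundles carry explicit ``nuclei`` / ``marker`` arrays and a JSON ``meta``
    entry. Extra keyword arguments override stored metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as bundle:
            if "nuclei" not in bundle or "marker" not in bundle:
                raise ValueError(f"{path}: bundle must contain 'nuclei' and 'marker'")
            nuclei = bundle["nuclei"]
            marker = bundle["marker"]
            stored = {}
            if "meta" in bundle:
                stored = json.loads(str(bundle["meta"]))
        stored.update(meta)
        return ChannelSlice(nuclei=nuclei, marker=marker, **stored)

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-D channel pages")
    n = pages.shape[0]
    for name, idx in (("nuclei", nuclei_channel), ("marker", marker_channel)):
        if not 0 <= idx < n:
            raise IndexError(
                f"{name} channel index {idx} out of range for {n}-page file {path}"
            )
    return ChannelSlice(
        nuclei=pages[nuclei_channel], marker=pages[marker_channel], **meta
    )


def write_slice(slc: ChannelSlice, path: str | Path) -> None:
    """Write a slice as a 2-page float TIFF or an ``.npz`` bundle with metadata.

    TIFF output stores nuclei on page 0 and marker on page 1; metadata other
    than the grids is preserved only by the ``.npz`` form.
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            nuclei=slc.nuclei,
            marker=slc.marker,
            meta=json.dumps(slc.meta_dict()),
        )
    else:
        stack = np.stack([slc.nuclei, slc.marker]).astype(np.float32)
        tifffile.imwrite(path, stack)


# -- cell table I/O -----------------------------------------------------------

def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write the canonical CSV (UTF-8, LF, header ``cell_id,x,y,...``)."""
    table.df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_cell_table(path: str | Path, meta: dict | None = None) -> CellTable:
    """Read a cell-table CSV; a missing phenotype column becomes
    ``unassigned`` with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = [c for c in TABLE_COLUMNS if c != "phenotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    if "phenotype" not in df.columns:
        warnings.warn(
            f"{path}: no phenotype column; all cells read as 'unassigned'",
            stacklevel=2,
        )
        df["phenotype"] = "unassigned"
    return CellTable(df, dict(meta or {}))
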