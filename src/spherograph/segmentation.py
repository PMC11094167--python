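"""Nuclei instance segmentation and cell extraction.

The default ``classical`` backend is fully self-contained: Otsu threshold,
Euclidean distance transform, peak seeding and marker-controlled watershed.
A ``pretrained`` backend delegating to an externally installed star-convex
segmentation model (StarDist ``2D_versatile_fluo``) can be selected when
that package is available; it is never required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Delaunay
from skimage import filters, measure, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max

from .core_io import CellRecord, CellTable

__all__ = [
    "LabelImage",
    "SegmentParams",
    "segment_nuclei",
    "extract_cells",
    "filter_spheroid",
]


@dataclass(frozen=True)
class LabelImage:
    """Instance label map: 0 = background, k >= 1 = instance k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", labels)

    @property
    def n_instances(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))


@dataclass(frozen=True)
class SegmentParams:
    """Classical-backend parameters.

    ``min_peak_separation_px`` should be of the order of a nucleus radius;
    ``min_area_px`` discards speckle far smaller than a nucleus;
    ``otsu_offset`` shifts the global threshold (fraction of the Otsu value).
    """

    min_peak_separation_px: int = 7
    min_area_px: int = 30
    otsu_offset: float = 0.0


def segment_nuclei(
    enhanced: np.ndarray,
    backend: str = "classical",
    params: SegmentParams | None = None,
) -> LabelImage:
    """Segment nuclei instances from the enhanced nuclear channel.

    ``classical`` (default): Otsu threshold -> distance transform -> peak
    seeding with minimum separation -> watershed. ``pretrained``: delegate
    to a star-convex CNN model if the optional dependency is installed.
    """
    img = np.asarray(enhanced, dtype=float)
    if img.ndim != 2:
        raise ValueError("enhanced must be a 2-D grid")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("enhanced image must lie in [0, 1]")
    if backend == "pretrained":
        return _segment_pretrained(img)
    if backend != "classical":
        raise ValueError(f"unknown backend {backend!r}")
    params = params or SegmentParams()

    if img.max() == 0:
        return LabelImage(np.zeros(img.shape, dtype=np.int32))
    thresh = filters.threshold_otsu(img) * (1.0 + params.otsu_offset)
    binary = img > thresh
    binary = morphology.remove_small_objects(binary, max_size=params.min_area_px - 1)
    if not binary.any():
        return LabelImage(np.zeros(img.shape, dtype=np.int32))

    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance,
        min_distance=params.min_peak_separation_px,
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = sk_seg.watershed(-distance, markers, mask=binary)

    labels = morphology.remove_small_objects(labels, max_size=params.min_area_px - 1)
    labels, _, _ = sk_seg.relabel_sequential(labels)
    return LabelImage(labels.astype(np.int32))


def _segment_pretrained(img: np.ndarray) -> LabelImage:
    try:
        from stardist.models import StarDist2D  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "backend 'pretrained' requires the optional 'stardist' package; "
            "it is not installed — use backend='classical' instead"
        ) from exc
    model = StarDist2D.from_pretrained("2D_versatile_fluo")  # pragma: no cover
    labels, _ = model.predict_instances(img)  # pragma: no cover
    return LabelImage(labels.astype(np.int32))  # pragma: no cover


def extract_cells(labels: LabelImage, meta: dict | None = None) -> CellTable:
    """One :class:`CellRecord` per instance: unweighted centroid and area.

    ``marker_sum`` is 0 and ``phenotype`` is ``unassigned``; both are filled
    by the tessellation and classification stages.
    """
    records = []
    for prop in measure.regionprops(labels.labels):
        row, col = prop.centroid  # unweighted mean of member pixel coords
        records.append(
            CellRecord(
                cell_id=int(prop.label),
                x=float(col),
                y=float(row),
                area_px=int(prop.area),
                marker_sum=0.0,
                phenotype="unassigned",
            )
        )
    return CellTable.from_records(records, meta)


def filter_spheroid(
    table: CellTable,
    method: str = "enclosing_fraction",
    param: float = 1.2,
) -> CellTable:
    """Drop detections that do not belong to the spheroid.

    ``enclosing_fraction`` keeps cells whose centroid lies within
    ``param × R_core`` of the centroid-of-centroids, where ``R_core`` is the
    90th percentile of centroid distances to that center (a robust spheroid
    radius, insensitive to far outliers). ``largest_component`` keeps the
    largest connected component of the Delaunay graph after deleting edges
    longer than ``param`` times the median edge length.

    Removed cells are dropped, not relabeled.
    """
    if len(table) == 0:
        raise ValueError("cell table is empty")
    if param <= 0:
        raise ValueError("param must be positive")
    if len(table) == 1:
        return table

    pts = table.centroids
    if method == "enclosing_fraction":
        center = pts.mean(axis=0)
        dist = np.hypot(*(pts - center).T)
        r_core = np.percentile(dist, 90)
        keep = dist <= param * r_core if r_core > 0 else np.ones(len(pts), bool)
    elif method == "largest_component":
        if len(table) < 3:
            return table
        tri = Delaunay(pts)
        edges = _triangulation_edges(tri)
        lengths = np.hypot(*(pts[edges[:, 0]] - pts[edges[:, 1]]).T)
        short = edges[lengths <= param * np.median(lengths)]
        keep = _largest_component_mask(len(pts), short)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    return table.with_df(table.df[keep])


def _triangulation_edges(tri: Delaunay) -> np.ndarray:
    """Unique undirected edge list (index pairs) of a Delaunay triangulation."""
    simplices = tri.simplices
    pairs = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
    )
    pairs.sort(axis=1)
    return np.unique(pairs, axis=0)


def _largest_component_mask(n: int, edges: np.ndarray) -> np.ndarray:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    if len(edges) == 0:
        return np.ones(n, dtype=bool)
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    counts = np.bincount(comp)
    return comp == counts.argmax()
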