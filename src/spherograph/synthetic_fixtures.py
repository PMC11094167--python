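"""Ground-truthed synthetic tumorsphere fixtures.

Generates (a) labeled point sets emulating a confocal plane through a
tumorsphere — cell centroids packed in a disc, with stem labels placed
either uniformly at random (the null) or grown as connected paths from the
center outward (the clustered arrangements seen in real spheroids) — and
(b) rendered two-channel images: bright nuclear blobs on a dark background
and a marker channel whose per-cell integrated intensity is drawn from a
two-component (differentiated-low / stem-high) distribution.

The exact ground truth (labels, centroids, per-cell marker draws, instance
mask) is returned with every fixture, so each pipeline stage can be tested
against what was planted. Defaults mirror the scale of MCF-7 tumorsphere
slices at 0.12 µm/px: a disc of radius ≈ 100 µm holding one to a few
hundred cells, stem fraction around 0.3.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import Delaunay

from .core_io import CellRecord, CellTable, ChannelSlice
from .segmentation import LabelImage

__all__ = ["FixtureSpec", "generate_points", "render_image"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic spheroid slice.

    ``arrangement`` is "random" (labels exchangeable — the null), "paths"
    (stem lineages grown as connected chains from the center) or "patches"
    (several compact stem patches). ``clustering_strength`` ≥ 0 biases
    growth along existing stem neighbors; 0 recovers the random case.
    Marker means/sds are per-phenotype integrated intensities
    (differentiated first, stem second).
    """

    n_cells: int = 200
    stem_fraction: float = 0.3
    arrangement: str = "random"
    clustering_strength: float = 20.0
    nucleus_radius_px: tuple[float, float] = (6.0, 0.6)  # mean, sd
    min_separation_px: float = 18.0
    marker_means: tuple[float, float] = (60.0, 200.0)  # (differentiated, stem)
    marker_sds: tuple[float, float] = (12.0, 20.0)
    marker_spot_sigma_px: float | None = None  # None -> 0.75 × nucleus radius
    marker_background: float = 0.02  # diffuse per-pixel background level
    noise_sd: float = 0.01
    image_shape: tuple[int, int] = (720, 720)
    disc_radius_px: float | None = None  # None -> auto from packing density
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stem_fraction < 1:
            raise ValueError("stem_fraction must lie in (0, 1)")
        if self.arrangement not in ("random", "paths", "patches"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.marker_means[1] <= self.marker_means[0]:
            raise ValueError("stem marker mean must exceed differentiated mean")
        if self.clustering_strength < 0:
            raise ValueError("clustering_strength must be >= 0")
        r = self.resolved_disc_radius()
        if r + self.min_separation_px > min(self.image_shape) / 2:
            raise ValueError(
                "image_shape too small for the packed disc; enlarge the image"
            )

    def resolved_disc_radius(self) -> float:
        if self.disc_radius_px is not None:
            return float(self.disc_radius_px)
        # random sequential packing fills ~40% of the max disc density
        area_per_cell = np.pi * (self.min_separation_px / 2) ** 2 / 0.40
        return float(np.sqrt(self.n_cells * area_per_cell / np.pi))

    def n_stem(self) -> int:
        return int(round(self.n_cells * self.stem_fraction))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def generate_points(spec: FixtureSpec) -> CellTable:
    """Pack centroids in a disc and assign ground-truth phenotypes.

    Centroids are placed by dart throwing with minimum separation
    ``min_separation_px``. Labels: for "random", a uniform sample of
    ``round(n_cells × stem_fraction)`` cells; for "paths"/"patches", stem
    lineages are seeded (at the center, or at several random seeds) and
    grown across Delaunay neighbor links, ``clustering_strength`` setting
    the odds of extending an existing lineage versus starting anywhere.
    The stem count is exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    pts = _pack_disc(spec, rng)
    n = len(pts)
    stem = np.zeros(n, dtype=bool)
    n_stem = spec.n_stem()

    if spec.arrangement == "random":
        stem[rng.choice(n, size=n_stem, replace=False)] = True
    else:
        stem = _grow_stem_labels(pts, n_stem, spec, rng)

    records = [
        CellRecord(
            cell_id=i + 1,
            x=float(pts[i, 0]),
            y=float(pts[i, 1]),
            area_px=max(1, int(round(np.pi * spec.nucleus_radius_px[0] ** 2))),
            marker_sum=0.0,
            phenotype="stem" if stem[i] else "differentiated",
        )
        for i in range(n)
    ]
    meta = {"fixture_spec": json.loads(spec.to_json())}
    return CellTable.from_records(records, meta)


def _pack_disc(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    center = np.array(spec.image_shape[::-1], dtype=float) / 2  # (x, y)
    radius = spec.resolved_disc_radius()
    sep2 = spec.min_separation_px**2
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 20000 * spec.n_cells
    while len(pts) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"packed only {len(pts)}/{spec.n_cells} cells; "
                "enlarge image_shape or disc_radius_px, or reduce "
                "min_separation_px"
            )
        r = radius * np.sqrt(rng.random())
        theta = 2 * np.pi * rng.random()
        p = center + r * np.array([np.cos(theta), np.sin(theta)])
        if all(np.sum((p - q) ** 2) >= sep2 for q in pts):
            pts.append(p)
    return np.array(pts)


def _grow_stem_labels(
    pts: np.ndarray, n_stem: int, spec: FixtureSpec, rng: np.random.Generator
) -> np.ndarray:
    n = len(pts)
    tri = Delaunay(pts)
    indptr, indices = tri.vertex_neighbor_vertices
    neighbors = [indices[indptr[i] : indptr[i + 1]] for i in range(n)]

    stem = np.zeros(n, dtype=bool)
    center = pts.mean(axis=0)
    dist_c = np.hypot(*(pts - center).T)
    if spec.arrangement == "paths":
        seeds = [int(np.argmin(dist_c))]
    else:  # patches: a few seeds scattered through the disc
        n_patches = max(2, n_stem // 25)
        seeds = rng.choice(n, size=n_patches, replace=False).tolist()
    for s in seeds[: n_stem]:
        stem[s] = True

    p_grow = spec.clustering_strength / (1.0 + spec.clustering_strength)
    while stem.sum() < n_stem:
        frontier = np.unique(
            np.concatenate([neighbors[i] for i in np.flatnonzero(stem)])
        )
        frontier = frontier[~stem[frontier]]
        if len(frontier) and rng.random() < p_grow:
            stem[rng.choice(frontier)] = True
        else:
            rest = np.flatnonzero(~stem)
            stem[rng.choice(rest)] = True
    return stem


def render_image(
    table: CellTable, spec: FixtureSpec
) -> tuple[ChannelSlice, LabelImage, np.ndarray]:
    """Render the two channels and the ground-truth instance mask.

    The nuclei channel is a sum of isotropic Gaussian blobs (amplitude 1,
    sigma = half the nucleus radius) at the planted centroids plus Gaussian
    noise. The marker channel spreads each cell's drawn integrated intensity
    as a Gaussian spot of common width, over a smooth diffuse background —
    the component the cleaning stage must remove. The instance mask paints a
    disc of the per-cell nucleus radius at each centroid (discs are disjoint
    because centroids respect the minimum separation).

    Returns ``(slice, truth_labels, marker_draws)`` where ``marker_draws[i]``
    is the integrated marker intensity planted for ``table.records[i]``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    h, w = spec.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    nuclei = np.zeros((h, w))
    marker = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)

    mean_r, sd_r = spec.nucleus_radius_px
    stem_mask = table.df["phenotype"].to_numpy() == "stem"
    draws = np.where(
        stem_mask,
        rng.normal(spec.marker_means[1], spec.marker_sds[1], len(table)),
        rng.normal(spec.marker_means[0], spec.marker_sds[0], len(table)),
    )
    draws = np.clip(draws, 0.0, None)

    # Punctate spots, narrow relative to the cell spacing: the cleaned
    # per-cell sums then stay proportional to the planted draws with little
    # bleed-through into neighboring territories.
    marker_sigma = spec.marker_spot_sigma_px or 0.75 * mean_r
    for i, rec in enumerate(table.df.itertuples(index=False)):
        r_i = max(2.0, rng.normal(mean_r, sd_r))
        d2 = (xx - rec.x) ** 2 + (yy - rec.y) ** 2
        nuclei += np.exp(-d2 / (2 * (r_i / 2) ** 2))
        labels[d2 <= r_i**2] = rec.cell_id
        spot = np.exp(-d2 / (2 * marker_sigma**2))
        marker += draws[i] * spot / spot.sum()

    if spec.marker_background > 0:
        # broad diffuse halo over the spheroid, ~3x the disc radius wide
        center = np.array([w, h]) / 2
        halo = np.exp(
            -((xx - center[0]) ** 2 + (yy - center[1]) ** 2)
            / (2 * (3 * spec.resolved_disc_radius()) ** 2)
        )
        marker += spec.marker_background * halo
    if spec.noise_sd > 0:
        nuclei += rng.normal(0, spec.noise_sd, (h, w))
        marker += rng.normal(0, spec.noise_sd, (h, w))
    nuclei = np.clip(nuclei, 0.0, None)
    marker = np.clip(marker, 0.0, None)

    slc = ChannelSlice(
        nuclei=nuclei,
        marker=marker,
        provenance=f"synthetic {spec.arrangement} n={spec.n_cells} seed={spec.seed}",
    )
    return slc, LabelImage(labels), draws
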