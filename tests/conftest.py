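import numpy as np
import pytest

from spherograph import (
    CellRecord,
    CellTable,
    FixtureSpec,
    generate_points,
    render_image,
)
from spherograph.graph_analysis import CellGraph


def make_table(points, phenotypes, area=10):
    """CellTable from (x, y) points and phenotype labels."""
    records = [
        CellRecord(i + 1, float(x), float(y), area, 0.0, ph)
        for i, ((x, y), ph) in enumerate(zip(points, phenotypes))
    ]
    return CellTable.from_records(records)


def make_graph(positions, stem, edges):
    """CellGraph from explicit node/edge arrays (0-based edge indices)."""
    n = len(stem)
    return CellGraph(
        cell_ids=np.arange(1, n + 1),
        positions=np.asarray(positions, dtype=float),
        stem=np.asarray(stem, dtype=bool),
        edges=np.asarray(edges, dtype=int).reshape(-1, 2),
    )


def random_graph(rng, n_min=3, n_max=8):
    """Small random labeled graph (Erdős–Rényi, arbitrary positions)."""
    n = int(rng.integers(n_min, n_max + 1))
    stem = rng.random(n) < rng.uniform(0.1, 0.9)
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < 0.5
    ]
    pos = rng.uniform(0, 100, size=(n, 2))
    return make_graph(pos, stem, np.array(edges, dtype=int).reshape(-1, 2))


@pytest.fixture(scope="session")
def easy_fixture():
    """One well-separated rendered spheroid reused across image-stage tests.

    n=200 cells, no nucleus overlap (18 px minimum separation for ~6 px
    nuclei), marker separation far above 5 sd, fixed seed.
    """
    spec = FixtureSpec(n_cells=200, stem_fraction=0.3, arrangement="random", seed=1)
    truth = generate_points(spec)
    slc, truth_labels, draws = render_image(truth, spec)
    return {
        "spec": spec,
        "truth": truth,
        "slice": slc,
        "truth_labels": truth_labels,
        "draws": draws,
    }
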