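"""Independent first-principles oracles used by the test suite.

Everything here is deliberately naive — explicit loops, flood fill,
pixel-by-pixel nearest-site search — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np


def brute_assortativity(n_nodes, edges, stem) -> float | None:
    """Newman attribute assortativity from the explicit 2x2 mixing matrix."""
    if len(edges) == 0:
        return None
    e = np.zeros((2, 2))
    for a, b in edges:
        ta, tb = int(stem[a]), int(stem[b])
        # each undirected edge contributes half to each direction
        e[ta, tb] += 0.5
        e[tb, ta] += 0.5
    e /= len(edges)
    a_marg = e.sum(axis=1)
    denom = 1.0 - float(a_marg @ a_marg)
    if denom == 0.0:
        return None
    return (float(np.trace(e)) - float(a_marg @ a_marg)) / denom


def brute_homophily(edges, stem) -> float | None:
    if len(edges) == 0:
        return None
    same = sum(1 for a, b in edges if stem[a] == stem[b])
    return same / len(edges)


def brute_stem_stats(n_nodes, edges, stem):
    """(components, mean degree) of the stem-induced subgraph by flood fill."""
    stem_nodes = [i for i in range(n_nodes) if stem[i]]
    if not stem_nodes:
        return 0, 0.0
    adj = {i: set() for i in stem_nodes}
    for a, b in edges:
        if stem[a] and stem[b]:
            adj[a].add(b)
            adj[b].add(a)
    seen = set()
    components = 0
    for start in stem_nodes:
        if start in seen:
            continue
        components += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj[v] - seen)
    mean_degree = sum(len(adj[i]) for i in stem_nodes) / len(stem_nodes)
    return components, mean_degree


def brute_nearest_site(shape, sites, site_ids) -> np.ndarray:
    """Pixel-by-pixel nearest-site map; lowest site index wins ties."""
    h, w = shape
    out = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            best, best_d = -1, np.inf
            for k, (sx, sy) in enumerate(sites):
                d = (c - sx) ** 2 + (r - sy) ** 2
                if d < best_d:
                    best, best_d = k, d
            out[r, c] = site_ids[best]
    return out


def gmm_crossing_equal(mu1, mu2):
    """Analytic equal-posterior crossing for equal weights and equal sds."""
    return 0.5 * (mu1 + mu2)


def expected_homophily_ratio(n, n_stem) -> float:
    """Closed-form null expectation of the homophily ratio.

    Under drawing the stem set uniformly without replacement, for any edge
    P(same type) = [m(m-1) + (n-m)(n-m-1)] / [n(n-1)], identical for every
    edge, hence equal to the expected edge-averaged ratio.
    """
    m = n_stem
    d = n - m
    return (m * (m - 1) + d * (d - 1)) / (n * (n - 1))
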