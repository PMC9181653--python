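"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's spatial index and sorted-gap
clustering: containment is an exhaustive scan over every volume, and
clustering is all-pairs connected components on the break graph.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def brute_force_locate(geom, points: np.ndarray):
    """Exhaustive point->volume scan over all nucleotide and histone
    volumes, applying the documented priority backbone > base > histone >
    water and the (bp_index, strand) tie-break."""
    cfg = geom.config
    half = cfg.rise_nm / 2.0
    base_r = cfg.base_diameter_nm / 2.0
    bb_r = cfg.backbone_radius_nm
    pts = np.atleast_2d(points)
    n = len(pts)
    kind = np.full(n, 3, dtype=int)  # water
    strand = np.full(n, -1, dtype=int)
    bp_index = np.full(n, -1, dtype=int)
    for i, p in enumerate(pts):
        diff = p[None, :] - geom.origins
        loc = np.einsum("nj,njk->nk", diff, geom.rotations)
        x, y, z = loc[:, 0], loc[:, 1], loc[:, 2]
        r = np.hypot(x, y)
        in_z = np.abs(z) <= half
        is_base = in_z & (r <= base_r)
        is_backbone = in_z & (r > base_r) & (r <= bb_r) & (np.abs(x) >= np.abs(y))
        s = (x < 0).astype(int)
        best = None  # (kind, bp, strand)
        for bp in np.flatnonzero(is_backbone | is_base):
            k = 0 if is_backbone[bp] else 1
            cand = (k, bp, s[bp])
            if best is None or cand < best:
                best = cand
        if best is not None:
            kind[i], bp_index[i], strand[i] = best[0], best[1], best[2]
            continue
        # histone scan
        hd = p[None, :] - geom.histone_origins
        hl = np.einsum("nj,njk->nk", hd, geom.histone_rotations)
        inside = (np.hypot(hl[:, 0], hl[:, 1]) <= cfg.histone_radius_nm) & (
            np.abs(hl[:, 2]) <= cfg.histone_height_nm / 2.0
        )
        if inside.any():
            kind[i] = 2
    return kind, strand, bp_index


def component_clusters(breaks, n_bp: int) -> set[frozenset]:
    """All-pairs connected components of the |bp_i - bp_j| <= n_bp graph,
    per history, strand-blind.  Returns a set of frozensets of break
    records for direct comparison with single-linkage output."""
    out: set[frozenset] = set()
    by_history: dict[int, list] = {}
    for b in breaks:
        by_history.setdefault(b.history_id, []).append(b)
    for group in by_history.values():
        m = len(group)
        bp = np.array([b.bp_index for b in group])
        adj = (np.abs(bp[:, None] - bp[None, :]) <= n_bp).astype(int)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for c in range(n_comp):
            out.add(frozenset(group[i] for i in np.flatnonzero(labels == c)))
    return out


def brute_damage_counts(breaks, n_bp: int) -> tuple[int, int, int]:
    """(total breaks, dsb count, ssb break count) recomputed from the
    all-pairs components: a component containing both strands contributes
    min(per-strand counts) DSBs."""
    total = len(breaks)
    dsb = 0
    for comp in component_clusters(breaks, n_bp):
        n0 = sum(1 for b in comp if b.strand == 0)
        n1 = len(comp) - n0
        if n0 and n1:
            dsb += min(n0, n1)
    return total, dsb, total - 2 * dsb
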