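"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (O(N*M) scans, O(n^4) facet
enumeration, dense random quadrature) and shares no code with the package
beyond the data types it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_pocket_residues(structure, model, ligand_atoms, cutoff):
    """All-pairs distance scan: residues with any heavy atom within cutoff
    of any ligand heavy atom (ligand residues excluded)."""
    ligand_ids = {a.residue_id for a in ligand_atoms}
    lig = [a for a in ligand_atoms if a.is_heavy]
    residues = set()
    for a in structure.model_atoms(model):
        if a.residue_id in ligand_ids or not a.is_heavy:
            continue
        for b in lig:
            d = np.linalg.norm(np.asarray(a.coords) - np.asarray(b.coords))
            if d <= cutoff:
                residues.add(a.residue_id)
                break
    return residues


def hull_facets(points: np.ndarray):
    """Enumerate convex-hull facets by plane-side testing every triple.

    Assumes points in general position (no 4 coplanar hull points).
    Returns a list of (i, j, k) index triples with outward orientation.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    centroid = points.mean(axis=0)
    facets = []
    for i, j, k in itertools.combinations(range(n), 3):
        normal = np.cross(points[j] - points[i], points[k] - points[i])
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        side = (points - points[i]) @ normal
        others = np.delete(side, [i, j, k])
        if (others <= 1e-10).all() or (others >= -1e-10).all():
            if (centroid - points[i]) @ normal > 0:
                facets.append((i, k, j))
            else:
                facets.append((i, j, k))
    return facets


def hull_volume_area(points: np.ndarray) -> tuple[float, float]:
    """Convex-hull volume and surface area from enumerated facets."""
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    volume = 0.0
    area = 0.0
    for i, j, k in hull_facets(points):
        a, b, c = points[i], points[j], points[k]
        cross = np.cross(b - a, c - a)
        area += 0.5 * np.linalg.norm(cross)
        volume += abs(np.dot(a - centroid, np.cross(b - centroid, c - centroid))) / 6.0
    return volume, area


def sasa_random_quadrature(
    coords: np.ndarray,
    radii: np.ndarray,
    subset,
    probe: float = 1.4,
    n_points: int = 20000,
    seed: int = 12345,
) -> float:
    """High-resolution Monte Carlo Shrake-Rupley with random directions."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    total = 0.0
    for i in subset:
        surface = coords[i] + expanded[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((surface - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > expanded[j] ** 2
        total += accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return total


def spearman_hand_ranked(x, y) -> float:
    """Rank-then-Pearson with explicit average ranks, written independently."""

    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den
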