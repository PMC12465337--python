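"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written as the most literal possible procedure (flood
fill, explicit loops, Riemann refinement) and deliberately shares no
code with the package.
"""

from __future__ import annotations

import numpy as np


def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]
                                and labels[rr, cc] == 0
                            ):
                                labels[rr, cc] = current
                                stack.append((rr, cc))
    return labels, current


def boundary_edge_count(mask: np.ndarray) -> int:
    """Pixel-edge perimeter by checking each pixel's 4 sides explicitly."""
    mask = np.asarray(mask, dtype=bool)
    edges = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]) or not mask[rr, cc]:
                    edges += 1
    return edges


def graph_branch_count(skeleton: np.ndarray) -> int:
    """Branch points via an explicit pixel-adjacency graph.

    Nodes are skeleton pixels, edges join 8-neighbours; pixels of degree
    >= 3 are branch pixels, and connected clusters of branch pixels
    (8-adjacency among themselves) count once.
    """
    import networkx as nx

    skeleton = np.asarray(skeleton, dtype=bool)
    g = nx.Graph()
    pts = list(zip(*np.nonzero(skeleton)))
    g.add_nodes_from(pts)
    h, w = skeleton.shape
    for r, c in pts:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (dr, dc) != (0, 0) and 0 <= rr < h and 0 <= cc < w and skeleton[rr, cc]:
                    g.add_edge((r, c), (rr, cc))
    branch_nodes = [n for n in g.nodes if g.degree(n) >= 3]
    sub = g.subgraph(branch_nodes)
    return nx.number_connected_components(sub) if branch_nodes else 0


def riemann_auc(days: np.ndarray, values: np.ndarray, n_refine: int = 4000) -> float:
    """AUC by midpoint Riemann sums of the piecewise-linear interpolant,
    refined within each day interval so no cell straddles a knot."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    total = 0.0
    for i in range(len(days) - 1):
        xs = np.linspace(days[i], days[i + 1], n_refine + 1)
        mids = (xs[:-1] + xs[1:]) / 2.0
        ys = np.interp(mids, days, values)
        total += float((ys * np.diff(xs)).sum())
    return total


def zsum_mean_loop(stack: np.ndarray, mask: np.ndarray) -> float:
    """Triple-loop z-sum masked mean."""
    total = 0.0
    count = 0
    for r in range(stack.shape[1]):
        for c in range(stack.shape[2]):
            if mask[r, c]:
                s = 0.0
                for z in range(stack.shape[0]):
                    s += stack[z, r, c]
                total += s
                count += 1
    return total / count


def masked_mean_loop(image: np.ndarray, mask: np.ndarray) -> float:
    """Explicit double-loop masked mean."""
    total, count = 0.0, 0
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            if mask[r, c]:
                total += image[r, c]
                count += 1
    return total / count if count else 0.0


def rank_by_sorting(values: np.ndarray) -> np.ndarray:
    """Average ranks (1 = lowest) via explicit sorting, handling ties."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
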