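"""Independent brute-force oracles: plain-Python flood fill and edge scans.

These deliberately avoid scipy/skimage and vectorized shortcuts so they can
serve as an independent cross-check of the package's landscape metrics.
"""

import math


def flood_fill_patches(values, code, connectivity=8):
    """Partition class-``code`` cells into connected patches by BFS.

    Returns a list of (area_cells, perimeter_edges) tuples.
    """
    nrows, ncols = len(values), len(values[0])
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = [[False] * ncols for _ in range(nrows)]
    patches = []
    for r0 in range(nrows):
        for c0 in range(ncols):
            if values[r0][c0] != code or seen[r0][c0]:
                continue
            queue = [(r0, c0)]
            seen[r0][c0] = True
            area, perim = 0, 0
            while queue:
                r, c = queue.pop()
                area += 1
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nrows and 0 <= cc < ncols) or values[rr][cc] != code:
                        perim += 1
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols and values[rr][cc] == code and not seen[rr][cc]:
                        seen[rr][cc] = True
                        queue.append((rr, cc))
            patches.append((area, perim))
    return patches


def like_adjacencies(values, code):
    """Single-count 4-neighbor like adjacencies of class ``code``."""
    nrows, ncols = len(values), len(values[0])
    g = 0
    for r in range(nrows):
        for c in range(ncols):
            if values[r][c] != code:
                continue
            if c + 1 < ncols and values[r][c + 1] == code:
                g += 1
            if r + 1 < nrows and values[r + 1][c] == code:
                g += 1
    return g


def max_like_adjacencies(a):
    n = int(math.isqrt(a))
    m = a - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def metrics_bruteforce(values, code):
    """LPI / COHESION / SPLIT / AI computed from scratch for one class."""
    nrows, ncols = len(values), len(values[0])
    total = nrows * ncols
    patches = flood_fill_patches(values, code, connectivity=8)
    if not patches:
        return None
    areas = [a for a, _ in patches]
    perims = [p for _, p in patches]
    lpi = 100.0 * max(areas) / total
    num = sum(perims)
    den = sum(p * math.sqrt(a) for a, p in patches)
    cohesion = (1.0 - num / den) / (1.0 - 1.0 / math.sqrt(total)) * 100.0
    split = total**2 / sum(a * a for a in areas)
    a_class = sum(areas)
    gmax = max_like_adjacencies(a_class)
    ai = 100.0 if gmax == 0 else 100.0 * like_adjacencies(values, code) / gmax
    return {"LPI": lpi, "COHESION": cohesion, "SPLIT": split, "AI": ai}
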