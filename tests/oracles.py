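"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity from its definition by exhaustive
pixel/element enumeration, deliberately sharing no code with the package
implementation it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_enclosed_dark_components(bright: np.ndarray) -> list[frozenset]:
    """Dark components not reachable from the border: explicit BFS.

    Background flood fill uses 4-neighbour moves; enclosed components are
    grouped with 8-neighbour moves.  Returns a list of pixel-coordinate
    frozensets, unordered.
    """
    h, w = bright.shape
    dark = ~bright
    visited = np.zeros_like(dark, dtype=bool)
    queue = deque()
    for r in range(h):
        for c in (0, w - 1):
            if dark[r, c] and not visited[r, c]:
                visited[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if dark[r, c] and not visited[r, c]:
                visited[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and dark[rr, cc] and not visited[rr, cc]:
                visited[rr, cc] = True
                queue.append((rr, cc))
    components = []
    seen = visited.copy()
    for r0 in range(h):
        for c0 in range(w):
            if dark[r0, c0] and not seen[r0, c0]:
                comp = set()
                seen[r0, c0] = True
                q = deque([(r0, c0)])
                while q:
                    r, c = q.popleft()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            if dr == dc == 0:
                                continue
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h
                                and 0 <= cc < w
                                and dark[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                q.append((rr, cc))
                components.append(frozenset(comp))
    return components


def crofton_perimeter(mask: np.ndarray) -> float:
    """Cauchy-Crofton perimeter by counting grid-line intercepts.

    Counts 0/1 transitions along rows, columns and both diagonals of the
    zero-padded mask; lines in the two diagonal families are spaced
    1/sqrt(2) apart.  P = (pi/2) * mean over the four families of
    (intercepts * spacing).
    """
    m = np.pad(mask.astype(int), 1)
    nh = np.abs(np.diff(m, axis=1)).sum()
    nv = np.abs(np.diff(m, axis=0)).sum()
    nd1 = np.abs(m[1:, 1:] - m[:-1, :-1]).sum()
    nd2 = np.abs(m[1:, :-1] - m[:-1, 1:]).sum()
    return float(np.pi / 2 * (nh + nv + (nd1 + nd2) / np.sqrt(2)) / 4)


def circularity_by_pixel_counting(mask: np.ndarray) -> float:
    """4*pi*area/perimeter^2 with exhaustively counted area and perimeter."""
    area = int(mask.sum())
    perim = crofton_perimeter(mask)
    return 4 * np.pi * area / perim**2


def annulus_sector_maxima(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    half_width: float,
    n_sectors: int,
) -> np.ndarray:
    """Per-angular-sector maximum over every pixel in the annulus r +/- half_width.

    Sectors are centered on the same angle grid the ray profiler uses
    (equally spaced starting at 0 rad, angle measured as atan2(drow, dcol)).
    """
    h, w = image.shape
    rows, cols = np.mgrid[0:h, 0:w]
    d = np.hypot(rows - center[0], cols - center[1])
    in_annulus = np.abs(d - radius) <= half_width
    theta = np.arctan2(rows - center[0], cols - center[1]) % (2 * np.pi)
    sector_width = 2 * np.pi / n_sectors
    # sector i covers angles within +/- sector_width/2 of i*sector_width
    sector = np.round(theta / sector_width).astype(int) % n_sectors
    maxima = np.full(n_sectors, -np.inf)
    vals = image[in_annulus]
    secs = sector[in_annulus]
    for s, v in zip(secs, vals):
        if v > maxima[s]:
            maxima[s] = v
    return maxima


def box_stats_by_definition(values: np.ndarray):
    """Tukey box statistics recomputed literally from the definition."""
    arr = np.sort(np.asarray(values, dtype=float))
    q1 = np.percentile(arr, 25)
    med = np.percentile(arr, 50)
    q3 = np.percentile(arr, 75)
    iqr = q3 - q1
    lo = [x for x in arr if x >= q1 - 1.5 * iqr]
    hi = [x for x in arr if x <= q3 + 1.5 * iqr]
    whisker_low = min(lo)
    whisker_high = max(hi)
    outliers = sorted(x for x in arr if x < whisker_low or x > whisker_high)
    return med, q1, q3, whisker_low, whisker_high, outliers


def random_chain_pair_fractions(p: float) -> dict[str, float]:
    """Chain-pair composition by enumeration over ordered (chain1, chain2).

    Each chain is 16:0 with probability p else 18:1, independently.
    """
    out = {"DP": 0.0, "DO": 0.0, "PO": 0.0}
    for c1, p1 in (("16:0", p), ("18:1", 1 - p)):
        for c2, p2 in (("16:0", p), ("18:1", 1 - p)):
            pair = {c1, c2}
            if pair == {"16:0"}:
                out["DP"] += p1 * p2
            elif pair == {"18:1"}:
                out["DO"] += p1 * p2
            else:
                out["PO"] += p1 * p2
    return out
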