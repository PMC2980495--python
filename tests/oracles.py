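"""Independent brute-force oracles used to check the implementation.

These are deliberately written with plain Python loops and the standard
library (``statistics.median``), sharing no code path with the package.
"""

from __future__ import annotations

from collections import deque
from statistics import median


def flood_fill_components(mask, connectivity: int = 8):
    """Exhaustive flood-fill labeling of a boolean pixel grid.

    Returns ``(n_components, labels)`` where ``labels`` is a nested list of
    component ids (0 = background).
    """
    n_rows = len(mask)
    n_cols = len(mask[0]) if n_rows else 0
    labels = [[0] * n_cols for _ in range(n_rows)]
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if mask[r0][c0] and labels[r0][c0] == 0:
                count += 1
                q = deque([(r0, c0)])
                labels[r0][c0] = count
                while q:
                    r, c = q.popleft()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < n_rows and 0 <= cc < n_cols
                                and mask[rr][cc] and labels[rr][cc] == 0):
                            labels[rr][cc] = count
                            q.append((rr, cc))
    return count, labels


def median_polish_reference(matrix, max_iter: int = 200, tol: float = 1e-12):
    """Exhaustive-sweep two-way median polish on a full (list-of-lists) matrix.

    Returns ``(mu, row_effects, col_effects, residuals)``.
    """
    r = [row[:] for row in matrix]
    n_rows = len(r)
    n_cols = len(r[0])
    mu = 0.0
    row_eff = [0.0] * n_rows
    col_eff = [0.0] * n_cols

    for _ in range(max_iter):
        biggest = 0.0
        for i in range(n_rows):
            m = median(r[i])
            biggest = max(biggest, abs(m))
            for j in range(n_cols):
                r[i][j] -= m
            row_eff[i] += m
        d = median(col_eff)
        col_eff = [c - d for c in col_eff]
        mu += d

        for j in range(n_cols):
            m = median(r[i][j] for i in range(n_rows))
            biggest = max(biggest, abs(m))
            for i in range(n_rows):
                r[i][j] -= m
            col_eff[j] += m
        d = median(row_eff)
        row_eff = [x - d for x in row_eff]
        mu += d

        if biggest <= tol:
            break
    return mu, row_eff, col_eff, r
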