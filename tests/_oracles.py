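"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (BFS flood fill, explicit loops) that
share no code path with the package.
"""
from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_components(binary: np.ndarray, connectivity: int = 26):
    """Connected components of a 3-D boolean array via BFS flood fill.

    Returns (labels, n_components); labels are 1-based, 0 is background.
    """
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    labels = np.zeros(binary.shape, dtype=int)
    n = 0
    shape = binary.shape
    for idx in np.argwhere(binary):
        idx = tuple(idx)
        if labels[idx]:
            continue
        n += 1
        queue = deque([idx])
        labels[idx] = n
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= nb[i] < shape[i] for i in range(3)):
                    if binary[nb] and not labels[nb]:
                        labels[nb] = n
                        queue.append(nb)
    return labels, n


def tfce_bruteforce(stat: np.ndarray, mask: np.ndarray, E: float, H: float,
                    dh: float, connectivity: int = 26) -> np.ndarray:
    """Per-threshold connected-component TFCE, one signed side at a time."""
    out = np.zeros(stat.shape)
    for sign in (1.0, -1.0):
        side = np.where(mask, sign * stat, 0.0)
        hmax = side.max()
        if hmax <= 0:
            continue
        for k in range(1, int(np.floor(hmax / dh + 1e-9)) + 1):
            h = k * dh
            above = side >= h - 1e-9 * dh
            labels, n = flood_fill_components(above, connectivity)
            for comp in range(1, n + 1):
                members = labels == comp
                extent = members.sum()
                out[members] += sign * (extent**E) * (h**H) * dh
    return out


def ranova_ss_oracle(wide: np.ndarray):
    """Repeated-measures one-way ANOVA by explicit sum-of-squares loops."""
    n, k = wide.shape
    grand = wide.sum() / (n * k)
    ss_cond = 0.0
    for j in range(k):
        m = sum(wide[i, j] for i in range(n)) / n
        ss_cond += n * (m - grand) ** 2
    ss_subj = 0.0
    for i in range(n):
        m = sum(wide[i, j] for j in range(k)) / k
        ss_subj += k * (m - grand) ** 2
    ss_tot = sum((wide[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    return f, df1, df2
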