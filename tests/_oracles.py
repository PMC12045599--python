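"""Brute-force oracles shared across test modules (independent of the
library code paths they check)."""

from collections import deque

import numpy as np


def flood_fill_label(mask):
    """Exhaustive 26-connected component labeling, independent of ndimage."""
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    for idx in zip(*np.nonzero(mask)):
        if labels[idx]:
            continue
        current += 1
        queue = deque([idx])
        labels[idx] = current
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)) \
                        and mask[n] and not labels[n]:
                    labels[n] = current
                    queue.append(n)
    return labels, current
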