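"""Small draw-based posterior summaries shared by the samplers."""

from __future__ import annotations

from typing import Tuple

import numpy as np


def hpd_from_draws(draws: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    """Shortest interval containing ``level`` of the draws (lo, hi).

    Sorted-window method; appropriate for unimodal marginals such as ΔR or a
    regression slope.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("no draws")
    k = max(int(np.ceil(level * n)), 1)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])
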