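"""Local-regression (loess-family) smoothing shared by spectra and curves."""

from __future__ import annotations

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Degree-1 local regression (lowess) of ``y`` on ``x``.

    ``span`` is the fraction of points in each local neighbourhood
    (tricube-weighted, no robustness iterations), matching the common R
    convention for ``span`` in loess-type smoothers.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        return y.copy()
    return lowess(y, x, frac=span, it=0, return_sorted=False)
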