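"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's estimation code paths: plain
normal equations assembled from explicitly constructed lag matrices,
solved with matrix inversion.
"""

from __future__ import annotations

import numpy as np


def brute_force_gc(x: np.ndarray, y: np.ndarray, order: int) -> float:
    """log variance-ratio Granger causality F_{y->x} by normal equations."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    x = x - x.mean()
    y = y - y.mean()
    n = x.shape[0]
    target = x[order:]

    def lags(series: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [series[order - k : n - k] for k in range(1, order + 1)]
        )

    def rss(design: np.ndarray) -> float:
        coef = np.linalg.inv(design.T @ design) @ (design.T @ target)
        resid = target - design @ coef
        return float(resid @ resid)

    rss_restricted = rss(lags(x))
    rss_full = rss(np.hstack([lags(x), lags(y)]))
    return float(np.log(rss_restricted / rss_full))


def ar_ols_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    """Own-past AR coefficients by explicit normal equations."""
    x = np.asarray(x, dtype=np.float64).ravel()
    x = x - x.mean()
    n = x.shape[0]
    target = x[order:]
    design = np.column_stack([x[order - k : n - k] for k in range(1, order + 1)])
    return np.linalg.inv(design.T @ design) @ (design.T @ target)
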