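"""Comparator normalization estimators: total-count ratio and OLS regression.

Both produce a single point estimate of the normalization factor with no
uncertainty attached, which is what the Bayesian model improves on.  They
share an output convention: ``log2_factor`` is the log2 factor placing the
query counts (x) on the reference scale (y), and ``slope = 2**log2_factor``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["PointEstimate", "ratio_estimate", "ols_estimate"]


@dataclass
class PointEstimate:
    method: str  # "ratio" or "ols"
    log2_factor: float
    slope: float
    intercept: float
    n_regions: int

    def to_json_record(self) -> dict:
        return asdict(self)


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"count vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be nonnegative")
    return x, y


def ratio_estimate(counts_x, counts_y, pseudocount: float = 1.0) -> PointEstimate:
    """Naive total-count ratio normalization factor.

    log2_factor = log2((sum(y) + pseudocount) / (sum(x) + pseudocount)); the
    pseudocount is applied once to each total (the level at which the ratio
    is taken), keeping the estimate finite for all-zero inputs and the
    estimator exactly antisymmetric under swapping x and y.
    """
    x, y = _check_pair(counts_x, counts_y)
    if x.size < 1:
        raise ValueError("need at least one region")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    log2_factor = float(np.log2((y.sum() + pseudocount) / (x.sum() + pseudocount)))
    return PointEstimate(
        method="ratio",
        log2_factor=log2_factor,
        slope=float(2.0 ** log2_factor),
        intercept=0.0,
        n_regions=int(x.size),
    )


def ols_estimate(counts_x, counts_y, log_scale: bool = False) -> PointEstimate:
    """Unweighted least-squares regression of reference on query counts.

    Fits y = m*x + b on the raw count scale (closed form: m = cov(x, y) /
    var(x)) and reports log2(m); raises if the slope is nonpositive, where a
    log2 normalization factor is undefined — one failure mode the Bayesian
    model avoids.  With ``log_scale=True`` the regression is instead fit on
    log2(counts + 1), and the slope-derived factor is the fitted mean offset.
    """
    x, y = _check_pair(counts_x, counts_y)
    if x.size < 2:
        raise ValueError("need at least 2 regions for regression")
    if log_scale:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    vx = float(np.var(x))
    if vx == 0.0:
        raise ValueError("counts_x is constant: regression design is degenerate")
    m = float(np.cov(x, y, ddof=0)[0, 1] / vx)
    b = float(y.mean() - m * x.mean())
    if log_scale:
        # on log scale the vertical offset at the mean is the log2 factor
        log2_factor = float(y.mean() - x.mean())
        return PointEstimate("ols", log2_factor, float(2.0 ** log2_factor), b, int(x.size))
    if m <= 0.0:
        raise ValueError(f"fitted slope {m:.4g} is not positive; log2 factor undefined")
    return PointEstimate(
        method="ols",
        log2_factor=float(np.log2(m)),
        slope=m,
        intercept=b,
        n_regions=int(x.size),
    )
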