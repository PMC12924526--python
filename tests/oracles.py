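"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computational paths: agreement is
computed straight from the defining double sums over pairable values, and
sequential sums of squares from explicit orthogonal projections.
"""

from __future__ import annotations

import numpy as np


def alpha_bruteforce(matrix, delta) -> float:
    """Krippendorff's alpha from the definition.

    ``matrix``: rows = units, columns = annotators, ``None`` = missing;
    ``delta(a, b)``: squared-distance function.  Observed disagreement
    averages within-unit ordered pairs weighted by 1/(m_u - 1); expected
    disagreement averages ordered pairs over the pooled values.
    """
    units = []
    for row in matrix:
        vals = [v for v in row if v is not None]
        if len(vals) >= 2:
            units.append(vals)
    if len(units) < 2:
        raise ValueError("need >= 2 items with pairable values")
    pooled = [v for u in units for v in u]
    n = len(pooled)

    d_o = 0.0
    for vals in units:
        m = len(vals)
        s = 0.0
        for i in range(m):
            for j in range(m):
                if i != j:
                    s += delta(vals[i], vals[j])
        d_o += s / (m - 1)
    d_o /= n

    d_e = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d_e += delta(pooled[i], pooled[j])
    d_e /= n * (n - 1)
    if d_e == 0:
        return float("nan")
    return 1.0 - d_o / d_e


def nominal_delta(a, b) -> float:
    return 0.0 if a == b else 1.0


def interval_delta(a, b) -> float:
    return (float(a) - float(b)) ** 2


def sequential_ss(y, blocks) -> tuple[list[float], float]:
    """Type-I sums of squares by explicit projection.

    ``blocks``: list of 2-D arrays, the design columns of each term in
    entry order.  Returns (per-term SS, residual SS) relative to the
    intercept-only model, via orthonormal bases built with QR.
    """
    y = np.asarray(y, float)
    n = y.size
    X = np.ones((n, 1))
    q_prev, _ = np.linalg.qr(X)
    rss_prev = float(np.sum((y - q_prev @ (q_prev.T @ y)) ** 2))
    out = []
    for blk in blocks:
        X = np.column_stack([X, blk])
        q, _ = np.linalg.qr(X)
        resid = y - q @ (q.T @ y)
        rss = float(resid @ resid)
        out.append(rss_prev - rss)
        rss_prev = rss
    return out, rss_prev
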