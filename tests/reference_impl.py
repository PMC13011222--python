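"""Independent reference implementations used as test oracles.

``slope_constrained_reference`` is a line-by-line rendition of the
method's published pseudocode — threshold estimation, per-segment
linear interpolation, sequential clipping — written with plain Python
loops and no shared code with the package, so agreement with the
optimized path is meaningful.  ``naive_metrics`` computes R²/MAE/RMSE
with explicit loops for the same reason.
"""

import math

import numpy as np


def slope_constrained_reference(values, p):
    """Reconstruct a series with bounded gaps; returns (filled, tau)."""
    x = [float(v) for v in values]
    n = len(x)

    # Step 1: empirical slope threshold from adjacent observed pairs
    slopes = []
    for i in range(1, n):
        if not math.isnan(x[i]) and not math.isnan(x[i - 1]):
            slopes.append(abs(x[i] - x[i - 1]))
    if not slopes:
        raise ValueError("no adjacent observed pair")
    tau = float(np.percentile(slopes, p))

    out = list(x)
    i = 0
    while i < n:
        if math.isnan(x[i]):
            a = i - 1
            b = i
            while b < n and math.isnan(x[b]):
                b += 1
            if a < 0 or b >= n:
                raise ValueError("unbounded missing run")
            # Step 2: linear interpolation over the segment
            # Step 3: sequential slope constraint
            prev = x[a]
            for k in range(a + 1, b):
                lin = x[a] + (k - a) / (b - a) * (x[b] - x[a])
                delta = lin - prev
                if abs(delta) > tau:
                    sign = 1 if delta > 0 else (-1 if delta < 0 else 0)
                    cur = prev + sign * tau
                else:
                    cur = lin
                out[k] = cur
                prev = cur
            i = b
        else:
            i += 1
    return out, tau


def naive_metrics(truth, imputed):
    """Loop-computed (r2, mae, rmse) for cross-checking vector code."""
    n = len(truth)
    mean = sum(truth) / n
    ss_res = sum((t - p) ** 2 for t, p in zip(truth, imputed))
    ss_tot = sum((t - mean) ** 2 for t in truth)
    mae = sum(abs(t - p) for t, p in zip(truth, imputed)) / n
    rmse = math.sqrt(ss_res / n)
    r2 = 1.0 - ss_res / ss_tot
    return r2, mae, rmse
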