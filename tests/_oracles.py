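"""Independent brute-force oracles, deliberately naive.

Pure-Python loop implementations of the median polish, the B-score scale
and the consensus hit rules, kept free of numpy vectorization and of any
import from the package's numerical code paths, so they can serve as an
independent check of the production implementations.
"""

from __future__ import annotations

import math


def naive_median(values):
    xs = sorted(v for v in values if v is not None and not math.isnan(v))
    if not xs:
        return math.nan
    n = len(xs)
    if n % 2 == 1:
        return xs[n // 2]
    return 0.5 * (xs[n // 2 - 1] + xs[n // 2])


def naive_median_polish(matrix, max_iter=100, tol=1e-6):
    """Row/column median sweeps on a list-of-lists; None/NaN = missing.

    Returns (overall, row_effects, col_effects, residuals, converged).
    """
    z = [[(math.nan if v is None else float(v)) for v in row] for row in matrix]
    n_rows, n_cols = len(z), len(z[0])
    overall = 0.0
    row_eff = [0.0] * n_rows
    col_eff = [0.0] * n_cols

    converged = False
    for _ in range(max_iter):
        adjustment = 0.0
        for i in range(n_rows):
            m = naive_median(z[i])
            adjustment += abs(m)
            for j in range(n_cols):
                z[i][j] -= m
            row_eff[i] += m
        shift = naive_median(col_eff)
        adjustment += abs(shift)
        col_eff = [c - shift for c in col_eff]
        overall += shift

        for j in range(n_cols):
            m = naive_median([z[i][j] for i in range(n_rows)])
            adjustment += abs(m)
            for i in range(n_rows):
                z[i][j] -= m
            col_eff[j] += m
        shift = naive_median(row_eff)
        adjustment += abs(shift)
        row_eff = [r - shift for r in row_eff]
        overall += shift

        if adjustment < tol:
            converged = True
            break
    return overall, row_eff, col_eff, z, converged


def naive_bscore(matrix, mad_constant=1.4826, max_iter=100, tol=1e-6):
    """B-scores of a plate matrix: polish residuals / (constant x median |residual|)."""
    _, _, _, resid, _ = naive_median_polish(matrix, max_iter=max_iter, tol=tol)
    flat = [v for row in resid for v in row if not math.isnan(v)]
    scale = mad_constant * naive_median([abs(v) for v in flat])
    out = []
    for row in resid:
        if scale > 0:
            out.append([v / scale for v in row])
        else:
            out.append([(math.nan if math.isnan(v) else 0.0) for v in row])
    return out, scale


def naive_consensus(score_matrix, threshold, min_sirnas, min_reps):
    """Exhaustive evaluation: >= min_sirnas rows each passing in >= min_reps columns."""
    qualifying = 0
    for row in score_matrix:
        n_pass = 0
        for v in row:
            if v is not None and not math.isnan(v) and v >= threshold:
                n_pass += 1
        if n_pass >= min_reps:
            qualifying += 1
    return qualifying >= min_sirnas
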