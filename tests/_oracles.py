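"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately takes a different computational route from the
code it checks: exhaustive grid searches, explicit least-squares ratios,
enumeration — slow but unambiguous.
"""

from __future__ import annotations

import numpy as np


def last_sunday_by_enumeration(year: int, month: int):
    """Last Sunday of a month found by walking every day of the month."""
    import datetime

    day = datetime.date(year, month, 1)
    sundays = []
    while day.month == month:
        if day.weekday() == 6:
            sundays.append(day)
        day += datetime.timedelta(days=1)
    return sundays[-1]


def grid_cosinor_acrophase(y, step: float = 0.01) -> float:
    """Acrophase by exhaustive grid search over the peak time.

    For each candidate acrophase phi on a grid, the mesor and amplitude
    are profiled by 2-parameter least squares; the phi with the smallest
    residual sum of squares wins.  Candidates whose best-fit amplitude is
    negative are equivalent to phi + 12 with positive amplitude.
    """
    y = np.asarray(y, dtype=float)
    t = np.arange(y.size, dtype=float)
    w = 2.0 * np.pi / 24.0
    best_phi, best_sse = None, np.inf
    for phi in np.arange(0.0, 24.0, step):
        design = np.column_stack([np.ones(y.size), np.cos(w * (t - phi))])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((y - design @ beta) ** 2))
        if sse < best_sse:
            best_sse = sse
            best_phi = (phi + 12.0) % 24.0 if beta[1] < 0 else phi
    return best_phi


def least_squares_ratio(ref, inc) -> float:
    """c* minimizing sum((ref - c*inc)^2): closed form sum(ref*inc)/sum(inc^2)."""
    ref = np.asarray(ref, dtype=float)
    inc = np.asarray(inc, dtype=float)
    return float(np.sum(ref * inc) / np.sum(inc * inc))


def circ_dist_hours(a, b):
    """Circular distance on the 24-h dial, in hours (always in [0, 12])."""
    d = np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 12.0) % 24.0 - 12.0)
    return d


def grid_circular_mean(phases, step: float = 0.001) -> float:
    """Circular mean by minimizing the sum of squared circular distances on a grid."""
    ph = np.asarray(phases, dtype=float)
    grid = np.arange(0.0, 24.0, step)
    d = (grid[:, None] - ph[None, :] + 12.0) % 24.0 - 12.0
    sse = np.sum(d * d, axis=1)
    return float(grid[int(np.argmin(sse))])


def tukey_fences(values):
    """Tukey 1.5*IQR fences from hand-rolled linearly-interpolated quartiles."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size

    def quantile(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def student_t_pvalue(a, b) -> float:
    """Classic equal-variance two-sample two-tailed t-test by explicit formula."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return float(2.0 * tdist.sf(abs(t_stat), na + nb - 2))
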