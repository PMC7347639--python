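"""Independent brute-force oracles used to validate the implementation.

Everything here is written as a deliberately naive, loop-based alternative
code path: sorted-list neighbourhoods and least-squares solves for the
smoother, hand-built average ranks plus a plain correlation coefficient for
Spearman, and exhaustive linear scans for onset rules and gap statistics.
"""

from __future__ import annotations

import datetime as dt

import numpy as np


def brute_lowess(x, y, frac, k_override=None):
    """Tricube-weighted local-linear smoother, one least-squares solve per point."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    k = k_override if k_override is not None else int(np.ceil(frac * n))
    k = min(max(k, 2), n)
    fitted = []
    for i in range(n):
        order = sorted(range(n), key=lambda j: (abs(x[j] - x[i]), j))
        nbr = order[:k]
        h = max(abs(x[j] - x[i]) for j in nbr)
        weights = []
        for j in nbr:
            u = 0.0 if h == 0 else abs(x[j] - x[i]) / h
            weights.append(max(0.0, 1.0 - u**3) ** 3)
        w = np.array(weights)
        xs = np.array([x[j] for j in nbr])
        ys = np.array([y[j] for j in nbr])
        if w.sum() <= 0:
            fitted.append(float(ys.mean()))
            continue
        xb = float((w * xs).sum() / w.sum())
        sxx = float((w * (xs - xb) ** 2).sum())
        if sxx <= 1e-12 * max(1.0, xb * xb):
            fitted.append(float((w * ys).sum() / w.sum()))
            continue
        design = np.vstack([np.ones_like(xs), xs]).T * np.sqrt(w)[:, None]
        target = ys * np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design, target, rcond=None)
        fitted.append(float(beta[0] + beta[1] * x[i]))
    return np.array(fitted)


def average_ranks(values):
    """Ranks 1..n with ties sharing the average of their positions."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # positions are 1-based
        for pos in range(i, j + 1):
            ranks[order[pos]] = avg
        i = j + 1
    return np.array(ranks)


def spearman_brute(x, y):
    """Pearson correlation of hand-built average ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def weekend_days_oracle(year):
    """Day-of-year numbers of Saturdays/Sundays via datetime iteration."""
    days = []
    day = dt.date(year, 1, 1)
    while day.year == year:
        if day.weekday() >= 5:
            days.append(day.timetuple().tm_yday)
        day += dt.timedelta(days=1)
    return days


def longest_gap_scan(missing_flags):
    """Longest run of True by checking every (start, end) run explicitly."""
    n = len(missing_flags)
    best = 0
    for start in range(n):
        for end in range(start, n):
            if all(missing_flags[start : end + 1]):
                best = max(best, end - start + 1)
    return best


def start_cumulative_scan(values, fraction):
    """First 1-based day where the running sum reaches fraction × total."""
    clean = [0.0 if v is None or np.isnan(v) else max(v, 0.0) for v in values]
    total = sum(clean)
    if total <= 0:
        return None
    running = 0.0
    for day, v in enumerate(clean, start=1):
        running += v
        if running >= fraction * total:
            return day
    return None


def start_consecutive_scan(values, run_length):
    """First day of the earliest run of run_length observed positive days."""
    n = len(values)
    for start in range(n - run_length + 1):
        window = values[start : start + run_length]
        if all(v is not None and not np.isnan(v) and v > 0 for v in window):
            return start + 1
    return None


def start_absolute_scan(values, threshold):
    """First observed day at or above the threshold."""
    for day, v in enumerate(values, start=1):
        if v is not None and not np.isnan(v) and v >= threshold:
            return day
    return None


def pooled_t_stat(a, b):
    """Two-sample pooled-variance t statistic from the textbook formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def ols_closed_form(x, y):
    """Slope/intercept/R² by the closed-form least-squares formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
    intercept = yb - slope * xb
    resid = y - intercept - slope * x
    r2 = 1 - (resid**2).sum() / ((y - yb) ** 2).sum()
    return slope, intercept, r2
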