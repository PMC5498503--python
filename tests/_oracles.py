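"""Independent brute-force oracles, deliberately written plainly and
separately from the package implementation."""

import numpy as np

MONTH_LEN = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


def daily_series_oracle(monthly):
    """Day-by-day piecewise-linear interpolation between month midpoints
    (day centres, wrapping December to January).  Pure-python loop."""
    starts = np.cumsum([0] + MONTH_LEN[:-1])
    mids = [s + n / 2.0 for s, n in zip(starts, MONTH_LEN)]
    knots_x = [mids[-1] - 365.0] + list(mids) + [mids[0] + 365.0]
    knots_y = [monthly[11]] + list(monthly) + [monthly[0]]
    out = []
    for d in range(365):
        x = d + 0.5
        for i in range(len(knots_x) - 1):
            if knots_x[i] <= x <= knots_x[i + 1]:
                w = (x - knots_x[i]) / (knots_x[i + 1] - knots_x[i])
                out.append((1 - w) * knots_y[i] + w * knots_y[i + 1])
                break
    assert len(out) == 365
    return np.array(out)


def degree_days_oracle(monthly_tmean, base, direction):
    daily = daily_series_oracle(monthly_tmean)
    total = 0.0
    for t in daily:
        if direction == "above" and t > base:
            total += t - base
        elif direction == "below" and t < base:
            total += base - t
    return total


def nffd_oracle(monthly_tmin):
    daily = daily_series_oracle(monthly_tmin)
    return sum(1 for t in daily if t > 0.0)


def auc_pairs_oracle(scores, labels):
    """All-pairs Mann–Whitney count, ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for a in neg:
            if p > a:
                total += 1.0
            elif p == a:
                total += 0.5
    return total / (len(pos) * len(neg))


def balanced_oneway_anova(y_by_group):
    """Method-of-moments estimators for the balanced one-way random
    model: sigma2_e = MS_within, sigma2_g = (MS_between - MS_within)/n."""
    groups = [np.asarray(g, dtype=float) for g in y_by_group]
    k = len(groups)
    n = len(groups[0])
    assert all(len(g) == n for g in groups)
    grand = np.mean([g.mean() for g in groups])
    ms_between = n * sum((g.mean() - grand) ** 2 for g in groups) / (k - 1)
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups) / (k * (n - 1))
    return max((ms_between - ms_within) / n, 0.0), ms_within
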