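"""Independent brute-force oracles.

Deliberately written sample-by-sample / from textbook formulas with no
vectorized shortcuts, so they stay independent of the implementation paths
they verify.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_metrics(raw) -> np.ndarray:
    """Loop-based recomputation of the 16-metric table of a regularized stream.

    Conventions mirrored from the documented contract: half-open 0.2 s
    windows of 10 samples; velocity defined from the second raw sample,
    acceleration from the third; cumulative channels as end-minus-start
    deltas; blood as window mean level; bleeding rate as positive inflow
    divided by the window length.
    """
    t = list(raw.time)
    n = len(t)
    dt = t[1] - t[0]
    per = int(round(0.2 / dt))
    n_win = n // per

    def pos(inst, k):
        arr = raw.aspirator_pos if inst == "a" else raw.bipolar_pos
        return [float(arr[k, 0]), float(arr[k, 1]), float(arr[k, 2])]

    def vel(inst, k):  # defined for k >= 1
        p1, p0 = pos(inst, k), pos(inst, k - 1)
        return [(p1[d] - p0[d]) / dt for d in range(3)]

    def norm(v):
        return math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)

    rows = []
    for w in range(n_win):
        a, b = w * per, (w + 1) * per
        row = []
        # forces
        for arr in (raw.aspirator_force, raw.bipolar_force):
            s = 0.0
            for k in range(a, b):
                s += float(arr[k])
            row.append(s / per)
        # velocity magnitudes
        for inst in ("a", "b"):
            s, cnt = 0.0, 0
            for k in range(a, b):
                if k >= 1:
                    s += norm(vel(inst, k))
                    cnt += 1
            row.append(s / cnt if cnt else 0.0)
        # acceleration magnitudes
        for inst in ("a", "b"):
            s, cnt = 0.0, 0
            for k in range(a, b):
                if k >= 2:
                    v1, v0 = vel(inst, k), vel(inst, k - 1)
                    s += norm([(v1[d] - v0[d]) / dt for d in range(3)])
                    cnt += 1
            row.append(s / cnt if cnt else 0.0)
        # tip separation
        s = 0.0
        for k in range(a, b):
            pa, pb = pos("a", k), pos("b", k)
            s += norm([pa[d] - pb[d] for d in range(3)])
        row.append(s / per)
        # relative velocity magnitude
        s, cnt = 0.0, 0
        for k in range(a, b):
            if k >= 1:
                va, vb = vel("a", k), vel("b", k)
                s += norm([va[d] - vb[d] for d in range(3)])
                cnt += 1
        row.append(s / cnt if cnt else 0.0)
        # path lengths
        for inst in ("a", "b"):
            s = 0.0
            for k in range(max(a, 1), b):
                p1, p0 = pos(inst, k), pos(inst, k - 1)
                s += norm([p1[d] - p0[d] for d in range(3)])
            row.append(s)
        # active fractions
        for arr in (raw.aspirator_active, raw.bipolar_active):
            s = 0.0
            for k in range(a, b):
                s += 1.0 if arr[k] else 0.0
            row.append(s / per)
        # tumor delta
        row.append(float(raw.tumor_removed[b - 1]) - float(raw.tumor_removed[a]))
        # blood mean level
        s = 0.0
        for k in range(a, b):
            s += float(raw.blood_present[k])
        row.append(s / per)
        # bleeding rate: positive inflow per second
        s = 0.0
        for k in range(max(a, 1), b):
            d = float(raw.blood_present[k]) - float(raw.blood_present[k - 1])
            if d > 0:
                s += d
        row.append(s / 0.2)
        # damage delta
        row.append(float(raw.healthy_damage[b - 1]) - float(raw.healthy_damage[a]))
        rows.append(row)
    return np.array(rows)


def loop_rmse(predictions, targets) -> float:
    s = 0.0
    n = 0
    for p, t in zip(list(predictions), list(targets)):
        s += (float(p) - float(t)) ** 2
        n += 1
    return math.sqrt(s / n)


def anova_f_oracle(groups: dict[str, list[float]]):
    """Textbook one-way ANOVA from sums of squares."""
    all_vals = [v for vals in groups.values() for v in vals]
    grand = sum(all_vals) / len(all_vals)
    ss_between = 0.0
    ss_within = 0.0
    for vals in groups.values():
        m = sum(vals) / len(vals)
        ss_between += len(vals) * (m - grand) ** 2
        for v in vals:
            ss_within += (v - m) ** 2
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    return ms_b / ms_w, df_b, df_w


def ols_oracle(x, y):
    """Closed-form simple OLS: slope, intercept, R^2, adjusted R^2, slope SE."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((yi - intercept - slope * xi) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - my) ** 2 for yi in y)
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    se = math.sqrt(ss_res / (n - 2) / sxx)
    return slope, intercept, r2, adj, se
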