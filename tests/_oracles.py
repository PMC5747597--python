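"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: plain loops, explicit
sums of squares and literal requirement tables.
"""

import math


def brute_selected_differences(values):
    """Three selected differences from a seven-value list, by enumeration."""
    v = list(values)
    d21, d23 = abs(v[1] - v[0]), abs(v[1] - v[2])
    d43, d45 = abs(v[3] - v[2]), abs(v[3] - v[4])
    d65, d67 = abs(v[5] - v[4]), abs(v[5] - v[6])
    return [min(d21, d23), min(d43, d45), min(d65, d67)]


def brute_requirements(n_subjects):
    k = int(math.floor(n_subjects / 33 + 0.5))
    return {
        "two_of": [73 * k, 87 * k, 96 * k],
        "all_of": [65 * k, 81 * k, 93 * k],
        "min_good": 24 * k,
        "max_bad": 3 * k,
    }


def brute_phase_verdicts(series_by_pid, bands, n_subjects):
    """(phase1_pass, phase2_pass) recomputed from raw seven-value series.

    series_by_pid: {pid: [7 values]} for one session x variable.
    bands: (b1, b2, b3) inclusive thresholds.
    """
    b1, b2, b3 = bands
    req = brute_requirements(n_subjects)
    all_diffs = []
    good = 0
    bad = 0
    for pid in series_by_pid:
        diffs = brute_selected_differences(series_by_pid[pid])
        all_diffs.extend(diffs)
        within = len([d for d in diffs if d <= b1])
        if within >= 2:
            good += 1
        if within == 0:
            bad += 1
    c1 = len([d for d in all_diffs if d <= b1])
    c2 = len([d for d in all_diffs if d <= b2])
    c3 = len([d for d in all_diffs if d <= b3])
    two_of_hits = 0
    if c1 >= req["two_of"][0]:
        two_of_hits += 1
    if c2 >= req["two_of"][1]:
        two_of_hits += 1
    if c3 >= req["two_of"][2]:
        two_of_hits += 1
    all_of = c1 >= req["all_of"][0] and c2 >= req["all_of"][1] and c3 >= req["all_of"][2]
    phase1 = two_of_hits >= 2 and all_of
    phase2 = good >= req["min_good"] and bad <= req["max_bad"]
    return phase1, phase2


def brute_icc_anova(matrix):
    """ICC(2,1) and ICC(3,1) from explicit sums of squares, loop-only."""
    n = len(matrix)
    k = len(matrix[0])
    grand = sum(sum(row) for row in matrix) / (n * k)
    row_means = [sum(row) / k for row in matrix]
    col_means = [sum(matrix[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((matrix[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc3 = (msr - mse) / (msr + (k - 1) * mse)
    return icc2, icc3


def brute_pearson(xs, ys):
    """Product-moment correlation via the raw summation formula."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxy = sum(x * y for x, y in zip(xs, ys))
    sxx = sum(x * x for x in xs)
    syy = sum(y * y for y in ys)
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den
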