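"""Independent brute-force oracles used by the tests.

Everything here is written as explicit Python loops over samples or matrix
entries, deliberately sharing no code with the library's vectorized
implementations.
"""

from __future__ import annotations

import math


def naive_zero_crossings(x, T):
    count = 0
    for k in range(len(x) - 1):
        a, b = x[k], x[k + 1]
        crosses = (a < 0 and b > 0) or (a > 0 and b < 0)
        if crosses and abs(a - b) >= T:
            count += 1
    return count


def naive_slope_sign_changes(x, T):
    count = 0
    for k in range(1, len(x) - 1):
        peak = x[k] > x[k - 1] and x[k] > x[k + 1]
        valley = x[k] < x[k - 1] and x[k] < x[k + 1]
        if (peak or valley) and (abs(x[k] - x[k + 1]) >= T or abs(x[k] - x[k - 1]) >= T):
            count += 1
    return count


def naive_rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def naive_mav(x):
    return sum(abs(v) for v in x) / len(x)


def naive_mavs(x):
    half = len(x) // 2
    first, second = x[:half], x[half:]
    return naive_mav(second) - naive_mav(first)


def naive_waveform_length(x):
    return sum(abs(x[k + 1] - x[k]) for k in range(len(x) - 1))


def naive_confusion_metrics(cm):
    """Per-class loop evaluation of overall/macro metrics (percent scale).

    Classes with an empty truth row are excluded from the macro averages;
    classes never predicted get precision 0. Macro F1 is the harmonic mean
    of the two macro values.
    """
    K = len(cm)
    total = sum(sum(row) for row in cm)
    overall = 100.0 * sum(cm[i][i] for i in range(K)) / total
    recalls, precisions = [], []
    for i in range(K):
        row_sum = sum(cm[i])
        if row_sum == 0:
            continue
        recalls.append(cm[i][i] / row_sum)
        col_sum = sum(cm[r][i] for r in range(K))
        precisions.append(cm[i][i] / col_sum if col_sum > 0 else 0.0)
    macro_recall = 100.0 * sum(recalls) / len(recalls)
    macro_precision = 100.0 * sum(precisions) / len(precisions)
    denom = macro_precision + macro_recall
    macro_f1 = 2 * macro_precision * macro_recall / denom if denom else 0.0
    return overall, macro_recall, macro_precision, macro_f1


def naive_window_starts(n_samples, window_len, stride):
    """Enumerate valid window start offsets one by one."""
    starts = []
    s = 0
    while s + window_len <= n_samples:
        starts.append(s)
        s += stride
    return starts
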