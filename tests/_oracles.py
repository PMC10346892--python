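"""Independent brute-force reference implementations used only by tests.

Deliberately written with naive Python loops, no numpy vectorization, so they
share no code path with the package implementations they check.
"""

import math


def brute_features(values):
    """The nine window features computed with plain loops.

    Order: mean, median, std (population), min, max, initial, final, MAV, WL.
    """
    values = [float(v) for v in values]
    W = len(values)
    assert W >= 2
    mean = sum(values) / W
    xs = sorted(values)
    if W % 2:
        median = xs[W // 2]
    else:
        median = 0.5 * (xs[W // 2 - 1] + xs[W // 2])
    var = sum((x - mean) ** 2 for x in values) / W
    mav = sum(abs(x - mean) for x in values) / W
    wl = sum(abs(values[i + 1] - values[i]) for i in range(W - 1))
    return [
        mean,
        median,
        math.sqrt(var),
        min(values),
        max(values),
        values[0],
        values[-1],
        mav,
        wl,
    ]


def brute_f1(cm):
    """Per-class F1 as the harmonic mean of precision and recall, plain loops."""
    K = len(cm)
    out = []
    for k in range(K):
        tp = cm[k][k]
        fp = sum(cm[i][k] for i in range(K)) - tp
        fn = sum(cm[k][j] for j in range(K)) - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        out.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return out


def brute_window_starts(length, window, shift):
    """All valid stride-`shift` window start positions, by enumeration."""
    return sorted(p for p in range(0, length + 1, shift) if p + window <= length)
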