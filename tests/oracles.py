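"""Independent naive-loop oracles used to verify the vectorised code paths.

Everything here is deliberately written as plain Python loops over formula
definitions, sharing no code with the package.
"""

import math


def naive_abs_energy(x):
    return sum(v * v for v in x)


def naive_mean(x):
    return sum(x) / len(x)


def naive_sample_sd(x):
    n = len(x)
    mu = naive_mean(x)
    return math.sqrt(sum((v - mu) ** 2 for v in x) / (n - 1))


def naive_autocorrelation(x, lag):
    n = len(x)
    mu = naive_mean(x)
    sigma2 = sum((v - mu) ** 2 for v in x) / n  # population variance
    if sigma2 == 0:
        return 0.0
    s = sum((x[i] - mu) * (x[i + lag] - mu) for i in range(n - lag))
    return s / ((n - lag) * sigma2)


def naive_c3(x, lag):
    n = len(x)
    terms = [x[i + 2 * lag] * x[i + lag] * x[i] for i in range(n - 2 * lag)]
    return sum(terms) / len(terms)


def naive_slope(x):
    n = len(x)
    tbar = (n - 1) / 2
    xbar = naive_mean(x)
    num = sum((t - tbar) * (x[t] - xbar) for t in range(n))
    den = sum((t - tbar) ** 2 for t in range(n))
    return num / den


def naive_quantile(x, q):
    """Linear interpolation between order statistics (type-7)."""
    s = sorted(x)
    pos = q * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    return s[lo] + (pos - lo) * (s[hi] - s[lo])


def naive_feature_vector(hr, rr, spo2, all_autocorr):
    """The 21 features in registry order, from the naive primitives."""
    return [
        naive_mean(hr), naive_sample_sd(hr), sum(hr), naive_slope(hr),
        naive_abs_energy(hr), naive_c3(hr, 2), naive_c3(hr, 3),
        naive_quantile(hr, 0.1), naive_quantile(hr, 0.3), naive_quantile(hr, 0.7),
        naive_mean(rr), naive_sample_sd(rr), naive_slope(rr),
        naive_abs_energy(rr), naive_c3(rr, 3),
        naive_mean(spo2), naive_sample_sd(spo2), naive_slope(spo2),
        naive_c3(spo2, 3), naive_abs_energy(spo2),
        all_autocorr,
    ]


def brute_force_onset(hr, criteria):
    """Earliest qualifying window start over every (start, criterion) pair.

    Checks each start minute against each criterion by scanning whether the
    next min_duration minutes all exceed the threshold, then extends to find
    whether the covering maximal run already started earlier (in which case
    this start is not the run's first minute).
    """
    best = None  # (start, threshold, run_length)
    n = len(hr)
    for thr, dur in criteria:
        for start in range(n - dur + 1):
            if hr[start] <= thr:
                continue
            if start > 0 and hr[start - 1] > thr:
                continue  # not the first minute of its maximal run
            end = start
            while end < n and hr[end] > thr:
                end += 1
            if end - start >= dur:
                cand = (start, thr, end - start)
                if best is None or start < best[0] or (start == best[0] and thr > best[1]):
                    best = cand
    return best


def auroc_pair_count(scores, labels):
    """Concordant-pair probability with ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
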