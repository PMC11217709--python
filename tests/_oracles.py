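"""Independent brute-force oracles used by the test suite.

Each oracle applies the literal rule definitions by direct minute scans on
plain Python lists, with no shared code with the implementation under test.
"""

from __future__ import annotations

import numpy as np

AWAKE, ASLEEP, MISSING = 0, 1, 2


def _sleep_periods(s):
    """Maximal runs of consecutive sleep minutes as (start, end_exclusive)."""
    periods = []
    i, n = 0, len(s)
    while i < n:
        if s[i] == ASLEEP:
            j = i
            while j < n and s[j] == ASLEEP:
                j += 1
            periods.append((i, j))
            i = j
        else:
            i += 1
    return periods


def _rule_initial(s, min_wake, k):
    """First k minutes of a sleep period become wake if the preceding
    min_wake minutes were all wake."""
    out = list(s)
    for a, b in _sleep_periods(s):
        if a >= min_wake and all(s[t] == AWAKE for t in range(a - min_wake, a)):
            for t in range(a, min(a + k, b)):
                out[t] = AWAKE
    return out


def _rule_bout(s, sleep_lt, flank_gt):
    """A sleep period shorter than sleep_lt flanked by more than flank_gt
    contiguous wake minutes on both sides becomes wake."""
    out = list(s)
    n = len(s)
    for a, b in _sleep_periods(s):
        if b - a >= sleep_lt:
            continue
        pre = 0
        i = a - 1
        while i >= 0 and s[i] == AWAKE:
            pre += 1
            i -= 1
        post = 0
        j = b
        while j < n and s[j] == AWAKE:
            post += 1
            j += 1
        if pre > flank_gt and post > flank_gt:
            for t in range(a, b):
                out[t] = AWAKE
    return out


def rescore_oracle(seq, rule1_direction="as_printed"):
    s = list(seq)
    if rule1_direction == "webster":
        s = _rule_initial(s, 4, 1)
    s = _rule_initial(s, 10, 3)
    s = _rule_bout(s, 6, 15)
    s = _rule_bout(s, 10, 20)
    return s


def onset_offset_oracle(seq):
    onset = offset = None
    for a, b in _sleep_periods(seq):
        if b - a >= 10:
            if onset is None:
                onset = a
            offset = b - 1
    return None if onset is None else (onset, offset)


def metrics_oracle(seq, long_min=5):
    """(tib, tst, n_awakenings, n_long, n_missing) or None if no onset."""
    oo = onset_offset_oracle(seq)
    if oo is None:
        return None
    onset, offset = oo
    inside = list(seq[onset : offset + 1])
    tib = len(inside)
    tst = sum(1 for c in inside if c == ASLEEP)
    n_awak = n_long = 0
    i = 0
    while i < tib:
        if inside[i] == AWAKE:
            j = i
            while j < tib and inside[j] == AWAKE:
                j += 1
            if j - i >= 2:
                n_awak += 1
            if j - i >= long_min:
                n_long += 1
            i = j
        else:
            i += 1
    n_missing = sum(1 for c in inside if c == MISSING)
    return tib, tst, n_awak, n_long, n_missing


def sdnn_rmssd_oracle(intervals):
    """Two-pass population SD and RMSSD of an interval series."""
    iv = [float(v) for v in intervals]
    n = len(iv)
    mean = sum(iv) / n
    sdnn = (sum((v - mean) ** 2 for v in iv) / n) ** 0.5
    diffs = [iv[k + 1] - iv[k] for k in range(n - 1)]
    rmssd = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
    return sdnn, rmssd


def signed_rank_p_oracle(diffs):
    """Exact two-sided signed-rank p-value by full sign enumeration.

    ``diffs`` must be nonzero and produce no tied ranks.
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    assert len(set(np.abs(d))) == len(d), "oracle requires untied magnitudes"
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for mask in range(2**n):
        w = sum(ranks[k] for k in range(n) if (mask >> k) & 1)
        ws.append(w)
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def fisher_p_oracle(table):
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(0, min(r1, c1) + 1) if pmf(x) <= p_obs * (1 + 1e-12))
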