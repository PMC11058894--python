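"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (explicit loops, closed
forms) and must stay independent of the code paths it validates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special


def ols_oracle(x, y):
    """Normal-equations least squares and squared Pearson r."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    design = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    r_num = np.sum((x - x.mean()) * (y - y.mean()))
    r_den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    return float(beta[0]), float(beta[1]), float((r_num / r_den) ** 2)


def bland_altman_oracle(d1, d2):
    """Two-pass mean/SD Bland-Altman with per-pair percentage differences."""
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    diff = [a - b for a, b in zip(d1, d2)]
    n = len(diff)
    mean = sum(diff) / n
    sd = math.sqrt(sum((d - mean) ** 2 for d in diff) / (n - 1))
    pct = [100.0 * (a - b) / ((a + b) / 2.0) for a, b in zip(d1, d2)]
    return mean, mean - 2 * sd, mean + 2 * sd, sum(pct) / n


def paired_t_oracle(d1, d2):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), p from the t CDF."""
    diff = np.asarray(d1, float) - np.asarray(d2, float)
    n = len(diff)
    mean = diff.mean()
    sd = math.sqrt(np.sum((diff - mean) ** 2) / (n - 1))
    t = mean / (sd / math.sqrt(n))
    p = 2 * special.stdtr(n - 1, -abs(t))
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def local_maxima_oracle(v) -> list[int]:
    """Samples strictly greater than both neighbours; plateaus collapse to
    their first sample; endpoints excluded."""
    v = list(v)
    n = len(v)
    out = []
    for i in range(1, n - 1):
        if v[i] <= v[i - 1]:
            continue
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j < n - 1 and v[j + 1] < v[i]:
            out.append(i)
    return out


def prominence_oracle(v, i) -> float:
    """Peak height minus the higher of the two valley minima, where each
    valley runs to the nearest strictly higher sample or the window edge."""
    h = v[i]
    lmin = h
    j = i - 1
    while j >= 0 and v[j] <= h:
        lmin = min(lmin, v[j])
        j -= 1
    rmin = h
    j = i + 1
    while j < len(v) and v[j] <= h:
        rmin = min(rmin, v[j])
        j += 1
    return h - max(lmin, rmin)


def detect_ea_oracle(times, values, window, prominence_frac=0.10):
    """Brute-force E/A selection over all qualifying local-maxima pairs.

    Returns (e_time, e_value, a_time, a_value) or None when fused.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    sel = [k for k in range(len(times)) if window[0] <= times[k] <= window[1]]
    w_t = [times[k] for k in sel]
    w_v = [values[k] for k in sel]
    if not w_v or max(w_v) <= min(w_v):
        return None
    floor = prominence_frac * max(w_v)
    cands = [
        (i, prominence_oracle(w_v, i))
        for i in local_maxima_oracle(w_v)
        if prominence_oracle(w_v, i) >= floor
    ]
    if len(cands) < 2:
        return None
    # enumerate all pairs; the best pair is the one whose larger member wins
    # on (value, prominence, earlier time) and then whose other member wins
    best = None
    for a in range(len(cands)):
        for b in range(a + 1, len(cands)):
            pair = sorted(
                (cands[a], cands[b]),
                key=lambda ip: (-w_v[ip[0]], -ip[1], w_t[ip[0]]),
            )
            key = tuple(
                (-w_v[ip[0]], -ip[1], w_t[ip[0]]) for ip in pair
            )
            if best is None or key < best[0]:
                best = (key, pair)
    pair = sorted(best[1], key=lambda ip: w_t[ip[0]])
    (ie, _), (ia, _) = pair
    return (w_t[ie], w_v[ie], w_t[ia], w_v[ia])


def auto_window_oracle(times, values, cycle_length, start_frac=0.35):
    times = np.asarray(times, float)
    for k in range(len(times)):
        if times[k] > start_frac * cycle_length and values[k] > 0:
            return (float(times[k]), float(times[-1]))
    return None
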