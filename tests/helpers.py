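"""Independent oracles used by the test suite.

Deliberately naive re-implementations (enumeration, brute-force loops,
textbook formulas) kept separate from the package's own code paths.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def ranksum_p_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Pools x and y, ranks them, and enumerates every C(n1+n2, n1) choice
    of which pooled values form the first group; the two-sided p is
    2 * min(P(W <= w), P(W >= w)) capped at 1, where W is the rank sum
    of the first group.  Assumes no ties (continuous data).
    """
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1  # no ties expected
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = [sum(c) for c in combinations(ranks, n1)]
    total = len(ws)
    p_le = sum(w <= w_obs for w in ws) / total
    p_ge = sum(w >= w_obs for w in ws) / total
    return min(1.0, 2 * min(p_le, p_ge))


def binomial_tail_threshold_enumeration(n, alpha):
    """Smallest accuracy (%) with exact tail <= alpha, via Fraction sums
    over all n + 1 outcomes of a fair coin."""
    denom = Fraction(1, 2 ** n)
    for k in range(n + 1):
        tail = sum(comb(n, j) for j in range(k, n + 1)) * denom
        if tail <= Fraction(alpha).limit_denominator(10 ** 9):
            return 100.0 * k / n
    raise AssertionError("no threshold found")


def brute_force_bins(signal, rate, onsets_s, epoch_start_ms, bin_width_ms, n_bins):
    """Per-trial, per-channel bin means over half-open sample ranges,
    computed with explicit Python loops."""
    spb = int(round(bin_width_ms / 1000.0 * rate))
    out = np.empty((len(onsets_s), signal.shape[0], n_bins))
    for t, onset in enumerate(onsets_s):
        start = int(round(onset * rate)) + int(round(epoch_start_ms / 1000.0 * rate))
        for c in range(signal.shape[0]):
            for b in range(n_bins):
                i0 = start + b * spb
                out[t, c, b] = signal[c, i0: i0 + spb].mean()
    return out


def pearson_formula(x, y):
    """r from the covariance ratio; p from the t-transform, n-2 df."""
    import scipy.stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * scipy.stats.t.sf(abs(t), n - 2)
    return r, p


def welch_formula(a, b):
    """Welch t statistic and two-sided p with Satterthwaite df."""
    import scipy.stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return t, p


def write_minimal_edf(path, signal_uv, rate, channel_names):
    """Write a minimal EDF file (one data record per second, int16).

    Only what an EDF reader needs: fixed-width ASCII headers and
    little-endian 16-bit samples scaled to the physical range.
    """
    signal_uv = np.asarray(signal_uv, float)
    ns, n_samp = signal_uv.shape
    rate = int(rate)
    assert n_samp % rate == 0, "whole seconds only"
    n_rec = n_samp // rate
    phys_max = max(1.0, np.abs(signal_uv).max())
    dig_max, dig_min = 32767, -32768

    def pad(s, width):
        return str(s)[:width].ljust(width)

    header = (
        pad(0, 8) + pad("synthetic", 80) + pad("synthetic", 80)
        + pad("01.01.20", 8) + pad("00.00.00", 8)
        + pad(256 + 256 * ns, 8) + pad("", 44) + pad(n_rec, 8) + pad(1, 8) + pad(ns, 4)
    )
    header += "".join(pad(name, 16) for name in channel_names)
    header += "".join(pad("", 80) for _ in range(ns))          # transducer
    header += "".join(pad("uV", 8) for _ in range(ns))         # physical dim
    header += "".join(pad(-phys_max, 8) for _ in range(ns))    # physical min
    header += "".join(pad(phys_max, 8) for _ in range(ns))     # physical max
    header += "".join(pad(dig_min, 8) for _ in range(ns))
    header += "".join(pad(dig_max, 8) for _ in range(ns))
    header += "".join(pad("", 80) for _ in range(ns))          # prefiltering
    header += "".join(pad(rate, 8) for _ in range(ns))         # samples/record
    header += "".join(pad("", 32) for _ in range(ns))          # reserved

    scale = dig_max / phys_max
    with open(path, "wb") as f:
        f.write(header.encode("ascii"))
        for r in range(n_rec):
            chunk = signal_uv[:, r * rate:(r + 1) * rate]
            digital = np.clip(np.round(chunk * scale), dig_min, dig_max).astype("<i2")
            f.write(digital.tobytes())
    return phys_max / dig_max  # quantization step in uV
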