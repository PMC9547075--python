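"""Independent oracle implementations used to cross-check the estimators.

These are deliberately written with different primitives from the
package code (direct O(N^2) sums, argrelextrema-based peak location)
so that agreement is evidence, not tautology.
"""

import numpy as np
from scipy.signal import argrelextrema


def brute_force_acg(x):
    """O(N^2) time-domain biased autocorrelation, normalised at lag 0."""
    n = x.size
    r = np.array([np.sum(x[: n - k] * x[k:]) for k in range(n)])
    return r / r[0]


def clean_room_peak_range(data_acg, ref_acg, freq, fs):
    """Second, structurally different peak-range implementation."""
    minima = argrelextrema(ref_acg, np.less)[0]
    maxima = argrelextrema(ref_acg, np.greater)[0]
    if minima.size == 0 or maxima.size == 0:
        return np.nan
    t1 = minima[0]
    peaks = maxima[maxima > t1]
    if peaks.size == 0:
        return np.nan
    p = peaks[0]
    troughs = minima[minima > p]
    if troughs.size == 0:
        return np.nan
    t2 = troughs[0]
    q = int(round(fs / (4 * freq)))
    if t2 + q >= len(data_acg):
        return np.nan

    def rng_of(vals):
        pk = vals[max(0, p - q): p + q + 1].max()
        tr = 0.5 * (vals[max(0, t1 - q): t1 + q + 1].min()
                    + vals[max(0, t2 - q): t2 + q + 1].min())
        return pk - tr

    return rng_of(data_acg) / rng_of(ref_acg)
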