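"""Independent brute-force oracles used by the test suite.

These are deliberately naive (explicit loops) and share only the parameter
definitions with the package, never its vectorized implementations.
"""

import numpy as np


def brute_force_motion_mask(x, fs_hz, dp):
    """All-windows scan matching the documented detection semantics.

    Every sample-aligned window of length t_motion is examined with an
    explicit loop; a window whose max-min excursion exceeds
    min(std_thresh * sd(diff(x)), amp_thresh) marks [start - t_mask,
    start + t_motion + t_mask) in the mask.
    """
    x = np.asarray(x, float)
    n = x.size
    w = int(round(dp.t_motion_s * fs_hz))
    m = int(round(dp.t_mask_s * fs_hz))
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    mu = sum(diffs) / len(diffs)
    sigma = (sum((d - mu) ** 2 for d in diffs) / len(diffs)) ** 0.5
    thresh = min(dp.std_thresh * sigma, dp.amp_thresh)
    mask = np.zeros(n, dtype=bool)
    for s in range(n - w + 1):
        lo = hi = x[s]
        for j in range(s + 1, s + w):
            v = x[j]
            if v < lo:
                lo = v
            if v > hi:
                hi = v
        if hi - lo > thresh:
            mask[max(0, s - m):min(n, s + w + m)] = True
    return mask
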