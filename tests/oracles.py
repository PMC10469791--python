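"""Independent oracles shared across test modules.

These deliberately avoid the package's vectorised code paths: attention is
an explicit per-row softmax loop, band power goes through Welch's method.
"""

import numpy as np
from scipy import signal


def brute_force_attention(Q, K, V, allowed=None):
    """Row-by-row scaled dot-product attention, no vectorisation."""
    n, m = Q.shape[0], K.shape[0]
    out = np.zeros((n, V.shape[1]))
    for i in range(n):
        logits = np.array([float(Q[i] @ K[j]) / np.sqrt(Q.shape[1])
                           for j in range(m)])
        if allowed is not None:
            logits[~allowed[i]] = -np.inf
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        out[i] = sum(w[j] * V[j] for j in range(m))
    return out


def welch_band_power(x, fs, lo, hi):
    f, p = signal.welch(x, fs=fs, nperseg=min(256, x.shape[-1]), axis=-1)
    sel = (f >= lo) & (f <= hi)
    return p[..., sel].mean(axis=-1)
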