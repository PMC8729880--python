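"""Independent Benjamini-Yekutieli step-up oracle used by the test suite."""

import numpy as np


def brute_force_by(p):
    p = np.asarray(p, dtype=float)
    m = p.size
    c = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = ranked * m * c / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
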