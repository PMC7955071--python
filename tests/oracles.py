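"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np


def sampen_reference(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Direct per-template transcription of sample entropy.

    For every template index i (i = 1..N-m), count the other templates j
    within Chebyshev distance r at length m (B) and at length m+1 (A);
    self-matches excluded.  Returns -ln(A/B).  Deliberately follows the
    definition template-by-template, independent of the package's
    pair-counting kernel.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    r = r_factor * x.std()
    n_templates = n - m
    # rows are the length-(m+1) windows; first m entries form the m-template
    windows = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    b_total = 0
    a_total = 0
    for i in range(n_templates):
        d_m = np.max(np.abs(windows[:, :m] - windows[i, :m]), axis=1)
        match_m = d_m <= r
        match_m[i] = False
        b_total += int(match_m.sum())
        match_m1 = match_m & (np.abs(windows[:, m] - windows[i, m]) <= r)
        a_total += int(match_m1.sum())
    if b_total == 0 or a_total == 0:
        return float("inf")
    return float(-np.log(a_total / b_total))


def kappa_reference(counts: np.ndarray) -> float:
    """Cohen's kappa spelled out scalar-by-scalar from the marginals."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p_o = sum(counts[i, i] for i in range(counts.shape[0])) / n
    p_e = 0.0
    for c in range(counts.shape[0]):
        a_c = counts[c, :].sum()
        b_c = counts[:, c].sum()
        p_e += a_c * b_c
    p_e /= n * n
    return (p_o - p_e) / (1.0 - p_e)
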