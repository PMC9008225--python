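"""Independent reference implementations used to cross-check the package."""

import numpy as np


def burst_oracle(t, start_isi=0.020, end_isi=0.010, min_ibi=0.010,
                 min_dur=0.020, min_spikes=4):
    """Exhaustive scan over candidate burst windows, written independently
    of the package implementation: enumerate all right-maximal runs whose
    first interval satisfies the start rule and whose interior intervals
    satisfy the continuation rule, pick them greedily left to right, then
    merge and filter by the stated duration/count rules."""
    t = np.asarray(t, float)
    if t.size < 2:
        return []
    isi = np.diff(t)
    candidates = []
    for i in range(isi.size):
        if isi[i] > start_isi:
            continue
        j = i
        while j + 1 < isi.size and isi[j + 1] <= end_isi:
            j += 1
        candidates.append((i, j + 1))
    chosen = []
    for i, j in candidates:
        if not chosen or i > chosen[-1][1]:
            chosen.append((i, j))
    merged = []
    for i, j in chosen:
        if merged and t[i] - t[merged[-1][1]] < min_ibi:
            merged[-1] = (merged[-1][0], j)
        else:
            merged.append((i, j))
    return [
        (t[i], t[j], j - i + 1)
        for i, j in merged
        if t[j] - t[i] >= min_dur and j - i + 1 >= min_spikes
    ]


def random_spike_train(rng, n_max=200, span_s=2.0):
    """Random trains mixing sparse background with dense clusters so all
    burst rules are exercised."""
    n = int(rng.integers(0, n_max))
    clusters = np.repeat(rng.uniform(0, span_s, max(n // 20, 1)), 5)
    clusters = clusters + rng.uniform(0, 0.03, clusters.size)
    return np.sort(np.concatenate([rng.uniform(0, span_s, n // 2), clusters]))
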