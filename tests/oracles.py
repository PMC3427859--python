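"""Independent oracles used by the test suite.

These are deliberately naive implementations — exhaustive scans and
explicit dynamic programming — kept separate from the package so the code
paths they check share nothing with them.
"""

from __future__ import annotations

import numpy as np


def brute_force_runs(values: np.ndarray, height: float, min_width: int
                     ) -> list[tuple[int, int]]:
    """All maximal runs of consecutive values >= height with length >=
    min_width, found by an explicit O(n^2) scan. Returns (first, last)
    index pairs."""
    n = len(values)
    runs = []
    i = 0
    while i < n:
        if values[i] >= height:
            j = i
            while j + 1 < n and values[j + 1] >= height:
                j += 1
            if j - i + 1 >= min_width:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def expected_run_count_dp(n: int, p: float, w: int) -> float:
    """Exact expected number of maximal success-runs of length >= w in n
    i.i.d. Bernoulli(p) trials, by dynamic programming.

    State: probability mass over the current run length (capped at w, an
    absorbing 'already long enough' bucket per run); the expectation
    accumulates the probability that a run first reaches length w.
    """
    # dist[k] = P(current run has length k), k in 0..w-1; reaching w adds
    # one expected run and collapses to the capped state.
    dist = np.zeros(w + 1)
    dist[0] = 1.0
    expected = 0.0
    for _ in range(n):
        new = np.zeros(w + 1)
        for k in range(w + 1):
            if dist[k] == 0.0:
                continue
            if k < w:
                new[k + 1 if k + 1 < w else w] += dist[k] * p
                if k + 1 == w:
                    expected += dist[k] * p
            else:
                new[w] += dist[k] * p  # run continues beyond w: same run
            new[0] += dist[k] * (1 - p)
        dist = new
    return expected


def brute_force_target_join(peaks, genes, fdr_threshold: float, window_bp: int
                            ) -> dict[str, int]:
    """All-pairs peak x gene distance scan. Returns {gene_id: min_distance}
    over genes with a passing peak within the window."""
    out: dict[str, int] = {}
    for g in genes:
        best = None
        for p in peaks:
            if p.arm_id != g.arm_id or not (p.fdr < fdr_threshold):
                continue
            if p.start_bp < g.tx_end and g.tx_start < p.end_bp:
                d = 0
            elif p.end_bp <= g.tx_start:
                d = g.tx_start - p.end_bp
            else:
                d = p.start_bp - g.tx_end
            if d <= window_bp and (best is None or d < best):
                best = d
        if best is not None:
            out[g.gene_id] = best
    return out
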