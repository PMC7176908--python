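"""Greedy maximal-run finding over ordered marker tracks.

Shared by segment calling (supports = donor-carrying calls, breakers = A
calls) and genome scanning (supports = concordant markers, breakers =
discordant markers).  Neutral positions (missing / non-evaluable) neither
support nor break a run.
"""

from __future__ import annotations

import numpy as np


def find_runs(support: np.ndarray, breaker: np.ndarray, max_interruptions: int = 0) -> list[tuple[int, int]]:
    """Maximal runs of supporting positions tolerating interior breakers.

    Returns ``(first, last)`` index pairs of supporting positions.  A run may
    absorb up to ``max_interruptions`` breaker positions strictly between two
    supports; a breaker beyond the budget closes the run at its last support.
    Breakers before the first or after the last support of a run never belong
    to it.  Positions that neither support nor break are ignored.
    """
    if support.shape != breaker.shape:
        raise ValueError("support/breaker shape mismatch")
    if np.any(support & breaker):
        raise ValueError("a position cannot both support and break a run")
    if max_interruptions < 0:
        raise ValueError("max_interruptions must be >= 0")
    runs: list[tuple[int, int]] = []
    start = last = -1
    used = 0
    pending = 0
    for i in np.flatnonzero(support | breaker):
        if support[i]:
            if start < 0:
                start, last, used, pending = i, i, 0, 0
            elif used + pending <= max_interruptions:
                used += pending
                pending = 0
                last = i
            else:
                runs.append((start, last))
                start, last, used, pending = i, i, 0, 0
        else:  # breaker
            if start >= 0:
                pending += 1
    if start >= 0:
        runs.append((start, last))
    return runs
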