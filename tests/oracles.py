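"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — O(visits^2) scans, exhaustive
enumeration of stochastic branches — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd


def brute_force_sharing_weights(contacts: pd.DataFrame,
                                window_days: int = 91) -> dict:
    """Distinct-patient co-visit counts by scanning all visit pairs."""
    dates = pd.to_datetime(contacts["date"])
    day = (dates - dates.min()).dt.days.to_numpy()
    phys = contacts["physician_id"].to_numpy()
    pat = contacts["patient_id"].to_numpy()
    sharing: dict[tuple, set] = {}
    n = len(contacts)
    for i in range(n):
        for j in range(n):
            if i == j or pat[i] != pat[j] or phys[i] == phys[j]:
                continue
            if abs(int(day[i]) - int(day[j])) <= window_days:
                key = tuple(sorted((phys[i], phys[j])))
                sharing.setdefault(key, set()).add(pat[i])
    return {k: len(v) for k, v in sharing.items()}


def brute_force_top_percent_median(values, c: float) -> float:
    """Median quarterly load of the top-c% busiest physicians, by plain
    sorting; set size ceil(c/100 * n) with a floor of one."""
    ordered = sorted(values, reverse=True)
    k = max(1, int(np.ceil(c / 100.0 * len(ordered))))
    top = ordered[:k]
    return float(np.median(top))


def expected_lost_after_removal(
    W: np.ndarray,
    C: np.ndarray,
    N: np.ndarray,
    removed: int,
    s: int,
    alpha: float = 0.0,
) -> float:
    """Exact expected lost-patient count after removing one physician.

    Enumerates every processing order of the searching patients and every
    candidate draw of the displacement process, weighting branches by their
    probabilities.  All physicians are assumed co-located, so the distance
    rule never triggers.  Patients are (recent_physician, rejections) pairs;
    a placement removes the patient from the process, the ``s``-th rejection
    loses them.
    """
    n = len(C)
    avail = tuple(i != removed for i in range(n))
    free = tuple(int(C[i] - N[i]) if avail[i] else 0 for i in range(n))
    searching = tuple(sorted((removed, 0) for _ in range(int(N[removed]))))
    avail_idx = tuple(i for i in range(n) if avail[i])

    def candidate_dist(recent: int) -> list[tuple[int, float]]:
        """(candidate, probability) pairs; candidate -1 = no candidate."""
        out: dict[int, float] = {}
        if alpha > 0.0:
            for j in avail_idx:
                out[j] = out.get(j, 0.0) + alpha / len(avail_idx)
        w = np.array([W[recent, j] if avail[j] else 0.0 for j in range(n)])
        tot = w.sum()
        if tot > 0:
            for j in range(n):
                if w[j] > 0:
                    out[j] = out.get(j, 0.0) + (1.0 - alpha) * w[j] / tot
        else:
            out[-1] = out.get(-1, 0.0) + (1.0 - alpha)
        return list(out.items())

    @lru_cache(maxsize=None)
    def round_value(free_t: tuple, searching_t: tuple, lost: int) -> float:
        if not searching_t:
            return float(lost)
        perms = list(itertools.permutations(range(len(searching_t))))
        return sum(
            process(tuple(searching_t[i] for i in order), 0, free_t, (), lost)
            for order in perms
        ) / len(perms)

    def process(order, i, free_t, carried, lost):
        if i == len(order):
            return round_value(free_t, tuple(sorted(carried)), lost)
        recent, rej = order[i]
        value = 0.0
        for cand, prob in candidate_dist(recent):
            if cand >= 0 and free_t[cand] > 0:
                nfree = list(free_t)
                nfree[cand] -= 1
                value += prob * process(order, i + 1, tuple(nfree), carried,
                                        lost)
            elif rej + 1 >= s:
                value += prob * process(order, i + 1, free_t, carried,
                                        lost + 1)
            else:
                value += prob * process(order, i + 1, free_t,
                                        carried + ((recent, rej + 1),), lost)
        return value

    return round_value(free, searching, 0)


def expected_lost_random_removal(W, C, N, s, alpha=0.0) -> float:
    """Expectation of :func:`expected_lost_after_removal` over a uniformly
    chosen removed physician."""
    n = len(C)
    return float(np.mean([
        expected_lost_after_removal(W, C, N, r, s, alpha) for r in range(n)
    ]))
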