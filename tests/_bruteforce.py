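"""Independent brute-force oracle for exact contingency-table tests.

Enumerates every distinct assignment of the column-label multiset to the row
slots (all equally likely under the null with fixed margins), tallies the
resulting tables, and computes the two-sided p-value as the fraction of
assignments whose table is no more probable than the observed one.  No
hypergeometric formula is used anywhere, so this is fully independent of the
implementation under test.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def _multiset_permutations(items: list[int]):
    counts = Counter(items)
    keys = sorted(counts)
    n = len(items)
    perm: list[int] = []

    def rec():
        if len(perm) == n:
            yield tuple(perm)
            return
        for k in keys:
            if counts[k] > 0:
                counts[k] -= 1
                perm.append(k)
                yield from rec()
                perm.pop()
                counts[k] += 1

    yield from rec()


def bruteforce_exact_p(table, tie_rtol: float = 1e-7) -> float:
    """Two-sided point-probability exact p by exhaustive label enumeration."""
    obs = np.asarray(table, dtype=int)
    row_m = obs.sum(axis=1)
    col_m = obs.sum(axis=0)
    labels = [j for j, c in enumerate(col_m) for _ in range(c)]
    tally: Counter = Counter()
    total = 0
    for arrangement in _multiset_permutations(labels):
        t = []
        pos = 0
        for rm in row_m:
            row = [0] * len(col_m)
            for lab in arrangement[pos:pos + rm]:
                row[lab] += 1
            t.append(tuple(row))
            pos += rm
        tally[tuple(t)] += 1
        total += 1
    obs_key = tuple(tuple(int(x) for x in row) for row in obs)
    obs_count = tally[obs_key]
    hits = sum(c for t, c in tally.items() if c <= obs_count * (1 + tie_rtol))
    return hits / total
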