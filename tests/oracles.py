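"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seed-and-extend code path: alignments
are found by exhaustively scanning every diagonal and every segment.
"""

from __future__ import annotations

import numpy as np

WORD = 7
PAD = 255  # sentinel byte that never matches a base


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def best_seeded_segment_per_strand(
    query: str, subject: str, reward: int = 1, penalty: int = -3,
    word: int = WORD,
) -> dict[str, int | None]:
    """Best raw score of an ungapped segment containing a full ``word``-run
    of matches, per strand, by brute force over all diagonals and segments.

    Returns {'+': score or None, '-': score or None}.
    """
    out: dict[str, int | None] = {}
    q = _codes(query)
    L = len(q)
    for strand in "+-":
        target = subject if strand == "+" else _revcomp(subject)
        t = _codes(target)
        padded = np.full(len(t) + 2 * L, PAD, dtype=np.uint8)
        padded[L:L + len(t)] = t
        # window starting at offset k aligns query position 0 with target
        # index k - L (diagonal d = k - L)
        windows = np.lib.stride_tricks.sliding_window_view(padded, L)
        M = (windows == q[None, :]).astype(int)
        if L >= word:
            runs = (np.lib.stride_tricks.sliding_window_view(M, word, axis=1)
                    .sum(axis=2) == word)
        else:
            runs = np.zeros((M.shape[0], 0), dtype=bool)
        best: int | None = None
        for row in np.flatnonzero(runs.any(axis=1)):
            m = M[row]
            scores = np.where(m == 1, reward, penalty)
            P = np.concatenate([[0], np.cumsum(scores)])
            C = np.concatenate([[0], np.cumsum(runs[row].astype(int))])
            for i in range(L):
                for j in range(i + word, L + 1):
                    # segment [i, j) must contain a run start in [i, j-word]
                    if C[j - word + 1] - C[i] <= 0:
                        continue
                    sc = int(P[j] - P[i])
                    if best is None or sc > best:
                        best = sc
        out[strand] = best
    return out


def exhaustive_two_sample_p(x, y) -> float:
    """Exact two-sided permutation p for the difference in means."""
    from itertools import combinations

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    nx, n = len(x), len(pooled)
    obs = abs(np.mean(pooled[:nx]) - np.mean(pooled[nx:]))
    total = count = 0
    idx = range(n)
    for comb in combinations(idx, nx):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        stat = abs(pooled[sel].mean() - pooled[~sel].mean())
        count += stat >= obs - 1e-12
        total += 1
    return count / total


def exhaustive_signflip_p(diffs) -> float:
    """Exact two-sided sign-flip p for the mean paired difference."""
    d = np.asarray(diffs, float)
    n = len(d)
    obs = abs(d.mean())
    count = 0
    for k in range(2 ** n):
        signs = np.array([1.0 if (k >> i) & 1 else -1.0 for i in range(n)])
        count += abs((signs * d).mean()) >= obs - 1e-12
    return count / 2 ** n
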