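"""Independent brute-force oracles used by the tests.

Everything here is written as plainly as possible (pure-python loops,
direct enumeration) and never calls the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def enumerate_windows(L: int, k: int, step: int) -> list[int]:
    """1-based start positions of all fixed-stride windows."""
    return [s + 1 for s in range(0, L - k + 1, step)] if L >= k else []


def tile_count(L: int, k: int, step: int) -> int:
    """Window count by direct enumeration."""
    return len(enumerate_windows(L, k, step))


def shannon_bits(sequence: str) -> float:
    """Entropy via an independent formulation (log-sum over counts)."""
    n = len(sequence)
    counts = {}
    for ch in sequence:
        counts[ch] = counts.get(ch, 0) + 1
    return math.log2(n) - sum(c * math.log2(c) for c in counts.values()) / n


def spie_oracle(
    v: np.ndarray,
    protein_ids: list[str],
    starts: list[int],
    steps: list[int],
    quantiles: tuple[float, ...],
    min_run: int = 2,
) -> tuple[list[float], list[int]]:
    """Full S-PIE scan by direct enumeration of every window.

    Returns (R, N) per peptide after the last grid point, following the
    "latest value kept" rule.
    """
    n = len(v)
    R = [0.0] * n
    Nassigned = [0] * n
    adj = [
        protein_ids[i] == protein_ids[i + 1] and starts[i + 1] - starts[i] == steps[i]
        for i in range(n - 1)
    ]
    grid = np.quantile(np.asarray(v, dtype=float), quantiles)
    for i0 in grid:
        above = [x > i0 for x in v]
        p = sum(above) / n
        if p == 0:
            break
        runs = []
        i = 0
        while i < n:
            if above[i]:
                j = i
                while j + 1 < n and adj[j] and above[j + 1]:
                    j += 1
                runs.append((i, j - i + 1))
                i = j + 1
            else:
                i += 1
        runs = [(s, L) for s, L in runs if L >= min_run]
        for N in sorted({L for _, L in runs}):
            total = hit = 0
            for w in range(n - N + 1):
                if all(adj[w + t] for t in range(N - 1)):
                    total += 1
                    if all(above[w + t] for t in range(N)):
                        hit += 1
            joint = hit / total if total else 0.0
            r = joint / p**N
            for s, L in runs:
                if L == N:
                    for t in range(s, s + L):
                        R[t] = r
                        Nassigned[t] = N
    return R, Nassigned


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Topological overlap by the naive triple loop."""
    n = a.shape[0]
    tom = np.zeros((n, n))
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom
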