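"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's optimized code paths:
selection is re-done with per-window scans over order keys, energies by
enumerating permutations, link statistics with explicit context sets.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import polarsketch as ps


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ----------------------------------------------------------------------
# Oracles
# ----------------------------------------------------------------------

def brute_force_selection(seq: ps.Sequence, w: int, k: int, order: ps.KmerOrder):
    """Per-window scan using order.key; returns (positions, charged)."""
    positions = set()
    charged = 0
    for a, b in seq.fragments:
        nk = b - a - k + 1
        if nk < w:
            continue
        prev_sel = None
        for j in range(nk - w + 1):
            window = []
            for i in range(j, j + w):
                pos = a + i
                code = ps.pack_kmer(seq.text[pos : pos + k], seq.alphabet)
                window.append((pos, code))
            sel = ps.select_in_window(window, order)
            positions.add(sel)
            if prev_sel is not None and sel != prev_sel:
                charged += 1
            prev_sel = sel
    return sorted(positions), charged


def enumerate_charged_probability(kmers: list[str]) -> float:
    """Exact P(context charged) over all orders of the distinct k-mers.

    A context of w+1 k-mers is charged when its two windows (k-mers
    0..w-1 and 1..w) select different positions under the leftmost-minimum
    rule.
    """
    distinct = sorted(set(kmers))
    total = charged = 0
    for perm in itertools.permutations(range(len(distinct))):
        rank = {m: r for m, r in zip(distinct, perm)}
        first = min(range(len(kmers) - 1), key=lambda i: (rank[kmers[i]], i))
        second = min(range(1, len(kmers)), key=lambda i: (rank[kmers[i]], i))
        total += 1
        charged += first != second
    return charged / total


def brute_force_link_stats(positions, w: int):
    """Acov/Aele/Aseg/L via explicit context-slot sets and pair sums."""
    pos = sorted(int(p) for p in positions)
    slots = set()
    for t in pos:
        slots.update(range(t - w, t + 1))
    # segments: maximal runs of positions at gaps <= w
    aseg = 0
    lsum = 0.0
    prev = None
    for t in pos:
        if prev is None or t - prev > w:
            aseg += 1
        else:
            lsum += 2 * (t - prev) / (w + 1) - 1
        prev = t
    return len(slots), len(pos), aseg, lsum


def brute_force_occurrences(text: str, t: int, k: int) -> list[int]:
    kmer = text[t : t + k]
    return [i for i in range(len(text) - k + 1) if text[i : i + k] == kmer]
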