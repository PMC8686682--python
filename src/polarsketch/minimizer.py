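"""Minimizer selection, charged contexts and density.

A minimizer (w, k, O) outputs, for every window of w consecutive k-mers,
the position of the smallest k-mer under the order O, preferring the
leftmost on ties.  Applied to a sequence it yields a set of selected
positions; the *specific density* is the number of selected positions over
the number of k-mers, and the *density factor* is density times (w + 1).

A *context* is w + 1 consecutive k-mers (two overlapping windows); it is
*charged* when its two windows select different positions.  On a break-free
sequence the number of selected positions equals the number of charged
contexts plus one, an identity this module reports fragment by fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .order import KmerOrder
from .sequence import Sequence


@dataclass(frozen=True)
class SelectionResult:
    """Selected positions and context bookkeeping for one (seq, w, k, O)."""

    positions: np.ndarray  # sorted absolute k-mer start positions
    charged_contexts: int
    n_windows: int
    n_contexts: int
    n_kmers: int
    n_fragments: int
    w: int
    k: int

    @property
    def n_selected(self) -> int:
        return int(self.positions.size)

    @property
    def density(self) -> float:
        if self.n_selected == 0:
            raise ValueError("empty selection has no density")
        return self.n_selected / self.n_kmers

    @property
    def density_factor(self) -> float:
        return self.density * (self.w + 1)


def select_in_window(window: list[tuple[int, int]], order: KmerOrder) -> int:
    """Position of the smallest k-mer in one window, leftmost on ties.

    ``window`` is a list of ``(absolute_position, packed_code)`` pairs of
    exactly w k-mers (w inferred from the list).  This is the definitional,
    per-window primitive; :func:`select_positions` is the vectorized scan.
    """
    if not window:
        raise ValueError("window must contain at least one k-mer")
    best_pos, best_key = None, None
    for pos, code in window:
        key = order.key(code)
        if best_key is None or key < best_key:
            best_pos, best_key = pos, key
    return best_pos


def select_positions(seq: Sequence, w: int, k: int, order: KmerOrder) -> SelectionResult:
    """Apply the minimizer to every window of every fragment of ``seq``.

    Windows and contexts never span breaks; fragments shorter than one
    window contribute neither windows nor k-mers to the counts.  Raises
    :class:`~polarsketch.sequence.TooShortError` if no fragment admits a
    window.
    """
    if w < 2:
        raise ValueError("w must be >= 2")
    frags = seq.require_windows(w, k)
    codes, _ = seq.kmer_codes(k)
    rank = order.rank_of(codes) if codes.size else codes

    all_positions: list[np.ndarray] = []
    charged = n_windows = n_contexts = n_kmers = 0
    for a, b in frags:
        nk = b - a - k + 1
        n_kmers += nk
        r = rank[a : a + nk]
        wins = np.lib.stride_tricks.sliding_window_view(r, w)
        sel = wins.argmin(axis=1) + np.arange(wins.shape[0]) + a
        all_positions.append(np.unique(sel))
        n_windows += sel.size
        n_contexts += sel.size - 1
        charged += int(np.count_nonzero(sel[1:] != sel[:-1]))

    positions = np.concatenate(all_positions) if all_positions else np.empty(0, np.int64)
    positions.sort()
    return SelectionResult(
        positions=positions,
        charged_contexts=charged,
        n_windows=n_windows,
        n_contexts=n_contexts,
        n_kmers=n_kmers,
        n_fragments=len(frags),
        w=w,
        k=k,
    )


def density_factor(sel: SelectionResult) -> float:
    """Density times (w + 1): ~2 for a random order, ~1 for a perfect one."""
    return sel.density_factor


def selection_report(sel: SelectionResult) -> dict:
    """JSON-ready summary of a selection."""
    return {
        "w": sel.w,
        "k": sel.k,
        "n_kmers": sel.n_kmers,
        "n_windows": sel.n_windows,
        "n_contexts": sel.n_contexts,
        "n_selected": sel.n_selected,
        "n_charged": sel.charged_contexts,
        "n_fragments": sel.n_fragments,
        "density": sel.density,
        "density_factor": sel.density_factor,
    }
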