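"""Context energy and sequence energy aggregates.

The *energy* E(c) of a context c (w + 1 consecutive k-mers) is the
probability that c is charged under a uniformly random order: with u(c)
the number of distinct k-mers in c,

    E(c) = 2 / u(c)   if the last k-mer occurs exactly once in c,
           1 / u(c)   otherwise.

When all k-mers of a context are distinct E(c) = 2/(w+1), the baseline.
Summing per-context energies gives the initial energy E0(S); the expected
number of selected positions under a random minimizer is 1 + E0(S).
Contexts below baseline are *energy savers* (deficit D(S) aggregates the
gap), contexts above are *energy spenders* (surplus X(S)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence as TSequence

import numpy as np

from .minimizer import select_positions
from .order import KmerOrder
from .sequence import Sequence, TooShortError


@dataclass(frozen=True)
class EnergyProfile:
    """Aggregate energies of a sequence for one (w, k)."""

    E0: float  # total initial energy, sum of E(c)
    D: float   # total deficit, sum of max(0, 2/(w+1) - E(c))
    X: float   # total surplus, sum of max(0, E(c) - 2/(w+1))
    n_contexts: int
    w: int
    k: int

    @property
    def baseline(self) -> float:
        return 2.0 / (self.w + 1)

    @property
    def mean_energy(self) -> float:
        return self.E0 / self.n_contexts

    @property
    def mean_deficit(self) -> float:
        return self.D / self.n_contexts

    @property
    def mean_surplus(self) -> float:
        return self.X / self.n_contexts


def context_energy(kmers: TSequence[int] | TSequence[str], w: int | None = None) -> float:
    """Energy of a single context given its w+1 k-mers (codes or strings).

    Equals the probability the context is charged under a uniformly random
    order on its distinct k-mers (tested against exhaustive enumeration).
    """
    items = list(kmers)
    if w is not None and len(items) != w + 1:
        raise ValueError(f"context must have w+1 = {w + 1} k-mers, got {len(items)}")
    if not items:
        raise ValueError("empty context")
    u = len(set(items))
    last_unique = items.count(items[-1]) == 1
    return (2.0 if last_unique else 1.0) / u


def energy_profile(seq: Sequence, w: int, k: int) -> EnergyProfile:
    """Sliding-window computation of E0, D and X over all contexts of S.

    Uses the previous-occurrence trick: with prev[i] the last index before
    i carrying the same k-mer (-1 if none), the distinct count of context
    [j, j+w] is #{i in [j, j+w] : prev[i] < j}, and the last k-mer is
    unique in the context iff prev[j+w] < j.  O(n) memory passes.
    """
    frags = [f for f in seq.fragments if f[1] - f[0] >= w + k]
    if not frags:
        raise TooShortError(f"no fragment of length >= w+k = {w + k}")
    codes, _ = seq.kmer_codes(k)
    baseline = 2.0 / (w + 1)

    E0 = D = X = 0.0
    n_ctx_total = 0
    for a, b in frags:
        nk = b - a - k + 1
        c = codes[a : a + nk]
        prev = _previous_occurrence(c)
        n_ctx = nk - w
        wins = np.lib.stride_tricks.sliding_window_view(prev, w + 1)
        u = (wins < np.arange(n_ctx)[:, None]).sum(axis=1)
        last_unique = prev[w:] < np.arange(n_ctx)
        E = np.where(last_unique, 2.0, 1.0) / u
        E0 += float(E.sum())
        D += float(np.maximum(0.0, baseline - E).sum())
        X += float(np.maximum(0.0, E - baseline).sum())
        n_ctx_total += n_ctx
    return EnergyProfile(E0=E0, D=D, X=X, n_contexts=n_ctx_total, w=w, k=k)


def _previous_occurrence(codes: np.ndarray) -> np.ndarray:
    """prev[i] = largest j < i with codes[j] == codes[i], else -1."""
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    prev_sorted = np.full(codes.size, -1, np.int64)
    same = sorted_codes[1:] == sorted_codes[:-1]
    prev_sorted[1:][same] = order[:-1][same]
    prev = np.empty(codes.size, np.int64)
    prev[order] = prev_sorted
    return prev


def expected_selected_mc(
    seq: Sequence,
    w: int,
    k: int,
    layers: TSequence[Iterable[str]] | TSequence[frozenset[int]] = (),
    trials: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo mean selected-position count over random compatible orders.

    With no layers this estimates 1 + E0(S); with layers it estimates the
    expectation bounded by the link-energy sandwich.  Returns
    ``(mean, standard_error)``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    code_layers = _as_code_layers(layers, seq.alphabet)
    rng = np.random.default_rng(seed)
    counts = np.empty(trials)
    for t in range(trials):
        order = KmerOrder(code_layers, seed=int(rng.integers(0, 2**62)))
        counts[t] = select_positions(seq, w, k, order).n_selected
    se = float(counts.std(ddof=1) / np.sqrt(trials)) if trials > 1 else 0.0
    return float(counts.mean()), se


def _as_code_layers(layers, alphabet: str) -> tuple[frozenset[int], ...]:
    from .order import pack_kmer

    out = []
    for layer in layers:
        items = list(layer)
        if items and isinstance(items[0], str):
            out.append(frozenset(pack_kmer(m, alphabet) for m in items))
        else:
            out.append(frozenset(int(x) for x in items))
    return tuple(out)
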