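"""Layered polar-set construction heuristics.

One round fixes an offset o, visits the k-mer positions t = o (mod w) in a
seeded random order and greedily admits each k-mer into the current layer,
evicting members it conflicts with.  Candidate k-mers are filtered first:
too frequent, self-colliding, or too close to a previous layer.  The
*monotonic* variant accepts an insertion only when it strictly increases
the total link energy (tracked incrementally with linked blocks).  Rounds
are stacked into layers, each round skipping regions already covered by
earlier layers and raising the frequency cutoff; members that end a round
without any link are pruned.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np

from .index import LinkedBlocks, SuffixIndex
from .order import KmerOrder, unpack_kmer
from .polar import LayeredPolarSet, spacing_threshold
from .sequence import Sequence


@dataclass(frozen=True)
class HeuristicConfig:
    """Tunables of the layered builder (defaults follow the recommended recipe:
    7 rounds, the last 2 monotonic, slackness 0.4, frequency cutoff covering
    85% of positions in round 1 rising linearly to 95% in the last round)."""

    rounds: int = 7
    monotonic_tail: int = 2
    s: float = 0.4
    freq_percentile_start: float = 0.85
    freq_percentile_end: float = 0.95
    seed: int = 0
    offsets: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.s < 0.5:
            raise ValueError("slackness s must satisfy 0 <= s < 1/2")
        if not 0 < self.freq_percentile_start <= self.freq_percentile_end <= 1:
            raise ValueError("need 0 < start <= end <= 1 for frequency percentiles")
        if not 0 <= self.monotonic_tail <= self.rounds:
            raise ValueError("monotonic_tail must be in [0, rounds]")

    def percentiles(self) -> np.ndarray:
        if self.rounds == 1:
            return np.array([self.freq_percentile_start])
        return np.linspace(self.freq_percentile_start, self.freq_percentile_end, self.rounds)


def frequency_threshold(idx: SuffixIndex, percentile: float) -> int:
    """Smallest f so that positions whose k-mer occurs <= f times make up
    at least ``percentile`` of all valid k-mer positions."""
    if not 0 < percentile <= 1:
        raise ValueError("percentile must be in (0, 1]")
    counts = idx.kmer_counts()
    c = np.sort(counts[counts > 0])
    if c.size == 0:
        return 1
    i = math.ceil(percentile * c.size) - 1
    return int(c[max(i, 0)])


# ----------------------------------------------------------------------
# Builder state shared across rounds
# ----------------------------------------------------------------------

class _BuildState:
    def __init__(self, seq: Sequence, idx: SuffixIndex, w: int, k: int, s: float):
        self.seq = seq
        self.idx = idx
        self.w = w
        self.k = k
        self.thr = spacing_threshold(w, s)
        codes, valid = seq.kmer_codes(k)
        self.codes = codes
        self.starts = np.flatnonzero(valid)
        from .polar import fragment_ids

        self.frag_of = fragment_ids(seq)
        self.union = LinkedBlocks(len(seq), w)  # uncovered occurrences, all layers
        self.prev_all: list[int] = []           # all occurrences of earlier layers
        self.prev_member_codes: set[int] = set()
        self._cov_cache: dict[int, bool] = {}

    def new_round(self) -> None:
        self._cov_cache.clear()

    def covered(self, t: int) -> bool:
        """Flanked within w bases by two earlier-layer occurrences."""
        hit = self._cov_cache.get(t)
        if hit is not None:
            return hit
        pa = self.prev_all
        i = bisect_left(pa, t)
        ok = (
            0 < i < len(pa)
            and pa[i - 1] < t
            and pa[i] > t
            and pa[i] - pa[i - 1] <= self.w
            and self.frag_of[pa[i - 1]] == self.frag_of[t] == self.frag_of[pa[i]]
        )
        # t itself cannot occur in prev_all (its k-mer is not in an earlier layer)
        self._cov_cache[t] = ok
        return ok

    def near_previous_layers(self, x: int) -> bool:
        """Any earlier-layer occurrence strictly closer than the threshold."""
        pa = self.prev_all
        i = bisect_left(pa, x)
        if i < len(pa) and pa[i] - x < self.thr:
            return True
        if i > 0 and x - pa[i - 1] < self.thr:
            return True
        return False


@dataclass
class RoundLog:
    round: int
    offset: int
    percentile: float
    max_freq: int
    monotonic: bool
    layer_size: int
    n_candidates: int = 0
    n_admitted: int = 0
    n_evicted: int = 0
    n_pruned: int = 0
    link_energy: float = 0.0  # total L after the round (all layers)


def polar_round(
    state: _BuildState,
    offset: int,
    max_freq: int,
    rng: np.random.Generator,
    monotonic: bool,
    round_no: int = 1,
    percentile: float = 1.0,
) -> tuple[set[int], RoundLog]:
    """Run one construction round; returns the new layer's k-mer codes.

    The round honours the layered polar-set condition against all earlier
    occurrences (covered or not) and against every occurrence of current
    members, so the final stack always validates.
    """
    w, thr = state.w, state.thr
    state.new_round()
    log = RoundLog(
        round=round_no, offset=offset, percentile=percentile,
        max_freq=max_freq, monotonic=monotonic, layer_size=0,
    )

    cand = state.starts[state.starts % w == offset].copy()
    rng.shuffle(cand)
    log.n_candidates = cand.size

    members: dict[int, tuple[list[int], list[int]]] = {}  # code -> (all occ, uncovered occ)
    cur_all: list[int] = []  # sorted, every occurrence of every member
    processed: set[int] = set()

    def conflicts_with(occ: list[int], unc: list[int]) -> set[int]:
        """Current members with an occurrence pair under threshold where at
        least one side is an uncovered occurrence."""
        out: set[int] = set()
        for x in unc:  # uncovered side is the candidate's
            i = bisect_left(cur_all, x)
            for nb in (i - 1, i):
                if 0 <= nb < len(cur_all) and abs(cur_all[nb] - x) < thr:
                    out.add(int(state.codes[cur_all[nb]]))
        unc_set = set(unc)
        for y in occ:
            if y in unc_set:
                continue  # handled above
            i = bisect_left(cur_all, y)
            for nb in (i - 1, i):
                if 0 <= nb < len(cur_all) and abs(cur_all[nb] - y) < thr:
                    other = cur_all[nb]
                    if not state.covered(other):  # uncovered side is the member's
                        out.add(int(state.codes[other]))
        return out

    for t in cand.tolist():
        code = int(state.codes[t])
        if code in processed or code in state.prev_member_codes:
            continue
        processed.add(code)
        occ = state.idx.occurrences(t)
        if len(occ) > max_freq:
            continue
        unc = [x for x in occ if not state.covered(x)]
        if not unc:
            continue
        # self-collision: an uncovered occurrence too close to any other
        # occurrence of the same k-mer
        if _self_collides(occ, set(unc), thr):
            continue
        # too close to an earlier layer at an uncovered occurrence
        if any(state.near_previous_layers(x) for x in unc):
            continue

        conf = conflicts_with(occ, unc)
        evicted_unc = [x for c in conf for x in members[c][1]]
        # trial on the energy ledger: remove evicted, insert the candidate
        lnum_before = state.union.Lnum
        for x in evicted_unc:
            state.union.remove(x)
        for x in unc:
            state.union.add(x)
        if monotonic and state.union.Lnum <= lnum_before:
            # first-choice hill climbing: keep only strict improvements
            for x in reversed(unc):
                state.union.remove(x)
            for x in evicted_unc:
                state.union.add(x)
            continue
        # commit
        for c in conf:
            all_c, _ = members.pop(c)
            _remove_sorted_many(cur_all, all_c)
        for y in occ:
            insort(cur_all, y)
        members[code] = (occ, unc)
        log.n_admitted += 1
        log.n_evicted += len(conf)

    _prune_linkless(state, members, cur_all, log)

    layer_codes = set(members)
    log.layer_size = len(layer_codes)
    log.link_energy = state.union.L
    # fold the accepted layer into the cross-round state
    state.prev_member_codes |= layer_codes
    merged = state.prev_all + [y for occ, _ in members.values() for y in occ]
    merged.sort()
    state.prev_all = merged
    return layer_codes, log


def _self_collides(occ: list[int], unc: set[int], thr: int) -> bool:
    for a, b in zip(occ, occ[1:]):
        if b - a < thr and (a in unc or b in unc):
            return True
    return False


def _remove_sorted_many(lst: list[int], items: list[int]) -> None:
    for y in items:
        i = bisect_left(lst, y)
        if i < len(lst) and lst[i] == y:
            lst.pop(i)


def _prune_linkless(state: _BuildState, members: dict, cur_all: list[int], log) -> None:
    """Drop members none of whose uncovered occurrences has a link."""
    w = state.w
    doomed = []
    for code, (_, unc) in members.items():
        linked = False
        for x in unc:
            p = state.union.peek_left(x - 1)
            if p is not None and x - p <= w:
                linked = True
                break
            q = state.union.peek_right(x + 1)
            if q is not None and q - x <= w:
                linked = True
                break
        if not linked:
            doomed.append(code)
    for code in doomed:
        all_c, unc = members.pop(code)
        for x in unc:
            state.union.remove(x)
        _remove_sorted_many(cur_all, all_c)
    log.n_pruned = len(doomed)


# ----------------------------------------------------------------------
# Multi-round driver
# ----------------------------------------------------------------------

def build_layered(
    seq: Sequence, w: int, k: int, config: HeuristicConfig | None = None
) -> tuple[LayeredPolarSet, list[RoundLog]]:
    """Build a layered polar set over ``rounds`` offsets.

    Returns the layered set (empty rounds are dropped) and per-round logs
    including the running total link energy, which is non-decreasing.
    """
    config = config or HeuristicConfig()
    rng = np.random.default_rng(config.seed)
    idx = SuffixIndex(seq, k)
    state = _BuildState(seq, idx, w, k, config.s)

    if config.offsets is not None:
        offsets = list(config.offsets)
        if len(offsets) != config.rounds:
            raise ValueError("offsets must have one entry per round")
    elif config.rounds <= w:
        offsets = rng.choice(w, size=config.rounds, replace=False).tolist()
    else:
        offsets = rng.choice(w, size=config.rounds, replace=True).tolist()

    pcts = config.percentiles()
    logs: list[RoundLog] = []
    layers: list[frozenset[str]] = []
    for r in range(config.rounds):
        max_freq = frequency_threshold(idx, float(pcts[r]))
        monotonic = r >= config.rounds - config.monotonic_tail
        layer_codes, log = polar_round(
            state, int(offsets[r]), max_freq, rng, monotonic,
            round_no=r + 1, percentile=float(pcts[r]),
        )
        logs.append(log)
        if layer_codes:
            layers.append(
                frozenset(unpack_kmer(c, k, seq.alphabet) for c in layer_codes)
            )
    lps = LayeredPolarSet(tuple(layers), s=config.s)
    return lps, logs


def compatible_order(lps: LayeredPolarSet, seed: int, alphabet: str = "ACGT") -> KmerOrder:
    """A seeded order compatible with the layered polar set."""
    return KmerOrder(lps.code_layers(alphabet), seed=seed)
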