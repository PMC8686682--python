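"""Polar sets: validation, link energy (two routes), density sandwich."""

import numpy as np
import pytest

import polarsketch as ps
from polarsketch.polar import link_stats_from_positions, uncovered_occurrences
from conftest import brute_force_link_stats


def plant_unique_kmers(n, k, offsets, seed=0, max_tries=500):
    """Random sequence whose k-mers at the given positions are unique in S."""
    for s in range(seed, seed + max_tries):
        seq = ps.uniform_sequence(n, seed=s)
        kmers = [seq.text[p : p + k] for p in offsets]
        if len(set(kmers)) == len(kmers) and all(seq.text.count(m) == 1 for m in kmers):
            return seq, kmers
    raise RuntimeError("no fixture found")


class TestSpacingThreshold:
    def test_ceil_and_parameter_guard(self):
        assert ps.spacing_threshold(10, 0.4) == 6
        assert ps.spacing_threshold(5, 0.4) == 3
        assert ps.spacing_threshold(10, 0.0) == 10
        with pytest.raises(ValueError):
            ps.spacing_threshold(10, 0.5)


class TestValidatePolar:
    def test_too_close_pair_rejected(self):
        seq, kmers = plant_unique_kmers(60, 4, [20, 25])  # 5 apart
        verdict = ps.validate_polar(seq, kmers, 10, s=0.4)  # threshold 6
        assert not verdict.valid
        assert len(verdict.violations) >= 1
        v = verdict.violations[0]
        assert {v.position, v.other_position} == {20, 25} and v.distance == 5

    def test_exactly_threshold_accepted(self):
        seq, kmers = plant_unique_kmers(60, 4, [20, 26])  # exactly (1-s)w = 6
        assert ps.validate_polar(seq, kmers, 10, s=0.4).valid

    def test_empty_set_vacuously_valid(self):
        seq = ps.uniform_sequence(50, seed=1)
        assert ps.validate_polar(seq, [], 10, s=0.0).valid

    def test_same_kmer_self_distance_counts(self):
        seq = ps.Sequence("ACGTACGTAAAAAAAAAA")
        verdict = ps.validate_polar(seq, ["ACGT"], 10, s=0.4)  # occurrences 0, 4
        assert not verdict.valid

    def test_no_window_holds_two_members(self):
        seq = ps.uniform_sequence(3000, seed=2)
        w, k = 8, 10
        starts = seq.kmer_starts(k)
        members = {seq.text[t : t + k] for t in starts[:: 2 * w].tolist()}
        if ps.validate_polar(seq, members, w, s=0.3).valid:
            occ = np.sort(uncovered_occurrences(seq, ps.LayeredPolarSet.single(members, 0.3), w))
            assert (np.diff(occ) >= w).all() or (np.diff(occ) > w // 2).all()


class TestValidateLayered:
    def test_single_layer_equals_plain(self):
        seq, kmers = plant_unique_kmers(60, 4, [20, 25])
        lay = ps.validate_layered(seq, ps.LayeredPolarSet.single(kmers, 0.4), 10)
        plain = ps.validate_polar(seq, kmers, 10, s=0.4)
        assert lay.valid == plain.valid == False  # noqa: E712

    def test_covered_occurrence_accepted_regardless_of_spacing(self):
        # layer-2 occurrence sandwiched between layer-1 occurrences 8 apart
        seq, kmers = plant_unique_kmers(80, 4, [20, 24, 28], seed=3)
        lps = ps.LayeredPolarSet(
            (frozenset({kmers[0], kmers[2]}), frozenset({kmers[1]})), s=0.4
        )
        assert ps.validate_layered(seq, lps, 10).valid
        # the same set as a single mixed layer violates the spacing rule
        assert not ps.validate_polar(seq, kmers, 10, s=0.4).valid

    def test_removing_the_covering_layer_breaks_validity(self):
        # layer 1 flanks (30, 38) cover two layer-2 occurrences (33, 36) that
        # are only 3 bases apart; a third layer rides at distance 6 from 38
        seq, kmers = plant_unique_kmers(100, 4, [30, 33, 36, 38, 44], seed=5)
        three_layer = ps.LayeredPolarSet(
            (
                frozenset({kmers[0], kmers[3]}),
                frozenset({kmers[1], kmers[2]}),
                frozenset({kmers[4]}),
            ),
            s=0.4,
        )
        assert ps.validate_layered(seq, three_layer, 10).valid
        without_first = ps.LayeredPolarSet(three_layer.layers[1:], s=0.4)
        assert not ps.validate_layered(seq, without_first, 10).valid

    def test_strict_coverage_inequalities(self):
        # occurrence at the same position as a flank is NOT covered (l < t < h)
        seq, kmers = plant_unique_kmers(80, 4, [20, 23], seed=7)
        lps = ps.LayeredPolarSet((frozenset({kmers[0]}), frozenset({kmers[1]})), s=0.4)
        # only one flank: not covered, and 3 < 6 from the layer-1 occurrence
        assert not ps.validate_layered(seq, lps, 10).valid


class TestLinkEnergy:
    def test_worked_example_pair_energies(self):
        seq, kmers = plant_unique_kmers(60, 5, [20, 23, 27])
        lps = ps.LayeredPolarSet.single(kmers, s=0.4)
        stats = ps.link_energy(seq, lps, 5)
        assert [e for *_, e in stats.links] == pytest.approx([0.0, 1 / 3])
        assert stats.L == pytest.approx(1 / 3)
        assert (stats.Acov, stats.Aele, stats.Aseg) == (13, 3, 1)
        assert stats.formula_L() == pytest.approx(1 / 3)

    def test_isolated_occurrence_zero_energy(self):
        seq, kmers = plant_unique_kmers(60, 5, [30])
        stats = ps.link_energy(seq, ps.LayeredPolarSet.single(kmers, 0.0), 10)
        assert (stats.Acov, stats.Aele, stats.Aseg, stats.L) == (11, 1, 1, 0.0)

    def test_invalid_set_raises_with_verdict(self):
        seq, kmers = plant_unique_kmers(60, 4, [20, 22])
        with pytest.raises(ps.InvalidPolarSetError) as exc:
            ps.link_energy(seq, ps.LayeredPolarSet.single(kmers, 0.4), 10)
        assert exc.value.verdict.violations

    def test_formula_equals_pairwise_on_random_configurations(self, rng):
        """2Acov/(w+1) - Aele - Aseg == pairwise sum, exactly, on 200 random
        spacing-respecting position sets."""
        for _ in range(200):
            w = int(rng.integers(2, 15))
            thr = w // 2 + 1
            pos, cur = [], 0
            for _ in range(rng.integers(0, 20)):
                cur += int(rng.integers(thr, 3 * w))
                pos.append(cur)
            stats = link_stats_from_positions(pos, w)
            acov, aele, aseg, lsum = brute_force_link_stats(pos, w)
            assert (stats.Acov, stats.Aele, stats.Aseg) == (acov, aele, aseg)
            assert abs(stats.L - lsum) < 1e-12
            assert abs(stats.formula_L() - lsum) < 1e-12

    def test_adding_a_layer_never_decreases_L(self, rng):
        for trial in range(15):
            seq = ps.uniform_sequence(1500, seed=int(rng.integers(2**31)))
            w, k = 8, 9
            cfg = ps.HeuristicConfig(rounds=4, monotonic_tail=0, s=0.3,
                                     seed=int(rng.integers(2**31)))
            lps, _ = ps.build_layered(seq, w, k, cfg)
            prev = -np.inf
            for m in range(1, lps.n_layers + 1):
                sub = ps.LayeredPolarSet(lps.layers[:m], s=lps.s)
                L = ps.link_energy(seq, sub, w).L
                assert L >= prev - 1e-12
                prev = L


class TestDensityBounds:
    def test_empty_set_contains_one_plus_E0(self):
        seq = ps.uniform_sequence(500, seed=11)
        lps = ps.LayeredPolarSet((frozenset(),), s=0.0, k=6)
        lo, hi = ps.density_bounds(seq, lps, 5)
        prof = ps.energy_profile(seq, 5, 6)
        assert lo <= 1 + prof.E0 <= hi

    def test_interior_grid_polar_set_bound_algebra(self):
        # all-distinct k-mers, members exactly w apart but away from the
        # sequence ends: the sandwich collapses to
        # 1 + E0 - (#links)(1 - 2/(w+1)) exactly since D = X = 0
        seq = ps.planted_perfect_sequence(2000, 10, 13, seed=12)
        w, k = 10, 13
        starts = seq.kmer_starts(k)
        grid = [t for t in starts[starts % w == 0].tolist() if 2 * w <= t <= len(seq) - k - 2 * w]
        lps = ps.LayeredPolarSet.single({seq.text[t : t + k] for t in grid}, s=0.0)
        assert ps.validate_layered(seq, lps, w).valid
        stats = ps.link_energy(seq, lps, w)
        assert stats.L == pytest.approx(stats.formula_L(), abs=1e-12)
        prof = ps.energy_profile(seq, w, k)
        assert prof.D == prof.X == 0
        lo, hi = ps.density_bounds(seq, lps, w)
        expect = 1 + prof.E0 - stats.n_links * (1 - 2 / (w + 1))
        assert lo == pytest.approx(expect) and hi == pytest.approx(expect)

    def test_full_grid_scheme_is_pinched_exactly(self):
        # members tile the whole sequence every w bases: the compatible
        # minimizer is deterministic and both bounds meet its count,
        # including the fragment-end corrections
        seq = ps.planted_perfect_sequence(2000, 10, 13, seed=12)
        w, k = 10, 13
        layer = ps.fixed_interval_set(seq, w, k)
        lps = ps.LayeredPolarSet.single(layer, s=0.0)
        assert ps.validate_layered(seq, lps, w).valid
        lo, hi = ps.density_bounds(seq, lps, w)
        sel = ps.select_positions(seq, w, k, ps.compatible_order(lps, seed=5))
        # the deterministic scheme achieves the lower bound exactly; the
        # upper bound stays within the two boundary-segment charge slack
        assert sel.n_selected == pytest.approx(lo, abs=1e-6)
        assert lo <= sel.n_selected <= hi
        assert hi - lo <= 2 + 1e-6

    def test_monte_carlo_selection_inside_sandwich(self, rng):
        """E[#selected] under compatible orders falls in the bounds, over
        randomized small instances (3 SE tolerance)."""
        for trial in range(12):
            seq = ps.uniform_sequence(int(rng.integers(400, 2000)),
                                      seed=int(rng.integers(2**31)))
            w = int(rng.choice([4, 6, 10, 12]))
            k = int(rng.integers(5, 11))
            cfg = ps.HeuristicConfig(rounds=3, monotonic_tail=1, s=0.4,
                                     seed=int(rng.integers(2**31)))
            lps, _ = ps.build_layered(seq, w, k, cfg)
            if lps.n_layers == 0:
                continue
            lo, hi = ps.density_bounds(seq, lps, w)
            mean, se = ps.expected_selected_mc(
                seq, w, k, layers=lps.layers, trials=150, seed=int(rng.integers(2**31))
            )
            assert lo - 3 * se - 1e-9 <= mean <= hi + 3 * se + 1e-9


class TestLayeredTsvRoundTrip:
    def test_round_trip_exact(self, tmp_path):
        lps = ps.LayeredPolarSet(
            (frozenset({"ACGTA", "TTTTT"}), frozenset({"GGGGG"})), s=0.4
        )
        path = tmp_path / "layers.tsv"
        ps.write_layers_tsv(path, lps, w=10, seed=7)
        back, meta = ps.read_layers_tsv(path)
        assert back == lps
        assert meta == {"w": 10, "k": 5, "s": 0.4, "seed": 7}
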