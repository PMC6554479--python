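"""CCC co-segregation: stats, filtering, Eq-2 arithmetic, scan vs oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from centwave import (
    GenotypeMatrix,
    LDScenario,
    SNPSite,
    block_schedule,
    ccc_scan,
    ccc_value,
    coevolution_profile,
    filter_sites,
    make_windows,
    relative_cooccurrence,
    simulate_genotypes,
    site_stats,
)
from centwave.ccc import pair_edges


def _matrix(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_ind, n_sites = dosage.shape
    sites = [SNPSite("chr1", 1000 * (s + 1)) for s in range(n_sites)]
    return GenotypeMatrix([f"i{k}" for k in range(n_ind)], sites, dosage)


def _random_matrix(rng, n_ind, n_sites, missing=0.15):
    d = rng.integers(0, 3, size=(n_ind, n_sites)).astype(np.int8)
    d[rng.random(d.shape) < missing] = -1
    return _matrix(d)


def brute_force_stats(matrix, s):
    """Per-cell loop oracle for call rate / frequencies."""
    n_obs = alt = 0
    for k in range(matrix.n_individuals):
        d = int(matrix.dosage[k, s])
        if d >= 0:
            n_obs += 1
            alt += d
    call_rate = n_obs / matrix.n_individuals
    f_alt = alt / (2 * n_obs) if n_obs else float("nan")
    return call_rate, f_alt


def brute_force_R(matrix, i, x, j, y, pairing):
    """Exhaustive per-individual loop oracle for relative co-occurrence."""
    num = n = 0
    for k in range(matrix.n_individuals):
        di, dj = int(matrix.dosage[k, i]), int(matrix.dosage[k, j])
        if di < 0 or dj < 0:
            continue
        n += 1
        dx = di if x == 1 else 2 - di
        dy = dj if y == 1 else 2 - dj
        num += (1 if dx > 0 and dy > 0 else 0) if pairing == "carrier" \
            else min(dx, dy)
    if n == 0:
        return float("nan"), 0
    return (num / n if pairing == "carrier" else num / (2 * n)), n


def brute_force_scan(matrix, threshold, min_overlap, pairing, reading):
    """All-pairs, all-allele-pairs exhaustive scan."""
    edges = set()
    for i, j in combinations(range(matrix.n_sites), 2):
        overlap = [k for k in range(matrix.n_individuals)
                   if matrix.dosage[k, i] >= 0 and matrix.dosage[k, j] >= 0]
        n = len(overlap)
        if n < min_overlap or n == 0:
            continue
        for x in (0, 1):
            fi = sum(int(matrix.dosage[k, i]) if x == 1 else 2 - int(matrix.dosage[k, i])
                     for k in overlap) / (2 * n)
            for y in (0, 1):
                fj = sum(int(matrix.dosage[k, j]) if y == 1 else 2 - int(matrix.dosage[k, j])
                         for k in overlap) / (2 * n)
                if fi <= 0 or fj <= 0:
                    continue
                R, _ = brute_force_R(matrix, i, x, j, y, pairing)
                pen = ((1 - fi) * (1 - fj) if reading == "one_minus_f"
                       else (1 - 1 / fi) * (1 - 1 / fj))
                if 4.5 * R * pen >= threshold:
                    edges.add((i, x, j, y))
    return edges


class TestSiteStats:
    def test_mixed_site_with_missing(self):
        st_ = site_stats(_matrix([[0], [1], [2], [-1]]), 0)
        assert st_.call_rate == 0.75
        assert st_.f_alt == 0.5 and st_.maf == 0.5

    def test_monomorphic_site_has_zero_maf(self):
        st_ = site_stats(_matrix([[0], [0], [0]]), 0)
        assert st_.maf == 0.0 and st_.f_ref == 1.0

    def test_all_missing_site_flagged_undefined(self):
        st_ = site_stats(_matrix([[-1], [-1]]), 0)
        assert st_.call_rate == 0.0 and not st_.defined

    def test_matches_per_cell_loop(self, rng):
        m = _random_matrix(rng, 40, 15)
        for s in range(m.n_sites):
            st_ = site_stats(m, s)
            cr, fa = brute_force_stats(m, s)
            assert st_.call_rate == pytest.approx(cr)
            assert st_.f_alt == pytest.approx(fa)


class TestFilterSites:
    def test_boundary_maf_is_removed(self):
        # f_alt exactly 0.01: 2 ALT alleles in 200 slots
        d = np.zeros((100, 1), dtype=np.int8)
        d[0, 0] = 2
        assert filter_sites(_matrix(d)).n_sites == 0

    def test_boundary_call_rate_is_removed(self):
        d = np.full((10, 1), -1, dtype=np.int8)
        d[:5, 0] = [0, 1, 2, 1, 1]  # call rate exactly 0.5, maf 0.5
        assert filter_sites(_matrix(d)).n_sites == 0

    def test_passing_site_kept(self):
        d = np.full((100, 1), -1, dtype=np.int8)
        d[:51, 0] = [1] * 30 + [0] * 21  # call rate 0.51, maf ~0.29
        assert filter_sites(_matrix(d)).n_sites == 1

    def test_survivors_equal_loop_oracle(self, rng):
        m = _random_matrix(rng, 60, 25, missing=0.4)
        kept = {s.pos for s in filter_sites(m).sites}
        expected = set()
        for s in range(m.n_sites):
            cr, fa = brute_force_stats(m, s)
            if cr > 0.5 and min(fa, 1 - fa) > 0.01:
                expected.add(m.sites[s].pos)
        assert kept == expected


class TestRelativeCooccurrence:
    def test_double_homozygotes_give_one(self):
        m = _matrix([[2, 2]] * 5)
        for pairing in ("carrier", "min_dosage"):
            R, n = relative_cooccurrence(m, 0, 1, 1, 1, pairing=pairing)
            assert R == 1.0 and n == 5

    def test_never_cooccurring_alleles_give_zero(self):
        m = _matrix([[2, 0], [2, 0], [0, 2]])
        for pairing in ("carrier", "min_dosage"):
            R, _ = relative_cooccurrence(m, 0, 1, 1, 1, pairing=pairing)
            assert R == 0.0

    def test_matches_per_individual_loop(self, rng):
        m = _random_matrix(rng, 50, 6)
        for pairing in ("carrier", "min_dosage"):
            for i, j in combinations(range(6), 2):
                for x in (0, 1):
                    for y in (0, 1):
                        R, n = relative_cooccurrence(m, i, x, j, y, pairing=pairing)
                        Rb, nb = brute_force_R(m, i, x, j, y, pairing)
                        assert n == nb and R == pytest.approx(Rb)

    def test_same_site_rejected(self):
        with pytest.raises(ValueError):
            relative_cooccurrence(_matrix([[0, 0]]), 0, 1, 0, 1)


class TestCCCValue:
    def test_zero_cooccurrence_gives_zero(self):
        assert ccc_value(0.0, 0.3, 0.4) == 0.0

    def test_monomorphic_allele_gives_zero(self):
        assert ccc_value(0.8, 1.0, 0.4) == 0.0

    def test_stated_arithmetic(self):
        assert ccc_value(0.3, 0.5, 0.5) == pytest.approx(4.5 * 0.3 * 0.25)

    def test_alternative_penalty_reading(self):
        # (1 - 1/f) penalties multiply to a positive value for f < 1
        assert ccc_value(0.3, 0.5, 0.5, reading="one_minus_inv_f") == \
            pytest.approx(4.5 * 0.3 * 1.0)

    @given(R=st.floats(0, 1), f=st.floats(0.01, 1.0), g=st.floats(0.01, 1.0))
    def test_default_reading_is_nonnegative_and_symmetric(self, R, f, g):
        v = ccc_value(R, f, g)
        assert v >= 0.0
        assert v == pytest.approx(ccc_value(R, g, f))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ccc_value(1.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            ccc_value(0.5, 0.0, 0.5)


class TestCCCScan:
    def test_planted_perfect_pair_matches_hand_computation(self):
        # two identical sites, 100 individuals, f_alt = 0.3, no missing:
        # 9 hom-ALT + 42 het + 49 hom-REF; carriers = 51
        col = np.array([2] * 9 + [1] * 42 + [0] * 49, dtype=np.int8)
        m = _matrix(np.stack([col, col], axis=1))
        edges = ccc_scan(m, threshold=0.7, min_overlap=100)
        assert len(edges) == 1
        e = edges[0]
        assert (e.allele_x, e.allele_y) == (1, 1)
        assert e.R == pytest.approx(0.51)
        assert e.n_overlap == 100
        assert e.ccc == pytest.approx(4.5 * 0.51 * 0.7**2)

    def test_unreachable_threshold_gives_empty_list(self):
        col = np.array([2] * 9 + [1] * 42 + [0] * 49, dtype=np.int8)
        m = _matrix(np.stack([col, col], axis=1))
        assert ccc_scan(m, threshold=1.2, min_overlap=100) == []

    def test_overlap_floor_suppresses_edges(self):
        col = np.array([2] * 9 + [1] * 42 + [0] * 49, dtype=np.int8)
        m = _matrix(np.stack([col, col], axis=1))
        assert ccc_scan(m, threshold=0.7, min_overlap=101) == []

    @pytest.mark.parametrize("pairing", ["carrier", "min_dosage"])
    @pytest.mark.parametrize("reading", ["one_minus_f", "one_minus_inv_f"])
    def test_matches_exhaustive_oracle(self, rng, pairing, reading):
        m = _random_matrix(rng, 50, 12)
        got = {(e.site_i, e.allele_x, e.site_j, e.allele_y)
               for e in ccc_scan(m, threshold=0.5037, min_overlap=20,
                                 pairing=pairing, reading=reading)}
        assert got == brute_force_scan(m, 0.5037, 20, pairing, reading)

    def test_symmetric_under_site_order_reversal(self, rng):
        m = _random_matrix(rng, 50, 10)
        rev = _matrix(m.dosage[:, ::-1].copy())
        fwd = {(e.site_i, e.allele_x, e.site_j, e.allele_y)
               for e in ccc_scan(m, threshold=0.4037, min_overlap=10)}
        k = m.n_sites - 1
        back = set()
        for e in ccc_scan(rev, threshold=0.4037, min_overlap=10):
            i, j = k - e.site_i, k - e.site_j
            back.add((j, e.allele_y, i, e.allele_x) if j < i
                     else (i, e.allele_x, j, e.allele_y))
        assert fwd == back

    def test_R_bounds_and_nonnegative_ccc_on_random_pairs(self, rng):
        m = _random_matrix(rng, 30, 20, missing=0.3)
        for _ in range(300):
            i, j = rng.choice(20, size=2, replace=False)
            edges = pair_edges(m, min(i, j), max(i, j), threshold=0.0, min_overlap=1)
            for e in edges:
                assert 0.0 <= e.R <= 1.0
                assert e.ccc >= 0.0

    def test_block_partitioned_scan_equals_plain_scan(self, rng):
        m = _random_matrix(rng, 40, 15)
        a = ccc_scan(m, threshold=0.4037, min_overlap=10, n_blocks=1)
        b = ccc_scan(m, threshold=0.4037, min_overlap=10, n_blocks=4)
        assert a == b


class TestBlockSchedule:
    @pytest.mark.parametrize("n_blocks,expected_jobs", [(20, 210), (1, 1), (3, 6)])
    def test_job_counts(self, n_blocks, expected_jobs):
        sched = block_schedule(100, n_blocks)
        assert len(sched.jobs) == expected_jobs

    @pytest.mark.parametrize("n_blocks", range(1, 11))
    def test_jobs_cover_every_pair_exactly_once(self, n_blocks):
        n_items = 23
        sched = block_schedule(n_items, n_blocks)
        seen = []
        for job in sched.jobs:
            seen.extend(sched.job_pairs(job))
        assert len(seen) == len(set(seen)) == n_items * (n_items - 1) // 2
        assert set(seen) == set(combinations(range(n_items), 2))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            block_schedule(5, 6)
        with pytest.raises(ValueError):
            block_schedule(5, 0)


class TestLDRecovery:
    def test_within_block_pairs_pass_and_cross_block_pairs_fail(self):
        m = filter_sites(simulate_genotypes(LDScenario(seed=7)))
        passing = {(e.site_i, e.site_j) for e in ccc_scan(m)}
        block = [s.pos // 100_000 for s in m.sites]
        within = [(i, j) for i, j in combinations(range(m.n_sites), 2)
                  if block[i] == block[j]]
        cross = [(i, j) for i, j in combinations(range(m.n_sites), 2)
                 if block[i] != block[j]]
        assert sum(p in passing for p in within) / len(within) >= 0.92
        assert sum(p in passing for p in cross) / len(cross) <= 0.04

    def test_within_block_mean_ccc_exceeds_cross_block_mean(self):
        m = filter_sites(simulate_genotypes(LDScenario(seed=9)))
        block = [s.pos // 100_000 for s in m.sites]
        within, cross = [], []
        for i, j in combinations(range(m.n_sites), 2):
            edges = pair_edges(m, i, j, threshold=0.0, min_overlap=1)
            best = max((e.ccc for e in edges), default=0.0)
            (within if block[i] == block[j] else cross).append(best)
        assert np.mean(within) > np.mean(cross)


class TestCoevolutionProfile:
    def _sites(self):
        return [SNPSite("chr1", 500), SNPSite("chr1", 600),
                SNPSite("chr1", 25_000), SNPSite("chr2", 7_000)]

    def test_single_edge_counts_distal_partner(self):
        from centwave.ccc import CCCEdge
        sites = self._sites()
        edges = [CCCEdge(0, 1, 2, 1, 1.0, 0.3, 0.3, 100, 1.0)]
        prof = coevolution_profile(edges, sites, "chr1", 0, 1000,
                                   make_windows(30_000, 10_000, chrom="chr1"))
        assert prof.values.tolist() == [0, 0, 1]
        assert prof.kind == "corr_snp"

    def test_partner_with_two_anchor_edges_counts_once(self):
        from centwave.ccc import CCCEdge
        sites = self._sites()
        edges = [CCCEdge(0, 1, 2, 1, 1.0, 0.3, 0.3, 100, 1.0),
                 CCCEdge(1, 1, 2, 1, 1.0, 0.3, 0.3, 100, 1.0)]
        prof = coevolution_profile(edges, sites, "chr1", 0, 1000,
                                   make_windows(30_000, 10_000, chrom="chr1"))
        assert prof.values.sum() == 1

    def test_other_chromosome_partners_excluded_from_profile(self):
        from centwave.ccc import CCCEdge
        sites = self._sites()
        edges = [CCCEdge(0, 1, 3, 1, 1.0, 0.3, 0.3, 100, 1.0)]
        prof = coevolution_profile(edges, sites, "chr1", 0, 1000,
                                   make_windows(30_000, 10_000, chrom="chr1"))
        assert prof.values.sum() == 0  # partner on chr2, grid on chr1

    def test_linked_block_scenario_peaks_in_planted_block(self):
        scenario = LDScenario(seed=3, linked_blocks=[(0, 2)])
        m = filter_sites(simulate_genotypes(scenario))
        edges = ccc_scan(m)
        # anchor = block 0's span; profile should peak in block 2's windows
        grid = make_windows(300_000, 10_000, chrom="chrSim")
        prof = coevolution_profile(edges, m.sites, "chrSim", 0, 100_000, grid)
        assert prof.values.sum() > 0
        peak_window = int(np.argmax(prof.values))
        assert 20 <= peak_window < 30  # block 2 occupies [200 kb, 300 kb)
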