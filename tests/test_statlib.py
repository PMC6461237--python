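"""Binning, circular statistics, library build/query/fallback/persistence."""

import math

import numpy as np
import pytest

from cbrecon import (BinKey, GeneratorSpec, LibraryConfig, PairStats,
                     StatLibrary, UndefinedMeanError, bin_assign,
                     build_library, circular_mean, generate, neighbor_fallback,
                     query)
from cbrecon.statlib import eligible_observations

from conftest import distinct_pair_chain


CFG = LibraryConfig()


class TestBinAssign:
    @pytest.mark.parametrize("ki,kip1,expected", [
        (1.0, 1.0, 1), (1.0, 1.3, 2), (1.3, 1.0, 3), (1.3, 1.3, 4),
        (1.2, 1.2, 4),  # boundary goes to the >= (helix-like) side
        (1.2, 1.0, 3),
    ])
    def test_four_way_kappa_sets(self, ki, kip1, expected):
        assert bin_assign(ki, kip1, 0.0, 0.0, CFG).dkappa_set == expected

    @pytest.mark.parametrize("tau,sector", [
        (0.0, 30), (-math.pi, 0), (math.pi - 1e-9, 59),
        (-math.pi + 0.5 * math.pi / 30, 0), (math.pi / 30, 31),
    ])
    def test_tau_sector_half_open_bins(self, tau, sector):
        assert bin_assign(1.0, 1.0, tau, 0.0, CFG).tau_sector == sector

    @pytest.mark.parametrize("psi,segment", [
        (-math.pi, 0), (math.pi - 1e-9, 89), (0.0, 45),
    ])
    def test_psi_segment_boundaries(self, psi, segment):
        assert bin_assign(1.0, 1.0, 0.0, psi, CFG).psi_segment == segment

    def test_non_finite_angle_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            bin_assign(1.0, float("nan"), 0.0, 0.0, CFG)


class TestCircularMean:
    def test_identical_angles(self):
        mean, r = circular_mean([0.7, 0.7, 0.7])
        assert mean == pytest.approx(0.7)
        assert r == pytest.approx(1.0)

    def test_symmetric_pair(self):
        mean, r = circular_mean([0.0, math.pi / 2])
        assert mean == pytest.approx(math.pi / 4)
        assert r == pytest.approx(math.sqrt(2) / 2)

    def test_antipodal_pair_is_undefined(self):
        with pytest.raises(UndefinedMeanError):
            circular_mean([0.0, math.pi])

    def test_wraparound_average(self):
        mean, _ = circular_mean([math.pi - 0.1, -math.pi + 0.1])
        assert abs(abs(mean) - math.pi) < 1e-12 or mean == pytest.approx(-math.pi)

    def test_matches_grid_minimizer_oracle(self):
        # brute-force grid search over the objective sum(1 - cos(g - tau_k))
        rng = np.random.default_rng(12)
        grid = np.linspace(-math.pi, math.pi, 200_000, endpoint=False)
        step = grid[1] - grid[0]
        for _ in range(20):
            angles = rng.uniform(-math.pi, math.pi, rng.integers(2, 40))
            c, s = np.cos(angles).mean(), np.sin(angles).mean()
            if math.hypot(c, s) < 1e-3:
                continue
            objective = 1.0 - c * np.cos(grid) - s * np.sin(grid)
            best = grid[np.argmin(objective)]
            mean, _ = circular_mean(angles)
            d = (mean - best + math.pi) % (2 * math.pi) - math.pi
            assert abs(d) <= step


@pytest.fixture(scope="module")
def small_library():
    spec = GeneratorSpec(n_chains=10, n_residues=30, noise_sigma=0.05, seed=21)
    return build_library(generate(spec))


class TestBuildLibrary:
    def test_ten_residue_chain_contributes_six_observations(self):
        _, trace = distinct_pair_chain(n_residues=10)
        obs = list(eligible_observations(trace))
        assert len(obs) == 6
        assert [o[0] for o in obs] == [1, 2, 3, 4, 5, 6]

    def test_identical_observations_collapse_to_one_cell(self):
        spec = GeneratorSpec(n_chains=1, n_residues=12, program="alpha",
                             noise_sigma=0.0, seed=5)
        from cbrecon import generate_backbone, decorate
        (trace,) = generate_backbone(spec)
        for r in trace.residues:
            r.res_name = "ALA"
        decorate([trace], spec)
        lib = build_library([trace], CFG)
        assert len(lib.bins) == 1
        (cells,) = lib.bins.values()
        assert list(cells) == [("ALA", "ALA")]
        ps = cells[("ALA", "ALA")]
        assert ps.count == 8
        assert ps.resultant_R == pytest.approx(1.0, abs=1e-12)

    def test_count_conservation(self, small_library):
        lib = small_library
        assert lib.total_count() == lib.n_observations
        agg_total = sum(lib.bin_aggregate(k).count for k in lib.bins)
        assert agg_total == lib.n_observations

    def test_insertion_order_independence(self):
        spec = GeneratorSpec(n_chains=6, n_residues=20, noise_sigma=0.05, seed=8)
        traces = generate(spec)
        lib_a = build_library(traces, CFG)
        lib_b = build_library(traces[::-1], CFG)
        assert lib_a.bins.keys() == lib_b.bins.keys()
        for key in lib_a.bins:
            assert lib_a.bins[key].keys() == lib_b.bins[key].keys()
            for pair, ps in lib_a.bins[key].items():
                qs = lib_b.bins[key][pair]
                assert ps.count == qs.count
                assert ps.mean_latitude == pytest.approx(qs.mean_latitude,
                                                         abs=1e-12)
                assert ps.mean_longitude == pytest.approx(qs.mean_longitude,
                                                          abs=1e-12)

    def test_empty_input_is_an_error(self):
        from conftest import manual_trace
        bare = manual_trace([(3.8 * i, 0, 0.1 * i ** 2) for i in range(6)])
        with pytest.raises(ValueError, match="no eligible"):
            build_library([bare], CFG)

    def test_save_load_round_trip_query_identity(self, small_library, tmp_path):
        path = tmp_path / "lib.tsv"
        small_library.save(path)
        loaded = StatLibrary.load(path)
        assert loaded.config == small_library.config
        assert loaded.n_observations == small_library.n_observations
        rng = np.random.default_rng(30)
        pairs = [("ALA", "LEU"), ("LEU", "LEU"), ("TRP", "CYS")]
        for _ in range(1000):
            key = BinKey(int(rng.integers(1, 5)), int(rng.integers(0, 60)),
                         int(rng.integers(0, 90)))
            pair = pairs[rng.integers(0, len(pairs))]
            d0, p0 = query(small_library, key, pair)
            d1, p1 = query(loaded, key, pair)
            assert (d0, p0) == (d1, p1)

    def test_version_check_on_load(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("# some other format\n")
        with pytest.raises(ValueError, match="not a"):
            StatLibrary.load(bad)


def _lib_with(cells: dict) -> StatLibrary:
    return StatLibrary(config=CFG, bins=cells)


def _ps(count, theta, phi, r=1.0):
    return PairStats(count=count, mean_latitude=theta, mean_longitude=phi,
                     resultant_R=r)


class TestQuery:
    def test_unique_pair_match_is_used_verbatim(self):
        key = BinKey(4, 10, 20)
        lib = _lib_with({key: {("ALA", "GLY"): _ps(1, 1.1, -0.4)}})
        d, prov = query(lib, key, ("ALA", "GLY"))
        assert (d.latitude, d.longitude) == (1.1, -0.4)
        assert prov.kind == "exact-single"
        assert prov.used_key == key

    def test_multiple_matches_are_circularly_averaged(self):
        key = BinKey(4, 10, 20)
        phis = [0.0, math.pi / 6, math.pi / 3]
        mean_phi, r = circular_mean(phis)
        lib = _lib_with({key: {("LEU", "LEU"): _ps(3, 1.0, mean_phi, r)}})
        d, prov = query(lib, key, ("LEU", "LEU"))
        assert d.longitude == pytest.approx(math.pi / 6)
        assert prov.kind == "exact-averaged"

    def test_missing_pair_falls_back_to_bin_aggregate(self):
        key = BinKey(2, 5, 5)
        lib = _lib_with({key: {("ALA", "SER"): _ps(2, 1.0, 0.2),
                               ("VAL", "THR"): _ps(1, 1.4, 0.4)}})
        d, prov = query(lib, key, ("TRP", "TRP"))
        assert prov.kind == "bin-average"
        assert d.latitude == pytest.approx((2 * 1.0 + 1 * 1.4) / 3)

    def test_empty_bin_uses_neighbor_with_recorded_key(self):
        key = BinKey(1, 0, 10)
        neighbor = BinKey(1, 0, 9)
        lib = _lib_with({neighbor: {("ALA", "ALA"): _ps(1, 0.9, 0.1)}})
        d, prov = query(lib, key, ("ALA", "ALA"))
        assert prov.kind == "neighbor-fallback"
        assert prov.requested_key == key
        assert prov.used_key == neighbor
        assert d.latitude == pytest.approx(0.9)

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            query(_lib_with({}), BinKey(1, 0, 0), ("ALA", "ALA"))


class TestNeighborFallback:
    SMALL = LibraryConfig(n_tau_sectors=6, n_psi_segments=9)

    def test_immediate_clockwise_psi_neighbor_wins(self):
        key = BinKey(3, 2, 4)
        lib = StatLibrary(config=CFG, bins={
            BinKey(3, 2, 3): {("A", "B"): _ps(1, 1, 0)},
            BinKey(3, 2, 5): {("A", "B"): _ps(1, 1, 0)},
        })
        assert neighbor_fallback(lib, key) == BinKey(3, 2, 3)

    def test_psi_ring_exhausted_then_tau_steps_clockwise(self):
        lib = StatLibrary(config=self.SMALL, bins={
            BinKey(2, 1, 4): {("A", "B"): _ps(1, 1, 0)},
        })
        assert neighbor_fallback(lib, BinKey(2, 2, 4)) == BinKey(2, 1, 4)

    def test_single_populated_bin_always_found_exhaustively(self):
        # every (start, populated) combination in a small partition
        cfg = self.SMALL
        for dk in (1, 3):
            for pop_t in range(cfg.n_tau_sectors):
                for pop_p in range(0, cfg.n_psi_segments, 4):
                    pop = BinKey(dk, pop_t, pop_p)
                    lib = StatLibrary(config=cfg,
                                      bins={pop: {("A", "B"): _ps(1, 1, 0)}})
                    for st in range(cfg.n_tau_sectors):
                        found = neighbor_fallback(lib, BinKey(dk, st, 5))
                        assert found == pop

    def test_cross_set_fallback_prefers_richest_set(self):
        lib = StatLibrary(config=self.SMALL, bins={
            BinKey(1, 0, 0): {("A", "B"): _ps(1, 1, 0)},
            BinKey(4, 2, 2): {("A", "B"): _ps(1, 1, 0)},
            BinKey(4, 3, 3): {("A", "B"): _ps(1, 1, 0)},
        })
        found = neighbor_fallback(lib, BinKey(2, 2, 2))
        assert found == BinKey(4, 2, 2)  # same (tau, psi) position in set 4

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            neighbor_fallback(StatLibrary(config=CFG, bins={}), BinKey(1, 0, 0))
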