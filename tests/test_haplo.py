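import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.haplo import (EhhCurve, ehh, ihs_scan, integrate_ihh, raw_ihs,
                             standardize_ihs, xpehh, xpehh_scan)
from sweepscan.panel import HaplotypePanel

from conftest import random_panel
from oracles import ehh_oracle, trapezoid_oracle


def panel_from(alleles, spacing_bp=20_000, pops=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    n, m = alleles.shape
    pos = (np.arange(m) + 1) * spacing_bp
    return HaplotypePanel("1", pos, alleles, pops or ["POP1"] * n)


class TestEhh:
    def test_unity_at_core(self):
        p = panel_from([[1, 0], [1, 1], [1, 0], [1, 1]])
        c = ehh(p, 0, "derived", "downstream")
        assert c.points[0] == (0.0, 1.0)

    def test_identical_carriers_stay_at_one(self):
        p = panel_from(np.tile([1, 0, 1, 0, 1], (5, 1)))
        c = ehh(p, 2, "derived", "downstream", max_extension_cm=10)
        assert all(e == 1.0 for _, e in c.points)

    def test_four_two_split_gives_seven_fifteenths(self):
        alle = [[1, 0]] * 4 + [[1, 1]] * 2
        p = panel_from(alle)
        c = ehh(p, 0, "derived", "downstream")
        assert c.points[1][1] == pytest.approx(7 / 15)

    def test_fewer_than_two_carriers_undefined(self):
        p = panel_from([[1, 0], [0, 0], [0, 1], [0, 0]])
        c = ehh(p, 0, "derived", "downstream")
        assert not c.defined and c.points == []

    def test_missing_carrier_dropped_from_extension(self):
        alle = np.array([[1, 0, 0], [1, 0, 0], [1, -1, 0], [1, 1, 1]],
                        dtype=np.int8)
        p = panel_from(alle)
        c = ehh(p, 0, "derived", "downstream", max_extension_cm=10)
        # hap 2 dropped at SNP 1: three carriers remain, split 2/1
        assert c.points[1][1] == pytest.approx(1 / 3)

    def test_matches_all_pairs_oracle_on_random_panels(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(4, 24))
            m = int(rng.integers(5, 60))
            p = random_panel(rng, n, m)
            core = int(rng.integers(0, m))
            cm = p.map_positions()
            for cls in ("derived", "ancestral", "pooled"):
                for direction in ("upstream", "downstream"):
                    exp = ehh_oracle(p.alleles, cm, core, cls, direction)
                    got = ehh(p, core, cls, direction).points
                    assert len(got) == len(exp)
                    for (d0, e0), (d1, e1) in zip(exp, got):
                        assert e1 == pytest.approx(e0, abs=0)
                        assert d1 == pytest.approx(d0, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_curves_non_increasing_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = random_panel(rng, int(rng.integers(4, 20)), int(rng.integers(3, 40)))
        core = int(rng.integers(0, p.n_variants))
        for direction in ("upstream", "downstream"):
            c = ehh(p, core, "pooled", direction)
            vals = [e for _, e in c.points]
            assert all(0.0 <= e <= 1.0 for e in vals)
            assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestIntegrateIhh:
    def test_rectangle(self):
        c = EhhCurve(0, "derived", "downstream",
                     [(0.0, 1.0), (0.4, 1.0)], carrier_count=4)
        assert integrate_ihh(c) == pytest.approx(0.4)

    def test_linear_decay_matches_fine_grid_quadrature(self):
        pts = [(0.25 * k, 1.0 - 0.95 * (0.25 * k)) for k in range(5)]
        c = EhhCurve(0, "derived", "downstream", pts, carrier_count=4)
        # independent fine-grid quadrature of the same piecewise line
        grid = np.linspace(0, 1, 100_001)
        fine = float(np.trapezoid(np.interp(grid, [p[0] for p in pts],
                                            [p[1] for p in pts]), grid))
        assert integrate_ihh(c) == pytest.approx(fine, abs=1e-9)
        assert integrate_ihh(c) == pytest.approx(trapezoid_oracle(pts), abs=1e-15)

    def test_empty_curve_is_zero(self):
        c = EhhCurve(0, "derived", "downstream", [(0.0, 1.0)],
                     carrier_count=4, truncated="at_core")
        assert integrate_ihh(c) == 0.0


class TestRawIhs:
    def test_mirror_symmetry_gives_zero(self):
        block = np.array([[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 0]],
                         dtype=np.int8)
        core = np.array([1, 1, 0, 0], dtype=np.int8)
        alle = np.hstack([block, core[:, None], block])
        p = panel_from(alle)
        s = raw_ihs(p, 3)
        assert s.raw == pytest.approx(0.0, abs=1e-12)

    def test_long_derived_haplotype_negative(self, ihs_sweep_panel):
        s = raw_ihs(ihs_sweep_panel, 7)
        assert s.raw < 0

    def test_sweep_fixture_matches_oracle_pipeline(self, ihs_sweep_panel):
        s = raw_ihs(ihs_sweep_panel, 7)
        cm = ihs_sweep_panel.map_positions()
        ihh = {}
        for cls in ("derived", "ancestral"):
            ihh[cls] = sum(
                trapezoid_oracle(ehh_oracle(ihs_sweep_panel.alleles, cm, 7,
                                            cls, d))
                for d in ("upstream", "downstream"))
        assert s.ihh_derived == pytest.approx(ihh["derived"], abs=1e-12)
        assert s.ihh_ancestral == pytest.approx(ihh["ancestral"], abs=1e-12)
        assert s.raw == pytest.approx(np.log(ihh["ancestral"] / ihh["derived"]),
                                      abs=1e-12)
        # frozen value from the pair-enumeration + quadrature oracles
        assert s.raw == pytest.approx(-1.5184661342283736, abs=1e-12)

    def test_swapping_allele_labels_negates_raw(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            p = random_panel(rng, 12, 21)
            core = 10
            flipped = HaplotypePanel(p.chrom, p.positions.copy(),
                                     p.alleles.copy(), list(p.pops))
            flipped.alleles[:, core] = 1 - flipped.alleles[:, core]
            a = raw_ihs(p, core)
            b = raw_ihs(flipped, core)
            if np.isfinite(a.raw):
                assert b.raw == pytest.approx(-a.raw, abs=1e-12)

    def test_frequency_clamp_and_polarization(self):
        alle = np.zeros((20, 5), dtype=np.int8)
        alle[0, 2] = 1  # derived frequency 0.05... below clamp? 1/20 = 0.05
        p = panel_from(alle)
        p.polarized[:] = False
        assert not raw_ihs(p, 2).defined  # unpolarized -> excluded


class TestStandardize:
    def test_occupied_bins_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(31)
        p = random_panel(rng, 30, 120)
        scores = ihs_scan(p)
        raw = np.array([s.raw for s in scores])
        std = np.array([s.standardized for s in scores])
        freq = np.array([s.derived_freq for s in scores])
        edges = np.linspace(0, 1, 21)
        for b in range(20):
            hi = freq <= edges[b + 1] if b == 19 else freq < edges[b + 1]
            m = np.isfinite(std) & (freq >= edges[b]) & hi
            if m.sum() >= 2:
                assert np.mean(std[m]) == pytest.approx(0, abs=1e-9)
                assert np.std(std[m]) == pytest.approx(1, abs=1e-9)
        # every standardized score has a defined raw score behind it
        assert np.isfinite(raw[np.isfinite(std)]).all()

    def test_two_score_bin_gives_plus_minus_one(self):
        from sweepscan.haplo import IhsScore
        scores = [IhsScore(0, 100, 0.52, raw=0.7),
                  IhsScore(1, 200, 0.53, raw=-0.7)]
        standardize_ihs(scores)
        assert scores[0].standardized == pytest.approx(1.0)
        assert scores[1].standardized == pytest.approx(-1.0)

    def test_single_score_bin_stays_undefined(self):
        from sweepscan.haplo import IhsScore
        scores = [IhsScore(0, 100, 0.52, raw=0.7),
                  IhsScore(1, 200, 0.97, raw=-0.7)]
        standardize_ihs(scores)
        assert not np.isfinite(scores[0].standardized)


class TestXpehh:
    def test_identical_panels_give_zero(self):
        rng = np.random.default_rng(41)
        p = random_panel(rng, 10, 30)
        for core in (0, 10, 29):
            s = xpehh(p, p, core)
            if s.defined:
                assert s.raw == pytest.approx(0.0, abs=1e-12)

    def test_normalization_zero_mean_unit_sd(self):
        rng = np.random.default_rng(43)
        p = random_panel(rng, 24, 80, pops=["A"] * 12 + ["B"] * 12)
        scores = xpehh_scan(p, "A", "B")
        norm = np.array([s.normalized for s in scores])
        d = np.isfinite(norm)
        assert d.sum() > 10
        assert np.mean(norm[d]) == pytest.approx(0, abs=1e-9)
        assert np.std(norm[d]) == pytest.approx(1, abs=1e-9)

    def test_long_haplotype_population_positive(self):
        rng = np.random.default_rng(47)
        m = 31
        # population A: one near-fixed long haplotype; B: diverse
        hap = rng.integers(0, 2, size=m).astype(np.int8)
        a = np.tile(hap, (10, 1))
        a[0] = rng.integers(0, 2, size=m)
        b = rng.integers(0, 2, size=(10, m)).astype(np.int8)
        p = panel_from(np.vstack([a, b]), pops=["A"] * 10 + ["B"] * 10)
        s = xpehh(p.subset_pop("A"), p.subset_pop("B"), 15)
        assert s.raw > 0

    def test_value_matches_pooled_oracle(self):
        rng = np.random.default_rng(53)
        p = random_panel(rng, 16, 25, pops=["A"] * 8 + ["B"] * 8)
        pa, pb = p.subset_pop("A"), p.subset_pop("B")
        core = 12
        s = xpehh(pa, pb, core)
        cm = p.map_positions()
        area = {}
        for name, sub in (("a", pa), ("b", pb)):
            area[name] = 0.0
        for direction in ("upstream", "downstream"):
            ea = ehh_oracle(pa.alleles, cm, core, "pooled", direction,
                            truncate=False)
            eb = ehh_oracle(pb.alleles, cm, core, "pooled", direction,
                            truncate=False)
            k = min(len(ea), len(eb))
            stop = k
            for i in range(k):
                if ea[i][1] < 0.05 and eb[i][1] < 0.05:
                    stop = i + 1
                    break
            area["a"] += trapezoid_oracle(ea[:stop])
            area["b"] += trapezoid_oracle(eb[:stop])
        if s.defined:
            assert s.raw == pytest.approx(np.log(area["a"] / area["b"]),
                                          abs=1e-12)
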