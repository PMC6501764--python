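"""Marey-curve fitting, RR profiles, pericentromeres, RR comparisons."""

import numpy as np
import pandas as pd
import pytest

import teointro as t
from teointro.marey import MareyError, RRProfile, integrate_rr


def _gmap(x_mb, cm, chrom="chr1"):
    return pd.DataFrame(
        {
            "marker": [f"m{i}" for i in range(len(x_mb))],
            "chrom": chrom,
            "pos_bp": (np.asarray(x_mb) * 1e6).astype(int),
            "pos_cM": np.asarray(cm, float),
        }
    )


class TestFitMarey:
    def test_linear_map_recovers_constant_slope(self):
        x = np.linspace(1, 150, 100)
        curve = t.fit_marey(_gmap(x, 0.5 * x), "chr1")
        grid = np.linspace(2e6, 149e6, 50)
        assert np.allclose(curve.rate(grid), 0.5, atol=1e-3)

    def test_out_of_order_marker_removed(self):
        x = np.linspace(1, 100, 40)
        cm = 0.6 * x
        cm[20] = cm[-1] + 30  # one wildly out-of-order genetic value
        curve = t.fit_marey(_gmap(x, cm), "chr1")
        grid = np.linspace(1.5e6, 99e6, 200)
        assert (curve.spline.derivative()(grid / 1e6) >= -1e-6).all()
        assert len(curve.markers_removed) >= 1

    def test_piecewise_rate_recovery(self):
        # 1.2 / 0.1 / 1.2 cM/Mb over thirds of a 150 Mb chromosome
        x = np.linspace(0.5, 150, 200)
        rate = np.where((x > 50) & (x <= 100), 0.1, 1.2)
        cm = np.concatenate([[0], np.cumsum(np.diff(x) * rate[1:])])
        curve = t.fit_marey(_gmap(x, cm), "chr1")
        for probe, expect in [(25, 1.2), (75, 0.1), (125, 1.2)]:
            assert curve.rate(probe * 1e6) == pytest.approx(expect, abs=0.15)

    def test_too_few_markers_rejected(self):
        with pytest.raises(MareyError):
            t.fit_marey(_gmap([1, 2, 3, 4], [0, 1, 2, 3]), "chr1")

    def test_effective_df_near_target(self):
        x = np.linspace(1, 150, 120)
        curve = t.fit_marey(_gmap(x, 0.6 * x + 0.05 * np.sin(x / 7)), "chr1", df=10)
        assert curve.effective_df == pytest.approx(10, abs=0.5)


class TestRRGrid:
    def test_linear_slope_everywhere(self):
        x = np.linspace(1, 100, 80)
        curve = t.fit_marey(_gmap(x, 0.62 * x), "chr1")
        assert t.rr_at(curve, 37_000_000) == pytest.approx(0.62, abs=1e-3)

    def test_grid_count_and_integral(self):
        x = np.linspace(0.25, 150, 200)
        cm = 0.8 * x
        curve = t.fit_marey(_gmap(x, cm), "chr1")
        profile = t.rr_grid(curve, 150_000_000, step_bp=500_000)
        assert len(profile) == 300
        map_len = cm[-1] - cm[0]
        assert integrate_rr(profile) == pytest.approx(map_len, rel=0.05)

    def test_midpoint_matches_nearest_grid_value(self):
        x = np.linspace(0.25, 100, 150)
        curve = t.fit_marey(_gmap(x, 0.7 * x + 3 * np.sin(x / 15)), "chr1")
        profile = t.rr_grid(curve, 100_000_000, step_bp=500_000)
        pos = 33_400_000
        k = int(np.argmin(np.abs(profile.positions - pos)))
        assert t.rr_at(curve, pos) == pytest.approx(profile.rr[k], abs=0.05)

    def test_position_outside_chromosome_rejected(self):
        x = np.linspace(1, 100, 80)
        curve = t.fit_marey(_gmap(x, 0.5 * x), "chr1")
        layout = t.GenomeLayout(("chr1",), {"chr1": 100_000_000})
        with pytest.raises(MareyError):
            t.rr_at(curve, 200_000_000, layout)


class TestPericentromere:
    def _profile(self, rr, step=500_000, chrom="chr1"):
        rr = np.asarray(rr, float)
        pos = np.arange(step / 2, step * len(rr), step)
        return RRProfile(chrom, pos, rr, step)

    def test_low_rr_plateau_detected(self):
        # RR = 0.1 on [40, 60] Mb, 0.8 elsewhere; centromere at 50 Mb
        rr = np.where((np.arange(200) >= 80) & (np.arange(200) < 120), 0.1, 0.8)
        prof = self._profile(rr)
        region = t.detect_pericentromere(prof, 50_000_000, rho=0.2)
        assert region is not None
        assert region.start == pytest.approx(40_000_001, abs=1)
        assert region.end == pytest.approx(60_000_000, abs=1)
        assert region.contains(50_000_000)

    def test_no_low_region_returns_none(self):
        prof = self._profile(np.full(100, 0.5))
        assert t.detect_pericentromere(prof, 25_000_000, rho=0.2) is None

    def test_matches_brute_force_scan(self, rng):
        for _ in range(50):
            rr = rng.random(80)
            prof = self._profile(rr)
            cen = int(rng.integers(1, prof.step_bp * 80))
            region = t.detect_pericentromere(prof, cen, rho=0.3)
            # brute force: all maximal runs of rr <= rho, pick containing one
            low = rr <= 0.3
            best = None
            i = 0
            while i < len(low):
                if low[i]:
                    j = i
                    while j < len(low) - 0 and j < len(low) and low[j]:
                        j += 1
                    start = int(prof.positions[i] - prof.step_bp / 2) + 1
                    end = int(prof.positions[j - 1] + prof.step_bp / 2)
                    if start <= cen <= end:
                        best = (max(1, start), end)
                    i = j
                else:
                    i += 1
            if best is None:
                assert region is None
            else:
                assert region is not None and (region.start, region.end) == best

    def test_monotone_in_threshold(self, rng):
        rr = rng.random(100)
        prof = self._profile(rr)
        cen = 20_000_000
        r_small = t.detect_pericentromere(prof, cen, rho=0.2)
        r_big = t.detect_pericentromere(prof, cen, rho=0.4)
        if r_small is not None:
            assert r_big is not None
            assert r_big.start <= r_small.start and r_big.end >= r_small.end


class TestRRAssociation:
    def _curves_and_events(self, rng, n=60, rr_by_class=None):
        x = np.linspace(0.25, 150, 200)
        curve = t.fit_marey(_gmap(x, 0.6 * x), "chr1")
        events = []
        for i in range(n):
            size = int(rng.choice([100_000, 400_000, 700_000, 2_000_000]))
            start = int(rng.integers(1, 140_000_000))
            events.append(
                t.IntrogressionEvent(f"e{i}", "chr1", start, start + size - 1, 1, 0.5, 0.5, 0.1)
            )
        return {"chr1": curve}, events

    def test_class_assignment_matches_binning_oracle(self, rng):
        curves, events = self._curves_and_events(rng)
        res = t.rr_event_association(events, curves, size_class_edges_mb=(0.25, 0.5, 1.0))
        for _, row in res["events"].iterrows():
            expect = int(np.digitize(row["size_mb"], [0.25, 0.5, 1.0]))
            assert row["size_class"] == expect

    def test_constant_rr_degenerate(self, rng):
        curves, events = self._curves_and_events(rng)
        res = t.rr_event_association(events, curves)
        # linear Marey curve: all midpoint RR equal, H-statistic collapses
        assert res["H"] == pytest.approx(0.0, abs=1e-6) or res["p"] > 0.9

    def test_planted_shift_detected(self, rng):
        # piecewise curve: low-RR middle; big events planted there
        x = np.linspace(0.5, 150, 200)
        rate = np.where((x > 50) & (x <= 100), 0.1, 1.2)
        cm = np.concatenate([[0], np.cumsum(np.diff(x) * rate[1:])])
        curve = t.fit_marey(_gmap(x, cm), "chr1")
        events = []
        for i in range(25):  # small events in high-RR flanks
            start = int(rng.choice([rng.integers(1e6, 45e6), rng.integers(105e6, 145e6)]))
            events.append(t.IntrogressionEvent(f"s{i}", "chr1", start, start + 150_000, 1, 0.5, 0.5, 0.1))
        for i in range(25):  # large events in the low-RR middle
            start = int(rng.integers(55e6, 95e6))
            events.append(t.IntrogressionEvent(f"l{i}", "chr1", start, start + 1_500_000, 1, 0.5, 0.5, 0.1))
        res = t.rr_event_association(events, {"chr1": curve}, size_class_edges_mb=(0.5,))
        assert res["p"] < 0.01


class TestCompareMaps:
    def test_identical_profiles_degenerate(self):
        rr = np.linspace(0.2, 1.0, 20)
        res = t.compare_maps(rr, rr)
        assert res["degenerate"] and res["p"] == 1.0

    def test_shifted_profile_detected_by_exact_enumeration(self):
        rng = np.random.default_rng(0)
        rr_b = rng.uniform(0.5, 1.5, 20)
        rr_a = rr_b - 0.3
        res = t.compare_maps(rr_a, rr_b, alternative="less")
        assert res["p"] < 0.01
        # exact: all 20 signed ranks negative -> one-sided p = 2^-20
        assert res["p"] == pytest.approx(2.0 ** -20, rel=0.01)

    def test_too_few_positions_rejected(self):
        with pytest.raises(MareyError):
            t.compare_maps(np.ones(3), np.zeros(3))


class TestPericentromereEnrichment:
    def _setup(self):
        layout = t.GenomeLayout(("chr1", "chr2"), {"chr1": 100_000_000, "chr2": 100_000_000},
                                {"chr1": 50_000_000, "chr2": 50_000_000})
        peri = {
            c: t.PericentromericRegion(c, 40_000_001, 60_000_000, 0.2)
            for c in ("chr1", "chr2")
        }
        return layout, peri

    def test_proportional_distribution_gives_zero(self):
        layout, peri = self._setup()
        events = []
        # 20% of genome is pericentromeric: put 2 of 10 events inside
        for i, mid in enumerate([45, 55]):
            events.append(t.IntrogressionEvent(f"in{i}", "chr1", mid * 10**6, mid * 10**6 + 10**6, 1, .5, .5, .1))
        for i, mid in enumerate([5, 10, 15, 20, 25, 70, 80, 90]):
            events.append(t.IntrogressionEvent(f"out{i}", "chr2", mid * 10**6, mid * 10**6 + 10**6, 1, .5, .5, .1))
        res = t.pericentromere_enrichment(events, peri, layout)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_statistic(self):
        layout, peri = self._setup()
        events = []
        for i in range(18):  # inside
            events.append(t.IntrogressionEvent(f"in{i}", "chr1", 45_000_000 + i, 45_000_100 + i * 2, 1, .5, .5, .1))
        for i in range(14):  # outside
            events.append(t.IntrogressionEvent(f"out{i}", "chr2", 5_000_000 + i, 5_000_100 + i * 2, 1, .5, .5, .1))
        res = t.pericentromere_enrichment(events, peri, layout)
        frac = 40_000_000 / 200_000_000
        e_in, e_out = 32 * frac, 32 * (1 - frac)
        chi2 = (18 - e_in) ** 2 / e_in + (14 - e_out) ** 2 / e_out
        assert res["chi2"] == pytest.approx(chi2, abs=1e-9)
        assert res["df"] == 1

    def test_zero_events_rejected(self):
        layout, peri = self._setup()
        with pytest.raises(MareyError):
            t.pericentromere_enrichment([], peri, layout)


def test_rr_integral_matches_map_length_on_simulation(f2_matrix):
    """End-to-end: simulated F2 -> map -> Marey -> integral vs map length."""
    mat, _ = f2_matrix
    clean, _ = t.clean_genotypes(t.filter_markers(mat))
    gmap = t.build_map(clean)
    for chrom, grp in gmap.groupby("chrom"):
        curve = t.fit_marey(gmap, chrom)
        length_bp = int(grp["pos_bp"].max()) + 1000
        profile = t.rr_grid(curve, length_bp, step_bp=500_000)
        assert integrate_rr(profile) == pytest.approx(
            float(grp["pos_cM"].max()), rel=0.08
        )
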