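"""Marker filtering, genotype cleaning, EM recombination fractions, Kosambi."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import teointro as t
from teointro.io import F2GenotypeMatrix
from teointro.linkage import (
    LinkageError,
    LowInformationWarning,
    a_allele_frequency,
    collapse_duplicate_markers,
    est_recfrac,
    f2_joint_probabilities,
    f2_log_likelihood,
    map_summary,
    two_locus_counts,
)


def _matrix(columns, positions=None, chrom="chr1"):
    """Matrix from per-marker call strings, e.g. ['AAB', 'HHB']."""
    calls = np.array([list(c) for c in columns], dtype="<U1").T
    n_mark = len(columns)
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_mark)]
    return F2GenotypeMatrix(
        calls, [f"m{i}" for i in range(n_mark)],
        np.array([chrom] * n_mark, object), np.array(positions),
    )


class TestFilterMarkers:
    def test_monomorphic_marker_removed(self):
        mat = _matrix(["A" * 20, "AABBHH" + "AB" * 7])
        out = t.filter_markers(mat, min_spacing_bp=1)
        assert out.markers == ["m1"]

    def test_greedy_thinning(self):
        mat = _matrix(["AB" * 5, "BA" * 5, "AH" * 5], positions=[1000, 1500, 2100])
        out = t.filter_markers(mat, min_spacing_bp=1000)
        assert [p for p in out.pos] == [1000, 2100]

    def test_matches_brute_force_frequency_filter(self, rng):
        calls = rng.choice(list("ABH-"), size=(60, 200), p=[0.3, 0.3, 0.3, 0.1])
        mat = F2GenotypeMatrix(
            calls, [f"m{i}" for i in range(200)],
            np.array(["chr1"] * 200, object),
            np.arange(1, 201) * 5000,  # spacing larger than threshold
        )
        out = t.filter_markers(mat, min_spacing_bp=1000)
        freq = a_allele_frequency(mat)
        expect = [mat.markers[j] for j in range(200) if 0.2 < freq[j] < 0.8]
        assert out.markers == expect

    def test_all_removed_is_error(self):
        with pytest.raises(LinkageError):
            t.filter_markers(_matrix(["A" * 10, "B" * 10]))


class TestCleanGenotypes:
    def test_flanked_missing_fill(self):
        calls = np.array([["A", "-", "A"]], dtype="<U1")
        mat = F2GenotypeMatrix(calls, ["m0", "m1", "m2"],
                               np.array(["chr1"] * 3, object), np.array([1, 2, 3]) * 1000)
        out, rep = t.clean_genotypes(mat)
        assert out.calls[0].tolist() == ["A", "A", "A"]
        assert rep.n_filled == 1

    def test_interspersed_allele_correction(self):
        calls = np.array([["H", "A", "H"]], dtype="<U1")
        mat = F2GenotypeMatrix(calls, ["m0", "m1", "m2"],
                               np.array(["chr1"] * 3, object), np.array([1, 2, 3]) * 1000)
        out, rep = t.clean_genotypes(mat, max_hap=6)
        assert out.calls[0].tolist() == ["H", "H", "H"]
        assert rep.n_corrected == 1

    def test_long_runs_untouched(self):
        seq = ["H"] + ["A"] * 6 + ["H"]  # run of 6 not shorter than max_hap
        calls = np.array([seq], dtype="<U1")
        mat = F2GenotypeMatrix(calls, [f"m{i}" for i in range(8)],
                               np.array(["chr1"] * 8, object), np.arange(1, 9) * 1000)
        out, _ = t.clean_genotypes(mat, max_hap=6)
        assert out.calls[0].tolist() == seq

    def test_matches_reference_scan_implementation(self, rng):
        def reference_clean(seq, max_hap):
            """Index-scanning re-implementation, snapshot per pass."""

            def one_rule(seq, rule):
                snap = list(seq)
                out = list(seq)
                i = 0
                while i < len(snap):
                    j = i
                    while j < len(snap) and snap[j] == snap[i]:
                        j += 1
                    if 0 < i and j < len(snap):
                        left, right, sym = snap[i - 1], snap[j], snap[i]
                        if rule == "fill" and sym == "-" and left == right != "-":
                            out[i:j] = [left] * (j - i)
                        if (
                            rule == "flip" and sym != "-" and left == right
                            and left not in (sym, "-") and j - i < max_hap
                        ):
                            out[i:j] = [left] * (j - i)
                    i = j
                return out

            seq = list(seq)
            while True:
                before = list(seq)
                seq = one_rule(seq, "fill")
                seq = one_rule(seq, "flip")
                if seq == before:
                    return seq

        for _ in range(30):
            n_mark = int(rng.integers(5, 40))
            seq = rng.choice(list("ABH"), size=n_mark)
            seq[rng.random(n_mark) < 0.05] = "-"
            err = rng.random(n_mark) < 0.05
            calls = seq.copy()
            calls[err] = rng.choice(list("ABH"), size=int(err.sum()))
            mat = F2GenotypeMatrix(
                calls[None, :].astype("<U1"), [f"m{i}" for i in range(n_mark)],
                np.array(["chr1"] * n_mark, object), np.arange(1, n_mark + 1) * 1000,
            )
            out, _ = t.clean_genotypes(mat, max_hap=6)
            assert out.calls[0].tolist() == reference_clean(calls.tolist(), 6)

    def test_near_identity_on_error_free_data(self, small_layout):
        # without recombination there is nothing to correct: exact identity
        tm0 = t.true_map_table(small_layout, markers_per_chrom=40, map_length_cM=0, rng=3)
        mat0, _ = t.simulate_f2(tm0, n=100, error_rate=0.0, missing_rate=0.0, seed=5)
        out0, rep0 = t.clean_genotypes(mat0)
        assert np.array_equal(out0.calls, mat0.calls)
        assert rep0.n_filled == 0 and rep0.n_corrected == 0
        # with recombination, the only error-free changes are genuine short
        # double crossovers, which are rare: well under 1% of calls
        tm = t.true_map_table(small_layout, markers_per_chrom=80, map_length_cM=100, rng=3)
        mat, _ = t.simulate_f2(tm, n=100, error_rate=0.0, missing_rate=0.0, seed=5)
        out, _ = t.clean_genotypes(mat)
        assert (out.calls != mat.calls).mean() < 0.01


class TestEstRecfrac:
    def grid_search(self, counts, step=0.0005):
        grid = np.arange(0.0, 0.5 + step, step)
        ll = [f2_log_likelihood(counts, r) for r in grid]
        return float(grid[int(np.argmax(ll))])

    def test_no_recombinants_gives_zero(self):
        g1 = np.array(list("AABB" * 10 + "HH" * 10))
        r = est_recfrac(two_locus_counts(g1, g1))
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_independence_gives_half(self):
        # counts exactly at the r = 0.5 F2 expectation (x16)
        counts = f2_joint_probabilities(0.5) * 16 * 16
        assert est_recfrac(counts) == pytest.approx(0.5, abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        for true_r in (0.05, 0.15, 0.3, 0.45):
            p = f2_joint_probabilities(true_r)
            counts = rng.multinomial(100, p.ravel()).reshape(3, 3)
            r_em = est_recfrac(counts)
            r_grid = self.grid_search(counts)
            assert r_em == pytest.approx(r_grid, abs=5e-4)

    def test_symmetric_in_locus_order(self, rng):
        p = f2_joint_probabilities(0.2)
        counts = rng.multinomial(200, p.ravel()).reshape(3, 3)
        assert est_recfrac(counts) == pytest.approx(est_recfrac(counts.T), abs=1e-10)

    def test_em_likelihood_nondecreasing(self):
        counts = np.array([[20, 5, 1], [6, 30, 4], [2, 5, 27]])
        r = 0.25
        ll_prev = f2_log_likelihood(counts, r)
        for _ in range(50):
            denom = r * r + (1 - r) * (1 - r)
            known = float((counts * np.where(np.array([[0,1,2],[1,0,1],[2,1,0]]) >= 0,
                                             np.array([[0,1,2],[1,0,1],[2,1,0]]), 0)).sum())
            e_hh = 2 * counts[1, 1] * (r * r / denom)
            r = min(max((known + e_hh) / (2 * counts.sum()), 0.0), 0.5)
            ll = f2_log_likelihood(counts, r)
            assert ll >= ll_prev - 1e-9
            ll_prev = ll

    def test_small_table_warns_empty_errors(self):
        with pytest.warns(LowInformationWarning):
            est_recfrac(np.array([[2, 0, 0], [0, 2, 0], [0, 0, 2]]))
        with pytest.raises(LinkageError):
            est_recfrac(np.zeros((3, 3)))


class TestKosambi:
    def test_closed_form_values(self):
        assert t.kosambi_cM(0.0) == 0.0
        assert t.kosambi_cM(0.2) == pytest.approx(21.18, abs=5e-3)
        assert t.inverse_kosambi(25.0) == pytest.approx(0.2311, abs=5e-5)

    def test_half_is_infinite_distance(self):
        with pytest.raises(LinkageError):
            t.kosambi_cM(0.5)

    @given(st.floats(0, 0.499))
    @settings(deadline=None)
    def test_mutually_inverse(self, r):
        assert t.inverse_kosambi(t.kosambi_cM(r)) == pytest.approx(r, abs=1e-10)


class TestBuildMap:
    def test_identical_markers_collapse_to_zero(self):
        col = "AB" * 10 + "HH"
        mat = _matrix([col, col])
        gmap = t.build_map(mat)
        assert gmap["pos_cM"].tolist() == [0.0]  # duplicate collapsed

    def test_closed_form_kosambi_chain(self, rng):
        # three markers with adjacent-pair r-hat 0.1, 0.1 (planted exactly)
        # by constructing count tables via monkeypatched estimation is
        # fragile; instead verify the chain arithmetic directly
        d = t.kosambi_cM(0.1)
        assert [0.0, d, 2 * d] == pytest.approx([0.0, 10.14, 20.27], abs=5e-3)

    def test_map_positions_nondecreasing(self, f2_matrix):
        mat, _ = f2_matrix
        clean, _ = t.clean_genotypes(t.filter_markers(mat))
        gmap = t.build_map(clean)
        for _, grp in gmap.groupby("chrom"):
            assert (np.diff(grp["pos_cM"]) >= 0).all()
            assert grp["pos_cM"].iloc[0] == 0.0

    def test_duplicate_collapse_preserves_length(self, f2_matrix):
        mat, _ = f2_matrix
        clean, _ = t.clean_genotypes(t.filter_markers(mat))
        with_dup = t.build_map(clean, collapse_duplicates=False)
        without = t.build_map(clean, collapse_duplicates=True)
        a = map_summary(with_dup).set_index("chrom")["map_length_cM"]
        b = map_summary(without).set_index("chrom")["map_length_cM"]
        assert np.allclose(a, b, rtol=0.02, atol=0.5)

    def test_recovers_simulated_map_length(self, small_layout):
        # dense-marker F2: estimated length within 15% of the true 150 cM
        layout = t.GenomeLayout(("chr1",), {"chr1": 150_000_000})
        tm = t.true_map_table(layout, markers_per_chrom=300, map_length_cM=150, rng=5)
        lengths = []
        for seed in range(20):
            mat, _ = t.simulate_f2(
                tm, n=170, error_rate=0.01, missing_rate=0.05, seed=seed
            )
            clean, _ = t.clean_genotypes(t.filter_markers(mat))
            lengths.append(float(t.build_map(clean)["pos_cM"].max()))
        assert np.all(np.abs(np.array(lengths) - 150) / 150 <= 0.15)
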