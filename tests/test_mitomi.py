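"""Relative-affinity fitting, slope statistics, library ranking and
H-box scanning (with a brute-force oracle)."""

import re
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from segclock.mitomi import (
    ALL_CACNNN,
    BindingSeries,
    HBoxHit,
    RelativeAffinity,
    compare_slopes,
    fit_relative_affinity,
    normalize_set,
    rank_library,
    read_binding_tsv,
    scan_hbox,
    write_bed,
)


def _series(free, bound, probe="p"):
    return BindingSeries(probe, tuple(free), tuple(bound))


class TestFitRelativeAffinity:
    def test_exact_line(self):
        free = [1.0, 2.0, 4.0, 8.0]
        aff = fit_relative_affinity(_series(free, [0.5 * f for f in free]))
        assert aff.slope == pytest.approx(0.5)
        assert aff.stderr == pytest.approx(0.0, abs=1e-12)
        assert aff.r_squared == pytest.approx(1.0)

    def test_intercept_does_not_bias_slope(self):
        free = [1.0, 2.0, 4.0, 8.0]
        aff = fit_relative_affinity(_series(free, [7.0 + 0.5 * f for f in free]))
        assert aff.slope == pytest.approx(0.5)

    def test_slope_ratio_recovers_affinity_ratio(self):
        # two noise-free series with true relative K_d ratio 4:1
        free = np.geomspace(1.0, 50.0, 6)
        a = fit_relative_affinity(_series(free, 2.0 * free, "strong"))
        b = fit_relative_affinity(_series(free, 0.5 * free, "weak"))
        assert a.slope / b.slope == pytest.approx(4.0)

    def test_non_binder_has_zero_slope(self):
        aff = fit_relative_affinity(_series([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]))
        assert aff.slope == 0.0

    def test_max_free_drops_saturating_points(self):
        free = [1.0, 2.0, 4.0, 8.0, 100.0]
        bound = [0.5, 1.0, 2.0, 4.0, 5.0]  # last point saturates
        aff = fit_relative_affinity(_series(free, bound), max_free=10.0)
        assert aff.slope == pytest.approx(0.5)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_relative_affinity(_series([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            _series([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            _series([1.0, 2.0, 3.0], [1.0, -2.0, 3.0])


class TestNormalizeSet:
    def test_strongest_slope_becomes_one(self):
        affs = [RelativeAffinity(str(s), s, 0.01, 1.0) for s in (2.0, 1.0, 0.5)]
        norm = normalize_set(affs)
        assert [a.normalized for a in norm] == pytest.approx([1.0, 0.5, 0.25])

    def test_single_element_normalizes_to_one(self):
        assert normalize_set([RelativeAffinity("x", 3.0, 0.1, 1.0)])[0].normalized == 1.0

    def test_negative_slope_clamped_with_warning(self):
        affs = [RelativeAffinity("a", 1.0, 0.1, 1.0),
                RelativeAffinity("b", -0.2, 0.1, 0.5)]
        with pytest.warns(UserWarning, match="clamped"):
            norm = normalize_set(affs)
        assert norm[1].normalized == 0.0

    def test_all_zero_set_rejected(self):
        with pytest.raises(ValueError):
            normalize_set([RelativeAffinity("a", 0.0, 0.1, 0.0)])

    @given(factor=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, factor):
        # a common scaling of all signals leaves normalized affinities
        # unchanged (slopes scale, ratios do not)
        free = np.array([1.0, 2.0, 4.0, 8.0])
        sets = []
        for scale in (1.0, factor):
            affs = [
                fit_relative_affinity(
                    _series(scale * free, scale * s * free, probe=str(s))
                )
                for s in (1.5, 0.75, 0.3)
            ]
            sets.append([a.normalized for a in normalize_set(affs)])
        assert sets[0] == pytest.approx(sets[1], rel=1e-9)


class TestCompareSlopes:
    def test_identical_slopes_give_p_one(self):
        a = RelativeAffinity("a", 1.0, 0.1, 1.0)
        assert compare_slopes(a, a) == pytest.approx(1.0)

    def test_huge_separation_is_significant(self):
        a = RelativeAffinity("a", 1.0, 0.01, 1.0)
        b = RelativeAffinity("b", 0.0, 0.01, 1.0)
        assert compare_slopes(a, b) < 1e-10

    def test_overlapping_fits_not_significant(self):
        # z = 0.1/sqrt(0.5) ~ 0.14: clearly non-significant
        a = RelativeAffinity("a", 1.0, 0.5, 1.0)
        b = RelativeAffinity("b", 0.9, 0.5, 1.0)
        p = compare_slopes(a, b)
        assert p > 0.05
        assert p == pytest.approx(0.8875, abs=1e-3)

    def test_degenerate_stderr_rejected(self):
        a = RelativeAffinity("a", 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            compare_slopes(a, a)


class TestRankLibrary:
    def test_consensus_family_and_top_hexamer(self):
        affs = []
        for mer in ALL_CACNNN:
            if mer == "CACGTG":
                slope = 1.0
            elif mer == "CACGCG":
                slope = 0.85
            elif mer[3] == "G" and mer[5] == "G":
                slope = 0.5
            else:
                slope = 0.08
            affs.append(RelativeAffinity(mer, slope, 0.01, 1.0))
        table, family, best = rank_library(affs)
        assert family == "CACGNG"
        assert best == "CACGTG"
        assert len(table) == 64

    def test_uniform_library_has_no_consensus(self):
        affs = [RelativeAffinity(m, 1.0, 0.01, 1.0) for m in ALL_CACNNN]
        _, family, _ = rank_library(affs)
        assert family is None

    def test_per_sequence_ranking_is_retained(self):
        # CACGCG strongest: ranking must not be collapsed into families
        affs = [
            RelativeAffinity(m, 1.0 if m == "CACGCG" else 0.2, 0.01, 1.0)
            for m in ALL_CACNNN
        ]
        table, _, best = rank_library(affs)
        assert best == "CACGCG"
        assert table.iloc[0]["probe_id"] == "CACGCG"

    def test_incomplete_library_rejected(self):
        affs = [RelativeAffinity(m, 1.0, 0.01, 1.0) for m in ALL_CACNNN[:-1]]
        with pytest.raises(ValueError, match="incomplete"):
            rank_library(affs)


def brute_force_hbox(seq: str, strict: bool = False):
    """Independent oracle: regex scan of every 6-mer window on both
    strands, collapsing palindromic duplicates to the + strand."""
    comp = str.maketrans("ACGTN", "TGCAN")
    pattern = re.compile("CACG[TC]G" if strict else "CACG[ACGTN]G")
    hits = set()
    for p in range(len(seq) - 5):
        window = seq[p : p + 6]
        fwd = bool(pattern.fullmatch(window))
        if fwd:
            hits.add((p, "+"))
        rc = window.translate(comp)[::-1]
        if pattern.fullmatch(rc):
            if fwd and rc == window:
                continue
            hits.add((p, "-"))
    return hits


class TestScanHbox:
    def test_hes6_promoter_twelve_mer(self):
        hits = scan_hbox("ACTCACGTGAGA")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (0, 12, "+")
        assert h.twelve_mer == "ACTCACGTGAGA"
        assert h.core == "CACGTG"

    def test_motif_free_sequence(self):
        assert scan_hbox("A" * 12) == []

    def test_minus_strand_core(self):
        hits = scan_hbox("AAAACGCGTGAAAA")
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].core == "CACGCG"

    def test_palindromic_core_reported_once_on_plus(self):
        hits = scan_hbox("AAACACGTGAAA")
        assert len(hits) == 1
        assert hits[0].strand == "+"

    def test_edge_hits_are_n_padded(self):
        hits = scan_hbox("CACGAGAAAAAA")
        h = next(h for h in hits if h.strand == "+")
        assert h.start == -3
        assert h.twelve_mer == "NNNCACGAGAAA"
        assert h.end - h.start == 12

    def test_strict_mode_requires_t_or_c(self):
        seq = "AAACACGAGAAAACACGTGAAA"
        assert len(scan_hbox(seq)) >= 2
        strict = scan_hbox(seq, strict=True)
        assert all(h.core[4] in "TC" for h in strict)
        assert not any(h.core == "CACGAG" for h in strict)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            scan_hbox("ACGTACGTXXXX")
        with pytest.raises(ValueError):
            scan_hbox("ACGT")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("strict", [False, True])
    def test_matches_brute_force_on_random_sequence(self, seed, strict):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        hits = {(h.start + 3, h.strand) for h in scan_hbox(seq, strict=strict)}
        assert hits == brute_force_hbox(seq, strict=strict)


class TestIO:
    def test_binding_tsv_round_trip(self, tmp_path):
        path = tmp_path / "binding.tsv"
        path.write_text(
            "probe_id\tfree\tbound\n"
            "p1\t1\t0.5\np1\t2\t1.0\np1\t4\t2.0\n"
            "p2\t1\t0.1\np2\t2\t0.2\np2\t4\t0.4\n"
        )
        series = read_binding_tsv(path)
        assert [s.probe_id for s in series] == ["p1", "p2"]
        assert fit_relative_affinity(series[0]).slope == pytest.approx(0.5)

    def test_bed_output(self, tmp_path):
        hits = scan_hbox("ACTCACGTGAGA", contig="hes6_up")
        path = tmp_path / "hits.bed"
        write_bed(hits, path, scores={"ACTCACGTGAGA": 0.137})
        assert path.read_text() == "hes6_up\t0\t12\tACTCACGTGAGA\t137\t+\n"

    def test_hbox_hit_invariants(self):
        with pytest.raises(ValueError):
            HBoxHit("c", 0, 11, "+", "ACTCACGTGAG", "CACGTG")
        with pytest.raises(ValueError):
            HBoxHit("c", 0, 12, "+", "ACTAAAAAAAGA", "AAAAAA")
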