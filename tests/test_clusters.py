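"""Greedy enhancer-module detection against brute-force window enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisclust.catalog import TFClass, load_paper_catalog
from cisclust.clusters import (
    ClusterConfig,
    best_window,
    find_modules,
    summarize_modules,
    write_modules_bed,
    write_modules_tsv,
)
from cisclust.scanner import BindingSiteHit, UpstreamRegion, collapse_hits, scan_region
from conftest import brute_force_best_count, interval_jaccard, random_dna


def hit(start, tf, region_id="R", length=8):
    return BindingSiteHit(
        region_id=region_id,
        start=start,
        end=start + length - 1,
        tf_class=tf,
        strand="+",
        matched_seq="A" * length,
        dissimilarity_percent=0.0,
        pattern="N" * length if length != 8 else "TGACGTCA",
    )


def random_hits(rng, n, region_length=1500):
    tfs = list(TFClass)
    return [
        hit(int(rng.integers(1, region_length - 8)), tfs[int(rng.integers(6))])
        for _ in range(n)
    ]


class TestBestWindow:
    def test_picks_densest_left_cluster(self):
        hits = [
            hit(10, TFClass.LEF1),
            hit(50, TFClass.POU3F2),
            hit(60, TFClass.USF1),
            hit(900, TFClass.FOXD3),
        ]
        found = best_window(hits, 200)
        assert found is not None
        (s, e), members = found
        assert len(members) == 3
        assert {h.start for h in members} == {10, 50, 60}

    def test_single_class_never_qualifies(self):
        hits = [hit(10, TFClass.MITF), hit(50, TFClass.MITF)]
        assert best_window(hits, 200) is None

    def test_empty_input(self):
        assert best_window([], 200) is None

    def test_excluded_interval_removes_hits(self):
        hits = [hit(10, TFClass.LEF1), hit(50, TFClass.USF1)]
        assert best_window(hits, 200, excluded=[(1, 100)]) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_rank1_count_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        hits = random_hits(rng, int(rng.integers(2, 31)))
        expected = brute_force_best_count(hits, 200)
        found = best_window(hits, 200)
        if expected is None:
            assert found is None
        else:
            assert found is not None and len(found[1]) == expected

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_adding_a_hit_never_decreases_rank1_count(self, seed):
        rng = np.random.default_rng(seed)
        hits = random_hits(rng, int(rng.integers(2, 15)))
        extra = random_hits(rng, 1)
        before = best_window(hits, 200)
        after = best_window(hits + extra, 200)
        n_before = len(before[1]) if before else 0
        n_after = len(after[1]) if after else 0
        assert n_after >= n_before


class TestFindModules:
    def test_three_separated_clusters_ranked_by_size(self):
        clusters = {
            1: [TFClass.MITF, TFClass.USF1],
            500: [TFClass.LEF1, TFClass.CREB, TFClass.FOXD3],
            1100: [TFClass.POU3F2, TFClass.USF1, TFClass.LEF1, TFClass.MITF],
        }
        hits = [
            hit(base + 40 * i, tf)
            for base, tfs in clusters.items()
            for i, tf in enumerate(tfs)
        ]
        mods = find_modules(hits, ClusterConfig(), region_length=1500)
        assert [m.n_sites for m in mods] == [4, 3, 2]
        assert [m.rank for m in mods] == [1, 2, 3]
        assert mods[0].start >= 1100

    def test_fewer_qualifying_clusters_than_k(self):
        hits = [hit(10, TFClass.MITF), hit(40, TFClass.USF1)]
        mods = find_modules(hits, ClusterConfig(), region_length=1500)
        assert len(mods) == 1

    def test_trim_to_span_reports_minimal_interval(self):
        hits = [hit(100, TFClass.MITF), hit(150, TFClass.USF1)]
        (mod,) = find_modules(hits, ClusterConfig(), region_length=1500)
        assert (mod.start, mod.end) == (100, 157)

    def test_tyr_style_fixture_recovers_three_planted_windows(self, catalog):
        """Three clusters laid out like a real promoter's (distal, mid, proximal)."""
        rng = np.random.default_rng(123)
        planted = {
            (1, 200): ["ATGCAAAT", "CACGTG", "CTTTGAT", "TGTTTGT"],
            (410, 640): ["TGTTTGT", "CTTTGAT", "CACGTG", "ATGCAAAT"],
            (1210, 1410): ["TGACGTCA", "CATGTG", "ATGCAAAT", "CACGTG"],
        }
        seq = list("C" * 1500)  # poly-C background has no catalog matches
        for (ws, we), patterns in planted.items():
            span = we - ws + 1
            for i, pat in enumerate(patterns):
                off = round(i * (span - 8) / 3)
                seq[ws - 1 + off : ws - 1 + off + len(pat)] = pat
        hits = collapse_hits(scan_region(UpstreamRegion("TYR", "".join(seq)), catalog))
        mods = find_modules(hits, ClusterConfig(), region_length=1500)
        assert len(mods) == 3
        for window in planted:
            overlapping = [
                m for m in mods if interval_jaccard(window, (m.start, m.end)) >= 0.5
            ]
            assert len(overlapping) == 1

    def test_modules_never_overlap(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            hits = random_hits(rng, int(rng.integers(5, 40)))
            mods = find_modules(hits, ClusterConfig(), region_length=1500)
            for a in mods:
                for b in mods:
                    if a is not b:
                        assert a.end < b.start or b.end < a.start

    def test_mixed_region_ids_rejected(self):
        with pytest.raises(ValueError):
            find_modules([hit(1, TFClass.MITF, "A"), hit(50, TFClass.USF1, "B")])


class TestSummarize:
    def test_nine_by_three_totals_27(self):
        mods = {
            f"G{i}": find_modules(
                [
                    hit(base + 30 * j, tf, region_id=f"G{i}")
                    for base in (1, 500, 1100)
                    for j, tf in enumerate([TFClass.MITF, TFClass.USF1])
                ],
                ClusterConfig(),
                region_length=1500,
            )
            for i in range(9)
        }
        summary = summarize_modules(mods)
        assert summary.total_modules == 27
        assert all(c == 3 for c in summary.per_region_counts.values())

    def test_empty_study(self):
        assert summarize_modules({}).total_modules == 0

    def test_region_tf_union(self):
        mods = {
            "R": find_modules(
                [
                    hit(1, TFClass.MITF),
                    hit(40, TFClass.USF1),
                    hit(500, TFClass.LEF1),
                    hit(540, TFClass.FOXD3),
                    hit(580, TFClass.POU3F2),
                ],
                ClusterConfig(),
                region_length=1500,
            )
        }
        summary = summarize_modules(mods)
        assert len(summary.region_tf_union("R")) == 5


def test_bed_and_tsv_export(tmp_path):
    hits = [hit(100, TFClass.MITF), hit(150, TFClass.USF1)]
    mods = find_modules(hits, ClusterConfig(), region_length=1500)
    bed = tmp_path / "m.bed"
    tsv = tmp_path / "m.tsv"
    write_modules_bed(mods, bed)
    write_modules_tsv(mods, tsv)
    bed_line = bed.read_text().splitlines()[0].split("\t")
    assert bed_line[:4] == ["R", "99", "157", "R.1"]  # 0-based half-open
    assert "MITF,USF1" in bed_line[4]
    assert tsv.read_text().splitlines()[1].split("\t")[2:5] == ["100", "157", "2"]
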