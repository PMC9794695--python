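"""Sliding windows, window calls, consolidation and crossover detection."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apoclone import (
    ChromosomeMap,
    CrossoverModel,
    GenotypeClass,
    ReproductionConfig,
    SeqSimConfig,
    WindowThresholds,
    build_landscape,
    call_window,
    consolidate,
    detect_crossovers,
    make_f1,
    make_marker_map,
    make_windows,
    simulate_meiotic_gamete,
    simulate_progeny,
    simulate_reads,
)
from apoclone.core import Haplotype, ProgenyGenome
from apoclone.landscape import GenotypeLandscape, Segment, smooth_classes
import pandas as pd


def landscape_from_classes(classes, chrom="c", window=200_000, step=100_000):
    """Build a synthetic landscape directly from window class labels."""
    starts = np.arange(len(classes)) * step
    frame = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + window,
        "index": np.arange(len(classes)), "n_markers": 10,
        "reads_P1": 10, "reads_P2": 10, "f": 0.5,
        "class": list(classes),
    })
    return GenotypeLandscape(sample_id="synthetic", frame=frame,
                             window=window, step=step)


class TestMakeWindows:
    def test_exact_multiple(self):
        cm = ChromosomeMap(names=("c",), lengths=(1_000_000,))
        ws = make_windows(cm)
        assert len(ws) == 9
        assert [w.start for w in ws] == list(range(0, 900_000, 100_000))
        assert all(w.end - w.start == 200_000 for w in ws)

    def test_single_window_chromosome(self):
        cm = ChromosomeMap(names=("c",), lengths=(200_000,))
        ws = make_windows(cm)
        assert len(ws) == 1 and ws[0].start == 0 and ws[0].end == 200_000

    def test_trailing_remainder_merged(self):
        cm = ChromosomeMap(names=("c",), lengths=(1_050_000,))
        ws = make_windows(cm)
        assert len(ws) == 9
        assert (ws[-1].start, ws[-1].end) == (800_000, 1_050_000)

    def test_step_larger_than_window_errors(self):
        cm = ChromosomeMap(names=("c",), lengths=(1_000_000,))
        with pytest.raises(ValueError):
            make_windows(cm, window=100_000, step=200_000)

    def test_starts_are_step_multiples(self):
        cm = ChromosomeMap.rice(scale=0.1)
        ws = make_windows(cm)
        assert all(w.start % 100_000 == 0 for w in ws)


class TestCallWindow:
    @pytest.fixture()
    def setup(self):
        cm = ChromosomeMap(names=("c",), lengths=(200_000,))
        mm = make_marker_map(cm, 20, seed=0)
        w = make_windows(cm)[0]
        return mm, w

    def place(self, mm, total_p1, total_p2):
        p1 = np.zeros(mm.n_markers, dtype=np.int64)
        p2 = np.zeros(mm.n_markers, dtype=np.int64)
        p1[: total_p1] = 1
        p2[mm.n_markers - total_p2:] = 1
        return p1, p2

    @pytest.mark.parametrize("reads,expected", [
        ((12, 0), GenotypeClass.HOM_P1),
        ((7, 6), GenotypeClass.HET),
        ((0, 12), GenotypeClass.HOM_P2),
        ((3, 1), GenotypeClass.NO_CALL),  # total 4 < default min_reads 5
    ])
    def test_classification(self, setup, reads, expected):
        mm, w = setup
        p1, p2 = self.place(mm, *reads)
        call = call_window(p1, p2, mm, w)
        assert call.klass == expected
        assert (call.reads_p1, call.reads_p2) == reads


class TestBuildLandscape:
    def test_clone_is_all_het(self, small_markers, f1):
        p1, p2 = simulate_reads(f1, small_markers, SeqSimConfig(10.0, 0.0), seed=0)
        ls = build_landscape("clone", p1, p2, small_markers,
                             make_windows(small_markers.chrom_map))
        called = ls.frame[ls.frame["class"] != "NO_CALL"]
        assert len(called) > 0 and (called["class"] == "HET").all()

    def test_homozygous_chromosome_all_hom_p1(self, small_markers):
        from apoclone.pipeline import _homozygous_parent

        g = _homozygous_parent(small_markers, 0)
        p1, p2 = simulate_reads(g, small_markers, SeqSimConfig(10.0, 0.0), seed=1)
        ls = build_landscape("hom", p1, p2, small_markers,
                             make_windows(small_markers.chrom_map))
        called = ls.frame[ls.frame["class"] != "NO_CALL"]
        assert (called["class"] == "HOM_P1").all()

    def test_f2_crossover_changes_class(self, small_markers, f1):
        prog = simulate_progeny(f1, small_markers, ReproductionConfig("SEXUAL"),
                                1, seed=6)[0]
        p1, p2 = simulate_reads(prog, small_markers, SeqSimConfig(10.0, 0.0), seed=2)
        ls = build_landscape("f2", p1, p2, small_markers,
                             make_windows(small_markers.chrom_map))
        assert ls.frame["class"].nunique() > 1

    def test_tetraploid_clone_looks_heterozygous(self, small_markers, f1):
        """Unrecombined tetraploids give the same all-HET landscape as clones:
        ploidy cannot come from the landscape."""
        tetra = simulate_progeny(f1, small_markers, ReproductionConfig("MIME_ONLY"),
                                 1, seed=7)[0]
        p1, p2 = simulate_reads(tetra, small_markers, SeqSimConfig(10.0, 0.002), seed=3)
        ls = build_landscape("tetra", p1, p2, small_markers,
                             make_windows(small_markers.chrom_map))
        called = ls.frame[ls.frame["class"] != "NO_CALL"]
        assert (called["class"] == "HET").all()

    def test_higher_depth_never_more_no_calls(self, f1):
        """Raising mean depth from 1.9x to 14.3x does not increase NO_CALL
        windows on the same genome (sparse map so NO_CALL occurs at 1.9x)."""
        cm = ChromosomeMap(names=("c",), lengths=(20_000_000,))
        mm = make_marker_map(cm, 600, seed=8)  # ~6 markers per 200 kb window
        clone = make_f1(mm)
        ws = make_windows(cm)
        counts = {}
        for depth in (1.9, 14.3):
            p1, p2 = simulate_reads(clone, mm, SeqSimConfig(depth, 0.002), seed=4)
            ls = build_landscape("s", p1, p2, mm, ws)
            counts[depth] = int((ls.frame["class"] == "NO_CALL").sum())
        assert counts[1.9] > 0  # the comparison is informative
        assert counts[14.3] <= counts[1.9]


def brute_force_segments(classes, starts, ends, chrom="c"):
    """Independent oracle: smoothing + maximal constant runs by enumeration."""
    NC = "NO_CALL"
    c = list(classes)
    sm = list(c)
    for i in range(1, len(c) - 1):
        if c[i - 1] == c[i + 1] and c[i] != c[i - 1] and c[i - 1] != NC:
            sm[i] = c[i - 1]
    # absorb NO_CALL runs with agreeing callable flanks
    filled = list(sm)
    i = 0
    while i < len(filled):
        if filled[i] == NC:
            j = i
            while j < len(filled) and filled[j] == NC:
                j += 1
            left = filled[i - 1] if i > 0 else None
            right = filled[j] if j < len(filled) else None
            if left is not None and left == right and left != NC:
                for k in range(i, j):
                    filled[k] = left
            i = j
        else:
            i += 1
    segs = []
    for i, k in enumerate(filled):
        if k == NC:
            continue
        if segs and segs[-1][2] == k and segs[-1][1] == i - 1:
            segs[-1] = (segs[-1][0], i, k)
        else:
            segs.append((i, i, k))
    return [Segment(chrom=chrom, start=int(starts[a]), end=int(ends[b]),
                    klass=k, n_windows=b - a + 1) for a, b, k in segs]


class TestConsolidate:
    def test_constant_run_single_segment(self):
        segs = consolidate(landscape_from_classes(["HET"] * 3))
        assert len(segs) == 1 and segs[0].klass == "HET"
        assert (segs[0].start, segs[0].end) == (0, 400_000)

    def test_isolated_flip_smoothed_away(self):
        segs = consolidate(landscape_from_classes(["HET", "HET", "HOM_P1", "HET", "HET"]))
        assert len(segs) == 1 and segs[0].klass == "HET"

    def test_true_transition_kept(self):
        segs = consolidate(landscape_from_classes(
            ["HET", "HET", "HOM_P1", "HOM_P1", "HOM_P1"]))
        assert [s.klass for s in segs] == ["HET", "HOM_P1"]
        events = detect_crossovers(segs)
        assert len(events) == 1

    def test_no_call_absorbed_when_flanks_agree(self):
        segs = consolidate(landscape_from_classes(["HET", "HET", "NO_CALL", "HET"]))
        assert len(segs) == 1 and segs[0].n_windows == 4

    def test_no_call_gap_when_flanks_disagree(self):
        segs = consolidate(landscape_from_classes(
            ["HET", "HET", "NO_CALL", "NO_CALL", "HOM_P2", "HOM_P2"]))
        assert [s.klass for s in segs] == ["HET", "HOM_P2"]
        assert segs[0].end == 300_000 and segs[1].start == 400_000

    def test_smoothing_can_be_disabled(self):
        ls = landscape_from_classes(["HET", "HET", "HOM_P1", "HET", "HET"])
        assert len(consolidate(ls, smooth=False)) == 3

    @given(st.lists(st.sampled_from(["HOM_P1", "HET", "HOM_P2", "NO_CALL"]),
                    min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_enumeration(self, classes):
        ls = landscape_from_classes(classes)
        got = consolidate(ls)
        expected = brute_force_segments(classes,
                                        ls.frame["start"].to_numpy(),
                                        ls.frame["end"].to_numpy())
        assert got == expected


class TestDetectCrossovers:
    def test_clonal_landscape_no_events(self):
        segs = consolidate(landscape_from_classes(["HET"] * 20))
        assert detect_crossovers(segs) == []

    def test_single_simulated_crossover_contained(self, f1, small_markers):
        """A gamete crossover at a known position yields exactly one HET-HOM
        event per flank whose interval contains the truth."""
        cm = small_markers.chrom_map
        rng = np.random.default_rng(10)
        gam = simulate_meiotic_gamete(f1, small_markers,
                                      CrossoverModel(obligate=1, extra_mean=0.0), rng)
        # progeny = recombinant gamete + all-P1 gamete (one CO per chromosome)
        all_p1 = Haplotype(
            origins={c: np.zeros(len(small_markers.positions_for(c)), dtype=np.int8)
                     for c in cm.names},
            breakpoints={c: np.empty(0, dtype=np.int64) for c in cm.names})
        prog = ProgenyGenome(ploidy=2, haplotypes=[gam, all_p1], mode_of_origin="SEXUAL")
        p1, p2 = simulate_reads(prog, small_markers, SeqSimConfig(10.0, 0.0), seed=5)
        ls = build_landscape("s", p1, p2, small_markers, make_windows(cm))
        events = detect_crossovers(consolidate(ls), chrom_map=cm)
        by_chrom = {}
        for e in events:
            by_chrom.setdefault(e.chrom, []).append(e)
        contained = total = 0
        for c in cm.names:
            t = int(gam.breakpoints[c][0])
            # skip crossovers too close to an end to flank a detectable segment
            if t < 300_000 or t > cm.length_of(c) - 300_000:
                continue
            total += 1
            contained += any(e.start <= t < e.end for e in by_chrom.get(c, []))
        assert total >= 2 and contained == total

    def test_alternating_classes_one_event_per_boundary(self):
        classes = ["HET", "HOM_P1"] * 4
        segs = consolidate(landscape_from_classes(classes), smooth=False)
        assert len(detect_crossovers(segs)) == len(segs) - 1

    def test_event_interval_clipped_to_chromosome(self):
        cm = ChromosomeMap(names=("c",), lengths=(500_000,))
        segs = [Segment("c", 0, 300_000, "HET", 2),
                Segment("c", 200_000, 500_000, "HOM_P1", 2)]
        (e,) = detect_crossovers(segs, chrom_map=cm)
        assert 0 <= e.start < e.end <= 500_000


class TestSmoothClasses:
    def test_no_call_flanks_do_not_overwrite(self):
        c = np.array([GenotypeClass.NO_CALL, GenotypeClass.HET, GenotypeClass.NO_CALL],
                     dtype=np.int8)
        assert np.array_equal(smooth_classes(c), c)

    def test_single_pass_reads_original_array(self):
        # alternating input: each flip is judged against the ORIGINAL classes,
        # so smoothing does not cascade along the chromosome
        c = np.array([1, 0, 1, 0, 1], dtype=np.int8)
        out = smooth_classes(c)
        assert out.tolist() == [1, 1, 0, 1, 1]
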