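"""Genome-wide genotype landscapes from low-coverage marker observations.

Reads supporting each parental allele are pooled over 200 kb windows sliding
by 100 kb; each window is classified HOM_P1 / HET / HOM_P2 (or NO_CALL below
a minimum read count) from the P1-read fraction.  Window sequences are
smoothed and merged into segments, and heterozygous<->homozygous transitions
between adjacent segments are reported as crossover events with a breakpoint
interval bounded by the window geometry (resolution <= window + step).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import ChromosomeMap, GenotypeClass, MarkerMap

DEFAULT_WINDOW = 200_000
DEFAULT_STEP = 100_000


class Window(NamedTuple):
    chrom: str
    start: int  # 0-based half-open
    end: int
    index: int


@dataclass(frozen=True)
class WindowThresholds:
    """Window classification rule.

    With the study's marker density a 200 kb window at 1.9x mean depth pools
    a few hundred informative reads, so an f >= 0.9 homozygous threshold and
    a 5-read call floor essentially never misclassify a heterozygous window.
    """

    min_reads: int = 5
    hom_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0.5 < self.hom_threshold <= 1.0:
            raise ValueError("hom_threshold must lie in (0.5, 1]")


def make_windows(chrom_map: ChromosomeMap, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP) -> list[Window]:
    """Sliding windows tiling each chromosome.

    Starts run 0, step, 2*step, ... while a full window fits; the trailing
    remainder is merged into the final window, so the last window may be
    longer than ``window`` but never shorter (a chromosome shorter than one
    window yields a single window covering it).
    """
    if step < 1 or window < step:
        raise ValueError("require window >= step >= 1")
    out: list[Window] = []
    idx = 0
    for name, length in chrom_map.items():
        if length <= window:
            out.append(Window(name, 0, length, idx))
            idx += 1
            continue
        n_full = (length - window) // step + 1
        for i in range(n_full):
            s = i * step
            e = s + window if i < n_full - 1 else length
            out.append(Window(name, s, e, idx))
            idx += 1
    return out


@dataclass
class WindowCall:
    window: Window
    n_markers: int
    reads_p1: int
    reads_p2: int
    klass: GenotypeClass

    @property
    def f(self) -> float:
        total = self.reads_p1 + self.reads_p2
        return self.reads_p1 / total if total else float("nan")


def _classify(reads_p1: np.ndarray, reads_p2: np.ndarray,
              th: WindowThresholds) -> np.ndarray:
    total = reads_p1 + reads_p2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, reads_p1 / np.maximum(total, 1), np.nan)
    klass = np.full(len(total), GenotypeClass.HET, dtype=np.int8)
    klass[f >= th.hom_threshold] = GenotypeClass.HOM_P1
    klass[f <= 1.0 - th.hom_threshold] = GenotypeClass.HOM_P2
    klass[total < th.min_reads] = GenotypeClass.NO_CALL
    return klass


def call_window(reads_p1: np.ndarray, reads_p2: np.ndarray, markers: MarkerMap,
                w: Window, thresholds: WindowThresholds = WindowThresholds()) -> WindowCall:
    """Classify a single window from one sample's per-marker read counts."""
    sl = markers.slice_for(w.chrom)
    pos0 = markers.pos[sl] - 1
    lo, hi = np.searchsorted(pos0, [w.start, w.end])
    p1 = int(reads_p1[sl][lo:hi].sum())
    p2 = int(reads_p2[sl][lo:hi].sum())
    klass = GenotypeClass(int(_classify(np.array([p1]), np.array([p2]), thresholds)[0]))
    covered = (reads_p1[sl][lo:hi] + reads_p2[sl][lo:hi]) > 0
    return WindowCall(window=w, n_markers=int(covered.sum()),
                      reads_p1=p1, reads_p2=p2, klass=klass)


@dataclass
class GenotypeLandscape:
    """Ordered per-window genotype calls for one sample, as a tidy frame.

    Columns: chrom, start, end, index, n_markers, reads_P1, reads_P2, f,
    class (string label).
    """

    sample_id: str
    frame: pd.DataFrame
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP

    @property
    def called_windows(self) -> int:
        return int((self.frame["class"] != "NO_CALL").sum())

    @property
    def het_fraction(self) -> float:
        called = self.frame["class"] != "NO_CALL"
        if not called.any():
            return float("nan")
        return float((self.frame.loc[called, "class"] == "HET").mean())

    def classes_for(self, chrom: str) -> np.ndarray:
        sub = self.frame[self.frame["chrom"] == chrom]
        return sub["class"].map(lambda s: int(GenotypeClass[s])).to_numpy(dtype=np.int8)


def build_landscape(sample_id: str, reads_p1: np.ndarray, reads_p2: np.ndarray,
                    markers: MarkerMap, windows: list[Window],
                    thresholds: WindowThresholds = WindowThresholds(),
                    window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
                    ) -> GenotypeLandscape:
    """One WindowCall per window, pooling reads over markers inside each."""
    rows = {k: [] for k in
            ("chrom", "start", "end", "index", "n_markers", "reads_P1", "reads_P2")}
    for chrom in markers.chrom_map.names:
        wins = [w for w in windows if w.chrom == chrom]
        if not wins:
            continue
        sl = markers.slice_for(chrom)
        pos0 = markers.pos[sl] - 1
        c1 = np.concatenate([[0], np.cumsum(reads_p1[sl])])
        c2 = np.concatenate([[0], np.cumsum(reads_p2[sl])])
        ccov = np.concatenate([[0], np.cumsum((reads_p1[sl] + reads_p2[sl]) > 0)])
        starts = np.array([w.start for w in wins])
        ends = np.array([w.end for w in wins])
        lo = np.searchsorted(pos0, starts)
        hi = np.searchsorted(pos0, ends)
        rows["chrom"].extend([chrom] * len(wins))
        rows["start"].extend(starts.tolist())
        rows["end"].extend(ends.tolist())
        rows["index"].extend([w.index for w in wins])
        rows["n_markers"].extend((ccov[hi] - ccov[lo]).tolist())
        rows["reads_P1"].extend((c1[hi] - c1[lo]).tolist())
        rows["reads_P2"].extend((c2[hi] - c2[lo]).tolist())
    frame = pd.DataFrame(rows)
    p1 = frame["reads_P1"].to_numpy(dtype=np.int64)
    p2 = frame["reads_P2"].to_numpy(dtype=np.int64)
    klass = _classify(p1, p2, thresholds)
    total = p1 + p2
    with np.errstate(invalid="ignore", divide="ignore"):
        frame["f"] = np.where(total > 0, p1 / np.maximum(total, 1), np.nan)
    frame["class"] = [GenotypeClass(int(k)).name for k in klass]
    return GenotypeLandscape(sample_id=sample_id, frame=frame, window=window, step=step)


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # start of first window, 0-based half-open
    end: int    # end of last window
    klass: str
    n_windows: int


@dataclass(frozen=True)
class CrossoverEvent:
    chrom: str
    start: int  # breakpoint interval, 0-based half-open
    end: int
    left_class: str
    right_class: str


def smooth_classes(classes: np.ndarray) -> np.ndarray:
    """Single-pass width-3 majority filter: an isolated window whose two
    neighbours share a (callable) class is reassigned to that class."""
    c = np.asarray(classes, dtype=np.int8)
    out = c.copy()
    no_call = int(GenotypeClass.NO_CALL)
    for i in range(1, len(c) - 1):
        if c[i - 1] == c[i + 1] != c[i] and c[i - 1] != no_call:
            out[i] = c[i - 1]
    return out


def consolidate(landscape: GenotypeLandscape, smooth: bool = True) -> list[Segment]:
    """Merge window calls into maximal constant-class segments.

    NO_CALL runs are absorbed into the surrounding segment when both callable
    neighbours agree, otherwise left as gaps (no segment emitted).
    """
    segments: list[Segment] = []
    no_call = int(GenotypeClass.NO_CALL)
    for chrom in dict.fromkeys(landscape.frame["chrom"]):
        sub = landscape.frame[landscape.frame["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        c = sub["class"].map(lambda s: int(GenotypeClass[s])).to_numpy(dtype=np.int8)
        if smooth:
            c = smooth_classes(c)
        # runs of constant class
        runs: list[tuple[int, int, int]] = []  # (class, first_idx, last_idx)
        for i, k in enumerate(c):
            if runs and runs[-1][0] == k:
                runs[-1] = (k, runs[-1][1], i)
            else:
                runs.append((int(k), i, i))
        # absorb NO_CALL runs flanked by agreeing classes
        merged: list[tuple[int, int, int]] = []
        i = 0
        while i < len(runs):
            k, a, b = runs[i]
            if (k == no_call and merged and i + 1 < len(runs)
                    and merged[-1][0] == runs[i + 1][0] != no_call):
                nk, na, nb = runs[i + 1]
                merged[-1] = (merged[-1][0], merged[-1][1], nb)
                i += 2
                continue
            if merged and merged[-1][0] == k:
                merged[-1] = (k, merged[-1][1], b)
            else:
                merged.append((k, a, b))
            i += 1
        for k, a, b in merged:
            if k == no_call:
                continue
            segments.append(Segment(chrom=chrom, start=int(starts[a]), end=int(ends[b]),
                                    klass=GenotypeClass(k).name, n_windows=b - a + 1))
    return segments


def detect_crossovers(segments: list[Segment], step: int = DEFAULT_STEP,
                      chrom_map: ChromosomeMap | None = None) -> list[CrossoverEvent]:
    """One event per adjacent pair of differing-class segments per chromosome.

    The true transition can fall anywhere between the start of the last
    window of the old class and the end of the first window of the new class
    (the window straddling it is classified with whichever side dominates),
    so the breakpoint interval extends one step beyond the segment boundary
    on each side: width <= window + step.  Clipped to the chromosome when a
    ``chrom_map`` is given.
    """
    events: list[CrossoverEvent] = []
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        length = chrom_map.length_of(chrom) if chrom_map is not None else None
        segs = sorted(segs, key=lambda s: s.start)
        for left, right in zip(segs, segs[1:]):
            if left.klass == right.klass:
                continue
            lo = max(0, min(left.end, right.start) - step)
            hi = max(left.end, right.start) + step
            if length is not None:
                hi = min(hi, length)
            events.append(CrossoverEvent(chrom=chrom, start=int(lo), end=int(hi),
                                         left_class=left.klass, right_class=right.klass))
    return events


def segments_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in segments],
                        columns=["chrom", "start", "end", "klass", "n_windows"])


def events_frame(events: list[CrossoverEvent]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in events],
                        columns=["chrom", "start", "end", "left_class", "right_class"])
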