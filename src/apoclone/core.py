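"""Core data containers shared by every pipeline stage.

The pipeline tracks two parental genomes (P1, P2) through an F1 hybrid and
its progeny.  Marker coordinates are 1-based (VCF convention); every interval
the package emits (windows, segments, crossover intervals, masks) is 0-based
half-open (BED convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

ORIGIN_P1 = 0
ORIGIN_P2 = 1

#: Nipponbare IRGSP-1.0 chromosome lengths (bp), the standard rice assembly.
RICE_CHROM_LENGTHS = (
    43270923, 35937250, 36413819, 35502694, 29958434, 31248787,
    29697621, 28443022, 23012720, 23207287, 29021106, 27531856,
)


class GenotypeClass(IntEnum):
    """Window/segment genotype classes on the P1/P2 axis."""

    HOM_P1 = 0
    HET = 1
    HOM_P2 = 2
    NO_CALL = 3

    @property
    def label(self) -> str:
        return self.name


CLASS_LABELS = {c: c.name for c in GenotypeClass}
LABEL_CLASSES = {c.name: c for c in GenotypeClass}


@dataclass(frozen=True)
class ChromosomeMap:
    """Ordered chromosome identifiers and their lengths in base pairs.

    The order fixed here is reused by every downstream structure (marker
    maps, haplotypes, landscapes).
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(int(l) < 1 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        object.__setattr__(self, "lengths", tuple(int(l) for l in self.lengths))

    def __len__(self) -> int:
        return len(self.names)

    def items(self):
        return zip(self.names, self.lengths)

    def length_of(self, name: str) -> int:
        return self.lengths[self.names.index(name)]

    @classmethod
    def rice(cls, scale: float = 1.0) -> "ChromosomeMap":
        """The 12 rice chromosomes; ``scale`` shrinks lengths proportionally."""
        return cls(
            names=tuple(f"chr{i:02d}" for i in range(1, 13)),
            lengths=tuple(max(1, int(round(l * scale))) for l in RICE_CHROM_LENGTHS),
        )


@dataclass
class MarkerMap:
    """Ordered biallelic SNP markers with the parental-origin allele at each.

    Markers are stored grouped by chromosome in ``chrom_map`` order, with
    1-based positions strictly increasing within each chromosome.
    ``allele_p1``/``allele_p2`` give the single-nucleotide state carried by
    each parent; they differ at every marker by construction.
    """

    chrom_map: ChromosomeMap
    chrom: np.ndarray
    pos: np.ndarray
    allele_p1: np.ndarray
    allele_p2: np.ndarray
    _slices: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele_p1 = np.asarray(self.allele_p1)
        self.allele_p2 = np.asarray(self.allele_p2)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.allele_p1) == len(self.allele_p2) == n):
            raise ValueError("marker arrays must have equal length")
        if np.any(self.allele_p1 == self.allele_p2):
            raise ValueError("allele_P1 must differ from allele_P2 at every marker")
        self._slices = {}
        cursor = 0
        seen = []
        for name, length in self.chrom_map.items():
            block = self.chrom[cursor:] == name
            k = int(np.argmin(block)) if not block.all() else len(block)
            if k:
                sl = slice(cursor, cursor + k)
                p = self.pos[sl]
                if np.any(np.diff(p) <= 0):
                    raise ValueError(f"positions not strictly increasing on {name}")
                if p[0] < 1 or p[-1] > length:
                    raise ValueError(f"marker position outside {name} bounds")
                self._slices[name] = sl
                cursor += k
                seen.append(name)
        if cursor != n:
            raise ValueError("markers must be grouped by chromosome in map order")

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def slice_for(self, chrom: str) -> slice:
        return self._slices.get(chrom, slice(0, 0))

    def positions_for(self, chrom: str) -> np.ndarray:
        return self.pos[self.slice_for(chrom)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "allele_P1": self.allele_p1,
                "allele_P2": self.allele_p2,
            }
        )


@dataclass
class Haplotype:
    """One chromosome set: per-marker parental-origin labels plus breakpoints.

    ``origins[chrom]`` is an int8 vector over that chromosome's markers
    (0 = P1, 1 = P2); ``breakpoints[chrom]`` holds the strictly increasing
    base-pair positions where the origin switches.  A marker at position
    ``pos`` lies after breakpoint ``b`` when ``pos >= b``.  Arrays are treated
    as immutable so clonal genomes may share them.
    """

    origins: dict[str, np.ndarray]
    breakpoints: dict[str, np.ndarray]

    def n_breakpoints(self) -> int:
        return int(sum(len(b) for b in self.breakpoints.values()))

    def validate(self, markers: MarkerMap) -> None:
        for name in markers.chrom_map.names:
            org = self.origins.get(name)
            bk = np.asarray(self.breakpoints.get(name, ()), dtype=np.int64)
            pos = markers.positions_for(name)
            if org is None or len(org) != len(pos):
                raise ValueError(f"origins missing or misaligned on {name}")
            if len(bk) and np.any(np.diff(bk) <= 0):
                raise ValueError(f"breakpoints not strictly increasing on {name}")
            if len(pos):
                start = int(org[0])
                expect = (start + np.searchsorted(bk, pos, side="right")) % 2
                if not np.array_equal(expect.astype(np.int8), org.astype(np.int8)):
                    raise ValueError(f"origin labels inconsistent with breakpoints on {name}")


@dataclass
class ProgenyGenome:
    """A simulated plant genome: ploidy-many haplotypes plus provenance."""

    ploidy: int
    haplotypes: list[Haplotype]
    mode_of_origin: str  # SEXUAL | MIME_SELF | PARTHENOGENESIS

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2, 4):
            raise ValueError("ploidy must be 1, 2 or 4")
        if len(self.haplotypes) != self.ploidy:
            raise ValueError("number of haplotypes must equal ploidy")

    def n_breakpoints(self) -> int:
        return sum(h.n_breakpoints() for h in self.haplotypes)

    def dose_p2(self, markers: MarkerMap) -> np.ndarray:
        """Fraction of haplotypes carrying the P2 allele at each marker."""
        out = np.zeros(markers.n_markers, dtype=np.float64)
        for name in markers.chrom_map.names:
            sl = markers.slice_for(name)
            if sl.stop == sl.start:
                continue
            acc = np.zeros(sl.stop - sl.start, dtype=np.float64)
            for h in self.haplotypes:
                acc += h.origins[name]
            out[sl] = acc / self.ploidy
        return out

    def is_fully_heterozygous(self, markers: MarkerMap) -> bool:
        return bool(np.all(self.dose_p2(markers) == 0.5))


@dataclass
class ObservationMatrix:
    """Per sample x marker read counts supporting each parental allele."""

    sample_ids: list[str]
    reads_p1: np.ndarray  # (n_samples, n_markers)
    reads_p2: np.ndarray

    def __post_init__(self) -> None:
        self.reads_p1 = np.asarray(self.reads_p1, dtype=np.int64)
        self.reads_p2 = np.asarray(self.reads_p2, dtype=np.int64)
        if self.reads_p1.shape != self.reads_p2.shape:
            raise ValueError("reads_p1 and reads_p2 shapes differ")
        if self.reads_p1.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match matrix rows")

    def row(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.sample_ids.index(sample_id)
        return self.reads_p1[i], self.reads_p2[i]


@dataclass
class FlowHistogram:
    """A flow-cytometry histogram: fluorescence channel vs nucleus count."""

    channels: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.channels.shape != self.counts.shape:
            raise ValueError("channels and counts must align")
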