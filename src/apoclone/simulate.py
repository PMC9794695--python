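"""Forward simulation of rice progeny genomes under three reproduction modes.

The simulator emulates the cross underlying the study system: two homozygous
inbred parents (P1, P2) whose F1 hybrid is heterozygous at every marker, and
progeny produced by

* ``SEXUAL``        -- selfing with normal meiosis: each progeny is the fusion
  of two independent recombinant gametes (diploid, segregating);
* ``MIME_ONLY``     -- a MiMe ("mitosis instead of meiosis") triple mutant:
  gametes are unreduced and unrecombined, so selfed progeny are tetraploid
  with two copies of each parental haplotype;
* ``MIME_BBM1``     -- MiMe plus egg-cell parthenogenesis: with probability
  ``p`` the egg develops without fertilization into a diploid clone of the
  F1, otherwise the progeny is tetraploid as in ``MIME_ONLY``.

Low-coverage sequencing observations (Poisson depth per marker, uniform
haplotype sampling, symmetric allele-flip errors) and flow-cytometry
histograms (Gaussian C-value peaks over a debris floor) are generated from
the same genomes, so downstream genotyping and ploidy calling can be tested
against known truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ChromosomeMap,
    FlowHistogram,
    Haplotype,
    MarkerMap,
    ObservationMatrix,
    ProgenyGenome,
)

MODES = ("SEXUAL", "MIME_ONLY", "MIME_BBM1")

#: Mean sequencing depth used for parents and the F1 in the study design.
PARENT_MEAN_DEPTH = 14.3
#: Mean sequencing depth used for progeny (low-coverage genotyping).
PROGENY_MEAN_DEPTH = 1.9
#: Genome-wide marker density of the study's high-confidence SNP set
#: (~268k markers over ~373 Mb), in markers per megabase.
STUDY_MARKER_DENSITY_PER_MB = 718.0


@dataclass(frozen=True)
class CrossoverModel:
    """Crossovers per chromosome per meiosis: obligate + Poisson extras.

    Rice bivalents show roughly 1.5-2 crossovers per chromosome; the default
    of one obligate crossover plus Poisson(0.5) extras, placed uniformly with
    no interference, reproduces that range.
    """

    obligate: int = 1
    extra_mean: float = 0.5

    def __post_init__(self) -> None:
        if self.obligate < 0 or self.extra_mean < 0:
            raise ValueError("crossover parameters must be nonnegative")


@dataclass(frozen=True)
class ReproductionConfig:
    mode: str = "MIME_BBM1"
    parthenogenesis_rate: float = 0.0
    crossovers: CrossoverModel = field(default_factory=CrossoverModel)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0.0 <= self.parthenogenesis_rate <= 1.0:
            raise ValueError("parthenogenesis_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SeqSimConfig:
    """Sequencing model: depth ~ Poisson(mean_depth) per marker; each read
    samples one haplotype uniformly and reports the other parental allele
    with probability ``error_rate``."""

    mean_depth: float = PROGENY_MEAN_DEPTH
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be nonnegative")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


@dataclass(frozen=True)
class FlowSimConfig:
    """Flow-cytometry model: one Gaussian peak per C-value class, channel
    proportional to DNA content, plus a uniform debris floor."""

    cv: float = 0.05
    nuclei: int = 20_000
    debris_fraction: float = 0.05
    n_channels: int = 512
    channels_per_c: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cv < 0.5:
            raise ValueError("cv must lie in (0, 0.5)")
        if not 0.0 <= self.debris_fraction < 1.0:
            raise ValueError("debris_fraction must lie in [0, 1)")
        if self.nuclei < 1 or self.n_channels < 2:
            raise ValueError("nuclei and n_channels must be positive")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct uniform 1-based positions on [1, length], sorted."""
    if n > length:
        raise ValueError(f"cannot place {n} distinct markers on a {length} bp chromosome")
    got = np.empty(0, dtype=np.int64)
    while len(got) < n:
        draw = rng.integers(1, length + 1, size=int(1.2 * (n - len(got))) + 16)
        got = np.unique(np.concatenate([got, draw]))
    if len(got) > n:
        got = np.sort(rng.choice(got, size=n, replace=False))
    return got


def make_marker_map(chrom_map: ChromosomeMap, n_markers_per_chrom, seed=None) -> MarkerMap:
    """Place markers uniformly on each chromosome with distinct parental alleles.

    ``n_markers_per_chrom`` may be a single integer or one integer per
    chromosome.
    """
    rng = _rng(seed)
    if np.isscalar(n_markers_per_chrom):
        counts = [int(n_markers_per_chrom)] * len(chrom_map)
    else:
        counts = [int(c) for c in n_markers_per_chrom]
        if len(counts) != len(chrom_map):
            raise ValueError("need one marker count per chromosome")
    if any(c < 1 for c in counts):
        raise ValueError("n_markers_per_chrom must be >= 1")
    chroms, poss = [], []
    for (name, length), n in zip(chrom_map.items(), counts):
        poss.append(_sample_positions(rng, length, n))
        chroms.extend([name] * n)
    pos = np.concatenate(poss)
    bases = np.array(list("ACGT"))
    i1 = rng.integers(0, 4, size=len(pos))
    i2 = (i1 + rng.integers(1, 4, size=len(pos))) % 4
    return MarkerMap(
        chrom_map=chrom_map,
        chrom=np.array(chroms, dtype=object),
        pos=pos,
        allele_p1=bases[i1],
        allele_p2=bases[i2],
    )


def marker_density_counts(chrom_map: ChromosomeMap,
                          per_mb: float = STUDY_MARKER_DENSITY_PER_MB) -> list[int]:
    """Marker counts per chromosome matching a genome-wide density."""
    return [max(1, int(round(l * per_mb / 1e6))) for l in chrom_map.lengths]


def make_f1(markers: MarkerMap) -> ProgenyGenome:
    """The fully heterozygous F1: one all-P1 and one all-P2 haplotype."""
    h1 = Haplotype(
        origins={c: np.zeros(len(markers.positions_for(c)), dtype=np.int8)
                 for c in markers.chrom_map.names},
        breakpoints={c: np.empty(0, dtype=np.int64) for c in markers.chrom_map.names},
    )
    h2 = Haplotype(
        origins={c: np.ones(len(markers.positions_for(c)), dtype=np.int8)
                 for c in markers.chrom_map.names},
        breakpoints={c: np.empty(0, dtype=np.int64) for c in markers.chrom_map.names},
    )
    return ProgenyGenome(ploidy=2, haplotypes=[h1, h2], mode_of_origin="SEXUAL")


def _require_het_diploid(f1: ProgenyGenome, markers: MarkerMap) -> None:
    if f1.ploidy != 2:
        raise ValueError("meiosis simulation requires a diploid genome")
    if not f1.is_fully_heterozygous(markers):
        raise ValueError("input genome must be fully heterozygous (F1-like)")


def simulate_meiotic_gamete(f1: ProgenyGenome, markers: MarkerMap,
                            co_model: CrossoverModel = CrossoverModel(),
                            seed=None) -> Haplotype:
    """One recombinant haploid gamete from a fully heterozygous diploid.

    Per chromosome the crossover count is ``obligate + Poisson(extra_mean)``;
    positions are uniform with no interference and segments alternate parental
    origin, starting from a fair coin.
    """
    _require_het_diploid(f1, markers)
    rng = _rng(seed)
    origins: dict[str, np.ndarray] = {}
    breakpoints: dict[str, np.ndarray] = {}
    for name, length in markers.chrom_map.items():
        pos = markers.positions_for(name)
        n_co = co_model.obligate + int(rng.poisson(co_model.extra_mean))
        bk = np.sort(rng.integers(1, length + 1, size=n_co)).astype(np.int64)
        bk = np.unique(bk)  # coincident draws collapse (their effects cancel pairwise anyway)
        start = int(rng.integers(0, 2))
        origins[name] = ((start + np.searchsorted(bk, pos, side="right")) % 2).astype(np.int8)
        breakpoints[name] = bk
    return Haplotype(origins=origins, breakpoints=breakpoints)


def _clone_of(f1: ProgenyGenome) -> ProgenyGenome:
    # shares origin arrays with the F1; haplotypes are treated as immutable
    return ProgenyGenome(ploidy=2, haplotypes=list(f1.haplotypes),
                         mode_of_origin="PARTHENOGENESIS")


def _mime_tetraploid(f1: ProgenyGenome) -> ProgenyGenome:
    h1, h2 = f1.haplotypes
    return ProgenyGenome(ploidy=4, haplotypes=[h1, h1, h2, h2],
                         mode_of_origin="MIME_SELF")


def simulate_progeny(f1: ProgenyGenome, markers: MarkerMap, rc: ReproductionConfig,
                     n: int, seed=None) -> list[ProgenyGenome]:
    """Simulate ``n`` selfed progeny of the F1 under the configured mode."""
    if n < 1:
        raise ValueError("n must be >= 1")
    _require_het_diploid(f1, markers)
    rng = _rng(seed)
    out: list[ProgenyGenome] = []
    for _ in range(n):
        if rc.mode == "SEXUAL":
            g1 = simulate_meiotic_gamete(f1, markers, rc.crossovers, rng)
            g2 = simulate_meiotic_gamete(f1, markers, rc.crossovers, rng)
            out.append(ProgenyGenome(ploidy=2, haplotypes=[g1, g2],
                                     mode_of_origin="SEXUAL"))
        elif rc.mode == "MIME_ONLY":
            out.append(_mime_tetraploid(f1))
        else:  # MIME_BBM1
            if rng.random() < rc.parthenogenesis_rate:
                out.append(_clone_of(f1))
            else:
                out.append(_mime_tetraploid(f1))
    return out


def endosperm_initial_cvalue(mode: str) -> int:
    """Initial endosperm C-value for a reproduction mode.

    Sexual endosperm arises from two haploid central-cell nuclei plus one
    haploid sperm nucleus (3C).  In MiMe plants all gametes are unreduced, so
    the two diploid central-cell nuclei fuse with a diploid sperm nucleus,
    doubling the starting DNA content to 6C.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    return 3 if mode == "SEXUAL" else 6


def endoreduplication_series(base_c: int, n_doublings: int = 2) -> list[int]:
    """C-value series produced by endoreduplication from a base C-value."""
    return [base_c * 2 ** k for k in range(n_doublings + 1)]


def endosperm_cvalue_mix(mode: str, weights=(0.45, 0.35, 0.20)) -> list[tuple[int, float]]:
    """A milky-stage endosperm C-value mixture: the initial C-value plus two
    rounds of endoreduplication, weighted toward the younger classes."""
    base = endosperm_initial_cvalue(mode)
    series = endoreduplication_series(base, n_doublings=len(weights) - 1)
    total = float(sum(weights))
    return [(c, w / total) for c, w in zip(series, weights)]


def simulate_reads(genome: ProgenyGenome, markers: MarkerMap,
                   sc: SeqSimConfig = SeqSimConfig(), seed=None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Low-coverage read counts per marker: (reads_P1, reads_P2).

    Depth is Poisson(mean_depth) per marker; each read picks one of the
    genome's haplotypes uniformly (so an unrecombined tetraploid gives the
    same 0.5/0.5 expected signal as a diploid clone) and is flipped to the
    other parental allele with probability ``error_rate``.
    """
    rng = _rng(seed)
    dose = genome.dose_p2(markers)
    depth = rng.poisson(sc.mean_depth, size=markers.n_markers)
    q = dose * (1.0 - sc.error_rate) + (1.0 - dose) * sc.error_rate
    reads_p2 = rng.binomial(depth, q)
    return (depth - reads_p2).astype(np.int64), reads_p2.astype(np.int64)


def simulate_observations(genomes: list[ProgenyGenome], markers: MarkerMap,
                          sc: SeqSimConfig = SeqSimConfig(), seed=None,
                          sample_ids: list[str] | None = None) -> ObservationMatrix:
    rng = _rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(len(genomes))]
    p1 = np.empty((len(genomes), markers.n_markers), dtype=np.int64)
    p2 = np.empty_like(p1)
    for i, g in enumerate(genomes):
        p1[i], p2[i] = simulate_reads(g, markers, sc, rng)
    return ObservationMatrix(sample_ids=list(sample_ids), reads_p1=p1, reads_p2=p2)


def simulate_flow_histogram(ploidy_mix: list[tuple[float, float]],
                            fc: FlowSimConfig = FlowSimConfig(),
                            seed=None) -> FlowHistogram:
    """Histogram of DAPI-stained nuclei for a mixture of C-value classes.

    ``ploidy_mix`` is a list of (C-value, fraction) pairs with fractions
    summing to 1; peak centers sit at ``C * channels_per_c`` with standard
    deviation ``cv * center``, over a uniform debris floor.
    """
    if not ploidy_mix:
        raise ValueError("ploidy_mix must not be empty")
    fracs = np.array([f for _, f in ploidy_mix], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError("mixture fractions must be nonnegative and sum to 1")
    rng = _rng(seed)
    n_signal = int(round(fc.nuclei * (1.0 - fc.debris_fraction)))
    per_peak = rng.multinomial(n_signal, fracs)
    counts = np.zeros(fc.n_channels, dtype=np.int64)
    for (cval, _), k in zip(ploidy_mix, per_peak):
        center = cval * fc.channels_per_c
        draws = rng.normal(center, fc.cv * center, size=int(k))
        ch = np.clip(np.rint(draws).astype(np.int64), 0, fc.n_channels - 1)
        counts += np.bincount(ch, minlength=fc.n_channels)
    n_debris = fc.nuclei - n_signal
    if n_debris > 0:
        ch = rng.integers(0, fc.n_channels, size=n_debris)
        counts += np.bincount(ch, minlength=fc.n_channels)
    return FlowHistogram(channels=np.arange(fc.n_channels), counts=counts)
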