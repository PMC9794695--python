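"""Shared fixtures: small synthetic genomes and a hand-built toy VCF."""
from __future__ import annotations

import numpy as np
import pytest

from apoclone import ChromosomeMap, make_f1, make_marker_map
from apoclone.simulate import marker_density_counts


@pytest.fixture(scope="session")
def small_map():
    """A desk-sized genome: 4 chromosomes of 2 Mb."""
    return ChromosomeMap(names=("chr1", "chr2", "chr3", "chr4"),
                         lengths=(2_000_000,) * 4)


@pytest.fixture(scope="session")
def small_markers(small_map):
    # ~718 markers/Mb, the density of the study's high-confidence set
    return make_marker_map(small_map, marker_density_counts(small_map), seed=42)


@pytest.fixture(scope="session")
def f1(small_markers):
    return make_f1(small_markers)


@pytest.fixture(scope="session")
def tiny_markers():
    """One 100 kb chromosome with 50 markers, for cheap per-progeny work."""
    cm = ChromosomeMap(names=("chr1",), lengths=(100_000,))
    return make_marker_map(cm, 50, seed=7)


@pytest.fixture(scope="session")
def tiny_f1(tiny_markers):
    return make_f1(tiny_markers)


# Hand-enumerated 10-site candidate VCF.  Kept sites under the default filter
# (parents homozygous-opposite in both replicates, every F1 replicate strictly
# inside (0.3, 0.7), depth > 3 everywhere): positions 100, 600 and 900.
TOY_SAMPLES = ["P1_1", "P1_2", "P2_1", "P2_2", "F1_1", "F1_2"]

TOY_SITES = [
    # pos, ref, alt, AD per sample, expected reason
    (100, "A", "G", [(10, 0), (8, 0), (0, 12), (0, 9), (5, 5), (6, 6)], "kept"),
    (200, "C", "T", [(10, 0), (9, 0), (0, 10), (0, 11), (2, 6), (5, 5)], "f1_ratio_out_of_bounds"),
    (300, "G", "A", [(10, 0), (3, 0), (0, 12), (0, 9), (5, 5), (6, 6)], "low_depth"),
    (400, "T", "C", [(10, 0), (11, 0), (9, 0), (11, 0), (5, 5), (6, 6)], "parents_share_allele"),
    (500, "A", "C", [(6, 5), (7, 4), (0, 12), (0, 9), (5, 5), (6, 6)], "p1_not_homozygous"),
    (600, "G", "T", [(0, 10), (0, 9), (12, 0), (8, 0), (6, 6), (4, 6)], "kept"),
    (700, "C", "G", [(10, 0), (9, 0), (0, 10), (0, 11), (3, 7), (5, 5)], "f1_ratio_out_of_bounds"),
    (800, "T", "A", [(10, 0), (9, 0), (0, 10), (0, 11), (7, 3), (5, 5)], "f1_ratio_out_of_bounds"),
    (900, "A", "T", [(20, 1), (15, 0), (0, 14), (1, 20), (8, 9), (7, 6)], "kept"),
    (1000, "G", "C", [(10, 0), (9, 0), (0, 10), (0, 11), (5, 5), (0, 0)], "low_depth"),
]
TOY_KEPT_POSITIONS = [100, 600, 900]


def toy_vcf_text(include_skippable: bool = True) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=2000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(TOY_SAMPLES),
    ]
    for pos, ref, alt, ads, _ in TOY_SITES:
        fields = [f"./.:{r},{a}" for r, a in ads]
        lines.append(f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t" + "\t".join(fields))
    if include_skippable:
        # an indel record genotyping must skip
        fields = ["./.:5,5"] * len(TOY_SAMPLES)
        lines.append("chr1\t1500\t.\tAT\tA\t.\tPASS\t.\tGT:AD\t" + "\t".join(fields))
    return "\n".join(lines) + "\n"


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(toy_vcf_text())
    return path
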