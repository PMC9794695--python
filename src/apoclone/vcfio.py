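"""Readers and writers for the pipeline's on-disk formats.

VCF carries per-sample allele depths (1-based positions, converted at
ingest); BED files are 0-based half-open; everything else is TSV with
``#``-prefixed provenance headers that the module's own readers skip.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from . import __version__
from .core import ChromosomeMap, FlowHistogram, MarkerMap, ObservationMatrix
from .landscape import (DEFAULT_STEP, DEFAULT_WINDOW, CrossoverEvent,
                        GenotypeLandscape, Segment)
from .markers import MaskSet

log = logging.getLogger("apoclone")

ROLES = ("P1", "P2", "F1", "PROGENY")


def provenance_lines(**fields) -> list[str]:
    items = [f"version={__version__}"] + [f"{k}={v}" for k, v in fields.items() if v is not None]
    return ["# apoclone " + " ".join(items)]


def _write_tsv(path, frame: pd.DataFrame, **prov) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(**prov):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _read_tsv(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        while True:
            line = fh.readline()
            if line.startswith("#"):
                for tok in line.lstrip("#").split()[1:]:
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    return frame, meta


# ---------------------------------------------------------------- chromosomes

def read_chrom_table(path) -> ChromosomeMap:
    frame, _ = _read_tsv(path)
    return ChromosomeMap(names=tuple(frame.iloc[:, 0].astype(str)),
                         lengths=tuple(frame.iloc[:, 1].astype(int)))


def write_chrom_table(path, chrom_map: ChromosomeMap, **prov) -> None:
    _write_tsv(path, pd.DataFrame({"chrom": chrom_map.names,
                                   "length": chrom_map.lengths}), **prov)


# ------------------------------------------------------------------- manifest

def read_manifest(path) -> pd.DataFrame:
    frame, _ = _read_tsv(path)
    required = {"sample_id", "role"}
    if not required.issubset(frame.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    bad = set(frame["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown roles in manifest: {sorted(bad)}")
    if frame["sample_id"].duplicated().any():
        raise ValueError("manifest sample_ids must be unique")
    if "replicate" not in frame.columns:
        frame["replicate"] = 1
    if "generation" not in frame.columns:
        frame["generation"] = ""
    return frame


def write_manifest(path, frame: pd.DataFrame, **prov) -> None:
    _write_tsv(path, frame, **prov)


# -------------------------------------------------------------------- markers

def write_marker_tsv(path, markers: MarkerMap, **prov) -> None:
    _write_tsv(path, markers.to_frame(), **prov)


def read_marker_tsv(path, chrom_map: ChromosomeMap | None = None) -> MarkerMap:
    frame, _ = _read_tsv(path)
    if chrom_map is None:
        names = list(dict.fromkeys(frame["chrom"].astype(str)))
        lengths = [int(frame.loc[frame["chrom"] == c, "pos"].max()) for c in names]
        chrom_map = ChromosomeMap(names=tuple(names), lengths=tuple(lengths))
    return MarkerMap(chrom_map=chrom_map,
                     chrom=frame["chrom"].to_numpy(dtype=object),
                     pos=frame["pos"].to_numpy(dtype=np.int64),
                     allele_p1=frame["allele_P1"].to_numpy(),
                     allele_p2=frame["allele_P2"].to_numpy())


# ----------------------------------------------------------------------- VCF

def write_observations_vcf(path, markers: MarkerMap, obs: ObservationMatrix,
                           **prov) -> None:
    """Write marker observations as a biallelic-SNP VCF with per-sample AD.

    REF is the P1 allele and ALT the P2 allele; AD holds (P1, P2) read
    counts.  GT is left uncalled — genotypes downstream come from windows,
    not single sites.
    """
    header = pysam.VariantHeader()
    for line in provenance_lines(**prov):
        header.add_line("##" + line.lstrip("# "))
    for name, length in markers.chrom_map.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths for the ref and alt alleles")
    for s in obs.sample_ids:
        header.add_sample(s)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(markers.n_markers):
            rec = out.new_record(
                contig=str(markers.chrom[j]),
                start=int(markers.pos[j]) - 1,
                stop=int(markers.pos[j]),
                alleles=(str(markers.allele_p1[j]), str(markers.allele_p2[j])),
            )
            for i, s in enumerate(obs.sample_ids):
                rec.samples[s]["GT"] = (None, None)
                rec.samples[s]["AD"] = (int(obs.reads_p1[i, j]), int(obs.reads_p2[i, j]))
            out.write(rec)


def read_vcf_observations(path, sample_ids: list[str] | None = None,
                          markers: MarkerMap | None = None,
                          ad_field: str = "AD"
                          ) -> tuple[ObservationMatrix, pd.DataFrame]:
    """Read per-sample allele depths from a biallelic-SNP VCF.

    Without ``markers`` the matrix rows hold (ref, alt) counts for every
    passing site, in file order.  With ``markers`` the counts are aligned to
    the marker map (positions matched exactly) and oriented to the P1/P2
    axis; markers absent from the VCF stay all-zero with a warning.
    Non-biallelic or non-SNP records are skipped and counted in the log.
    """
    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if sample_ids is None:
        sample_ids = all_samples
    missing = set(sample_ids) - set(all_samples)
    if missing:
        raise ValueError(f"samples not in VCF: {sorted(missing)}")
    col = np.array([all_samples.index(s) for s in sample_ids])

    rows_chrom, rows_pos, rows_ref, rows_alt = [], [], [], []
    counts = []
    n_skipped = 0
    marker_index: dict[tuple[str, int], int] = {}
    if markers is not None:
        marker_index = {(str(c), int(p)): i
                        for i, (c, p) in enumerate(zip(markers.chrom, markers.pos))}
        p1 = np.zeros((len(sample_ids), markers.n_markers), dtype=np.int64)
        p2 = np.zeros_like(p1)
        seen = np.zeros(markers.n_markers, dtype=bool)

    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        try:
            ad = var.format(ad_field)
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(f"record {var.CHROM}:{var.POS} lacks the {ad_field} field")
        ad = np.maximum(np.asarray(ad, dtype=np.int64), 0)[col]
        if markers is None:
            rows_chrom.append(var.CHROM)
            rows_pos.append(var.POS)
            rows_ref.append(var.REF)
            rows_alt.append(var.ALT[0])
            counts.append(ad[:, :2])
        else:
            i = marker_index.get((var.CHROM, var.POS))
            if i is None:
                n_skipped += 1
                continue
            a1, a2 = str(markers.allele_p1[i]), str(markers.allele_p2[i])
            if var.REF == a1 and var.ALT[0] == a2:
                p1[:, i], p2[:, i] = ad[:, 0], ad[:, 1]
            elif var.REF == a2 and var.ALT[0] == a1:
                p1[:, i], p2[:, i] = ad[:, 1], ad[:, 0]
            else:
                log.warning("alleles at %s:%d do not match the marker map; zeroed",
                            var.CHROM, var.POS)
                continue
            seen[i] = True
    if n_skipped:
        log.info("skipped %d non-marker or non-biallelic-SNP records", n_skipped)

    if markers is None:
        ad3 = np.stack(counts, axis=1) if counts else np.zeros((len(sample_ids), 0, 2), int)
        obs = ObservationMatrix(sample_ids=list(sample_ids),
                                reads_p1=ad3[:, :, 0], reads_p2=ad3[:, :, 1])
        sites = pd.DataFrame({"chrom": rows_chrom, "pos": rows_pos,
                              "ref": rows_ref, "alt": rows_alt})
        return obs, sites
    if not seen.all():
        log.warning("%d markers absent from the VCF; their counts are zero",
                    int((~seen).sum()))
    obs = ObservationMatrix(sample_ids=list(sample_ids), reads_p1=p1, reads_p2=p2)
    sites = markers.to_frame().rename(columns={"allele_P1": "ref", "allele_P2": "alt"})
    return obs, sites


# ------------------------------------------------------------------ BED masks

def read_masks_bed(paths, label: str = "ERROR_PRONE") -> MaskSet:
    if isinstance(paths, (str, Path)):
        paths = [paths]
    masks = MaskSet()
    for path in paths:
        frame = pd.read_csv(path, sep="\t", comment="#", header=None)
        for _, row in frame.iterrows():
            name = str(row[3]) if frame.shape[1] > 3 else label
            masks.add(str(row[0]), int(row[1]), int(row[2]), name)
    return masks


def write_bed(path, frame: pd.DataFrame, **prov) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(**prov):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False, header=False)


def write_segments_bed(path, segments_by_sample: dict[str, list[Segment]], **prov) -> None:
    rows = [(s.chrom, s.start, s.end, f"{sample}:{s.klass}")
            for sample, segs in segments_by_sample.items() for s in segs]
    write_bed(path, pd.DataFrame(rows), **prov)


def write_events_bed(path, events_by_sample: dict[str, list[CrossoverEvent]], **prov) -> None:
    rows = [(e.chrom, e.start, e.end, f"{sample}:{e.left_class}>{e.right_class}")
            for sample, events in events_by_sample.items() for e in events]
    write_bed(path, pd.DataFrame(rows), **prov)


# ------------------------------------------------------------------ landscape

def write_landscape_tsv(path, landscapes: list[GenotypeLandscape], **prov) -> None:
    frames = []
    for ls in landscapes:
        frame = ls.frame.copy()
        frame.insert(0, "sample", ls.sample_id)
        frames.append(frame)
    merged = pd.concat(frames, ignore_index=True)
    if landscapes:
        prov.setdefault("window", landscapes[0].window)
        prov.setdefault("step", landscapes[0].step)
    _write_tsv(path, merged, **prov)


def read_landscape_tsv(path) -> list[GenotypeLandscape]:
    frame, meta = _read_tsv(path)
    window = int(meta.get("window", DEFAULT_WINDOW))
    step = int(meta.get("step", DEFAULT_STEP))
    out = []
    for sample, sub in frame.groupby("sample", sort=False):
        out.append(GenotypeLandscape(sample_id=str(sample),
                                     frame=sub.drop(columns="sample").reset_index(drop=True),
                                     window=window, step=step))
    return out


# ----------------------------------------------------------------- histograms

def write_histogram_tsv(path, hist: FlowHistogram, **prov) -> None:
    _write_tsv(path, pd.DataFrame({"channel": hist.channels, "count": hist.counts}), **prov)


def read_histogram_tsv(path) -> FlowHistogram:
    frame, _ = _read_tsv(path)
    return FlowHistogram(channels=frame.iloc[:, 0].to_numpy(),
                         counts=frame.iloc[:, 1].to_numpy())


# ---------------------------------------------------------------------- truth

def write_truth_tsv(path, sample_ids, genomes, **prov) -> None:
    frame = pd.DataFrame({
        "sample": sample_ids,
        "ploidy": [g.ploidy for g in genomes],
        "mode_of_origin": [g.mode_of_origin for g in genomes],
        "n_breakpoints": [g.n_breakpoints() for g in genomes],
    })
    _write_tsv(path, frame, **prov)
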