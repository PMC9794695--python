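"""High-confidence parental SNP marker selection.

A candidate SNP becomes a marker when the two inbred parents are homozygous
for different alleles (each in every replicate), every F1 replicate is
heterozygous with a reference allelic ratio strictly inside (0.3, 0.7), and
sequencing depth exceeds three reads in every replicate of every role.
Repeat- and SV-prone intervals are removed beforehand via BED masks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ChromosomeMap, MarkerMap


@dataclass(frozen=True)
class SampleSiteCall:
    """Read support for one sample at one candidate site."""

    ref_count: int
    alt_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    def genotype_class(self, max_minor_fraction: float = 0.05) -> str:
        if self.depth == 0:
            return "MISSING"
        minor = min(self.ref_count, self.alt_count)
        if minor == 0 or minor / self.depth <= max_minor_fraction:
            return "HOM_REF" if self.ref_count >= self.alt_count else "HOM_ALT"
        return "HET"


def allelic_ratio(call) -> float:
    """Reference allelic ratio ref/(ref+alt); undefined at zero depth."""
    ref, alt = (call.ref_count, call.alt_count) if hasattr(call, "ref_count") else call
    depth = ref + alt
    if depth <= 0:
        raise ValueError("allelic ratio undefined at zero depth")
    return ref / depth


@dataclass(frozen=True)
class MarkerFilterParams:
    """Filter thresholds.

    ``min_depth`` of 4 encodes "depth larger than three"; the ratio bounds
    are strict (open interval).  ``max_minor_fraction`` is the tolerance under
    which a parental replicate still counts as homozygous at high depth.
    """

    min_depth: int = 4
    ratio_low: float = 0.3
    ratio_high: float = 0.7
    max_minor_fraction: float = 0.05
    mask_flank: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_low < self.ratio_high <= 1.0:
            raise ValueError("require 0 <= ratio_low < ratio_high <= 1")
        if self.min_depth < 1 or self.mask_flank < 0:
            raise ValueError("min_depth must be >= 1 and mask_flank >= 0")


@dataclass
class MaskSet:
    """Per-chromosome excluded intervals (0-based half-open), labeled by source."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, label: str = "ERROR_PRONE") -> None:
        if end <= start or start < 0:
            raise ValueError("mask interval must be 0-based half-open with end > start")
        iv = self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))
        self.intervals[chrom] = np.vstack([iv, [[start, end]]]).astype(np.int64)
        lb = self.labels.get(chrom, np.empty(0, dtype=object))
        self.labels[chrom] = np.append(lb, label)

    def merged(self, flank: int = 0) -> dict[str, np.ndarray]:
        out = {}
        for chrom, iv in self.intervals.items():
            if not len(iv):
                continue
            iv = iv.copy()
            iv[:, 0] = np.maximum(iv[:, 0] - flank, 0)
            iv[:, 1] = iv[:, 1] + flank
            iv = iv[np.argsort(iv[:, 0], kind="stable")]
            merged = [iv[0].tolist()]
            for s, e in iv[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.array(merged, dtype=np.int64)
        return out

    @property
    def n_intervals(self) -> int:
        return int(sum(len(v) for v in self.intervals.values()))


def sites_in_masks(sites: pd.DataFrame, masks: MaskSet, flank: int = 0) -> np.ndarray:
    """Boolean vector: True where a site (1-based ``pos``) falls in a mask."""
    hit = np.zeros(len(sites), dtype=bool)
    merged = masks.merged(flank)
    for chrom, sub in sites.groupby("chrom", sort=False):
        iv = merged.get(chrom)
        if iv is None:
            continue
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
        idx = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < iv[np.clip(idx, 0, None), 1])
        hit[sub.index.to_numpy()] = inside
    return hit


def apply_masks(sites: pd.DataFrame, masks: MaskSet, flank: int = 0) -> pd.DataFrame:
    """Retain exactly the candidate sites outside every (flanked) mask interval.

    ``sites`` must be sorted by position within each chromosome.
    """
    for chrom, sub in sites.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"candidate sites unsorted on {chrom}")
    keep = ~sites_in_masks(sites.reset_index(drop=True), masks, flank)
    return sites.reset_index(drop=True).loc[keep].reset_index(drop=True)


def _counts(reps) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(reps, dtype=np.int64)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("replicate counts must have shape (n_reps, n_sites, 2)")
    return arr[:, :, 0], arr[:, :, 1]


def _hom_for(ref: np.ndarray, alt: np.ndarray, max_minor: float):
    """Per replicate x site: homozygous-for-ref / homozygous-for-alt flags."""
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_frac = np.where(depth > 0, ref / np.maximum(depth, 1), np.nan)
    hom_ref = (depth > 0) & ((alt == 0) | (1.0 - ref_frac <= max_minor))
    hom_alt = (depth > 0) & ((ref == 0) | (ref_frac <= max_minor))
    return hom_ref, hom_alt


def select_informative_markers(p1_reps, p2_reps, f1_reps, sites: pd.DataFrame,
                               params: MarkerFilterParams = MarkerFilterParams(),
                               chrom_map: ChromosomeMap | None = None
                               ) -> tuple[MarkerMap, pd.DataFrame]:
    """Apply the high-confidence marker filter to aligned candidate sites.

    Parameters
    ----------
    p1_reps, p2_reps, f1_reps
        Per role, an array of shape (n_reps, n_sites, 2) of (ref, alt) read
        counts, all aligned to ``sites``.
    sites
        DataFrame with columns chrom, pos (1-based), ref, alt.
    chrom_map
        Chromosome order/lengths for the output map; inferred from the sites
        when omitted.

    Returns
    -------
    (MarkerMap, audit)
        The surviving markers with parental allele assignment, and a per-site
        audit frame with the first failing reason (``kept`` for survivors).
    """
    n_sites = len(sites)
    roles = {"P1": _counts(p1_reps), "P2": _counts(p2_reps), "F1": _counts(f1_reps)}
    for role, (ref, alt) in roles.items():
        if ref.shape[1] != n_sites:
            raise ValueError(f"{role} replicate counts not aligned to the candidate sites")

    reason = np.full(n_sites, "kept", dtype=object)

    def fail(mask: np.ndarray, why: str) -> None:
        reason[(reason == "kept") & mask] = why

    # depth > 3 in every replicate of every role (strictest reading)
    low = np.zeros(n_sites, dtype=bool)
    for ref, alt in roles.values():
        low |= np.any(ref + alt < params.min_depth, axis=0)
    fail(low, "low_depth")

    p1_hom_ref, p1_hom_alt = _hom_for(*roles["P1"], params.max_minor_fraction)
    p2_hom_ref, p2_hom_alt = _hom_for(*roles["P2"], params.max_minor_fraction)
    p1_ref = np.all(p1_hom_ref, axis=0)
    p1_alt = np.all(p1_hom_alt, axis=0)
    p2_ref = np.all(p2_hom_ref, axis=0)
    p2_alt = np.all(p2_hom_alt, axis=0)
    fail(~(p1_ref | p1_alt), "p1_not_homozygous")
    fail(~(p2_ref | p2_alt), "p2_not_homozygous")
    # parents must be fixed for different alleles
    opposite = (p1_ref & p2_alt) | (p1_alt & p2_ref)
    fail(~opposite, "parents_share_allele")

    f1_ref, f1_alt = roles["F1"]
    f1_depth = f1_ref + f1_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(f1_depth > 0, f1_ref / np.maximum(f1_depth, 1), np.nan)
    in_bounds = (ratio > params.ratio_low) & (ratio < params.ratio_high)
    fail(~np.all(in_bounds & (f1_depth > 0), axis=0), "f1_ratio_out_of_bounds")

    keep = reason == "kept"
    audit = sites[["chrom", "pos"]].copy()
    audit["reason"] = reason

    kept = sites.loc[keep]
    p1_is_ref = (p1_ref & p2_alt)[keep]
    allele_p1 = np.where(p1_is_ref, kept["ref"].to_numpy(), kept["alt"].to_numpy())
    allele_p2 = np.where(p1_is_ref, kept["alt"].to_numpy(), kept["ref"].to_numpy())

    if chrom_map is None:
        names = list(dict.fromkeys(sites["chrom"]))
        lengths = [int(sites.loc[sites["chrom"] == c, "pos"].max()) for c in names]
        chrom_map = ChromosomeMap(names=tuple(names), lengths=tuple(lengths))

    if not keep.any():
        warnings.warn("no candidate site survived the marker filter", stacklevel=2)
    marker_map = MarkerMap(
        chrom_map=chrom_map,
        chrom=kept["chrom"].to_numpy(dtype=object),
        pos=kept["pos"].to_numpy(dtype=np.int64),
        allele_p1=allele_p1,
        allele_p2=allele_p2,
    )
    return marker_map, audit
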