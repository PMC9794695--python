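"""Clonality classification and event-level ploidy summaries.

A progeny plant counts as clonal when its genotype landscape retains the
F1's genome-wide heterozygosity (HET fraction of called windows above a
threshold) with zero crossover events; any detected crossover marks it
recombinant.  The k-marker panel test quantifies how unlikely the observed
all-heterozygous pattern would be under sexual segregation, and event-level
summaries reproduce the percent-diploid bookkeeping with an exact binomial
confidence interval.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .flow import PloidyCall
from .landscape import CrossoverEvent, GenotypeLandscape


@dataclass
class ClonalityReport:
    sample_id: str
    called_windows: int
    het_fraction: float
    n_crossover_events: int
    classification: str  # CLONAL | RECOMBINANT | AMBIGUOUS


def assess_clonality(landscape: GenotypeLandscape, events: list[CrossoverEvent],
                     clonal_min_het: float = 0.99) -> ClonalityReport:
    """Classify one sample from its landscape and detected crossovers.

    Requires at least one called window.  The HET-fraction threshold (default
    0.99) tolerates rare noise windows without surrendering the clonal call.
    """
    called = landscape.called_windows
    if called == 0:
        raise ValueError(f"no called windows for sample {landscape.sample_id}")
    het = landscape.het_fraction
    if len(events) >= 1:
        cls = "RECOMBINANT"
    elif het >= clonal_min_het:
        cls = "CLONAL"
    else:
        cls = "AMBIGUOUS"
    return ClonalityReport(sample_id=landscape.sample_id, called_windows=called,
                           het_fraction=het, n_crossover_events=len(events),
                           classification=cls)


@dataclass
class PanelTestResult:
    k: int
    n: int
    all_het_count: int
    prob_sexual: float       # per-plant all-heterozygous probability under selfing
    log10_lr_clonal: float   # log10 likelihood ratio, clonal vs sexual


def panel_test(het_calls: np.ndarray) -> PanelTestResult:
    """Test clonality from n plants genotyped at k unlinked diagnostic markers.

    ``het_calls`` is an (n, k) boolean array (True = heterozygous).  Under
    selfing each unlinked marker stays heterozygous with probability 1/2, so
    a plant matches the F1 at all k loci with probability (1/2)^k; under
    error-free clonal reproduction every plant does.  The likelihood ratio
    compares a point mass at n (clonal) with Binomial(n, (1/2)^k) (sexual)
    for the observed all-heterozygous count.
    """
    het = np.asarray(het_calls, dtype=bool)
    if het.ndim != 2 or het.shape[1] < 1:
        raise ValueError("het_calls must be an (n, k) array with k >= 1")
    n, k = het.shape
    all_het = int(het.all(axis=1).sum())
    p_sex = 0.5 ** k
    log10_sexual = stats.binom.logpmf(all_het, n, p_sex) / np.log(10)
    log10_clonal = 0.0 if all_het == n else -np.inf
    return PanelTestResult(k=k, n=n, all_het_count=all_het, prob_sexual=p_sex,
                           log10_lr_clonal=float(log10_clonal - log10_sexual))


def genotype_panel(genomes, markers, panel_indices) -> np.ndarray:
    """Error-free heterozygosity of each genome at the given marker indices."""
    idx = np.asarray(panel_indices, dtype=int)
    out = np.empty((len(genomes), len(idx)), dtype=bool)
    for i, g in enumerate(genomes):
        dose = g.dose_p2(markers)[idx]
        out[i] = (dose > 0) & (dose < 1)
    return out


@dataclass
class EventSummary:
    event_id: str
    n_analyzed: int
    n_diploid: int
    n_tetraploid: int
    percent_diploid: int
    ci_low: float   # exact (Clopper-Pearson) 95% CI on the diploid fraction
    ci_high: float


def _percent(n_diploid: int, n_analyzed: int) -> int:
    # round half up, matching the printed per-event percentages
    return int(np.floor(100.0 * n_diploid / n_analyzed + 0.5))


def summarize_counts(event_id: str, n_diploid: int, n_tetraploid: int) -> EventSummary:
    """Event summary from raw 2n/4n plant counts."""
    n = n_diploid + n_tetraploid
    if n < 1:
        raise ValueError("event must contain at least one analyzed plant")
    lo, hi = proportion_confint(n_diploid, n, alpha=0.05, method="beta")
    return EventSummary(event_id=event_id, n_analyzed=n, n_diploid=n_diploid,
                        n_tetraploid=n_tetraploid, percent_diploid=_percent(n_diploid, n),
                        ci_low=float(lo), ci_high=float(hi))


def summarize_event(calls: list[PloidyCall | str], event_id: str,
                    chimeric_as: str = "tetraploid") -> EventSummary:
    """Percent-diploid summary for one transformation event.

    ``calls`` may be PloidyCall objects or bare call strings.  Chimeric
    2n/4n plants are counted in the tetraploid column by default (the
    published per-event tables flag them there); ``chimeric_as`` may instead
    be ``"diploid"`` or ``"excluded"``.  UNCALLED plants are excluded.
    """
    if chimeric_as not in ("tetraploid", "diploid", "excluded"):
        raise ValueError("chimeric_as must be tetraploid, diploid or excluded")
    labels = [c.call if isinstance(c, PloidyCall) else str(c) for c in calls]
    n2 = labels.count("DIPLOID")
    n4 = labels.count("TETRAPLOID")
    nc = labels.count("CHIMERIC_2N_4N")
    if chimeric_as == "tetraploid":
        n4 += nc
    elif chimeric_as == "diploid":
        n2 += nc
    if n2 + n4 == 0:
        raise ValueError(f"no callable plants in event {event_id}")
    return summarize_counts(event_id, n2, n4)
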