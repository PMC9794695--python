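# Methods

This note documents the models, parameter choices and numerical conventions
behind `apoclone`, and what the simulation-based tests do and do not show
about real data.

## Reproduction-mode model

All genomes are expressed on a biallelic marker grid over the 12 rice
chromosomes (IRGSP-1.0 lengths by default). The two inbred parents are
homozygous for opposite alleles at every marker; the F1 is heterozygous
everywhere. Progeny are generated by:

* **SEXUAL** — selfing with normal meiosis. Each progeny fuses two
  independent gametes of the same F1. Per chromosome per meiosis the
  crossover count is `obligate + Poisson(extra_mean)` with defaults 1 and
  0.5; positions are uniform with no interference, and segments alternate
  parental origin starting from a fair coin. The obligate-plus-extras
  default puts each bivalent at ~1.5 crossovers, in the range cytology
  reports for rice; both knobs are configurable and nothing downstream
  assumes this distribution.
* **MIME_ONLY** — gametes are unreduced and unrecombined, so each progeny is
  tetraploid with two copies of each parental haplotype and zero
  breakpoints.
* **MIME_BBM1** — with probability `p` (the parthenogenesis rate) the egg
  develops unfertilized into a diploid clone sharing the F1's haplotypes;
  otherwise tetraploid as in MIME_ONLY. Diploid counts over n progeny are
  exactly Binomial(n, p) by construction.

Endosperm: the initial C-value is 3 for sexual seed (two haploid central-cell
nuclei + one haploid sperm) and 6 for both MiMe modes (all three nuclei
diploid). Endoreduplication doubles the base; the default milky-stage
mixture weights the base and its first two doublings 0.45/0.35/0.20 —
chosen as a plausible developing-seed profile, only the *positions* of the
peaks carry signal downstream.

## Sequencing observation model

Per marker, depth ~ Poisson(λ); each read picks one haplotype uniformly and
reports the other parental allele with probability ε (default 0.002), reads
independent given depth. Defaults λ = 1.9 (progeny) and 14.3 (parents/F1)
follow the study design this package verifies. Two consequences the tests
lean on:

* at a heterozygous site both alleles are observed with probability
  `1 − 2e^(−λ/2) + e^(−λ)` (≈ 0.376 at λ = 1.9) — the closed form the
  simulator is checked against;
* an unrecombined tetraploid has allele dose 0.5 at every marker, identical
  in expectation to a diploid clone. Ploidy therefore comes from the flow
  module; the landscape cannot and does not try to call it.

Marker density defaults to 718/Mb, matching a ~268k genome-wide
high-confidence set over ~373 Mb.

## Marker filter

A candidate site is kept iff (a) every P1 replicate is homozygous for one
allele and every P2 replicate for the other; (b) every F1 replicate is
heterozygous with reference allelic ratio strictly inside (0.3, 0.7); (c)
depth > 3 in **every replicate of every role** — the strictest reading of
the depth rule, chosen for reproducibility. Parental homozygosity tolerates
a minor-allele fraction ≤ 0.05 (so one stray error read at 20× does not
discard a good site); sites with zero depth in any required replicate are
rejected, never imputed. The audit output records the first failing rule per
site. The allelic ratio is computed against the VCF reference allele as
stated; the kept marker's P1/P2 allele assignment follows the parental
genotypes, so reference orientation does not propagate downstream.

Tightening any threshold can only shrink the kept set (tested as a
monotonicity property). At 14.3× the strict F1 ratio bound rejects a
substantial minority (~35%) of true sites by sampling noise alone; this is
expected and matches the filter's high-confidence intent.

## Windows, segments, crossovers

Windows are 200 kb sliding by 100 kb; starts are step multiples, and the
trailing remainder is merged into the final window so no window is shorter
than a step. Reads (not per-marker genotype votes) are pooled per window —
the right choice at 1.9× where most markers have 0–2 reads. Classification:
NO_CALL below 5 informative reads, HOM_P1 at f ≥ 0.9, HOM_P2 at f ≤ 0.1,
HET otherwise. At the default density a window pools ~270 reads, so a true
HET window essentially never misclassifies; thresholds are configurable.

Consolidation applies one pass of a width-3 majority filter (an isolated
window whose two callable neighbours agree is reassigned — judged against
the original classes, so smoothing cannot cascade), merges constant runs,
and absorbs NO_CALL runs whose flanking classes agree; disagreeing flanks
leave a gap. `--no-smooth` disables the filter.

A crossover event is emitted between adjacent differing-class segments. The
window straddling the true transition is classified with whichever side
dominates (a window goes homozygous only when ≥ ~80% of its span is
homozygous), so the truth may fall inside the first window of the *new*
class. The breakpoint interval therefore extends one step beyond the segment
boundary on each side — `[min(left.end, right.start) − step,
max(left.end, right.start) + step)`, clipped to the chromosome — giving
resolution ≤ window + step (300 kb at defaults). Measured on ~200 simulated
F2 chromosomes at λ = 1.9, ε = 0.002, ~97% of true crossovers are recovered
with a containing interval; the misses are crossover pairs closer than the
window resolution and crossovers within ~200 kb of a chromosome end. Clonal
chromosomes at the same settings produce essentially zero false events.

## Clonality, panel test, ploidy, summaries

* **Clonality**: RECOMBINANT if ≥ 1 crossover event; otherwise CLONAL if the
  HET fraction of called windows is ≥ 0.99 (room for rare noise windows);
  otherwise AMBIGUOUS. Zero called windows is an error, not a class.
* **Panel test**: k unlinked diagnostic markers each stay heterozygous under
  selfing with probability 1/2, so a sexual plant matches the F1 at all k
  with probability (1/2)^k (0.0625 at k = 4). The reported log10 likelihood
  ratio compares a point mass at n (error-free clonal) with
  Binomial(n, (1/2)^k); a single non-het plant sends it to −∞ — the test is
  deliberately brittle, matching its error-free premise.
* **Flow ploidy**: histograms are smoothed (moving average, 5 channels);
  peaks are `scipy.signal.find_peaks` maxima with prominence ≥ 5% of the
  smoothed maximum. Peak mass is summed in a proportional ±20% gate around
  each peak (constant-CV instruments have channel-proportional widths),
  bounded by midpoints between peaks, after subtracting a 10th-percentile
  baseline standing in for uniform debris. The dominant peak's ratio to the
  2C control calls DIPLOID in [0.8, 1.2] and TETRAPLOID in [1.7, 2.3]; a
  2n/4n chimera requires G1 peaks in both bands, each holding ≥ 25% of
  non-debris nuclei. The 25% floor sits above a typical leaf G2/M share
  (and its estimation noise) and below any mixed-ploidy sector worth
  flagging; with it, 1,000 simulated leaf histograms (CV ≤ 0.08, debris
  ≤ 20%) classify without error.
* **Endosperm profile**: the smallest detected peak fixes the base C-value
  (3 or 6, whichever is nearer); peaks matching doublings of the base within
  20% join the endoreduplication series.
* **Event summaries**: percent diploid is rounded half-up, which reproduces
  every unambiguous published per-event percentage used as a fixture.
  Chimeric plants count in the tetraploid column by default — the published
  tables footnote them there — with `diploid` and `excluded` conventions
  available. The 95% CI is exact Clopper–Pearson (statsmodels), appropriate
  for events with a handful of plants.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.Generator`; a global seed fans
out to stages by fixed offsets, so identical seeds give bit-identical
outputs (including written VCFs — no timestamps enter any file). Test
simulations use the full rice genome at study marker density where the claim
demands it (crossover recovery: 17 F2 plants × 12 chromosomes; panel test:
765 clones) and small scaled genomes elsewhere; the bundled demo scales
chromosome lengths to 2% purely to stay desk-sized.

## What the simulations do not show

The generator emulates the *statistical* structure of the study design —
marker density, depth, error, reproduction genetics — not its discovery
pipeline. Real data add alignment artefacts, reference bias, repeat-driven
false SNPs (here delegated to input BED masks), segmental depth variation,
and possible meiosis-II leakage in *osd1* backgrounds (triads/tetrads),
none of which are modelled. Chimeric plants are simulated only as histogram
mixtures; whether they arise pre- or post-zygotically is not represented.
Passing tests therefore validate the inference machinery and its stated
operating points, not the upstream variant calling.
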