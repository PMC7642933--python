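# Methods

## Overview

`mipfit` models a pooled competitive-fitness assay: many self-fertilizing
strains grown on shared plates, propagated by transferring a bottlenecked
subsample to a fresh plate roughly once per generation, with relative
abundances read out by molecular inversion probes (MIPs) targeting
strain-private SNVs. This note records the models, parameter choices and
numerical conventions, and what the simulator does and does not emulate.

## Panel design

Strain-private sites are variants whose (chromosome, position, alt allele)
occurs in exactly one strain of the pooled set; two strains varying at the
same position with *different* alt bases both remain usable. Site spacing
uses a greedy linear scan in karyotype order (I, II, III, IV, V, X;
unrecognized contigs after, alphabetically) accepting the first site per
chromosome and every later site at least `min_spacing_bp` (default 300,
boundary inclusive) beyond the last accepted one, across all strains
jointly. A second candidate set (e.g. wild isolates) can be screened
against reserved sites with a centre-to-centre exclusion window (default
350 bp, boundary inclusive).

Probe geometry defaults to 20 nt arms flanking a 100 nt gap-fill;
candidates slide the gap-fill so the SNV sits at different offsets (every
10 nt by default). The scoring function is this package's own default (the
original oligo-scoring criteria used for such probes are not public): an
equally weighted sum of four [0, 1] terms — both arms inside a 30–70% GC
window (linear falloff outside), arm melting-temperature agreement under
the Wallace rule (2·(A+T) + 4·(G+C); zero credit at ≥10 °C difference), a
homopolymer-run penalty (any run >4 nt zeroes the term), and SNV
centrality within the gap-fill. Arms containing non-ACGT bases are
rejected outright (−inf). Weights are configurable (`ScoringWeights`).

Panels keep the top scorer per chromosome (ties to the leftmost target)
and then draw `panel_size` (default 4) of the per-chromosome winners
uniformly without replacement. The random draw uses a per-strain
substream keyed by (seed, CRC32 of the strain id), so results are
reproducible and independent of strain input order. Probes are designed
against the plus strand only.

## Quantification

A read is `[extension arm][gap-fill][ligation arm]`, with the UMI either
in the read header (last colon-separated field) or inline after the
ligation arm. Reads are assigned to the unique probe whose two arms both
match within a configurable mismatch tolerance (default 0, i.e. exact);
ambiguous matches are dropped, never multi-assigned. The base at the
probe's SNV offset classifies the event as ALT, REF or OTHER.

UMI deduplication counts each distinct (probe, UMI) once; a UMI seen with
conflicting calls goes to its majority call, with exact ties discarded and
counted. Per-probe abundance is ALT/(ALT+REF): OTHER calls are excluded
from the denominator, since only variant and reference events are
diagnostic (this is a documented choice; the alternative denominator is a
one-line change). No per-probe normalization is applied before averaging.

Library QC flags probes whose total UMI count falls below 20% of the
library's mean per-probe total and removes only probes flagged in *every*
library. Strain abundance is the unweighted mean of the strain's retained
probe abundances, with a sample SD (n−1); single-probe strains report
SD 0 with `sd_defined=False`.

The false-positive rate is estimated from probes whose target strain is
absent from the genomic template: the pooled per-event rate is
ΣALT/Σtotal over those probes, and the per-probe mean/SD summarise the
per-(library, probe) rates. The detection limit is mean + k·SD with k = 5.

## Fitness

Fold-change rate per replicate: trajectories are floored at 1e-3
elementwise, then FCR = log2(A_end/A_0)/G_eff, where G_eff is the index of
the first generation at or below the floor (a collapsed strain carries no
information afterwards) or the full length otherwise. A trajectory whose
A_0 is already at the floor indicates a strain that should have been
start-filtered and raises. Strains whose starting abundance (averaged
over replicates' generation-0 samples) is below 2.5e-3 are class 0 and
excluded from FCR analysis.

Mean FCR pools replicates unweighted across conditions. Classes 1–4 use
half-open intervals with default boundaries (−0.4315, −0.0985, 0.2327);
`ClassBounds.from_model(a0, generations)` instead derives boundaries as
log2(cutoff/a0)/generations for cutoffs (1e-3, 1e-2, 1e-1). With a0 = 0.02
and 10 generations the derived values (−0.4322, −0.1000, +0.2322) differ
from the defaults by <2%; the defaults follow the published convention,
and the model path documents the discrepancy (the a0 behind the published
figures is evidently ≈0.0199 rather than exactly 0.02).

Condition comparisons test strain × condition pairs whose mean FCRs
differ by more than 20% *relative* difference (|a−b|/max(|a|,|b|);
scale-free across positive and negative rates; an absolute-difference mode
is available) with a two-sided Wilcoxon rank-sum on replicate FCRs and
Benjamini–Hochberg adjustment over all tested pairs. PCA centers and
scales columns to unit variance (n−1 SD, dropping zero-variance columns
with a warning) and uses SVD; loading signs are fixed so each component's
largest-magnitude loading is positive.

## Simulator

Growth is a discrete-generation selection-with-drift model: expected next
abundance A′_s ∝ A_s·w_s, realized as one multinomial draw of
`bottleneck_n` individuals per transfer (default 10,000, matching the
5–10k animals moved per cycle; `bottleneck_n=None` gives the
infinite-population update). Abundances sum to 1 at every generation by
construction. All randomness flows from one seed through deterministic
`SeedSequence` substreams.

Sequencing is simulated at the capture-event level: each probe carries a
persistent lognormal efficiency with σ = ln 9 / (z₀.₉₉ − z₀.₀₁) ≈ 0.472,
calibrated so the 1st–99th percentile of per-probe depth spans ninefold;
totals are Poisson around a mean depth of 1566 events per probe; ALT
events are Binomial(total, A·(1−fpr) + (1−A)·fpr) with a per-event miscall
rate of 1.3e-4. These defaults emulate the depth spread and false-positive
behaviour observed in real MIP libraries. FASTQ emission writes exactly
one read per capture event with enumerated UMIs, so reads → parse → dedup
is the identity on the generating count table.

What the simulator does **not** emulate: cross-progeny contamination,
males/outcrossing, starvation physiology, transfer-method (chunk vs wash)
biases, sequencing errors inside the gap-fill beyond the SNV base, and
UMI collisions (enumerated UMIs are distinct by construction). Passing
tests therefore demonstrate correctness of the pipeline arithmetic and
statistical behaviour under the stated generative model, not robustness
to those real-data artifacts.

## Statistical notes

The FCR estimator is a log ratio, hence concave in the endpoint
abundance. Under a multinomial bottleneck of size N a neutral strain at
abundance A0 acquires per-generation variance σ² ≈ (1−A0)/(A0·N) in
ln-abundance, biasing the estimated FCR by −σ²/(2 ln 2) — about −0.0035
per generation at A0 = 1/50 and N = 10,000. This is two orders of
magnitude below the narrowest class width (0.33) and immaterial for
classification, but it is the correct null centre when testing the
estimator on neutral simulations; the test suite uses this closed-form
correction rather than zero.

Problem sizes used in the simulation-backed tests — 50-strain pools,
7 generations, 8 replicates, 20–100 seeds, ~1e6 events for
false-positive-rate recovery — were chosen to give comfortable statistical
resolution for each property (e.g. the class-recovery margins are several
standard errors wide at these sizes).

## Numerical conventions

Coordinates are 1-based inclusive in VCF and emitted TSVs, 0-based
half-open internally. Sample SDs use the n−1 denominator throughout.
Score ties in panel assembly break to the leftmost genomic position;
classification intervals are closed on the left. TSV outputs carry '#'
provenance headers naming the tool version and resolved parameters, and
gzip inputs are handled transparently.
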