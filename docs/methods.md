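# Methods

This note documents the models, conventions and numerical choices behind
`borgtools`, in the order the pipeline runs them.

## Tandem direct-repeat arrays

**Definition.** A reported array is a perfect tandem repeat: a span equal to
`unit × copies` byte-for-byte, where the unit is the *minimal period* of the
underlying maximal periodic region. Normalization is fixed as:

1. find a maximal region in which every position matches the position one
   period earlier (one mismatch ends the region; positions holding `N` or
   any non-ACGT code never match, so arrays never span `N`s);
2. compute the region's minimal period with failure-function border
   arithmetic and re-extend maximally at that period — this is what collapses
   a chain of overlapping ≥ 50 nt self-matches into, say, a 12 bp unit
   repeated 40 times;
3. trim the region, anchored at its left edge, to a whole number of unit
   copies.

An array is reported iff its trimmed span is ≥ `min_match` (default 50 bp)
and it has ≥ `min_copies` (default 3) copies. `min_match` is read as the
repeat-search floor on the matched length, so units far shorter than 50 bp
are reportable once the minimal period is resolved. Left-anchored trimming
is deterministic but means that when an array is flanked by a chance
*partial* unit copy, coordinates under reverse complement can shift by less
than one unit; arrays delimited by non-unit bases (as the simulator plants
them) map exactly.

**Search strategy.** Sequences up to 5 kb are scanned at every period up to
`L / min_copies`. Longer sequences first collect candidate periods from the
spacings of duplicated 16-mers (rolling polynomial hash mod 2⁶⁴, spacings at
lags 1–3 within each duplicate group, plus all periods ≤ 32 unconditionally)
and then run the same exact per-period scan at each candidate. Any array
meeting the reporting thresholds repeats each of its unit-phase 16-mers at
unit-length spacing, so its period is always seeded; the per-period scan is
exact regardless of how the period was proposed. Runs shorter than the
arithmetic floor `max(min_match − p, (min_copies − 1)·p)` are skipped at
period `p`: an array rejected there is always re-discovered at its own
minimal period, where the run covers its whole span.

**Context.** An array fully inside one gene is `within_gene` (partial
overlap: `gene_overlapping`; else `intergenic`). It yields a perfect
amino-acid repeat (`aa_repeat`) iff the unit length is a multiple of 3 and
the array start is in frame — frame counted from the gene start on `+`
genes and from the gene end on `−` genes.

## Terminal inverted repeats

The ITR is the longest prefix length `k` (capped at `L/2`) whose reverse
complement matches the suffix with at most `max_mismatch_frac · k`
mismatches (default 0: perfect). Genomes shorter than `2 · min_len` return
nothing. Chance matching extends a planted ITR by a geometric tail
(~1/3 expected extra bases against random flanks), which is why the
simulator plants a mismatched base just inside each arm.

## GC skew and replichores

Windowed skew is (G − C)/(G + C) per window (default 1,000 bp window,
100 bp step — fine enough to resolve Mb-scale replichores while smoothing
local composition); windows without G or C get skew 0 and are flagged.
Cumulative skew is the per-base running sum of +1 per G and −1 per C.

Replichores follow an ends-origin model: both chromosome ends are origins
and the terminus is the internal global extremum of the cumulative curve,
taking whichever of the maximum/minimum has the larger magnitude. A maximum
means the first segment is G-rich forward, so replichore 1 leads on `+` and
replichore 2 on `−`; a minimum swaps them. Two degenerate outcomes are
flagged instead of interpreted: extremum magnitude below `2√L` (the scale of
a null random walk's excursions) → `no_replichore_signal`; extremum within
1% of an end → `not_bidirectional_from_ends`. Strand bias assigns each gene
to the replichore holding its midpoint; concordance means the two majority
strands differ.

**Elevated-GC islands.** Per-gene GC is compared to a robust baseline:
median gene GC, scaled by 1.4826 × MAD. A gene is flagged at
`z ≥ 2` robust SDs above the median. No hard threshold exists in nature for
"a few percent of genes"; the median/MAD choice keeps the baseline immune
to the islands themselves. At z = 2 the per-gene false-positive rate is the
normal tail (~2.3% one-sided for ~1 kb genes), so a 200-gene genome is
expected to carry a handful of chance flags alongside the true islands —
the tests bound the false-positive count rather than demanding zero.

## Taxonomy voting

Each gene contributes one best-hit path over seven ranks (domain → species;
hits are assumed pre-filtered by the homology search's E-value ceiling). At
each rank a label is called iff it takes strictly more than half the votes.
By default the denominator is *all* genes, no-hit genes included: a contig
dominated by novel proteins then gets `no_domain` even if every actual hit
agrees — exactly the signature that separates these elements from cellular
contigs — while the genus tally (ignoring no-hit genes) still identifies
the host-genus plurality. `denominator="hits_only"` is available as a
dialect switch. Exact 50% and ties yield no call, which makes the call
monotone: an extra vote for the winner can never revoke it.

## The screen

Criterion 1 ("credible partial alignment to a complete reference") is
quantified as ≥ 10% of the contig or ≥ 5 kb aligned; the caller supplies the
aligned fraction (0 without references). Criteria 2–5 are as voted/measured:
no domain call; GC in the closed interval [0.30, 0.35]; ≥ 3 repeat regions
(each itself ≥ 3 copies); strict genus dominance. "Most or all of the other
criteria" is quantified as ≥ 3 of 4 (configurable). Classification is a pure
function of the features.

Binning is single linkage: two candidates link when coverages differ by
≤ 20% of their mean *and* GC differs by ≤ 0.02 — invented defaults for an
operation the literature leaves qualitative ("similar coverage"), exposed as
parameters. Contigs are processed in id order, so binning is permutation
invariant. End-overlap detection reports perfect suffix–prefix matches
≥ 100 bp between all four oriented adjacencies of each member pair (found by
rolling-hash candidates verified by direct comparison) and never auto-joins.

## Host linkage

Counts are converted to depths (counts × read length / element length)
before correlation by default, since element lengths differ ~10-fold
between the ECEs and their hosts; correlating raw counts is available.
Pearson r with two-sided p per pair, Benjamini–Hochberg across all tested
pairs (the FDR procedure is a choice; nothing finer-grained is specified by
the screening protocol), significance at r > 0.92 ∧ q ≤ 0.05. Copy ratios
are per-sample depth ratios over samples where the host reaches a 1× depth
floor, summarized by min/max (and median in the validation scripts);
ratios are computed on linear depths, no log transform.

## Motifs and spacers

CxxCH motifs (C, any, any, C, H) are counted greedily left-to-right without
overlap — haem-binding motifs cannot share cysteines — with `X` never
satisfying a C/H position; ≥ 3 motifs ⇒ multihaem cytochrome. Spacer
matching is ungapped over the full spacer length on both target strands
(at 25–40 bp with ≤ 1 mismatch an alignment is effectively gapless, so the
full-length-window Hamming dialect is declared rather than local alignment);
primary hits need alignment length > 24 bp (strict) and ≤ 1 mismatch;
arrays with a primary hit in a target have their remaining spacers
re-searched there at ≤ 3 mismatches. Tightening any threshold only removes
matches.

## The synthetic community

The generator emulates the downstream artifacts of a real discovery study,
with every feature planted and recorded:

- **Genomes.** i.i.d. per-base draws at the local target composition;
  planted features first, flanks filled around them. Defaults are the study
  conditions: four Borg-like genomes of 661,708–918,293 bp; ITRs of
  1.5–2.6 kb (> 1 kb); 25–54 planted arrays per genome with aperiodic units
  of 20–60 bp at 3–8 copies, a non-unit blocker base on each side so copy
  number is unambiguous; GC baseline 0.33 with hosts at 0.43 (+10 points);
  replichore split 0.55–0.65 with skew strength 0.10 (G excess among G+C on
  the leading strand — enough drift for the cumulative extremum to localize
  the planted terminus within a few hundred bp on Mb genomes); strand
  fidelity 0.97; ~2% of genes rewritten at +10 GC points as islands.
- **Annotations.** Borg genes: 70% no hit, 15% *Methanoperedens*, 10%
  spread over other archaeal genera, 5% bacterial — no rank approaches a
  majority, the genus plurality is unambiguous. Hosts: 80% *Methanoperedens*
  hits (clear domain call). Backgrounds: a dominant random bacterial genus
  at a random 30–90% hit rate. Sixteen genes per Borg genome get proteins
  with exactly 3–32 planted CxxCH motifs on a C/H-free backbone (the exact
  count is checkable; unconstrained random proteins can and occasionally do
  contain genuine chance motifs).
- **Abundances.** Host depth per sample is lognormal (σ = 0.9) around a mean
  drawn from the host's depth range; each Borg's expected depth is its
  host's times a fixed ratio drawn in [2, 8]; backgrounds are independent.
  Counts are negative binomial at CV 0.05 (Poisson when the requested
  variance would undershoot the Poisson floor) — overdispersed like real
  mapping counts, though the real variance structure is unknown and this
  choice is a stand-in, not an inference.

What the generator does *not* emulate — read-level errors, assembly
chimeras and collapsed repeats, strain microheterogeneity, compositional
autocorrelation, mobile elements shared between host and ECE — bounds what
passing tests show: they demonstrate the operations are correct and
calibrated under the declared feature model, not that real metagenomes are
this clean. Repeat counts recovered from real assemblies are lower bounds
wherever assemblers collapse arrays.

## Problem sizes and determinism

The validation scripts run the full pipeline on the four-genome community
(≈ 3.2 Mb of Borg sequence), 1,000 null profile pairs and 1,000 background
contigs of 6–30 kb — sizes chosen so the whole cycle completes in about a
minute on one CPU while keeping ≥ 150 planted arrays and 1,000-draw null
calibrations. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configuration gives byte-identical
output files.
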