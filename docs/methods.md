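# Methods

## Scope and data model

The package operates on four object families: annotated hairpins
(`Precursor`: sequence plus 1-based inclusive mature/star intervals),
scored amiRNA–transcript alignments (`DuplexAlignment`/`TargetHit`),
design candidates (`DesignCandidate`/`DesignReport`), and audit tables
(DE records, TPS bins, RACE tallies). All coordinates are 1-based
inclusive (the miRBase convention); sequences are normalised to uppercase
RNA internally, with DNA emitted only by the oligo module. Arm lengths are
constrained to 19–24 nt; N is tolerated in hairpin flanks but rejected
inside the mature/star arms, where it would poison exact read matching.

## Foldback anatomy

The distal stem–loop is defined purely from annotation: the residues
strictly between the 3′ end of the 5′-proximal arm and the 5′ end of the
3′-proximal arm. No secondary-structure prediction is involved, which makes
the metric deterministic and independent of folding parameters; the cost is
that unpaired residues flanking the duplex are attributed to the loop
segment regardless of their pairing state. Cohort summaries use the
standard even/odd median and linear-interpolated quartiles. Adjacent arms
yield a zero-length loop with an empty span rather than an error.

## TPS scoring

Penalties follow the TargetFinder scheme: mismatch 1, G:U wobble 0.5,
single-nucleotide bulge 1, each doubled when the amiRNA position lies in
the 5′ core (positions 2–13); Watson–Crick pairs contribute 0. All
constants live in `ScoringScheme` and can be overridden without code
change. Scores are therefore always multiples of 0.5, exactly
representable in binary floating point, so score comparisons use exact
equality.

Alignment is antiparallel: amiRNA position 1 pairs the 3′-most base of the
site. Gapped alignment is limited to one single-nucleotide bulge on either
strand, found by explicit enumeration of every bulge placement per window
(O(L·21·k) per transcript) rather than dynamic programming — transparent
and exhaustively testable at these lengths. Per-position states cover all
21 amiRNA positions; a target bulge is represented as a state on the
amiRNA position whose partner sits immediately 5′ (site-wise) of the
inserted base, and that column scores only the bulge penalty (the
co-consumed pair is not separately scored). For each distinct transcript
span only the best-scoring alignment is kept; hits sort by (TPS, start).
Only the sense strand is scanned (targets are mRNAs), transcript N scores
as a mismatch, and an amiRNA containing N is rejected outright. Hits above
the report cap (default 11) are never emitted.

The predicted cleavage coordinate is the base paired to amiRNA position 10
— the 5′-terminal nucleotide of the 3′ cleavage fragment that 5′-RLM-RACE
captures; the scissile bond lies between it and the base paired to position
11. A bulge between those positions makes the site ambiguous and raises.

## Candidate design and the amiRNA\* strand

Each N-free 21-nt target window yields one candidate: the window's reverse
complement with position 1 forced to U and position 19 forced to C.
Position 1 biases AGO1 loading; C19, under the 2-nt 3′-overhang duplex
register (amiRNA position *i* pairs star position 20 − *i* for
*i* = 1..19), is what places the AGO-non-preferred G at star position 1.
Both forced positions fall outside the doubled core, so each costs at most
1.0 of on-target TPS — and only 0.5 when the forced U faces a G (wobble),
or 0 when the window already conforms.

Optimality is implemented as on-target TPS ≤ 1 (not strictly = 1): a
window needing no substitutions scores 0, which is a strictly better
interaction and there is no principled reason to exclude it; the strict
behaviour is available by passing `on_target_max` explicitly. The
off-target bar is strict: any site on a non-intended transcript with
TPS < 4 rejects the candidate; a site at exactly 4.0 is tolerated.
Ranking sorts optimal candidates by (on-target TPS, margin of the worst
off-target above 4 descending, window position). Multi-gene group
targeting is out of scope — one intended transcript per run.

The star template language is a list of 21 entries, each `"pair"`
(complement the amiRNA partner under the register above) or a literal
base. Star positions 20–21 have no partner (they are the star's unpaired
3′ overhang), so the shipped default template fixes them to the literals
`C`,`U`; `"pair"` at those positions is an error rather than a silent
guess. Position 1 is the literal `G`, which coincides with the complement
of the forced amiRNA C19.

## Oligo layouts

The main design constraints are fixed: CTTG/CATG 5′ overhangs, two
overlapping partially complementary oligos, 60 bases each on the OsMIR390
template, and a 21 + 16 + 21 = 58-nt insert core. The residue-level
partition used here is the self-consistent layout forward =
CTTG + core[1..L−2], reverse = CATG + revcomp(core[3..L]): both oligos
have length L + 2, they overlap over core[3..L−2], and together they carry
the full core, so re-parsing reconstructs the amiRNA and amiRNA\*
verbatim. Oligo lengths are template constants independent of amiRNA
content, and the chimeric orderings hold by construction (OsMIR390-AtL
oligos longer than OsMIR390; AtMIR390a-OsL shorter than AtMIR390a). Loop
sequences in `data/templates.synthetic.json` are synthetic stand-ins with
the documented lengths (16 nt for the Os loop), guarded by load-time
length and overhang validation; swap in measured loop sequences via
`load_templates(path)` without touching code. BsaI screening reports every
GGTCTC (plus strand) and GAGACC (minus strand) occurrence with 1-based
position.

## Read-stack profiling

Reads are mapped by exact sense-strand substring matching against the
hairpin — a precision-first choice appropriate to hairpin-space mapping,
where spurious one-mismatch placements would contaminate the stack; a
one-mismatch mode exists (`mismatches=1`) but is off by default. A read
matching k loci credits 1/k to each (switchable to first-locus). Lengths
outside 18–26 are excluded from the matrix but counted in `total_input`.
"Accurately processed" requires exact 5′ **and** 3′ ends: 20-nt and 21-nt
species must be distinguishable, so length is part of the identity. With
zero mapped reads all fractions are reported as undefined (`None`), never
as 0.

## Specificity audit

DE estimation is consumed, not reproduced: the audit takes a
DESeq2-dialect results table (`gene_id, baseMean, log2FoldChange, padj`)
and classifies UNDER/OVER/NS at q < 0.01 with sign of log2FC; missing q is
NS; an optional pre-filter drops genes with zero counts in ≥ 5 of 8
samples when zero-counts are supplied. Binning uses each gene's minimum
TPS over its predicted sites, 0.5-wide bins from 0 to the cap (integer
bins are recoverable by aggregation), plus a "no predicted site" stratum;
the [4, 11] interval summary uses closed bounds. The enrichment test is
the two-sided Fisher exact test on {predicted in [4, 11] vs not predicted}
× {UNDER vs not}, with the standard two-sided definition (sum of all
tables at fixed margins whose probability does not exceed the observed
table's — not a mid-p variant), computed via `scipy.stats.fisher_exact`
and cross-checked in the test suite against an independent full
hypergeometric enumeration; a zero margin returns p = 1.0 with a
degenerate-table note. RACE tallies enforce the TPS ≤ 7 eligibility preset
(weaker interactions are not expected to be cleaved); pass `max_tps=None`
to tally regardless.

## Pigment formulas

Closed-form three-wavelength formulas for 80 % acetone extracts
(chl a = 12.21·A663 − 2.81·A647; chl b = 20.13·A647 − 5.03·A663;
carotenoid = (1000·A470 − 3.27·chl a − 104·chl b)/227), in mg/L of
extract. Negative results are returned as-is with a warning (blank or
scatter artifacts), never clipped, because clipping would silently bias
downstream ratios. A dilution factor (e.g. 2 for the usual 1:2 dilution)
multiplies all outputs; a helper converts to mg/g fresh weight.

## Synthetic-data generators

All generators derive independent streams from one user seed via fixed
per-generator offsets, so adding a generator never perturbs existing
fixtures, and identical seeds give byte-identical outputs.

*Reads*: with probability `fidelity` a read is the exact mature species;
otherwise a 5′ shift in [−3, 3] and a length in [18, 26] are drawn
uniformly, resampling any draw that leaves the hairpin or coincides with
the exact mature coordinates — so the expected accurate fraction equals
`fidelity` exactly and is recoverable within binomial error (the test
suite checks 3 standard errors at depth 10⁴). The generator emulates
imprecise drosha/dicer-style processing around the mature species only; it
does not emulate star-strand accumulation, sequencing error, adapter
artifacts or cross-mapping from elsewhere in a genome, so passing tests
demonstrate correct accounting, not mapper robustness on real libraries.

*Transcriptomes*: a planted site starts from the amiRNA's perfect
complement and applies randomly placed edits composing the requested TPS
from the available increments (core mismatch 2, core G:U / non-core
mismatch 1, non-core G:U 0.5); the result is verified with `find_sites`
and re-drawn if any cheaper alignment exists, so the planted minimum TPS
is exact. Requested values must be non-negative multiples of 0.5.
Background transcripts are rejection-sampled to contain no site at or
below the report cap (rejections are rare: random 21-mers score far above
11). *DE tables*: planted genes draw q uniformly below the threshold with
negative log2FC, others above it, so classification recovers the planted
set exactly; baseMean is log-normal window dressing.

## Problem sizes and numerical choices

Default test and demonstration scales — transcripts of a few hundred nt,
read depths of 10³–10⁴, Fisher enumeration over all 2×2 tables with total
≤ 40 — were chosen as the smallest sizes at which every statistical check
is meaningful (3-SE binomial bounds, exhaustive oracle agreement) while the
full suite stays fast on one CPU. Scores and fractions use exact binary
arithmetic where possible (0.5-granular scores; fractional multi-mapping
uses 1/k floats with approximate comparison in tests). Ties: site hits
sort by (TPS, start, end); precursor comparisons break accuracy ties
lexicographically by name; equal-probability Fisher tables are included in
the two-sided sum with a 1e-9 log-scale tolerance in the test oracle.

## Known limitations

- No secondary-structure (MFE) validation of designed precursors; the
  duplex register is positional, not thermodynamic.
- TargetFinder-style scoring constants reproduce the documented 1–11
  behaviour but possible special cases of the original tool
  (consecutive-mismatch caps, position-1 rules) are not modelled; the
  constants are config-exposed for recalibration.
- Exact-match read mapping understates accuracy on error-containing real
  libraries; the one-mismatch mode trades precision for sensitivity.
- Template loop sequences are synthetic stand-ins; real layouts should be
  substituted for wet-lab use.
- Fisher enrichment assumes gene-level independence; correlated regulons
  violate it, as they do for any marginal 2×2 test.
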