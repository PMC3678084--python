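# Methods

## Candidate geometry

An siRNA duplex covers a 23-nt window `w[1..23]` on the target mRNA
(1-based, 5′→3′). The passenger (sense) strand is `w[3..23]` and the guide
(antisense) strand is the reverse complement of `w[1..21]`, giving a 19-bp
duplex core with 2-nt 3′ overhangs on both strands. Guide position 1 pairs
`w[21]`; the seed (guide positions 2–8) pairs `w[14..20]`. Enumeration
slides the window one nucleotide at a time, so an mRNA of length L yields
L − 22 candidates; overlapping passing candidates are all reported (no
spacing constraint is imposed).

## Selection rules

Five conditions are evaluated per candidate, all on the guide strand with
positions counted from its 5′ end:

| rule | predicate | default |
|------|-----------|---------|
| 1 | position 1 is A or U | fixed |
| 2 | A/U count at positions 1–7 | ≥ 4 (of 7; the often-quoted "≥ 57%" is exactly floor(4/7·100)) |
| 3 | position 19 is G or C | fixed |
| 4 | longest G/C run in the 21-mer | ≤ 9 nt |
| 5 | seed-duplex T_m | ≤ 21.5 °C, inclusive |

Rules 1–3 encode the end-asymmetry that favors guide-strand RISC loading
(an A/U-rich, thermodynamically weak guide 5′ end and a G/C-clamped
passenger 5′ end); rule 4 excludes G/C runs that keep the cleaved
passenger fragments annealed; rule 5 caps the seed–target duplex
stability that drives seed-dependent off-target repression. The G/C-run
rule is evaluated on the guide 21-mer: within the 19-bp core any run in
the guide implies an equal-length run in the passenger, and reading a
single strand keeps the operand unambiguous. The overall verdict is the
conjunction of the five predicates. Reynolds-style (A specifically at
position 1) and Amarzguioui-style (G/C but not U at position 19)
preferences are emitted as informational annotations only.

## Seed-duplex melting temperature

The seed duplex is modeled as the fully complementary 7-bp RNA/RNA helix
formed by guide positions 2–8 and its Watson–Crick complement; dangling
ends and flanking target context are ignored, treating seed stability as
a property of the 7-mer alone. Under the two-state nearest-neighbor
model,

    T_m (°C) = 1000·ΔH° / (ΔS° + R·ln(C_T/4)) − 273.15 + 16.6·log10([Na+])

with ΔH° and ΔS° the sums of the six interior stack terms plus helix
initiation (ΔH_init = 0, ΔS_init = −10.8 cal·mol⁻¹·K⁻¹), R = 1.987
cal·mol⁻¹·K⁻¹, C_T = 100 µM total strand (non-self-complementary form of
the concentration term), and [Na⁺] = 100 mM in the standard sodium
correction. Stack parameters are the RNA/RNA set of Freier et al. (1986),
shipped as `data/freier1986_rna_nn.tsv` and replaceable by any TSV with
the same layout; the loader validates that all 16 dinucleotide stacks are
present and that the table is duplex-symmetric (each stack equal to its
reverse complement read from the other strand). The implementation agrees
with Biopython's independent `Tm_NN` nearest-neighbor code to < 10⁻⁶ °C
over random seeds, which the test suite checks.

Numerical choices: the six stacks are canonicalized and summed in sorted
order, so `seed_tm(x) == seed_tm(reverse_complement(x))` holds *exactly*
in floating point, not merely to rounding. Threshold comparisons are
inclusive ("≤") on the design side; on the off-target side a guide is
classed a `strong` inducer when its seed T_m is at or above the benchmark
and `weak` below it, so a seed exactly at the benchmark passes the design
filter and is simultaneously classed strong — the dichotomy's two
published inequalities overlap at equality, and each module follows its
own stated contract. Both thresholds default to 21.5 °C for design and
21.0 °C for seed-space summaries and are configurable.

### Seed-space statistic

Enumerating all 4⁷ = 16,384 seeds under this parameterization, 26.06%
(4,270 seeds) melt at or below 21 °C, the quantity `scripts/acceptance.py`
recomputes. The commonly quoted figure of ~22% for this statistic
corresponds under the same model to a cutoff near 20 °C (`fraction_below(20.0)`
= 21.90%); the discrepancy is inherent to the published
parameterization and is reported as computed rather than calibrated away.
Mean seed T_m increases strictly with seed G/C count, and the available
fraction is monotone in the threshold (both property-tested).

## Off-target audit

The scanner reports every exact occurrence of the reverse complement of
the guide seed in a supplied UTR collection, counted overlap-inclusively
(shift-by-one scan) since each occurrence is a potential binding site.
Only perfect Watson–Crick heptamer matches at guide positions 2–8 are
considered: G:U wobble and position-1 (t1) conventions from the miRNA
target-prediction literature are deliberately excluded, as the off-target
trigger modeled here is the exact 7-nt seed match. The audit makes no
attempt to predict per-transcript repression magnitude; the
stability-governed strong/weak dichotomy is the model's claim. The tool
scans whatever FASTA it is given (typically 3′-UTRs) and does not itself
distinguish UTR from CDS.

## Input handling

Input may be DNA- or RNA-alphabet FASTA; sequences are upper-cased and T
is mapped to U, with the original alphabet recorded. IUPAC ambiguity
codes are rejected by default with the offending position named — the
rules and the T_m model are undefined on them. When
`skip_ambiguous_windows` is set, the designer instead drops every 23-nt
window overlapping an ambiguous character and logs the count. Duplicate
FASTA ids are retained with a warning; design reports key on
(id, window_start). Coordinates are 1-based inclusive throughout.

## Ordering

The five conditions are pass/fail, so ranking is presentation only and
never changes the pass set: passing candidates are ordered by seed T_m
ascending (weakest off-target inducer first), ties by A/U count at
positions 1–7 descending, then by window start ascending — a total,
deterministic order.

## Synthetic data

`generate_synthetic_mrna(length, gc_fraction, seed)` draws residues
i.i.d. with P(G) = P(C) = gc_fraction/2, reproducibly for a fixed seed.
Test mRNAs use lengths 60–500 nt at 40–50% GC, matching typical coding
GC content; UTR stand-ins for the scanner use up to 10 kb. I.i.d.
sequences lack the dinucleotide bias, repeats and local composition
structure of real transcripts, so passing tests demonstrate correctness
of the enumeration, rules, thermodynamics and scanning — not siRNA
efficacy on real genes, which was established by the wet-lab work the
rules summarize. Deterministic fixtures (poly-A mRNAs with a single
planted compliant window; UTRs with planted heptamer sites) make the
expected outputs exactly derivable by hand.

## Limitations

- The T_m model is a two-state, fully complementary helix at fixed salt;
  mismatches, internal loops, dangling ends and alternative salt
  corrections are out of scope.
- No mRNA accessibility or secondary-structure filtering, no
  mismatch-tolerant transcriptome-wide specificity search, and no
  chemical-modification planning.
- The seed-space availability statistic depends on the chosen
  nearest-neighbor parameterization (see above); swapping the parameter
  table changes absolute T_m values and hence the pass set.
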