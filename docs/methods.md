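# Methods

## The design model

Cas12a recognizes a 4-nt T-rich PAM located 5′ of the protospacer and
cuts distally. The toolkit models the target geometry with three
constants: a 23-nt spacer (configurable 20–25 nt), a nominal cleavage
coordinate 18 bp 3′ of the PAM on the targeted strand, and an editing
window around that cut — edits within ±20 bp incorporate at high
frequency, incorporation declines to ~30 bp, and is poor beyond. The
cut is represented as a single coordinate; the staggered two-strand cut
(5′ overhangs) is exposed as an optional annotation with configurable
per-strand offsets (defaults 18 and 23 nt) because only the 18 bp
distance is treated as a hard constant. Homology arms default to 50 bp
per side.

Internally all coordinates are 0-based half-open; user-facing tables
are 1-based inclusive. Reference sequences must be unambiguous
uppercase DNA — only patterns (PAM codes, degenerate primers) may carry
IUPAC codes, which prevents a wildcard in a reference from silently
matching anything. Translation uses the standard nuclear code only; the
host is *S. cerevisiae* and the target ORFs are codon-optimized genes.

## The PAM registry

Per-variant PAM compatibility is shipped as an editable YAML registry
(`src/hicas12a/data/pam_profiles.yaml`). Each rule is an IUPAC 4-mer
pattern with an ordinal efficiency class (high / moderate / low / none)
and a provenance tag (yeast_benchmarked, reported_mammalian,
reported_in_vitro). Classification is deterministic and total:
exclusion rules — carve-outs from broader family claims, such as TVTT
and TSTG inside the impLbCas12a TNTN family — are consulted first, then
the most specific matching entry (fewest concrete 4-mers) wins, ties
going to the higher class; unmatched 4-mers are "none".

Classes are deliberately ordinal rather than numeric. Per-PAM editing
percentages exist only as bar heights in figures, not printed values,
and encoding guessed numbers would lend false precision. The carved-out
TVTT/TSTG patterns are classified "low" rather than "none": the
benchmarking reports them as falling below the efficiency bar, not as
unrecognized. TTTT is covered by the TNTN family claim rather than a
dedicated measurement; the registry's notes field records this.
Variants with negligible yeast activity (FnCas12a-EP16, PrCas12a-3Rv)
classify every 4-mer "none" while retaining their reported in-vitro
patterns for documentation.

## Guide scanning and ranking

Both strands are scanned at every position with spacer room; each site
records the PAM, spacer, strand-local PAM start, and the cleavage
coordinate mapped to the sense strand. Output order is deterministic
(ascending sense PAM coordinate, plus strand first). No genome-wide
off-target search is attempted — the intended use is locus-scale design
— but duplicate spacers within a locus trigger a warning. Ranking for a
given codon edit sorts stably by window class, then |distance| from cut
to the nearest edited base, then PAM class, then coordinate.

The distance–efficiency relationship can be fit with a third-order
polynomial by ordinary least squares (numpy normal-equation solution;
coefficient covariance s²(XᵀX)⁻¹, pointwise t-based 95 % bands). At
least 5 points and a full-rank cubic design are required so a residual
degree of freedom remains.

## Donor design and immunization

The payload codon is the codon of the target residue at minimum Hamming
distance from the wild-type codon, ties broken by an optional host
codon-preference table and then lexicographically. After applying the
payload the edited sequence is re-scanned: the design is considered
re-cleavable if the guide's full spacer occurs exactly (either strand)
immediately 3′ of a PAM of class ≥ "low". The exact-match policy is a
deliberate simplification — no mismatch-tolerance model is available
for these variants in yeast — and a configurable threshold class is the
only knob. While re-cleavable, one synonymous immunizing codon swap is
added per iteration, searching PAM positions first (a PAM knockout is
the most specific disruption) and then protospacer positions ordered by
proximity to the cut, since synonymous marks far from the cleavage site
co-convert poorly and yield impure edits. If no synonymous option
exists the design fails with an instruction to supply an explicit
immunizing edit. Arms flank the minimal interval covering every applied
change; designs whose edits sit closer to a locus end than one arm
length are rejected rather than truncated.

The two-step PAM-replacement planner requires an opposite-strand
installer guide whose editing window covers every base of the PAM being
replaced; installers with all bases in the high window are preferred
and the declining window (≤30 bp) is accepted, which matches the
geometry of the palindromic-PAM layout the scheme is built on (the
installer's cut sits 19–22 bp from the far PAM base). Step 1 writes the
test PAM and a TAA stop codon placed outside the efficient guide's
protospacer and PAM — it must not disturb the protospacer, or step 2
could not cut — and as close to the installer's cut as possible. Step 2
reverts every protein-changing codon to wild type and relies on the
standard immunization loop to block re-cutting of the reverted allele.
Whether real step-1 donors carry additional marks beyond the stop codon
is not documented; the planner emits the minimal design and flags it in
the plan's notes.

## Cassettes, parts, and Golden Gate

Cassette architecture is fixed: TEF1p, a 77-bp pre-tRNA(Gly) (only the
5′ pre-tRNA is needed for processing), then one DR → spacer → donor
block per guide in the order given, optionally with the AAAT
synSeparator before each DR after the first, and CYC1t. The canonical
20-nt LbCas12a direct repeat is the default DR. The shipped promoter,
pre-tRNA and terminator sequences are synthetic stand-ins of realistic
length — the architecture, not the part sequence, is what the package
models — and real constructs should override them via `RunConfig.parts`.

Golden Gate emission assumes a BsaI-style Type IIS enzyme (recognition
site and 4-nt overhangs configurable): primers add the recognition
site, one spacer base, and the fusion overhang to each end of the
insert. Inserts are scanned on both strands for internal recognition
sites, which are reported with 1-based positions and are fatal (the
user must recode). A simulated digestion reconstructs the released
fragment and must round-trip the insert exactly; identical overhangs
are rejected as ligation-ambiguous.

## NNK libraries

NNK (N ∈ {A,C,G,T}, K ∈ {G,T}) enumerates 32 codons per position — all
20 residues plus the single TAG stop. A k-codon scan is 32·k distinct
constructs over a 3·k bp region; the design warns when the region
extends beyond the high editing window. Degenerate inverse-PCR primer
pairs are emitted per position with a configurable 20-nt anchor.
Coverage fold is transformants / distinct constructs. Observed
amino-acid coverage uses a denominator of 20 non-wild-type outcomes per
position (19 substitutions + stop as one class; wild-type-synonymous
observations excluded), with numerator and denominator both reported so
other conventions can be recomputed.

## Amplicon analysis

Merged single-end reads are filtered for the presence of both primers
(mismatch budget configurable, default 0) and oriented to the sense
strand; the filter is idempotent. Codon extraction is anchor-based, not
alignment-based: codons are read at fixed offsets from the located
forward primer, and the reverse primer must sit at the
reference-consistent spacing, so reads with indels between the primers
fail anchoring and are tallied separately — consistent with a
count-then-percentage scheme that never aligns. Percentages are per
position over all counted codons and sum to 100. Editing efficiency is
edited/(edited+wild-type) among reads matching either diagnostic
window, with non-matching reads reported as a separate class.
Enrichment divides per-codon percentages treated/untreated; a codon
absent from the untreated table gets a pseudo-percentage denominator
(default half the smallest positive untreated percentage, always
reported), and a codon absent from the treated table gets ratio 0. MIC
plates are background-subtracted (48 h − 0 h), replicate-averaged, and
row-normalized to the 0-drug column, which must show positive growth.

## The read simulator and what passing tests show

`simulate_reads` draws reads multinomially from planted window
mixtures, places each read on a random strand, and applies uniform
per-base substitution errors (≤10 %); every run is reproducible from
its seed, which is recorded in each record's description. The simulator
emulates composition, orientation and substitution noise only — not
indels, quality-score structure, PCR bias, chimeras, or coverage
gradients — so passing recovery tests demonstrates correctness of the
counting arithmetic and its estimators under sampling noise, not
robustness to every real-library artifact. Likewise the synthetic locus
generator produces uniform-random ORFs with the right geometric
properties (PAM density, arm room); it does not reproduce the
composition of real yeast genes, so design tests certify geometry and
safety logic, not biological editing rates.

## Problem sizes and numerical choices

The test and acceptance workloads use loci of 0.3–1 kb, 50–100
randomized design cases, and read sets of n = 2000 at fractions
0.05–0.95 and error rates 0–0.005 — sizes chosen so the binomial
standard error makes 3σ recovery checks meaningful while the whole
suite stays fast. Statistical assertions use 3 standard errors
(individual checks at ~99.7 % confidence); the χ² mixture check uses
α = 0.01. The cubic fit requires n ≥ 5 and rank-4 design; percentage
sums are checked to 1e-9.

## Known limitations

- No on-target activity prediction (spacer-sequence effects are real
  but unmodeled here; external predictors fill that role) and no
  genome-wide off-target search.
- Exact-match re-cleavage policy may overcall safety if the nuclease
  tolerates spacer mismatches; the threshold class is configurable but
  there is no positional mismatch model.
- Amplicon counting cannot attribute anchor-failed reads; both
  denominators (counted vs. counted+failed) are recoverable from the
  reported tallies.
- Paired-end merging, plasmid backbone modeling, and crRNA-array
  secondary-structure prediction are out of scope.
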