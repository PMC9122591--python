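# Methods

This note documents the models behind `psimpra`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Pairing geometry and the complementarity patch

A pseudouridylation pocket is represented by its two guide elements,
each written 5′→3′: `guide5` (the 5′ side of the internal loop, pairing
target bases 3′ of the Ψ) and `guide3` (the 3′ side, pairing bases 5′ of
the Ψ). Guides are 2–11 nt. The duplex is anchored at the Ψ-proximal
guide ends — the loop bases adjacent to the hairpin's upper stem:
`guide3`'s 5′-terminal base pairs target −1 and `guide5`'s 3′-terminal
base pairs target +2, both antiparallel, with the Ψ and the +1 base
unpaired. A complementarity window of (up, down) bases therefore reads

    patch = revcomp(guide3[:up]) + U + G + revcomp(guide5[-down:])

This anchoring is what makes the four window levels (3,2), (5,4), (8,8),
(10,10) *nest*: shorter windows are sub-strings of longer ones around
the Ψ, so level series differ only in how far the duplex extends. The +1
base is fixed to G in synthetic designs (it is unpaired and typically a
purine at natural sites). Windows requested beyond a guide's length are
truncated to the guide and flagged rather than rejected, since short
guide arms occur in real pocket annotations.

The same register drives the scan pattern (`ideal_target`: 10 bases per
flank, +1 wildcarded, distal positions padded with N for short guides)
and snoRNA retargeting (`design_ptc_snorna` replaces the Ψ-proximal 8 nt
of `guide5` and 3 nt of `guide3` by default, leaving stems and H/ACA
boxes untouched — replacing more risks breaking snoRNA maturation).

## Library assembly

Constructs are DNA-alphabet on disk (U accepted on input, normalized to
T). Each full sequence is adapter + variable sequence + 8-nt barcode +
adapter. Barcodes are drawn by seeded rejection sampling under three
constraints: pairwise Hamming distance ≥ 2 (single sequencing errors
cannot convert barcodes), no homopolymer run ≥ 5, and no cloning-enzyme
site on either strand. Designs whose assembled sequence contains a
cloning site (defaults AscI `GGCGCGCC` + SpeI `ACTAGT`; the Pol-I plasmid
variant HindIII + BamHI) are flagged `omitted` in the manifest and
dropped from the emitted FASTA. The shipped backbone, adapters and
reporter-backbone pieces are synthetic defaults; real plasmid context is
drop-in configuration. Native Ψ sites are windowed into 75-mers with the
Ψ at 1-based position 42 (41 nt upstream, 33 nt downstream — the 3′
flank leaves room for RT priming); sites too close to a molecule end are
skipped with a warning.

At the published panel scale — 99 targeting arms over 68 snoRNAs, the
+1-mutation series on a 30-snoRNA subset — the synthetic sub-library
counts 99×(4 levels + 1 control) + 30×4 = 615 designs, and 108 native
sites give 216 constructs. (A published library of this design reports
606 synthetic constructs, i.e. 9 of the 615 removed by restriction
screening of the particular sequences involved; which designs are
removed depends on the actual guide sequences, so the deterministic
arithmetic, not the post-screen count, is what the tests pin down.)

## Ψ-score model

Internally all coordinates are 0-based half-open; SAM's 1-based closed
convention is converted at the I/O boundary. Fragments are the union
interval of a retained read pair (5′-most coordinate to 3′-most), kept
only if properly paired, mapping quality ≥ 255 and inside the expected
PCR-insert window of their reference — the window comes from the design
manifest, never inferred. All references are plus-strand constructs
(targeted RT from a fixed downstream primer makes the library
strand-resolved); minus-strand logic is rejected.

`starts[i]` counts fragments with 5′ boundary exactly at `i`;
`coverage[i]` counts fragments with `start ≤ i < end`. Coverage is
fragment-level (the union interval), not mate-level; for overlapping
mates the two conventions differ only at boundary bases. The Ψ-score of
site *p* is `starts[p+1]/coverage[p+1]` — the adduct stops RT one base
3′ of the Ψ — with the binomial standard error `sqrt(S/C·(1−S/C)/C)`.
Sites with stop-position coverage below 100 are emitted masked with NaN
fields, never as zeros. Condition comparison is a two-tailed paired
*t*-test over per-site CMC − input deltas; sites masked in either
condition are excluded and counted. No multiple-testing correction is
applied; the comparison table carries raw p-values.

## Context-bias analysis

Per reporter, ordinary least squares of score on Ψ fraction; constant
scores get slope 0 and R² = 0 by convention. "Coefficient of variance"
is read as the coefficient of variation sd/mean with *sample* sd
(ddof = 1) — the population/sample choice is undetermined by the group
sizes alone, so it is fixed and stated here. The ladder partitions the
729 hexamers by their first k downstream bases (k = 0…5; k = 6 would
give singleton groups with undefined sample sd), computes each group's
CV, and averages unweighted — groups are equal-sized by construction, so
weighting only matters for incomplete data, which raises an error
instead. Groups with mean 0 are excluded with a logged count.

## Transcriptome scan

Complementarity is counted as the number of matched flank positions
within the 20 bases surrounding a uridine (10 per side, +1 wildcarded,
so a full-length pattern has 19 countable positions), not the longest
contiguous run; a `contiguous` mode is available in which the U and
wildcard positions bridge runs without extending them. The count
vocabulary (14, 16, 17, 18) refers to matched-position totals; all bins
≥ the threshold are emitted, including 15. Scanning is plus-strand only.
Background is a seeded uniform sample of transcript uridines without
replacement; hit scoring keeps only sites with coverage strictly greater
than 90 in both conditions.

## Readthrough and expression analyses

The fluorescence calibration line is OLS of the downstream/upstream
fluorophore ratio on the no-stop-reporter fraction (0, 0.5, 1, 2, 4,
8%), fitted on replicate means (a per-replicate fit is available behind
a flag); a sample's readthrough is the line inverted at the mean of its
replicate ratios, with below-baseline (negative) estimates reported
as-is and flagged. Dual-luciferase readthrough is the ratio of
stop-construct to no-stop-construct Renilla/Firefly ratios. The
differential analysis takes pre-normalized expression (TMM or
equivalent — normalization itself is out of scope), adds a pseudocount
of 1, uses the log2 ratio between contexts (the ratio form, rather than
a simple difference, is what the pseudocount stabilizes), computes
Spearman's ρ against per-construct ΔΨ-score, and cuts snoRNAs into 3
equal-quantile bins with ties broken by stable order.

## The simulator

Reverse transcription is modeled as a walk from a fixed 3′ primer
toward the 5′ end. Three events can set a fragment's 5′ boundary:

* **Ψ stop** — under the CMC condition, on a molecule modified with
  probability `stoichiometry`, RT terminates at the base one downstream
  of the Ψ with probability `min(1, p_term × context_modifier)`;
* **background stop** — at every base with probability `p_bg`
  (memoryless, i.e. geometric along the walk — the simplest model whose
  input-condition profiles look right; the true background-stop
  distribution is not characterized, so this is a declared modeling
  choice, not an inference);
* **full length** — otherwise the fragment runs to a normal-sampled
  boundary (`frag_len` mean/sd, default 130 ± 15 nt).

Because the background is memoryless and the Ψ draw independent, the
realized boundary is simply the maximum of the independently drawn stop
positions, which is how the implementation vectorizes the walk.
Fragments shorter than 20 nt are discarded as unsequenceable. Under the
INPUT condition Ψ stops never fire. Paired-end detail is collapsed to
fragment intervals; the SAM writer fabricates two 50-nt mates covering
the interval ends for alignment-path round trips. One global seed
drives everything through `SeedSequence([seed, *subkeys])` splitting,
with reference names hashed by CRC32.

Defaults are chosen once as realistic study conditions: `p_term = 0.3`
(pooled reporter scores at 100% Ψ center near 30%), `p_bg = 0.002`
(input-condition scores of a few per mille), `coverage = 2000`
(comfortably above the 100-read mask). The default context effect gives
each downstream position an independent mean-centered lognormal factor
per base with log-sd (0.16, 0.08, 0.05, 0.03, 0.02, 0.01): proximal
bases dominate and the expected pooled score CV,
`sqrt(Σσ²) ≈ 0.19`, is on the ~20% scale reported for pooled
single-site reporter sets. Realized CVs vary by seed (each position's
factor is drawn from only three base values), and the per-k decay
profile is a modeling choice, not a fit.

**What the simulator does not emulate:** sequencing errors, PCR
duplicates, adapter/ligation biases, mate-level coverage structure,
minus-strand transcription, RT fall-off gradients, or CMC chemistry
itself. Passing tests therefore demonstrate correctness of the counting,
scoring and design logic under the stated statistical model — not
robustness to the full error structure of real libraries.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale: 2,000 fragments
per construct for recovery checks, 1,000 per reporter × 6 ratios for the
mixing experiment, 50 kb transcriptomes for scan equivalence, 1,000
fragments for the counting oracle. Degenerate inputs are handled
explicitly: empty fragment sets give zero profiles; zero coverage masks
a call; constant mixing scores define R² = 0; zero-mean CV groups are
excluded with a count; all-masked comparisons and empty scan bins raise
or emit `n = 0` respectively. Quantile ties are broken by first
occurrence; barcode sampling caps attempts and reports progress on
exhaustion.

## Known limitations

* The 606/216 printed construct counts of the published library depend
  on its actual supplementary guide/site tables; only the design
  arithmetic (615/216) is reproducible from scratch.
* Real snoRNA pocket annotations and transcriptomes (e.g. GENCODE) are
  inputs, not bundled; the scan's absolute hit counts on real data are
  out of scope.
* GLMM-based construct-level significance is not implemented; the
  paired *t* and binomial SE are the supported inference tools.
* The `contiguous` scan mode's bridging convention (U/wildcards join
  runs) is one of several defensible definitions; the default `total`
  mode does not depend on it.
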