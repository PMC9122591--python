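# psimpra

Design and quantification of massively parallel snoRNA-target reporter
libraries for pseudouridine (Ψ) sequencing.

H/ACA box snoRNAs guide the pseudouridine synthase DKC1 to a target
uridine by base-pairing: the two single-stranded guide elements of a
hairpin's internal loop (the *pseudouridylation pocket*) pair with the
sequence flanking the substrate U, leaving the U and the base at +1
unpaired. `psimpra` implements the computational side of an MPRA-based
assay that probes this targeting code: it designs barcoded reporter
libraries with graded snoRNA complementarity, simulates and quantifies
CMC/RT-stop (Ψ-seq) sequencing over them, measures how downstream
sequence context biases the readout, scans transcriptomes for candidate
snoRNA targets, and calibrates stop-codon readthrough reporters.

The package is aimed at computational biologists building or analyzing
Ψ-seq reporter experiments, and ships a simulator so every stage runs
and is tested without any external data.

## The quantities computed

**Ψ-score.** CMC forms a bulky adduct at Ψ that terminates reverse
transcription one base downstream, so truncated cDNAs map with their
5′-most coordinate at position *p* + 1 for a Ψ at *p*. With `S` reads
starting at a position and `C` reads covering it,

    psi_score(p) = S(p+1) / C(p+1),    se = sqrt((S/C · (1 − S/C)) / C)

Sites with `C < 100` are masked. Scores of CMC-treated and input
(untreated) libraries are compared per site with a paired *t*-test.

**Design arithmetic.** Per pocket, four target variants with (up, down)
complementarity windows (3,2), (5,4), (8,8), (10,10) around the U (the
+1 base is an unpaired G), a U→G negative control, and optionally four
+1-position perturbations (C/A/U substitution or deletion) of the
(10,10) design. Native rRNA/snRNA Ψ sites are windowed into 75-mers with
the Ψ at position 42. All constructs carry unique 8-nt barcodes
(pairwise Hamming ≥ 2) and are screened for cloning-enzyme restriction
sites on both strands.

**Context bias.** A set of 3⁶ = 729 reporters — one T followed by every
{A,C,G}⁶ hexamer in a T-free backbone — measures how the 6 bases
downstream of the Ψ distort the score: per-reporter OLS of score on Ψ
fraction, and a coefficient-of-variation ladder grouping reporters by
their first *k* downstream bases (1 group of 729 up to 243 groups of 3).

**Target scan.** Each pocket's ideal 21-nt target (10 flank bases per
side, +1 wildcarded) is matched against every transcript uridine;
uridines with ≥ 14 of the 20 flank positions matched are candidate
targets, scored against 1,000 random background uridines.

## Worked example

Design a library for one pocket, simulate CMC and input runs at 40%
stoichiometry with a 30% adduct-termination rate, and call Ψ-scores:

```python
from psimpra import (PseudouridylationPocket, SimulationConfig,
                     design_synthetic_library)
from psimpra.synthetic_data import simulate_library_fragments
from psimpra.read_end_quant import call_sites, compare_conditions

pocket = PseudouridylationPocket("ACA61", 1, guide5="AUCCUGGAGU",
                                 guide3="CUCAGUGGAC")
constructs, manifest = design_synthetic_library([pocket], seed=0)

cmc = SimulationConfig(seed=1, stoichiometry=0.4, p_term=0.3,
                       p_bg=0.002, coverage=2000)
inp = SimulationConfig(seed=2, stoichiometry=0.4, p_term=0.3,
                       p_bg=0.002, coverage=2000, condition="INPUT")
frags_c, lens, psis = simulate_library_fragments(constructs, cmc)
frags_i, _, _ = simulate_library_fragments(constructs, inp)
table, summary = compare_conditions(call_sites(frags_c, lens, psis),
                                    call_sites(frags_i, lens, psis))
print(table)
print(summary)
```

Output:

```
      ref_id  psi_pos0  score_cmc  score_input    delta
 ACA61_a1_L3        61   0.115124     0.001687 0.113437
 ACA61_a1_L5        61   0.116913     0.002255 0.114658
 ACA61_a1_L8        61   0.114636     0.001675 0.112960
ACA61_a1_L10        61   0.115778     0.002836 0.112941
{'t': 281.73, 'p': 9.86e-08, 'n': 4, 'n_excluded': 0}
```

Each CMC Ψ-score sits near stoichiometry × termination probability
(0.4 × 0.3 = 0.12) while input scores stay at the background stop rate;
the paired *t* confirms the CMC-specific stop pileup. The same steps are
available from the shell (`psimpra design synthetic`, `psimpra simulate
reads`, `psimpra quantify`, `psimpra compare`, `psimpra scan`, …).

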