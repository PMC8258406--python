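# Methods

This note documents the models, defaults, and numerical choices behind the
package, and what the synthetic material does and does not establish.

## Primer model

A walking (PST) primer is `adaptor + N^k + palindrome` with k = 6–12
(default 10, the value used by every primer in the shipped catalog) and a
6- or 8-nt self-reverse-complementary 3' end. Its *core* is the
degenerate run plus the palindrome; all thermodynamic metrics refer to the
core, because only the core pairs with template. A sequence-specific
primer (SSP) is `adaptor + hybridizing`, with the hybridizing part plain
ACGT. In the shipped tables, case is the annotation: uppercase adaptor,
lowercase hybridizing region. The universal tail primer equals the 19-nt
adaptor.

## Melting temperature

Unified nearest-neighbor parameters (SantaLucia 1998), two-state model:

    Tm = ΔH / (ΔS + R ln C_eff) − 273.15

with the primer-in-excess convention (C_eff based on primer
concentration). Salt: divalent cations are folded into an effective
monovalent concentration, Mon_eff = Mon + 120·√[Mg²⁺] (mM), applied as
the entropic correction ΔS += 0.368·(L−1)·ln(Mon_eff). Self-complementary
defined sequences get the standard −1.4 cal/mol/K symmetry term.

Degeneracy is handled analytically twice:

1. **Stack averaging.** A nearest-neighbor stack containing ambiguity
   codes contributes the arithmetic mean of ΔH and ΔS over its
   expansions. This is the exact pool average at O(L) cost, instead of
   enumerating 4^k variants.
2. **Mixing entropy.** A degenerate primer is a mixture: of the 4^k
   variants, only a fraction can productively anneal at any one site, so
   the operative concentration is below the nominal one. We charge half
   the ideal mixing entropy, C_eff = C·D^(−1/2) with D the pool
   degeneracy. The exponent interpolates between two limits that are both
   physically wrong: 0 (the whole pool anneals — overestimates Tm of a
   10-N core by ~11 °C against the catalog's published column) and 1
   (only the exact complement anneals — underestimates by ~14 °C, because
   variants with few mismatches still hybridize). At 1/2 the computed Tm
   of all 25 catalog cores and the three SSPs sits within ±1.6 °C of
   their published values; the half-entropy choice is exposed as
   ``mixing_entropy_fraction`` for users who want either limit.

Preset conditions: cores are evaluated at 50 mM monovalent / 2 mM Mg²⁺ /
0.5 µM primer; SSP hybridizing parts at 50 mM / 0 mM / 0.25 µM.
Sequences under 8 nt are rejected (two-state NN is meaningless there).
For defined sequences the implementation agrees with Biopython's
`Tm_NN` under the same parameter set to < 0.1 °C (cross-checked in the
test suite; the in-package implementation exists because no installed
library averages degenerate stacks).

## GC content and linguistic complexity

GC weights each base by its expected G+C fraction (G/C/S = 1, A/T/W = 0,
N and the two-fold half-GC codes = 1/2, B/V = 2/3, D/H = 1/3), rounded
half-up to one decimal. This is the only weighting that reproduces every
published catalog value (e.g. 9/16 = 56.3 for a 10-N + GACGTC core).

Linguistic complexity is substring-vocabulary richness:
100 · (distinct substrings over all lengths) / Σ_k min(4^k, L−k+1),
rounded to integer. Saturated hexamers score 100, a homopolymer 32. The
catalog prints a handful of LC values (89/78/73/83) that no
substring-vocabulary ratio reproduces; the published formula behind those
rows is not stated, so only the saturated (LC = 100) rows are asserted.

## Site model

Walking-primer sites are exact palindrome occurrences; because the
palindrome is its own reverse complement, each occurrence supports both
extension directions, and a direction survives only when the k
degenerate-pairing bases also fit on the template. Overlapping
occurrences are all reported; template ambiguity codes never match.

SSP sites use an invented but conservative mismatch model: the
3'-terminal 12 nt must match exactly (extension initiates there), at most
2 mismatches elsewhere. Both knobs are exposed (`SSPMatchCriteria`). With
budget 0 the scan reduces to exact search on both strands (property
tested).

## Amplification semantics

Products arise from facing site pairs within the amplifiable window
(default 3,000 nt). The window is measured on the genomic span *including*
the degenerate flank(s), excluding adaptor tails; total band length adds
both adaptors. SPECIFIC products need one SSP end and one palindrome end;
IRAP-like products two inverted SSP targets; RAPD-like products two
facing palindrome sites, and these are generated only when the
exponential phase exceeds the ~20-cycle threshold. All in-window pairs
produce bands, not just the nearest — real gels show multiple bands per
lane. Product sequences copy template bases throughout (primer-introduced
degeneracy is not propagated). A `proofreading=True` flag models the
known failure mode of 3'→5' exonuclease polymerases (degradation of the
walking primer's 3' end) as total loss of palindrome-derived products —
deliberately crude, metadata more than mechanism.

The yield model is invented for testability: per-cycle annealing
efficiency e(T) = 1/(1 + exp((T − Tm)/s)) with scale s = 2 °C; linear
phase contributes cycles·e(driver at 72 °C), each exponential cycle
multiplies by 1 + min(e of the two ends), round 2 by (1 + e_tail)^28.
It is monotone in annealing temperature and never changes product
membership, only ordering.

Cycling defaults follow the published protocol: 20 linear cycles at
72 °C, 3 exponential at 60 °C, 28 second-round cycles at 72 °C.
Recommendation-type bounds (≤ 5 exponential cycles) warn rather than
raise, because exploring the RAPD regime requires deliberately exceeding
them; hard errors are reserved for structural impossibilities (negative
counts, linear anneal not hotter than exponential anneal).

## Synthetic material

Hosts are i.i.d. base strings (default GC 0.45 — roughly plant-genome
composition) with no repeat structure: controllable truth, at the price
of not exercising repeat-rich failure modes. The Ac-like element is
4,600 nt with enforced 11-bp terminal inverted repeats and 30-nt
SSP-targetable tag regions within 200 bp of both termini (the internal
hexameric transposase-binding arrays of the real element are not modeled
— nothing simulated depends on them). Insertion duplicates the 8 bp left
of the cut to the element's right flank (one of the two equivalent
target-site-duplication conventions; truth tables use it consistently).

A cohort is four inbred lines plus two F1 hybrids. All lines share one
ancestral host and differ only in insertion content — without a shared
background no band could ever be monomorphic across lines. A hybrid is
its two parental haplotypes amplified independently with band union.
Default panel: one insertion fixed in all lines, five line-unique ones,
on a 60-kb host. Insertion positions are rejection-sampled until (a) the
assembled junction carries exactly one palindrome of the configured
walking primer inside the amplifiable window, and (b) all expected band
lengths are pairwise separated beyond the band-matching tolerance. This
guarantees the 1:1 insertion-to-band truth used by the recovery and
polymorphism tests; real templates offer no such guarantee, so passing
tests demonstrate correctness of the machinery, not expected success
rates on real genomes. Within-line transposition (unique bands among
individuals of an inbred line) is not modeled.

## Band comparison

Two bands match when |a − b| ≤ t·max(a, b), default t = 2% —
approximately agarose sizing error; the published experiments score
bands by eye. Cross-sample band classes use single-linkage clustering of
sorted sizes with the smallest member as class representative
(deterministic, order-independent). Hybrid consistency demands every
parental band reappear in the F1 (threshold configurable, default 1.0).

## Known limitations

- No thermodynamic scoring of partially mismatched duplexes; SSP
  specificity is a counting rule, not a ΔG model.
- No primer-dimer sequence prediction (the protocol's single-primer
  second round reduces dimers; the package documents, but does not
  simulate, that effect).
- Yield is ordinal, not kinetic; no plateau or competition effects.
- The optimal linear-phase ("critical") cycle number is template-specific
  and empirical; the simulator exposes it but cannot derive it.
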