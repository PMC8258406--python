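# pstpcr

An in-silico engine for **palindromic sequence-targeted PCR, version 2**
(PST-PCR v.2) — a genome-walking and transposon-display protocol that
captures unknown DNA flanking a known sequence tag without restriction
digestion or ligation.

## Who this is for

Molecular biologists designing PST-PCR experiments (walking-primer
screens, transposon display of DNA-transposon families such as maize
*Ac*/*Ds*) and method developers who want to predict, before touching a
thermocycler, which amplicons a primer combination will produce from a
given template.

## The method in brief

A **PST (walking) primer** is built 5'→3' as

```
adaptor (19 nt) + dN_k (fully degenerate, k = 6–12) + palindrome (6 or 8 nt)
```

The 3'-terminal palindrome is self-reverse-complementary (it resembles a
type II restriction site, e.g. GACGTC = *Aat*II), so it can anneal at
every genomic occurrence of that hexamer in either orientation. The
**core** (dN_k + palindrome) is the only part expected to pair with
template; its melting temperature T_m is computed with a nearest-neighbor
ΔH/ΔS model at 50 mM monovalent cation, 2 mM Mg²⁺, 0.5 µM primer, with
the degenerate pool's reduced effective concentration charged as mixing
entropy. A **sequence-specific primer (SSP)** carries the *same* adaptor
plus a 25–35 nt hybridizing sequence (GC 40–60%, T_m ≥ 65 °C, no
self-dimers) targeting the known tag.

Round 1 cycles a **linear phase** (annealing at 72 °C — only the SSP
extends, accumulating single-stranded copies) then 1–3 **exponential
cycles** at 55–65 °C where the walking primer joins. Round 2 reamplifies
with a **single universal tail primer** matching the shared adaptor.
Predicted products are classed `SPECIFIC` (SSP end + palindrome end,
within the ~3,000-base amplifiable window), `IRAP_LIKE` (two inverted SSP
targets), or `RAPD_LIKE` (two palindrome sites; only past the ~20-cycle
exponential threshold).

## Worked example

```python
from pstpcr import make_pst_primer, load_ssp_primers, pst_pcr_v2, generate_host

pst = make_pst_primer("GACGTC", 10, id="5601")          # AatII-type walking primer
print("core:", pst.core)
print("Tm %.1f C  GC %.1f%%" % (pst.metrics.tm_C, pst.metrics.gc_percent))

ssp = load_ssp_primers()[0]                              # 5633, Ac 5' terminus
host = generate_host(2000, 0.45, seed=1)
template = host[:100] + ssp.hybridizing + host[127:600] + "GACGTC" + host[606:]

for p in pst_pcr_v2(template, ssp, pst):
    print(p.product_class, f"{p.genomic_span.start}-{p.genomic_span.end}",
          f"{p.total_length} nt", f"yield {p.relative_yield:.1f}")
```

prints

```
core: NNNNNNNNNNGACGTC
Tm 48.0 C  GC 56.3%
SPECIFIC 100-616 554 nt yield 40761.5
```

The SSP target starts at 100, the nearest palindrome occupies 600–606,
and the walking primer's ten degenerate bases pair beyond it, so the
product covers template 100–616 and the two 19-nt adaptor tails bring the
band to (616 − 100) + 38 = 554 nt. The yield value is a relative copy
number from the logistic annealing-efficiency model — useful for ordering
bands, not an absolute quantity.

A full virtual transposon display — synthetic maize-like cohort (4 inbred
lines, 2 F1 hybrids, Ac-like 4.6-kb elements with 11-bp TIRs and 8-bp
target-site duplications), amplification, band calling, text gel, and a
0/1 presence matrix — is a few lines:

```python
from pstpcr import make_cohort, run_transposon_display, presence_matrix

cohort = make_cohort(seed=1)
patterns = run_transposon_display(cohort.samples, cohort.ssp, cohort.pst)
matrix = presence_matrix(list(patterns.values()))
```

The same operations are available from the shell:

```bash
pstpcr synth --seed 1 --out cohort/
pstpcr amplify --fasta cohort/B73.fasta --ssp 5633 --pst 5601 --out out/
pstpcr config --dump
```

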