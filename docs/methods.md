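# Methods

`junctionprimer` designs transcript-specific RT-qPCR primer pairs anchored on
exon–exon junctions and screens them by in-silico PCR. This note records the
models, the defaults and why they were chosen, what the synthetic fixtures do
and do not emulate, and the numerical choices that affect results.

## Junction selection

For a gene with transcripts *T* and a user-chosen target set *S ⊆ T*, a
junction *j* (identified genomically by its donor/acceptor coordinates and
strand, so the same splice event unifies across isoforms) is **perfect** when
every transcript in *S* contains *j* and no transcript in *T∖S* does. A primer
pair anchored on a perfect junction amplifies exactly the chosen isoforms from
cDNA.

Perfect junctions are the set `{ j : members(j) = S }`. A consequence worth
stating: enlarging *S* never preserves a perfect junction (the membership
class changes), so the perfect sets of nested target sets are disjoint — there
is no monotone relationship between their sizes.

When no perfect junction exists, all junctions are ranked by

1. coverage (number of targets containing *j*), descending;
2. leakage (number of unselected isoforms containing *j*), ascending;
3. presence on the canonical transcript (annotation-tagged, or the longest
   cDNA with lexicographic tie-break when the annotation carries no tag);
4. genomic coordinate (determinism).

Warnings name every unselected isoform the top junction would co-detect
(`non_targeted_detected`) and every target it misses (`target_not_detected`).
All junctions tied at the top rank are passed to design; the per-pair
specificity screen then separates them on evidence rather than on an
arbitrary choice.

## Variant masking

Positions where a short variant reaches allele frequency ≥ 1 % (configurable;
the boundary is inclusive, the conservative reading for assay safety) are
projected through the exon structure into cDNA coordinates and replaced by
`N`. Indels mask their whole REF footprint. Enumeration rejects any primer
window containing `N`, making the mask a hard exclusion rather than a
penalty: a common variant under a primer can destabilise annealing in samples
carrying the alternate allele and bias quantification. One numerical detail:
VCF INFO floats round-trip through float32 in the reader, so frequencies are
restored to 6 significant digits before the threshold comparison — otherwise
a printed `AF=0.01` record falls below a 0.01 threshold.

## Melting temperature

Nearest-neighbor model with the unified Allawi–SantaLucia dinucleotide
parameters (ΔH in kcal/mol, ΔS in cal/mol/K), terminal A·T / G·C initiation
terms and the self-complementarity symmetry correction. Salt is handled with
the entropy correction ΔS += 0.368 (N−1) ln[Na⁺_eq] with the von Ahsen
monovalent equivalent for divalent cations, and the duplex term uses
Tm = 1000·ΔH / (ΔS + R ln C) − 273.15 with C = [oligo]/2 for
non-self-complementary duplexes (equal strand concentrations).

Defaults: 50 mM monovalent, 0 mM Mg²⁺, 500 nM per strand. These are declared
package defaults — the constraint windows (Tm 59/60/62 °C, GC 0.35–0.65,
length 18/20/25) were chosen for intercalating-dye qPCR practice, and all are
configurable. The implementation agrees with an independent route
(Biopython's `Tm_NN`, same table and corrections) to < 10⁻⁹ °C; the test
suite keeps the two routes separate. Predicted amplicon Tm uses the same
model; for ~100–200 bp products it should be read as a rough melt-curve
guide, not a calibrated prediction.

## Dimer and hairpin screening

Self- and cross-complementarity are scored with an ungapped alignment of one
primer against the reverse of the other: +1 per Watson–Crick pair, −1 per
mismatch, maximised over all offsets (floored at 0), with a variant
restricted to alignments covering a primer's 3′ terminus, and a hairpin
variant over fold diagonals with a minimum loop of 3 nt. Pairs are rejected
when any score ≥ 8 or a 3′-anchored dimer score ≥ 5. This is a deterministic,
brute-force-verifiable contract; it deliberately avoids thermodynamic duplex
folding, whose parameters would be another undocumented degree of freedom.

## Candidate enumeration

Enumeration is exhaustive over the anchored window — no stochastic search, no
external design engine — so identical inputs give identical output.

* **span mode** (default): exactly one primer of each pair crosses the
  junction with at least 4 bases on the 3′ side and 4 on the 5′ side of the
  boundary (configurable); its mate lies entirely on the opposite side.
* **flank mode**: both primers sit off the junction with their 3′ ends on
  opposite sides, so the amplicon crosses it but neither primer does. This
  only protects against genomic signal when the intron is long relative to
  the product cap, and is offered for experiments where genomic carry-over
  is not a concern.

Amplicons are bounded to 70–200 nt by default (qPCR practice). Each pair
carries a penalty

    |Tm_f − Tm_opt| + |Tm_r − Tm_opt| + |Tm_f − Tm_r|
      + 0.25·(|len_f − len_opt| + |len_r − len_opt|)
      + 5·(|gc_f − 0.5| + |gc_r − 0.5|)

in Tm-equivalent degrees; a pair at the exact optima scores 0. The quadratic
heterodimer check runs lazily in penalty order until the per-junction cap
(50) is filled. When nothing survives, a rejection histogram (per cause:
`gc`, `tm_low`, `tm_high`, `masked`, `junction_overlap`, `homodimer`,
`heterodimer`, `pair_tm_diff`, `amplicon_len`, `primer_overlap`) explains
why.

## In-silico PCR and the two-round screen

Binding sites are found by an exhaustive Hamming scan of every position on
both strands of every database sequence (vectorised sliding windows; no
seeding heuristic, so no qualifying site can be missed). A site qualifies at
≤ 3 total mismatches; a site can support a product only with 0 mismatches in
its 3′-terminal 5 nt (a mismatched 3′ end blocks extension). Products are
emitted for convergent cross-role site pairs on one sequence within a length
cap (2000 nt for cDNA, 5000 nt for genome). Single-primer alignments that
support no product are kept as "unproductive hits" and reported.

Round 1 screens the spliced-transcript database — the dominant template in an
RT reaction — and classifies products as `on_target` (selected transcript),
`non_target_isoform` (unselected isoform of the gene) or `off_target_gene`.
Pairs with cross-gene products are rejected, **unless every pair has one**,
in which case all are kept and flagged so the user can decide. The best
survivors (default 10, by penalty then fewest products) advance to the
genomic round; genomic products down-rank a pair (they matter only when
genomic DNA survives the RT reaction) but never silently remove it, and a
genome product whose locus coincides with the contiguous footprint of an
on-target single-exon amplicon is not counted against the pair.

A consequence of honest exhaustive search worth knowing: a junction-spanning
primer at the *minimal* 4-base 5′ overlap keeps ≥ 20 contiguous exon-matching
bases, so it can bind genomic DNA at the intron–exon boundary within the
3-mismatch budget with a clean 3′ end, and short genomic products that never
cross the intron are then reported. This is real chemistry (5′ mismatches do
not block priming) and is exactly why the genomic round exists; spanning
primers with balanced overlaps are far more protective than minimal-overlap
ones, and the ranking reflects that through the genomic-product weight.

## Final score and report

    final = pair_penalty + 2·(non-target-isoform products)
          + 5·(cross-gene products) + 3·(genomic products)
          + 0.1·(unproductive hits)

Lower is better; the weights are this package's own ranking device (no
external definition exists) and are configurable. Rows are sorted by score,
then amplicon length, then pair id — a total order, so reports are
byte-reproducible. CSV/TSV/JSON writers fix temperatures and scores at two
decimals and round-trip losslessly. Exit codes: 0 = pairs found, 3 = pairs
found but all carry specificity flags, 4 = no candidate satisfied the
constraints.

## Synthetic loci

The fixture generator builds a plus-strand gene on `chr1`: two leading exons
shared by all isoforms (a common first junction) and a private exon run per
isoform (each isoform owns discriminating junctions), with exon lengths
80–300 nt and introns 500–5000 nt by default. Background sequence is i.i.d.
at 45 % GC; 150-nt windows flanking every junction are drawn with
block-stratified exact composition (10-nt blocks at exactly 60 % GC). The
stratification exists because i.i.d. windows left ~8 % of junctions with no
feasible primer at default constraints (local G/C clumps), which would have
made design-dependent tests vacuous; roughly 0.4 % of junctions remain
infeasible and the rejection histogram documents those. Optional plants:
an intron-less copy of the canonical cDNA on `chr2` (processed pseudogene),
and a decoy transcript of another gene carrying a verbatim copy of the cDNA
around the shared junction (a universal cross-gene off-target). The VCF
plants allele frequencies straddling the 1 % threshold, including one record
exactly at the boundary and one multi-base deletion. One seeded generator
drives everything; identical seeds give byte-identical files.

What the fixtures do **not** emulate: splice-site motifs, strand variety
(generated loci are plus-strand; minus-strand correctness is covered by unit
tests), repeat families, paralogous gene families beyond the single planted
decoy, homopolymer-rich or GC-extreme genomes, and expression levels. A green
end-to-end test therefore establishes the bookkeeping — selection algebra,
masking projection, search exhaustiveness, classification, ranking — on
realistic-scale clean sequence, not performance on hard genomes.

## Known limitations

* Binding is Hamming-based (no gaps, no thermodynamic duplex energies);
  mismatch counts stand in for binding strength.
* The canonical-transcript preference is a tie-break, not a restriction to
  canonical junctions (the alternative reading of "targeted preferentially").
* Custom transcripts (FASTA with a `junctions=` header token, or GenBank
  with exon features) carry no genomic exon structure, so variant masking
  and the genomic-footprint exemption do not apply to them.
* Single-exon genes have no junction and are rejected with a structured
  error rather than falling back to unanchored design.
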