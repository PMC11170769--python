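# junctionprimer

Transcript-specific RT-qPCR primer design on exon–exon junctions, with
common-variant masking and two-round in-silico PCR specificity screening.

## The problem

Intercalating-dye RT-qPCR measures gene expression through total
double-stranded signal, so *any* amplification — residual genomic DNA, an
unintended isoform, another gene — inflates the readout. Good assays
therefore anchor a primer on an exon–exon junction (a sequence that exists
in spliced mRNA but not in genomic DNA), pick junctions that discriminate
the isoforms of interest, keep primers off common polymorphisms (which can
destabilise annealing in some samples), and verify by in-silico PCR that no
other template in the transcriptome or genome can amplify. `junctionprimer`
automates that whole chain for users who have a genome FASTA and a GTF/GFF3
annotation — any species, no downloads.

## What it computes

For a gene with transcripts *T* and user-selected targets *S ⊆ T*:

1. **Junction selection** — junctions present in every target and absent
   from every unselected isoform ("perfect" junctions, the set
   `{j : members(j) = S}`). If none exist, junctions are ranked by coverage
   of *S*, leakage into *T∖S*, canonical-transcript preference and
   coordinate, and the user is warned which isoforms will be co-detected or
   missed.
2. **Masking** — VCF positions with allele frequency ≥ 1 % (configurable)
   are projected into cDNA space and excluded from primer placement.
3. **Design** — exhaustive enumeration of junction-anchored pairs under
   nearest-neighbor Tm (unified Allawi–SantaLucia parameters with salt
   correction), GC, length, amplicon-length, and dimer/hairpin constraints.
   In `span` mode one primer crosses the junction with minimum overlaps on
   both sides; in `flank` mode the primers bracket it.
4. **Two-round specificity screen** — an exhaustive mismatch-bounded
   (≤ 3, with a clean 3′-terminal window required for extension) binding
   search over the spliced-transcript database, rejecting pairs predicted
   to amplify other genes (unless *all* pairs are affected, in which case
   everything is reported flagged), then over genomic DNA, down-ranking
   pairs with predicted genomic products.
5. **Ranking** — `final = pair_penalty + 2·(isoform off-targets) +
   5·(cross-gene) + 3·(genomic) + 0.1·(unproductive single-primer hits)`;
   lower is better. See `docs/methods.md` for every model and default.

## Worked example

Generate a synthetic 3-isoform locus (ground truth included) and design
primers specific to isoform `T1`, avoiding common variants:

```bash
junctionprimer make-fixture --seed 42 -o fixture/
junctionprimer design --genome fixture/genome.fa --gtf fixture/annotation.gtf \
    --gene GENE1 --transcripts T1 --vcf fixture/common.vcf -o out/ --seed 42
```

The run exits 0 and writes `out/primers.csv`, ranked best-first. The top of
the table from exactly this command:

```
pair_id,forward,reverse,junction,junction_locus,amplicon_len,fwd_tm,rev_tm,...
P007,CGGTGTGTGAACCGGAACAG,TGCGATACCGCGATCTCCTT,e2-e3,chr1:5279^9274(+),150,59.87,59.79,...
P006,CGGTGTGTGAACCGGAACAG,AGTGTGCGATACCGCGATCT,e2-e3,chr1:5279^9274(+),154,59.87,60.08,...
```

Reading row `P007`: the pair anchors on junction `e2-e3` of `T1` (genomic
donor^acceptor `chr1:5279^9274`, a junction no other isoform contains — the
selector chose it because it is *perfect* for `{T1}`). The forward primer
crosses that junction, so the 150 nt amplicon cannot arise from genomic DNA.
Both primers melt near the 60 °C optimum (59.87/59.79 °C, pair penalty
1.16), the predicted amplicon melt is 83.87 °C, the screen detected exactly
`T1` (`detected_transcripts=T1`), found no isoform, cross-gene or genomic
products (`genomic_products=0`), and one harmless single-primer alignment
(`unproductive_hits=1`) gives the final score 1.26 = 1.16 + 0.1·1.

Exit codes: `0` usable pairs, `3` pairs exist but all carry specificity
flags (reported so the user can make an informed decision), `4` nothing
satisfied the constraints (a rejection histogram is logged).

The same pipeline is available as a library:

```python
from junctionprimer import run_pipeline
result = run_pipeline("genome.fa", "annotation.gtf", "GENE1", {"T1"},
                      vcf="common.vcf")
result.rows[0].forward        # 'CGGTGTGTGAACCGGAACAG'
```

`junctionprimer specificity --fwd ... --rev ... --db seqs.fa` screens an
existing pair against any FASTA database.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a seeded synthetic locus with a
planted processed pseudogene and a planted cross-gene decoy — fixture
generation, annotation loading, variant masking, junction selection, design,
both screening rounds, and the ranked report — and writes the results
manifest to `--out` (a summary of the run goes to stderr).
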