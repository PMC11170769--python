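"""Seeded synthetic loci with known ground truth.

Each generated locus is a multi-isoform gene laid out on ``chr1``: two
leading exons shared by every isoform (so all isoforms share the first
junction) followed by a private run of exons per isoform (so every isoform
owns at least one discriminating junction).  Exon and intron sequences are
drawn i.i.d. with a configurable GC bias, and 60%-GC primer-friendly windows
are injected around every junction so that design at default thermodynamic
parameters is feasible rather than vacuously empty.

Optional plants:

* a processed pseudogene — an intron-less copy of the canonical isoform's
  cDNA dropped onto ``chr2``, the classic source of genomic qPCR background;
* a decoy transcript of another gene carrying a verbatim copy of the cDNA
  around the shared junction, creating a universal cross-gene off-target.

Common variants are written to a VCF with allele frequencies straddling the
1% masking threshold (including one exactly at the boundary and one
multi-base deletion).  Everything is derived from one seeded generator:
identical seeds give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

__all__ = ["SyntheticLocusSpec", "GroundTruth", "LocusFixture", "generate_locus"]

_PAD = 800  # flat flanks around the gene body


@dataclass(frozen=True)
class SyntheticLocusSpec:
    seed: int = 42
    n_isoforms: int = 3
    n_exons: int = 4                      # per isoform (2 shared + private run)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (500, 5000)
    gc_bias: float = 0.45                 # background GC of exons/introns
    friendly_gc: float = 0.60             # GC of windows around junctions
    friendly_window: int = 150            # nt of friendly sequence per side
    n_common_variants: int = 12
    plant_pseudogene: bool = False
    plant_cdna_offtarget: bool = False

    def __post_init__(self) -> None:
        if self.n_isoforms < 1 or not 4 <= self.n_exons <= 8:
            raise ValueError("need >=1 isoforms with 4-8 exons each")
        for lo, hi in (self.exon_len, self.intron_len):
            if not 0 < lo <= hi:
                raise ValueError("length ranges must be positive and ordered")


@dataclass
class GroundTruth:
    seed: int
    junction_matrix: dict[str, dict[str, int]]       # label -> {tx: 0/1}
    junction_labels: dict[str, str]                  # label -> chrom:donor^acceptor(strand)
    perfect_junctions: dict[str, list[str]]          # "T1+T2" -> labels
    masked: dict[str, list[int]]                     # chrom -> positions (AF >= 1%)
    variant_afs: list[tuple[str, int, int, float]]   # chrom, pos, ref_len, af
    pseudogene_locus: tuple[str, int, int] | None = None
    decoy_locus: tuple[str, int, int] | None = None  # decoy id span of copied cdna
    decoy_source_span: tuple[int, int] | None = None  # copied window in canonical cdna

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "junction_matrix": self.junction_matrix,
            "junction_labels": self.junction_labels,
            "perfect_junctions": self.perfect_junctions,
            "masked": {k: sorted(v) for k, v in self.masked.items()},
            "variant_afs": self.variant_afs,
            "pseudogene_locus": self.pseudogene_locus,
            "decoy_locus": self.decoy_locus,
            "decoy_source_span": self.decoy_source_span,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class LocusFixture:
    spec: SyntheticLocusSpec
    genome: dict[str, str]
    gtf: str
    vcf: str
    decoys: dict[str, str]               # decoy transcript id -> sequence
    decoy_genes: dict[str, str]          # decoy transcript id -> gene id
    truth: GroundTruth
    gene_id: str = "GENE1"

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "vcf": outdir / "common.vcf",
            "decoys": outdir / "decoys.fa",
            "truth": outdir / "truth.json",
        }
        paths["genome"].write_text("".join(
            f">{name}\n{_wrap(seq)}\n" for name, seq in self.genome.items()))
        paths["gtf"].write_text(self.gtf)
        paths["vcf"].write_text(self.vcf)
        paths["decoys"].write_text("".join(
            f">{tx} gene={gene}\n{_wrap(self.decoys[tx])}\n"
            for tx, gene in self.decoy_genes.items()))
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def _draw(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _draw_fixed_gc(rng: np.random.Generator, n: int, gc: float,
                   block: int = 10) -> str:
    """Block-stratified exact-composition draw for primer-friendly windows.

    Every ``block``-nt block carries exactly ``round(gc * block)`` G/C
    letters, randomly arranged.  An i.i.d. draw at the same mean GC clumps
    often enough (long G/C runs, 70%+ windows) that some junctions admit no
    primer at the default GC/Tm constraints, which would make every
    design-dependent test of that junction vacuous; stratification bounds
    the composition of every primer-sized window while staying sequence-
    random."""
    out = []
    for start in range(0, n, block):
        size = min(block, n - start)
        n_gc = round(gc * size)
        letters = [rng.choice(["G", "C"]) for _ in range(n_gc)]
        letters += [rng.choice(["A", "T"]) for _ in range(size - n_gc)]
        out.extend(rng.permutation(letters))
    return "".join(out)


def _perfect_set(members: dict[str, set[str]], targets: set[str],
                 all_tx: set[str]) -> list[str]:
    """Set-algebra definition of perfect junctions, by construction."""
    unselected = all_tx - targets
    return sorted(
        label for label, txs in members.items()
        if targets <= txs and not (txs & unselected)
    )


def generate_locus(spec: SyntheticLocusSpec) -> LocusFixture:
    """Build the locus, annotation, variants and decoys for one seed."""
    rng = np.random.default_rng(spec.seed)
    n_private = spec.n_exons - 2

    # ---- exon layout along chr1: shared e1, e2, then per-isoform runs ----
    exon_seqs: list[str] = []
    exon_coords: list[tuple[int, int]] = []
    cursor = _PAD
    chrom_parts = [_draw(rng, _PAD, spec.gc_bias)]
    n_exons_total = 2 + spec.n_isoforms * n_private
    for _ in range(n_exons_total):
        length = int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
        seq = _draw(rng, length, spec.gc_bias)
        # primer-friendly windows at both exon ends (junction flanks)
        w = min(spec.friendly_window, length)
        seq = _draw_fixed_gc(rng, w, spec.friendly_gc) + seq[w:]
        if len(seq) > w:
            tail = min(spec.friendly_window, len(seq) - w)
            seq = seq[: len(seq) - tail] + _draw_fixed_gc(
                rng, tail, spec.friendly_gc)
        exon_seqs.append(seq)
        exon_coords.append((cursor, cursor + length))
        chrom_parts.append(seq)
        cursor += length
        intron = int(rng.integers(spec.intron_len[0], spec.intron_len[1] + 1))
        chrom_parts.append(_draw(rng, intron, spec.gc_bias))
        cursor += intron
    chrom_parts.append(_draw(rng, _PAD, spec.gc_bias))
    chr1 = "".join(chrom_parts)

    # isoform i (1-based) -> exon indices into the layout
    tx_exons: dict[str, list[int]] = {}
    for i in range(spec.n_isoforms):
        private = [2 + i * n_private + k for k in range(n_private)]
        tx_exons[f"T{i + 1}"] = [0, 1] + private
    all_tx = set(tx_exons)

    # ---- ground-truth junction incidence, by construction ----
    members: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for tx, idxs in tx_exons.items():
        for a, b in zip(idxs, idxs[1:]):
            donor = exon_coords[a][1]
            acceptor = exon_coords[b][0]
            label = f"J{a + 1}_{b + 1}"
            members.setdefault(label, set()).add(tx)
            labels[label] = f"chr1:{donor}^{acceptor}(+)"
    junction_matrix = {
        label: {tx: int(tx in txs) for tx in sorted(all_tx)}
        for label, txs in members.items()
    }
    perfect = {}
    for r in range(1, len(all_tx) + 1):
        for subset in combinations(sorted(all_tx), r):
            perfect["+".join(subset)] = _perfect_set(
                members, set(subset), all_tx)

    # ---- GTF (1-based inclusive); T1 is canonical ----
    gtf_lines = []
    for tx in sorted(tx_exons):
        for rank, exon_idx in enumerate(tx_exons[tx], start=1):
            start, end = exon_coords[exon_idx]
            attrs = (
                f'gene_id "GENE1"; transcript_id "{tx}"; '
                f'exon_number "{rank}"; gene_name "GENE1";'
            )
            if tx == "T1":
                attrs += ' tag "Ensembl_canonical";'
            gtf_lines.append(
                f"chr1\tsynthetic\texon\t{start + 1}\t{end}\t.\t+\t.\t{attrs}"
            )
    # write rows in genomic order regardless of rank order
    gtf_lines.sort(key=lambda l: int(l.split("\t")[3]))
    gtf = f"#!seed {spec.seed}\n" + "\n".join(gtf_lines) + "\n"

    # ---- spliced cDNA of the canonical isoform (the loader must agree) ----
    canonical_cdna = "".join(exon_seqs[i] for i in tx_exons["T1"])

    # ---- common variants straddling the masking threshold ----
    af_cycle = [0.25, 0.05, 0.02, 0.01, 0.009, 0.002]
    exonic_pool = [
        pos for start, end in exon_coords for pos in range(start, end)
    ]
    gene_span = (exon_coords[0][0], exon_coords[-1][1])
    intronic_pool = [
        pos for pos in range(*gene_span)
        if not any(s <= pos < e for s, e in exon_coords)
    ]
    n_exonic = spec.n_common_variants // 2
    positions = sorted(
        {int(p) for p in rng.choice(exonic_pool, size=n_exonic, replace=False)}
        | {int(p) for p in rng.choice(
            intronic_pool, size=spec.n_common_variants - n_exonic,
            replace=False)}
    )
    vcf_rows = []
    variant_afs = []
    masked: set[int] = set()
    for k, pos in enumerate(positions):
        af = af_cycle[k % len(af_cycle)]
        ref_len = 3 if k == 0 else 1  # first record is a deletion
        ref = chr1[pos : pos + ref_len]
        if ref_len == 1:
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        else:
            alt = ref[0]
        vcf_rows.append(
            f"chr1\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\tAF={af}"
        )
        variant_afs.append(("chr1", pos, ref_len, af))
        if af >= 0.01:
            masked.update(range(pos, pos + ref_len))
    vcf = (
        "##fileformat=VCFv4.2\n"
        f"##source=junctionprimer synthetic locus seed={spec.seed}\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
        + "".join(f"##contig=<ID={c},length={n}>\n"
                  for c, n in (("chr1", len(chr1)),))
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        + "\n".join(vcf_rows) + "\n"
    )

    # ---- optional plants ----
    genome = {"chr1": chr1}
    pseudogene_locus = None
    if spec.plant_pseudogene:
        pad = _draw(rng, _PAD, spec.gc_bias)
        genome["chr2"] = pad + canonical_cdna + _draw(rng, _PAD, spec.gc_bias)
        pseudogene_locus = ("chr2", _PAD, _PAD + len(canonical_cdna))

    decoys: dict[str, str] = {}
    decoy_genes: dict[str, str] = {}
    decoy_locus = None
    decoy_source_span = None
    if spec.plant_cdna_offtarget:
        # copy the cDNA around the junction shared by all isoforms (after the
        # first exon of the canonical cDNA) into an unrelated transcript
        j0 = len(exon_seqs[tx_exons["T1"][0]]) - 1
        lo = max(0, j0 - 260)
        hi = min(len(canonical_cdna), j0 + 261)
        insert = canonical_cdna[lo:hi]
        head = _draw(rng, 300, spec.gc_bias)
        tail = _draw(rng, 300, spec.gc_bias)
        decoys["DECOY_T1"] = head + insert + tail
        decoy_genes["DECOY_T1"] = "DECOY_G1"
        decoy_locus = ("DECOY_T1", len(head), len(head) + len(insert))
        decoy_source_span = (lo, hi)

    truth = GroundTruth(
        seed=spec.seed,
        junction_matrix=junction_matrix,
        junction_labels=labels,
        perfect_junctions=perfect,
        masked={"chr1": sorted(masked)},
        variant_afs=variant_afs,
        pseudogene_locus=pseudogene_locus,
        decoy_locus=decoy_locus,
        decoy_source_span=decoy_source_span,
    )
    return LocusFixture(
        spec=spec, genome=genome, gtf=gtf, vcf=vcf, decoys=decoys,
        decoy_genes=decoy_genes, truth=truth,
    )
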