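"""Scoring, ranking and tabular reporting; end-to-end pipeline orchestration.

``final_score`` combines the thermodynamic pair penalty with weighted counts
of predicted specificity problems (lower is better)::

    final = pair_penalty + w_iso * n_non_target_isoform
                         + w_gene * n_off_target_gene
                         + w_gen  * n_genomic
                         + w_unprod * n_unproductive_hits

The score is this package's own ranking device — it has no external
definition — and is labelled as such in the output.  Reports are written as
CSV/TSV/JSON with temperatures and scores fixed at two decimals; re-parsing
a written report reconstructs every field exactly.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path

from Bio import SeqIO

from .junction_selection import (
    JunctionSelection,
    SelectionRequest,
    select_junctions,
)
from .primer_design import (
    DesignParams,
    DesignResult,
    PrimerPair,
    generate_pairs,
    melting_temperature,
)
from .specificity import SpecificityParams, SpecificityReport, two_round_filter
from .transcript_model import (
    GeneModel,
    GenomeRef,
    load_annotation,
    load_genome,
)
from .variant_masking import VariantMask, apply_mask, load_common_variants

__all__ = [
    "ScoreWeights",
    "ResultRow",
    "PipelineResult",
    "final_score",
    "build_rows",
    "write_report",
    "read_report",
    "run_pipeline",
]

EXIT_OK = 0
EXIT_ALL_FLAGGED = 3
EXIT_NO_CANDIDATES = 4


@dataclass(frozen=True)
class ScoreWeights:
    w_iso: float = 2.0      # per non-target isoform product
    w_gene: float = 5.0     # per cross-gene product
    w_gen: float = 3.0      # per genomic product
    w_unprod: float = 0.1   # per unproductive single-primer hit


def final_score(pair: PrimerPair, report: SpecificityReport,
                weights: ScoreWeights | None = None) -> float:
    weights = weights or ScoreWeights()
    return (
        pair.pair_penalty
        + weights.w_iso * report.count("non_target_isoform")
        + weights.w_gene * report.count("off_target_gene")
        + weights.w_gen * report.count("genomic")
        + weights.w_unprod * len(report.unproductive_hits)
    )


def _q2(value: float) -> float:
    """Quantize to the 2-decimal figure that will be printed."""
    return float(f"{value:.2f}")


@dataclass(frozen=True)
class ResultRow:
    pair_id: str
    forward: str
    reverse: str
    junction: str          # exon-rank label on the design template, e.g. e2-e3
    junction_locus: str    # genomic donor^acceptor label
    amplicon_len: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    amplicon_tm: float
    pair_penalty: float
    final_score: float
    detected_transcripts: str    # ';'-joined transcript ids
    non_target_isoforms: str
    off_target_genes: str
    genomic_products: int
    unproductive_hits: int
    flagged: bool

    _FLOATS = ("fwd_tm", "rev_tm", "fwd_gc", "rev_gc", "amplicon_tm",
               "pair_penalty", "final_score")
    _INTS = ("amplicon_len", "genomic_products", "unproductive_hits")


def build_rows(
    scored: list[tuple[PrimerPair, SpecificityReport]],
    junction_labels: dict[str, tuple[str, str]],
    amplicon_tms: dict[str, float],
    gene_of: dict[str, str],
    weights: ScoreWeights | None = None,
) -> list[ResultRow]:
    """Assemble and rank the report table (final_score, amplicon_len, id)."""
    rows = []
    for pair, rep in scored:
        exon_label, locus_label = junction_labels[pair.pair_id]
        detected = sorted({p.seq_id for p in rep.products
                           if p.category == "on_target" and p.db == "cdna"})
        non_target = sorted({p.seq_id for p in rep.products
                             if p.category == "non_target_isoform"})
        off_genes = sorted({gene_of.get(p.seq_id, p.seq_id)
                            for p in rep.products
                            if p.category == "off_target_gene"})
        rows.append(ResultRow(
            pair_id=pair.pair_id,
            forward=pair.forward.sequence,
            reverse=pair.reverse.sequence,
            junction=exon_label,
            junction_locus=locus_label,
            amplicon_len=pair.amplicon_len,
            fwd_tm=_q2(pair.forward.tm),
            rev_tm=_q2(pair.reverse.tm),
            fwd_gc=_q2(pair.forward.gc),
            rev_gc=_q2(pair.reverse.gc),
            amplicon_tm=_q2(amplicon_tms.get(pair.pair_id, float("nan"))),
            pair_penalty=_q2(pair.pair_penalty),
            final_score=_q2(final_score(pair, rep, weights)),
            detected_transcripts=";".join(detected),
            non_target_isoforms=";".join(non_target),
            off_target_genes=";".join(off_genes),
            genomic_products=rep.count("genomic"),
            unproductive_hits=len(rep.unproductive_hits),
            flagged=rep.flagged,
        ))
    rows.sort(key=lambda r: (r.final_score, r.amplicon_len, r.pair_id))
    return rows


_COLUMNS = [f.name for f in dataclass_fields(ResultRow)]


def write_report(rows: list[ResultRow], path: str | Path,
                 fmt: str = "csv") -> Path:
    """Write the ranked table; an empty list produces a header-only file."""
    path = Path(path)
    if fmt not in ("csv", "tsv", "json"):
        raise ValueError(f"unknown report format {fmt!r}")
    if fmt == "json":
        payload = [
            {name: getattr(row, name) for name in _COLUMNS} for row in rows
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return path
    delim = "," if fmt == "csv" else "\t"
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delim, lineterminator="\n")
        writer.writerow(_COLUMNS)
        for row in rows:
            writer.writerow([
                f"{getattr(row, name):.2f}" if name in ResultRow._FLOATS
                else getattr(row, name)
                for name in _COLUMNS
            ])
    return path


def read_report(path: str | Path, fmt: str | None = None) -> list[ResultRow]:
    """Parse a written report back into typed rows (inverse of write_report)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "json":
        return [ResultRow(**record) for record in json.loads(path.read_text())]
    delim = "," if fmt == "csv" else "\t"
    rows = []
    with path.open(newline="") as handle:
        for record in csv.DictReader(handle, delimiter=delim):
            kwargs = {}
            for name in _COLUMNS:
                raw = record[name]
                if name in ResultRow._FLOATS:
                    kwargs[name] = float(raw)
                elif name in ResultRow._INTS:
                    kwargs[name] = int(raw)
                elif name == "flagged":
                    kwargs[name] = raw == "True"
                else:
                    kwargs[name] = raw
            rows.append(ResultRow(**kwargs))
    return rows


def _load_decoys(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    seqs: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seqs[record.id] = str(record.seq).upper()
        match = re.search(r"gene=(\S+)", record.description)
        gene_of[record.id] = match.group(1) if match else f"{record.id}_GENE"
    return seqs, gene_of


@dataclass
class PipelineResult:
    gene: GeneModel
    selection: JunctionSelection
    scored: list[tuple[PrimerPair, SpecificityReport]]
    rows: list[ResultRow]
    rejections: dict[str, int]
    exit_code: int


def run_pipeline(
    genome: str | Path | GenomeRef,
    gtf: str | Path,
    gene_name: str,
    targets: set[str] | str = "ALL",
    params: DesignParams | None = None,
    spec_params: SpecificityParams | None = None,
    weights: ScoreWeights | None = None,
    vcf: str | Path | None = None,
    maf: float = 0.01,
    af_key: str = "AF",
    decoys: str | Path | None = None,
) -> PipelineResult:
    """Run junction selection, masked design, and the two-round screen.

    ``targets`` may be the sentinel ``"ALL"`` or a set of transcript ids.
    When junction selection is imperfect, every junction tied at the top rank
    is passed to design and the per-pair specificity screen disambiguates.
    """
    params = params or DesignParams()
    spec_params = spec_params or SpecificityParams()
    if not isinstance(genome, GenomeRef):
        genome = load_genome(genome)
    genes = load_annotation(gtf, genome)
    by_name = {g.gene_id: g for g in genes}
    by_name.update({g.gene_name: g for g in genes})
    if gene_name not in by_name:
        raise KeyError(f"gene {gene_name!r} not present in the annotation")
    gene = by_name[gene_name]
    if targets == "ALL":
        target_set = frozenset(gene.transcript_ids)
    else:
        target_set = frozenset(targets)
    selection = select_junctions(SelectionRequest(gene, target_set))
    if selection.perfect:
        chosen = selection.junctions
    else:
        top = selection.junctions[0]
        chosen = [r for r in selection.junctions
                  if (r.coverage, r.leakage, r.on_canonical)
                  == (top.coverage, top.leakage, top.on_canonical)]

    mask: VariantMask | None = None
    if vcf is not None:
        mask = load_common_variants(vcf, threshold=maf, af_key=af_key)

    pairs: list[PrimerPair] = []
    junction_labels: dict[str, tuple[str, str]] = {}
    amplicon_tms: dict[str, float] = {}
    rejections: dict[str, int] = {}
    counter = 0
    for ranked in chosen:
        junction = ranked.junction
        # design template: canonical if it carries the junction, else the
        # first (sorted) containing transcript among the targets, else any
        carriers = sorted(ranked.transcripts)
        if gene.canonical_id in ranked.transcripts:
            template_tx = gene.canonical
        else:
            in_targets = [t for t in carriers if t in target_set]
            template_tx = gene.transcript((in_targets or carriers)[0])
        jindex = template_tx.junctions().index(junction)
        jpos = template_tx.junction_positions[jindex]
        template = apply_mask(template_tx, mask)
        result: DesignResult = generate_pairs(template, jpos, params)
        for cause, count in result.rejections.items():
            rejections[cause] = rejections.get(cause, 0) + count
        for pair in result.pairs:
            counter += 1
            pair = pair.with_id(f"P{counter:03d}")
            pairs.append(pair)
            junction_labels[pair.pair_id] = (
                template_tx.junction_label(junction), junction.label())
            amplicon = template_tx.cdna[pair.amplicon_start:pair.amplicon_end]
            amplicon_tms[pair.pair_id] = melting_temperature(amplicon, params)

    if not pairs:
        return PipelineResult(gene, selection, [], [], rejections,
                              EXIT_NO_CANDIDATES)

    cdna_db = {
        tx.transcript_id: tx.cdna for g in genes for tx in g.transcripts
    }
    gene_of = {
        tx.transcript_id: g.gene_id for g in genes for tx in g.transcripts
    }
    if decoys is not None:
        decoy_seqs, decoy_genes = _load_decoys(decoys)
        cdna_db.update(decoy_seqs)
        gene_of.update(decoy_genes)
    scored = two_round_filter(
        pairs, cdna_db, genome.sequences, gene, target_set, spec_params,
        transcript_gene=gene_of)
    rows = build_rows(scored, junction_labels, amplicon_tms, gene_of, weights)
    all_flagged = bool(scored) and all(
        rep.flagged or not (rep.pass_round1 and rep.pass_round2)
        for _, rep in scored
    )
    exit_code = EXIT_ALL_FLAGGED if all_flagged else EXIT_OK
    return PipelineResult(gene, selection, scored, rows, rejections, exit_code)
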