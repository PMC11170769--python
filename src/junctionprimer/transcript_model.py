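"""Gene/transcript models: spliced cDNA construction and exon-exon junction enumeration.

Coordinates are 0-based half-open internally.  GTF/GFF3 input (1-based,
inclusive) is converted on ingestion.  A junction is identified genomically by
its (donor, acceptor, strand) triple — the donor is the genomic coordinate one
past the last base of the upstream exon, the acceptor the first base of the
downstream exon — so that the same splice event is unified across isoforms
regardless of where it falls in each spliced cDNA.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pyfaidx
from Bio import SeqIO

__all__ = [
    "GenomeRef",
    "ExonRecord",
    "TranscriptModel",
    "GeneModel",
    "JunctionID",
    "AnnotationError",
    "load_annotation",
    "load_genome",
    "build_cdna",
    "enumerate_junctions",
    "parse_custom_transcript",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_RE = re.compile(r"^[ACGTN]*$")


class AnnotationError(ValueError):
    """Raised when genome/annotation input is inconsistent or malformed."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRef:
    """Uppercase DNA sequences keyed by chromosome name (alphabet A/C/G/T/N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise AnnotationError(f"chromosome {name!r} has empty sequence")
            if not _VALID_RE.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise AnnotationError(
                    f"chromosome {name!r} contains unsupported letters {bad}; "
                    "only A/C/G/T/N are allowed"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True, order=True)
class ExonRecord:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    rank: int  # 1..n in transcription (5'->3' of the mRNA) order

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"exon {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class JunctionID:
    """Genomic identity of a splice junction.

    ``donor`` is (chrom, genomic end of the upstream exon) and ``acceptor``
    (chrom, genomic start of the downstream exon), both in genome coordinates
    irrespective of strand, so equality means the same genomic splice event.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def label(self) -> str:
        return f"{self.chrom}:{self.donor}^{self.acceptor}({self.strand})"


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: list[ExonRecord]
    is_canonical: bool = False
    cdna: str = ""
    junction_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.exons:
            ranks = sorted(e.rank for e in self.exons)
            if ranks != list(range(1, len(self.exons) + 1)):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon ranks {ranks} "
                    "are not 1..n consecutive"
                )
            self.exons = sorted(self.exons, key=lambda e: e.rank)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def junctions(self) -> list[JunctionID]:
        """Junctions in transcription order (one per adjacent exon pair)."""
        out = []
        for up, down in zip(self.exons, self.exons[1:]):
            if up.strand == "+":
                out.append(JunctionID(up.chrom, up.end, down.start, "+"))
            else:
                # transcription runs right-to-left: upstream exon ends at its
                # genomic start; the genomic donor/acceptor keep genome order
                out.append(JunctionID(up.chrom, down.end, up.start, "-"))
        return out

    def genomic_positions(self) -> list[int]:
        """Genomic coordinate of every cDNA base, index = cDNA offset."""
        coords: list[int] = []
        for exon in self.exons:
            if exon.strand == "+":
                coords.extend(range(exon.start, exon.end))
            else:
                coords.extend(range(exon.end - 1, exon.start - 1, -1))
        return coords

    def junction_label(self, junction: JunctionID) -> str:
        """Exon-rank label (e.g. ``e2-e3``) for a junction of this transcript."""
        for i, j in enumerate(self.junctions()):
            if j == junction:
                return f"e{i + 1}-e{i + 2}"
        raise KeyError(f"{junction} not in transcript {self.transcript_id}")


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise AnnotationError(f"gene {self.gene_id}: duplicate transcript ids")
        if sum(t.is_canonical for t in self.transcripts) != 1:
            raise AnnotationError(
                f"gene {self.gene_id}: exactly one canonical transcript required"
            )

    @property
    def canonical_id(self) -> str:
        return next(t.transcript_id for t in self.transcripts if t.is_canonical)

    @property
    def canonical(self) -> TranscriptModel:
        return next(t for t in self.transcripts if t.is_canonical)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(f"{transcript_id} not in gene {self.gene_id}")

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(t.transcript_id for t in self.transcripts)


def load_genome(fasta_path: str | Path) -> GenomeRef:
    """Read a genome FASTA into memory (uppercased, alphabet-checked)."""
    fa = pyfaidx.Fasta(str(fasta_path), sequence_always_upper=True)
    try:
        return GenomeRef({name: str(fa[name][:]) for name in fa.keys()})
    finally:
        fa.close()


def build_cdna(
    exons: list[ExonRecord], genome: GenomeRef
) -> tuple[str, list[int]]:
    """Splice exons into the mature cDNA and locate junctions within it.

    Returns the cDNA (5'->3' of the mRNA) and the cDNA offset of the last base
    of each upstream exon, one per junction, strictly increasing.
    """
    chroms = {e.chrom for e in exons}
    strands = {e.strand for e in exons}
    if len(chroms) != 1 or len(strands) != 1:
        raise AnnotationError("exons of one transcript must share chrom and strand")
    chrom = chroms.pop()
    if chrom not in genome:
        raise AnnotationError(f"chromosome {chrom!r} absent from genome")
    chrom_seq = genome[chrom]
    parts = []
    for exon in sorted(exons, key=lambda e: e.rank):
        if exon.end > len(chrom_seq):
            raise AnnotationError(
                f"exon {chrom}:{exon.start}-{exon.end} exceeds chromosome "
                f"length {len(chrom_seq)}"
            )
        piece = chrom_seq[exon.start : exon.end]
        parts.append(piece if exon.strand == "+" else reverse_complement(piece))
    cdna = "".join(parts)
    junction_positions = []
    offset = 0
    for part in parts[:-1]:
        offset += len(part)
        junction_positions.append(offset - 1)
    return cdna, junction_positions


def enumerate_junctions(gene: GeneModel) -> dict[JunctionID, set[str]]:
    """Map every junction of the gene to the transcripts that contain it."""
    incidence: dict[JunctionID, set[str]] = {}
    for tx in gene.transcripts:
        for junction in tx.junctions():
            incidence.setdefault(junction, set()).add(tx.transcript_id)
    return incidence


def _rank_exons(
    chrom: str, strand: str, intervals: list[tuple[int, int]]
) -> list[ExonRecord]:
    """Build rank-ordered exons from genomic intervals (any input order)."""
    ordered = sorted(intervals, reverse=(strand == "-"))
    return [
        ExonRecord(chrom, start, end, strand, rank)
        for rank, (start, end) in enumerate(ordered, start=1)
    ]


def load_annotation(
    annotation_file: str | Path, genome: str | Path | GenomeRef
) -> list[GeneModel]:
    """Read exon features from a GTF/GFF3 file and build spliced gene models.

    The canonical transcript is the one tagged ``Ensembl_canonical``; absent a
    tag, the transcript with the longest cDNA (ties broken by lexicographically
    smallest transcript id) is used.
    """
    if not isinstance(genome, GenomeRef):
        genome = load_genome(genome)
    db = gffutils.create_db(
        str(annotation_file),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # gene_id -> transcript_id -> (name, strand, chrom, intervals, canonical)
    per_gene: dict[str, dict[str, dict]] = {}
    gene_names: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks {exc} attribute"
            ) from None
        if feat.seqid not in genome:
            raise AnnotationError(
                f"transcript {tx_id}: chromosome {feat.seqid!r} absent from genome"
            )
        gene_names.setdefault(
            gene_id, feat.attributes.get("gene_name", [gene_id])[0]
        )
        tx = per_gene.setdefault(gene_id, {}).setdefault(
            tx_id, {"chrom": feat.seqid, "strand": feat.strand, "intervals": [],
                    "canonical": False}
        )
        # GTF/GFF3 1-based inclusive -> 0-based half-open
        tx["intervals"].append((feat.start - 1, feat.end))
        tags = feat.attributes.get("tag", [])
        if "Ensembl_canonical" in tags:
            tx["canonical"] = True
    # transcripts declared but exon-less are fatal
    for kind in ("transcript", "mRNA"):
        try:
            feats = list(db.features_of_type(kind))
        except Exception:  # pragma: no cover - feature type absent
            feats = []
        for feat in feats:
            tx_id = feat.attributes.get("transcript_id", [feat.id])[0]
            gene_id = feat.attributes.get("gene_id", ["?"])[0]
            if tx_id not in per_gene.get(gene_id, {}):
                raise AnnotationError(f"transcript {tx_id} has zero exons")

    genes = []
    for gene_id in sorted(per_gene):
        transcripts = []
        for tx_id in sorted(per_gene[gene_id]):
            info = per_gene[gene_id][tx_id]
            exons = _rank_exons(info["chrom"], info["strand"], info["intervals"])
            cdna, junctions = build_cdna(exons, genome)
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    exons=exons,
                    is_canonical=info["canonical"],
                    cdna=cdna,
                    junction_positions=junctions,
                )
            )
        if sum(t.is_canonical for t in transcripts) != 1:
            for t in transcripts:
                t.is_canonical = False
            # deterministic fallback: longest cDNA, then smallest id
            best = min(transcripts, key=lambda t: (-len(t.cdna), t.transcript_id))
            best.is_canonical = True
        genes.append(GeneModel(gene_id, gene_names[gene_id], transcripts))
    return genes


def parse_custom_transcript(path: str | Path) -> TranscriptModel:
    """Read a user transcript from FASTA or GenBank.

    FASTA headers mark splice junctions with a ``junctions=`` token holding
    comma-separated 0-based cDNA offsets of the last base of each upstream
    exon, e.g. ``>seq1 junctions=119,339``.  GenBank input derives the same
    offsets from its exon features.  The returned model has no genomic exons;
    it carries only the spliced sequence and junction offsets.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        record = next(SeqIO.parse(str(path), "fasta"))
        seq = str(record.seq).upper()
        if not _VALID_RE.match(seq):
            raise AnnotationError(f"{record.id}: sequence letters outside A/C/G/T/N")
        match = re.search(r"junctions=([\d,\s]+)", record.description)
        if match is None:
            warnings.warn(
                f"{record.id}: no 'junctions=' token in FASTA header; "
                "treating the sequence as junction-free",
                stacklevel=2,
            )
            junctions: list[int] = []
        else:
            junctions = []
            for token in match.group(1).split(","):
                token = token.strip()
                if not token:
                    continue
                try:
                    pos = int(token)
                except ValueError:
                    raise AnnotationError(
                        f"{record.id}: non-integer junction offset {token!r}"
                    ) from None
                if not 0 <= pos < len(seq) - 1:
                    raise AnnotationError(
                        f"{record.id}: junction offset {pos} out of range for a "
                        f"{len(seq)} nt sequence"
                    )
                junctions.append(pos)
            junctions.sort()
        name = record.id
    else:
        record = next(SeqIO.parse(str(path), "genbank"))
        seq = str(record.seq).upper()
        if not _VALID_RE.match(seq):
            raise AnnotationError(f"{record.id}: sequence letters outside A/C/G/T/N")
        exon_ends = sorted(
            int(f.location.end) for f in record.features if f.type == "exon"
        )
        junctions = [end - 1 for end in exon_ends[:-1]]
        for pos in junctions:
            if not 0 <= pos < len(seq) - 1:
                raise AnnotationError(
                    f"{record.id}: exon boundary {pos} out of range for a "
                    f"{len(seq)} nt sequence"
                )
        name = record.id
    return TranscriptModel(
        transcript_id=name,
        gene_id=name,
        exons=[],
        is_canonical=True,
        cdna=seq,
        junction_positions=junctions,
    )
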