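"""In-silico PCR: exhaustive mismatch-bounded primer binding search and the
two-round (spliced transcripts, then genome) specificity screen.

The binding-site search is a full Hamming scan of every position on both
strands of every database sequence — no seeding heuristic, so no qualifying
site can be missed.  A pair of sites yields a predicted amplification product
only when it is *productive*: convergent orientation on one sequence, product
length within the cap, and zero mismatches in each primer's 3'-terminal
window (a mismatched 3' end blocks polymerase extension).  Non-productive
single-primer alignments are kept for reporting.

Round 1 screens the spliced-transcript (cDNA) database, the dominant template
in an RT-qPCR reaction, and rejects pairs predicted to amplify other genes —
unless every pair is affected, in which case all are kept and flagged so the
caller can make an informed choice.  The best survivors are then screened
against genomic DNA; genomic products down-rank a pair rather than remove it,
because a junction-spanning assay tolerates genomic DNA by construction and
the report keeps the evidence visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .primer_design import PrimerPair
from .transcript_model import GeneModel, reverse_complement

__all__ = [
    "BindingSite",
    "AmplificationProduct",
    "SpecificityReport",
    "SpecificityParams",
    "find_binding_sites",
    "predict_products",
    "classify_products",
    "two_round_filter",
]


@dataclass(frozen=True)
class SpecificityParams:
    max_mismatch: int = 3
    max_mismatch_3p: int = 0          # allowed mismatches in the 3' window
    three_prime_window: int = 5       # nt counted as the 3'-terminal window
    max_product_cdna: int = 2000
    max_product_genome: int = 5000
    top_n_round2: int = 10


@dataclass(frozen=True)
class BindingSite:
    db: str          # cdna | genome
    seq_id: str
    start: int       # 0-based half-open, forward coordinates of the db sequence
    end: int
    strand: str      # + : primer sequence matches the forward strand
    mismatches: int
    mismatches_3p: int
    primer_role: str  # forward | reverse


@dataclass(frozen=True)
class AmplificationProduct:
    db: str
    seq_id: str
    start: int       # 5' end of the plus-strand site
    end: int         # 5' end of the minus-strand site (half-open)
    length: int
    fwd_site: BindingSite
    rev_site: BindingSite
    category: str = ""  # on_target | non_target_isoform | off_target_gene | genomic


@dataclass
class SpecificityReport:
    pair_id: str
    products: list[AmplificationProduct] = field(default_factory=list)
    unproductive_hits: list[BindingSite] = field(default_factory=list)
    pass_round1: bool = False
    pass_round2: bool = False
    flagged: bool = False  # kept despite round-1 off-targets (all-pairs case)

    def count(self, category: str) -> int:
        return sum(1 for p in self.products if p.category == category)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_binding_sites(
    primer: str,
    db: dict[str, str],
    max_mismatch: int = 3,
    max_mismatch_3p: int | None = None,
    db_name: str = "cdna",
    primer_role: str = "forward",
    three_prime_window: int = 5,
) -> list[BindingSite]:
    """Exhaustively scan both strands of every db sequence for the primer.

    A site is reported wherever the full-length Hamming distance is at most
    ``max_mismatch``; ``mismatches_3p`` counts mismatches in the primer's
    3'-terminal window (the low-coordinate side of the window for sites on
    the minus strand).  ``max_mismatch_3p`` additionally filters on that
    count when given.  Site coordinates are always on the forward strand of
    the database sequence.
    """
    if not primer or any(b not in "ACGT" for b in primer):
        raise ValueError(f"primer {primer!r} must be non-empty over A/C/G/T")
    m = len(primer)
    w = min(three_prime_window, m)
    fwd = _encode(primer)
    rc = _encode(reverse_complement(primer))
    sites = []
    for seq_id in db:
        seq = db[seq_id]
        n = len(seq)
        if n < m:
            continue
        arr = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(arr, m)
        for strand, pattern in (("+", fwd), ("-", rc)):
            diff = windows != pattern
            total = diff.sum(axis=1)
            # 3' terminus: high-coordinate end of a + site, low end of a - site
            tail = diff[:, -w:].sum(axis=1) if strand == "+" else \
                diff[:, :w].sum(axis=1)
            hits = np.flatnonzero(total <= max_mismatch)
            for start in hits:
                mm3 = int(tail[start])
                if max_mismatch_3p is not None and mm3 > max_mismatch_3p:
                    continue
                sites.append(BindingSite(
                    db=db_name, seq_id=seq_id, start=int(start),
                    end=int(start) + m, strand=strand,
                    mismatches=int(total[start]), mismatches_3p=mm3,
                    primer_role=primer_role,
                ))
    sites.sort(key=lambda s: (s.seq_id, s.start, s.strand, s.primer_role))
    return sites


def predict_products(
    fwd_sites: list[BindingSite],
    rev_sites: list[BindingSite],
    max_offtarget_len: int,
) -> list[AmplificationProduct]:
    """Pair convergent, extension-competent sites into predicted amplicons.

    Both cross-role orientations are considered: the forward primer on the
    plus strand with the reverse primer on the minus strand downstream, and
    the role-swapped arrangement.  Each site must have a clean 3' window
    (``mismatches_3p == 0``); the product runs from the plus-strand site's 5'
    end to the minus-strand site's 5' end and must be within the length cap.
    """
    products = []
    for plus_pool, minus_pool in ((fwd_sites, rev_sites),
                                  (rev_sites, fwd_sites)):
        plus = [s for s in plus_pool if s.strand == "+" and s.mismatches_3p == 0]
        minus = [s for s in minus_pool if s.strand == "-" and s.mismatches_3p == 0]
        for ps in plus:
            for ms in minus:
                if ps.seq_id != ms.seq_id:
                    continue
                length = ms.end - ps.start
                if length <= 0 or length > max_offtarget_len:
                    continue
                fwd_site, rev_site = (
                    (ps, ms) if ps.primer_role == "forward" else (ms, ps)
                )
                products.append(AmplificationProduct(
                    db=ps.db, seq_id=ps.seq_id, start=ps.start, end=ms.end,
                    length=length, fwd_site=fwd_site, rev_site=rev_site,
                ))
    products.sort(key=lambda p: (p.seq_id, p.start, p.end))
    return products


def _transcript_gene_map(genes: list[GeneModel]) -> dict[str, str]:
    return {
        tx.transcript_id: gene.gene_id
        for gene in genes
        for tx in gene.transcripts
    }


def _genomic_footprint(gene: GeneModel, product: AmplificationProduct
                       ) -> tuple[str, int, int] | None:
    """Contiguous genomic interval of an intra-exonic cdna product, else None."""
    try:
        tx = gene.transcript(product.seq_id)
    except KeyError:
        return None
    if not tx.exons:
        return None
    coords = tx.genomic_positions()
    span = coords[product.start : product.end]
    lo, hi = min(span), max(span)
    if hi - lo + 1 != len(span):  # crosses a junction -> not contiguous
        return None
    return tx.exons[0].chrom, lo, hi + 1


def classify_products(
    products: list[AmplificationProduct],
    gene: GeneModel,
    targets: frozenset[str] | set[str],
    transcript_gene: dict[str, str] | None = None,
) -> list[AmplificationProduct]:
    """Attach on/off-target categories to predicted products.

    cDNA products: on a selected transcript -> ``on_target``; on an
    unselected isoform of the same gene -> ``non_target_isoform``; on another
    gene's transcript -> ``off_target_gene``.  Genome products are
    ``genomic`` unless their locus coincides exactly with the contiguous
    genomic footprint of an on-target cDNA product (possible only when the
    amplicon stays inside one exon), in which case they are ``on_target``.
    """
    transcript_gene = transcript_gene or {}
    own = {tx.transcript_id for tx in gene.transcripts}
    targets = set(targets)
    # loci of intra-exonic on-target products, for the genome-side exemption
    on_target_loci = set()
    for product in products:
        if product.db == "cdna" and product.seq_id in targets:
            footprint = _genomic_footprint(gene, product)
            if footprint is not None:
                on_target_loci.add(footprint)
    out = []
    for product in products:
        if product.db == "cdna":
            if product.seq_id in targets:
                category = "on_target"
            elif product.seq_id in own:
                category = "non_target_isoform"
            elif product.seq_id in transcript_gene:
                category = "off_target_gene"
            else:
                raise KeyError(
                    f"cdna sequence {product.seq_id!r} is not a known "
                    "transcript: database/annotation mismatch"
                )
        else:
            locus = (product.seq_id, product.start, product.end)
            category = "on_target" if locus in on_target_loci else "genomic"
        out.append(AmplificationProduct(
            db=product.db, seq_id=product.seq_id, start=product.start,
            end=product.end, length=product.length, fwd_site=product.fwd_site,
            rev_site=product.rev_site, category=category,
        ))
    return out


def _screen_db(pair: PrimerPair, db: dict[str, str], db_name: str,
               max_len: int, params: SpecificityParams
               ) -> tuple[list[AmplificationProduct], list[BindingSite]]:
    fwd_sites = find_binding_sites(
        pair.forward.sequence, db, params.max_mismatch, None, db_name,
        "forward", params.three_prime_window)
    rev_sites = find_binding_sites(
        pair.reverse.sequence, db, params.max_mismatch, None, db_name,
        "reverse", params.three_prime_window)
    products = predict_products(fwd_sites, rev_sites, max_len)
    productive = {
        (s.seq_id, s.start, s.strand, s.primer_role)
        for p in products for s in (p.fwd_site, p.rev_site)
    }
    unproductive = [
        s for s in fwd_sites + rev_sites
        if (s.seq_id, s.start, s.strand, s.primer_role) not in productive
    ]
    return products, unproductive


def two_round_filter(
    pairs: list[PrimerPair],
    cdna_db: dict[str, str],
    genome_db: dict[str, str],
    gene: GeneModel,
    targets: frozenset[str] | set[str],
    params: SpecificityParams | None = None,
    transcript_gene: dict[str, str] | None = None,
) -> list[tuple[PrimerPair, SpecificityReport]]:
    """Run the sequential cDNA-then-genome specificity screen.

    Round 1 rejects pairs with predicted products on other genes, unless all
    pairs have one — then every pair is kept and flagged.  The best
    ``top_n_round2`` survivors (by pair penalty, then fewest round-1
    products) advance to the genome round, whose products mark
    ``pass_round2 = False`` but never remove a pair.
    """
    if not pairs:
        raise ValueError("no primer pairs to screen")
    if not cdna_db or not genome_db:
        raise ValueError("empty sequence database")
    params = params or SpecificityParams()
    transcript_gene = transcript_gene if transcript_gene is not None else {}

    round1: list[tuple[PrimerPair, SpecificityReport]] = []
    for pair in pairs:
        products, unproductive = _screen_db(
            pair, cdna_db, "cdna", params.max_product_cdna, params)
        products = classify_products(products, gene, targets, transcript_gene)
        report = SpecificityReport(
            pair_id=pair.pair_id, products=products,
            unproductive_hits=unproductive,
        )
        report.pass_round1 = report.count("off_target_gene") == 0
        round1.append((pair, report))

    clean = [entry for entry in round1 if entry[1].pass_round1]
    if clean:
        survivors = clean
    else:  # every pair has a cross-gene product: keep all, flagged
        survivors = round1
        for _, report in survivors:
            report.flagged = True
    survivors.sort(key=lambda entry: (
        entry[0].pair_penalty, len(entry[1].products), entry[0].pair_id))
    survivors = survivors[: params.top_n_round2]

    for pair, report in survivors:
        products, unproductive = _screen_db(
            pair, genome_db, "genome", params.max_product_genome, params)
        products = classify_products(
            products + report.products, gene, targets, transcript_gene)
        report.products = products
        report.unproductive_hits = report.unproductive_hits + unproductive
        report.pass_round2 = report.count("genomic") == 0
    return survivors
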