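"""Choose junctions that discriminate the user's target isoforms.

A junction is *perfect* for a target set when every target contains it and no
unselected isoform does: priming on it amplifies exactly the chosen
transcripts.  When no perfect junction exists the gene's junctions are ranked
by how closely they approach that ideal (coverage of targets descending,
leakage into unselected isoforms ascending, presence on the canonical
transcript, then genomic coordinate), and the caller is warned about every
isoform the best junction would wrongly detect or miss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .transcript_model import GeneModel, JunctionID, enumerate_junctions

__all__ = [
    "SelectionRequest",
    "JunctionSelection",
    "RankedJunction",
    "NoJunctionsError",
    "select_junctions",
    "junction_matrix",
]


class NoJunctionsError(ValueError):
    """The gene has a single exon: junction-anchored design is impossible."""


@dataclass(frozen=True)
class SelectionRequest:
    gene: GeneModel
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("targets must be non-empty")
        known = set(t.transcript_id for t in self.gene.transcripts)
        unknown = set(self.targets) - known
        if unknown:
            raise ValueError(
                f"unknown target transcript(s) {sorted(unknown)} "
                f"for gene {self.gene.gene_id}"
            )

    @property
    def unselected(self) -> frozenset[str]:
        return frozenset(
            t.transcript_id for t in self.gene.transcripts
        ) - self.targets


@dataclass(frozen=True)
class RankedJunction:
    junction: JunctionID
    coverage: int  # number of targets containing it
    leakage: int   # number of unselected isoforms containing it
    on_canonical: bool
    transcripts: frozenset[str]


@dataclass
class JunctionSelection:
    junctions: list[RankedJunction]
    perfect: bool
    warnings: list[tuple[str, str]] = field(default_factory=list)
    # warning kinds: non_targeted_detected | target_not_detected


def _ranked(gene: GeneModel, targets: frozenset[str]) -> list[RankedJunction]:
    incidence = enumerate_junctions(gene)
    canonical_junctions = set(gene.canonical.junctions())
    unselected = frozenset(t.transcript_id for t in gene.transcripts) - targets
    ranked = [
        RankedJunction(
            junction=j,
            coverage=len(members & targets),
            leakage=len(members & unselected),
            on_canonical=j in canonical_junctions,
            transcripts=frozenset(members),
        )
        for j, members in incidence.items()
    ]
    ranked.sort(key=lambda r: (
        -r.coverage, r.leakage, not r.on_canonical,
        r.junction.chrom, r.junction.donor, r.junction.acceptor,
    ))
    return ranked


def select_junctions(request: SelectionRequest) -> JunctionSelection:
    """Apply the perfect-junction rule with ranked fallback and warnings.

    If perfect junctions exist they are returned alone (no warnings).
    Otherwise all junctions are returned in rank order and the warnings list
    names every unselected isoform containing the top-ranked junction
    (``non_targeted_detected``) and every target lacking it
    (``target_not_detected``).
    """
    gene = request.gene
    ranked = _ranked(gene, request.targets)
    if not ranked:
        raise NoJunctionsError(
            f"gene {gene.gene_id} has no exon-exon junction (single-exon "
            "transcripts only); junction-anchored design is impossible"
        )
    n_targets = len(request.targets)
    perfect = [r for r in ranked
               if r.coverage == n_targets and r.leakage == 0]
    if perfect:
        return JunctionSelection(junctions=perfect, perfect=True)
    top = ranked[0]
    warnings = [
        (tx, "non_targeted_detected")
        for tx in sorted(top.transcripts & request.unselected)
    ] + [
        (tx, "target_not_detected")
        for tx in sorted(request.targets - top.transcripts)
    ]
    return JunctionSelection(junctions=ranked, perfect=False, warnings=warnings)


def junction_matrix(gene: GeneModel) -> pd.DataFrame:
    """Binary junction x transcript incidence, deterministically ordered.

    Rows are junction labels sorted by genomic coordinate, columns transcript
    ids sorted lexicographically; entry 1 iff the transcript contains the
    junction.
    """
    incidence = enumerate_junctions(gene)
    junctions = sorted(incidence)
    columns = gene.transcript_ids
    data = [
        [int(tx in incidence[j]) for tx in columns]
        for j in junctions
    ]
    return pd.DataFrame(
        data, index=[j.label() for j in junctions], columns=columns, dtype=int
    )
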