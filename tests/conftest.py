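"""Shared fixtures: synthetic loci on disk and hand-built gene models."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from junctionprimer.fixtures import SyntheticLocusSpec, generate_locus
from junctionprimer.transcript_model import (
    ExonRecord,
    GeneModel,
    GenomeRef,
    TranscriptModel,
    build_cdna,
    load_annotation,
)


def make_genome(length: int = 4000, chrom: str = "chr1",
                seed: int = 0) -> GenomeRef:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeRef({chrom: seq})


def make_gene(
    structures: dict[str, list[tuple[int, int]]],
    genome: GenomeRef | None = None,
    strand: str = "+",
    canonical: str | None = None,
    gene_id: str = "G1",
) -> GeneModel:
    """Build a GeneModel from per-transcript exon intervals (0-based)."""
    if genome is None:
        top = max(end for exons in structures.values() for _, end in exons)
        genome = make_genome(length=top + 100)
    chrom = next(iter(genome.sequences))
    canonical = canonical or sorted(structures)[0]
    transcripts = []
    for tx_id in sorted(structures):
        intervals = sorted(structures[tx_id], reverse=(strand == "-"))
        exons = [
            ExonRecord(chrom, start, end, strand, rank)
            for rank, (start, end) in enumerate(intervals, start=1)
        ]
        cdna, junctions = build_cdna(exons, genome)
        transcripts.append(TranscriptModel(
            transcript_id=tx_id, gene_id=gene_id, exons=exons,
            is_canonical=tx_id == canonical, cdna=cdna,
            junction_positions=junctions,
        ))
    return GeneModel(gene_id, gene_id, transcripts)


def random_gene(rng: np.random.Generator) -> GeneModel:
    """Random multi-isoform gene over an exon ladder (<=6 isoforms, <=12 exons)."""
    n_exons = int(rng.integers(2, 13))
    n_isoforms = int(rng.integers(1, 7))
    ladder = [(i * 200, i * 200 + 100) for i in range(n_exons)]
    structures = {}
    for i in range(n_isoforms):
        k = int(rng.integers(1, n_exons + 1))
        chosen = sorted(rng.choice(n_exons, size=k, replace=False))
        structures[f"T{i + 1}"] = [ladder[j] for j in chosen]
    genome = make_genome(length=n_exons * 200 + 100, seed=int(rng.integers(1 << 16)))
    return make_gene(structures, genome)


def all_target_subsets(gene: GeneModel):
    ids = gene.transcript_ids
    for r in range(1, len(ids) + 1):
        for subset in itertools.combinations(ids, r):
            yield frozenset(subset)


@pytest.fixture(scope="session")
def default_locus(tmp_path_factory):
    """Default 3-isoform synthetic locus written to disk, with ground truth."""
    fixture = generate_locus(SyntheticLocusSpec(seed=42))
    paths = fixture.write(tmp_path_factory.mktemp("locus42"))
    return fixture, paths


@pytest.fixture(scope="session")
def planted_locus(tmp_path_factory):
    """Locus with a processed pseudogene and a decoy cross-gene transcript."""
    fixture = generate_locus(SyntheticLocusSpec(
        seed=11, plant_pseudogene=True, plant_cdna_offtarget=True))
    paths = fixture.write(tmp_path_factory.mktemp("locus11"))
    return fixture, paths


@pytest.fixture(scope="session")
def default_gene(default_locus):
    fixture, paths = default_locus
    genes = load_annotation(paths["gtf"], paths["genome"])
    return genes[0]
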