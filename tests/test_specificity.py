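"""Binding-site search, product prediction, classification, two-round filter."""

from __future__ import annotations

import numpy as np
import pytest

from junctionprimer.fixtures import SyntheticLocusSpec, generate_locus
from junctionprimer.primer_design import DesignParams, generate_pairs
from junctionprimer.report import run_pipeline
from junctionprimer.specificity import (
    BindingSite,
    SpecificityParams,
    classify_products,
    find_binding_sites,
    predict_products,
    two_round_filter,
)
from junctionprimer.transcript_model import load_annotation, reverse_complement
from junctionprimer.variant_masking import apply_mask


def naive_hamming_scan(primer, db, max_mismatch, window=5):
    """Position-by-position oracle over both strands (pure Python)."""
    hits = []
    for seq_id, seq in db.items():
        for strand, pattern in (("+", primer),
                                ("-", reverse_complement(primer))):
            m = len(pattern)
            for start in range(len(seq) - m + 1):
                window_seq = seq[start:start + m]
                mm = sum(a != b for a, b in zip(window_seq, pattern))
                if mm <= max_mismatch:
                    tail = (window_seq[-window:], pattern[-window:]) \
                        if strand == "+" else \
                        (window_seq[:window], pattern[:window])
                    mm3 = sum(a != b for a, b in zip(*tail))
                    hits.append((seq_id, start, strand, mm, mm3))
    return sorted(hits)


def site_tuples(sites):
    return sorted((s.seq_id, s.start, s.strand, s.mismatches, s.mismatches_3p)
                  for s in sites)


def random_db(rng, n=10_000):
    return {"s": "".join(rng.choice(list("ACGT"), size=n))}


class TestFindBindingSites:
    def test_planted_exact_site(self):
        rng = np.random.default_rng(0)
        db = random_db(rng)
        primer = "ACGTTGCAACGGATCCTAGG"
        seq = db["s"][:100] + primer + db["s"][100 + len(primer):]
        db = {"s": seq}
        sites = find_binding_sites(primer, db, max_mismatch=0)
        assert [(s.start, s.strand, s.mismatches) for s in sites] == [
            (100, "+", 0)]

    def test_planted_reverse_complement_site(self):
        rng = np.random.default_rng(1)
        db = random_db(rng)
        primer = "ACGTTGCAACGGATCCTAGG"
        rc = reverse_complement(primer)
        seq = db["s"][:200] + rc + db["s"][200 + len(rc):]
        sites = find_binding_sites(primer, {"s": seq}, max_mismatch=0)
        assert [(s.start, s.strand) for s in sites] == [(200, "-")]

    @pytest.mark.parametrize("seed,k", [(0, 0), (1, 1), (2, 2), (3, 3)])
    def test_matches_naive_scan(self, seed, k):
        rng = np.random.default_rng(seed)
        db = random_db(rng, 5_000)
        primer = "".join(rng.choice(list("ACGT"),
                                    size=int(rng.integers(18, 26))))
        got = find_binding_sites(primer, db, max_mismatch=k)
        assert site_tuples(got) == naive_hamming_scan(primer, db, k)

    def test_mismatch_3p_filter(self):
        db = {"s": "AAAACGTACGTACGTACGTT" + "C" * 30}
        primer = "AAAACGTACGTACGTACGTA"  # one mismatch, at the 3' terminus
        with_filter = find_binding_sites(primer, db, 1, max_mismatch_3p=0)
        without = find_binding_sites(primer, db, 1)
        assert with_filter == []
        assert [(s.start, s.mismatches, s.mismatches_3p)
                for s in without] == [(0, 1, 1)]

    def test_primer_with_n_rejected(self):
        with pytest.raises(ValueError):
            find_binding_sites("ACGTN", {"s": "ACGTACGT"}, 0)


def _site(role, strand, start, length=20, seq_id="s", mm3=0, db="genome"):
    return BindingSite(db=db, seq_id=seq_id, start=start, end=start + length,
                       strand=strand, mismatches=0, mismatches_3p=mm3,
                       primer_role=role)


class TestPredictProducts:
    def test_convergent_pair_yields_product(self):
        products = predict_products(
            [_site("forward", "+", 10)], [_site("reverse", "-", 110)], 5000)
        (product,) = products
        assert (product.start, product.end, product.length) == (10, 130, 120)

    def test_same_strand_sites_never_pair(self):
        assert predict_products(
            [_site("forward", "+", 10)], [_site("reverse", "+", 110)], 5000
        ) == []

    def test_distance_cap_enforced(self):
        assert predict_products(
            [_site("forward", "+", 10)], [_site("reverse", "-", 9990)], 5000
        ) == []

    def test_role_swapped_orientation_detected(self):
        products = predict_products(
            [_site("forward", "-", 500)], [_site("reverse", "+", 300)], 5000)
        (product,) = products
        assert (product.start, product.end) == (300, 520)
        assert product.fwd_site.strand == "-"

    def test_three_prime_mismatch_blocks_product(self):
        assert predict_products(
            [_site("forward", "+", 10, mm3=1)],
            [_site("reverse", "-", 110)], 5000) == []

    def test_order_invariance(self):
        fwd = [_site("forward", "+", x) for x in (10, 400)]
        rev = [_site("reverse", "-", x) for x in (110, 500)]
        a = predict_products(fwd, rev, 5000)
        b = predict_products(fwd[::-1], rev[::-1], 5000)
        assert a == b


@pytest.fixture(scope="module")
def planted_pipeline(tmp_path_factory):
    """Pipeline run on a locus with a pseudogene and a decoy transcript,
    targeting T1+T2 of three isoforms (imperfect: shared junction leaks)."""
    fixture = generate_locus(SyntheticLocusSpec(
        seed=13, plant_pseudogene=True, plant_cdna_offtarget=True))
    paths = fixture.write(tmp_path_factory.mktemp("locus13"))
    result = run_pipeline(paths["genome"], paths["gtf"], "GENE1",
                          {"T1", "T2"}, decoys=paths["decoys"])
    return fixture, paths, result


class TestClassification:
    def test_categories_on_planted_locus(self, planted_pipeline):
        fixture, paths, result = planted_pipeline
        assert result.rows, "design produced no pairs"
        categories = {
            p.category for _, rep in result.scored for p in rep.products
        }
        assert {"on_target", "non_target_isoform",
                "off_target_gene", "genomic"} <= categories
        for _, rep in result.scored:
            for p in rep.products:
                if p.category == "off_target_gene":
                    assert p.seq_id == "DECOY_T1"
                if p.category == "non_target_isoform":
                    assert p.seq_id == "T3"
                if p.category == "on_target" and p.db == "cdna":
                    assert p.seq_id in {"T1", "T2"}

    def test_genomic_products_hit_planted_pseudogene(self, planted_pipeline):
        fixture, _, result = planted_pipeline
        chrom, lo, hi = fixture.truth.pseudogene_locus
        genomic = [
            p for _, rep in result.scored for p in rep.products
            if p.category == "genomic"
        ]
        assert genomic
        for p in genomic:
            assert p.seq_id == chrom
            assert lo <= p.start and p.end <= hi

    def test_unknown_seq_id_fatal(self, default_gene):
        product = predict_products(
            [_site("forward", "+", 10, seq_id="??", db="cdna")],
            [_site("reverse", "-", 110, seq_id="??", db="cdna")], 5000)
        with pytest.raises(KeyError, match="mismatch"):
            classify_products(product, default_gene, {"T1"}, {})


class TestTwoRoundFilter:
    def _designed_pairs(self, gene, targets, n=6):
        tx = gene.transcript(sorted(targets)[0])
        template = apply_mask(tx, None)
        jpos = tx.junction_positions[-1]
        pairs = generate_pairs(template, jpos,
                               DesignParams(max_candidates=n)).pairs
        return [p.with_id(f"P{i}") for i, p in enumerate(pairs)], tx

    def test_single_clean_pair_passes_both_rounds(self, default_gene,
                                                  default_locus):
        fixture, paths = default_locus
        targets = {"T1"}
        pairs, tx = self._designed_pairs(default_gene, targets, n=1)
        cdna_db = {t.transcript_id: t.cdna for t in default_gene.transcripts}
        genome = {
            name: seq for name, seq in fixture.genome.items()
        }
        scored = two_round_filter(pairs, cdna_db, genome, default_gene,
                                  targets)
        assert len(scored) == 1
        _, rep = scored[0]
        assert rep.pass_round1
        # private junction of T1: exactly one on-target product
        on_target = [p for p in rep.products if p.category == "on_target"
                     and p.db == "cdna"]
        assert [p.seq_id for p in on_target] == ["T1"]

    def test_on_target_amplicon_rediscovered(self, default_gene, default_locus):
        """Self-consistency: the designed amplicon is found by the screen."""
        fixture, _ = default_locus
        targets = {"T1"}
        pairs, tx = self._designed_pairs(default_gene, targets, n=4)
        cdna_db = {t.transcript_id: t.cdna for t in default_gene.transcripts}
        scored = two_round_filter(pairs, cdna_db, fixture.genome,
                                  default_gene, targets)
        for pair, rep in scored:
            spans = [(p.start, p.end) for p in rep.products
                     if p.category == "on_target" and p.seq_id == "T1"]
            assert (pair.amplicon_start, pair.amplicon_end) in spans

    def test_dirty_pair_rejected_in_round_one(self, tmp_path):
        """A pair whose amplicon exists in a decoy gene is dropped when a
        clean alternative exists."""
        fixture = generate_locus(SyntheticLocusSpec(
            seed=20, plant_cdna_offtarget=True))
        paths = fixture.write(tmp_path)
        genes = load_annotation(paths["gtf"], paths["genome"])
        gene = genes[0]
        targets = set(gene.transcript_ids)
        # shared junction J1_2 is inside the decoy copy -> dirty;
        # a private junction of T1 is not -> clean
        t1 = gene.transcript("T1")
        dirty = generate_pairs(t1.cdna, t1.junction_positions[0],
                               DesignParams(max_candidates=2)).pairs
        clean = generate_pairs(t1.cdna, t1.junction_positions[2],
                               DesignParams(max_candidates=2)).pairs
        pairs = [p.with_id(f"D{i}") for i, p in enumerate(dirty)]
        pairs += [p.with_id(f"C{i}") for i, p in enumerate(clean)]
        cdna_db = {t.transcript_id: t.cdna for t in gene.transcripts}
        cdna_db["DECOY_T1"] = fixture.decoys["DECOY_T1"]
        scored = two_round_filter(
            pairs, cdna_db, fixture.genome, gene, targets,
            transcript_gene={"DECOY_T1": "DECOY_G1"})
        kept = {pair.pair_id for pair, _ in scored}
        assert kept and all(pid.startswith("C") for pid in kept)
        assert all(rep.pass_round1 for _, rep in scored)

    def test_universal_offtarget_keeps_all_flagged(self, tmp_path):
        fixture = generate_locus(SyntheticLocusSpec(
            seed=22, plant_cdna_offtarget=True))
        paths = fixture.write(tmp_path)
        gene = load_annotation(paths["gtf"], paths["genome"])[0]
        targets = set(gene.transcript_ids)
        t1 = gene.transcript("T1")
        pairs = generate_pairs(t1.cdna, t1.junction_positions[0],
                               DesignParams(max_candidates=4)).pairs
        pairs = [p.with_id(f"P{i}") for i, p in enumerate(pairs)]
        cdna_db = {t.transcript_id: t.cdna for t in gene.transcripts}
        cdna_db["DECOY_T1"] = fixture.decoys["DECOY_T1"]
        scored = two_round_filter(
            pairs, cdna_db, fixture.genome, gene, targets,
            transcript_gene={"DECOY_T1": "DECOY_G1"})
        assert len(scored) == len(pairs)
        assert all(rep.flagged for _, rep in scored)
        assert all(rep.count("off_target_gene") >= 1 for _, rep in scored)

    def test_product_sites_excluded_from_unproductive(self, default_gene,
                                                      default_locus):
        fixture, _ = default_locus
        targets = {"T1"}
        pairs, _ = self._designed_pairs(default_gene, targets, n=3)
        cdna_db = {t.transcript_id: t.cdna for t in default_gene.transcripts}
        scored = two_round_filter(pairs, cdna_db, fixture.genome,
                                  default_gene, targets)
        for _, rep in scored:
            productive = {
                (s.db, s.seq_id, s.start, s.strand, s.primer_role)
                for p in rep.products for s in (p.fwd_site, p.rev_site)
            }
            for site in rep.unproductive_hits:
                key = (site.db, site.seq_id, site.start, site.strand,
                       site.primer_role)
                assert key not in productive

    def test_db_reordering_invariance(self, default_gene, default_locus):
        fixture, _ = default_locus
        targets = {"T2"}
        tx = default_gene.transcript("T2")
        pairs = generate_pairs(tx.cdna, tx.junction_positions[1],
                               DesignParams(max_candidates=2)).pairs
        pairs = [p.with_id(f"P{i}") for i, p in enumerate(pairs)]
        cdna_db = {t.transcript_id: t.cdna for t in default_gene.transcripts}
        reordered = dict(reversed(list(cdna_db.items())))
        a = two_round_filter(pairs, cdna_db, fixture.genome, default_gene,
                             targets)
        b = two_round_filter(pairs, reordered, fixture.genome, default_gene,
                             targets)
        assert [(p.pair_id, sorted((x.seq_id, x.start, x.end, x.category)
                                   for x in rep.products))
                for p, rep in a] == \
               [(p.pair_id, sorted((x.seq_id, x.start, x.end, x.category)
                                   for x in rep.products))
                for p, rep in b]

    def test_empty_inputs_fatal(self, default_gene):
        with pytest.raises(ValueError):
            two_round_filter([], {"a": "ACGT"}, {"b": "ACGT"},
                             default_gene, {"T1"})
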