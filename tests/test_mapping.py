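"""Mismatch-tolerant tag mapping and the per-library statistics."""

import numpy as np
import pytest

import oracles
from tagdge.datasets import dge_library_counters, library_stats_from_counters
from tagdge.errors import InputError
from tagdge.mapping import (
    STATUS_EXACT_UNIQ,
    STATUS_MM1_AMB,
    STATUS_UNKNOWN,
    LibraryStats,
    map_library,
    map_tag,
)
from tagdge.qc import TagLibrary
from tagdge.reference import Transcriptome, build_tag_index

BASES = list("ACGT")


def _mutate(tag: str, positions: list[int], rng) -> str:
    out = list(tag)
    for pos in positions:
        out[pos] = rng.choice([b for b in BASES if b != tag[pos]])
    return "".join(out)


def random_transcriptome(rng, n_genes: int) -> Transcriptome:
    records = []
    for i in range(n_genes):
        length = int(rng.integers(100, 200))
        records.append((f"g{i:03d}", "".join(rng.choice(BASES, size=length))))
    return Transcriptome(records)


class TestMapTag:
    def test_exact_private_hit(self):
        tag = "CATG" + "ACGTTGCAACGTTGCAA"
        index = build_tag_index(Transcriptome([("G", "AA" + tag)]))
        a = map_tag(tag, index)
        assert a.status == STATUS_EXACT_UNIQ
        assert a.genes == frozenset({"G"}) and a.mismatches == 0

    def test_distance_two_is_unknown(self):
        tag = "CATG" + "ACGTTGCAACGTTGCAA"
        index = build_tag_index(Transcriptome([("G", tag)]))
        query = "CATG" + "TTGTTGCAACGTTGCAA"  # two substitutions in the variable region
        a = map_tag(query, index)
        assert a.status == STATUS_UNKNOWN and a.genes == frozenset()

    def test_one_mismatch_to_two_genes_is_ambiguous(self):
        t1 = "CATG" + "AAGTTGCAACGTTGCAA"
        t2 = "CATG" + "ACGTTGCAACGTTGCAT"
        index = build_tag_index(Transcriptome([("G1", t1), ("G2", t2)]))
        query = "CATG" + "ACGTTGCAACGTTGCAA"  # 1 mismatch from both
        a = map_tag(query, index)
        assert a.status == STATUS_MM1_AMB
        assert a.genes == frozenset({"G1", "G2"}) and a.mismatches == 1
        genes, tier = oracles.map_tag_bruteforce(query, {t1: {"G1"}, t2: {"G2"}})
        assert genes == set(a.genes) and tier == 1

    def test_exact_hit_ignores_mismatch_hits_elsewhere(self):
        t1 = "CATG" + "ACGTTGCAACGTTGCAA"
        t2 = "CATG" + "ACGTTGCAACGTTGCAT"  # distance 1 from t1
        index = build_tag_index(Transcriptome([("G1", t1), ("G2", t2)]))
        a = map_tag(t1, index)
        assert a.status == STATUS_EXACT_UNIQ and a.genes == frozenset({"G1"})

    def test_malformed_tag_rejected(self):
        index = build_tag_index(Transcriptome([("G", "CATG" + "A" * 13 + "CGTA")]))
        with pytest.raises(InputError):
            map_tag("CATGNNN", index)


class TestMapLibraryOracle:
    @pytest.mark.parametrize("seed", range(4))
    def test_equals_exhaustive_hamming_scan(self, seed):
        rng = np.random.default_rng(seed)
        tr = random_transcriptome(rng, 60)
        index = build_tag_index(tr)
        ref_tags = list(index.genes_by_tag)
        queries = {}
        for _ in range(120):
            base = rng.choice(ref_tags)
            k = int(rng.integers(0, 3))  # plant 0, 1 or 2 mismatches
            positions = list(rng.choice(21, size=k, replace=False))
            queries[_mutate(base, positions, rng)] = int(rng.integers(2, 50))
        result = map_library(TagLibrary("t", queries), index)
        brute_index = {t: set(g) for t, g in index.genes_by_tag.items()}
        for tag, a in result.assignments.items():
            genes, tier = oracles.map_tag_bruteforce(tag, brute_index)
            assert set(a.genes) == genes
            if tier is None:
                assert a.status == STATUS_UNKNOWN
            else:
                assert a.mismatches == tier

    def test_partition_and_subset_invariants(self, small_world):
        transcriptome, _, libraries = small_world
        index = build_tag_index(transcriptome)
        from tagdge.qc import clean_library
        from tagdge.synthetic import default_adapters

        clean, _ = clean_library(libraries[0], default_adapters())
        res = map_library(clean, index)
        assert res.all_mapped_total + res.unknown_total == res.clean_total
        assert res.all_mapped_distinct + res.unknown_distinct == res.clean_distinct
        assert res.unambiguous_total <= res.all_mapped_total
        assert res.unambiguous_mapped_genes <= res.all_mapped_genes
        # per-gene unambiguous recount
        recount: dict[str, int] = {}
        for tag, a in res.assignments.items():
            if a.unambiguous:
                g = next(iter(a.genes))
                recount[g] = recount.get(g, 0) + res.counts[tag]
        assert recount == res.gene_counts()

    def test_degenerate_all_exact_private(self):
        rng = np.random.default_rng(9)
        records = [
            (f"g{i}", "CATG" + "".join(rng.choice(BASES, size=17))) for i in range(20)
        ]
        tr = Transcriptome(records)
        index = build_tag_index(tr)
        lib = TagLibrary("t", {seq: 5 for _, seq in records})
        res = map_library(lib, index)
        assert res.all_mapped_total == res.unambiguous_total == res.clean_total

    def test_empty_library(self):
        index = build_tag_index(Transcriptome([("G", "CATG" + "A" * 10 + "CGTACGT")]))
        res = map_library(TagLibrary("t", {}), index)
        assert res.clean_total == 0 and res.all_mapped_total == 0


class TestLibraryStats:
    def test_published_counters_reproduce_published_percentages(self):
        expected = {
            "3DAF": (46.52, 53.59, 46.31, 53.39, 44.67, 44.41, 53.48, 46.41),
            "50DAF": (34.24, 54.66, 34.14, 54.46, 49.06, 48.77, 65.76, 45.34),
            "70DAF": (37.46, 56.32, 37.37, 56.12, 49.82, 49.58, 62.54, 43.68),
        }
        for _, row in dge_library_counters().iterrows():
            s = library_stats_from_counters(row)
            assert (
                s.all_mapped_total_pct,
                s.all_mapped_distinct_pct,
                s.unambiguous_total_pct,
                s.unambiguous_distinct_pct,
                s.all_mapped_genes_pct,
                s.unambiguous_mapped_genes_pct,
                s.unknown_total_pct,
                s.unknown_distinct_pct,
            ) == expected[s.stage_label]

    def test_zero_reference_genes_rejected(self):
        with pytest.raises(InputError):
            LibraryStats(
                stage_label="x",
                clean_total=0,
                clean_distinct=0,
                all_mapped_total=0,
                all_mapped_distinct=0,
                unambiguous_total=0,
                unambiguous_distinct=0,
                all_mapped_genes=0,
                unambiguous_mapped_genes=0,
                unknown_total=0,
                unknown_distinct=0,
                reference_gene_count=0,
            )

    def test_empty_library_percentages_zero(self):
        s = LibraryStats(
            stage_label="x",
            clean_total=0,
            clean_distinct=0,
            all_mapped_total=0,
            all_mapped_distinct=0,
            unambiguous_total=0,
            unambiguous_distinct=0,
            all_mapped_genes=0,
            unambiguous_mapped_genes=0,
            unknown_total=0,
            unknown_distinct=0,
            reference_gene_count=100,
        )
        assert s.all_mapped_total_pct == 0.0 and s.unknown_total_pct == 0.0
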