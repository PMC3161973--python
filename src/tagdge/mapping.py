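"""Mismatch-tolerant mapping of clean tags to the virtual tag database.

Each observed 21-nt tag is assigned to reference genes allowing at most one
nucleotide mismatch (Hamming distance; no indels).  Exact hits take
absolute priority: a tag with an exact database hit never claims 1-mismatch
hits, even to other genes.  When there is no exact hit, the gene set is the
union over all reference tags at Hamming distance exactly 1, found by
enumerating the 63 single-substitution neighbors (3 alternative bases x 21
positions) of the observed tag against the index hash.

Tags hitting multiple genes are *ambiguous*; their copies count toward the
library-level "all tags mapped" totals (once per tag, no fractional
splitting across genes) but are excluded from per-gene expression counts,
which use unambiguous assignments only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from tagdge.errors import InputError
from tagdge.qc import TagLibrary
from tagdge.reference import TAG_LEN, TagIndex

_BASES = "ACGT"

STATUS_EXACT_UNIQ = "exact-unambiguous"
STATUS_EXACT_AMB = "exact-ambiguous"
STATUS_MM1_UNIQ = "mismatch1-unambiguous"
STATUS_MM1_AMB = "mismatch1-ambiguous"
STATUS_UNKNOWN = "unknown"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (report-table convention; banker's rounding is not)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TagAssignment:
    tag: str
    status: str
    genes: frozenset[str]
    mismatches: int

    def __post_init__(self) -> None:
        assert (self.status == STATUS_UNKNOWN) == (len(self.genes) == 0)

    @property
    def unambiguous(self) -> bool:
        return len(self.genes) == 1


def one_mismatch_neighbors(tag: str):
    """Yield the 63 tags at Hamming distance exactly 1 from *tag*."""
    for i, orig in enumerate(tag):
        for b in _BASES:
            if b != orig:
                yield tag[:i] + b + tag[i + 1 :]


def map_tag(tag: str, index: TagIndex) -> TagAssignment:
    """Assign one clean tag to reference genes with <=1 mismatch."""
    if len(tag) != TAG_LEN or any(b not in _BASES for b in tag):
        raise InputError(f"malformed tag {tag!r}: expected {TAG_LEN} nt over ACGT")
    exact = index.genes(tag)
    if exact:
        status = STATUS_EXACT_UNIQ if len(exact) == 1 else STATUS_EXACT_AMB
        return TagAssignment(tag=tag, status=status, genes=exact, mismatches=0)
    genes: set[str] = set()
    for neighbor in one_mismatch_neighbors(tag):
        genes.update(index.genes(neighbor))
    if not genes:
        return TagAssignment(tag=tag, status=STATUS_UNKNOWN, genes=frozenset(), mismatches=0)
    status = STATUS_MM1_UNIQ if len(genes) == 1 else STATUS_MM1_AMB
    return TagAssignment(tag=tag, status=status, genes=frozenset(genes), mismatches=1)


@dataclass
class MappingResult:
    """Per-tag assignments plus the derived per-gene and library counters."""

    stage_label: str
    assignments: dict[str, TagAssignment]
    counts: dict[str, int]  # clean tag -> copy number

    @property
    def clean_total(self) -> int:
        return sum(self.counts.values())

    @property
    def clean_distinct(self) -> int:
        return len(self.counts)

    def _tier(self, mapped: bool, unambiguous_only: bool = False):
        for tag, a in self.assignments.items():
            is_mapped = a.status != STATUS_UNKNOWN
            if is_mapped != mapped:
                continue
            if unambiguous_only and not a.unambiguous:
                continue
            yield tag, a

    @property
    def all_mapped_total(self) -> int:
        return sum(self.counts[t] for t, _ in self._tier(mapped=True))

    @property
    def all_mapped_distinct(self) -> int:
        return sum(1 for _ in self._tier(mapped=True))

    @property
    def unambiguous_total(self) -> int:
        return sum(self.counts[t] for t, _ in self._tier(mapped=True, unambiguous_only=True))

    @property
    def unambiguous_distinct(self) -> int:
        return sum(1 for _ in self._tier(mapped=True, unambiguous_only=True))

    @property
    def unknown_total(self) -> int:
        return sum(self.counts[t] for t, _ in self._tier(mapped=False))

    @property
    def unknown_distinct(self) -> int:
        return sum(1 for _ in self._tier(mapped=False))

    @property
    def all_mapped_genes(self) -> frozenset[str]:
        """Genes hit by >=1 mapped tag, ambiguous tags included."""
        out: set[str] = set()
        for _, a in self._tier(mapped=True):
            out.update(a.genes)
        return frozenset(out)

    @property
    def unambiguous_mapped_genes(self) -> frozenset[str]:
        return frozenset(
            next(iter(a.genes)) for _, a in self._tier(mapped=True, unambiguous_only=True)
        )

    def gene_counts(self) -> dict[str, int]:
        """Per-gene expression counts from unambiguous assignments only."""
        out: dict[str, int] = {}
        for tag, a in self._tier(mapped=True, unambiguous_only=True):
            gene = next(iter(a.genes))
            out[gene] = out.get(gene, 0) + self.counts[tag]
        return out

    def assignments_frame(self) -> pd.DataFrame:
        rows = [
            (t, a.status, ",".join(sorted(a.genes)), a.mismatches, self.counts[t])
            for t, a in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["tag", "status", "gene_ids", "mismatches", "count"])


def map_library(clean: TagLibrary, index: TagIndex) -> MappingResult:
    """Map every distinct clean tag of a library against the index."""
    assignments = {tag: map_tag(tag, index) for tag in clean.counts}
    return MappingResult(
        stage_label=clean.stage_label, assignments=assignments, counts=dict(clean.counts)
    )


@dataclass
class LibraryStats:
    """Per-library mapping summary: totals, distinct counts and percentages.

    Percentages are 100 x numerator/denominator rounded half-up to two
    decimals; mapped percentages are relative to the clean totals, gene
    percentages relative to the reference gene count.
    """

    stage_label: str
    clean_total: int
    clean_distinct: int
    all_mapped_total: int
    all_mapped_distinct: int
    unambiguous_total: int
    unambiguous_distinct: int
    all_mapped_genes: int
    unambiguous_mapped_genes: int
    unknown_total: int
    unknown_distinct: int
    reference_gene_count: int

    def __post_init__(self) -> None:
        if self.reference_gene_count <= 0:
            raise InputError("reference_gene_count must be positive")
        if self.clean_total == 0:
            warnings.warn(
                f"library {self.stage_label!r} has no clean tags; percentages are 0",
                stacklevel=2,
            )

    @staticmethod
    def _pct(numer: int, denom: int) -> float:
        if denom == 0:
            return 0.0
        return round_half_up(100.0 * numer / denom, 2)

    @property
    def all_mapped_total_pct(self) -> float:
        return self._pct(self.all_mapped_total, self.clean_total)

    @property
    def all_mapped_distinct_pct(self) -> float:
        return self._pct(self.all_mapped_distinct, self.clean_distinct)

    @property
    def unambiguous_total_pct(self) -> float:
        return self._pct(self.unambiguous_total, self.clean_total)

    @property
    def unambiguous_distinct_pct(self) -> float:
        return self._pct(self.unambiguous_distinct, self.clean_distinct)

    @property
    def all_mapped_genes_pct(self) -> float:
        return self._pct(self.all_mapped_genes, self.reference_gene_count)

    @property
    def unambiguous_mapped_genes_pct(self) -> float:
        return self._pct(self.unambiguous_mapped_genes, self.reference_gene_count)

    @property
    def unknown_total_pct(self) -> float:
        return self._pct(self.unknown_total, self.clean_total)

    @property
    def unknown_distinct_pct(self) -> float:
        return self._pct(self.unknown_distinct, self.clean_distinct)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Clean Tag", "Total number", self.clean_total),
            ("Clean Tag", "Distinct Tag number", self.clean_distinct),
            ("All Tag Mapping to Gene", "Total number", self.all_mapped_total),
            ("All Tag Mapping to Gene", "Total % of clean tag", self.all_mapped_total_pct),
            ("All Tag Mapping to Gene", "Distinct Tag number", self.all_mapped_distinct),
            ("All Tag Mapping to Gene", "Distinct Tag % of clean tag", self.all_mapped_distinct_pct),
            ("Unambiguous Tag Mapping to Gene", "Total number", self.unambiguous_total),
            ("Unambiguous Tag Mapping to Gene", "Total % of clean tag", self.unambiguous_total_pct),
            ("Unambiguous Tag Mapping to Gene", "Distinct Tag number", self.unambiguous_distinct),
            (
                "Unambiguous Tag Mapping to Gene",
                "Distinct Tag % of clean tag",
                self.unambiguous_distinct_pct,
            ),
            ("All Tag-mapped Genes", "number", self.all_mapped_genes),
            ("All Tag-mapped Genes", "% of ref genes", self.all_mapped_genes_pct),
            ("Unambiguous Tag-mapped Genes", "number", self.unambiguous_mapped_genes),
            ("Unambiguous Tag-mapped Genes", "% of ref genes", self.unambiguous_mapped_genes_pct),
            ("Unknown Tag", "Total number", self.unknown_total),
            ("Unknown Tag", "Total % of clean tag", self.unknown_total_pct),
            ("Unknown Tag", "Distinct Tag number", self.unknown_distinct),
            ("Unknown Tag", "Distinct Tag % of clean tag", self.unknown_distinct_pct),
        ]
        df = pd.DataFrame(rows, columns=["category", "metric", "value"])
        df.insert(0, "stage", self.stage_label)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def library_stats(result: MappingResult, reference_gene_count: int) -> LibraryStats:
    """Summarize a MappingResult into the per-library statistics table."""
    return LibraryStats(
        stage_label=result.stage_label,
        clean_total=result.clean_total,
        clean_distinct=result.clean_distinct,
        all_mapped_total=result.all_mapped_total,
        all_mapped_distinct=result.all_mapped_distinct,
        unambiguous_total=result.unambiguous_total,
        unambiguous_distinct=result.unambiguous_distinct,
        all_mapped_genes=len(result.all_mapped_genes),
        unambiguous_mapped_genes=len(result.unambiguous_mapped_genes),
        unknown_total=result.unknown_total,
        unknown_distinct=result.unknown_distinct,
        reference_gene_count=reference_gene_count,
    )
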