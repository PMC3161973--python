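"""Virtual tag database construction from a reference transcriptome.

In NlaIII-anchored DGE, every mRNA is represented by 21-nt tags: the CATG
recognition site plus the 17 bases immediately downstream (the MmeI cut
offset).  The mapping target is therefore not the transcriptome itself but
the *virtual tag database*: the set of all CATG+17 tags extractable from the
sense strand of every reference gene.  This module builds that database and
reports how many genes are identifiable by at least one unique
(single-gene) tag.

Coordinates are 0-based half-open internally; report writers print 1-based
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tagdge.errors import InputError

ANCHOR = "CATG"
DOWNSTREAM = 17
TAG_LEN = len(ANCHOR) + DOWNSTREAM  # 21
_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class TagSite:
    """One extractable tag: gene, 0-based offset of the C of CATG, 21-nt tag."""

    gene_id: str
    offset: int
    tag: str


@dataclass
class Transcriptome:
    """Ordered collection of (gene_id, sequence) records over {A,C,G,T,N}."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene_id, seq in self.records:
            if gene_id in seen:
                raise InputError(f"duplicate gene id: {gene_id!r}")
            seen.add(gene_id)
            if not seq:
                raise InputError(f"empty sequence for gene {gene_id!r}")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise InputError(f"gene {gene_id!r} contains invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [gene_id for gene_id, _ in self.records]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Transcriptome":
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise InputError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in self.records]
        SeqIO.write(recs, str(path), "fasta")


def extract_tags(sequence: str, gene_id: str = "") -> list[TagSite]:
    """Extract all CATG+17 tag sites from the sense strand of *sequence*.

    One site per occurrence of CATG with at least 17 bases downstream, in
    5'->3' order.  Tags containing N are excluded (unmatchable under the
    clean-tag rules).  Overlapping CATG occurrences each yield a site.
    """
    sites: list[TagSite] = []
    start = sequence.find(ANCHOR)
    while start != -1:
        end = start + TAG_LEN
        if end <= len(sequence):
            tag = sequence[start:end]
            if "N" not in tag:
                sites.append(TagSite(gene_id=gene_id, offset=start, tag=tag))
        start = sequence.find(ANCHOR, start + 1)
    return sites


@dataclass
class TagIndex:
    """Map from 21-nt tag sequence to the set of gene ids containing it.

    A tag shared by more than one gene is *ambiguous*; only unambiguous tags
    contribute to gene-level expression downstream.
    """

    genes_by_tag: dict[str, frozenset[str]]
    n_reference_genes: int
    tags_per_gene: dict[str, int] = field(default_factory=dict)

    def __contains__(self, tag: str) -> bool:
        return tag in self.genes_by_tag

    def __len__(self) -> int:
        return len(self.genes_by_tag)

    def genes(self, tag: str) -> frozenset[str]:
        return self.genes_by_tag.get(tag, frozenset())

    def is_ambiguous(self, tag: str) -> bool:
        return len(self.genes_by_tag.get(tag, ())) > 1

    @property
    def n_genes_with_unique_tag(self) -> int:
        """Genes identifiable by >=1 tag private to a single gene."""
        owners = {next(iter(gs)) for gs in self.genes_by_tag.values() if len(gs) == 1}
        return len(owners)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (tag, ",".join(sorted(gs)), int(len(gs) > 1))
            for tag, gs in sorted(self.genes_by_tag.items())
        ]
        pd.DataFrame(rows, columns=["tag", "gene_ids", "ambiguous"]).to_csv(
            path, sep="\t", index=False
        )

    def summary(self) -> pd.DataFrame:
        n_amb = sum(1 for gs in self.genes_by_tag.values() if len(gs) > 1)
        return pd.DataFrame(
            {
                "metric": [
                    "reference_genes",
                    "distinct_tags",
                    "ambiguous_tags",
                    "genes_with_unique_tag",
                ],
                "value": [
                    self.n_reference_genes,
                    len(self.genes_by_tag),
                    n_amb,
                    self.n_genes_with_unique_tag,
                ],
            }
        )


def build_tag_index(transcriptome: Transcriptome | Iterable[tuple[str, str]]) -> TagIndex:
    """Build the virtual tag database: all CATG+17 tags of every gene.

    All CATG sites are indexed (not only the 3'-most); sense strand only.
    """
    if not isinstance(transcriptome, Transcriptome):
        transcriptome = Transcriptome(list(transcriptome))
    genes_by_tag: dict[str, set[str]] = {}
    tags_per_gene: dict[str, int] = {}
    for gene_id, seq in transcriptome:
        sites = extract_tags(seq, gene_id)
        tags_per_gene[gene_id] = len({s.tag for s in sites})
        for site in sites:
            genes_by_tag.setdefault(site.tag, set()).add(gene_id)
    return TagIndex(
        genes_by_tag={t: frozenset(g) for t, g in genes_by_tag.items()},
        n_reference_genes=len(transcriptome),
        tags_per_gene=tags_per_gene,
    )
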