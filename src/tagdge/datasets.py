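"""Bundled summary tables from a published *Siraitia grosvenorii* fruit
transcriptome / DGE study, used as worked-example inputs.

* ``dge_library_counters`` — per-library tag and mapping counters for the
  three developmental stages (3, 50 and 70 days after flowering) against a
  43,891-gene reference transcriptome.
* ``secondary_metabolite_unigenes`` — unigene counts per secondary
  metabolite pathway category.
* ``mogroside_v_content`` — mogroside V content (% fresh weight) by stage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from tagdge.mapping import LibraryStats


def _read(name: str) -> pd.DataFrame:
    with resources.files("tagdge.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def dge_library_counters() -> pd.DataFrame:
    return _read("dge_library_counters.tsv")


def secondary_metabolite_unigenes() -> pd.Series:
    df = _read("secondary_metabolite_unigenes.tsv")
    return pd.Series(df["count"].values, index=df["category"].values, name="count")


def mogroside_v_content() -> pd.Series:
    df = _read("mogroside_v_content.tsv")
    return pd.Series(df["mogroside_v_percent"].values, index=df["stage"].values)


def library_stats_from_counters(row: pd.Series) -> LibraryStats:
    """Build a LibraryStats from one row of ``dge_library_counters``."""
    return LibraryStats(
        stage_label=str(row["stage"]),
        clean_total=int(row["clean_total"]),
        clean_distinct=int(row["clean_distinct"]),
        all_mapped_total=int(row["all_mapped_total"]),
        all_mapped_distinct=int(row["all_mapped_distinct"]),
        unambiguous_total=int(row["unambiguous_total"]),
        unambiguous_distinct=int(row["unambiguous_distinct"]),
        all_mapped_genes=int(row["all_mapped_genes"]),
        unambiguous_mapped_genes=int(row["unambiguous_mapped_genes"]),
        unknown_total=int(row["unknown_total"]),
        unknown_distinct=int(row["unknown_distinct"]),
        reference_gene_count=int(row["reference_gene_count"]),
    )
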