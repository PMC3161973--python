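"""Anchor-gene co-expression candidate selection.

Tailoring-enzyme discovery by guilt-by-association: family members (e.g.
CYP450s, UDP-glucosyltransferases) whose developmental expression profiles
track pathway anchor genes of known role (e.g. squalene epoxidase, SQE;
cucurbitadienol synthase, CS) are prioritized as candidates.  A family
member is selected when it (1) is differentially expressed in at least one
stage pair, (2) shows net up-regulation from the first to the last stage,
and (3) has Pearson correlation above a threshold (default 0.99) to at
least one anchor over the log2 expression profile.

Profiles are log2 TPM relative to the first stage; hierarchical clustering
of survivors with the anchors (average linkage on 1 - Pearson r) provides
the leaf order for heatmap rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from tagdge.errors import InputError
from tagdge.expression import DEResult, ExpressionMatrix, TPM_FLOOR

DEFAULT_R_THRESHOLD = 0.99


def profile_matrix(expr: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Per-gene log2 expression profiles relative to the first stage.

    Each row is log2(max(TPM, 0.001)) per stage minus the first-stage
    value, i.e. log2 ratios versus stage 1 (first row entry is 0).
    """
    missing = [g for g in genes if g not in expr.counts.index]
    if missing:
        raise InputError(f"unknown gene ids: {missing[:5]}")
    t = expr.tpm.loc[genes].clip(lower=TPM_FLOOR)
    log2t = np.log2(t)
    return log2t.sub(log2t.iloc[:, 0], axis=0)


def pearson_r(a, b) -> float:
    """Sample Pearson correlation; NaN when either vector is constant
    (treated as r = 0 by the selection gate)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("vectors must have equal length")
    if a.size < 2:
        raise InputError("vectors must have length >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = math.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        return math.nan
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


def hcluster(matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage agglomerative clustering on correlation distance.

    Distance between rows is d = 1 - Pearson r.  Rows are pre-sorted by
    label so ties break lexicographically and the result is deterministic.
    Returns (leaf order as row labels, scipy linkage matrix).
    """
    if matrix.shape[0] < 2:
        raise InputError("clustering needs at least 2 rows")
    m = matrix.sort_index(kind="stable")
    rows = m.to_numpy(dtype=float)
    # pdist 'correlation' is undefined for constant rows; compute manually
    n = rows.shape[0]
    labels = list(m.index)
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_r(rows[i], rows[j])
            dists.append(1.0 - (0.0 if math.isnan(r) else r))
    link = average(np.asarray(dists))
    order = [labels[i] for i in leaves_list(link)]
    return order, link


@dataclass
class AnchorSet:
    """Named anchor genes and their log2 profiles from the expression matrix."""

    anchors: dict[str, str]  # label -> gene_id
    profiles: pd.DataFrame  # label x stages, log2 relative to stage 1

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix, anchors: dict[str, str]) -> "AnchorSet":
        missing = [g for g in anchors.values() if g not in expr.counts.index]
        if missing:
            raise InputError(f"anchor genes absent from expression matrix: {missing}")
        prof = profile_matrix(expr, list(anchors.values()))
        prof.index = list(anchors.keys())
        if not np.isfinite(prof.to_numpy()).all():
            raise InputError("anchor profiles must be finite")
        return cls(anchors=dict(anchors), profiles=prof)

    @classmethod
    def from_tsv(cls, path: str | Path, expr: ExpressionMatrix) -> "AnchorSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"label", "gene_id"}.issubset(df.columns):
            raise InputError(f"{path}: expected columns 'label' and 'gene_id'")
        return cls.from_expression(expr, dict(zip(df["label"], df["gene_id"])))


@dataclass
class CandidateReport:
    """Per family member: best anchor, correlation, gate flags, selection."""

    table: pd.DataFrame  # gene_id index: family, best_anchor, r_best, de_flag, up_flag, selected
    leaf_order: list[str]
    clustered: pd.DataFrame  # survivors + anchors, rows in leaf order

    def selected_genes(self) -> list[str]:
        return sorted(self.table.index[self.table["selected"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def select_candidates(
    expr: ExpressionMatrix,
    family_table: dict[str, str] | pd.Series,
    anchors: AnchorSet,
    de_results: list[DEResult],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    strict_monotone: bool = False,
) -> CandidateReport:
    """Select family members co-expressed with anchors.

    Gates per family member: differentially expressed in >=1 stage pair;
    up-regulated over the developmental period (last vs first stage log2
    ratio > 0; with ``strict_monotone``, every consecutive stage must
    increase); max Pearson r to any anchor over the log2 profile above
    ``r_threshold``.  Constant (zero-variance) profiles get r = 0 so they
    fail the correlation gate rather than being dropped.
    """
    family = pd.Series(dict(family_table)) if not isinstance(family_table, pd.Series) else family_table
    members = [g for g in family.index if g in expr.counts.index]
    members = sorted(members)
    if not members:
        raise InputError("no family members present in the expression matrix")
    de_union: frozenset[str] = frozenset().union(*(r.de_genes() for r in de_results)) if de_results else frozenset()
    prof = profile_matrix(expr, members)
    rows = []
    for g in members:
        row = prof.loc[g].to_numpy()
        if strict_monotone:
            up = bool(np.all(np.diff(row) > 0))
        else:
            up = bool(row[-1] - row[0] > 0)
        best_anchor, r_best = "", -np.inf
        for label in anchors.profiles.index:
            r = pearson_r(row, anchors.profiles.loc[label].to_numpy())
            if math.isnan(r):
                r = 0.0
            if r > r_best:
                best_anchor, r_best = label, r
        de_flag = g in de_union
        selected = de_flag and up and (r_best > r_threshold)
        rows.append((g, family[g], best_anchor, r_best, de_flag, up, selected))
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "family", "best_anchor", "r_best", "de_flag", "up_flag", "selected"],
    ).set_index("gene_id")
    survivors = list(table.index[table["selected"]])
    cluster_input = pd.concat([prof.loc[survivors], anchors.profiles])
    if cluster_input.shape[0] >= 2:
        leaf_order, _ = hcluster(cluster_input)
        clustered = cluster_input.loc[leaf_order]
    else:
        leaf_order = list(cluster_input.index)
        clustered = cluster_input
    return CandidateReport(table=table, leaf_order=leaf_order, clustered=clustered)
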