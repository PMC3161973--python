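"""TPM quantification and Audic-Claverie differential expression.

With a single tag library per condition, differential expression between
two libraries of sizes N1 and N2 is assessed with the Audic-Claverie
statistic.  Given x copies of a gene's tags in library 1, the probability
of observing y copies in library 2 under equal underlying expression is

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

the negative-binomial posterior predictive obtained by integrating the
Poisson rate under a flat prior.  The two-sided p-value doubles the smaller
tail probability (capped at 1).  All probabilities are computed in
log-space via log-gamma; both tails are direct sums whose truncation error
is controlled by a geometric bound, so even p-values near the floating
point underflow limit retain full relative precision.

Multiple testing is controlled with Benjamini-Hochberg FDR; expression is
normalized to TPM (tags per million clean tags).  Genes with zero counts in
both libraries of a pair are untestable and are excluded from the BH family
so they do not dilute the FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from tagdge.errors import InputError
from tagdge.mapping import MappingResult

DEFAULT_FDR = 0.001
DEFAULT_LFC = 1.0
TPM_FLOOR = 0.001

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NULL = "null"


def tpm(count: int, clean_total: int) -> float:
    """Tags per million: 1e6 * count / clean_total."""
    if clean_total <= 0:
        raise InputError("clean_total must be positive")
    if count < 0:
        raise InputError("count must be non-negative")
    return 1e6 * count / clean_total


def log2_ratio(tpm_a: float, tpm_b: float, floor: float = TPM_FLOOR) -> float:
    """log2 fold change b vs a; zeros replaced by *floor* (default 0.001 TPM).

    The floor is applied only to values that are exactly 0, so small but
    nonzero TPM values are used as-is.
    """
    if floor <= 0:
        raise InputError("floor must be positive")
    a = floor if tpm_a == 0 else tpm_a
    b = floor if tpm_b == 0 else tpm_b
    return math.log2(b / a)


def _log_pmf(ks: np.ndarray, x: int, logr: float, log1pr: float) -> np.ndarray:
    """log p(k|x) for an array of k, with r = N2/N1."""
    return (
        ks * logr
        + gammaln(x + ks + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ks + 1.0)
        - (x + ks + 1.0) * log1pr
    )


def _log_upper_tail(x: int, y: int, logr: float, log1pr: float) -> float:
    """log sum_{k>=y} p(k|x), summed until a geometric bound certifies
    the truncated remainder is below 1e-18 of the accumulated sum."""
    logq = logr - log1pr  # log(r/(1+r)) < 0
    total = -np.inf
    k0 = y
    block = 512
    while True:
        ks = np.arange(k0, k0 + block, dtype=float)
        lp = _log_pmf(ks, x, logr, log1pr)
        total = np.logaddexp(total, logsumexp(lp))
        k_last = k0 + block - 1
        # term ratio t(k+1)/t(k) = q*(x+k+1)/(k+1), decreasing toward q
        log_rho = logq + math.log((x + k_last + 2.0) / (k_last + 2.0))
        if log_rho < 0:
            rho = math.exp(log_rho)
            log_bound = lp[-1] + log_rho - math.log1p(-rho)
            if log_bound < total + math.log(1e-18):
                return float(min(total, 0.0))
        k0 += block


def audic_claverie_log_p(x: int, y: int, N1: int, N2: int) -> float:
    """Natural log of the two-sided Audic-Claverie p-value.

    Useful when the p-value underflows double precision (counts far out in
    a tail); the log value retains full relative precision.
    """
    if x < 0 or y < 0:
        raise InputError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise InputError("library sizes must be positive")
    logr = math.log(N2) - math.log(N1)
    log1pr = math.log(N1 + N2) - math.log(N1)
    log_lower = min(
        float(logsumexp(_log_pmf(np.arange(y + 1, dtype=float), x, logr, log1pr))), 0.0
    )
    log_upper = _log_upper_tail(x, y, logr, log1pr)
    return min(0.0, math.log(2.0) + min(log_lower, log_upper))


def audic_claverie_p(x: int, y: int, N1: int, N2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts x (library 1, size N1)
    and y (library 2, size N2): min(1, 2*min(P[K<=y], P[K>=y]))."""
    return math.exp(audic_claverie_log_p(x, y, N1, N2))


def audic_claverie_log_p_grid(x: int, y_max: int, N1: int, N2: int) -> np.ndarray:
    """log two-sided p-values for all y in 0..y_max at fixed x, in one pass.

    Same statistic as :func:`audic_claverie_log_p`; the pmf is evaluated
    once out to K chosen so the truncated upper-tail remainder is below
    1e-18 relative, and both tails come from running log-sums.
    """
    if x < 0 or y_max < 0:
        raise InputError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise InputError("library sizes must be positive")
    logr = math.log(N2) - math.log(N1)
    log1pr = math.log(N1 + N2) - math.log(N1)
    logq = logr - log1pr
    r = N2 / N1
    mean = (x + 1) * r
    sd = math.sqrt((x + 1) * r * (1.0 + r))
    K = int(max(y_max, mean + 20 * sd)) + 64
    while True:
        ks = np.arange(K + 1, dtype=float)
        lp = _log_pmf(ks, x, logr, log1pr)
        log_rho = logq + math.log((x + K + 2.0) / (K + 2.0))
        if log_rho < 0:
            rho = math.exp(log_rho)
            log_remainder = lp[K] + log_rho - math.log1p(-rho)
            log_upper_at_ymax = float(logsumexp(lp[y_max:]))
            if log_remainder < log_upper_at_ymax + math.log(1e-18):
                break
        K = 2 * K + 256
    log_lower = np.minimum(np.logaddexp.accumulate(lp), 0.0)
    log_upper = np.minimum(np.logaddexp.accumulate(lp[::-1])[::-1], 0.0)
    out = math.log(2.0) + np.minimum(log_lower[: y_max + 1], log_upper[: y_max + 1])
    return np.minimum(out, 0.0)


def audic_claverie_point(x: int, y: int, N1: int, N2: int) -> float:
    """Point probability p(y|x) (log-space evaluation)."""
    if x < 0 or y < 0:
        raise InputError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise InputError("library sizes must be positive")
    logr = math.log(N2) - math.log(N1)
    log1pr = math.log(N1 + N2) - math.log(N1)
    return float(np.exp(_log_pmf(np.array([float(y)]), x, logr, log1pr)[0]))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ExpressionMatrix:
    """Genes x stages expression: raw unambiguous tag counts, clean totals
    per stage, and the derived TPM matrix."""

    counts: pd.DataFrame  # genes x stages, int
    clean_totals: pd.Series  # per stage

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.clean_totals.index):
            raise InputError("counts columns and clean_totals index must agree")
        if (self.clean_totals <= 0).any():
            raise InputError("clean totals must be positive")

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tpm(self) -> pd.DataFrame:
        return 1e6 * self.counts / self.clean_totals

    @classmethod
    def from_mapping_results(
        cls, results: list[MappingResult], gene_ids: list[str]
    ) -> "ExpressionMatrix":
        counts = pd.DataFrame(0, index=pd.Index(gene_ids, name="gene_id"), columns=[], dtype=int)
        totals = {}
        for res in results:
            col = pd.Series(res.gene_counts(), dtype=int).reindex(gene_ids, fill_value=0)
            counts[res.stage_label] = col
            totals[res.stage_label] = res.clean_total
        return cls(counts=counts, clean_totals=pd.Series(totals)[counts.columns])

    def to_tsv(self, path: str | Path) -> None:
        out = self.tpm.copy()
        out.columns = [f"tpm_{s}" for s in self.stages]
        for s in self.stages:
            out[f"count_{s}"] = self.counts[s]
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, clean_totals: dict[str, int]) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        stages = list(clean_totals)
        counts = df[[f"count_{s}" for s in stages]].copy()
        counts.columns = stages
        return cls(counts=counts.astype(int), clean_totals=pd.Series(clean_totals))


@dataclass
class DEResult:
    """Pairwise differential-expression table for one stage pair."""

    stage_a: str
    stage_b: str
    table: pd.DataFrame  # per gene: x, y, tpm_a, tpm_b, log2_ratio, p, q, call
    fdr_threshold: float = DEFAULT_FDR
    lfc_threshold: float = DEFAULT_LFC

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == CALL_UP).sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == CALL_DOWN).sum())

    def de_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["call"] != CALL_NULL])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def call_de(
    expr: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
) -> DEResult:
    """Call differential expression between two stages.

    Per gene, the Audic-Claverie two-sided p-value is computed from raw
    unambiguous counts and library clean totals, adjusted across all
    testable genes (nonzero in at least one library) by Benjamini-Hochberg,
    and a gene is called up (down) when q < fdr_threshold and the log2
    TPM ratio (b vs a, zeros floored at 0.001) is >= lfc_threshold
    (<= -lfc_threshold).
    """
    for s in (stage_a, stage_b):
        if s not in expr.stages:
            raise InputError(f"stage {s!r} not in expression matrix")
    x = expr.counts[stage_a]
    y = expr.counts[stage_b]
    n1 = int(expr.clean_totals[stage_a])
    n2 = int(expr.clean_totals[stage_b])
    tpm_a = expr.tpm[stage_a]
    tpm_b = expr.tpm[stage_b]
    lfc = pd.Series(
        [log2_ratio(a, b) for a, b in zip(tpm_a, tpm_b)], index=expr.counts.index
    )
    testable = (x > 0) | (y > 0)
    p = pd.Series(np.nan, index=expr.counts.index)
    p[testable] = [audic_claverie_p(int(xi), int(yi), n1, n2) for xi, yi in zip(x[testable], y[testable])]
    q = pd.Series(np.nan, index=expr.counts.index)
    if testable.any():
        q[testable] = bh_fdr(p[testable].to_numpy())
    call = pd.Series(CALL_NULL, index=expr.counts.index)
    sig = testable & (q < fdr_threshold)
    call[sig & (lfc >= lfc_threshold)] = CALL_UP
    call[sig & (lfc <= -lfc_threshold)] = CALL_DOWN
    table = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "tpm_a": tpm_a,
            "tpm_b": tpm_b,
            "log2_ratio": lfc,
            "p_value": p,
            "q_value": q,
            "call": call,
        }
    )
    return DEResult(
        stage_a=stage_a,
        stage_b=stage_b,
        table=table,
        fdr_threshold=fdr_threshold,
        lfc_threshold=lfc_threshold,
    )
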