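"""End-to-end pipeline orchestration and report-level count summaries.

``run_pipeline`` chains the stages build-index -> qc -> map -> quantify ->
dge -> candidates over documented FASTA/TSV artifacts and writes a run
manifest with a content hash for every output, so a rerun on identical
inputs is byte-identical and verifiable.  Stage failures abort with the
stage name and cause.

All outputs are UTF-8, tab-separated, "." decimal, no thousands
separators.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tagdge._version import __version__ as _pkg_version
from tagdge.candidates import AnchorSet, CandidateReport, select_candidates
from tagdge.errors import InputError, StageError
from tagdge.expression import DEResult, ExpressionMatrix, call_de
from tagdge.mapping import MappingResult, library_stats, map_library, round_half_up
from tagdge.qc import TagLibrary, clean_library
from tagdge.reference import Transcriptome, build_tag_index

logger = logging.getLogger("tagdge")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed for one pipeline run."""

    transcriptome: Path
    libraries: dict[str, Path]  # stage label -> raw library TSV (ordered)
    families: Path
    anchors: Path
    outdir: Path
    fdr_threshold: float = 0.001
    lfc_threshold: float = 1.0
    r_threshold: float = 0.99
    adapters: list[str] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.transcriptome = Path(self.transcriptome)
        self.libraries = {k: Path(v) for k, v in self.libraries.items()}
        self.families = Path(self.families)
        self.anchors = Path(self.anchors)
        self.outdir = Path(self.outdir)
        if not 0 < self.fdr_threshold < 1:
            raise InputError("fdr_threshold must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise InputError("lfc_threshold must be non-negative")
        if len(set(self.libraries)) != len(self.libraries) or not self.libraries:
            raise InputError("stage labels must be unique and non-empty")

    @property
    def stage_labels(self) -> list[str]:
        return list(self.libraries)


@dataclass
class CountSummary:
    """Labeled counts with derived total and percentages (1-decimal, half-up)."""

    counts: pd.Series
    denominator: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> pd.Series:
        return self.counts.map(lambda c: round_half_up(100.0 * c / self.denominator, 1))

    def to_frame(self) -> pd.DataFrame:
        total_row = pd.DataFrame(
            {
                "count": [self.total],
                "percent": [round_half_up(100.0 * self.total / self.denominator, 1)],
            },
            index=["Total"],
        )
        return pd.concat(
            [pd.DataFrame({"count": self.counts, "percent": self.percentages}), total_row]
        )


def summarize_counts(table: dict[str, int] | pd.Series, denominator: int | str = "sum") -> CountSummary:
    """Summarize a category->count table against a denominator.

    ``denominator`` is either an externally supplied reference count or
    "sum" for the table's own total.
    """
    counts = pd.Series(table, dtype=int) if not isinstance(table, pd.Series) else table.astype(int)
    if (counts < 0).any():
        raise InputError("counts must be non-negative")
    if denominator == "sum":
        denom = int(counts.sum())
    else:
        denom = int(denominator)
    if denom <= 0:
        raise InputError("denominator must be positive")
    return CountSummary(counts=counts, denominator=denom)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Runner:
    """Tracks outputs and wraps stage execution with timing and errors."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.outputs: list[Path] = []

    def run(self, stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        logger.info("stage %s: start", stage)
        try:
            result = fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, exc) from exc
        logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
        return result

    def register(self, *paths: Path) -> None:
        self.outputs.extend(paths)


def load_family_table(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "family"}.issubset(df.columns):
        raise InputError(f"{path}: expected columns 'gene_id' and 'family'")
    return pd.Series(df["family"].values, index=df["gene_id"].values, name="family")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    runner = _Runner(out)

    def _build_index():
        transcriptome = Transcriptome.from_fasta(config.transcriptome)
        index = build_tag_index(transcriptome)
        index.to_tsv(out / "tag_index.tsv")
        index.summary().to_csv(out / "index_summary.tsv", sep="\t", index=False)
        runner.register(out / "tag_index.tsv", out / "index_summary.tsv")
        return transcriptome, index

    transcriptome, index = runner.run("build-index", _build_index)

    def _qc():
        cleans = []
        reports = []
        for stage, path in config.libraries.items():
            if not path.exists():
                raise InputError(f"library file not found: {path}")
            raw = TagLibrary.from_tsv(path, stage_label=stage)
            clean, stats = clean_library(raw, config.adapters)
            clean.to_tsv(out / f"clean_{stage}.tsv")
            runner.register(out / f"clean_{stage}.tsv")
            cleans.append(clean)
            frame = stats.to_frame()
            frame.insert(0, "stage", stage)
            reports.append(frame)
        pd.concat(reports).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        runner.register(out / "qc_report.tsv")
        return cleans

    cleans = runner.run("qc", _qc)

    def _map():
        results: list[MappingResult] = []
        stats_frames = []
        for clean in cleans:
            res = map_library(clean, index)
            res.assignments_frame().to_csv(
                out / f"assignments_{clean.stage_label}.tsv", sep="\t", index=False
            )
            pd.Series(res.gene_counts(), name="count").rename_axis("gene_id").sort_index().to_csv(
                out / f"gene_counts_{clean.stage_label}.tsv", sep="\t"
            )
            runner.register(
                out / f"assignments_{clean.stage_label}.tsv",
                out / f"gene_counts_{clean.stage_label}.tsv",
            )
            stats_frames.append(library_stats(res, len(transcriptome)).to_frame())
            results.append(res)
        pd.concat(stats_frames).to_csv(out / "library_stats.tsv", sep="\t", index=False)
        runner.register(out / "library_stats.tsv")
        return results

    results = runner.run("map", _map)

    def _quantify():
        expr = ExpressionMatrix.from_mapping_results(results, transcriptome.gene_ids)
        expr.to_tsv(out / "expression_matrix.tsv")
        runner.register(out / "expression_matrix.tsv")
        return expr

    expr = runner.run("quantify", _quantify)

    def _dge():
        stages = config.stage_labels
        de_results: list[DEResult] = []
        summary_rows = []
        for i in range(len(stages)):
            for j in range(i + 1, len(stages)):
                a, b = stages[i], stages[j]
                res = call_de(expr, a, b, config.fdr_threshold, config.lfc_threshold)
                res.to_tsv(out / f"de_{a}_vs_{b}.tsv")
                runner.register(out / f"de_{a}_vs_{b}.tsv")
                summary_rows.append((a, b, res.n_up, res.n_down))
                de_results.append(res)
        pd.DataFrame(summary_rows, columns=["stage_a", "stage_b", "n_up", "n_down"]).to_csv(
            out / "de_summary.tsv", sep="\t", index=False
        )
        runner.register(out / "de_summary.tsv")
        return de_results

    de_results = runner.run("dge", _dge)

    def _candidates() -> CandidateReport:
        if not config.anchors.exists():
            raise InputError(f"anchors file not found: {config.anchors}")
        if not config.families.exists():
            raise InputError(f"family annotation file not found: {config.families}")
        anchors = AnchorSet.from_tsv(config.anchors, expr)
        family = load_family_table(config.families)
        report = select_candidates(
            expr, family, anchors, de_results, r_threshold=config.r_threshold
        )
        report.to_tsv(out / "candidate_report.tsv")
        report.clustered.to_csv(out / "clustered_matrix.tsv", sep="\t", index_label="gene_id")
        runner.register(out / "candidate_report.tsv", out / "clustered_matrix.tsv")
        return report

    runner.run("candidates", _candidates)

    def _report():
        import numpy
        import scipy

        manifest = {
            "inputs": {
                "transcriptome": str(config.transcriptome),
                "libraries": {k: str(v) for k, v in config.libraries.items()},
                "families": str(config.families),
                "anchors": str(config.anchors),
            },
            "thresholds": {
                "fdr": config.fdr_threshold,
                "lfc": config.lfc_threshold,
                "r": config.r_threshold,
            },
            "adapters": list(config.adapters),
            "seed": config.rng_seed,
            "versions": {
                "tagdge": _pkg_version,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
            "outputs": {p.name: _sha256(p) for p in sorted(runner.outputs)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    runner.run("report", _report)
    return out
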