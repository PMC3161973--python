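"""Clean-tag quality control.

Raw DGE tag libraries contain adapter read-through, tags with uncalled
bases, empty/malformed tags, low-complexity artefacts and singletons
(copy number 1, most likely sequencing error).  ``clean_library`` removes
all of these and books every removed copy under exactly one reason, in a
fixed precedence order so the accounting is deterministic:

    empty/malformed -> adapter -> contains-N -> low-complexity -> singleton

A clean tag is 21 nt, starts with CATG, has no N, matches no adapter,
passes the complexity rule and has copy number >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tagdge.errors import InputError
from tagdge.reference import ANCHOR, TAG_LEN

# Removal reasons in precedence order.
REASONS = ("empty", "adapter", "contains_n", "low_complexity", "singleton")


@dataclass
class TagLibrary:
    """One stage's tag-count table: tag sequence -> copy number."""

    stage_label: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for tag, n in self.counts.items():
            if n < 0:
                raise InputError(f"negative count for tag {tag!r} in {self.stage_label}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct(self) -> int:
        return len(self.counts)

    @classmethod
    def from_tsv(cls, path: str | Path, stage_label: str | None = None) -> "TagLibrary":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
        if not {"tag", "count"}.issubset(df.columns):
            raise InputError(f"{path}: expected columns 'tag' and 'count'")
        label = stage_label if stage_label is not None else Path(path).stem
        return cls(stage_label=label, counts=dict(zip(df["tag"], df["count"])))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(sorted(self.counts.items()), columns=["tag", "count"])
        df.to_csv(path, sep="\t", index=False)


@dataclass
class QCStats:
    """Removed copy/distinct counts per reason; conserves the raw total."""

    stage_label: str
    raw_total: int
    raw_distinct: int
    clean_total: int
    clean_distinct: int
    removed_copies: dict[str, int] = field(default_factory=dict)
    removed_distinct: dict[str, int] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return sum(self.removed_copies.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("raw_total", self.raw_total), ("raw_distinct", self.raw_distinct)]
        rows += [(f"removed_{r}", self.removed_copies.get(r, 0)) for r in REASONS]
        rows += [("clean_total", self.clean_total), ("clean_distinct", self.clean_distinct)]
        return pd.DataFrame(rows, columns=["metric", "value"])


def low_complexity(tag: str) -> bool:
    """True iff the 17-nt variable region is low complexity.

    The rule: longest homopolymer run >= 15 within the 17 variable bases, or
    the variable region contains <= 2 distinct bases.
    """
    if len(tag) != TAG_LEN:
        raise InputError(f"low_complexity expects a {TAG_LEN}-nt tag, got {len(tag)} nt")
    var = tag[len(ANCHOR):]
    if len(set(var)) <= 2:
        return True
    run = best = 1
    for prev, cur in zip(var, var[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best >= 15


def _removal_reason(tag: str, count: int, adapters: tuple[str, ...]) -> str | None:
    """First matching removal reason, or None if the tag is clean."""
    if len(tag) != TAG_LEN or not tag.startswith(ANCHOR):
        return "empty"
    if any(a and a in tag for a in adapters):
        return "adapter"
    if "N" in tag:
        return "contains_n"
    if low_complexity(tag):
        return "low_complexity"
    if count < 2:
        return "singleton"
    return None


def clean_library(raw: TagLibrary, adapters: list[str] | None = None) -> tuple[TagLibrary, QCStats]:
    """Apply the clean-tag filters to a raw library.

    Adapter matching is exact substring match of each provided adapter
    against the tag.  Every removed copy is booked under the first matching
    reason; raw total = clean total + sum of removed copies.
    """
    adapters_t = tuple(a.upper() for a in (adapters or []))
    clean: dict[str, int] = {}
    removed_copies = {r: 0 for r in REASONS}
    removed_distinct = {r: 0 for r in REASONS}
    for tag, count in raw.counts.items():
        reason = _removal_reason(tag, count, adapters_t)
        if reason is None:
            clean[tag] = count
        else:
            removed_copies[reason] += count
            removed_distinct[reason] += 1
    lib = TagLibrary(stage_label=raw.stage_label, counts=clean)
    stats = QCStats(
        stage_label=raw.stage_label,
        raw_total=raw.total,
        raw_distinct=raw.distinct,
        clean_total=lib.total,
        clean_distinct=lib.distinct,
        removed_copies=removed_copies,
        removed_distinct=removed_distinct,
    )
    return lib, stats
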