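"""Synthetic transcriptomes and tag libraries with planted ground truth.

The generator emulates the data a three-stage fruit-development DGE
experiment produces: a reference transcriptome in which every quantifiable
gene carries at least one NlaIII CATG site with 17 downstream bases, and
one raw tag library per developmental stage (default labels 3DAF, 50DAF,
70DAF — days after flowering).  Planted structure:

* two anchor genes with fixed relative-expression profiles across the
  stages, default (1.0, 1.25, 8.89) for SQE and (1.0, 2.85, 9.69) for CS,
  i.e. 7.11x and 3.40x between stages 2 and 3 and 8.89x / 9.69x between
  stages 1 and 3;
* candidate family members whose log2 profiles equal their anchor's up to
  Gaussian noise (default sd 0.05 in log2), so the noiseless correlation
  is exactly 1;
* differentially expressed genes at a configurable fold change, decoy
  family members that fail the co-expression gates, and flat background;
* sequencing substitution errors, singleton noise tags (guaranteed to be
  at Hamming distance >= 2 from every reference tag), N-containing tags
  and adapter contaminants.

Sampling is multinomial over normalized expected expression per stage
(Poisson-equivalent at these library sizes, matching the sampling model of
the Audic-Claverie statistic).  Everything is determined by the configured
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tagdge.errors import InvalidConfigError
from tagdge.qc import TagLibrary
from tagdge.reference import ANCHOR, TAG_LEN, Transcriptome, extract_tags
from tagdge.mapping import one_mismatch_neighbors

DEFAULT_STAGES = ("3DAF", "50DAF", "70DAF")
DEFAULT_ANCHOR_PROFILES = {
    "SQE": (1.0, 1.25, 8.89),
    "CS": (1.0, 2.85, 9.69),
}
# 12-nt adapter core used for planted contaminants; QC removes any tag
# containing it.
ADAPTER_CORE = "TCGTATGCCGTC"
_BASES = np.array(list("ACGT"))

FAMILY_BY_ANCHOR = {"SQE": "CYP450", "CS": "UDPG"}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the simulated conditions."""

    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (300, 1500)
    n_stages: int = 3
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    library_size: int = 1_000_000
    anchor_profiles: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ANCHOR_PROFILES.items()}
    )
    # stage-1 abundance of the anchors in background units; pathway anchors
    # are well-expressed, which keeps their sampled profiles tight
    anchor_base_expression: float = 8.0
    n_candidates_per_anchor: int = 5
    candidate_log2_noise_sd: float = 0.05
    n_de_genes: int = 50
    de_fold_change: float = 8.0
    n_family_decoys: int = 10
    substitution_error_rate: float = 0.001
    singleton_noise_tags: int = 2000
    n_tag_rate: float = 0.001
    adapter_contam_rate: float = 0.001
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise InvalidConfigError("library_size must be positive")
        if self.gene_length_range[0] < TAG_LEN:
            raise InvalidConfigError(
                f"gene_length_range lower bound must be >= {TAG_LEN} nt"
            )
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise InvalidConfigError("gene_length_range must be (low, high) with low <= high")
        for name, rate in [
            ("substitution_error_rate", self.substitution_error_rate),
            ("n_tag_rate", self.n_tag_rate),
            ("adapter_contam_rate", self.adapter_contam_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if len(self.stage_labels) != self.n_stages:
            raise InvalidConfigError("stage_labels must have length n_stages")
        if self.candidate_log2_noise_sd < 0:
            raise InvalidConfigError("candidate_log2_noise_sd must be non-negative")
        if self.anchor_base_expression <= 0:
            raise InvalidConfigError("anchor_base_expression must be positive")
        for label, prof in self.anchor_profiles.items():
            if len(prof) != self.n_stages:
                raise InvalidConfigError(
                    f"anchor profile {label!r} must have length n_stages={self.n_stages}"
                )
            if any(v <= 0 for v in prof):
                raise InvalidConfigError(f"anchor profile {label!r} must be strictly positive")
        n_planted = (
            len(self.anchor_profiles)
            + self.n_candidates_per_anchor * len(self.anchor_profiles)
            + self.n_de_genes
            + self.n_family_decoys
        )
        if self.n_genes < n_planted + 1:
            raise InvalidConfigError(
                f"n_genes={self.n_genes} too small for {n_planted} planted genes"
            )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "anchor_profiles"
        }
        d["anchor_profiles"] = {k: list(v) for k, v in self.anchor_profiles.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["gene_length_range"] = tuple(d["gene_length_range"])
        d["stage_labels"] = tuple(d["stage_labels"])
        d["anchor_profiles"] = {k: tuple(v) for k, v in d["anchor_profiles"].items()}
        return cls(**d)


@dataclass
class SimulationTruth:
    """Planted per-gene truth for recovery tests."""

    expected_tpm: pd.DataFrame  # genes x stages
    de_labels: pd.DataFrame  # genes x stage pairs, values in {up, down, null}
    candidate_labels: pd.DataFrame  # genes: is_candidate (bool), anchor (str)
    family_labels: pd.Series  # gene -> family string ("" = no family)
    anchor_genes: dict[str, str]  # anchor label -> gene id
    stage_labels: tuple[str, ...]
    stage_rel_totals: pd.Series | None = None  # pre-normalization stage sums

    def planted_candidates(self) -> list[str]:
        return sorted(self.candidate_labels.index[self.candidate_labels["is_candidate"]])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.expected_tpm.to_csv(outdir / "truth_expected_tpm.tsv", sep="\t", index_label="gene_id")
        self.de_labels.to_csv(outdir / "truth_de_labels.tsv", sep="\t", index_label="gene_id")
        self.candidate_labels.to_csv(
            outdir / "truth_candidates.tsv", sep="\t", index_label="gene_id"
        )
        fam = self.family_labels[self.family_labels != ""]
        fam.rename("family").to_csv(outdir / "families.tsv", sep="\t", index_label="gene_id")
        pd.DataFrame(
            {"label": list(self.anchor_genes), "gene_id": list(self.anchor_genes.values())}
        ).to_csv(outdir / "anchors.tsv", sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _has_extractable_tag(seq: str) -> bool:
    return len(extract_tags(seq)) > 0


def _relative_profiles(config: SyntheticConfig, rng: np.random.Generator) -> tuple[
    pd.DataFrame, pd.DataFrame, pd.Series, dict[str, str]
]:
    """Assign roles and per-stage relative expression to every gene."""
    n = config.n_genes
    gene_ids = [f"Gene{i:05d}" for i in range(n)]
    anchor_labels = list(config.anchor_profiles)
    rel = np.zeros((n, config.n_stages))
    is_candidate = np.zeros(n, dtype=bool)
    anchor_of = np.array([""] * n, dtype=object)
    family = np.array([""] * n, dtype=object)
    anchor_genes: dict[str, str] = {}

    i = 0
    for label in anchor_labels:
        rel[i] = config.anchor_base_expression * np.asarray(config.anchor_profiles[label])
        anchor_genes[label] = gene_ids[i]
        i += 1
    for label in anchor_labels:
        prof = np.log2(np.asarray(config.anchor_profiles[label]))
        for _ in range(config.n_candidates_per_anchor):
            scale = rng.lognormal(mean=0.0, sigma=0.5)
            noise = rng.normal(0.0, config.candidate_log2_noise_sd, size=config.n_stages)
            rel[i] = scale * 2.0 ** (prof + noise)
            is_candidate[i] = True
            anchor_of[i] = label
            family[i] = FAMILY_BY_ANCHOR.get(label, "CYP450")
            i += 1
    fc = config.de_fold_change
    for j in range(config.n_de_genes):
        scale = rng.lognormal(mean=0.0, sigma=0.5)
        pattern = np.ones(config.n_stages)
        # up genes rise after stage 1, down genes fall; the mirrored patterns
        # keep stage totals balanced so TPM normalization stays comparable
        # across stages
        if j % 2 == 0:
            pattern[1:] = fc
        else:
            pattern[0] = fc
        rel[i] = scale * pattern
        i += 1
    # Decoy family members: profiles deliberately uncorrelated with anchors
    flat = np.ones(config.n_stages)
    down = np.ones(config.n_stages)
    down[1:] = 0.25
    transient = np.ones(config.n_stages)
    if config.n_stages >= 2:
        transient[1] = 4.0
    decoy_patterns = [flat, down, transient]
    for j in range(config.n_family_decoys):
        scale = rng.lognormal(mean=0.0, sigma=0.5)
        rel[i] = scale * decoy_patterns[j % len(decoy_patterns)]
        family[i] = "CYP450" if j % 2 == 0 else "UDPG"
        i += 1
    # flat background, scaled up so planted genes stay a small fraction of
    # each stage's total and normalization barely shifts across stages
    rel[i:] = 3.0 * rng.lognormal(mean=0.0, sigma=0.7, size=(n - i, 1))

    stage_totals = rel.sum(axis=0)
    expected_tpm = pd.DataFrame(
        1e6 * rel / stage_totals[None, :],
        index=pd.Index(gene_ids, name="gene_id"),
        columns=list(config.stage_labels),
    )
    candidate_labels = pd.DataFrame(
        {"is_candidate": is_candidate, "anchor": anchor_of},
        index=expected_tpm.index,
    )
    family_labels = pd.Series(family, index=expected_tpm.index, name="family")
    rel_totals = pd.Series(stage_totals, index=list(config.stage_labels))
    return expected_tpm, candidate_labels, family_labels, anchor_genes, rel_totals


def _de_labels(expected_tpm: pd.DataFrame, fold: float = 2.0) -> pd.DataFrame:
    """Tri-state labels per stage pair from expected TPM ratios."""
    stages = list(expected_tpm.columns)
    out = {}
    for ai in range(len(stages)):
        for bi in range(ai + 1, len(stages)):
            a, b = stages[ai], stages[bi]
            ratio = expected_tpm[b] / expected_tpm[a]
            lab = pd.Series("null", index=expected_tpm.index)
            lab[ratio >= fold] = "up"
            lab[ratio <= 1.0 / fold] = "down"
            out[f"{a}_vs_{b}"] = lab
    return pd.DataFrame(out)


def generate_transcriptome(config: SyntheticConfig) -> tuple[Transcriptome, SimulationTruth]:
    """Generate the reference transcriptome and the planted truth tables.

    Every gene is quantifiable: sequences lacking a CATG site with 17
    downstream bases get one written in at a random valid position.
    """
    rng = np.random.default_rng(config.rng_seed)
    expected_tpm, candidate_labels, family_labels, anchor_genes, rel_totals = _relative_profiles(
        config, rng
    )
    lo, hi = config.gene_length_range
    records: list[tuple[str, str]] = []
    for gene_id in expected_tpm.index:
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length)
        if not _has_extractable_tag(seq):
            pos = int(rng.integers(0, length - TAG_LEN + 1))
            seq = seq[:pos] + ANCHOR + seq[pos + len(ANCHOR):]
            if not _has_extractable_tag(seq):  # inserted site broken by chance? impossible
                raise AssertionError("tag injection failed")
        records.append((str(gene_id), seq))
    truth = SimulationTruth(
        expected_tpm=expected_tpm,
        de_labels=_de_labels(expected_tpm),
        candidate_labels=candidate_labels,
        family_labels=family_labels,
        anchor_genes=anchor_genes,
        stage_labels=tuple(config.stage_labels),
        stage_rel_totals=rel_totals,
    )
    return Transcriptome(records), truth


def _tag_weights(tags: list[str]) -> np.ndarray:
    """3'-most tag gets probability 0.8 plus its uniform share."""
    k = len(tags)
    w = np.full(k, 0.2 / k)
    w[-1] += 0.8
    return w


def _apply_substitution_errors(
    counts: dict[str, int], rate: float, rng: np.random.Generator
) -> dict[str, int]:
    """Mutate copies at the per-base substitution rate (conditioned >=1 sub)."""
    if rate == 0:
        return counts
    p_any = 1.0 - (1.0 - rate) ** TAG_LEN
    out: dict[str, int] = {}
    for tag, count in counts.items():
        n_err = int(rng.binomial(count, p_any))
        if count - n_err:
            out[tag] = out.get(tag, 0) + count - n_err
        for _ in range(n_err):
            while True:
                hits = rng.random(TAG_LEN) < rate
                if hits.any():
                    break
            mutated = list(tag)
            for pos in np.flatnonzero(hits):
                choices = [b for b in "ACGT" if b != tag[pos]]
                mutated[pos] = choices[int(rng.integers(3))]
            mtag = "".join(mutated)
            out[mtag] = out.get(mtag, 0) + 1
    return out


def _random_unknown_tag(ref_tags: frozenset[str], rng: np.random.Generator) -> str:
    """Random CATG+17 tag at Hamming distance >= 2 from every reference tag."""
    while True:
        tag = ANCHOR + _random_sequence(rng, TAG_LEN - len(ANCHOR))
        if tag in ref_tags:
            continue
        if any(nb in ref_tags for nb in one_mismatch_neighbors(tag)):
            continue
        return tag


def simulate_libraries(
    transcriptome: Transcriptome, truth: SimulationTruth, config: SyntheticConfig
) -> list[TagLibrary]:
    """Sample one raw tag library per stage.

    Per stage: gene counts are multinomial over normalized expected
    expression; each gene's copies pick one of its extractable tags
    (3'-most with probability 0.8, uniform otherwise); substitution errors
    are applied per copy; singleton noise tags, N-containing tags and
    adapter contaminants are injected on top.  The raw total equals
    library_size plus all injected noise copies.
    """
    if len(truth.stage_labels) != config.n_stages:
        raise InvalidConfigError("truth stage count does not match config.n_stages")
    rng = np.random.default_rng([config.rng_seed, 1])
    gene_tags: dict[str, list[str]] = {}
    for gene_id, seq in transcriptome:
        tags = [s.tag for s in extract_tags(seq, gene_id)]
        seen: list[str] = []
        for t in tags:
            if t not in seen:
                seen.append(t)
        gene_tags[gene_id] = seen
    ref_tags = frozenset(t for tags in gene_tags.values() for t in tags)
    gene_ids = list(truth.expected_tpm.index)
    libraries: list[TagLibrary] = []
    for stage in truth.stage_labels:
        probs = truth.expected_tpm[stage].to_numpy()
        probs = probs / probs.sum()
        gene_counts = rng.multinomial(config.library_size, probs)
        counts: dict[str, int] = {}
        for gene_id, n in zip(gene_ids, gene_counts):
            if n == 0:
                continue
            tags = gene_tags[gene_id]
            if len(tags) == 1:
                per_tag = [int(n)]
            else:
                per_tag = rng.multinomial(int(n), _tag_weights(tags))
            for t, c in zip(tags, per_tag):
                if c:
                    counts[t] = counts.get(t, 0) + int(c)
        counts = _apply_substitution_errors(counts, config.substitution_error_rate, rng)
        # singleton noise: true unknowns, one copy each
        for _ in range(config.singleton_noise_tags):
            tag = _random_unknown_tag(ref_tags, rng)
            while tag in counts:
                tag = _random_unknown_tag(ref_tags, rng)
            counts[tag] = 1
        # N-containing tags
        remaining = int(round(config.n_tag_rate * config.library_size))
        while remaining > 0:
            base = ANCHOR + _random_sequence(rng, TAG_LEN - len(ANCHOR))
            pos = int(rng.integers(len(ANCHOR), TAG_LEN))
            ntag = base[:pos] + "N" + base[pos + 1:]
            c = min(remaining, 3)
            counts[ntag] = counts.get(ntag, 0) + c
            remaining -= c
        # adapter contaminants: CATG + 5 random nt + 12-nt adapter core
        remaining = int(round(config.adapter_contam_rate * config.library_size))
        while remaining > 0:
            atag = ANCHOR + _random_sequence(rng, 5) + ADAPTER_CORE
            c = min(remaining, 3)
            counts[atag] = counts.get(atag, 0) + c
            remaining -= c
        libraries.append(TagLibrary(stage_label=stage, counts=counts))
    return libraries


def default_adapters() -> list[str]:
    """Adapter sequences the QC stage should screen for."""
    return [ADAPTER_CORE]
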