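"""Synthetic-data generator: determinism, guarantees and sampling model."""

import numpy as np
import pandas as pd
import pytest

import oracles
from tagdge.candidates import pearson_r
from tagdge.errors import InvalidConfigError
from tagdge.reference import build_tag_index
from tagdge.synthetic import (
    ADAPTER_CORE,
    SyntheticConfig,
    generate_transcriptome,
    simulate_libraries,
)


def noiseless_config(**kw) -> SyntheticConfig:
    base = dict(
        n_genes=60,
        gene_length_range=(100, 300),
        library_size=50_000,
        n_candidates_per_anchor=2,
        n_de_genes=6,
        n_family_decoys=3,
        substitution_error_rate=0.0,
        singleton_noise_tags=0,
        n_tag_rate=0.0,
        adapter_contam_rate=0.0,
        rng_seed=11,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_short_gene_length_rejected(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(gene_length_range=(20, 100))

    @pytest.mark.parametrize("field, value", [
        ("substitution_error_rate", 1.5),
        ("n_tag_rate", -0.1),
        ("library_size", 0),
        ("candidate_log2_noise_sd", -1.0),
    ])
    def test_invalid_rates_rejected(self, field, value):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(**{field: value})

    def test_anchor_profile_length_must_match_stages(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(anchor_profiles={"SQE": (1.0, 2.0)})

    def test_yaml_roundtrip(self, tmp_path):
        cfg = noiseless_config()
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SyntheticConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestGenerateTranscriptome:
    def test_deterministic_bytes(self, tmp_path):
        cfg = noiseless_config(n_genes=50, rng_seed=1)
        t1, _ = generate_transcriptome(cfg)
        t2, _ = generate_transcriptome(cfg)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        t1.to_fasta(p1)
        t2.to_fasta(p2)
        assert len(t1) == 50
        assert p1.read_bytes() == p2.read_bytes()

    def test_every_gene_has_extractable_tag(self):
        cfg = noiseless_config(n_genes=200, n_de_genes=10, rng_seed=3)
        transcriptome, _ = generate_transcriptome(cfg)
        with_tag = sum(1 for _, seq in transcriptome if oracles.scan_tags(seq))
        assert with_tag == 200

    def test_truth_tables_populated(self, small_world):
        _, truth, _ = small_world
        assert truth.expected_tpm.shape[1] == 3
        assert set(truth.anchor_genes) == {"SQE", "CS"}
        assert truth.candidate_labels["is_candidate"].sum() == 6
        assert (truth.de_labels.to_numpy() != "null").any()

    def test_planted_anchor_fold_changes(self, small_world):
        _, truth, _ = small_world
        tpm = truth.expected_tpm
        # undo the per-stage TPM normalization to recover the planted
        # relative profile (1, 1.25, 8.89) exactly
        rel = tpm.loc[truth.anchor_genes["SQE"]] * truth.stage_rel_totals
        assert rel.iloc[2] / rel.iloc[1] == pytest.approx(8.89 / 1.25)
        assert rel.iloc[2] / rel.iloc[0] == pytest.approx(8.89)

    def test_de_labels_consistent_with_expected_ratios(self, small_world):
        _, truth, _ = small_world
        tpm = truth.expected_tpm
        lab = truth.de_labels["3DAF_vs_50DAF"]
        ratio = tpm["50DAF"] / tpm["3DAF"]
        assert ((lab == "up") == (ratio >= 2.0)).all()
        assert ((lab == "down") == (ratio <= 0.5)).all()


class TestSimulateLibraries:
    def test_deterministic(self):
        cfg = noiseless_config(singleton_noise_tags=50, n_tag_rate=0.001)
        tr, truth = generate_transcriptome(cfg)
        l1 = simulate_libraries(tr, truth, cfg)
        l2 = simulate_libraries(tr, truth, cfg)
        assert [lib.counts for lib in l1] == [lib.counts for lib in l2]

    def test_copy_conservation(self, small_config, small_world):
        _, _, libraries = small_world
        cfg = small_config
        noise = (
            cfg.singleton_noise_tags
            + round(cfg.n_tag_rate * cfg.library_size)
            + round(cfg.adapter_contam_rate * cfg.library_size)
        )
        for lib in libraries:
            assert lib.total == cfg.library_size + noise

    def test_zero_expression_stage_yields_no_tags(self):
        cfg = noiseless_config()
        tr, truth = generate_transcriptome(cfg)
        gene = truth.expected_tpm.index[-1]  # background gene
        tpm = truth.expected_tpm.copy()
        stage = tpm.columns[0]
        tpm.loc[gene, stage] = 0.0
        truth.expected_tpm = tpm
        libs = simulate_libraries(tr, truth, cfg)
        gene_tags = {s.tag for s in _tags_of(tr, gene)}
        assert not gene_tags & set(libs[0].counts)

    def test_no_errors_means_all_tags_in_reference(self):
        cfg = noiseless_config()
        tr, truth = generate_transcriptome(cfg)
        index = build_tag_index(tr)
        for lib in simulate_libraries(tr, truth, cfg):
            assert all(tag in index for tag in lib.counts)

    def test_noise_classes_present_and_distinct(self):
        cfg = noiseless_config(
            singleton_noise_tags=100, n_tag_rate=0.002, adapter_contam_rate=0.002
        )
        tr, truth = generate_transcriptome(cfg)
        index = build_tag_index(tr)
        lib = simulate_libraries(tr, truth, cfg)[0]
        n_tags = [t for t in lib.counts if "N" in t]
        adapter_tags = [t for t in lib.counts if ADAPTER_CORE in t]
        unknown_singletons = [
            t
            for t, c in lib.counts.items()
            if c == 1 and t not in index and "N" not in t and ADAPTER_CORE not in t
        ]
        assert n_tags and adapter_tags
        assert len(unknown_singletons) >= 100
        # planted unknowns are >= 2 mismatches from every reference tag
        brute = {t: set(g) for t, g in index.genes_by_tag.items()}
        for t in unknown_singletons[:20]:
            genes, tier = oracles.map_tag_bruteforce(t, brute)
            assert tier is None

    def test_stage_mismatch_rejected(self, small_world):
        tr, truth, _ = small_world
        cfg = noiseless_config(n_stages=2, stage_labels=("a", "b"),
                               anchor_profiles={"SQE": (1.0, 2.0), "CS": (1.0, 3.0)})
        with pytest.raises(InvalidConfigError):
            simulate_libraries(tr, truth, cfg)

    def test_binomial_sampling_mean(self):
        # one gene at relative expression 1e-3: over 200 seeds the mean
        # observed count must sit within 3 standard errors of its expectation
        cfg = noiseless_config(n_stages=1, stage_labels=("s",),
                               anchor_profiles={"SQE": (1.0,), "CS": (1.0,)},
                               library_size=100_000, rng_seed=0)
        tr, truth = generate_transcriptome(cfg)
        gene = truth.expected_tpm.index[-1]
        tpm = truth.expected_tpm.copy()
        tpm["s"] = (1e6 - 1e3) / (len(tpm) - 1)
        tpm.loc[gene, "s"] = 1e3  # relative expression 1e-3
        truth.expected_tpm = tpm
        gene_tags = {s.tag for s in _tags_of(tr, gene)}
        expectation = 1e-3 * cfg.library_size
        observed = []
        for seed in range(200):
            cfg_i = noiseless_config(n_stages=1, stage_labels=("s",),
                                     anchor_profiles={"SQE": (1.0,), "CS": (1.0,)},
                                     library_size=100_000, rng_seed=seed)
            lib = simulate_libraries(tr, truth, cfg_i)[0]
            observed.append(sum(c for t, c in lib.counts.items() if t in gene_tags))
        se = np.std(observed, ddof=1) / np.sqrt(len(observed))
        assert abs(np.mean(observed) - expectation) <= 3 * se

    def test_candidate_empirical_profile_tracks_anchor(self):
        cfg = noiseless_config(library_size=500_000, candidate_log2_noise_sd=0.0)
        tr, truth = generate_transcriptome(cfg)
        libs = simulate_libraries(tr, truth, cfg)
        index = build_tag_index(tr)
        from tagdge.expression import ExpressionMatrix
        from tagdge.mapping import map_library

        results = [map_library(lib, index) for lib in libs]
        expr = ExpressionMatrix.from_mapping_results(results, tr.gene_ids)
        log_tpm = np.log2(expr.tpm.clip(lower=0.001))
        for gene in truth.planted_candidates():
            anchor_gene = truth.anchor_genes[truth.candidate_labels.loc[gene, "anchor"]]
            r = pearson_r(log_tpm.loc[gene], log_tpm.loc[anchor_gene])
            assert r > 0.99


def _tags_of(transcriptome, gene_id):
    from tagdge.reference import extract_tags

    seq = dict(transcriptome.records)[gene_id]
    return extract_tags(seq, gene_id)
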