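import numpy as np
import pandas as pd
import pytest

from tcrkit.network import ld1_edges_bruteforce, levenshtein
from tcrkit.simulate import (
    ConfigError,
    GeneratorConfig,
    SampleSpec,
    _PrivateSupply,
    generate_cdr3,
    generate_cohort,
    generate_public_pool,
    generate_repertoire,
    write_cohort,
)
from conftest import small_generator_config


class TestGenerateCDR3:
    def test_length_constraint_and_motif(self, rng):
        seq = generate_cdr3(rng, length_mean=8, length_sd=0)
        assert len(seq) == 8
        assert seq.startswith("C") and seq.endswith("F")

    def test_mean_length_recovered(self):
        rng = np.random.default_rng(123)
        lengths = [len(generate_cdr3(rng)) for _ in range(10_000)]
        assert np.mean(lengths) == pytest.approx(15, abs=0.1)

    def test_deterministic_stream(self):
        a = [generate_cdr3(np.random.default_rng(9)) for _ in range(5)]
        b = [generate_cdr3(np.random.default_rng(9)) for _ in range(5)]
        assert a == b

    def test_invalid_bounds_rejected(self, rng):
        with pytest.raises(ConfigError):
            generate_cdr3(rng, length_bounds=(4, 30))


class TestPublicPool:
    def test_clusters_are_ld1_stars(self, rng):
        pool = generate_public_pool(small_generator_config(), rng)
        cluster = pool[pool["cluster_id"] == 0]["cdr3_aa"].tolist()
        assert len(cluster) >= 2
        # the seed is at LD 1 from every mutant, so the cluster's LD=1 graph
        # has at least size-1 edges (a star at minimum)
        edges = ld1_edges_bruteforce(cluster)
        assert len(edges) >= len(cluster) - 1

    def test_clusters_disjoint(self, rng):
        pool = generate_public_pool(small_generator_config(), rng)
        assert pool["cdr3_aa"].is_unique

    def test_distant_clusters_unconnected(self, rng):
        pool = generate_public_pool(small_generator_config(), rng)
        c0 = pool[pool["cluster_id"] == 0]["cdr3_aa"].tolist()
        # find a cluster whose seed is far from c0's seed
        for cid in range(1, 50):
            ci = pool[pool["cluster_id"] == cid]["cdr3_aa"].tolist()
            if ci and levenshtein(c0[0], ci[0]) > 4:
                cross = {
                    (a, b) for a in c0 for b in ci if levenshtein(a, b) == 1
                }
                assert not cross
                return
        pytest.fail("no distant cluster found")

    def test_oversized_pool_rejected(self, rng):
        cfg = GeneratorConfig(
            n_clusters=10**7, cluster_size=100, length_mean=8, length_sd=0
        )
        with pytest.raises(ConfigError):
            generate_public_pool(cfg, rng)


def _spec(**kw):
    defaults = dict(
        sample_id="S001",
        patient_id="P001",
        lesion_id="P001-L1",
        aliquot_id="P001-L1-A1",
        group="no_nact",
        true_fraction=0.08,
        exponent=4.0,
        richness=300,
        reads_per_template=10.0,
    )
    defaults.update(kw)
    return SampleSpec(**defaults)


class TestGenerateRepertoire:
    @pytest.fixture()
    def setup(self, rng):
        cfg = small_generator_config()
        pool = generate_public_pool(cfg, rng)
        supply = _PrivateSupply(cfg, set(pool["cdr3_aa"]), rng)
        return cfg, pool, supply, rng

    def test_dna_mass_inverts_fraction(self, setup):
        cfg, pool, supply, rng = setup
        rep = generate_repertoire(_spec(), pool, supply, rng, cfg)
        genomes = rep.input_dna_ng * 1000 / 6.6
        assert rep.total_templates / genomes == pytest.approx(0.08, rel=1e-12)

    def test_mass_formula_example(self):
        from tcrkit.simulate import _dna_mass_ng

        # 10,000 templates at fraction 0.08 -> 825 ng
        assert _dna_mass_ng(10_000, 0.08) == pytest.approx(825.0)
        with pytest.raises(ConfigError):
            _dna_mass_ng(10_000, 1.5)

    def test_zero_public_rate_excludes_pool(self, rng):
        cfg = GeneratorConfig(
            n_patients=(2, 2, 2), richness_range=(100, 200), n_clusters=50,
            cluster_size=5, public_rate=0.0, seed=1,
        )
        cohort = generate_cohort(cfg)
        pool_seqs = set(cohort.truth.pool["cdr3_aa"])
        for rep in cohort.repertoires:
            assert not (set(rep.clonotypes["cdr3_aa"]) & pool_seqs)

    def test_richness_honoured(self, setup):
        cfg, pool, supply, rng = setup
        rep = generate_repertoire(_spec(richness=250), pool, supply, rng, cfg)
        assert rep.n_clonotypes == 250


class TestGenerateCohort:
    def test_structure(self, small_cohort):
        truth = small_cohort.truth.samples
        assert (truth["role"] == "primary").sum() == 10
        assert (truth["role"] == "aliquot_replicate").sum() == 3
        assert (truth["role"] == "second_lesion").sum() == 4
        assert len(small_cohort.repertoires) == 17
        assert small_cohort.manifest["sample_id"].is_unique

    def test_default_config_matches_study_design(self):
        cfg = GeneratorConfig()
        assert cfg.n_patients == (35, 35, 15)
        assert len(cfg.aliquot_replicates) == 3
        assert len(cfg.lesion_pairs) == 4

    def test_replicates_share_lesion(self, small_cohort):
        man = small_cohort.manifest
        by_lesion = man.groupby("lesion_id")["sample_id"].count()
        assert (by_lesion == 2).sum() == 3  # the aliquot-replicate lesions

    def test_deterministic_files(self, small_cohort, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        write_cohort(small_cohort, a_dir)
        write_cohort(generate_cohort(small_generator_config()), b_dir)
        for f in sorted(a_dir.rglob("*")):
            if f.is_file():
                twin = b_dir / f.relative_to(a_dir)
                assert twin.read_bytes() == f.read_bytes(), f.name

    def test_ground_truth_provenance(self, small_cohort):
        pool_seqs = set(small_cohort.truth.pool["cdr3_aa"])
        rep = small_cohort.repertoires[0]
        seqs = rep.clonotypes["cdr3_aa"]
        labels = {small_cohort.truth.provenance(s) for s in seqs[:20]}
        assert labels <= {"private"} | {
            f"public_cluster_{c}" for c in small_cohort.truth.pool["cluster_id"]
        }
        assert any(s in pool_seqs for s in seqs)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(public_rate=1.5)
        with pytest.raises(ConfigError):
            GeneratorConfig(richness_range=(0, 10))
        with pytest.raises(ConfigError):
            GeneratorConfig(cluster_size=1)
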