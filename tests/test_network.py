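import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tcrkit.io import Repertoire, build_cohort_table, collapse_clonotypes
from tcrkit.network import (
    NetworkError,
    PathologyDBError,
    build_ld1_network,
    class_connectivity,
    degree_vs_sharing,
    ld1_edges,
    ld1_edges_bruteforce,
    levenshtein,
    pathology_match,
    read_pathology_db,
    sharing_index,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seqs(rng, n, with_mutants=True):
    """Random CDR3-like sequences, plus planted single-edit variants so the
    LD=1 graph is nonempty."""
    seqs = set()
    while len(seqs) < n:
        L = int(np.clip(rng.normal(13, 2), 8, 20))
        seqs.add("C" + "".join(rng.choice(list(AA), L - 2)) + "F")
    seqs = sorted(seqs)
    if with_mutants:
        for s in seqs[: max(2, n // 10)]:
            pos = int(rng.integers(1, len(s) - 1))
            sub = s[:pos] + rng.choice([c for c in AA if c != s[pos]]) + s[pos + 1:]
            dele = s[:pos] + s[pos + 1:]
            seqs.extend([sub, dele])
    return sorted(set(seqs))


class TestLevenshtein:
    def test_worked_examples(self):
        assert levenshtein("CASSLG", "CASSLG") == 0
        assert levenshtein("CASSF", "CASTF") == 1
        assert levenshtein("CASSF", "CASSFG") == 1
        assert levenshtein("KITTEN", "SITTING") == 3

    def test_empty_rejected(self):
        with pytest.raises(NetworkError):
            levenshtein("", "CASSF")

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.text(alphabet=AA, min_size=1, max_size=15),
        st.text(alphabet=AA, min_size=1, max_size=15),
    )
    def test_agrees_with_edlib(self, a, b):
        import edlib

        assert levenshtein(a, b) == edlib.align(a, b)["editDistance"]

    def test_metric_properties(self, rng):
        seqs = _random_seqs(rng, 10)
        for a in seqs[:5]:
            for b in seqs[:5]:
                assert levenshtein(a, b) == levenshtein(b, a)
                assert (levenshtein(a, b) == 0) == (a == b)


class TestLD1Network:
    def test_toy_network(self):
        net = build_ld1_network(["CASSF", "CASTF", "CASSFG", "CAKKF"])
        assert net.edges == {("CASSF", "CASTF"), ("CASSF", "CASSFG")}
        assert net.n_nodes == 4
        assert net.n_edges == 2
        assert net.connectivity_fraction == 0.5

    def test_singleton(self):
        net = build_ld1_network(["CASSF"])
        assert net.n_edges == 0
        assert net.connectivity_fraction == 0.0

    def test_fast_path_equals_dp_oracle(self, rng):
        for _ in range(20):
            seqs = _random_seqs(rng, int(rng.integers(20, 120)))
            assert ld1_edges(seqs) == ld1_edges_bruteforce(seqs)

    def test_fast_path_equals_edlib_oracle(self, rng):
        import edlib

        seqs = _random_seqs(rng, 150)
        expected = {
            (a, b)
            for i, a in enumerate(seqs)
            for b in seqs[i + 1:]
            if edlib.align(a, b, k=1)["editDistance"] == 1
        }
        assert ld1_edges(seqs) == expected

    def test_degree_sum_is_twice_edges(self, rng):
        net = build_ld1_network(_random_seqs(rng, 100))
        assert sum(net.degree.values()) == 2 * net.n_edges

    def test_isolated_node_lowers_connectivity(self):
        base = build_ld1_network(["CASSF", "CASTF"])
        plus = build_ld1_network(["CASSF", "CASTF", "CWWWWWWWWWWF"])
        assert plus.connectivity_fraction < base.connectivity_fraction

    def test_exports(self, tmp_path, rng):
        net = build_ld1_network(["CASSF", "CASTF"])
        net.write_edgelist(tmp_path / "e.tsv")
        assert (tmp_path / "e.tsv").read_text().splitlines()[1] == "CASSF\tCASTF"
        net.write_graphml(tmp_path / "g.graphml", {"templates": {"CASSF": 3, "CASTF": 1}})
        assert (tmp_path / "g.graphml").exists()


def _cohort(samples):
    """samples: {sample_id: (patient_id, {clone: count})}"""
    reps = [
        Repertoire(
            sample_id=sid,
            clonotypes=collapse_clonotypes(list(counts.items())),
            patient_id=pid,
            lesion_id=f"{pid}-L1",
            aliquot_id=sid,
            group="no_nact",
        )
        for sid, (pid, counts) in samples.items()
    ]
    return build_cohort_table(reps), reps


class TestSharingIndex:
    def test_patient_level_counting(self):
        table, _ = _cohort(
            {
                "s1": ("P1", {"CASSF": 1, "CAAAF": 1}),
                "s2": ("P1", {"CASSF": 2}),
                "s3": ("P2", {"CASSF": 1}),
                "s4": ("P3", {"CASSF": 1}),
            }
        )
        sh = sharing_index(table)
        assert sh.level("CASSF") == 3 and sh.is_public("CASSF")
        assert sh.level("CAAAF") == 1 and not sh.is_public("CAAAF")

    def test_invariant_to_replicate_splitting(self):
        whole, _ = _cohort({"s1": ("P1", {"CASSF": 4}), "s2": ("P2", {"CASSF": 1})})
        split, _ = _cohort(
            {
                "s1a": ("P1", {"CASSF": 2}),
                "s1b": ("P1", {"CASSF": 2}),
                "s2": ("P2", {"CASSF": 1}),
            }
        )
        assert sharing_index(whole).level("CASSF") == sharing_index(split).level("CASSF")

    def test_recovers_planted_public_pool(self, small_cohort):
        table = build_cohort_table(small_cohort.repertoires)
        sh = sharing_index(table)
        recovered = sh.public_set()
        # brute-force recomputation from the repertoires themselves
        by_patient = {}
        for rep in small_cohort.repertoires:
            for s in rep.productive_frame()["cdr3_aa"]:
                by_patient.setdefault(s, set()).add(rep.patient_id)
        expected = {s for s, pats in by_patient.items() if len(pats) > 1}
        assert recovered == expected
        # private sequences are globally unique, so every public clone is a
        # planted pool member
        assert recovered <= set(small_cohort.truth.pool["cdr3_aa"])


class TestDegreeVsSharing:
    def test_planted_clusters_increase_degree_with_sharing(self):
        # patients share a tight LD=1 cluster; singletons are isolated
        cluster = ["CAAAAF", "CAAATF", "CAAAGF", "CAAACF"]  # star on CAAAAF? no: pairwise
        samples = {
            f"s{i}": (f"P{i}", {c: 1 for c in cluster} | {f"CWW{AA[i]}WWWF": 1})
            for i in range(4)
        }
        table, reps = _cohort(samples)
        sh = sharing_index(table)
        from tcrkit.network import build_repertoire_network

        nets = {r.sample_id: build_repertoire_network(r) for r in reps}
        out = degree_vs_sharing(nets, sh)
        out = out.sort_values("sharing_level")
        assert out["mean_degree"].is_monotonic_increasing
        assert out["sharing_level"].tolist() == [1, 4]

    def test_all_private_single_row(self):
        table, reps = _cohort({"s1": ("P1", {"CASSF": 1, "CASTF": 1})})
        sh = sharing_index(table)
        from tcrkit.network import build_repertoire_network

        out = degree_vs_sharing({r.sample_id: build_repertoire_network(r) for r in reps}, sh)
        assert out["sharing_level"].tolist() == [1]

    def test_empty_networks_empty_table(self):
        table, _ = _cohort({"s1": ("P1", {"CASSF": 1})})
        out = degree_vs_sharing({}, sharing_index(table))
        assert out.empty


class TestClassConnectivity:
    def test_planted_public_clusters_beat_random_private(self, small_cohort):
        table = build_cohort_table(small_cohort.repertoires)
        sh = sharing_index(table)
        rep = max(small_cohort.repertoires, key=lambda r: r.n_clonotypes)
        cc = class_connectivity(rep, sh, n_sub=1000, seed=3)
        assert cc.public_fraction is not None and cc.private_fraction is not None
        # desk-scale fixture: the planted clusters still dominate clearly;
        # the full-scale contrast is checked on the default cohort
        assert cc.public_fraction > 3 * cc.private_fraction
        assert cc.public_fraction > 0

    def test_small_class_uses_all_and_flags(self):
        table, reps = _cohort(
            {
                "s1": ("P1", {"CASSF": 1, "CASTF": 1, "CAAAF": 1}),
                "s2": ("P2", {"CASSF": 1}),
            }
        )
        sh = sharing_index(table)
        cc = class_connectivity(reps[0], sh, n_sub=1000, seed=0)
        assert not cc.public_subsampled and not cc.private_subsampled
        assert cc.n_public == 1 and cc.n_private == 2

    def test_empty_class_reported_missing(self):
        table, reps = _cohort({"s1": ("P1", {"CASSF": 1})})
        sh = sharing_index(table)
        cc = class_connectivity(reps[0], sh, seed=0)
        # the only clone is private, so the public class is empty
        assert cc.public_fraction is None
        assert cc.private_fraction is not None

    def test_deterministic_under_seed(self, small_cohort):
        table = build_cohort_table(small_cohort.repertoires)
        sh = sharing_index(table)
        rep = small_cohort.repertoires[0]
        a = class_connectivity(rep, sh, n_sub=50, seed=42)
        b = class_connectivity(rep, sh, n_sub=50, seed=42)
        assert a == b


class TestPathologyMatch:
    def _toy(self):
        counts = {f"CAS{c}F": n for c, n in zip("ABCDEGHIKL", range(10, 0, -1))}
        rep = Repertoire(
            sample_id="s1",
            clonotypes=collapse_clonotypes(list(counts.items())),
            patient_id="P1",
        )
        table = build_cohort_table([rep])
        sh = sharing_index(table)
        net = build_ld1_network(list(counts))
        return rep, net, sh

    def test_single_db_hit_in_expanded_set(self):
        rep, net, sh = self._toy()
        db = pd.DataFrame({"cdr3_aa": ["CASAF"], "pathology": ["Influenza"]})
        pm = pathology_match(rep, net, sh, db)
        assert pm.n_expanded == 1  # top 10% of 10 clones
        assert pm.expanded_fraction == 1.0
        assert pm.pathology_counts["Influenza"] == 1

    def test_no_overlap_gives_zero(self):
        rep, net, sh = self._toy()
        db = pd.DataFrame({"cdr3_aa": ["CWWWWF"], "pathology": ["CMV"]})
        pm = pathology_match(rep, net, sh, db)
        assert pm.expanded_fraction == 0.0
        assert pm.connected_public_fraction == 0.0

    def test_full_overlap_gives_one(self):
        rep, net, sh = self._toy()
        db = pd.DataFrame(
            {"cdr3_aa": rep.clonotypes["cdr3_aa"], "pathology": "Colorectal cancer"}
        )
        pm = pathology_match(rep, net, sh, db)
        assert pm.expanded_fraction == 1.0
        assert pm.connected_public_fraction == 1.0

    def test_db_reader_filters_and_validates(self, tmp_path):
        path = tmp_path / "db.csv"
        pd.DataFrame(
            {
                "CDR3.beta.aa": ["CASSF", "casxf*", "CATTF"],
                "Species": ["Human", "Human", "Mouse"],
                "Pathology": ["Influenza", "EBV", "CMV"],
            }
        ).to_csv(path, index=False)
        db = read_pathology_db(path)
        assert db["cdr3_aa"].tolist() == ["CASSF"]
        pd.DataFrame({"Species": ["Human"]}).to_csv(path, index=False)
        with pytest.raises(PathologyDBError):
            read_pathology_db(path)
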