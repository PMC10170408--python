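"""CDR3 sequence-convergence networks at Levenshtein distance 1.

Nodes are the unique CDR3-beta amino-acid sequences of one repertoire; an
edge joins two sequences whose Levenshtein (unit-cost edit) distance is
exactly 1.  The network connectivity fraction (edges / nodes) measures how
much sequence convergence a repertoire carries.  Cohort-level analyses
classify clones as public (detected in more than one patient) or private and
compare the connectivity of the two classes on equally sized random
subsamples, and annotate highly connected/shared or highly expanded clones
against a pathology-associated TCR database by exact sequence match.

Edge finding uses length-bucketed masked-position hashing for substitutions
and deletion-variant hashing for single indels; both constructions guarantee
distance exactly 1, and the result is tested against an all-pairs
dynamic-programming oracle.
"""
from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CohortTable, Repertoire
from .stats import mean_ci


class NetworkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# edit distance
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance by the two-row dynamic-programming recurrence."""
    if not a or not b:
        raise NetworkError("sequences must be nonempty")
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        append = cur.append
        for j, cb in enumerate(b, 1):
            append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def ld1_edges_bruteforce(sequences: Sequence[str]) -> set[tuple[str, str]]:
    """All-pairs LD=1 oracle: full DP distance on every candidate pair.

    Pairs whose lengths differ by more than 1 are skipped, which is exact
    because LD >= |len(a) - len(b)|.  Quadratic; for tests and small inputs.
    """
    seqs = sorted(set(sequences))
    edges = set()
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            if abs(len(a) - len(b)) <= 1 and levenshtein(a, b) == 1:
                edges.add((a, b))
    return edges


def ld1_edges(sequences: Sequence[str]) -> set[tuple[str, str]]:
    """LD=1 edge set via hashing, equivalent to the all-pairs DP oracle.

    Substitutions: two equal-length sequences are at LD 1 iff they agree
    everywhere except one position, i.e. they share a (length, position,
    masked-sequence) key.  Single indels: a length-L sequence and a
    length-(L-1) sequence are at LD 1 iff the shorter equals one of the
    longer's deletion variants.  Edges are returned as lexicographically
    ordered pairs.
    """
    seqs = sorted(set(sequences))
    edges: set[tuple[str, str]] = set()

    sub_buckets: defaultdict[tuple[int, int, str], list[str]] = defaultdict(list)
    for s in seqs:
        L = len(s)
        for i in range(L):
            sub_buckets[(L, i, s[:i] + s[i + 1:])].append(s)
    for bucket in sub_buckets.values():
        if len(bucket) > 1:
            for i, a in enumerate(bucket):
                for b in bucket[i + 1:]:
                    edges.add((a, b) if a < b else (b, a))

    seq_set = set(seqs)
    for s in seqs:
        for i in range(len(s)):
            d = s[:i] + s[i + 1:]
            if d and d in seq_set:
                edges.add((d, s) if d < s else (s, d))
    return edges


@dataclass
class SimilarityNetwork:
    """LD=1 graph over the unique CDR3 sequences of one repertoire."""

    nodes: list[str]
    edges: set[tuple[str, str]]
    sample_id: str | None = None
    _degree: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        deg = dict.fromkeys(self.nodes, 0)
        for a, b in self.edges:
            if a == b:
                raise NetworkError(f"self-loop on {a!r}")
            deg[a] += 1
            deg[b] += 1
        self._degree = deg

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def connectivity_fraction(self) -> float:
        """Edges per node; 0 for an empty or edgeless network."""
        return self.n_edges / self.n_nodes if self.n_nodes else 0.0

    @property
    def degree(self) -> dict[str, int]:
        return self._degree

    def degree_array(self) -> np.ndarray:
        return np.array([self._degree[s] for s in self.nodes], dtype=np.int64)

    def to_networkx(self, node_attrs: Mapping[str, Mapping[str, object]] | None = None):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if node_attrs:
            for key, values in node_attrs.items():
                nx.set_node_attributes(g, dict(values), key)
        return g

    def write_edgelist(self, path: str | Path) -> None:
        """Edge-list TSV (source, target) for external visualization."""
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")

    def write_graphml(
        self, path: str | Path, node_attrs: Mapping[str, Mapping[str, object]] | None = None
    ) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(node_attrs), str(path))


def build_ld1_network(
    sequences: Iterable[str], sample_id: str | None = None
) -> SimilarityNetwork:
    """Build the LD=1 convergence network over deduplicated sequences."""
    nodes = sorted(set(sequences))
    return SimilarityNetwork(nodes=nodes, edges=ld1_edges(nodes), sample_id=sample_id)


def build_repertoire_network(repertoire: Repertoire) -> SimilarityNetwork:
    """Network over a repertoire's productive clonotype sequences."""
    return build_ld1_network(
        repertoire.productive_frame()["cdr3_aa"], sample_id=repertoire.sample_id
    )


# ---------------------------------------------------------------------------
# public/private sharing
# ---------------------------------------------------------------------------

@dataclass
class SharingIndex:
    """Cohort-wide clone -> number-of-patients mapping.

    A clone detected in several samples of one patient (replicate aliquots,
    second lesions) still has sharing level 1; public means detected in at
    least two distinct patients.
    """

    clones: np.ndarray
    sharing_level: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.sharing_level < 1):
            raise NetworkError("sharing_level must be >= 1 for detected clones")
        self._index = {c: i for i, c in enumerate(self.clones)}

    @property
    def public(self) -> np.ndarray:
        return self.sharing_level > 1

    def level(self, clone: str) -> int:
        return int(self.sharing_level[self._index[clone]])

    def is_public(self, clone: str) -> bool:
        return self.level(clone) > 1

    def public_set(self) -> set[str]:
        return set(self.clones[self.public])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cdr3_aa": self.clones, "sharing_level": self.sharing_level, "public": self.public}
        )


def sharing_index(cohort: CohortTable) -> SharingIndex:
    """Patient-level sharing of every clone in the cohort table."""
    patients = cohort.manifest.loc[cohort.sample_ids, "patient_id"].to_numpy()
    codes, _ = pd.factorize(patients)
    n_pat = codes.max() + 1
    # clones x patients detection indicator via sparse product
    import scipy.sparse as sp

    incidence = (cohort.counts > 0).astype(np.int8)
    assign = sp.csr_matrix(
        (np.ones(len(codes), dtype=np.int8), (np.arange(len(codes)), codes)),
        shape=(len(codes), n_pat),
    )
    per_patient = incidence @ assign
    level = np.asarray((per_patient > 0).sum(axis=1)).ravel().astype(np.int64)
    return SharingIndex(clones=cohort.clones, sharing_level=level)


def degree_vs_sharing(
    networks: Mapping[str, SimilarityNetwork], sharing: SharingIndex
) -> pd.DataFrame:
    """Mean node degree (with 95% CI) by cohort sharing level.

    Each clone contributes the degree it has in its home repertoire's
    network, once per repertoire in which it appears.
    """
    levels: list[int] = []
    degrees: list[int] = []
    for net in networks.values():
        for seq in net.nodes:
            levels.append(sharing.level(seq))
            degrees.append(net.degree[seq])
    if not levels:
        return pd.DataFrame(columns=["sharing_level", "mean_degree", "ci_low", "ci_high", "n"])
    df = pd.DataFrame({"sharing_level": levels, "degree": degrees})
    rows = []
    for lvl, grp in df.groupby("sharing_level"):
        vals = grp["degree"].to_numpy(dtype=float)
        if len(vals) >= 2 and vals.std() > 0:
            m, lo, hi = mean_ci(vals)
        else:
            m = float(vals.mean())
            lo = hi = m
        rows.append({"sharing_level": int(lvl), "mean_degree": m, "ci_low": lo, "ci_high": hi, "n": len(vals)})
    return pd.DataFrame(rows)


def _sample_seed(master_seed: int, sample_id: str) -> int:
    """Stable per-sample seed below 2**31 derived from a master seed."""
    digest = hashlib.sha256(f"{master_seed}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ClassConnectivity:
    """Connectivity fractions of the subsampled public/private networks.

    A fraction is None when the repertoire has no clones of that class;
    ``*_subsampled`` flags whether the class exceeded ``n_sub`` and was
    actually downsampled.
    """

    sample_id: str | None
    public_fraction: float | None
    private_fraction: float | None
    n_public: int
    n_private: int
    public_subsampled: bool
    private_subsampled: bool


def class_connectivity(
    repertoire: Repertoire,
    sharing: SharingIndex,
    n_sub: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ClassConnectivity:
    """Public vs private connectivity on equal-size random subsamples.

    Clones of the repertoire are split by cohort public/private status; each
    class is subsampled to ``n_sub`` clones uniformly without replacement
    (the whole class when smaller, flagged), an LD=1 network is built within
    the class sample, and edges/nodes is returned per class.
    """
    rng = np.random.default_rng(seed)
    seqs = repertoire.productive_frame()["cdr3_aa"].to_numpy()
    is_pub = np.array([sharing.is_public(s) for s in seqs])
    results: dict[str, tuple[float | None, int, bool]] = {}
    for label, mask in (("public", is_pub), ("private", ~is_pub)):
        members = np.sort(seqs[mask])
        if members.size == 0:
            results[label] = (None, 0, False)
            continue
        subsampled = members.size > n_sub
        chosen = rng.choice(members, size=n_sub, replace=False) if subsampled else members
        net = build_ld1_network(chosen)
        results[label] = (net.connectivity_fraction, int(members.size), subsampled)
    return ClassConnectivity(
        sample_id=repertoire.sample_id,
        public_fraction=results["public"][0],
        private_fraction=results["private"][0],
        n_public=results["public"][1],
        n_private=results["private"][1],
        public_subsampled=results["public"][2],
        private_subsampled=results["private"][2],
    )


def cohort_class_connectivity(
    repertoires: Sequence[Repertoire],
    sharing: SharingIndex,
    n_sub: int = 1000,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Per-sample public/private subsampled connectivity table.

    Each sample's subsampling RNG is seeded from the master seed and the
    sample id, so results are reproducible and independent of run order.
    """
    rows = []
    for rep in repertoires:
        cc = class_connectivity(
            rep, sharing, n_sub=n_sub, seed=_sample_seed(master_seed, rep.sample_id)
        )
        rows.append(cc.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pathology-database matching
# ---------------------------------------------------------------------------

PATHOLOGY_DB_COLUMNS = {"cdr3": ("CDR3.beta.aa", "cdr3_beta_aa", "cdr3_aa", "CDR3"),
                        "species": ("Species", "species"),
                        "pathology": ("Pathology", "pathology", "Category")}


class PathologyDBError(ValueError):
    pass


def read_pathology_db(path: str | Path, human_only: bool = True) -> pd.DataFrame:
    """Read a pathology-associated TCR CSV (McPAS-like layout).

    Keeps rows with a valid CDR3-beta amino-acid sequence; optionally
    restricted to human entries.  Returns columns cdr3_aa, pathology.
    """
    raw = pd.read_csv(path, dtype=str)
    resolved = {}
    for canonical, candidates in PATHOLOGY_DB_COLUMNS.items():
        for cand in candidates:
            if cand in raw.columns:
                resolved[canonical] = cand
                break
    if "cdr3" not in resolved or "pathology" not in resolved:
        raise PathologyDBError(
            f"pathology database must provide CDR3 and pathology columns; found {list(raw.columns)}"
        )
    df = pd.DataFrame(
        {
            "cdr3_aa": raw[resolved["cdr3"]].astype(str).str.strip().str.upper(),
            "pathology": raw[resolved["pathology"]].astype(str).str.strip(),
        }
    )
    if human_only and "species" in resolved:
        df = df[raw[resolved["species"]].astype(str).str.contains("human", case=False, na=False)]
    from .io import AA_ALPHABET

    df = df[df["cdr3_aa"].map(lambda s: bool(s) and set(s) <= AA_ALPHABET)]
    df = df.drop_duplicates()
    if df.empty:
        raise PathologyDBError("pathology database empty after filtering")
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class PathologyMatch:
    sample_id: str | None
    connected_public_fraction: float
    expanded_fraction: float
    n_connected_public: int
    n_expanded: int
    pathology_counts: pd.Series


def _top_decile(df: pd.DataFrame, by: str, top_frac: float) -> set[str]:
    """Top ``top_frac`` of clones ranked by ``by`` descending, ties broken by
    lexicographic sequence order."""
    k = max(1, int(np.ceil(top_frac * len(df))))
    ranked = df.sort_values([by, "cdr3_aa"], ascending=[False, True], kind="stable")
    return set(ranked["cdr3_aa"].head(k))


def pathology_match(
    repertoire: Repertoire,
    network: SimilarityNetwork,
    sharing: SharingIndex,
    db: pd.DataFrame,
    top_frac: float = 0.10,
) -> PathologyMatch:
    """Fraction of top clones matching known pathology-associated TCRs.

    Set A unions the top decile by network degree and the top decile by
    sharing level ("highest connectivity and/or sharing level"); set B is
    the top decile by template count (most expanded).  A match is exact
    sequence identity (LD = 0) against the database.
    """
    if db.empty:
        raise PathologyDBError("empty pathology database")
    df = repertoire.productive_frame()[["cdr3_aa", "templates"]].copy()
    df["degree"] = df["cdr3_aa"].map(network.degree).fillna(0).astype(int)
    df["sharing_level"] = df["cdr3_aa"].map(lambda s: sharing.level(s))
    set_a = _top_decile(df, "degree", top_frac) | _top_decile(df, "sharing_level", top_frac)
    set_b = _top_decile(df, "templates", top_frac)
    db_seqs = set(db["cdr3_aa"])
    hits_a = set_a & db_seqs
    hits_b = set_b & db_seqs
    tallies = (
        db[db["cdr3_aa"].isin(hits_a | hits_b)]
        .groupby("pathology")["cdr3_aa"]
        .nunique()
        .sort_values(ascending=False)
    )
    return PathologyMatch(
        sample_id=repertoire.sample_id,
        connected_public_fraction=len(hits_a) / len(set_a),
        expanded_fraction=len(hits_b) / len(set_b),
        n_connected_public=len(set_a),
        n_expanded=len(set_b),
        pathology_counts=tallies,
    )
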