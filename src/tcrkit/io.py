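"""Reading, validating and combining immunoSEQ-style rearrangement files.

One rearrangement file holds one sample's TCR-beta repertoire, one row per
detected rearrangement.  Rearrangements with identical CDR3 amino-acid
sequence are collapsed into a single clonotype; the rearranged-template count
is the abundance unit (one template is the proxy for one T cell).  A cohort
is a set of such files plus a manifest CSV linking each sample to its
patient, lesion, aliquot, treatment group and input DNA mass.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

GROUPS = ("no_nact", "short_interval", "long_interval")

#: canonical column -> accepted header names, in priority order.  Mirrors the
#: immunoSEQ v2 rearrangement export; callers may override any entry with a
#: ``dialect`` mapping of canonical name -> actual header.
DEFAULT_DIALECT_CANDIDATES: dict[str, tuple[str, ...]] = {
    "cdr3_aa": ("amino_acid", "aminoAcid", "cdr3_amino_acid", "cdr3aa"),
    "templates": ("templates", "count (templates/reads)", "count", "template_count"),
    "reads": ("seq_reads", "reads", "read_count"),
    "frame": ("frame_type", "frame", "sequenceStatus"),
    "v_gene": ("v_resolved", "vGeneName", "v_gene"),
    "j_gene": ("j_resolved", "jGeneName", "j_gene"),
}

REQUIRED_COLUMNS = ("cdr3_aa", "templates", "frame")


class RepertoireIOError(Exception):
    """Base error for rearrangement-file handling."""


class MissingColumnError(RepertoireIOError):
    """A required column could not be resolved in the file header."""


class EmptyRepertoireError(RepertoireIOError):
    """No (productive) rows survived filtering."""


class ValidationError(RepertoireIOError):
    """A row failed validation; the message carries the row number."""


@dataclass(frozen=True, slots=True)
class ClonotypeRecord:
    """One collapsed CDR3-beta clonotype.

    ``templates`` counts rearranged DNA templates (>=1, proxy for T cells);
    ``reads`` counts supporting sequencing reads (>=0; may legitimately be
    below ``templates`` in some export dialects).
    """

    cdr3_aa: str
    templates: int
    reads: int = 0
    productive: bool = True
    v_gene: str | None = None
    j_gene: str | None = None

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValidationError("cdr3_aa must be nonempty")
        if self.templates < 1:
            raise ValidationError(f"templates must be >= 1, got {self.templates}")
        if self.reads < 0:
            raise ValidationError(f"reads must be >= 0, got {self.reads}")


_CLONOTYPE_COLUMNS = ["cdr3_aa", "templates", "reads", "productive", "v_gene", "j_gene"]


@dataclass
class Repertoire:
    """One sample's collapsed clonotype table plus identifiers.

    ``clonotypes`` is a DataFrame with columns cdr3_aa, templates, reads,
    productive, v_gene, j_gene; cdr3_aa values are unique.  Nonproductive
    clonotypes are retained in storage but excluded from analyses through
    :meth:`productive_frame`.
    """

    sample_id: str
    clonotypes: pd.DataFrame
    patient_id: str | None = None
    lesion_id: str | None = None
    aliquot_id: str | None = None
    group: str | None = None
    input_dna_ng: float | None = None

    def __post_init__(self) -> None:
        df = self.clonotypes
        missing = [c for c in _CLONOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"clonotype table missing columns {missing}")
        if df["cdr3_aa"].duplicated().any():
            dup = df.loc[df["cdr3_aa"].duplicated(), "cdr3_aa"].iloc[0]
            raise ValidationError(f"duplicate clonotype after collapsing: {dup!r}")
        if self.group is not None and self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")

    # -- abundance totals ---------------------------------------------------
    def productive_frame(self) -> pd.DataFrame:
        return self.clonotypes[self.clonotypes["productive"]]

    @property
    def total_templates(self) -> int:
        return int(self.productive_frame()["templates"].sum())

    @property
    def total_reads(self) -> int:
        return int(self.productive_frame()["reads"].sum())

    @property
    def n_clonotypes(self) -> int:
        return int(self.productive_frame().shape[0])

    @property
    def records(self) -> tuple[ClonotypeRecord, ...]:
        return tuple(self.iter_records())

    def iter_records(self) -> Iterator[ClonotypeRecord]:
        for row in self.clonotypes.itertuples(index=False):
            yield ClonotypeRecord(
                cdr3_aa=row.cdr3_aa,
                templates=int(row.templates),
                reads=int(row.reads),
                productive=bool(row.productive),
                v_gene=row.v_gene if isinstance(row.v_gene, str) else None,
                j_gene=row.j_gene if isinstance(row.j_gene, str) else None,
            )

    def with_metadata(self, **kwargs) -> "Repertoire":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CohortTable:
    """Sparse clones x samples template-count matrix with sample metadata.

    Equivalent to a combined rearrangement table: one row per distinct
    productive CDR3 across the cohort, one column per sample, each cell the
    template count of that clonotype in that sample (zero when absent).
    """

    clones: np.ndarray            # distinct cdr3_aa, row axis
    sample_ids: list[str]         # column axis
    counts: sp.csr_matrix         # int64, shape (n_clones, n_samples)
    manifest: pd.DataFrame        # indexed by sample_id

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValidationError("duplicate sample_id in cohort")
        if self.counts.shape != (len(self.clones), len(self.sample_ids)):
            raise ValidationError("counts shape does not match clone/sample axes")

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column_totals(self) -> pd.Series:
        totals = np.asarray(self.counts.sum(axis=0)).ravel()
        return pd.Series(totals, index=self.sample_ids, name="total_templates")

    def sample_counts(self, sample_id: str) -> pd.Series:
        """Nonzero clone counts of one sample as a Series indexed by cdr3_aa."""
        j = self.sample_ids.index(sample_id)
        col = self.counts.getcol(j).tocoo()
        return pd.Series(col.data, index=self.clones[col.row], name=sample_id)

    def subset_samples(self, keep: Sequence[str]) -> "CohortTable":
        """Restrict to the given samples, dropping clones absent everywhere."""
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        sub = self.counts[:, idx].tocsr()
        present = np.asarray((sub != 0).sum(axis=1)).ravel() > 0
        return CohortTable(
            clones=self.clones[present],
            sample_ids=keep,
            counts=sub[present].tocsr(),
            manifest=self.manifest.loc[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        """Dense clones x samples DataFrame (small cohorts only)."""
        return pd.DataFrame(
            self.counts.toarray(), index=self.clones, columns=self.sample_ids
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "cdr3_aa"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def resolve_dialect(
    header: Sequence[str], dialect: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Map canonical column names onto the file's actual headers.

    ``dialect`` overrides win; otherwise the default candidate lists are
    searched in order.  Raises :class:`MissingColumnError` naming the first
    required canonical column that cannot be resolved.
    """
    resolved: dict[str, str] = {}
    header_set = set(header)
    for canonical, candidates in DEFAULT_DIALECT_CANDIDATES.items():
        if dialect and canonical in dialect:
            if dialect[canonical] in header_set:
                resolved[canonical] = dialect[canonical]
            elif canonical in REQUIRED_COLUMNS:
                raise MissingColumnError(
                    f"column {dialect[canonical]!r} (for {canonical!r}) not in header"
                )
            continue
        for cand in candidates:
            if cand in header_set:
                resolved[canonical] = cand
                break
        else:
            if canonical in REQUIRED_COLUMNS:
                raise MissingColumnError(
                    f"required column {canonical!r} not found in header; "
                    f"tried {candidates}"
                )
    return resolved


_PRODUCTIVE_FRAMES = {"in", "in-frame", "inframe", "productive"}


def _validate_rows(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Uppercase sequences, derive productivity, validate counts.

    Any character outside the 20-letter amino-acid alphabet (stop codons
    '*', frameshift 'X' etc.) marks the record nonproductive, as does an
    out-of-frame or stop frame annotation.
    """
    out = pd.DataFrame()
    out["cdr3_aa"] = df["cdr3_aa"].astype(str).str.strip().str.upper()
    templates = pd.to_numeric(df["templates"], errors="coerce")
    bad = templates.isna() | (templates <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: row {row + 1}: template count must be a positive integer, "
            f"got {df['templates'].iloc[row]!r}"
        )
    out["templates"] = templates.astype(np.int64)
    if "reads" in df.columns:
        reads = pd.to_numeric(df["reads"], errors="coerce").fillna(0)
        if (reads < 0).any():
            row = int(np.flatnonzero((reads < 0).to_numpy())[0])
            raise ValidationError(f"{path}: row {row + 1}: negative read count")
        out["reads"] = reads.astype(np.int64)
    else:
        out["reads"] = 0
    frame_ok = (
        df["frame"].astype(str).str.strip().str.lower().isin(_PRODUCTIVE_FRAMES)
    )
    seq_ok = out["cdr3_aa"].map(lambda s: bool(s) and set(s) <= AA_ALPHABET)
    out["productive"] = (frame_ok & seq_ok).to_numpy()
    empty = out["cdr3_aa"] == ""
    if empty.any():
        row = int(np.flatnonzero(empty.to_numpy())[0])
        raise ValidationError(f"{path}: row {row + 1}: empty CDR3 sequence")
    for col in ("v_gene", "j_gene"):
        out[col] = df[col].astype(str).replace({"nan": None, "": None}) if col in df.columns else None
    return out


def collapse_clonotypes(rows: pd.DataFrame | Iterable[tuple[str, int]]) -> pd.DataFrame:
    """Collapse raw rearrangement rows into one record per CDR3 sequence.

    Template and read counts are summed; V/J labels are taken from the row
    with the highest template count; a clonotype is productive only if every
    contributing row is.  Accepts either a validated row DataFrame or an
    iterable of ``(cdr3_aa, templates)`` pairs (convenience for tests).
    Collapsing is idempotent.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows), columns=["cdr3_aa", "templates"])
    df = rows.copy()
    for col, default in (("reads", 0), ("productive", True), ("v_gene", None), ("j_gene", None)):
        if col not in df.columns:
            df[col] = default
    # row with max templates within each clonotype donates the V/J labels
    df = df.sort_values(["cdr3_aa", "templates"], kind="stable", ascending=[True, False])
    agg = df.groupby("cdr3_aa", sort=True).agg(
        templates=("templates", "sum"),
        reads=("reads", "sum"),
        productive=("productive", "all"),
        v_gene=("v_gene", "first"),
        j_gene=("j_gene", "first"),
    )
    return agg.reset_index()[_CLONOTYPE_COLUMNS]


def read_rearrangement_file(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    productive_only: bool = True,
    sample_id: str | None = None,
) -> Repertoire:
    """Parse one tab-separated rearrangement file into a collapsed Repertoire.

    Parameters
    ----------
    path
        Tab-separated file, one row per rearrangement.
    dialect
        Optional canonical-name -> header overrides; unknown extra columns
        are ignored.
    productive_only
        Drop out-of-frame/stop rows before collapsing (the default, matching
        productive-template analyses).
    sample_id
        Defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise RepertoireIOError(f"no such file: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    colmap = resolve_dialect(raw.columns, dialect)
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    rows = _validate_rows(df, str(path))
    if productive_only:
        rows = rows[rows["productive"]]
    if rows.empty:
        raise EmptyRepertoireError(
            f"{path}: no {'productive ' if productive_only else ''}rearrangements"
        )
    return Repertoire(
        sample_id=sample_id or path.stem,
        clonotypes=collapse_clonotypes(rows).reset_index(drop=True),
    )


def write_rearrangement_file(repertoire: Repertoire, path: str | Path) -> None:
    """Write a Repertoire back to the default tab-separated dialect."""
    df = repertoire.clonotypes
    out = pd.DataFrame(
        {
            "amino_acid": df["cdr3_aa"],
            "templates": df["templates"],
            "seq_reads": df["reads"],
            "frame_type": np.where(df["productive"], "In", "Out"),
            "v_resolved": df["v_gene"].fillna(""),
            "j_resolved": df["j_gene"].fillna(""),
        }
    )
    out.to_csv(path, sep="\t", index=False)


MANIFEST_COLUMNS = ("sample_id", "patient_id", "lesion_id", "aliquot_id", "group", "input_dna_ng")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample manifest CSV, indexed by sample_id."""
    df = pd.read_csv(path, dtype={c: str for c in MANIFEST_COLUMNS if c != "input_dna_ng"})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"manifest missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in manifest")
    df["input_dna_ng"] = df["input_dna_ng"].astype(float)
    return df.set_index("sample_id", drop=False)


def load_cohort(
    manifest_path: str | Path,
    data_dir: str | Path,
    dialect: Mapping[str, str] | None = None,
    productive_only: bool = True,
) -> list[Repertoire]:
    """Read every sample listed in the manifest from ``data_dir``.

    Each sample's rearrangement file is expected at ``<data_dir>/<sample_id>.tsv``.
    """
    manifest = read_manifest(manifest_path)
    data_dir = Path(data_dir)
    reps = []
    for sid, meta in manifest.iterrows():
        rep = read_rearrangement_file(
            data_dir / f"{sid}.tsv", dialect=dialect, productive_only=productive_only
        )
        reps.append(
            rep.with_metadata(
                sample_id=sid,
                patient_id=meta["patient_id"],
                lesion_id=meta["lesion_id"],
                aliquot_id=meta["aliquot_id"],
                group=meta["group"],
                input_dna_ng=float(meta["input_dna_ng"]),
            )
        )
    return reps


def build_cohort_table(repertoires: Sequence[Repertoire]) -> CohortTable:
    """Combine per-sample repertoires into the sparse clones x samples table.

    Only productive clonotypes enter the table.  Column sums equal each
    repertoire's total productive templates; every nonzero cell traces to
    exactly one collapsed clonotype.
    """
    sample_ids = [r.sample_id for r in repertoires]
    if len(sample_ids) != len(set(sample_ids)):
        raise ValidationError("duplicate sample_id among repertoires")
    seqs: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for j, rep in enumerate(repertoires):
        df = rep.productive_frame()
        seqs.append(df["cdr3_aa"].to_numpy())
        counts.append(df["templates"].to_numpy(dtype=np.int64))
        cols.append(np.full(len(df), j, dtype=np.int64))
    all_seqs = np.concatenate(seqs) if seqs else np.array([], dtype=object)
    codes, clones = pd.factorize(all_seqs, sort=True)
    mat = sp.coo_matrix(
        (np.concatenate(counts) if counts else np.array([], dtype=np.int64),
         (codes, np.concatenate(cols) if cols else np.array([], dtype=np.int64))),
        shape=(len(clones), len(sample_ids)),
        dtype=np.int64,
    ).tocsr()
    manifest = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": [r.patient_id for r in repertoires],
            "lesion_id": [r.lesion_id for r in repertoires],
            "aliquot_id": [r.aliquot_id for r in repertoires],
            "group": [r.group for r in repertoires],
            "input_dna_ng": [r.input_dna_ng for r in repertoires],
            "total_templates": [r.total_templates for r in repertoires],
            "total_reads": [r.total_reads for r in repertoires],
        }
    ).set_index("sample_id", drop=False)
    return CohortTable(clones=np.asarray(clones), sample_ids=sample_ids, counts=mat, manifest=manifest)
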