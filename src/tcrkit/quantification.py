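"""Per-sample T-cell fraction, sequencing coverage, and the cohort QC filter.

The T-cell fraction of a bulk-tissue sample is the number of rearranged
TCR-beta DNA templates (one template ~ one T cell) divided by the number of
cell genomes put into the assay, where genomes = input DNA mass / 6.6 pg
(mean diploid DNA content per cell).  Sequencing coverage is reads per
template; shallow samples (coverage below 5 by default) are excluded from
clonality and network analyses because their low-frequency clones are
unreliable.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortTable

#: mean DNA content of a diploid human cell, picograms
PG_DNA_PER_GENOME = 6.6
PG_PER_NG = 1000.0

DEFAULT_MIN_COVERAGE = 5.0


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class SampleQuantification:
    sample_id: str
    genomes: float
    t_cell_fraction: float
    coverage: float
    included: bool


def genomes_from_dna(input_dna_ng: float) -> float:
    """Cell-equivalents in the assay input: mass[pg] / 6.6 pg per genome."""
    if input_dna_ng <= 0:
        raise QuantificationError(f"input_dna_ng must be > 0, got {input_dna_ng}")
    return input_dna_ng * PG_PER_NG / PG_DNA_PER_GENOME


def t_cell_fraction(total_templates: int, input_dna_ng: float) -> float:
    """Fraction of input genomes carrying a rearranged TCR-beta template.

    Values above 1 are physically implausible (more templates than genomes)
    and trigger a warning, not an error — they can arise from DNA
    quantification noise in heavily infiltrated samples.
    """
    if total_templates < 0:
        raise QuantificationError("total_templates must be >= 0")
    frac = total_templates / genomes_from_dna(input_dna_ng)
    if frac > 1:
        warnings.warn(
            f"T-cell fraction {frac:.3g} exceeds 1; check input DNA mass",
            stacklevel=2,
        )
    return frac


def sequencing_coverage(total_reads: int, total_templates: int) -> float:
    """Reads per detected template."""
    if total_templates <= 0:
        raise QuantificationError(
            "coverage undefined: sample has no templates"
        )
    return total_reads / total_templates


def quantify_cohort(
    cohort: CohortTable, min_coverage: float = DEFAULT_MIN_COVERAGE
) -> pd.DataFrame:
    """Per-sample quantification table from the cohort manifest.

    Columns: genomes, t_cell_fraction, coverage, included (coverage >=
    ``min_coverage``).  Requires manifest columns input_dna_ng,
    total_templates, total_reads.
    """
    man = cohort.manifest
    rows = []
    for sid, meta in man.iterrows():
        genomes = genomes_from_dna(float(meta["input_dna_ng"]))
        frac = t_cell_fraction(int(meta["total_templates"]), float(meta["input_dna_ng"]))
        cov = sequencing_coverage(int(meta["total_reads"]), int(meta["total_templates"]))
        rows.append(
            SampleQuantification(
                sample_id=sid,
                genomes=genomes,
                t_cell_fraction=frac,
                coverage=cov,
                included=bool(cov >= min_coverage),
            )
        )
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows]).set_index("sample_id", drop=False)
    return df


def qc_filter(
    cohort: CohortTable,
    quantifications: pd.DataFrame,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[CohortTable, pd.DataFrame]:
    """Drop samples whose coverage is below ``min_coverage``.

    Returns the retained cohort (counts of retained samples untouched) and an
    exclusion report listing each dropped sample with its coverage.  An empty
    retained cohort is legal.
    """
    cov = quantifications["coverage"]
    excluded = quantifications.loc[cov < min_coverage, ["sample_id", "coverage"]].copy()
    excluded["reason"] = f"coverage < {min_coverage}"
    keep = [s for s in cohort.sample_ids if s not in set(excluded["sample_id"])]
    if not keep:
        empty = CohortTable(
            clones=np.array([], dtype=object),
            sample_ids=[],
            counts=cohort.counts[:0, :0].tocsr(),
            manifest=cohort.manifest.iloc[0:0],
        )
        return empty, excluded.reset_index(drop=True)
    return cohort.subset_samples(keep), excluded.reset_index(drop=True)


def select_one_per_patient(quantifications: pd.DataFrame, manifest: pd.DataFrame) -> list[str]:
    """One dataset per patient for the fraction analysis: highest coverage wins.

    Deterministic tie-break on sample_id.
    """
    merged = quantifications.join(manifest["patient_id"], how="inner").reset_index(drop=True)
    merged = merged.sort_values(["coverage", "sample_id"], ascending=[False, True], kind="stable")
    return merged.drop_duplicates("patient_id")["sample_id"].sort_values().tolist()
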