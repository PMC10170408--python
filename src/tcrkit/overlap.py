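"""Morisita-Horn overlap between repertoires.

For clone count vectors x, y aligned on the union clone axis,

    MHI(x, y) = 2 sum_i x_i y_i
                / [ (sum x_i^2 / X^2 + sum y_i^2 / Y^2) * X * Y ],

with X = sum x_i, Y = sum y_i.  The index is abundance-weighted, invariant
to proportional rescaling of either vector, 1 exactly when the frequency
vectors are proportional and 0 exactly when the supports are disjoint.

Cohort-wide, every unordered sample pair is computed and labelled by its
comparison class — technical replicates of one lesion, different lesions of
one patient, or different patients — which is how technical reproducibility,
within-liver heterogeneity and background between-patient overlap are read
off the same matrix.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortTable


class OverlapError(ValueError):
    pass


COMPARISON_CLASSES = (
    "between_patient",
    "within_patient_between_lesion",
    "within_lesion_replicate",
)


def morisita_horn(x, y) -> float:
    """MHI of two aligned count vectors."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise OverlapError("count vectors must share the clone axis")
    X, Y = xv.sum(), yv.sum()
    if X <= 0 or Y <= 0:
        raise OverlapError("zero-total count vector")
    num = 2.0 * float(xv @ yv)
    if num == 0.0:
        return 0.0
    denom = (float(xv @ xv) / X**2 + float(yv @ yv) / Y**2) * X * Y
    return float(num / denom)


@dataclass
class OverlapMatrix:
    """Symmetric pairwise MHI matrix with per-pair comparison classes."""

    mhi: pd.DataFrame           # square, indexed by sample_id
    pairs: pd.DataFrame         # long format: sample_a, sample_b, mhi, comparison_class

    def class_summary(self) -> pd.DataFrame:
        """Mean and min-max MHI per comparison class."""
        return (
            self.pairs.groupby("comparison_class")["mhi"]
            .agg(["mean", "min", "max", "count"])
            .reindex([c for c in COMPARISON_CLASSES if c in set(self.pairs["comparison_class"])])
            .reset_index()
        )


def _comparison_class(meta_a: pd.Series, meta_b: pd.Series) -> str:
    if meta_a["patient_id"] != meta_b["patient_id"]:
        return "between_patient"
    if meta_a["lesion_id"] != meta_b["lesion_id"]:
        return "within_patient_between_lesion"
    return "within_lesion_replicate"


def pairwise_mhi(cohort: CohortTable) -> OverlapMatrix:
    """All unordered pairwise MHI values over the cohort table.

    Vectorised through the sparse cross-product of the counts matrix; the
    diagonal is exactly 1.
    """
    if cohort.n_samples < 2:
        raise OverlapError("need at least 2 samples")
    counts = cohort.counts.astype(np.float64).tocsc()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        bad = cohort.sample_ids[int(np.argmax(totals <= 0))]
        raise OverlapError(f"sample {bad!r} has zero templates")
    cross = np.asarray((counts.T @ counts).todense())
    sumsq = cross.diagonal()
    simpson = sumsq / totals**2                      # per-sample sum p_i^2
    denom = (simpson[:, None] + simpson[None, :]) * np.outer(totals, totals)
    mhi = 2.0 * cross / denom
    np.fill_diagonal(mhi, 1.0)
    mhi_df = pd.DataFrame(mhi, index=cohort.sample_ids, columns=cohort.sample_ids)

    man = cohort.manifest
    rows = []
    ids = cohort.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append(
                {
                    "sample_a": ids[i],
                    "sample_b": ids[j],
                    "mhi": float(mhi[i, j]),
                    "comparison_class": _comparison_class(man.loc[ids[i]], man.loc[ids[j]]),
                }
            )
    return OverlapMatrix(mhi=mhi_df, pairs=pd.DataFrame(rows))
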