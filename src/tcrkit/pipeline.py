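"""End-to-end cohort analysis: quantification, diversity, networks, overlap.

``run_all`` wires the stages together over a list of repertoires (read from
disk or freshly simulated), applies the coverage-based QC exclusion, and
writes a report bundle of CSV tables plus a machine-readable JSON summary.
Every stage is a pure function of (inputs, config, seed); rerunning with the
same configuration reproduces the same tables.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import diversity, network, overlap, quantification, stats
from .io import CohortTable, Repertoire, build_cohort_table, load_cohort
from .powerlaw import (
    DegenerateDistributionError,
    InsufficientDataError,
    powerlaw_gof,
)

log = logging.getLogger("tcrkit")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and sample."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run (serialised next to outputs)."""

    output_dir: str | Path = "tcrkit_out"
    input_dir: str | Path | None = None          # directory with manifest.csv + rearrangements/
    simulate: bool = False                       # generate the default synthetic cohort instead
    pathology_db: str | Path | None = None
    min_coverage: float = quantification.DEFAULT_MIN_COVERAGE
    q_step: float = 0.2
    q_max: float = 10.0
    n_sub: int = 1000
    n_boot: int = 1000
    top_frac: float = 0.10
    min_degree_sample: int = 50
    seed: int = 0

    def q_grid(self) -> np.ndarray:
        return np.round(np.arange(0.0, self.q_max + 1e-9, self.q_step), 10)


@dataclass
class RunResult:
    quantifications: pd.DataFrame
    exclusions: pd.DataFrame
    diversity_summary: pd.DataFrame
    network_summary: pd.DataFrame
    degree_vs_sharing: pd.DataFrame
    class_connectivity: pd.DataFrame
    overlap_summary: pd.DataFrame
    group_comparisons: pd.DataFrame
    regressions: pd.DataFrame
    pathology: pd.DataFrame | None
    sharing: network.SharingIndex
    summary: dict = field(default_factory=dict)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def analyze_cohort(
    repertoires: Sequence[Repertoire], config: RunConfig
) -> RunResult:
    """Run every analysis stage in memory and return the result tables."""
    qgrid = config.q_grid()
    cohort = _stage("cohort_table", build_cohort_table, repertoires)
    quant = _stage("quantification", quantification.quantify_cohort, cohort, config.min_coverage)
    retained_cohort, exclusions = _stage(
        "qc_filter", quantification.qc_filter, cohort, quant, config.min_coverage
    )
    for row in exclusions.itertuples(index=False):
        log.info("excluded %s (coverage %.2f)", row.sample_id, row.coverage)
    retained_ids = set(retained_cohort.sample_ids)
    retained_reps = [r for r in repertoires if r.sample_id in retained_ids]

    # --- diversity ---------------------------------------------------------
    div_rows = []
    for rep in retained_reps:
        prof = _stage(
            f"diversity[{rep.sample_id}]",
            diversity.diversity_profile,
            rep.productive_frame()["templates"].to_numpy(),
            qgrid,
        )
        div_rows.append(
            {
                "sample_id": rep.sample_id,
                "group": rep.group,
                "SR": prof.SR,
                "clonality": prof.clonality,
                "total_templates": rep.total_templates,
            }
        )
    div = pd.DataFrame(div_rows)

    # --- sharing + per-sample networks ------------------------------------
    sharing = _stage("sharing_index", network.sharing_index, retained_cohort)
    networks: dict[str, network.SimilarityNetwork] = {}
    net_rows = []
    for rep in retained_reps:
        net = _stage(f"network[{rep.sample_id}]", network.build_repertoire_network, rep)
        networks[rep.sample_id] = net
        degrees = net.degree_array()
        row = {
            "sample_id": rep.sample_id,
            "group": rep.group,
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "connectivity_fraction": net.connectivity_fraction,
            "powerlaw_alpha": np.nan,
            "powerlaw_xmin": np.nan,
            "powerlaw_gof_p": np.nan,
            "powerlaw_plausible": False,
        }
        if int((degrees >= 1).sum()) >= config.min_degree_sample:
            try:
                fit = powerlaw_gof(
                    degrees,
                    n_boot=config.n_boot,
                    seed=network._sample_seed(config.seed, rep.sample_id),
                )
                row.update(
                    powerlaw_alpha=fit.alpha,
                    powerlaw_xmin=fit.xmin,
                    powerlaw_gof_p=fit.gof_p,
                    powerlaw_plausible=fit.plausible,
                )
            except (DegenerateDistributionError, InsufficientDataError) as exc:
                log.info("power-law fit skipped for %s: %s", rep.sample_id, exc)
        net_rows.append(row)
    nets = pd.DataFrame(net_rows)

    dvs = _stage("degree_vs_sharing", network.degree_vs_sharing, networks, sharing)
    cc = _stage(
        "class_connectivity",
        network.cohort_class_connectivity,
        retained_reps,
        sharing,
        config.n_sub,
        config.seed,
    )

    # --- overlap -----------------------------------------------------------
    if retained_cohort.n_samples >= 2:
        ov = _stage("pairwise_mhi", overlap.pairwise_mhi, retained_cohort)
        overlap_summary = ov.class_summary()
        overlap_pairs = ov.pairs
        overlap_matrix = ov.mhi
    else:
        overlap_summary = pd.DataFrame()
        overlap_pairs = pd.DataFrame()
        overlap_matrix = pd.DataFrame()

    # --- group statistics --------------------------------------------------
    frac_view = quant.join(cohort.manifest[["patient_id", "group"]])
    one_per_patient = quantification.select_one_per_patient(quant, cohort.manifest)
    frac_view = frac_view.loc[one_per_patient]
    comparisons = []
    for metric, table, col in (
        ("t_cell_fraction", frac_view, "t_cell_fraction"),
        ("clonality", div.set_index("sample_id"), "clonality"),
    ):
        by_group = {
            g: table.loc[table["group"] == g, col].to_numpy()
            for g in table["group"].unique()
        }
        for ga, gb in (
            ("short_interval", "no_nact"),
            ("long_interval", "no_nact"),
            ("short_interval", "long_interval"),
        ):
            if ga in by_group and gb in by_group and len(by_group[ga]) >= 2 and len(by_group[gb]) >= 2:
                cmp_ = stats.welch_t(by_group[ga], by_group[gb], ga, gb)
                comparisons.append(
                    {
                        "metric": metric,
                        "group_a": ga,
                        "group_b": gb,
                        "mean_a": cmp_.mean_a,
                        "mean_b": cmp_.mean_b,
                        "ci_a_low": cmp_.ci_a[0],
                        "ci_a_high": cmp_.ci_a[1],
                        "ci_b_low": cmp_.ci_b[0],
                        "ci_b_high": cmp_.ci_b[1],
                        "t": cmp_.t_statistic,
                        "df": cmp_.welch_df,
                        "p": cmp_.p_two_sided,
                    }
                )
    group_comparisons = pd.DataFrame(comparisons)

    regressions = []
    if len(div) >= 3:
        fit = stats.ols_fit(div["total_templates"], div["clonality"])
        regressions.append({"response": "clonality", "predictor": "total_templates", **dataclasses.asdict(fit)})
    if len(nets) >= 3:
        fit = stats.ols_fit(nets["n_nodes"], nets["connectivity_fraction"])
        regressions.append(
            {"response": "connectivity_fraction", "predictor": "n_nodes", **dataclasses.asdict(fit)}
        )
    regressions = pd.DataFrame(regressions)

    # --- pathology annotation (optional) -----------------------------------
    pathology = None
    if config.pathology_db is not None:
        db = _stage("pathology_db", network.read_pathology_db, config.pathology_db)
        path_rows = []
        for rep in retained_reps:
            pm = _stage(
                f"pathology_match[{rep.sample_id}]",
                network.pathology_match,
                rep,
                networks[rep.sample_id],
                sharing,
                db,
                config.top_frac,
            )
            path_rows.append(
                {
                    "sample_id": rep.sample_id,
                    "connected_public_fraction": pm.connected_public_fraction,
                    "expanded_fraction": pm.expanded_fraction,
                    "n_connected_public": pm.n_connected_public,
                    "n_expanded": pm.n_expanded,
                }
            )
        pathology = pd.DataFrame(path_rows)
    else:
        log.warning("no pathology database supplied; annotation stage skipped")

    # --- machine-readable roll-up ------------------------------------------
    public_pct = 100.0 * float(sharing.public.mean()) if len(sharing.clones) else float("nan")
    summary = {
        "n_samples": len(repertoires),
        "n_excluded": int(len(exclusions)),
        "n_retained": int(retained_cohort.n_samples),
        "n_cohort_clones": int(retained_cohort.n_clones),
        "public_clone_pct": public_pct,
        "mean_clonality": float(div["clonality"].mean()) if len(div) else float("nan"),
        "mean_connectivity_fraction_pct": 100.0 * float(nets["connectivity_fraction"].mean())
        if len(nets)
        else float("nan"),
    }
    result = RunResult(
        quantifications=quant,
        exclusions=exclusions,
        diversity_summary=div,
        network_summary=nets,
        degree_vs_sharing=dvs,
        class_connectivity=cc,
        overlap_summary=overlap_summary,
        group_comparisons=group_comparisons,
        regressions=regressions,
        pathology=pathology,
        sharing=sharing,
        summary=summary,
    )
    result.summary["overlap_pairs"] = len(overlap_pairs)
    result._overlap_pairs = overlap_pairs  # type: ignore[attr-defined]
    result._overlap_matrix = overlap_matrix  # type: ignore[attr-defined]
    return result


def run_all(config: RunConfig) -> RunResult:
    """Load or simulate the cohort, analyze it, and write the report bundle."""
    if config.simulate:
        from .simulate import GeneratorConfig, generate_cohort

        cohort = generate_cohort(GeneratorConfig(seed=config.seed))
        repertoires = cohort.repertoires
    elif config.input_dir is not None:
        base = Path(config.input_dir)
        repertoires = _stage(
            "load_cohort", load_cohort, base / "manifest.csv", base / "rearrangements"
        )
    else:
        raise PipelineError("either input_dir or simulate must be set")

    result = analyze_cohort(repertoires, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.quantifications.to_csv(out / "quantification.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    result.diversity_summary.to_csv(out / "diversity_summary.csv", index=False)
    result.network_summary.to_csv(out / "network_summary.csv", index=False)
    result.degree_vs_sharing.to_csv(out / "degree_vs_sharing.csv", index=False)
    result.class_connectivity.to_csv(out / "class_connectivity.csv", index=False)
    result.overlap_summary.to_csv(out / "overlap_class_summary.csv", index=False)
    getattr(result, "_overlap_pairs").to_csv(out / "overlap_pairs.csv", index=False)
    getattr(result, "_overlap_matrix").to_csv(out / "overlap_matrix.csv")
    result.group_comparisons.to_csv(out / "group_comparisons.csv", index=False)
    result.regressions.to_csv(out / "regressions.csv", index=False)
    if result.pathology is not None:
        result.pathology.to_csv(out / "pathology_match.csv", index=False)
    cfg = {k: str(v) if isinstance(v, Path) else v for k, v in dataclasses.asdict(config).items()}
    with open(out / "run_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    return result
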