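"""Synthetic TCR-beta cohort generator with planted ground truth.

Emulates the statistical structure of a three-group neoadjuvant-chemotherapy
(NACT) liver-metastasis cohort so that every pipeline stage can be verified
against known truth:

* per-group T-cell fractions (log-normal; group means 6.3% / 10.6% / 6.2%
  for no-NACT / short-interval / long-interval),
* per-group clonal-abundance shape (clone template counts follow a discrete
  power law whose exponent is the evenness knob; defaults put mean clonality
  near 5.0 for no-NACT and 5.8 for the NACT groups),
* a shared public clone pool organised in Levenshtein-distance-1 motif
  clusters (seed sequence plus single-substitution mutants), against a
  background of globally unique private clones,
* replicate structure: technical aliquot replicates (multinomial template
  resamples of one clone distribution, high overlap) and second lesions of
  the same patient (sharing half the clone pool, intermediate overlap).

Private sequences are globally unique across the cohort, so the planted
public pool is exactly the set of clones detectable in more than one
patient — a clean oracle for the sharing analysis.  Input DNA mass is set by
inverting the T-cell-fraction formula, so quantification recovers each
sample's true fraction exactly.

The same configuration and master seed always reproduce the same cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GROUPS, Repertoire, collapse_clonotypes, write_rearrangement_file
from .powerlaw import sample_discrete_powerlaw
from .quantification import PG_DNA_PER_GENOME, PG_PER_NG

AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

CDR3_MIN, CDR3_MAX = 8, 25


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator settings; defaults are the study conditions."""

    # patients per group: no_nact / short_interval / long_interval
    n_patients: tuple[int, int, int] = (35, 35, 15)
    # group mean T-cell fractions and the log-scale spread
    fraction_means: tuple[float, float, float] = (0.063, 0.106, 0.062)
    fraction_sigma_log: float = 0.6
    # discrete power-law exponent of the clone-abundance model per group
    # (the evenness knob: lower exponent = heavier tail = more clonal)
    abundance_exponents: tuple[float, float, float] = (4.35, 3.85, 3.85)
    # integer template multiplier: sets mean templates per clone (~scale x
    # power-law mean), leaving clone frequencies - hence clonality - unchanged
    template_scale: int = 5
    # unique clones per sample, drawn uniformly from this range
    richness_range: tuple[int, int] = (1500, 20000)
    # public motif-cluster pool
    n_clusters: int = 6800
    cluster_size: int = 10
    public_rate: float = 0.2          # fraction of a sample's clones from the pool
    # CDR3 length model (normal, truncated to [8, 25])
    length_mean: float = 15.0
    length_sd: float = 2.0
    # sequencing-depth model: per-sample reads-per-template (log-normal)
    reads_per_template_mean: float = 10.0
    reads_per_template_sigma_log: float = 0.45
    # replicate plan: patients (1-based rank within group) with a second
    # aliquot of the same lesion, and with a second lesion
    aliquot_replicates: tuple[tuple[str, int], ...] = (
        ("no_nact", 1), ("short_interval", 1), ("long_interval", 1),
    )
    lesion_pairs: tuple[tuple[str, int], ...] = (
        ("no_nact", 2), ("no_nact", 3), ("short_interval", 2), ("long_interval", 2),
    )
    lesion_share_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.public_rate <= 1 and 0 <= self.lesion_share_fraction <= 1):
            raise ConfigError("rates must lie in [0, 1]")
        if min(self.n_patients) < 1 or self.cluster_size < 2 or self.template_scale < 1:
            raise ConfigError("counts must be positive (cluster_size >= 2)")
        if self.richness_range[0] < 1 or self.richness_range[0] > self.richness_range[1]:
            raise ConfigError("invalid richness range")
        lo, hi = CDR3_MIN, CDR3_MAX
        if not (lo <= self.length_mean <= hi):
            raise ConfigError(f"length_mean must lie in [{lo}, {hi}]")


@dataclass(frozen=True)
class SampleSpec:
    """Everything needed to realise one sample."""

    sample_id: str
    patient_id: str
    lesion_id: str
    aliquot_id: str
    group: str
    true_fraction: float
    exponent: float
    richness: int
    reads_per_template: float


@dataclass
class GroundTruth:
    """Planted per-sample truth plus clone provenance.

    ``pool`` maps every public-pool sequence to its motif cluster; any clone
    not in the pool is private by construction, so provenance of every
    emitted clone is decidable.
    """

    samples: pd.DataFrame      # sample_id, patient_id, group, true_fraction, ...
    pool: pd.DataFrame         # cdr3_aa, cluster_id

    def provenance(self, cdr3_aa: str) -> str:
        hit = self.pool.loc[self.pool["cdr3_aa"] == cdr3_aa, "cluster_id"]
        return f"public_cluster_{int(hit.iloc[0])}" if len(hit) else "private"


@dataclass
class SyntheticCohort:
    repertoires: list[Repertoire]
    manifest: pd.DataFrame
    truth: GroundTruth
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def _draw_lengths(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    L = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.clip(L, CDR3_MIN, CDR3_MAX)


def _random_seq_batch(
    rng: np.random.Generator, n: int, mean: float = 15.0, sd: float = 2.0
) -> np.ndarray:
    """n random CDR3-like sequences (convention: start 'C', end 'F').

    Vectorised per length class: interior residues uniform over the
    20-letter alphabet.
    """
    lengths = _draw_lengths(rng, n, mean, sd)
    out = np.empty(n, dtype=object)
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        codes = AA[rng.integers(0, len(AA), size=(idx.size, int(L)))]
        codes[:, 0] = ord("C")
        codes[:, -1] = ord("F")
        block = codes.tobytes()
        out[idx] = [
            block[i * L : (i + 1) * L].decode("ascii") for i in range(idx.size)
        ]
    return out


def generate_cdr3(
    rng: np.random.Generator,
    length_mean: float = 15.0,
    length_sd: float = 2.0,
    length_bounds: tuple[int, int] = (CDR3_MIN, CDR3_MAX),
) -> str:
    """One random CDR3-beta-like amino-acid sequence."""
    if length_bounds[0] < CDR3_MIN or length_bounds[1] > CDR3_MAX:
        raise ConfigError(f"length bounds must lie within [{CDR3_MIN}, {CDR3_MAX}]")
    L = int(np.clip(np.rint(rng.normal(length_mean, length_sd)), *length_bounds))
    interior = AA[rng.integers(0, len(AA), size=L - 2)].tobytes().decode("ascii")
    return "C" + interior + "F"


def _mutate(rng: np.random.Generator, seq: str) -> str:
    """Single interior substitution (keeps the C...F convention)."""
    pos = int(rng.integers(1, len(seq) - 1))
    old = seq[pos]
    choices = [chr(c) for c in AA if chr(c) != old]
    return seq[:pos] + choices[int(rng.integers(0, len(choices)))] + seq[pos + 1:]


def generate_public_pool(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Motif-cluster pool: per cluster one seed plus single-substitution mutants.

    Every mutant is at Levenshtein distance 1 from its seed (so each cluster
    is at least a star in the LD=1 graph) and clusters are mutually disjoint
    after global deduplication.
    """
    space = float(len(AA)) ** max(round(config.length_mean) - 2, 1)
    if config.n_clusters * config.cluster_size > space:
        raise ConfigError("public pool larger than the sequence space")
    seeds = pd.unique(
        _random_seq_batch(rng, config.n_clusters, config.length_mean, config.length_sd)
    )
    rows: list[tuple[str, int]] = []
    for cid, seed in enumerate(seeds):
        members = {seed}
        attempts = 0
        while len(members) < config.cluster_size and attempts < config.cluster_size * 20:
            members.add(_mutate(rng, seed))
            attempts += 1
        rows.extend((s, cid) for s in sorted(members))
    pool = pd.DataFrame(rows, columns=["cdr3_aa", "cluster_id"])
    return pool.drop_duplicates("cdr3_aa", keep="first").reset_index(drop=True)


class _PrivateSupply:
    """Hands out globally unique private sequences, never colliding with the
    public pool."""

    def __init__(self, config: GeneratorConfig, pool_seqs: set[str], rng: np.random.Generator):
        self._config = config
        self._exclude = set(pool_seqs)
        self._rng = rng
        self._buffer: list[str] = []

    def _refill(self, n: int) -> None:
        need = max(n, 50_000)
        batch = _random_seq_batch(
            self._rng, int(need * 1.05) + 100, self._config.length_mean, self._config.length_sd
        )
        fresh = [s for s in pd.unique(batch) if s not in self._exclude]
        self._exclude.update(fresh)
        self._buffer.extend(fresh)

    def take(self, n: int) -> np.ndarray:
        while len(self._buffer) < n:
            self._refill(n - len(self._buffer))
        out, self._buffer = self._buffer[:n], self._buffer[n:]
        return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# per-sample realisation
# ---------------------------------------------------------------------------

def _dna_mass_ng(total_templates: int, fraction: float) -> float:
    """Invert fraction = templates / (mass * 1000 / 6.6)."""
    if not 0 < fraction <= 1:
        raise ConfigError(f"infeasible T-cell fraction {fraction}")
    return total_templates * PG_DNA_PER_GENOME / (fraction * PG_PER_NG)


def _assemble(
    spec: SampleSpec, seqs: np.ndarray, templates: np.ndarray, rng: np.random.Generator
) -> Repertoire:
    reads = np.rint(templates * spec.reads_per_template).astype(np.int64)
    df = pd.DataFrame(
        {
            "cdr3_aa": seqs,
            "templates": templates.astype(np.int64),
            "reads": np.maximum(reads, templates),
            "productive": True,
            "v_gene": None,
            "j_gene": None,
        }
    )
    df = collapse_clonotypes(df)
    total = int(df["templates"].sum())
    return Repertoire(
        sample_id=spec.sample_id,
        clonotypes=df.reset_index(drop=True),
        patient_id=spec.patient_id,
        lesion_id=spec.lesion_id,
        aliquot_id=spec.aliquot_id,
        group=spec.group,
        input_dna_ng=_dna_mass_ng(total, spec.true_fraction),
    )


def generate_repertoire(
    spec: SampleSpec,
    pool: pd.DataFrame,
    private_supply: _PrivateSupply,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> Repertoire:
    """Realise one sample: clone set, abundances, reads and DNA mass."""
    n_pub = int(round(config.public_rate * spec.richness))
    n_pub = min(n_pub, len(pool))
    n_priv = spec.richness - n_pub
    pub_seqs = rng.choice(pool["cdr3_aa"].to_numpy(), size=n_pub, replace=False)
    priv_seqs = private_supply.take(n_priv)
    seqs = np.concatenate([pub_seqs, priv_seqs])
    counts = sample_discrete_powerlaw(spec.exponent, 1, seqs.size, rng) * config.template_scale
    return _assemble(spec, seqs, counts, rng)


def _resample_aliquot(parent: Repertoire, spec: SampleSpec, rng: np.random.Generator) -> Repertoire:
    """Technical replicate: multinomial template resample of the parent's
    clone distribution at the parent's depth; zero-count clones drop out."""
    df = parent.productive_frame()
    p = df["templates"].to_numpy(dtype=float)
    p = p / p.sum()
    counts = rng.multinomial(parent.total_templates, p)
    keep = counts > 0
    return _assemble(spec, df["cdr3_aa"].to_numpy()[keep], counts[keep], rng)


def _second_lesion(
    parent: Repertoire,
    spec: SampleSpec,
    pool: pd.DataFrame,
    private_supply: _PrivateSupply,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> Repertoire:
    """Second metastasis of the same patient: shares a configurable fraction
    of the first lesion's clones (with their abundances); the rest is fresh."""
    df = parent.productive_frame()
    n_shared = min(int(round(config.lesion_share_fraction * spec.richness)), len(df))
    shared_idx = rng.choice(len(df), size=n_shared, replace=False)
    shared_seqs = df["cdr3_aa"].to_numpy()[shared_idx]
    shared_counts = df["templates"].to_numpy()[shared_idx]
    n_new = spec.richness - n_shared
    n_pub = int(round(config.public_rate * n_new))
    new_pub = rng.choice(pool["cdr3_aa"].to_numpy(), size=n_pub, replace=False)
    new_priv = private_supply.take(n_new - n_pub)
    new_seqs = np.concatenate([new_pub, new_priv])
    new_counts = sample_discrete_powerlaw(spec.exponent, 1, new_seqs.size, rng) * config.template_scale
    seqs = np.concatenate([shared_seqs, new_seqs])
    counts = np.concatenate([shared_counts, new_counts])
    return _assemble(spec, seqs, counts, rng)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _truncated_lognormal(rng: np.random.Generator, mean: float, sigma: float, cap: float = 0.9) -> float:
    mu = np.log(mean) - sigma**2 / 2
    for _ in range(100):
        x = float(rng.lognormal(mu, sigma))
        if x < cap:
            return x
    return cap


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate the full cohort: all samples, manifest and ground truth.

    Patient P-numbers run consecutively across groups; the replicate plan
    adds extra datasets (second aliquots and second lesions) on top of the
    per-patient baseline sample, mirroring a cohort in which every patient
    contributes one dataset and a few contribute two.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    pool = generate_public_pool(config, rng)
    supply = _PrivateSupply(config, set(pool["cdr3_aa"]), rng)

    aliquot_set = set(config.aliquot_replicates)
    lesion_set = set(config.lesion_pairs)
    repertoires: list[Repertoire] = []
    truth_rows: list[dict] = []
    sample_counter = 0
    patient_counter = 0
    for group, n_pat, frac_mean, exponent in zip(
        GROUPS, config.n_patients, config.fraction_means, config.abundance_exponents
    ):
        for rank in range(1, n_pat + 1):
            patient_counter += 1
            pid = f"P{patient_counter:03d}"
            fraction = _truncated_lognormal(rng, frac_mean, config.fraction_sigma_log)
            richness = int(rng.integers(config.richness_range[0], config.richness_range[1] + 1))
            rpt = float(
                rng.lognormal(
                    np.log(config.reads_per_template_mean)
                    - config.reads_per_template_sigma_log**2 / 2,
                    config.reads_per_template_sigma_log,
                )
            )
            sample_counter += 1
            spec = SampleSpec(
                sample_id=f"S{sample_counter:03d}",
                patient_id=pid,
                lesion_id=f"{pid}-L1",
                aliquot_id=f"{pid}-L1-A1",
                group=group,
                true_fraction=fraction,
                exponent=exponent,
                richness=richness,
                reads_per_template=rpt,
            )
            rep = generate_repertoire(spec, pool, supply, rng, config)
            repertoires.append(rep)
            truth_rows.append({**spec.__dict__, "role": "primary"})

            if (group, rank) in aliquot_set:
                sample_counter += 1
                rspec = replace(
                    spec,
                    sample_id=f"S{sample_counter:03d}",
                    aliquot_id=f"{pid}-L1-A2",
                )
                repertoires.append(_resample_aliquot(rep, rspec, rng))
                truth_rows.append({**rspec.__dict__, "role": "aliquot_replicate"})
            if (group, rank) in lesion_set:
                sample_counter += 1
                richness2 = int(
                    rng.integers(config.richness_range[0], config.richness_range[1] + 1)
                )
                lspec = replace(
                    spec,
                    sample_id=f"S{sample_counter:03d}",
                    lesion_id=f"{pid}-L2",
                    aliquot_id=f"{pid}-L2-A1",
                    true_fraction=_truncated_lognormal(rng, frac_mean, config.fraction_sigma_log),
                    richness=richness2,
                )
                repertoires.append(_second_lesion(rep, lspec, pool, supply, rng, config))
                truth_rows.append({**lspec.__dict__, "role": "second_lesion"})

    manifest = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in repertoires],
            "patient_id": [r.patient_id for r in repertoires],
            "lesion_id": [r.lesion_id for r in repertoires],
            "aliquot_id": [r.aliquot_id for r in repertoires],
            "group": [r.group for r in repertoires],
            "input_dna_ng": [r.input_dna_ng for r in repertoires],
        }
    ).set_index("sample_id", drop=False)
    truth = GroundTruth(samples=pd.DataFrame(truth_rows), pool=pool)
    return SyntheticCohort(repertoires=repertoires, manifest=manifest, truth=truth, config=config)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write per-sample rearrangement TSVs, the manifest CSV and ground truth."""
    out_dir = Path(out_dir)
    data_dir = out_dir / "rearrangements"
    data_dir.mkdir(parents=True, exist_ok=True)
    for rep in cohort.repertoires:
        write_rearrangement_file(rep, data_dir / f"{rep.sample_id}.tsv")
    cohort.manifest.to_csv(out_dir / "manifest.csv", index=False)
    cohort.truth.samples.to_csv(out_dir / "ground_truth_samples.csv", index=False)
    cohort.truth.pool.to_csv(out_dir / "ground_truth_public_pool.csv", index=False)
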