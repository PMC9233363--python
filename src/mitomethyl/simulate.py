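"""Synthetic whole-mitochondrial-genome bisulfite datasets with planted effects.

Generates a circular reference, a forensic-style cohort (control and drug-use
groups with ages, drug flags and nuisance covariates), and per-sample,
per-brain-area cytosine call tables whose statistical structure matches what
the downstream analysis assumes: low (~2% mean, <8% max) site-level
methylation, strand-asymmetric coverage (heavy chain deeper than light chain),
paired NAcc/PFC samples per individual, and planted brain-area, age-slope and
drug-use effect sites. A ground-truth sidecar records the planted sites and
effect sizes for recovery testing.

Effects are additive on the logit scale, which keeps per-cell probabilities in
(0, 1) at low baselines. Coverage is negative-binomial around a site- and
sample-specific mean so that light-chain sites drop below the coverage filter
consistently across samples, as in real strand-biased data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import REPORT_COLUMNS, annotate_contexts, cytosine_positions, write_cytosine_report

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_reference",
    "generate_cohort",
    "plant_truth",
    "simulate_methylation",
    "simulate_dataset",
    "write_reference",
    "read_reference",
    "write_cohort",
    "read_cohort",
    "write_truth",
    "read_truth",
]

AREAS = ("NAcc", "PFC")

# Cohort regimes: control ages ~ N(54.9, 21.5), drug ages ~ N(37.5, 12.0),
# truncated at the 18-year inclusion floor; covariate frequencies follow the
# study population (alcohol 7/39 vs 2/14, PMI<=6h 32/39 vs 9/14, cause-of-death
# mix per group; drug-type mix 2 heroin / 5 ATS-only / 3 ketamine-only /
# 4 ATS+ketamine out of 14).
CONTROL_AGE = (54.9, 21.5)
DRUG_AGE = (37.5, 12.0)
MIN_AGE = 18.0
ALCOHOL_RATE = {"control": 7 / 39, "drug": 2 / 14}
PMI_LE6_RATE = {"control": 32 / 39, "drug": 9 / 14}
CAUSE_LEVELS = ("accident", "homicide", "suicide", "natural", "undetermined")
CAUSE_PROBS = {
    "control": np.array([17, 3, 2, 15, 2]) / 39,
    "drug": np.array([4, 5, 3, 1, 1]) / 14,
}
DRUG_TYPE_LEVELS = ("heroin", "ats_only", "ketamine_only", "ats_ketamine")
DRUG_TYPE_PROBS = np.array([2, 5, 3, 4]) / 14

COHORT_COLUMNS = [
    "id",
    "group",
    "heroin",
    "ats",
    "ketamine",
    "age",
    "alcohol",
    "pmi_class",
    "batch",
    "collector",
    "cause_of_death",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the study regime: 39 controls and 14 drug users, a
    16,569-bp circular genome, ~2% mean site methylation capped below 8%,
    heavy-chain coverage well above the light chain, and planted effect-site
    counts matching the three indices (105 brain-area, 70 age, 35 drug-use
    sites). Effect sizes are logit-scale shifts/slopes.
    """

    n_control: int = 39
    n_drug: int = 14
    genome_length: int = 16569
    gc_fraction: float = 0.44
    baseline_mean: float = 0.02
    baseline_max: float = 0.08
    n_ba_sites: int = 105
    n_age_sites: int = 70
    n_du_sites: int = 35
    ba_effect: float = 1.0
    age_slope: float = 0.03
    du_effect: float = 1.5
    du_age_shift_years: float = 0.0
    coverage_mean_H: float = 100.0
    coverage_mean_L: float = 40.0
    coverage_dispersion: float = 20.0
    site_depth_sd: float = 0.5
    sample_depth_sd: float = 0.15
    individual_sd: float = 0.3
    n_batches: int = 3
    n_collectors: int = 2
    missing_pfc_fraction: float = 1 / 14
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.baseline_mean < self.baseline_max < 1:
            raise ValueError("need 0 < baseline_mean < baseline_max < 1")
        if not self.coverage_mean_H >= self.coverage_mean_L > 0:
            raise ValueError("need coverage_mean_H >= coverage_mean_L > 0")
        for name in ("n_control", "n_drug", "n_ba_sites", "n_age_sites", "n_du_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")
        if not 0 <= self.missing_pfc_fraction <= 1:
            raise ValueError("missing_pfc_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


@dataclass
class SimulationTruth:
    """The planted effects a synthetic dataset carries.

    Site keys are (position, strand) tuples; values are logit-scale effect
    sizes (shifts for brain-area and drug-use sites, per-year slopes for age
    sites). ``ages`` and ``groups`` record the per-individual truth.
    """

    ba_sites: dict[tuple[int, str], float] = field(default_factory=dict)
    age_sites: dict[tuple[int, str], float] = field(default_factory=dict)
    du_sites: dict[tuple[int, str], float] = field(default_factory=dict)
    ages: dict[str, float] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(sites):
            return [[pos, strand, eff] for (pos, strand), eff in sorted(sites.items())]

        return json.dumps(
            {
                "ba_sites": enc(self.ba_sites),
                "age_sites": enc(self.age_sites),
                "du_sites": enc(self.du_sites),
                "ages": self.ages,
                "groups": self.groups,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)

        def dec(rows):
            return {(int(p), s): float(e) for p, s, e in rows}

        return cls(
            ba_sites=dec(d["ba_sites"]),
            age_sites=dec(d["age_sites"]),
            du_sites=dec(d["du_sites"]),
            ages={k: float(v) for k, v in d["ages"].items()},
            groups=dict(d["groups"]),
        )


def generate_reference(length: int, gc_fraction: float = 0.44, seed: int = 0) -> str:
    """A random circular DNA sequence with the given GC content.

    Stands in for the 16,569-bp revised Cambridge Reference Sequence; position
    ``length`` wraps to position 1 in all downstream context calls.
    """
    if length < 100:
        raise ValueError("length must be >= 100 (too short to place planted sites)")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
    return "".join(bases)


def _truncated_normal_ages(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Ages with the *observed* mean after truncation at the 18-year floor.

    The pre-truncation location is solved so that the truncated distribution's
    mean equals the target (truncation alone would inflate it).
    """
    from scipy.optimize import brentq

    def truncated_mean(loc):
        a = (MIN_AGE - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd)

    loc = brentq(lambda m: truncated_mean(m) - mean, mean - 3 * sd, mean + sd, xtol=1e-6)
    a = (MIN_AGE - loc) / sd
    ages = stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=n, random_state=rng)
    return np.round(ages, 1)


def generate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample-metadata table for a control + drug-use cohort.

    Ages are truncated-normal (floor 18 years) with group-specific means;
    drug-type flags, alcohol, postmortem-interval class and cause of death are
    drawn at the study frequencies; batch and collector are uniform nuisance
    categories shared by both groups.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    ages_c = _truncated_normal_ages(config.n_control, *CONTROL_AGE, rng)
    ages_d = _truncated_normal_ages(config.n_drug, *DRUG_AGE, rng)
    drug_types = rng.choice(DRUG_TYPE_LEVELS, size=config.n_drug, p=DRUG_TYPE_PROBS)
    for i in range(config.n_control + config.n_drug):
        if i < config.n_control:
            group, age = "control", ages_c[i]
            heroin = ats = ketamine = False
        else:
            j = i - config.n_control
            group, age = "drug", ages_d[j]
            dt = drug_types[j]
            heroin = dt == "heroin"
            ats = dt in ("ats_only", "ats_ketamine")
            ketamine = dt in ("ketamine_only", "ats_ketamine")
        rows.append(
            {
                "id": f"S{i + 1:03d}",
                "group": group,
                "heroin": heroin,
                "ats": ats,
                "ketamine": ketamine,
                "age": age,
                "alcohol": bool(rng.random() < ALCOHOL_RATE[group]),
                "pmi_class": "le6h" if rng.random() < PMI_LE6_RATE[group] else "gt6h",
                "batch": f"B{rng.integers(config.n_batches) + 1}",
                "collector": f"D{rng.integers(config.n_collectors) + 1}",
                "cause_of_death": rng.choice(CAUSE_LEVELS, p=CAUSE_PROBS[group]),
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def plant_truth(
    config: SimulationConfig,
    reference: str,
    cohort: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Choose disjoint planted effect sites among the reference's cytosines.

    Brain-area and drug-use shifts and per-year age slopes are the configured
    magnitudes with random sign, biased toward the directions the study
    reports (NAcc above PFC, hypermethylation with age and with drug use):
    80% of planted sites take the positive direction.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sites = cytosine_positions(reference)
    n_needed = config.n_ba_sites + config.n_age_sites + config.n_du_sites
    if n_needed > len(sites):
        raise ValueError(f"cannot plant {n_needed} sites among {len(sites)} cytosines")
    chosen = rng.choice(len(sites), size=n_needed, replace=False)
    picks = [sites[i] for i in chosen]
    ba = picks[: config.n_ba_sites]
    age = picks[config.n_ba_sites : config.n_ba_sites + config.n_age_sites]
    du = picks[config.n_ba_sites + config.n_age_sites :]

    def signed(n, magnitude):
        return magnitude * np.where(rng.random(n) < 0.8, 1.0, -1.0)

    truth = SimulationTruth(
        ba_sites=dict(zip(ba, signed(len(ba), config.ba_effect))),
        age_sites=dict(zip(age, signed(len(age), config.age_slope))),
        du_sites=dict(zip(du, signed(len(du), config.du_effect))),
        ages=dict(zip(cohort["id"], cohort["age"].astype(float))),
        groups=dict(zip(cohort["id"], cohort["group"])),
    )
    return truth


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    config: SimulationConfig,
    cohort: pd.DataFrame,
    reference: str,
    truth: SimulationTruth,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-sample, per-area cytosine call tables.

    For each individual and brain area, per-site coverage is negative-binomial
    with a strand-dependent mean modulated by lognormal site- and sample-depth
    factors (shared site factors make light-chain dropout consistent across
    samples). Methylated counts are binomial with a probability assembled on
    the logit scale: site baseline + brain-area shift (NAcc only) + age slope x
    (age - cohort mean age) + drug-use shift (drug group only) + individual
    noise. A configured fraction of drug-use individuals lacks a PFC sample
    (heroin users first, as in the study).

    Returns a dict keyed by (individual id, area).
    """
    for sites in (truth.ba_sites, truth.age_sites, truth.du_sites):
        for pos, strand in sites:
            if not 1 <= pos <= len(reference):
                raise ValueError(f"planted position {pos} absent from reference")
    site_keys = cytosine_positions(reference)
    annotation = annotate_contexts(reference, site_keys)
    n_sites = len(site_keys)
    key_index = {k: i for i, k in enumerate(site_keys)}
    strands = np.array([s for _, s in site_keys])

    master = np.random.SeedSequence([config.seed, 3])
    ss_global, ss_samples = master.spawn(2)
    rng = np.random.default_rng(ss_global)

    # per-site baseline means: beta with the configured mean, capped below the max
    b = 30.0
    a = b * config.baseline_mean / (1 - config.baseline_mean)
    base_p = rng.beta(a, b, size=n_sites)
    base_p = np.clip(base_p, 1e-4, config.baseline_max)
    base_logit = _logit(base_p)

    site_depth = np.exp(rng.normal(0.0, config.site_depth_sd, size=n_sites))
    strand_mean = np.where(strands == "H", config.coverage_mean_H, config.coverage_mean_L)

    ba_vec = np.zeros(n_sites)
    for k, eff in truth.ba_sites.items():
        ba_vec[key_index[k]] = eff
    age_vec = np.zeros(n_sites)
    for k, eff in truth.age_sites.items():
        age_vec[key_index[k]] = eff
    du_vec = np.zeros(n_sites)
    for k, eff in truth.du_sites.items():
        du_vec[key_index[k]] = eff

    mean_age = float(cohort["age"].mean())
    drug_ids = list(cohort.loc[cohort["group"] == "drug", "id"])
    n_missing = int(round(config.missing_pfc_fraction * len(drug_ids)))
    heroin_first = sorted(
        drug_ids,
        key=lambda i: (not bool(cohort.set_index("id").loc[i, "heroin"]), i),
    )
    missing_pfc = set(heroin_first[:n_missing])

    calls: dict[tuple[str, str], pd.DataFrame] = {}
    sample_streams = ss_samples.spawn(len(cohort) * len(AREAS))
    stream_i = 0
    k_disp = config.coverage_dispersion
    for _, person in cohort.iterrows():
        pid, group, age = person["id"], person["group"], float(person["age"])
        for area in AREAS:
            srng = np.random.default_rng(sample_streams[stream_i])
            stream_i += 1
            if area == "PFC" and pid in missing_pfc:
                continue
            effective_age = age + (config.du_age_shift_years if group == "drug" else 0.0)
            logit_p = base_logit + age_vec * (effective_age - mean_age)
            if area == "NAcc":
                logit_p = logit_p + ba_vec
            if group == "drug":
                logit_p = logit_p + du_vec
            if config.individual_sd > 0:
                logit_p = logit_p + srng.normal(0.0, config.individual_sd, size=n_sites)
            p = np.clip(_expit(logit_p), 1e-6, 1 - 1e-6)

            sample_depth = np.exp(srng.normal(0.0, config.sample_depth_sd))
            mu = strand_mean * site_depth * sample_depth
            coverage = srng.negative_binomial(k_disp, k_disp / (k_disp + mu), size=n_sites)
            meth = srng.binomial(coverage, p)
            df = pd.DataFrame(
                {
                    "position": [k[0] for k in site_keys],
                    "strand": strands,
                    "count_methylated": meth,
                    "count_unmethylated": coverage - meth,
                    "context": annotation["context"].to_numpy(),
                    "trinucleotide": annotation["trinucleotide"].to_numpy(),
                },
                columns=REPORT_COLUMNS,
            )
            calls[(pid, area)] = df
    return calls


def simulate_dataset(config: SimulationConfig):
    """Generate a complete dataset: reference, cohort, truth, and call tables."""
    reference = generate_reference(config.genome_length, config.gc_fraction, seed=config.seed)
    cohort = generate_cohort(config)
    truth = plant_truth(config, reference, cohort)
    calls = simulate_methylation(config, cohort, reference, truth)
    return reference, cohort, truth, calls


# ---------------------------------------------------------------------------
# file IO for the sidecar artifacts
# ---------------------------------------------------------------------------

def write_reference(reference: str, path: str | Path, name: str = "chrM_synthetic") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i : i + 70] + "\n")
    return path


def read_reference(path: str | Path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def write_cohort(cohort: pd.DataFrame, path: str | Path, overwrite: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, sep="\t", index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    for col in ("heroin", "ats", "ketamine", "alcohol"):
        df[col] = df[col].astype(bool)
    return df[COHORT_COLUMNS]


def write_truth(truth: SimulationTruth, path: str | Path, overwrite: bool = False) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(truth.to_json())
    return path


def read_truth(path: str | Path) -> SimulationTruth:
    return SimulationTruth.from_json(Path(path).read_text())


def write_call_sets(
    calls: Mapping[tuple[str, str], pd.DataFrame],
    directory: str | Path,
    overwrite: bool = False,
) -> dict[tuple[str, str], Path]:
    """One cytosine-report file per individual per available brain area."""
    directory = Path(directory)
    paths = {}
    for (pid, area), df in calls.items():
        paths[(pid, area)] = write_cytosine_report(
            df, directory / f"{pid}_{area}.tsv", overwrite=overwrite
        )
    return paths
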