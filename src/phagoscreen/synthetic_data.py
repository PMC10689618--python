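"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the study's data sources so the whole pipeline is
testable without any download:

* :func:`gen_screen` — 384-well plate tables for a singlicate five-dose
  phagocytosis screen (two fluorescence channels per well) with planted
  increase / decrease / toxic compounds and multiplicative lognormal noise;
* :func:`gen_timecourses` — hourly live-imaging phagocytosis signals whose
  plateau follows a four-parameter logistic in dose;
* :func:`gen_network_tables` — per-drug network gene sets, gene-phenotype
  annotations and a phenotype cluster map, with group-discriminative genes
  planted at configurable presence probabilities;
* :func:`gen_patient_table` — EHR-like person/exposure/diagnosis/visit
  tables with confounded exposure and exponential event times at a known
  true hazard ratio (:func:`simulate_survival_rows` produces the reduced
  survival rows directly for parameter-recovery experiments).

Ground-truth labels are assigned deterministically by count (a seeded
shuffle, then the first floor(f*n) ids per class) so recovery tests are
exact rather than binomially slack.  All dates in the EHR emulation are
fractional ages in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import ValidationError
from .hit_calling import Timecourse, four_param_logistic

DEFAULT_DOSES_UM = (1.39, 2.78, 5.56, 11.11, 22.22)

#: Concept ids used by the EHR emulation.
EXPOSURE_CONCEPT = "ADRB2_AGONIST"
DISEASE_CONCEPT = "SZ"

DAYS_PER_YEAR = 365.25


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _yaml_config(cls):
    """Attach a from_yaml constructor to a config dataclass."""

    @classmethod
    def from_yaml(klass, path):
        with open(path, "r", encoding="utf-8") as fh:
            return klass(**yaml.safe_load(fh))

    cls.from_yaml = from_yaml
    return cls


# ---------------------------------------------------------------------------
# Plate screen
# ---------------------------------------------------------------------------


@_yaml_config
@dataclass(frozen=True)
class ScreenSimConfig:
    """Conditions of the simulated plate screen.

    Defaults mirror the screen itself: 3,280 library compounds dosed in
    singlicate at {1.39, 2.78, 5.56, 11.11, 22.22} µM on 384-well plates with
    four high-control rows, one positive-control row and no-cell low-control
    wells.  Planted hits respond at ``decrease_level_pct`` / ``increase_level_pct``
    percent of plate median at doses above ``effect_above_um``; toxic
    compounds lose green (viability) signal, with red reduced proportionally.
    """

    n_compounds: int = 3280
    doses_um: tuple = DEFAULT_DOSES_UM
    frac_increase: float = 0.05
    frac_decrease: float = 0.05
    frac_toxic: float = 0.02
    increase_level_pct: float = 140.0
    decrease_level_pct: float = 50.0
    toxic_green_fraction: float = 0.5
    effect_above_um: float = 5.0
    cv_noise: float = 0.05
    plate_format: int = 384
    seed: int = 0
    base_green: float = 1.0e6
    base_red: float = 2.0e5

    def __post_init__(self) -> None:
        if self.frac_increase + self.frac_decrease + self.frac_toxic > 1.0:
            raise ValidationError("class fractions must sum to <= 1")
        if min(self.frac_increase, self.frac_decrease, self.frac_toxic) < 0:
            raise ValidationError("class fractions must be non-negative")
        d = self.doses_um
        if any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValidationError("doses must be positive and strictly increasing")
        if self.cv_noise < 0:
            raise ValidationError("cv_noise must be >= 0")


@dataclass
class ScreenSim:
    """A simulated screen: raw well table plus the ground-truth sidecar."""

    wells: pd.DataFrame
    truth: pd.DataFrame
    config: ScreenSimConfig

    def write(self, wells_path, truth_path) -> None:
        self.wells.to_csv(wells_path, index=False)
        self.truth.to_csv(truth_path, index=False)


_PLATE_GEOMETRY = {384: (16, 24), 96: (8, 12)}


def _plate_layout(plate_format: int, n_high_rows=4, n_positive_rows=1, n_low_cols=2):
    """Well roles for one plate: (row letter, col, role) triples.

    Rows A..D are untreated high controls, row E the positive control,
    the last two columns of the remaining rows are no-cell low controls and
    everything else is a data well.
    """
    if plate_format not in _PLATE_GEOMETRY:
        raise ValidationError(f"unsupported plate format: {plate_format}")
    n_rows, n_cols = _PLATE_GEOMETRY[plate_format]
    rows = [chr(ord("A") + i) for i in range(n_rows)]
    layout, data_wells = [], []
    for i, row in enumerate(rows):
        for col in range(1, n_cols + 1):
            if i < n_high_rows:
                role = "high_control"
            elif i < n_high_rows + n_positive_rows:
                role = "positive_control"
            elif col > n_cols - n_low_cols:
                role = "low_control"
            else:
                role = "data"
                data_wells.append((row, col))
            layout.append((row, col, role))
    if not data_wells:
        raise ValidationError("plate layout leaves no data wells")
    return layout, data_wells


def planted_labels(n_compounds: int, config: ScreenSimConfig, rng) -> pd.DataFrame:
    """Deterministic-by-count class labels after a seeded shuffle."""
    ids = [f"C{i:05d}" for i in range(n_compounds)]
    order = rng.permutation(n_compounds)
    n_inc = int(np.floor(config.frac_increase * n_compounds))
    n_dec = int(np.floor(config.frac_decrease * n_compounds))
    n_tox = int(np.floor(config.frac_toxic * n_compounds))
    labels = np.full(n_compounds, "no_effect", dtype=object)
    labels[order[:n_inc]] = "increase"
    labels[order[n_inc : n_inc + n_dec]] = "decrease"
    labels[order[n_inc + n_dec : n_inc + n_dec + n_tox]] = "toxic"
    return pd.DataFrame({"compound_id": ids, "true_class": labels})


def gen_screen(config: ScreenSimConfig) -> ScreenSim:
    """Simulate the full plate screen.

    Every (compound, dose) pair occupies one data well; wells are laid onto
    plates in compound order.  With no planted effects and zero noise, every
    data well's red:green ratio equals the plate median exactly and the
    downstream classifier returns 100% no-effect calls.
    """
    rng = np.random.default_rng(config.seed)
    layout, data_wells = _plate_layout(config.plate_format)
    if len(data_wells) < len(config.doses_um):
        raise ValidationError(
            f"plate layout has {len(data_wells)} data wells, fewer than "
            f"{len(config.doses_um)} doses; screen infeasible"
        )
    truth = planted_labels(config.n_compounds, config, rng)
    label_of = dict(zip(truth["compound_id"], truth["true_class"]))

    pairs = [
        (cid, dose) for cid in truth["compound_id"] for dose in config.doses_um
    ]
    per_plate = len(data_wells)
    n_plates = int(np.ceil(len(pairs) / per_plate))

    records = []
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        chunk = pairs[p * per_plate : (p + 1) * per_plate]
        assigned = dict(zip(data_wells, chunk))
        for row, col, role in layout:
            red, green = config.base_red, config.base_green
            compound_id, conc = "", np.nan
            if role == "low_control":
                red, green = 0.02 * red, 0.02 * green
            elif role == "positive_control":
                red = 0.3 * red
            elif role == "data":
                if (row, col) not in assigned:
                    continue  # trailing plate, unfilled well
                compound_id, conc = assigned[(row, col)]
                label = label_of[compound_id]
                if conc > config.effect_above_um:
                    if label == "increase":
                        red *= config.increase_level_pct / 100.0
                    elif label == "decrease":
                        red *= config.decrease_level_pct / 100.0
                    elif label == "toxic":
                        # dead cells neither fluoresce nor phagocytose
                        green *= config.toxic_green_fraction
                        red *= config.toxic_green_fraction
            records.append(
                (plate_id, row, col, role, compound_id, conc, red, green)
            )

    wells = pd.DataFrame(
        records,
        columns=[
            "plate_id",
            "well_row",
            "well_col",
            "role",
            "compound_id",
            "concentration_um",
            "red_intensity",
            "green_intensity",
        ],
    )
    noise_r = _lognormal_noise(rng, config.cv_noise, len(wells))
    noise_g = _lognormal_noise(rng, config.cv_noise, len(wells))
    wells["red_intensity"] = wells["red_intensity"] * noise_r
    wells["green_intensity"] = wells["green_intensity"] * noise_g
    return ScreenSim(wells=wells, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Live-imaging time courses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillParams:
    """4PL plateau parameters for the time-course generator (percent units)."""

    bottom: float = 40.0
    top: float = 100.0
    ec50_um: float = 5.0
    slope: float = 1.0


def gen_timecourses(
    doses_um,
    hill: HillParams | None = None,
    hours: int = 24,
    seed: int = 0,
    cv_noise: float = 0.0,
    tau_hours: float = 8.0,
) -> list:
    """Hourly phagocytosis signal per dose, vehicle (dose 0) included.

    The signal accumulates as ``plateau(dose) * (1 - exp(-t/tau))`` with the
    plateau given by a 4PL in dose; at the EC50 the whole curve sits midway
    between the bottom- and top-plateau curves.  Noise, when requested, is
    multiplicative lognormal per time point.
    """
    hill = hill or HillParams()
    if hours < 2:
        raise ValidationError("need at least 2 hourly time points")
    doses = list(doses_um)
    if any(d <= 0 for d in doses):
        raise ValidationError("doses must be positive (vehicle is added automatically)")
    rng = np.random.default_rng(seed)
    t = np.arange(hours, dtype=float)
    accumulation = 1.0 - np.exp(-t / tau_hours)
    out = []
    for dose in [0.0] + doses:
        plateau = float(
            four_param_logistic(dose, hill.bottom, hill.top, hill.ec50_um, hill.slope)
        )
        signal = plateau * accumulation * _lognormal_noise(rng, cv_noise, hours)
        out.append(Timecourse(hours=tuple(t), signal=tuple(signal), dose_um=dose))
    return out


# ---------------------------------------------------------------------------
# Drug network tables
# ---------------------------------------------------------------------------


@_yaml_config
@dataclass(frozen=True)
class NetworkSimConfig:
    """Conditions of the simulated drug-network meta-analysis input.

    Defaults mirror the published analysis scale: 239 drugs (52 increase,
    43 decrease, 144 no-effect), a 1,947-gene disease universe and 77
    phenotypes in 10 clusters.  ``planted_genes`` maps gene id ->
    {group: presence probability}; groups not listed fall back to
    ``background_presence``.
    """

    n_drugs: dict = field(
        default_factory=lambda: {"increase": 52, "decrease": 43, "no_effect": 144}
    )
    gene_universe_size: int = 1947
    n_phenotypes: int = 77
    n_phenotype_clusters: int = 10
    planted_genes: dict = field(
        default_factory=lambda: {
            "G00001": {"decrease": 0.9},
            "G00002": {"increase": 0.9},
            "G00003": {"no_effect": 0.9},
        }
    )
    background_presence: float = 0.1
    background_genes_per_drug: int = 30
    genes_per_phenotype: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.planted_genes) > self.gene_universe_size:
            raise ValidationError("more planted genes than the gene universe holds")
        for gene, probs in self.planted_genes.items():
            for g, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"presence probability {p} for {gene}/{g} outside [0, 1]"
                    )

    def universe(self) -> list:
        return [f"G{i:05d}" for i in range(self.gene_universe_size)]


def gen_network_tables(config: NetworkSimConfig):
    """Simulate per-drug network gene sets and phenotype annotations.

    Returns a :class:`~phagoscreen.network_meta.DrugNetworkSet`.  Planted
    genes enter each drug's network with their per-group probability;
    background genes are a uniform sample of the remaining universe.
    Phenotypes are annotated to random gene subsets and partitioned
    round-robin into clusters.
    """
    from .network_meta import DrugNetworkSet  # local import avoids a cycle

    rng = np.random.default_rng(config.seed)
    universe = config.universe()
    planted = list(config.planted_genes)
    missing = [g for g in planted if g not in set(universe)]
    if missing:
        raise ValidationError(f"planted gene(s) outside the universe: {missing}")
    background_pool = [g for g in universe if g not in set(planted)]

    drug_genes, drug_groups = {}, {}
    i = 0
    for group in sorted(config.n_drugs):
        for _ in range(config.n_drugs[group]):
            drug_id = f"D{i:04d}"
            i += 1
            genes = set(
                rng.choice(
                    background_pool,
                    size=min(config.background_genes_per_drug, len(background_pool)),
                    replace=False,
                )
            )
            for gene in planted:
                p = config.planted_genes[gene].get(group, config.background_presence)
                if rng.random() < p:
                    genes.add(gene)
            drug_genes[drug_id] = genes
            drug_groups[drug_id] = group

    phenotypes = [f"PH{j:03d}" for j in range(config.n_phenotypes)]
    gene_phenotypes: dict = {}
    for ph in phenotypes:
        annotated = rng.choice(
            universe, size=min(config.genes_per_phenotype, len(universe)), replace=False
        )
        for g in annotated:
            gene_phenotypes.setdefault(g, set()).add(ph)
    phenotype_clusters = {
        ph: f"CL{j % config.n_phenotype_clusters}" for j, ph in enumerate(phenotypes)
    }
    return DrugNetworkSet(
        drug_genes=drug_genes,
        gene_phenotypes=gene_phenotypes,
        phenotype_clusters=phenotype_clusters,
        drug_groups=drug_groups,
    )


# ---------------------------------------------------------------------------
# EHR cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfounderSpec:
    """One baseline covariate with its confounding strengths.

    ``dist`` is ("bernoulli", p) or ("normal", mean, sd);
    ``logit_exposure`` is the covariate's log-odds effect on exposure,
    ``log_hazard`` its log-hazard effect on the outcome.
    """

    name: str
    dist: tuple
    logit_exposure: float = 0.0
    log_hazard: float = 0.0

    def draw(self, rng, n: int) -> np.ndarray:
        kind = self.dist[0]
        if kind == "bernoulli":
            return (rng.random(n) < self.dist[1]).astype(float)
        if kind == "normal":
            return rng.normal(self.dist[1], self.dist[2], n)
        raise ValidationError(f"unknown covariate distribution: {kind!r}")


#: Default confounding structure: a pediatric-asthma-like indicator that
#: strongly drives exposure and raises the outcome hazard, plus a milder
#: continuous utilization score.
DEFAULT_CONFOUNDERS = (
    ConfounderSpec("asthma", ("bernoulli", 0.3), logit_exposure=2.5, log_hazard=0.7),
    ConfounderSpec("utilization", ("normal", 0.0, 1.0), logit_exposure=0.5, log_hazard=0.2),
)


@_yaml_config
@dataclass(frozen=True)
class CohortSimConfig:
    """Conditions of the simulated observational cohort.

    The planted truth is ``true_hr``, the hazard ratio of a pediatric
    exposure (ages within ``exposure_age_range``) on the adult outcome.
    Event times are exponential with hazard
    ``baseline_hazard * exp(log(true_hr)*exposed + sum(beta_j x_j))`` and are
    administratively censored ``max_followup_years`` after the index
    diagnosis.
    """

    n_patients: int = 20000
    true_hr: float = 0.75
    confounders: tuple = DEFAULT_CONFOUNDERS
    exposure_intercept: float = -2.0
    baseline_hazard: float = 0.04
    max_followup_years: float = 15.0
    exposure_age_range: tuple = (6.0, 18.0)
    diagnosis_age_min: float = 18.0
    index_age_range: tuple = (19.0, 30.0)
    outpatient_visit_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_hr <= 0:
            raise ValidationError("true_hr must be positive")
        # accept plain dicts (e.g. from YAML) for the confounder specs
        conv = tuple(
            c if isinstance(c, ConfounderSpec)
            else ConfounderSpec(
                name=c["name"],
                dist=tuple(c["dist"]),
                logit_exposure=c.get("logit_exposure", 0.0),
                log_hazard=c.get("log_hazard", 0.0),
            )
            for c in self.confounders
        )
        object.__setattr__(self, "confounders", conv)
        lo, hi = self.exposure_age_range
        if not (0 <= lo <= hi <= self.diagnosis_age_min):
            raise ValidationError(
                "exposure_age_range must lie within [0, diagnosis_age_min]"
            )
        if self.baseline_hazard < 0 or self.max_followup_years < 0:
            raise ValidationError("hazard and follow-up must be non-negative")


def _draw_cohort_core(config: CohortSimConfig, rng):
    """Covariates, exposure, and uncensored event times for n patients."""
    n = config.n_patients
    covs = {c.name: c.draw(rng, n) for c in config.confounders}
    lin_exp = config.exposure_intercept + sum(
        c.logit_exposure * covs[c.name] for c in config.confounders
    )
    exposed = (rng.random(n) < expit(lin_exp)).astype(int)
    log_h = (
        np.log(config.baseline_hazard if config.baseline_hazard > 0 else 1.0)
        + np.log(config.true_hr) * exposed
        + sum(c.log_hazard * covs[c.name] for c in config.confounders)
    )
    if config.baseline_hazard == 0:
        t_event = np.full(n, np.inf)
    else:
        t_event = rng.exponential(1.0 / np.exp(log_h))
    return covs, exposed, t_event


def simulate_survival_rows(config: CohortSimConfig) -> pd.DataFrame:
    """Reduced survival rows (time, event, exposure, covariates) directly.

    Skips the EHR event-table layer; used for Cox parameter-recovery and
    de-confounding experiments where only the survival reduction matters.
    The planted truth is attached in ``.attrs["true_hr"]``.
    """
    rng = np.random.default_rng(config.seed)
    covs, exposed, t_event = _draw_cohort_core(config, rng)
    time = np.minimum(t_event, config.max_followup_years)
    event = t_event < config.max_followup_years
    out = pd.DataFrame(
        {
            "person_id": [f"S{i:06d}" for i in range(config.n_patients)],
            "time": time,
            "event": event,
            "exposure": exposed,
            "weight": 1.0,
            **covs,
        }
    )
    out = out[out["time"] > 0].reset_index(drop=True)
    out.attrs["true_hr"] = config.true_hr
    return out


def gen_patient_table(config: CohortSimConfig):
    """Simulate EHR-like event tables with a planted hazard ratio.

    Every patient receives the adult disease diagnosis (the study population
    is diagnosed patients); exposed patients get a pediatric exposure record
    at a uniform age within the exposure window.  A qualifying outcome is an
    inpatient visit at the event time with a disease diagnosis logged 0-2
    days later (inside the 3-day billing lag the outcome rule allows);
    outpatient noise visits carry no diagnosis.  Returns
    (:class:`~phagoscreen.cohort_study.PatientTable`, truth DataFrame with
    person_id, true_exposure, true_event_time).
    """
    from .cohort_study import PatientTable  # local import avoids a cycle

    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    covs, exposed, t_event = _draw_cohort_core(config, rng)
    pids = [f"S{i:06d}" for i in range(n)]
    index_age = rng.uniform(*config.index_age_range, n)
    obs_end = index_age + config.max_followup_years

    persons = pd.DataFrame(
        {"person_id": pids, "obs_start_age": 0.0, "obs_end_age": obs_end}
    )
    lo, hi = config.exposure_age_range
    exp_rows = [
        {"person_id": pid, "concept_id": EXPOSURE_CONCEPT, "age": rng.uniform(lo, hi)}
        for pid, z in zip(pids, exposed)
        if z
    ]
    dx_rows = [
        {"person_id": pid, "concept_id": DISEASE_CONCEPT, "age": a}
        for pid, a in zip(pids, index_age)
    ]
    visit_rows = []
    for i, pid in enumerate(pids):
        if t_event[i] < config.max_followup_years:
            v_age = index_age[i] + t_event[i]
            visit_rows.append(
                {"person_id": pid, "visit_type": "inpatient", "age": v_age}
            )
            lag = rng.integers(0, 3) / DAYS_PER_YEAR
            dx_rows.append(
                {"person_id": pid, "concept_id": DISEASE_CONCEPT, "age": v_age + lag}
            )
        for _ in range(rng.poisson(config.outpatient_visit_rate)):
            visit_rows.append(
                {
                    "person_id": pid,
                    "visit_type": "outpatient",
                    "age": rng.uniform(index_age[i], obs_end[i]),
                }
            )
    covariates = pd.DataFrame({"person_id": pids, **covs})
    truth = pd.DataFrame(
        {"person_id": pids, "true_exposure": exposed, "true_event_time": t_event}
    )
    table = PatientTable(
        persons=persons,
        exposures=pd.DataFrame(exp_rows, columns=["person_id", "concept_id", "age"]),
        diagnoses=pd.DataFrame(dx_rows, columns=["person_id", "concept_id", "age"]),
        visits=pd.DataFrame(visit_rows, columns=["person_id", "visit_type", "age"]),
        covariates=covariates,
    )
    return table, truth
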