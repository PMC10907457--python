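"""Synthetic two-arm RCT generator with latent-domain structure.

The generator emulates a paediatric neurodevelopmental trial sample:
two arms of 41/42 children, age 10.5 ± 2.4 y, ~73.5% male, FSIQ 104.1 ± 18,
assessed on an ~18-variable battery at baseline and after a 91-day
medication phase.  Scores arise from a block latent-factor model: each
participant has one standard-normal ability per neurocognitive domain, and
each observed variable loads mainly on one domain, with unique noise
chosen so every standardized score has unit variance.  Day-91 latents are
an AR(1)-style carry-over of baseline (test–retest correlation ``r``) plus
fresh innovation, onto which two kinds of treatment effect can be
injected for the active arm:

* ``effect_mean`` — an additive shift on selected latent domain means,
  the classic mean treatment effect an ANCOVA should recover;
* ``effect_network`` — a within-domain coupling of the day-91 unique
  noises (a convex variance-preserving mixture with a domain-shared
  component), which raises within-domain similarity of normalized scores
  and therefore the modularity of the individual networks, without
  moving any marginal mean or variance.

Deficit structure relative to neurotypical norms is injected as a
per-variable mean shift (in oriented SD units) that the norm tables
deliberately exclude, so the norm-referenced deviance rate of each
variable is Φ(−1 − shift) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .battery import BatterySpec, Direction, default_battery, from_frame, TrialDataset
from .deficits import NormTable

#: default mapping from latent domain to the battery variables it drives
DEFAULT_DOMAINS: dict[str, list[str]] = {
    "processing_speed": ["bs_rt", "bs_sd"],
    "response_inhibition": ["gng_rt", "gng_false_alarms"],
    "visual_attention": ["ssv1_rt", "ssv2_rt", "ssv1_errors", "ssv2_errors"],
    "auditory_attention": ["ssa1_rt", "ssa2_rt", "ssa1_errors", "ssa2_errors"],
    "verbal_working_memory": ["wisc_ds"],
    "visual_working_memory": ["wnv_ss"],
    "verbal_memory": ["ravlt_imprinting", "ravlt_recall"],
    "visual_memory": ["rvdlt_imprinting", "rvdlt_recall"],
}

#: natural-scale neurotypical mean, SD and oldest age covered by norms
DEFAULT_SCALES: dict[str, tuple[float, float, float]] = {
    "bs_rt": (520.0, 110.0, 16.0),
    "bs_sd": (140.0, 60.0, 16.0),
    "gng_rt": (480.0, 90.0, 13.0),
    "gng_false_alarms": (6.0, 4.0, 13.0),
    "ssv1_rt": (550.0, 120.0, 13.0),
    "ssv2_rt": (800.0, 200.0, 13.0),
    "ssv1_errors": (3.0, 2.5, 13.0),
    "ssv2_errors": (8.0, 5.0, 13.0),
    "ssa1_rt": (600.0, 130.0, 13.0),
    "ssa2_rt": (850.0, 210.0, 13.0),
    "ssa1_errors": (3.5, 2.5, 13.0),
    "ssa2_errors": (9.0, 5.0, 13.0),
    "wisc_ds": (10.0, 3.0, 16.0),
    "wnv_ss": (10.0, 3.0, 13.0),
    "ravlt_imprinting": (45.0, 9.0, 13.0),
    "ravlt_recall": (9.0, 3.0, 13.0),
    "rvdlt_imprinting": (40.0, 9.0, 13.0),
    "rvdlt_recall": (8.0, 3.0, 13.0),
}

#: cohort mean shift vs norms, oriented SD units (negative = impaired).
#: Heterogeneous by design: severe inhibition deficits, moderate memory
#: deficits, and *faster* (but error-prone) go/no-go responding.
DEFAULT_DEFICIT_SHIFT: dict[str, float] = {
    "bs_rt": 0.44,
    "bs_sd": -0.20,
    "gng_rt": 0.88,
    "gng_false_alarms": -1.05,
    "ssv1_rt": -0.20,
    "ssv2_rt": -0.30,
    "ssv1_errors": -0.25,
    "ssv2_errors": -0.35,
    "ssa1_rt": -0.20,
    "ssa2_rt": -0.30,
    "ssa1_errors": -0.30,
    "ssa2_errors": -0.61,
    "wisc_ds": -0.35,
    "wnv_ss": -0.25,
    "ravlt_imprinting": -0.30,
    "ravlt_recall": -0.46,
    "rvdlt_imprinting": -0.30,
    "rvdlt_recall": -0.35,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic trial; the defaults are the study conditions."""

    seed: int
    n_placebo: int = 41
    n_active: int = 42
    age_mean: float = 10.5
    age_sd: float = 2.4
    male_fraction: float = 0.735
    iq_mean: float = 104.1
    iq_sd: float = 18.0
    loading: float = 0.8
    loading_matrix: Optional[np.ndarray] = None  # (n_raw_vars, n_domains)
    test_retest_r: float = 0.7
    deficit_shift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DEFICIT_SHIFT))
    effect_mean: dict[str, float] = field(default_factory=dict)
    effect_network: float = 1.0
    missing_rate: float = 0.01
    domains: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_DOMAINS.items()})

    def __post_init__(self) -> None:
        if self.n_placebo < 1 or self.n_active < 1:
            raise ValueError("need at least one participant per arm")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must be in [0, 1]")
        if not (0.0 <= self.test_retest_r <= 1.0):
            raise ValueError("test_retest_r must be in [0, 1]")
        if self.age_sd <= 0 or self.iq_sd <= 0:
            raise ValueError("all SDs must be positive")
        if self.effect_network < 1.0:
            raise ValueError("effect_network must be >= 1 (1 = no coupling)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        unknown = set(self.effect_mean) - set(self.domains)
        if unknown:
            raise ValueError(f"effect_mean names unknown domains: {sorted(unknown)}")

    @property
    def domain_names(self) -> list[str]:
        return list(self.domains)

    @property
    def n_domains(self) -> int:
        return len(self.domains)


@dataclass
class GroundTruth:
    """Generating quantities returned alongside the data for recovery tests."""

    latent_baseline: pd.DataFrame  # id x domain
    latent_d91: pd.DataFrame
    loading_matrix: np.ndarray  # raw vars x domains
    unique_sd: np.ndarray  # per raw var
    variables: list[str]
    domain_names: list[str]
    effect_mean: dict[str, float]
    effect_network: float


def _build_loading_matrix(config: SimConfig, raw_names: list[str]) -> np.ndarray:
    if config.loading_matrix is not None:
        L = np.asarray(config.loading_matrix, dtype=float)
        if L.shape != (len(raw_names), config.n_domains):
            raise ValueError(
                f"loading_matrix shape {L.shape} != ({len(raw_names)}, {config.n_domains})"
            )
        return L
    L = np.zeros((len(raw_names), config.n_domains))
    for j, dom in enumerate(config.domain_names):
        for v in config.domains[dom]:
            if v not in raw_names:
                raise ValueError(f"domain {dom!r} references unknown variable {v!r}")
            L[raw_names.index(v), j] = config.loading
    return L


def inject_network_effect(
    innovations: np.ndarray,
    domain_index: np.ndarray,
    active_mask: np.ndarray,
    effect_network: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Couple active-arm unique innovations within each latent domain.

    Each active-arm innovation u is replaced by
    ``sqrt(1-m)*u + sqrt(m)*eta_d`` with a per-participant, per-domain
    shared draw ``eta_d`` and mixing weight ``m = 1 - 1/effect_network``;
    the square-root mixture preserves the unit marginal variance exactly.
    ``effect_network = 1`` is the identity.
    """
    m = 1.0 - 1.0 / float(effect_network)
    if m == 0.0:
        return innovations
    n, p = innovations.shape
    n_dom = int(domain_index.max()) + 1
    eta = rng.standard_normal((n, n_dom))
    mixed = np.sqrt(1.0 - m) * innovations + np.sqrt(m) * eta[:, domain_index]
    out = innovations.copy()
    out[active_mask] = mixed[active_mask]
    return out


def generate_trial(
    config: SimConfig, spec: Optional[BatterySpec] = None
) -> tuple[TrialDataset, GroundTruth]:
    """Simulate one trial; deterministic given ``config.seed``.

    Returns the (unoriented, natural-scale) dataset plus the ground truth.
    """
    spec = spec or default_battery()
    raw = spec.raw_names
    rng = np.random.default_rng(config.seed)
    n = config.n_placebo + config.n_active

    L = _build_loading_matrix(config, raw)
    psi = 1.0 - (L**2).sum(axis=1)
    if np.any(psi < -1e-12):
        raise ValueError("implied covariance not positive definite (loadings too large)")
    psi = np.clip(psi, 0.0, None)  # psi == 0 is the noiseless boundary
    unique_sd = np.sqrt(psi)

    ids = [f"P{i + 1:03d}" for i in range(n)]
    arm = np.array(["placebo"] * config.n_placebo + ["active"] * config.n_active)
    arm = arm[rng.permutation(n)]
    active = arm == "active"
    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    age = rng.normal(config.age_mean, config.age_sd, n)
    iq = rng.normal(config.iq_mean, config.iq_sd, n)

    d = config.n_domains
    a0 = rng.standard_normal((n, d))
    innov = rng.standard_normal((n, d))
    r = config.test_retest_r
    a1 = r * a0 + np.sqrt(1.0 - r**2) * innov
    effect_vec = np.array([config.effect_mean.get(dom, 0.0) for dom in config.domain_names])
    a1 = a1 + np.outer(active.astype(float), effect_vec)

    domain_index = np.argmax(np.abs(L), axis=1)
    u0 = rng.standard_normal((n, len(raw)))
    u1 = rng.standard_normal((n, len(raw)))
    u1 = inject_network_effect(u1, domain_index, active, config.effect_network, rng)

    shift = np.array([config.deficit_shift.get(v, 0.0) for v in raw])
    s0 = a0 @ L.T + u0 * unique_sd + shift
    s1 = a1 @ L.T + u1 * unique_sd + shift

    rows = []
    for t, s in (("baseline", s0), ("d91", s1)):
        mask = rng.random(s.shape) < config.missing_rate
        for i in range(n):
            row = {"id": ids[i], "timepoint": t, "arm": arm[i], "sex": sex[i],
                   "age": round(float(age[i]), 2), "iq": round(float(iq[i]), 1)}
            for j, v in enumerate(raw):
                if mask[i, j]:
                    row[v] = np.nan
                    continue
                mu, sd, _ = DEFAULT_SCALES.get(v, (0.0, 1.0, np.inf))
                oriented = s[i, j]
                if spec.variable(v).direction == Direction.lower_better:
                    row[v] = mu - sd * oriented
                else:
                    row[v] = mu + sd * oriented
            rows.append(row)
    frame = pd.DataFrame(rows)
    data = from_frame(frame, spec)

    truth = GroundTruth(
        latent_baseline=pd.DataFrame(a0, index=pd.Index(ids, name="id"), columns=config.domain_names),
        latent_d91=pd.DataFrame(a1, index=pd.Index(ids, name="id"), columns=config.domain_names),
        loading_matrix=L,
        unique_sd=unique_sd,
        variables=raw,
        domain_names=config.domain_names,
        effect_mean=dict(config.effect_mean),
        effect_network=config.effect_network,
    )
    return data, truth


def generate_norms(config: SimConfig, spec: Optional[BatterySpec] = None) -> NormTable:
    """Neurotypical norm table: the generating distribution *without* the
    cohort's deficit shifts, broken into age bands.  Variables whose norms
    stop at age 13 leave older participants un-normable, reproducing the
    per-variable n variation a real battery shows.
    """
    spec = spec or default_battery()
    rows = []
    for v in spec.norm_names:
        mu, sd, max_age = DEFAULT_SCALES.get(v, (0.0, 1.0, 16.0))
        edges = [6.0, 8.0, 10.0, 13.0, 16.0]
        edges = [e for e in edges if e <= max_age] + [max_age]
        edges = sorted(set(edges))
        for lo, hi in zip(edges[:-1], edges[1:]):
            rows.append({"variable": v, "age_min": lo, "age_max": hi, "mean": mu, "sd": sd})
    return NormTable(pd.DataFrame(rows))
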