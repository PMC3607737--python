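"""Synthetic OKS/EQ-5D cohorts with realistic joint structure.

No patient-level data ship with this package, so estimation and evaluation
paths are exercised on simulated cohorts built from a one-factor latent
health trait:

* each patient carries a latent knee-health trait; repeated questionnaires
  from the same patient share it (inducing within-patient clustering), and
  surgery shifts its mean upward;
* each OKS item is an ordered-categorical indicator of the trait with four
  strictly increasing thresholds, calibrated so that the marginal item
  means and SDs reproduce the published pre-operative summary statistics of
  the large UK knee-replacement cohorts the mapping models were developed
  on (pre-operative total OKS ~18.6, post-operative ~33.8);
* EQ-5D responses are drawn either from the packaged published response
  mapping model given the simulated OKS dummies (``published_model`` mode,
  which makes parameter-recovery experiments possible because the
  generating coefficients are known) or from ordered thresholds on the same
  latent trait (``latent_thresholds`` mode).

The single factor mirrors the strong first principal component seen in real
OKS/EQ-5D data; what the generator does *not* emulate is multi-dimensional
symptom structure, secular trends, or dataset-specific coefficient shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import norm

from .oks import ITEM_COLUMNS, ITEMS, dummy_design
from .tariff import EQ5D_COLUMNS, EQ5DState, TariffValueSet, load_tariff

__all__ = [
    "CohortParams",
    "generate_cohort",
    "inject_missingness",
    "PRESETS",
]

# Published marginal summaries used as calibration targets: pre-operative
# mean (SD) of each OKS item and the pre-operative mean total score, from
# the national PROMs knee-replacement cohort the mapping was estimated on.
PREOP_ITEM_MEAN_SD = {
    "pain": (0.55, 0.66),
    "washing": (2.79, 1.03),
    "transport": (2.06, 0.86),
    "walking": (1.99, 1.14),
    "standing": (1.64, 0.82),
    "limping": (0.88, 0.99),
    "kneeling": (0.79, 0.89),
    "night_pain": (1.26, 1.19),
    "work": (1.39, 0.88),
    "instability": (1.85, 1.18),
    "shopping": (1.67, 1.23),
    "stairs": (1.71, 0.92),
}
PREOP_TOTAL_MEAN = 18.59
POSTOP_TOTAL_MEAN = 33.79

# Pre-operative EQ-5D level-2 / level-3 proportions per domain (same
# cohort), used only by the latent_thresholds EQ-5D mode.
PREOP_EQ5D_PROPORTIONS = {
    "mobility": (0.934, 0.004),
    "self_care": (0.328, 0.010),
    "usual_activities": (0.762, 0.152),
    "pain_discomfort": (0.584, 0.406),
    "anxiety_depression": (0.352, 0.046),
}


@dataclass
class CohortParams:
    """Generator configuration.

    ``questionnaires_per_patient`` maps a questionnaire count to its
    probability.  ``phase_pattern`` is ``preop`` (every questionnaire
    pre-operative), ``postop``, or ``mixed`` (first questionnaire
    pre-operative, the rest post-operative).  The latent trait has unit
    marginal variance split between the patient level (``icc``) and the
    questionnaire level; ``sigma_item`` adds item-specific noise.
    """

    n_patients: int = 1000
    questionnaires_per_patient: dict = field(default_factory=lambda: {1: 1.0})
    phase_pattern: str = "mixed"
    icc: float = 0.75
    sigma_item: float = 0.6
    eq5d_mode: str = "published_model"
    sigma_domain: float = 0.6
    tariff: TariffValueSet | None = None

    def __post_init__(self) -> None:
        if not 0 < self.icc < 1:
            raise ValueError("icc must be in (0, 1)")
        if self.phase_pattern not in ("preop", "postop", "mixed"):
            raise ValueError(f"unknown phase_pattern {self.phase_pattern!r}")
        if self.eq5d_mode not in ("published_model", "latent_thresholds"):
            raise ValueError(f"unknown eq5d_mode {self.eq5d_mode!r}")
        probs = np.array(list(self.questionnaires_per_patient.values()), float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("questionnaires_per_patient must be a distribution")


def PRESETS(name: str, n_patients: int = 1000, **overrides) -> CohortParams:
    """Named study-condition presets.

    ``preop_like`` / ``postop_like`` give one questionnaire per patient at
    the corresponding phase, matching the published phase-specific summary
    statistics; ``mixed`` gives each patient a pre-operative questionnaire
    and one or two post-operative follow-ups.
    """
    if name == "preop_like":
        base = dict(phase_pattern="preop", questionnaires_per_patient={1: 1.0})
    elif name == "postop_like":
        base = dict(phase_pattern="postop", questionnaires_per_patient={1: 1.0})
    elif name == "mixed":
        base = dict(
            phase_pattern="mixed",
            questionnaires_per_patient={2: 0.7, 3: 0.3},
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return CohortParams(n_patients=n_patients, **base)


# -- threshold calibration -------------------------------------------------


def _item_moments(loc: float, spread: float, sd_latent: float) -> tuple[float, float]:
    """Mean and SD of an item score with thresholds loc + spread*(m - 1.5)."""
    c = loc + spread * (np.arange(4) - 1.5)
    p_exceed = norm.sf(c / sd_latent)  # P(latent > c_m) at phase mean 0
    mean = p_exceed.sum()
    # score^2 expands over pairs of exceedance indicators
    second = sum(
        norm.sf(max(c[m], c[k]) / sd_latent) for m in range(4) for k in range(4)
    )
    var = max(second - mean**2, 1e-12)
    return mean, float(np.sqrt(var))


def _calibrate_item(target_mean: float, target_sd: float, sd_latent: float):
    def resid(x):
        loc, log_spread = x
        mean, sd = _item_moments(loc, np.exp(log_spread), sd_latent)
        return [mean - target_mean, sd - target_sd]

    sol = least_squares(resid, x0=[0.0, 0.0], xtol=1e-12, ftol=1e-12)
    loc, spread = sol.x[0], float(np.exp(sol.x[1]))
    c = loc + spread * (np.arange(4) - 1.5)
    if not np.all(np.diff(c) > 0):
        raise ValueError("calibrated item thresholds are not increasing")
    return c


def _calibrate_thresholds(sd_latent: float) -> dict[str, np.ndarray]:
    return {
        item: _calibrate_item(mean, sd, sd_latent)
        for item, (mean, sd) in PREOP_ITEM_MEAN_SD.items()
    }


def _postop_shift(thresholds: dict, sd_latent: float) -> float:
    """Latent mean shift making the expected post-operative total OKS match."""

    def total_mean(mu):
        return sum(
            norm.sf((c - mu) / sd_latent).sum() for c in thresholds.values()
        )

    return brentq(lambda mu: total_mean(mu) - POSTOP_TOTAL_MEAN, 0.0, 6.0)


def _calibrate_domain_thresholds(sd_latent: float) -> dict[str, np.ndarray]:
    # worse latent health -> higher EQ-5D level; two decreasing cutpoints on
    # the latent scale: level 3 below t3, level 2 in [t3, t2)
    out = {}
    for domain, (p2, p3) in PREOP_EQ5D_PROPORTIONS.items():
        t2 = norm.ppf(p2 + p3) * sd_latent  # P(latent < t2) = P(level >= 2)
        t3 = norm.ppf(p3) * sd_latent
        out[domain] = np.array([t2, t3])
    return out


# -- generation ------------------------------------------------------------


def generate_cohort(
    params: CohortParams | None = None, seed: int | None = None, **preset_kwargs
) -> pd.DataFrame:
    """Simulate a questionnaire-level cohort table.

    Columns: ``patient_id``, ``timepoint`` (``preop`` or ``postop_<k>``),
    ``phase``, the 12 ``oks_*`` item scores, the 5 ``eq_*`` EQ-5D levels and
    the tariff ``utility`` of the simulated EQ-5D state.  Deterministic
    given ``seed``.
    """
    if params is None:
        params = CohortParams(**preset_kwargs)
    rng = np.random.default_rng(seed)
    tariff = params.tariff if params.tariff is not None else load_tariff()

    sd_b = np.sqrt(params.icc)
    sd_w = np.sqrt(1.0 - params.icc)
    sd_latent = np.sqrt(1.0 + params.sigma_item**2)
    thresholds = _calibrate_thresholds(sd_latent)
    mu_post = _postop_shift(thresholds, sd_latent)

    counts = np.array(list(params.questionnaires_per_patient.keys()))
    probs = np.array(list(params.questionnaires_per_patient.values()))
    n_quest = rng.choice(counts, size=params.n_patients, p=probs)
    patient_trait = sd_b * rng.standard_normal(params.n_patients)

    rows_patient, rows_phase, rows_timepoint, rows_latent = [], [], [], []
    for i in range(params.n_patients):
        for j in range(n_quest[i]):
            if params.phase_pattern == "preop":
                phase = "preop"
            elif params.phase_pattern == "postop":
                phase = "postop"
            else:
                phase = "preop" if j == 0 else "postop"
            mu = 0.0 if phase == "preop" else mu_post
            rows_patient.append(i + 1)
            rows_phase.append(phase)
            rows_timepoint.append(
                "preop" if phase == "preop" else f"postop_{j if params.phase_pattern == 'mixed' else j + 1}"
            )
            rows_latent.append(mu + patient_trait[i] + sd_w * rng.standard_normal())

    n = len(rows_latent)
    latent = np.asarray(rows_latent)
    data = {
        "patient_id": rows_patient,
        "timepoint": rows_timepoint,
        "phase": rows_phase,
    }
    for item, column in zip(ITEMS, ITEM_COLUMNS):
        v = latent + params.sigma_item * rng.standard_normal(n)
        data[column] = (v[:, None] > thresholds[item][None, :]).sum(axis=1)
    cohort = pd.DataFrame(data)

    if params.eq5d_mode == "published_model":
        from .response_mapping import load_published_model

        model = load_published_model()
        dists = model.predict_distributions(dummy_design(cohort).to_numpy())
        u = rng.random((n, 5))
        cum = np.cumsum(dists, axis=2)
        levels = 1 + (u[:, :, None] > cum).sum(axis=2)
    else:
        dom_thresholds = _calibrate_domain_thresholds(
            np.sqrt(1.0 + params.sigma_domain**2)
        )
        levels = np.empty((n, 5), dtype=int)
        for d, domain in enumerate(dom_thresholds):
            v = latent + params.sigma_domain * rng.standard_normal(n)
            t2, t3 = dom_thresholds[domain]
            levels[:, d] = np.where(v < t3, 3, np.where(v < t2, 2, 1))
    for d, col in enumerate(EQ5D_COLUMNS):
        cohort[col] = levels[:, d]

    cache: dict[tuple, float] = {}
    utilities = np.empty(n)
    for i, row in enumerate(map(tuple, levels)):
        if row not in cache:
            cache[row] = tariff.utility(EQ5DState.from_levels(row))
        utilities[i] = cache[row]
    cohort["utility"] = utilities
    return cohort


def inject_missingness(
    cohort: pd.DataFrame,
    rate: float,
    seed: int | None = None,
    columns=ITEM_COLUMNS,
) -> pd.DataFrame:
    """Blank item cells completely at random at the given rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = cohort.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    for col in columns:
        mask = rng.random(len(out)) < rate
        out[col] = out[col].astype(float).where(~mask, np.nan)
    return out
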