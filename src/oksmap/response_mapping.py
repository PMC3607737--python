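"""Response mapping: predict EQ-5D domain responses from OKS, then value them.

Rather than regressing utility on OKS directly, response mapping fits one
model per EQ-5D domain predicting the probability that a respondent selects
level 1, 2 or 3 on that domain given their OKS item responses.  A predicted
utility is then the *expected value* of the tariff over the implied
distribution of the 243 health states (domains treated as independent given
the OKS covariates, consistent with fitting each domain separately).

Two links are supported:

``multinomial``
    one multinomial logit per domain with level 1 as the base category, so
    the coefficients are L2-vs-L1 and L3-vs-L1 log-odds contrasts.  The
    published model shipped with this package (see
    :func:`load_published_model`) has this form: 48 OKS level dummies plus
    an intercept per contrast.
``ordinal``
    a proportional-odds (ordered logit) model per domain, estimation only —
    no published ordinal coefficients exist.

The expected-value construction is implemented twice: a 243-state
enumeration (the reference) and an algebraically equivalent closed-form
decomposition over the additive tariff terms (the fast path).  A Monte
Carlo valuation is also provided; it converges to the expected value at the
usual root-n rate and exists mainly as a diagnostic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from statsmodels.discrete.discrete_model import MNLogit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .oks import DUMMY_COLUMNS, dummy_design
from .tariff import (
    DOMAINS,
    EQ5D_COLUMNS,
    EQ5DState,
    TariffValueSet,
    enumerate_states,
    state_utilities,
)
from .tariff import _packaged_data

__all__ = [
    "DomainCoefficientBlock",
    "OrdinalDomainBlock",
    "ResponseMappingModel",
    "predict_domain_distributions",
    "expected_utility",
    "monte_carlo_utility",
    "highest_probability_assignment",
    "fit_response_mapping",
    "load_published_model",
    "predict_expected_utilities",
    "PUBLISHED_COEFFICIENTS_SHA256",
]

CONTRASTS = ("L2vsL1", "L3vsL1")

#: Checksum of the packaged published-model coefficient file.
PUBLISHED_COEFFICIENTS_SHA256 = (
    "cb5b5409cde3cc54786c811134604d1f10a7712ea8da68d6d0a96f090a478a83"
)

# Spot-check anchors verified every time the published model is loaded:
# (question, level, domain, contrast) -> coefficient.
_PUBLISHED_ANCHORS = {
    ("pain", 0, "pain_discomfort", "L3vsL1"): 3.729,
    ("shopping", 0, "mobility", "L2vsL1"): 1.837,
    ("washing", 1, "self_care", "L2vsL1"): 3.855,
    ("constant", None, "mobility", "L2vsL1"): -2.444,
    ("constant", None, "mobility", "L3vsL1"): -10.015,
}


class CoefficientIntegrityError(RuntimeError):
    """The packaged coefficient file does not match its recorded checksum."""


@dataclass
class DomainCoefficientBlock:
    """Multinomial-logit coefficients for one EQ-5D domain.

    ``coef`` has shape (2, p): row 0 the L2-vs-L1 contrast, row 1 L3-vs-L1,
    over ``feature_names``; ``intercept`` holds the two constants.
    """

    domain: str
    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: np.ndarray
    se: np.ndarray | None = None
    intercept_se: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.intercept = np.asarray(self.intercept, dtype=float)
        if self.coef.shape != (2, len(self.feature_names)):
            raise ValueError(
                f"{self.domain}: coef shape {self.coef.shape} does not match "
                f"(2, {len(self.feature_names)})"
            )
        if self.intercept.shape != (2,):
            raise ValueError(f"{self.domain}: need exactly 2 intercepts")

    def probabilities(self, design: np.ndarray) -> np.ndarray:
        """Level probabilities (n, 3) for a design matrix (n, p)."""
        eta = design @ self.coef.T + self.intercept  # (n, 2)
        # softmax over (0, eta2, eta3), guarded against overflow
        z = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)


@dataclass
class OrdinalDomainBlock:
    """Proportional-odds (ordered logit) parameters for one EQ-5D domain.

    P(level <= k) = logistic(threshold_k - x.beta); two increasing
    thresholds separate the three levels.
    """

    domain: str
    feature_names: tuple[str, ...]
    beta: np.ndarray
    thresholds: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (2,):
            raise ValueError(f"{self.domain}: need exactly 2 thresholds")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ValueError(f"{self.domain}: thresholds must be increasing")

    def probabilities(self, design: np.ndarray) -> np.ndarray:
        xb = design @ self.beta
        with np.errstate(over="ignore"):
            cdf1 = 1.0 / (1.0 + np.exp(-(self.thresholds[0] - xb)))
            cdf2 = 1.0 / (1.0 + np.exp(-(self.thresholds[1] - xb)))
        return np.column_stack([cdf1, cdf2 - cdf1, 1.0 - cdf2])


@dataclass
class ResponseMappingModel:
    """Five per-domain response models plus provenance metadata."""

    blocks: dict
    link: str = "multinomial"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [d for d in DOMAINS if d not in self.blocks]
        if missing:
            raise ValueError(f"model missing domain blocks: {missing}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.blocks[DOMAINS[0]].feature_names

    def predict_distributions(self, design) -> np.ndarray:
        """Per-domain level probabilities, shape (n, 5, 3)."""
        design = np.atleast_2d(np.asarray(design, dtype=float))
        p = len(self.feature_names)
        if design.shape[1] != p:
            raise ValueError(
                f"design has {design.shape[1]} columns; model expects {p}"
            )
        return np.stack(
            [self.blocks[d].probabilities(design) for d in DOMAINS], axis=1
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format coefficient table (multinomial link only)."""
        if self.link != "multinomial":
            raise NotImplementedError("only multinomial blocks serialize to CSV")
        rows = []
        for domain in DOMAINS:
            block = self.blocks[domain]
            for c, contrast in enumerate(CONTRASTS):
                for j, name in enumerate(block.feature_names):
                    item, lvl = name.rsplit("_", 1)
                    rows.append(
                        dict(
                            question=item,
                            level=int(lvl),
                            eq5d_domain=domain,
                            contrast=contrast,
                            coefficient=block.coef[c, j],
                            se=None if block.se is None else block.se[c, j],
                        )
                    )
                rows.append(
                    dict(
                        question="constant",
                        level=None,
                        eq5d_domain=domain,
                        contrast=contrast,
                        coefficient=block.intercept[c],
                        se=None
                        if block.intercept_se is None
                        else block.intercept_se[c],
                    )
                )
        return pd.DataFrame(rows)


def predict_domain_distributions(model: ResponseMappingModel, design) -> np.ndarray:
    """Functional alias for :meth:`ResponseMappingModel.predict_distributions`."""
    return model.predict_distributions(design)


def _validate_distributions(dists: np.ndarray) -> np.ndarray:
    dists = np.asarray(dists, dtype=float)
    if dists.ndim == 2:
        dists = dists[None, :, :]
    if dists.ndim != 3 or dists.shape[1:] != (5, 3):
        raise ValueError(f"expected distributions of shape (n, 5, 3), got {dists.shape}")
    if np.any(dists < -1e-12) or np.any(np.abs(dists.sum(axis=2) - 1.0) > 1e-9):
        raise ValueError("domain distributions must be probabilities summing to 1")
    return dists


_STATE_LEVEL_IDX = np.array([s.levels for s in enumerate_states()]) - 1  # (243, 5)


def expected_utility(
    dists, tariff: TariffValueSet, method: str = "decomposition"
) -> np.ndarray | float:
    """Expected tariff utility of independent per-domain level distributions.

    ``enumeration`` sums utility x product-probability over all 243 states;
    ``decomposition`` exploits the additive tariff:

        E[U] = full_health
               - any_problem * (1 - prod_d P(L1_d))
               - sum_d [P(L2_d) dec_d(2) + P(L3_d) dec_d(3)]
               - n3 * (1 - prod_d (1 - P(L3_d)))

    The two agree to ~1e-15; enumeration is kept as the reference
    implementation.
    """
    squeeze = np.asarray(dists).ndim == 2
    dists = _validate_distributions(dists)
    if method == "enumeration":
        probs = np.ones((dists.shape[0], 243))
        for d in range(5):
            probs *= dists[:, d, :][:, _STATE_LEVEL_IDX[:, d]]
        out = probs @ state_utilities(tariff)
    elif method == "decomposition":
        p1, p2, p3 = dists[:, :, 0], dists[:, :, 1], dists[:, :, 2]
        dec = np.array([tariff.decrements[d] for d in DOMAINS])  # (5, 2)
        out = (
            tariff.full_health
            - tariff.any_problem * (1.0 - p1.prod(axis=1))
            - (p2 * dec[:, 0] + p3 * dec[:, 1]).sum(axis=1)
            - tariff.n3 * (1.0 - (1.0 - p3).prod(axis=1))
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(out[0]) if squeeze else out


def monte_carlo_utility(
    dists, tariff: TariffValueSet, n_draws: int = 10_000, seed: int | None = None
) -> np.ndarray | float:
    """Mean tariff utility over ``n_draws`` sampled states per record."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    squeeze = np.asarray(dists).ndim == 2
    dists = _validate_distributions(dists)
    rng = np.random.default_rng(seed)
    n = dists.shape[0]
    u = rng.random((n, 5, n_draws))
    cum = np.cumsum(dists, axis=2)
    # sampled level index 0..2 per record/domain/draw
    levels = (u[:, :, None, :] > cum[:, :, :, None]).sum(axis=2)
    dec = np.array([tariff.decrements[d] for d in DOMAINS])  # (5, 2)
    dec_draw = np.zeros_like(u)
    for lvl in (1, 2):
        for d in range(5):
            dec_draw[:, d][levels[:, d] == lvl] = dec[d, lvl - 1]
    any_problem = (levels > 0).any(axis=1)
    any_n3 = (levels == 2).any(axis=1)
    utilities = (
        tariff.full_health
        - tariff.any_problem * any_problem
        - dec_draw.sum(axis=1)
        - tariff.n3 * any_n3
    )
    out = utilities.mean(axis=1)
    return float(out[0]) if squeeze else out


def highest_probability_assignment(dists) -> EQ5DState | list[EQ5DState]:
    """Modal state: per domain, the most probable level (ties -> healthier).

    This is the "highest probability" construction, known to be biased — in
    particular it under-predicts severe problems — and is provided for
    diagnostics only; use :func:`expected_utility` for predictions.
    """
    squeeze = np.asarray(dists).ndim == 2
    dists = _validate_distributions(dists)
    # argmax returns the first maximum, i.e. the lower (healthier) level on ties
    levels = dists.argmax(axis=2) + 1
    states = [EQ5DState.from_levels(row) for row in levels]
    return states[0] if squeeze else states


class DegenerateOutcomeError(ValueError):
    """An EQ-5D domain has an empty response level in the estimation data."""


def fit_response_mapping(
    data: pd.DataFrame,
    link: str = "multinomial",
    cluster_col: str | None = None,
    maxiter: int = 500,
    coding: str = "dummies48",
) -> ResponseMappingModel:
    """Fit the five per-domain response models by maximum likelihood.

    ``data`` must hold complete OKS items plus observed EQ-5D levels in the
    ``eq_mo .. eq_ad`` columns.  With ``cluster_col`` set, standard errors
    are cluster-robust, grouping repeated questionnaires within patient
    (point estimates are unaffected).  Domains whose data lack an entire
    response level raise :class:`DegenerateOutcomeError` naming the level.
    """
    if link not in ("multinomial", "ordinal"):
        raise ValueError(f"unknown link {link!r}")
    from .oks import design_matrix

    design = design_matrix(data, coding)
    X = design.to_numpy()
    groups = None
    if cluster_col is not None:
        if cluster_col not in data.columns:
            raise ValueError(f"cluster column {cluster_col!r} not in data")
        groups = pd.factorize(data[cluster_col])[0]

    blocks: dict = {}
    diagnostics: dict = {}
    for domain, col in zip(DOMAINS, EQ5D_COLUMNS):
        if col not in data.columns:
            raise ValueError(f"missing observed EQ-5D column {col!r}")
        y = data[col].to_numpy(dtype=int)
        present = set(np.unique(y))
        absent = sorted({1, 2, 3} - present)
        if absent or not present <= {1, 2, 3}:
            raise DegenerateOutcomeError(
                f"domain {domain!r}: no observations at level(s) {absent}"
                if absent
                else f"domain {domain!r}: levels outside 1-3 present"
            )
        if link == "multinomial":
            blocks[domain], diagnostics[domain] = _fit_mnlogit_domain(
                domain, X, y, tuple(design.columns), groups, maxiter
            )
        else:
            blocks[domain], diagnostics[domain] = _fit_ologit_domain(
                domain, X, y, tuple(design.columns), maxiter
            )
    return ResponseMappingModel(
        blocks=blocks,
        link=link,
        metadata={
            "source": "fit_response_mapping",
            "n_obs": int(len(data)),
            "cluster_col": cluster_col,
            "diagnostics": diagnostics,
        },
    )


def _fit_mnlogit_domain(domain, X, y, names, groups, maxiter):
    exog = np.column_stack([np.ones(len(y)), X])
    model = MNLogit(y, exog)
    cov_kwargs = {}
    if groups is not None:
        cov_kwargs = dict(cov_type="cluster", cov_kwds={"groups": groups})
    # lbfgs is robust to the quasi-separation that sparse severe-problem
    # levels produce; newton can silently diverge to NaN there
    res = model.fit(method="lbfgs", maxiter=4 * maxiter, disp=False, **cov_kwargs)
    converged = bool(res.mle_retvals.get("converged", True))
    if not np.isfinite(np.asarray(res.params)).all():
        res = model.fit(method="newton", maxiter=maxiter, disp=False, **cov_kwargs)
        converged = bool(res.mle_retvals.get("converged", True))
        if not np.isfinite(np.asarray(res.params)).all():
            raise RuntimeError(
                f"domain {domain!r}: multinomial fit diverged (separation?)"
            )
    params = np.asarray(res.params)  # (p+1, 2): columns are L2, L3 vs L1
    try:
        with np.errstate(invalid="ignore"):
            se = np.asarray(res.bse)
    except ValueError:  # singular Hessian: no covariance available
        se = np.full_like(params, np.nan)
    block = DomainCoefficientBlock(
        domain=domain,
        feature_names=names,
        coef=params[1:, :].T,
        intercept=params[0, :],
        se=se[1:, :].T,
        intercept_se=se[0, :],
        converged=converged,
    )
    return block, {"converged": converged, "llf": float(res.llf)}


def _fit_ologit_domain(domain, X, y, names, maxiter):
    model = OrderedModel(y, X, distr="logit")
    res = model.fit(method="lbfgs", maxiter=4 * maxiter, disp=False)
    converged = bool(res.mle_retvals.get("converged", True))
    if not np.isfinite(np.asarray(res.params)).all():
        res = model.fit(method="bfgs", maxiter=maxiter, disp=False)
        converged = bool(res.mle_retvals.get("converged", True))
        if not np.isfinite(np.asarray(res.params)).all():
            raise RuntimeError(f"domain {domain!r}: ordinal fit diverged")
    params = np.asarray(res.params)
    k = X.shape[1]
    beta = params[:k]
    # statsmodels parameterizes the second cutpoint as log-increment
    thresholds = model.transform_threshold_params(params)[1:-1]
    block = OrdinalDomainBlock(
        domain=domain,
        feature_names=names,
        beta=beta,
        thresholds=np.asarray(thresholds),
        converged=converged,
    )
    return block, {"converged": converged, "llf": float(res.llf)}


def load_published_model(path=None, verify_checksum: bool = True) -> ResponseMappingModel:
    """Load the published OKS->EQ-5D multinomial response-mapping model.

    The packaged file transcribes the final published coefficient table at
    its printed precision (three decimals), so predictions are close — but
    not bit-identical — to the authors' full-precision model.  The file
    checksum and several anchor coefficients are verified on every load.
    """
    if path is None:
        path = _packaged_data("response_mapping_coefficients.csv")
        if verify_checksum:
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            if digest != PUBLISHED_COEFFICIENTS_SHA256:
                raise CoefficientIntegrityError(
                    f"coefficient file checksum mismatch: {digest}"
                )
    table = pd.read_csv(path)
    blocks = {}
    for domain in DOMAINS:
        sub = table[table["eq5d_domain"] == domain]
        coef = np.zeros((2, 48))
        se = np.zeros((2, 48))
        intercept = np.zeros(2)
        intercept_se = np.zeros(2)
        for c, contrast in enumerate(CONTRASTS):
            rows = sub[sub["contrast"] == contrast].set_index(
                sub.loc[sub["contrast"] == contrast].apply(
                    lambda r: "constant"
                    if r["question"] == "constant"
                    else f"{r['question']}_{int(r['level'])}",
                    axis=1,
                )
            )
            for j, name in enumerate(DUMMY_COLUMNS):
                coef[c, j] = rows.loc[name, "coefficient"]
                se[c, j] = rows.loc[name, "se"]
            intercept[c] = rows.loc["constant", "coefficient"]
            intercept_se[c] = rows.loc["constant", "se"]
        blocks[domain] = DomainCoefficientBlock(
            domain=domain,
            feature_names=DUMMY_COLUMNS,
            coef=coef,
            intercept=intercept,
            se=se,
            intercept_se=intercept_se,
        )
    model = ResponseMappingModel(
        blocks=blocks,
        link="multinomial",
        metadata={"source": "published", "file": str(path)},
    )
    _verify_anchors(model)
    return model


def _verify_anchors(model: ResponseMappingModel) -> None:
    lookup = {name: j for j, name in enumerate(DUMMY_COLUMNS)}
    for (question, level, domain, contrast), expected in _PUBLISHED_ANCHORS.items():
        c = CONTRASTS.index(contrast)
        block = model.blocks[domain]
        if question == "constant":
            actual = block.intercept[c]
        else:
            actual = block.coef[c, lookup[f"{question}_{level}"]]
        if abs(actual - expected) > 1e-9:
            raise CoefficientIntegrityError(
                f"anchor mismatch at ({question}, {level}, {domain}, "
                f"{contrast}): {actual} != {expected}"
            )


def predict_expected_utilities(
    model: ResponseMappingModel,
    data: pd.DataFrame,
    tariff: TariffValueSet,
    method: str = "decomposition",
) -> np.ndarray:
    """Expected utilities for a cohort table of complete OKS responses."""
    design = dummy_design(data).to_numpy()
    dists = model.predict_distributions(design)
    return expected_utility(dists, tariff, method=method)
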