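"""Direct and composite OKS -> EQ-5D utility mapping models.

Eight specifications are supported, identified by ``spec_id``:

===================  ========================================================
``ols``              least squares on utility; predictions capped at 1
``glm_gamma``        GLM on disutility (1 - utility), gamma family
                     (identity link by default)
``glm_log_gaussian`` GLM on disutility, Gaussian family, log link
``fractional_logit`` quasi-likelihood binomial/logit on utility rescaled to
                     [0, 1]; back-transformed predictions stay inside the
                     tariff range
``two_part``         logistic model for the ceiling P(utility = 1), plus OLS
                     for utility below the ceiling; combined as
                     ``U* = P + (1 - P) U``
``three_part``       multinomial model for {perfect, severe (N3), mild
                     moderate}, plus one OLS per non-perfect class; combined
                     as ``U* = P_perfect + P_n3 U_n3 +
                     (1 - P_perfect - P_n3) U_mm``
``rm_ordinal``       ordered-logit response mapping, valued by the
                     expected-value method
``rm_multinomial``   multinomial response mapping, valued by the
                     expected-value method
===================  ========================================================

Every specification can be driven by any of the three explanatory codings
(48 level dummies, 12 item scores, or the total score).  The logistic /
multinomial first parts of the composite models may merge sparsely
populated item levels (``merge_map``) to avoid perfect separation; by
default level 0 and 1 of washing/drying are merged for the two-part model
and of washing/drying and work for the three-part model, which mirrors the
merges needed on the original estimation data.  Merges never apply to the
continuous parts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import response_mapping as rm
from .oks import design_matrix
from .tariff import (
    DOMAINS,
    EQ5D_COLUMNS,
    EQ5DState,
    TariffValueSet,
    classify_state,
    from_unit_interval,
    load_tariff,
    to_unit_interval,
)

__all__ = [
    "SPEC_IDS",
    "MappingFit",
    "eq1_prediction",
    "eq2_prediction",
    "observed_utilities",
    "observed_outcome_classes",
    "fit_mapping",
    "DEFAULT_MERGE_MAPS",
    "SeparationWarning",
]

SPEC_IDS = (
    "ols",
    "glm_gamma",
    "glm_log_gaussian",
    "fractional_logit",
    "two_part",
    "three_part",
    "rm_ordinal",
    "rm_multinomial",
)

#: Default part-1 level merges for the composite models (dummies48 coding).
DEFAULT_MERGE_MAPS = {
    "two_part": {"washing": [0, 1]},
    "three_part": {"washing": [0, 1], "work": [0, 1]},
}

#: Gamma-family responses must be positive; exact-zero disutilities
#: (perfect health) are shifted by this amount under the default policy.
GAMMA_ZERO_SHIFT = 1e-6

_CLASSES = ("perfect", "n3", "mild_moderate")


class SeparationWarning(UserWarning):
    """A logistic part shows signs of (quasi-)separation."""


def eq1_prediction(p_perfect, u_conditional):
    """Two-part expected utility: ``P + (1 - P) U``.

    ``P`` is the predicted probability of perfect health (utility 1) and
    ``U`` the predicted utility conditional on imperfect health.  The result
    is a convex combination of 1 and ``U``.
    """
    p = np.asarray(p_perfect, dtype=float)
    u = np.asarray(u_conditional, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_perfect must lie in [0, 1]")
    out = p + (1.0 - p) * u
    return float(out) if out.ndim == 0 else out


def eq2_prediction(p_perfect, p_n3, u_n3, u_mild_moderate):
    """Three-part expected utility:
    ``P_perfect + P_n3 U_n3 + (1 - P_perfect - P_n3) U_mm``.

    A convex combination of 1, the expected utility given severe problems on
    at least one domain (the N3 class) and the expected utility given only
    mild/moderate problems.
    """
    pp = np.asarray(p_perfect, dtype=float)
    pn = np.asarray(p_n3, dtype=float)
    if np.any(pp < 0) or np.any(pn < 0) or np.any(pp + pn > 1 + 1e-12):
        raise ValueError("class probabilities must be in [0, 1] with sum <= 1")
    out = pp + pn * np.asarray(u_n3, float) + (1.0 - pp - pn) * np.asarray(
        u_mild_moderate, float
    )
    return float(out) if out.ndim == 0 else out


def observed_utilities(data: pd.DataFrame, tariff: TariffValueSet) -> np.ndarray:
    """Tariff utilities of the observed EQ-5D responses in a cohort table."""
    missing = [c for c in EQ5D_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort table missing EQ-5D columns: {missing}")
    levels = data[list(EQ5D_COLUMNS)].to_numpy(dtype=int)
    cache: dict[tuple, float] = {}
    out = np.empty(len(levels))
    for i, row in enumerate(map(tuple, levels)):
        if row not in cache:
            cache[row] = tariff.utility(EQ5DState.from_levels(row))
        out[i] = cache[row]
    return out


def observed_outcome_classes(data: pd.DataFrame) -> np.ndarray:
    """Three-part outcome class of each observed EQ-5D response."""
    levels = data[list(EQ5D_COLUMNS)].to_numpy(dtype=int)
    out = np.empty(len(levels), dtype=object)
    for i, row in enumerate(map(tuple, levels)):
        out[i] = classify_state(EQ5DState.from_levels(row))
    return out


@dataclass
class FittedPart:
    """One estimated component of a mapping fit.

    ``kind`` selects the mean function applied to the linear predictor
    (intercept first in ``params``): ``linear`` (identity), ``logit``
    (sigmoid), ``glm`` (inverse of ``meta['link']``), or ``mnlogit``
    (softmax over ``meta['classes']`` with the first class as base).
    """

    kind: str
    feature_names: tuple[str, ...]
    params: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        return np.column_stack(
            [np.ones(len(X)), X[list(self.feature_names)].to_numpy(dtype=float)]
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._design(X)
        if self.kind == "mnlogit":
            eta = Z @ self.params  # (n, K-1)
            z = np.concatenate([np.zeros((len(Z), 1)), eta], axis=1)
            z -= z.max(axis=1, keepdims=True)
            ez = np.exp(z)
            return ez / ez.sum(axis=1, keepdims=True)
        eta = Z @ self.params
        if self.kind == "linear":
            return eta
        if self.kind == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        if self.kind == "glm":
            link = self.meta["link"]
            if link == "identity":
                return eta
            if link == "log":
                return np.exp(eta)
            if link == "logit":
                return 1.0 / (1.0 + np.exp(-eta))
            raise ValueError(f"unknown link {link!r}")
        raise ValueError(f"unknown part kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "params": self.params.tolist(),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedPart":
        return cls(
            kind=d["kind"],
            feature_names=tuple(d["feature_names"]),
            params=np.asarray(d["params"]),
            meta=d.get("meta", {}),
        )


@dataclass
class MappingFit:
    """A fitted mapping specification plus its prediction rule."""

    spec_id: str
    coding: str
    parts: dict
    merge_map: dict = field(default_factory=dict)
    tariff_name: str = "uk_tto"
    metadata: dict = field(default_factory=dict)

    def predict(self, data: pd.DataFrame, tariff: TariffValueSet | None = None):
        """Predicted EQ-5D utilities for a cohort of complete OKS responses."""
        if tariff is None:
            tariff = load_tariff(self.tariff_name)
        X = design_matrix(data, self.coding)
        spec = self.spec_id
        if spec == "ols":
            return np.minimum(self.parts["mean"].predict(X), 1.0)
        if spec in ("glm_gamma", "glm_log_gaussian"):
            return 1.0 - self.parts["disutility"].predict(X)
        if spec == "fractional_logit":
            return from_unit_interval(self.parts["fraction"].predict(X), tariff)
        if spec == "two_part":
            Xm = design_matrix(data, self.coding, self.merge_map or None)
            p = self.parts["ceiling"].predict(Xm)
            u = self.parts["conditional"].predict(X)
            return eq1_prediction(p, u)
        if spec == "three_part":
            Xm = design_matrix(data, self.coding, self.merge_map or None)
            probs = self.parts["classes"].predict(Xm)
            classes = self.parts["classes"].meta["classes"]
            pp = probs[:, classes.index("perfect")]
            pn = probs[:, classes.index("n3")]
            return eq2_prediction(
                pp, pn, self.parts["u_n3"].predict(X), self.parts["u_mm"].predict(X)
            )
        if spec in ("rm_ordinal", "rm_multinomial"):
            model: rm.ResponseMappingModel = self.parts["response_model"]
            dists = model.predict_distributions(X.to_numpy(dtype=float))
            return rm.expected_utility(dists, tariff)
        raise ValueError(f"unknown specification {spec!r}")

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "oksmap-mapping-fit",
            "version": 1,
            "spec_id": self.spec_id,
            "coding": self.coding,
            "merge_map": self.merge_map,
            "tariff_name": self.tariff_name,
            "metadata": self.metadata,
            "parts": {},
        }
        for name, part in self.parts.items():
            if isinstance(part, rm.ResponseMappingModel):
                payload["parts"][name] = _response_model_to_dict(part)
            else:
                payload["parts"][name] = part.to_dict()
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MappingFit":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        payload = json.loads(text)
        if payload.get("format") != "oksmap-mapping-fit":
            raise ValueError("not a serialized mapping fit")
        parts = {}
        for name, d in payload["parts"].items():
            if d.get("kind") == "response_model":
                parts[name] = _response_model_from_dict(d)
            else:
                parts[name] = FittedPart.from_dict(d)
        return cls(
            spec_id=payload["spec_id"],
            coding=payload["coding"],
            parts=parts,
            merge_map=payload.get("merge_map", {}),
            tariff_name=payload.get("tariff_name", "uk_tto"),
            metadata=payload.get("metadata", {}),
        )


def _response_model_to_dict(model: rm.ResponseMappingModel) -> dict:
    blocks = {}
    for domain in DOMAINS:
        b = model.blocks[domain]
        if model.link == "multinomial":
            blocks[domain] = {
                "coef": b.coef.tolist(),
                "intercept": b.intercept.tolist(),
            }
        else:
            blocks[domain] = {
                "beta": b.beta.tolist(),
                "thresholds": b.thresholds.tolist(),
            }
    return {
        "kind": "response_model",
        "link": model.link,
        "feature_names": list(model.feature_names),
        "blocks": blocks,
    }


def _response_model_from_dict(d: dict) -> rm.ResponseMappingModel:
    names = tuple(d["feature_names"])
    blocks = {}
    for domain in DOMAINS:
        bd = d["blocks"][domain]
        if d["link"] == "multinomial":
            blocks[domain] = rm.DomainCoefficientBlock(
                domain=domain,
                feature_names=names,
                coef=np.asarray(bd["coef"]),
                intercept=np.asarray(bd["intercept"]),
            )
        else:
            blocks[domain] = rm.OrdinalDomainBlock(
                domain=domain,
                feature_names=names,
                beta=np.asarray(bd["beta"]),
                thresholds=np.asarray(bd["thresholds"]),
            )
    return rm.ResponseMappingModel(blocks=blocks, link=d["link"])


# -- estimation ------------------------------------------------------------


def fit_mapping(
    data: pd.DataFrame,
    spec_id: str,
    coding: str = "dummies48",
    merge_map: dict | str | None = "auto",
    tariff: TariffValueSet | None = None,
    cluster_col: str | None = None,
    glm_gamma_link: str = "identity",
    gamma_zero_policy: str = "shift",
) -> MappingFit:
    """Estimate one of the eight mapping specifications on complete cases.

    ``merge_map='auto'`` applies :data:`DEFAULT_MERGE_MAPS` to the part-1
    model of the composite specifications under the dummies48 coding; pass
    ``{}`` to disable merging or a custom map to override.
    ``gamma_zero_policy`` is ``'shift'`` (add a tiny constant to exact-zero
    disutilities) or ``'drop'`` (exclude perfect-health records from the
    gamma fit).
    """
    if spec_id not in SPEC_IDS:
        raise ValueError(f"unknown specification {spec_id!r}; choose from {SPEC_IDS}")
    if tariff is None:
        tariff = load_tariff()
    if merge_map == "auto":
        merge_map = (
            dict(DEFAULT_MERGE_MAPS.get(spec_id, {})) if coding == "dummies48" else {}
        )
    merge_map = merge_map or {}

    y = observed_utilities(data, tariff)
    X = design_matrix(data, coding)
    meta: dict = {"n_obs": int(len(data)), "coding": coding}
    parts: dict = {}

    if spec_id == "ols":
        parts["mean"] = _fit_linear(X, y)
    elif spec_id in ("glm_gamma", "glm_log_gaussian"):
        dis = tariff.full_health - y
        if spec_id == "glm_gamma":
            family = sm.families.Gamma(link=_LINKS[glm_gamma_link]())
            if gamma_zero_policy == "shift":
                n_zero = int((dis <= 0).sum())
                if n_zero:
                    warnings.warn(
                        f"{n_zero} zero disutilities shifted by {GAMMA_ZERO_SHIFT} "
                        "for the gamma family",
                        UserWarning,
                        stacklevel=2,
                    )
                dis = np.where(dis <= 0, GAMMA_ZERO_SHIFT, dis)
            elif gamma_zero_policy == "drop":
                keep = dis > 0
                if not keep.any():
                    raise ValueError("no positive disutilities to fit gamma family")
                dis, X = dis[keep], X.loc[keep]
            else:
                raise ValueError(f"unknown gamma_zero_policy {gamma_zero_policy!r}")
            link_name = glm_gamma_link
        else:
            family = sm.families.Gaussian(link=sm.families.links.Log())
            link_name = "log"
        parts["disutility"] = _fit_glm(X, dis, family, link_name)
        meta["family"] = spec_id
    elif spec_id == "fractional_logit":
        frac = to_unit_interval(y, tariff)
        family = sm.families.Binomial(link=sm.families.links.Logit())
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*non-integer.*")
            parts["fraction"] = _fit_glm(X, frac, family, "logit")
    elif spec_id == "two_part":
        Xm = design_matrix(data, coding, merge_map or None)
        ceiling = (y >= tariff.maximum - 1e-12).astype(int)
        if ceiling.all() or not ceiling.any():
            raise ValueError("two-part model needs both ceiling and non-ceiling records")
        parts["ceiling"] = _fit_logit(Xm, ceiling)
        below = y < tariff.maximum - 1e-12
        parts["conditional"] = _fit_linear(X.loc[below], y[below], drop_empty=True)
    elif spec_id == "three_part":
        Xm = design_matrix(data, coding, merge_map or None)
        classes = observed_outcome_classes(data)
        empty = [c for c in _CLASSES if not (classes == c).any()]
        if empty:
            raise ValueError(f"three-part model: empty outcome class(es) {empty}")
        parts["classes"] = _fit_mnlogit_classes(Xm, classes)
        for name, cls_label in (("u_n3", "n3"), ("u_mm", "mild_moderate")):
            mask = classes == cls_label
            parts[name] = _fit_linear(X.loc[mask], y[mask], drop_empty=True)
    else:  # response mapping
        link = "ordinal" if spec_id == "rm_ordinal" else "multinomial"
        parts["response_model"] = rm.fit_response_mapping(
            data, link=link, cluster_col=cluster_col, coding=coding
        )
    return MappingFit(
        spec_id=spec_id,
        coding=coding,
        parts=parts,
        merge_map=merge_map,
        tariff_name=tariff.name,
        metadata=meta,
    )


_LINKS = {
    "identity": sm.families.links.Identity,
    "log": sm.families.links.Log,
    "logit": sm.families.links.Logit,
}


def _add_const(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def _check_rank(X: pd.DataFrame) -> None:
    Z = _add_const(X)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # name the columns involved in collinearity via QR pivoting
        _, r = np.linalg.qr(Z)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(Z.shape) * np.finfo(float).eps
        bad = [
            (["const"] + list(X.columns))[j]
            for j in range(Z.shape[1])
            if j < len(diag) and diag[j] < tol
        ]
        raise ValueError(f"design is rank deficient; suspect columns: {bad}")


def _drop_empty(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Prune columns that make the intercepted design rank deficient.

    Zero-variance indicators (an item level absent from the subset) and
    exact collinearity (an item never at its reference level, so its
    dummies sum to the intercept) both occur routinely in the conditional
    parts of composite models; pivoted QR keeps a maximal independent set.
    """
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    Z = _add_const(X)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        from scipy.linalg import qr

        Z = Z.copy()
        Z[:, 0] *= 1e6  # keep the intercept ahead of any dummy in the pivot order
        _, r, piv = qr(Z, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > diag.max() * max(Z.shape) * np.finfo(float).eps).sum())
        names = ["const"] + list(X.columns)
        keep = {names[j] for j in piv[:rank]}
        collinear = [c for c in X.columns if c not in keep]
        X = X[[c for c in X.columns if c in keep]]
        constant = constant + collinear
    return X, constant


def _fit_linear(X: pd.DataFrame, y: np.ndarray, drop_empty: bool = False) -> FittedPart:
    if len(X) == 0:
        raise ValueError("empty subset for a linear part")
    dropped: list[str] = []
    if drop_empty:
        # subset models (e.g. utility given severe problems) routinely lack
        # whole item levels; those indicators carry no information there
        X, dropped = _drop_empty(X)
    _check_rank(X)
    res = sm.OLS(y, _add_const(X)).fit()
    return FittedPart(
        kind="linear",
        feature_names=tuple(X.columns),
        params=np.asarray(res.params),
        meta={
            "rsquared": float(res.rsquared),
            "nobs": int(res.nobs),
            "dropped_columns": dropped,
        },
    )


def _fit_glm(X: pd.DataFrame, y: np.ndarray, family, link_name: str) -> FittedPart:
    Z = _add_const(X)
    model = sm.GLM(y, Z, family=family)
    try:
        res = model.fit()
    except Exception:
        # identity-link gamma can need admissible starting values
        start = np.zeros(Z.shape[1])
        start[0] = max(float(np.mean(y)), 1e-4)
        res = model.fit(start_params=start, maxiter=300)
    return FittedPart(
        kind="glm",
        feature_names=tuple(X.columns),
        params=np.asarray(res.params),
        meta={"link": link_name, "family": type(family).__name__, "nobs": int(res.nobs)},
    )


def _safe_bse(res) -> np.ndarray:
    try:
        with np.errstate(invalid="ignore"):
            return np.asarray(res.bse)
    except ValueError:  # singular Hessian: no covariance available
        return np.full(np.asarray(res.params).shape, np.nan)


def _separation_suspected(params: np.ndarray, bse: np.ndarray) -> bool:
    return bool(np.any(~np.isfinite(bse)) or np.any(np.abs(params) > 15))


def _fit_logit(X: pd.DataFrame, y: np.ndarray) -> FittedPart:
    X, dropped = _drop_empty(X)
    model = sm.Logit(y, _add_const(X))
    res = model.fit(method="lbfgs", disp=False, maxiter=2000)
    if not np.isfinite(np.asarray(res.params)).all():
        res = model.fit(disp=False, maxiter=200)
        if not np.isfinite(np.asarray(res.params)).all():
            raise RuntimeError("ceiling model diverged (separation?)")
    bse = _safe_bse(res)
    if _separation_suspected(np.asarray(res.params), bse):
        warnings.warn(
            "possible separation in the ceiling model; consider merging sparse "
            "item levels via merge_map",
            SeparationWarning,
            stacklevel=2,
        )
    return FittedPart(
        kind="logit",
        feature_names=tuple(X.columns),
        params=np.asarray(res.params),
        meta={"nobs": int(res.nobs), "dropped_columns": dropped},
    )


def _fit_mnlogit_classes(X: pd.DataFrame, classes: np.ndarray) -> FittedPart:
    # encode with 'perfect' as base; column order of the softmax output is
    # base followed by the remaining classes in _CLASSES order
    X, dropped = _drop_empty(X)
    codes = np.array([_CLASSES.index(c) for c in classes])
    model = sm.MNLogit(codes, _add_const(X))
    res = model.fit(method="lbfgs", maxiter=2000, disp=False)
    if not np.isfinite(np.asarray(res.params)).all():
        res = model.fit(method="newton", maxiter=200, disp=False)
        if not np.isfinite(np.asarray(res.params)).all():
            raise RuntimeError("class model diverged (separation?)")
    params = np.asarray(res.params)
    bse = _safe_bse(res)
    if _separation_suspected(params, bse):
        warnings.warn(
            "possible separation in the class model; consider merging sparse "
            "item levels via merge_map",
            SeparationWarning,
            stacklevel=2,
        )
    return FittedPart(
        kind="mnlogit",
        feature_names=tuple(X.columns),
        params=params,
        meta={"classes": list(_CLASSES), "nobs": int(res.nobs),
              "dropped_columns": dropped},
    )
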