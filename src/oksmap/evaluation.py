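"""Prediction scoring, clustered validation splits and model comparison.

Model accuracy follows the conventions of the mapping literature: mean
squared error (MSE, the selection criterion), mean absolute error (MAE,
secondary) and the signed mean residual (predicted minus observed).
Validation splits are made at the *patient* level so that repeated
questionnaires from one patient never straddle the estimation/validation
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .direct_models import SPEC_IDS, fit_mapping, observed_utilities
from .tariff import DOMAINS, EQ5D_COLUMNS, TariffValueSet, load_tariff

__all__ = [
    "AccuracyReport",
    "accuracy",
    "patient_level_split",
    "compare_models",
    "residual_diagnostics",
    "response_level_calibration",
    "DEFAULT_OKS_BANDS",
]

#: Decade bands of total OKS used for error diagnostics.
DEFAULT_OKS_BANDS = ((0, 10), (11, 20), (21, 30), (31, 40), (41, 48))


@dataclass
class AccuracyReport:
    """MSE/MAE/mean-residual summary of a prediction vector."""

    mse: float
    mae: float
    mean_residual: float
    n: int
    strata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "mean_residual": self.mean_residual,
            "n": self.n,
        }


def _aligned(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError(
            f"observed and predicted must be aligned 1-d vectors; got shapes "
            f"{observed.shape} and {predicted.shape}"
        )
    if observed.size == 0:
        raise ValueError("empty input")
    return observed, predicted


def accuracy(observed, predicted) -> AccuracyReport:
    """MSE, MAE and mean residual of predicted vs observed utilities."""
    observed, predicted = _aligned(observed, predicted)
    resid = predicted - observed
    return AccuracyReport(
        mse=float(np.mean(resid**2)),
        mae=float(np.mean(np.abs(resid))),
        mean_residual=float(np.mean(resid)),
        n=int(observed.size),
    )


def patient_level_split(
    records: pd.DataFrame,
    fraction: float = 0.25,
    seed: int | None = None,
    patient_col: str = "patient_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allocate a fraction of *patients* to a validation sample.

    All questionnaires from a sampled patient travel together, so the
    validation set is independent of the estimation set at the patient
    level.  Returns ``(estimation, validation)``.
    """
    if patient_col not in records.columns:
        raise ValueError(f"records lack a {patient_col!r} column")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    patients = np.sort(records[patient_col].unique())
    n_val = int(round(fraction * len(patients)))
    validation_patients = set(rng.choice(patients, size=n_val, replace=False))
    in_val = records[patient_col].isin(validation_patients)
    return records.loc[~in_val].copy(), records.loc[in_val].copy()


def compare_models(
    data: pd.DataFrame,
    specs=SPEC_IDS,
    coding: str = "dummies48",
    seed: int | None = None,
    fraction: float = 0.25,
    tariff: TariffValueSet | None = None,
    cluster_col: str | None = None,
) -> pd.DataFrame:
    """Head-to-head comparison of mapping specifications.

    Each specification is fitted on the estimation partition of a
    patient-level split and scored on both partitions; rows are ordered by
    validation MSE (the selection criterion), with ties broken by
    validation MAE and then by the number of model parts (parsimony).
    Specifications that fail to fit are retained in the table with the
    failure reason and NaN scores.
    """
    if tariff is None:
        tariff = load_tariff()
    est, val = patient_level_split(data, fraction=fraction, seed=seed)
    y_est = observed_utilities(est, tariff)
    y_val = observed_utilities(val, tariff)
    n_parts = {"two_part": 2, "three_part": 3}
    rows = []
    for spec in specs:
        row: dict = {"spec_id": spec, "coding": coding, "status": "ok", "reason": ""}
        try:
            fit = fit_mapping(est, spec, coding=coding, tariff=tariff,
                              cluster_col=cluster_col)
            rep_est = accuracy(y_est, fit.predict(est, tariff))
            rep_val = accuracy(y_val, fit.predict(val, tariff))
            row.update(
                mse_validation=rep_val.mse,
                mse_estimation=rep_est.mse,
                mae_validation=rep_val.mae,
                mae_estimation=rep_est.mae,
            )
        except Exception as exc:  # a failing spec must not sink the others
            row.update(
                status="failed",
                reason=f"{type(exc).__name__}: {exc}",
                mse_validation=np.nan,
                mse_estimation=np.nan,
                mae_validation=np.nan,
                mae_estimation=np.nan,
            )
        row["n_parts"] = n_parts.get(spec, 1)
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["mse_validation", "mae_validation", "n_parts"], na_position="last"
    ).reset_index(drop=True)
    table["rank"] = np.where(table["status"] == "ok", np.arange(1, len(table) + 1), -1)
    return table


def residual_diagnostics(
    observed, predicted, oks_totals, bands=DEFAULT_OKS_BANDS
) -> dict:
    """Error structure diagnostics mirroring the usual mapping plots.

    Reports the mean residual within the observed-utility strata below and
    at-or-above 0.5 (ceiling/floor shrinkage shows up as opposite signs
    here), MSE by total-OKS band, and the range/SD of predictions vs
    observations.  Bands with no records are reported as ``None``.
    """
    observed, predicted = _aligned(observed, predicted)
    oks_totals = np.asarray(oks_totals)
    if oks_totals.shape != observed.shape:
        raise ValueError("oks_totals must align with observed")
    resid = predicted - observed
    strata = {}
    for label, mask in (("<0.5", observed < 0.5), (">=0.5", observed >= 0.5)):
        strata[label] = (
            {"mean_residual": float(resid[mask].mean()), "n": int(mask.sum())}
            if mask.any()
            else None
        )
    by_band = {}
    for lo, hi in bands:
        mask = (oks_totals >= lo) & (oks_totals <= hi)
        by_band[f"{lo}-{hi}"] = (
            {"mse": float(np.mean(resid[mask] ** 2)), "n": int(mask.sum())}
            if mask.any()
            else None
        )
    return {
        "residual_by_observed_stratum": strata,
        "mse_by_oks_band": by_band,
        "observed_range": (float(observed.min()), float(observed.max())),
        "predicted_range": (float(predicted.min()), float(predicted.max())),
        "observed_sd": float(observed.std()),
        "predicted_sd": float(predicted.std()),
    }


def response_level_calibration(data: pd.DataFrame, dists: np.ndarray) -> pd.DataFrame:
    """Observed vs mean-predicted response-level proportions per domain.

    ``dists`` is the (n, 5, 3) array of predicted level probabilities for
    the same records.  Returns a 15-row table (5 domains x 3 levels) with
    the observed proportion, the mean predicted probability and their
    difference (predicted minus observed).
    """
    missing = [c for c in EQ5D_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort table missing EQ-5D columns: {missing}")
    dists = np.asarray(dists, dtype=float)
    if dists.shape != (len(data), 5, 3):
        raise ValueError(
            f"dists shape {dists.shape} does not match ({len(data)}, 5, 3)"
        )
    rows = []
    for d, (domain, col) in enumerate(zip(DOMAINS, EQ5D_COLUMNS)):
        levels = data[col].to_numpy(dtype=int)
        for lvl in (1, 2, 3):
            obs = float(np.mean(levels == lvl))
            pred = float(dists[:, d, lvl - 1].mean())
            rows.append(
                {
                    "domain": domain,
                    "level": lvl,
                    "observed_proportion": obs,
                    "predicted_proportion": pred,
                    "difference": pred - obs,
                }
            )
    return pd.DataFrame(rows)
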