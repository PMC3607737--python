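"""EQ-5D-3L health states and additive value-set (tariff) valuation.

The EQ-5D-3L describes health on five domains — mobility, self-care, usual
activities, pain/discomfort and anxiety/depression — each at one of three
levels (1 = no problems, 2 = some problems, 3 = severe problems), giving
3**5 = 243 possible health states.

A *tariff* (value set) converts a state into a utility on a scale where 1 is
full health and 0 is death.  The additive tariffs implemented here subtract:

* a constant once any domain departs from level 1 (the "any problem" term),
* a per-domain decrement for level 2 or level 3,
* the *N3* term, a further constant subtracted once if any domain is at
  level 3.

The packaged UK time-trade-off set spans [-0.594, 1] over the 243 states.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "EQ5DState",
    "TariffValueSet",
    "load_tariff",
    "enumerate_states",
    "classify_state",
    "utility",
    "state_utilities",
    "to_unit_interval",
    "from_unit_interval",
]

#: Canonical domain order, used everywhere (states, tariffs, model blocks).
DOMAINS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

#: Column names for observed EQ-5D levels in cohort tables.
EQ5D_COLUMNS = ("eq_mo", "eq_sc", "eq_ua", "eq_pd", "eq_ad")

_TERM_BY_DOMAIN = {
    "mobility": "MO",
    "self_care": "SC",
    "usual_activities": "UA",
    "pain_discomfort": "PD",
    "anxiety_depression": "AD",
}


class TariffConfigurationError(ValueError):
    """A tariff constants table is incomplete or violates tariff invariants."""


@dataclass(frozen=True)
class EQ5DState:
    """One respondent's level (1/2/3) on each of the five EQ-5D domains."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for domain in DOMAINS:
            level = getattr(self, domain)
            if level not in (1, 2, 3):
                raise ValueError(
                    f"EQ-5D level for {domain} must be 1, 2 or 3; got {level!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, d) for d in DOMAINS)

    @classmethod
    def from_levels(cls, levels) -> "EQ5DState":
        return cls(*(int(v) for v in levels))

    def __str__(self) -> str:  # e.g. "11223"
        return "".join(str(v) for v in self.levels)


@dataclass(frozen=True)
class TariffValueSet:
    """Constants of an additive EQ-5D-3L value set.

    ``decrements`` maps each domain to its (level-2, level-3) utility
    decrements; ``any_problem`` is subtracted once when any domain is above
    level 1 and ``n3`` once when any domain is at level 3.
    """

    name: str
    full_health: float
    any_problem: float
    decrements: dict[str, tuple[float, float]]
    n3: float

    def __post_init__(self) -> None:
        missing = [d for d in DOMAINS if d not in self.decrements]
        if missing:
            raise TariffConfigurationError(
                f"tariff {self.name!r} missing decrements for {missing}"
            )
        if self.any_problem < 0 or self.n3 < 0:
            raise TariffConfigurationError(
                f"tariff {self.name!r}: constants must be non-negative"
            )
        for domain, (l2, l3) in self.decrements.items():
            if l2 < 0 or l3 < l2:
                raise TariffConfigurationError(
                    f"tariff {self.name!r}, {domain}: need 0 <= L2 <= L3 "
                    f"decrement, got ({l2}, {l3})"
                )

    def utility(self, state: EQ5DState) -> float:
        """Utility of ``state`` under this value set."""
        u = self.full_health
        levels = state.levels
        if any(v > 1 for v in levels):
            u -= self.any_problem
        for domain, level in zip(DOMAINS, levels):
            if level > 1:
                u -= self.decrements[domain][level - 2]
        if any(v == 3 for v in levels):
            u -= self.n3
        return u

    @property
    def minimum(self) -> float:
        """Utility of the worst state (all domains at level 3)."""
        return self.utility(EQ5DState(3, 3, 3, 3, 3))

    @property
    def maximum(self) -> float:
        """Utility of full health (all domains at level 1)."""
        return self.utility(EQ5DState(1, 1, 1, 1, 1))


def _packaged_data(filename: str) -> Path:
    return Path(importlib.resources.files("oksmap.data") / filename)


def load_tariff(name: str = "uk_tto", path: str | Path | None = None) -> TariffValueSet:
    """Load a tariff from a long-format constants CSV.

    The file has columns ``tariff_name, term, value`` with terms
    ``full_health, any_problem, MO2, MO3, SC2, SC3, UA2, UA3, PD2, PD3,
    AD2, AD3, N3``.  Only the UK time-trade-off set (``uk_tto``) ships with
    the package; further tariffs can be supplied via ``path`` without code
    changes.
    """
    src = Path(path) if path is not None else _packaged_data("uk_tto_tariff.csv")
    table = pd.read_csv(src)
    rows = table[table["tariff_name"] == name]
    if rows.empty:
        raise TariffConfigurationError(f"no tariff named {name!r} in {src}")
    values = dict(zip(rows["term"], rows["value"]))
    required = {"full_health", "any_problem", "N3"} | {
        f"{_TERM_BY_DOMAIN[d]}{lvl}" for d in DOMAINS for lvl in (2, 3)
    }
    missing = sorted(required - set(values))
    if missing:
        raise TariffConfigurationError(
            f"tariff {name!r} missing constants: {missing}"
        )
    decrements = {
        d: (values[f"{_TERM_BY_DOMAIN[d]}2"], values[f"{_TERM_BY_DOMAIN[d]}3"])
        for d in DOMAINS
    }
    return TariffValueSet(
        name=name,
        full_health=values["full_health"],
        any_problem=values["any_problem"],
        decrements=decrements,
        n3=values["N3"],
    )


def enumerate_states() -> list[EQ5DState]:
    """All 243 EQ-5D-3L states in lexicographic order.

    Mobility varies slowest and anxiety/depression fastest, so the first
    state is 11111 and the last 33333.  This ordering is relied on by the
    243-state enumeration of expected utilities.
    """
    levels = (1, 2, 3)
    return [
        EQ5DState(mo, sc, ua, pd_, ad)
        for mo in levels
        for sc in levels
        for ua in levels
        for pd_ in levels
        for ad in levels
    ]


def classify_state(state: EQ5DState) -> str:
    """Three-way outcome class used by the three-part mapping model.

    ``perfect``      — all domains at level 1 (utility 1 at full health);
    ``n3``           — severe problems (level 3) on at least one domain, so
                       the tariff's N3 decrement applies;
    ``mild_moderate``— everything else.
    The classes are mutually exclusive and exhaustive.
    """
    levels = state.levels
    if all(v == 1 for v in levels):
        return "perfect"
    if any(v == 3 for v in levels):
        return "n3"
    return "mild_moderate"


def utility(state: EQ5DState, tariff: TariffValueSet) -> float:
    """Utility of ``state`` under ``tariff`` (1 = full health)."""
    return tariff.utility(state)


def state_utilities(tariff: TariffValueSet) -> np.ndarray:
    """Utilities of all 243 states in ``enumerate_states`` order."""
    return np.array([tariff.utility(s) for s in enumerate_states()])


def to_unit_interval(u, tariff: TariffValueSet | None = None, clamp: bool = False):
    """Rescale utility onto [0, 1]: ``(u + 0.594) / 1.594`` for the UK set.

    Generally ``(u - min) / (max - min)`` for the tariff's range.  Used by
    the fractional-logit mapping model.  Out-of-range input raises unless
    ``clamp`` is set.
    """
    lo, hi = _tariff_range(tariff)
    u = np.asarray(u, dtype=float)
    if clamp:
        u = np.clip(u, lo, hi)
    elif np.any(u < lo) or np.any(u > hi):
        raise ValueError(f"utility outside [{lo}, {hi}]; pass clamp=True to clip")
    out = (u - lo) / (hi - lo)
    return float(out) if out.ndim == 0 else out


def from_unit_interval(p, tariff: TariffValueSet | None = None):
    """Inverse of :func:`to_unit_interval`."""
    lo, hi = _tariff_range(tariff)
    p = np.asarray(p, dtype=float)
    out = p * (hi - lo) + lo
    return float(out) if out.ndim == 0 else out


def _tariff_range(tariff: TariffValueSet | None) -> tuple[float, float]:
    if tariff is None:
        tariff = load_tariff()
    return tariff.minimum, tariff.maximum
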