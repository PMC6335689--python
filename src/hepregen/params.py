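"""Model parameterization and derived homeostatic constants.

The regeneration model is governed by 33 tunable rate/saturation/threshold
constants (per-day time base) plus two structural constants: the senescent
functional cell fraction ``epsilon`` and the pre-resection non-senescent mass
``N_ss``.  Seven additional constants ``k1..k7`` are not free parameters: they
are homeostatic in/out-fluxes chosen so that every molecular species is at
steady state (all concentrations = 1) in the intact liver, and they are held
fixed during regeneration.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "PARAM_NAMES",
    "ParameterSet",
    "DerivedConstants",
    "derived_constants",
    "id71_optimal",
    "rat_baseline",
]

#: Canonical ordering of the 33 tunable parameters (ASCII transliteration of
#: the published symbols: kappa_IL6 for the IL-6 first-order decay, KM_JAK for
#: the JAK activation Michaelis constant, theta_ap/beta_ap for the apoptosis
#: switch midpoint/slope, and so on).
PARAM_NAMES: tuple[str, ...] = (
    "M",
    "k_IL6",
    "kappa_IL6",
    "V_JAK",
    "KM_JAK",
    "kappa_JAK",
    "proSTAT3",
    "V_ST3",
    "KM_ST3",
    "kappa_ST3",
    "V_SOCS3",
    "KM_SOCS3",
    "kappa_SOCS3",
    "KI_SOCS3",
    "V_IE",
    "KM_IE",
    "kappa_IE",
    "k_deg",
    "kappa_ECM",
    "k_GF",
    "kappa_GF",
    "k_up",
    "k_QP",
    "k_PR",
    "k_RQ",
    "k_prol",
    "k_req",
    "theta_req",
    "beta_req",
    "k_ap",
    "theta_ap",
    "beta_ap",
    "k_G",
)


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates its domain constraints."""


@dataclass(frozen=True)
class ParameterSet:
    """The 33 named model constants plus the structural pair (epsilon, N_ss).

    All rates are per day.  ``M`` is the organ-scale metabolic load
    (dimensionless demand per unit liver mass); ``theta_ap``/``beta_ap`` are
    the midpoint and slope of the apoptosis switch; ``theta_req``/``beta_req``
    those of the requiescence switch.  ``epsilon`` is the senescent,
    replication-incompetent but functional cell fraction entering the per-cell
    load denominator M/(N + epsilon); ``N_ss`` the non-senescent steady-state
    mass, with N_ss + epsilon = 1 in the intact organ.
    """

    M: float
    k_IL6: float
    kappa_IL6: float
    V_JAK: float
    KM_JAK: float
    kappa_JAK: float
    proSTAT3: float
    V_ST3: float
    KM_ST3: float
    kappa_ST3: float
    V_SOCS3: float
    KM_SOCS3: float
    kappa_SOCS3: float
    KI_SOCS3: float
    V_IE: float
    KM_IE: float
    kappa_IE: float
    k_deg: float
    kappa_ECM: float
    k_GF: float
    kappa_GF: float
    k_up: float
    k_QP: float
    k_PR: float
    k_RQ: float
    k_prol: float
    k_req: float
    theta_req: float
    beta_req: float
    k_ap: float
    theta_ap: float
    beta_ap: float
    k_G: float
    epsilon: float = 0.01
    N_ss: float = 0.99

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidParameterError(f"{name} is not finite: {value!r}")
            if value < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {value}")
        if self.beta_ap <= 0 or self.beta_req <= 0:
            raise InvalidParameterError("tanh slopes beta_ap and beta_req must be > 0")
        if self.M <= 0:
            raise InvalidParameterError("metabolic load M must be > 0")
        if self.epsilon < 0:
            raise InvalidParameterError("epsilon must be >= 0")
        if self.N_ss + self.epsilon <= 0:
            raise InvalidParameterError("N_ss + epsilon must be > 0")
        if self.KI_SOCS3 <= 0:
            raise InvalidParameterError(
                "KI_SOCS3 must be > 0 (enters a 1/KI_SOCS3 homeostatic term)"
            )

    # -- conversion ---------------------------------------------------------

    def as_dict(self) -> dict[str, float]:
        """The 33 tunable parameters as a flat name -> value mapping."""
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, **overrides: float) -> "ParameterSet":
        """A copy with the given parameters overridden (e.g. ``replace(M=4)``)."""
        return dataclasses.replace(self, **overrides)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())

    @classmethod
    def from_dict(
        cls,
        values: Mapping[str, float],
        *,
        epsilon: float = 0.01,
        N_ss: float = 0.99,
    ) -> "ParameterSet":
        missing = [n for n in PARAM_NAMES if n not in values]
        if missing:
            raise InvalidParameterError(f"missing parameters: {missing}")
        unknown = [
            n
            for n in values
            if n not in PARAM_NAMES
            and n not in ("epsilon", "N_ss")
            and not n.startswith("_")  # annotation keys in fixture files
        ]
        if unknown:
            raise InvalidParameterError(f"unknown parameters: {unknown}")
        kwargs = {n: float(values[n]) for n in PARAM_NAMES}
        kwargs["epsilon"] = float(values.get("epsilon", epsilon))
        kwargs["N_ss"] = float(values.get("N_ss", N_ss))
        return cls(**kwargs)

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)
            fh.write("\n")


@dataclass(frozen=True)
class DerivedConstants:
    """Homeostatic in/out-flux constants k1..k7 (per day).

    Chosen so the seven molecular balance equations vanish at the intact-organ
    baseline (all species = 1, N = N_ss); they stay fixed after resection.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float


def derived_constants(p: ParameterSet) -> DerivedConstants:
    """Compute k1..k7 from the steady-state conditions of the molecular system.

    The baseline per-cell load is M/(N_ss + epsilon); with the default
    structural constants N_ss + epsilon = 1, so the load reduces to M itself.
    """
    base_load = p.M / (p.N_ss + p.epsilon)
    jak_flux = p.V_JAK / (1.0 + p.KM_JAK)
    pro2 = p.proSTAT3 * p.proSTAT3
    st3_flux = p.V_ST3 * pro2 / (pro2 + p.KM_ST3 * (1.0 + 1.0 / p.KI_SOCS3))
    ie_flux = p.V_IE / (1.0 + p.KM_IE)
    socs3_flux = p.V_SOCS3 / (1.0 + p.KM_SOCS3)

    c = DerivedConstants(
        k1=jak_flux - p.k_IL6 * base_load + p.kappa_IL6,
        k2=p.kappa_JAK - jak_flux,
        k3=-st3_flux + ie_flux + socs3_flux + p.kappa_ST3,
        k4=-socs3_flux + p.kappa_SOCS3,
        k5=-ie_flux + p.kappa_IE,
        k6=p.k_deg + p.kappa_ECM,
        k7=-p.k_GF * base_load + p.k_up + p.kappa_GF,
    )
    for name in ("k1", "k2", "k3", "k4", "k5", "k6", "k7"):
        if not math.isfinite(getattr(c, name)):
            raise InvalidParameterError(f"derived constant {name} is not finite")
    return c


def _load_fixture(name: str) -> ParameterSet:
    with resources.files("hepregen.data").joinpath(name).open() as fh:
        return ParameterSet.from_dict(json.load(fh))


def id71_optimal() -> ParameterSet:
    """The human-timescale optimized parameter set (reference virtual patient).

    This is the multivariate-optimization fit to the liver-volume time series
    of a single hepatectomy patient; it anchors every cohort analysis, with
    selected parameters overridden per virtual patient.
    """
    return _load_fixture("id71_optimal.json")


def rat_baseline() -> ParameterSet:
    """Synthetic stand-in for the rodent baseline parameterization.

    The original rodent values are not shipped here; this fixture applies the
    reported direction and rough magnitude of the rat-to-human fold changes in
    reverse to the human-optimized set (metabolic load from the allometric
    rat-mass relation, ten-fold faster relative cell-mass growth, lower
    apoptosis midpoint, higher KM_ST3 and kappa_JAK).  It is non-authoritative
    and serves only as the calibration initial guess.
    """
    return _load_fixture("rat_baseline_synthetic.json")
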