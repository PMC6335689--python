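"""Virtual-patient cohorts: Sobol sampling, mode maps, influence classes,
threshold maps and the SVM decision boundary.

A *virtual patient* is the reference parameterization with a handful of
parameters — typically the metabolic load M and the cell-death sensitivity
beta_ap — overridden by values drawn from a space-filling Sobol sequence
within physiologically plausible bounds.  Sweeping a cohort at a fixed
resection level yields a response-mode map over the varied parameters;
scanning each patient over resection levels yields a threshold-of-failure
map whose separatrix divides the bistable (recovery + failure) zone from the
monostable failure zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .params import PARAM_NAMES, ParameterSet
from .response import (
    FATE_HORIZON,
    ResponseMode,
    ThresholdResult,
    classify_response,
    threshold_of_failure,
)
from .simulate import SolverOptions, simulate_resection

__all__ = [
    "DEFAULT_BOUNDS",
    "TENFOLD_PARAMS",
    "VirtualPatient",
    "InfluenceClass",
    "ThresholdMap",
    "sobol_cohort",
    "paired_sobol_axes",
    "sweep_modes",
    "classify_parameter_influence",
    "decision_boundary",
    "recovery_region_extent",
    "threshold_map",
]

logger = logging.getLogger(__name__)

#: Default cohort bounds for the two critical perioperative parameters.
#: Chosen to contain every published operating point (M from 1.139 to 22,
#: beta_ap from 0.0045 to 0.085).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "M": (0.5, 25.0),
    "beta_ap": (0.005, 0.12),
}

#: Parameters conventionally swept over a ten-fold range (the strongly
#: rescaled ones in the rat-to-human translation); all others use two-fold.
TENFOLD_PARAMS = ("M", "k_G", "theta_ap", "KM_ST3", "kappa_JAK")

#: default horizon (days) for mode-map simulations — long enough for the
#: reference patient to reach its recovery plateau.
MODE_HORIZON = 3650.0


@dataclass(frozen=True)
class VirtualPatient:
    params: ParameterSet
    varied: tuple[str, ...]
    index: int = 0

    def varied_values(self) -> dict[str, float]:
        return {name: getattr(self.params, name) for name in self.varied}


@dataclass(frozen=True)
class InfluenceClass:
    """One-at-a-time sweep classification of a parameter (four-way taxonomy:
    outcome recovery-only vs recovery-and-failure, crossed with sensitivity)."""

    parameter: str
    outcome_class: Literal["recovery-only", "recovery-and-failure"]
    sensitivity: Literal[
        "sensitive-improves", "sensitive-decelerates", "sensitive", "insensitive"
    ]
    levels: np.ndarray
    final_mass: np.ndarray  # NaN where the level failed


@dataclass(frozen=True)
class ThresholdMap:
    """Per-cell threshold of failure over a paired (M, beta_ap) design."""

    M_values: np.ndarray
    beta_ap_values: np.ndarray
    thresholds: np.ndarray  # (len(M), len(beta)) of ThresholdResult, object dtype
    reference_params: ParameterSet

    def ordinal(self) -> np.ndarray:
        """Float view for plotting/monotonicity: none-safe below the grid,
        none-found above it."""
        out = np.empty(self.thresholds.shape)
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                out[i, j] = self.thresholds[i, j].ordinal()
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.M_values):
            for j, b in enumerate(self.beta_ap_values):
                t: ThresholdResult = self.thresholds[i, j]
                rows.append(
                    {"M": m, "beta_ap": b, "status": t.status, "threshold_pct": t.percent}
                )
        return pd.DataFrame(rows)


def _sobol_unit(d: int, n: int, seed: int | None) -> np.ndarray:
    import warnings

    sampler = qmc.Sobol(d=d, scramble=True, seed=seed)
    with warnings.catch_warnings():
        # the published designs use n = 1000 and 50, not powers of two; the
        # balance caveat is irrelevant for space-filling use
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        return sampler.random(n)


def _scale(u: np.ndarray, bounds: Sequence[tuple[float, float]]) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + u * (hi - lo)


def sobol_cohort(
    varied: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    n: int,
    seed: int | None = None,
    reference: ParameterSet | None = None,
) -> list[VirtualPatient]:
    """``n`` virtual patients with ``varied`` parameters Sobol-sampled within
    ``bounds`` and everything else at the reference values.

    Deterministic given the seed (scrambled Sobol sequence).
    """
    from .params import id71_optimal

    if reference is None:
        reference = id71_optimal()
    if n < 1:
        raise ValueError("n must be >= 1")
    for name in varied:
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter: {name}")
        lo, hi = bounds[name]
        if not hi > lo:
            raise ValueError(f"bounds for {name} must have positive width")
    u = _sobol_unit(len(varied), n, seed)
    values = _scale(u, [bounds[name] for name in varied])
    patients = []
    for i in range(n):
        overrides = {name: float(values[i, k]) for k, name in enumerate(varied)}
        patients.append(
            VirtualPatient(reference.replace(**overrides), tuple(varied), index=i)
        )
    return patients


def paired_sobol_axes(
    M_bounds: tuple[float, float],
    beta_bounds: tuple[float, float],
    n_per_axis: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent 1-D Sobol axes (sorted), crossed into an
    ``n_per_axis x n_per_axis`` design: every metabolic-load value is paired
    with every cell-death-sensitivity value."""
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be >= 2")
    m = _scale(_sobol_unit(1, n_per_axis, seed), [M_bounds])[:, 0]
    seed2 = None if seed is None else seed + 1
    b = _scale(_sobol_unit(1, n_per_axis, seed2), [beta_bounds])[:, 0]
    return np.sort(m), np.sort(b)


def sweep_modes(
    cohort: Sequence[VirtualPatient],
    resection_fraction: float,
    horizon: float = MODE_HORIZON,
    solver: SolverOptions = SolverOptions(),
) -> list[tuple[VirtualPatient, ResponseMode | None]]:
    """Classify every patient's response at one resection level.

    Per-patient integration failures are logged and yield None rather than
    aborting a long cohort run; results are independent of execution order.
    """
    out: list[tuple[VirtualPatient, ResponseMode | None]] = []
    for patient in cohort:
        try:
            tr = simulate_resection(
                patient.params,
                resection_fraction,
                horizon=horizon,
                solver=solver,
                failure_exit=0.05,
            )
            out.append((patient, classify_response(tr)))
        except Exception:
            logger.exception("patient %d failed", patient.index)
            out.append((patient, None))
    return out


def modes_frame(
    results: Sequence[tuple[VirtualPatient, ResponseMode | None]],
) -> pd.DataFrame:
    """Tidy one-row-per-patient view of a mode sweep."""
    rows = []
    for patient, mode in results:
        row: dict = {"patient": patient.index, **patient.varied_values()}
        row["mode"] = None if mode is None else mode.label
        if mode is not None:
            row["n_end"] = mode.n_end
        rows.append(row)
    return pd.DataFrame(rows)


def classify_parameter_influence(
    name: str,
    bounds: tuple[float, float] | None = None,
    n_levels: int = 7,
    resection_fraction: float = 2.0 / 3.0,
    reference: ParameterSet | None = None,
    horizon: float = MODE_HORIZON,
    delta_sens: float = 0.05,
    solver: SolverOptions = SolverOptions(),
) -> InfluenceClass:
    """One-at-a-time sweep of a parameter and its directional influence.

    The parameter is swept over ``bounds`` (default: ten-fold around the
    reference for the strongly rescaled parameters, two-fold otherwise) on a
    log grid.  The outcome class records whether any level drives the liver
    to failure; sensitivity is judged from the spread of the long-term mass
    fraction across non-failing levels and its correlation with the
    parameter value.
    """
    from .params import id71_optimal

    if n_levels < 5:
        raise ValueError("need at least 5 sweep levels")
    if reference is None:
        reference = id71_optimal()
    ref_value = getattr(reference, name)  # raises AttributeError for unknown
    if bounds is None:
        fold = 10.0 if name in TENFOLD_PARAMS else 2.0
        bounds = (ref_value / fold, ref_value * fold)
    levels = np.geomspace(bounds[0], bounds[1], n_levels)

    finals = np.full(n_levels, np.nan)
    any_failure = False
    for i, value in enumerate(levels):
        p = reference.replace(**{name: float(value)})
        tr = simulate_resection(
            p, resection_fraction, horizon=horizon, solver=solver, failure_exit=0.05
        )
        mode = classify_response(tr)
        if mode.label == "failure":
            any_failure = True
        else:
            finals[i] = mode.n_end

    outcome = "recovery-and-failure" if any_failure else "recovery-only"
    ok = ~np.isnan(finals)
    spread = float(np.ptp(finals[ok])) if ok.sum() >= 2 else np.inf
    if spread <= delta_sens and not any_failure:
        sensitivity = "insensitive"
    elif any_failure:
        sensitivity = "sensitive" if (spread > delta_sens or ok.sum() < 2) else "insensitive"
    else:
        slope = np.corrcoef(np.log(levels[ok]), finals[ok])[0, 1]
        sensitivity = "sensitive-improves" if slope > 0 else "sensitive-decelerates"
    return InfluenceClass(name, outcome, sensitivity, levels, finals)


def decision_boundary(
    points: np.ndarray,
    labels: Sequence[str],
    C_grid: Sequence[float] | None = None,
    cv: int = 5,
    seed: int | None = None,
) -> SVC:
    """Cubic-polynomial-kernel SVM separating normal growth from the rest.

    The regularization constant is selected by cross-validation over a log
    grid spanning [1, 1e4].  Returns the fitted classifier; its decision
    function can be evaluated on a grid to draw the boundary.
    """
    points = np.asarray(points, dtype=float)
    y = np.asarray(["normal" if l == "normal" else "other" for l in labels])
    if len(set(y)) < 2:
        raise ValueError("need at least two classes to fit a boundary")
    if C_grid is None:
        C_grid = np.logspace(0, 4, 9)
    n_min = min(np.sum(y == "normal"), np.sum(y == "other"))
    cv = int(min(cv, n_min)) if n_min >= 2 else 2
    search = GridSearchCV(
        SVC(kernel="poly", degree=3, gamma="scale"),
        {"C": list(C_grid)},
        cv=cv,
        n_jobs=None,
    )
    search.fit(points, y)
    return search.best_estimator_


def recovery_region_extent(
    results: Sequence[tuple[VirtualPatient, ResponseMode | None]],
) -> float:
    """Fraction of the sampled parameter space in the normal-recovery mode
    (Monte-Carlo area estimate under the cohort's sampling bounds)."""
    modes = [m for _, m in results if m is not None]
    if not modes:
        raise ValueError("empty mode map")
    return sum(m.label == "normal" for m in modes) / len(modes)


def threshold_map(
    M_bounds: tuple[float, float] = DEFAULT_BOUNDS["M"],
    beta_bounds: tuple[float, float] = DEFAULT_BOUNDS["beta_ap"],
    n_per_axis: int = 50,
    seed: int | None = None,
    reference: ParameterSet | None = None,
    grid: Sequence[float] | None = None,
    horizon: float = FATE_HORIZON,
    solver: SolverOptions = SolverOptions(),
) -> ThresholdMap:
    """Threshold of failure over the paired (M, beta_ap) Sobol design.

    The resulting map splits into a bistable zone (finite threshold; both
    recovery and failure attractors exist) and a monostable "none-safe" zone,
    separated by the separatrix.  Per-cell failures are logged as None cells.
    """
    from .params import id71_optimal

    if reference is None:
        reference = id71_optimal()
    Ms, betas = paired_sobol_axes(M_bounds, beta_bounds, n_per_axis, seed)
    thresholds = np.empty((len(Ms), len(betas)), dtype=object)
    for i, m in enumerate(Ms):
        for j, b in enumerate(betas):
            p = reference.replace(M=float(m), beta_ap=float(b))
            try:
                thresholds[i, j] = threshold_of_failure(
                    p, grid=grid, horizon=horizon, solver=solver
                )
            except Exception:
                logger.exception("cell (M=%g, beta_ap=%g) failed", m, b)
                thresholds[i, j] = None
    return ThresholdMap(Ms, betas, thresholds, reference)
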