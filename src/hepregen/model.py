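"""Right-hand side of the 11-variable liver regeneration system.

State layout (all dimensionless, relative to the intact organ):

======== =====================================================================
``Q``     quiescent hepatocyte fraction
``P``     primed hepatocyte fraction
``R``     replicating hepatocyte fraction
``IL6``   interleukin-6 (Kupffer-cell cytokine), baseline 1
``JAK``   activated JAK, baseline 1
``STAT3`` activated STAT3, baseline 1
``SOCS3`` SOCS3 feedback inhibitor, baseline 1
``IE``    immediate-early gene product driving priming, baseline 1
``GF``    growth factor (HGF) driving replication, baseline 1
``ECM``   extracellular matrix, baseline 1
``G``     relative cell mass (hypertrophy of cycling cells), baseline 1
======== =====================================================================

The functional liver mass is ``N = Q + G*(P + R)``; organ-scale demand per
functional cell is ``M / (N + epsilon)``, where the senescent fraction
``epsilon`` keeps the denominator away from zero in failure scenarios.  Two
saturating tanh switches close the cell-state loop: ``sigma_ap`` (apoptosis as
per-cell load rises, i.e. as ``(N + epsilon)/M`` falls below ``theta_ap``) and
``sigma_req`` (return to quiescence once growth factor falls below
``theta_req``).

The time base is days.  The published source never states the unit explicitly;
a per-day base is the only one consistent with the rate magnitudes and the
multi-year recovery horizons, and is used throughout this package.
"""

from __future__ import annotations

import math

import numpy as np

from .params import DerivedConstants, ParameterSet, derived_constants

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "sigma_ap",
    "sigma_req",
    "total_mass",
    "baseline_state",
    "rhs",
    "rhs_jacobian",
]

STATE_NAMES: tuple[str, ...] = (
    "Q", "P", "R", "IL6", "JAK", "STAT3", "SOCS3", "IE", "GF", "ECM", "G",
)
N_STATES = len(STATE_NAMES)

#: tanh arguments are clipped here; tanh(50) is 1 to double precision, so the
#: clip changes no value but avoids overflow warnings for extreme states.
_TANH_CLIP = 50.0


def _tanh_switch(arg):
    return 0.5 * (1.0 + np.tanh(np.clip(arg, -_TANH_CLIP, _TANH_CLIP)))


def sigma_ap(N, p: ParameterSet):
    """Apoptosis switch in [0, 1]: rises as per-cell load grows.

    ``sigma_ap = (1 + tanh((theta_ap - (N + eps)/M) / beta_ap)) / 2``;
    decreasing in the mass fraction ``N``, increasing in the load ``M``.
    Accepts scalars or arrays.
    """
    return _tanh_switch((p.theta_ap - (np.asarray(N) + p.epsilon) / p.M) / p.beta_ap)


def sigma_req(GF, p: ParameterSet):
    """Requiescence switch in [0, 1]: primed cells revert once GF is low.

    ``sigma_req = (1 + tanh((theta_req - GF) / beta_req)) / 2``.
    """
    return _tanh_switch((p.theta_req - np.asarray(GF)) / p.beta_req)


def total_mass(state) -> float:
    """Functional liver mass fraction ``N = Q + G*(P + R)``.

    Quiescent cells contribute unit mass; cycling (primed/replicating) cells
    carry the relative cell mass ``G``, so hypertrophy enters through the
    cycling pool.  ``state`` is an 11-vector or an (n, 11) array.
    """
    s = np.asarray(state)
    return s[..., 0] + s[..., 10] * (s[..., 1] + s[..., 2])


def baseline_state(p: ParameterSet) -> np.ndarray:
    """The intact-organ steady state: Q = N_ss, P = R = 0, species and G = 1."""
    y = np.ones(N_STATES)
    y[0] = p.N_ss
    y[1] = y[2] = 0.0
    return y


def rhs(
    t: float,
    y: np.ndarray,
    p: ParameterSet,
    c: DerivedConstants | None = None,
) -> np.ndarray:
    """Time derivatives of the 11 state variables (per day).

    The system is autonomous; ``t`` is accepted for solver compatibility only.
    ``c`` may be precomputed with :func:`hepregen.params.derived_constants`
    and reused across calls (it depends only on ``p``).
    """
    if c is None:
        c = derived_constants(p)
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.argmax(~np.isfinite(y)))]
        raise ValueError(f"non-finite state component: {bad}")

    Q, P, R, IL6, JAK, ST3, SOCS3, IE, GF, ECM, G = y
    N = Q + G * (P + R)
    load = p.M / (N + p.epsilon)
    s_ap = float(sigma_ap(N, p))
    s_req = float(sigma_req(GF, p))

    prime = p.k_QP * (IE - 1.0) * Q           # IE above baseline primes Q
    advance = p.k_PR * (GF - 1.0) * P         # GF above baseline drives P -> R
    requiesce = p.k_req * s_req * P
    revert = p.k_RQ * ECM * R                 # restored matrix returns R -> Q

    jak_act = p.V_JAK * IL6 / (IL6 + p.KM_JAK)
    pro2 = p.proSTAT3 * p.proSTAT3
    st3_act = p.V_ST3 * JAK * pro2 / (pro2 + p.KM_ST3 * (1.0 + SOCS3 / p.KI_SOCS3))
    ie_prod = p.V_IE * ST3 / (ST3 + p.KM_IE)
    socs3_prod = p.V_SOCS3 * ST3 / (ST3 + p.KM_SOCS3)

    dy = np.empty(N_STATES)
    dy[0] = -prime + revert + requiesce - p.k_ap * s_ap * Q
    dy[1] = prime - advance - requiesce - p.k_ap * s_ap * P
    dy[2] = advance - revert + p.k_prol * R - p.k_ap * s_ap * R
    dy[3] = p.k_IL6 * load - jak_act - p.kappa_IL6 * IL6 + c.k1
    dy[4] = jak_act - p.kappa_JAK * JAK + c.k2
    dy[5] = st3_act - ie_prod - socs3_prod - p.kappa_ST3 * ST3 + c.k3
    dy[6] = socs3_prod - p.kappa_SOCS3 * SOCS3 + c.k4
    dy[7] = ie_prod - p.kappa_IE * IE + c.k5
    dy[8] = p.k_GF * load - p.k_up * GF * ECM - p.kappa_GF * GF + c.k7
    dy[9] = -p.k_deg * IL6 * ECM - p.kappa_ECM * ECM + c.k6
    dy[10] = p.k_G * load - p.k_G * p.M
    return dy


def rhs_jacobian(
    t: float,
    y: np.ndarray,
    p: ParameterSet,
    c: DerivedConstants | None = None,
) -> np.ndarray:
    """Analytic 11x11 Jacobian of :func:`rhs` (the system is stiff; an exact
    Jacobian lets the implicit solver take far larger steps)."""
    Q, P, R, IL6, JAK, ST3, SOCS3, IE, GF, ECM, G = y
    N = Q + G * (P + R)
    Ne = N + p.epsilon
    # d(load)/dN and d(sigma_ap)/dN; sech^2 underflows harmlessly in the tails
    dload = -p.M / (Ne * Ne)
    a_ap = (p.theta_ap - Ne / p.M) / p.beta_ap
    a_ap = min(max(a_ap, -_TANH_CLIP), _TANH_CLIP)
    s_ap = 0.5 * (1.0 + math.tanh(a_ap))
    dsap = -0.5 * (1.0 - math.tanh(a_ap) ** 2) / (p.M * p.beta_ap)
    a_rq = (p.theta_req - GF) / p.beta_req
    a_rq = min(max(a_rq, -_TANH_CLIP), _TANH_CLIP)
    s_req = 0.5 * (1.0 + math.tanh(a_rq))
    dsrq = -0.5 * (1.0 - math.tanh(a_rq) ** 2) / p.beta_req

    # dN/dx for x in (Q, P, R, G)
    nQ, nP, nR, nG = 1.0, G, G, P + R

    J = np.zeros((N_STATES, N_STATES))

    # cellular states ------------------------------------------------------
    ap = p.k_ap
    # dQ'
    J[0, 0] = -p.k_QP * (IE - 1.0) - ap * (s_ap + Q * dsap * nQ)
    J[0, 1] = p.k_req * s_req - ap * Q * dsap * nP
    J[0, 2] = p.k_RQ * ECM - ap * Q * dsap * nR
    J[0, 7] = -p.k_QP * Q
    J[0, 8] = p.k_req * dsrq * P
    J[0, 9] = p.k_RQ * R
    J[0, 10] = -ap * Q * dsap * nG
    # dP'
    J[1, 0] = p.k_QP * (IE - 1.0) - ap * P * dsap * nQ
    J[1, 1] = -p.k_PR * (GF - 1.0) - p.k_req * s_req - ap * (s_ap + P * dsap * nP)
    J[1, 2] = -ap * P * dsap * nR
    J[1, 7] = p.k_QP * Q
    J[1, 8] = -p.k_PR * P - p.k_req * dsrq * P
    J[1, 10] = -ap * P * dsap * nG
    # dR'
    J[2, 0] = -ap * R * dsap * nQ
    J[2, 1] = p.k_PR * (GF - 1.0) - ap * R * dsap * nP
    J[2, 2] = -p.k_RQ * ECM + p.k_prol - ap * (s_ap + R * dsap * nR)
    J[2, 8] = p.k_PR * P
    J[2, 9] = -p.k_RQ * R
    J[2, 10] = -ap * R * dsap * nG

    # molecular species ----------------------------------------------------
    djak = p.V_JAK * p.KM_JAK / (IL6 + p.KM_JAK) ** 2
    pro2 = p.proSTAT3 * p.proSTAT3
    D = pro2 + p.KM_ST3 * (1.0 + SOCS3 / p.KI_SOCS3)
    die = p.V_IE * p.KM_IE / (ST3 + p.KM_IE) ** 2
    dsocs = p.V_SOCS3 * p.KM_SOCS3 / (ST3 + p.KM_SOCS3) ** 2

    for i, gain in ((3, p.k_IL6), (8, p.k_GF), (10, p.k_G)):
        J[i, 0] += gain * dload * nQ
        J[i, 1] += gain * dload * nP
        J[i, 2] += gain * dload * nR
        J[i, 10] += gain * dload * nG

    J[3, 3] += -djak - p.kappa_IL6
    J[4, 3] = djak
    J[4, 4] = -p.kappa_JAK
    J[5, 4] = p.V_ST3 * pro2 / D
    J[5, 5] = -die - dsocs - p.kappa_ST3
    J[5, 6] = -p.V_ST3 * JAK * pro2 * (p.KM_ST3 / p.KI_SOCS3) / (D * D)
    J[6, 5] = dsocs
    J[6, 6] = -p.kappa_SOCS3
    J[7, 5] = die
    J[7, 7] = -p.kappa_IE
    J[8, 8] += -p.k_up * ECM - p.kappa_GF
    J[8, 9] = -p.k_up * GF
    J[9, 3] = -p.k_deg * ECM
    J[9, 9] = -p.k_deg * IL6 - p.kappa_ECM
    return J
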