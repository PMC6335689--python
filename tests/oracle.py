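"""Independent transcription of the model equations, used only as a test
oracle.

Deliberately written in a different style from the package (plain floats,
no shared helpers, every balance written out longhand) so that agreement
with ``hepregen.model.rhs`` is a genuine dual-implementation check.
"""

import math


def oracle_rhs(y, pd):
    """11 time-derivatives from a dict of parameter values (ASCII names,
    plus 'epsilon' and 'N_ss')."""
    Q, P, R, IL6, JAK, STAT3, SOCS3, IE, GF, ECM, G = [float(v) for v in y]
    eps = pd.get("epsilon", 0.01)
    Nss = pd.get("N_ss", 0.99)
    M = pd["M"]

    N = Q + G * (P + R)
    load = M / (N + eps)
    base = M / (Nss + eps)

    def th(x):
        return math.tanh(max(-50.0, min(50.0, x)))

    s_ap = 0.5 * (1.0 + th((pd["theta_ap"] - (N + eps) / M) / pd["beta_ap"]))
    s_req = 0.5 * (1.0 + th((pd["theta_req"] - GF) / pd["beta_req"]))

    pro2 = pd["proSTAT3"] ** 2
    k1 = pd["V_JAK"] / (1.0 + pd["KM_JAK"]) - pd["k_IL6"] * base + pd["kappa_IL6"]
    k2 = pd["kappa_JAK"] - pd["V_JAK"] / (1.0 + pd["KM_JAK"])
    k3 = (
        -pd["V_ST3"] * pro2 / (pro2 + pd["KM_ST3"] * (1.0 + 1.0 / pd["KI_SOCS3"]))
        + pd["V_IE"] / (1.0 + pd["KM_IE"])
        + pd["V_SOCS3"] / (1.0 + pd["KM_SOCS3"])
        + pd["kappa_ST3"]
    )
    k4 = -pd["V_SOCS3"] / (1.0 + pd["KM_SOCS3"]) + pd["kappa_SOCS3"]
    k5 = -pd["V_IE"] / (1.0 + pd["KM_IE"]) + pd["kappa_IE"]
    k6 = pd["k_deg"] + pd["kappa_ECM"]
    k7 = -pd["k_GF"] * base + pd["k_up"] + pd["kappa_GF"]

    dQ = (
        -pd["k_QP"] * (IE - 1.0) * Q
        + pd["k_RQ"] * ECM * R
        + pd["k_req"] * s_req * P
        - pd["k_ap"] * s_ap * Q
    )
    dP = (
        pd["k_QP"] * (IE - 1.0) * Q
        - pd["k_PR"] * (GF - 1.0) * P
        - pd["k_req"] * s_req * P
        - pd["k_ap"] * s_ap * P
    )
    dR = (
        pd["k_PR"] * (GF - 1.0) * P
        - pd["k_RQ"] * ECM * R
        + pd["k_prol"] * R
        - pd["k_ap"] * s_ap * R
    )
    dIL6 = (
        pd["k_IL6"] * load
        - pd["V_JAK"] * IL6 / (IL6 + pd["KM_JAK"])
        - pd["kappa_IL6"] * IL6
        + k1
    )
    dJAK = pd["V_JAK"] * IL6 / (IL6 + pd["KM_JAK"]) - pd["kappa_JAK"] * JAK + k2
    dSTAT3 = (
        pd["V_ST3"] * JAK * pro2 / (pro2 + pd["KM_ST3"] * (1.0 + SOCS3 / pd["KI_SOCS3"]))
        - pd["V_IE"] * STAT3 / (STAT3 + pd["KM_IE"])
        - pd["V_SOCS3"] * STAT3 / (STAT3 + pd["KM_SOCS3"])
        - pd["kappa_ST3"] * STAT3
        + k3
    )
    dSOCS3 = pd["V_SOCS3"] * STAT3 / (STAT3 + pd["KM_SOCS3"]) - pd["kappa_SOCS3"] * SOCS3 + k4
    dIE = pd["V_IE"] * STAT3 / (STAT3 + pd["KM_IE"]) - pd["kappa_IE"] * IE + k5
    dGF = pd["k_GF"] * load - pd["k_up"] * GF * ECM - pd["kappa_GF"] * GF + k7
    dECM = -pd["k_deg"] * IL6 * ECM - pd["kappa_ECM"] * ECM + k6
    dG = pd["k_G"] * load - pd["k_G"] * M

    return [dQ, dP, dR, dIL6, dJAK, dSTAT3, dSOCS3, dIE, dGF, dECM, dG]
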