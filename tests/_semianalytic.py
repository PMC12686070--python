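"""Independent steady-state oracle: direct root-finding on the balance equations.

Deliberately does not reuse the package's integrator. At a persistent
steady state the limiting factor equals a/mu_max, which yields closed-form
residual concentrations for nutrient limitation (R* rule) and a 1-D root
problem for light limitation; biomass follows from mass balance. The
consistent candidate is the one with the smallest biomass cap.
"""

from scipy.optimize import brentq

from terlake import ModelParams, Supply, light_limitation


def steady_state_oracle(params: ModelParams, supply: Supply):
    """Return (A*, N*, P*, limiter) or washout equivalents."""
    r = params.a / params.mu_max
    washout = (0.0, supply.N_in, supply.P_in, "washout")
    if r >= 1:
        return washout
    n_star = params.m_N * r / (1 - r)
    p_star = params.m_P * r / (1 - r)
    candidates = []

    a_n = (supply.N_in - n_star) / params.c_N
    if a_n > 0:
        p = supply.P_in - params.c_P * a_n
        if p >= p_star - 1e-12 and light_limitation(a_n, params) >= r - 1e-12:
            candidates.append((a_n, n_star, p, "N"))

    a_p = (supply.P_in - p_star) / params.c_P
    if a_p > 0:
        n = supply.N_in - params.c_N * a_p
        if n >= n_star - 1e-12 and light_limitation(a_p, params) >= r - 1e-12:
            candidates.append((a_p, n, p_star, "P"))

    if light_limitation(0.0, params) > r:
        hi = 10 * max(a_n, a_p, 1.0)
        if light_limitation(hi, params) < r:
            a_l = brentq(lambda A: light_limitation(A, params) - r, 1e-9, hi, xtol=1e-10)
            n = supply.N_in - params.c_N * a_l
            p = supply.P_in - params.c_P * a_l
            if n >= n_star - 1e-9 and p >= p_star - 1e-9:
                candidates.append((a_l, n, p, "light"))

    if not candidates:
        return washout
    return min(candidates, key=lambda c: c[0])
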