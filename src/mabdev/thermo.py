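"""Two-state unfolding thermodynamics.

The kernel shared by the simulator and the DSC deconvolution: an
independent two-state transition with midpoint ``tm`` (°C) and van't Hoff
enthalpy ``dhvh`` (kcal/mol) has equilibrium constant

    K(T) = exp[(dH_vH / R) * (1/T_m - 1/T)]      (T in kelvin)

unfolded population f = K / (1 + K), and contributes an excess heat
capacity  dH_cal * df/dT  with  df/dT = dH_vH / (R T^2) * f (1 - f).
"""

from __future__ import annotations

import numpy as np

from .constants import R_KCAL, celsius_to_kelvin


def unfolded_fraction(t_c, tm_c: float, dhvh: float):
    """Two-state unfolded population f(T) on a Celsius grid."""
    tk = celsius_to_kelvin(np.asarray(t_c, dtype=float))
    tmk = celsius_to_kelvin(tm_c)
    lnk = (dhvh / R_KCAL) * (1.0 / tmk - 1.0 / tk)
    # logistic in lnK, computed stably on both tails
    out = np.empty_like(lnk)
    pos = lnk >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-lnk[pos]))
    ek = np.exp(lnk[~pos])
    out[~pos] = ek / (1.0 + ek)
    return out


def dfraction_dT(t_c, tm_c: float, dhvh: float):
    """Derivative df/dT (per °C) of the two-state population."""
    tk = celsius_to_kelvin(np.asarray(t_c, dtype=float))
    f = unfolded_fraction(t_c, tm_c, dhvh)
    return dhvh / (R_KCAL * tk * tk) * f * (1.0 - f)


def excess_heat_capacity(t_c, transitions):
    """Sum of two-state peaks.

    ``transitions`` is an iterable of objects with ``tm``/``tm_true``,
    calorimetric area and van't Hoff enthalpy accessors; here we accept
    plain (tm, area, dhvh) triples to stay agnostic.
    """
    t_c = np.asarray(t_c, dtype=float)
    cp = np.zeros_like(t_c)
    for tm, area, dhvh in transitions:
        cp += area * dfraction_dT(t_c, tm, dhvh)
    return cp


def global_unfolded_fraction(t_c, transitions):
    """Calorimetric-weighted global unfolded fraction.

    Weights each transition's population by its share of the total
    calorimetric enthalpy, which equals the normalised running integral
    of the noiseless thermogram.
    """
    t_c = np.asarray(t_c, dtype=float)
    triples = list(transitions)
    total = sum(area for _, area, _ in triples)
    if total <= 0:
        raise ValueError("total calorimetric enthalpy must be positive")
    f = np.zeros_like(t_c)
    for tm, area, dhvh in triples:
        f += (area / total) * unfolded_fraction(t_c, tm, dhvh)
    return f
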