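"""Physical constants and unit helpers.

All public interfaces use degrees Celsius; conversion to kelvin happens
inside the thermodynamic kernel only, because instrument exports are in °C.
Enthalpies are in kcal/mol throughout, hence the gas constant below.
"""

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.987204e-3

#: Offset between Celsius and kelvin scales.
KELVIN_OFFSET = 273.15

#: Numerical factor linking the full width at half maximum of a two-state
#: excess-heat-capacity peak to its van't Hoff enthalpy:
#: FWHM ~= FWHM_FACTOR * R * T_m[K]^2 / dH_vH.  It comes from solving
#: f(1-f) = 1/8 for the two-state population f, i.e. ln(f/(1-f)) = ±1.7627.
FWHM_FACTOR = 2.0 * 1.76275


def celsius_to_kelvin(t_c):
    return t_c + KELVIN_OFFSET


def width_from_dhvh(tm_c: float, dhvh: float) -> float:
    """FWHM (°C) of a two-state peak with midpoint ``tm_c`` and van't Hoff
    enthalpy ``dhvh`` (kcal/mol)."""
    tk = celsius_to_kelvin(tm_c)
    return FWHM_FACTOR * R_KCAL * tk * tk / dhvh


def dhvh_from_width(tm_c: float, width: float) -> float:
    """Inverse of :func:`width_from_dhvh`."""
    tk = celsius_to_kelvin(tm_c)
    return FWHM_FACTOR * R_KCAL * tk * tk / width
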