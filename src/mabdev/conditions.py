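"""Formulation metadata attached to every measured or simulated trace."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError


@dataclass(frozen=True)
class FormulationCondition:
    """One (mAb, pH, NaCl) formulation.

    The study design screens each antibody across pH 4-8 combined with
    0, 50 or 150 mM NaCl; arbitrary values inside those physical ranges
    are accepted.
    """

    mab_id: str
    pH: float
    nacl_mM: float

    def __post_init__(self):
        if not (4.0 <= self.pH <= 8.0):
            raise InvalidInputError(f"pH must lie in [4, 8], got {self.pH}")
        if self.nacl_mM < 0:
            raise InvalidInputError(f"NaCl concentration must be >= 0, got {self.nacl_mM}")

    @property
    def sample_id(self) -> str:
        nacl = int(self.nacl_mM) if float(self.nacl_mM).is_integer() else self.nacl_mM
        ph = int(self.pH) if float(self.pH).is_integer() else self.pH
        return f"{self.mab_id}_pH{ph}_NaCl{nacl}"
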