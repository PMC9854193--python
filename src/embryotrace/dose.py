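"""Injection-dose arithmetic for zygotic ribonucleoprotein delivery."""

from __future__ import annotations

import math
from dataclasses import dataclass

AVOGADRO = 6.02214076e23

__all__ = ["InjectionDose", "round_sig", "molecules_per_embryo",
           "molecules_per_cell", "molar_ratio"]


@dataclass
class InjectionDose:
    """A single zygotic injection: molar concentration, volume (L), and the
    number of synchronous divisions over which the dose is diluted."""

    concentration_m: float
    volume_l: float
    n_cycles: int = 0

    def __post_init__(self) -> None:
        if self.concentration_m < 0 or self.volume_l < 0 or self.n_cycles < 0:
            raise ValueError("dose fields must be non-negative")


def round_sig(x: float, n: int) -> float:
    """Round x to n significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, n - 1 - int(math.floor(math.log10(abs(x)))))


def molecules_per_embryo(dose: InjectionDose) -> float:
    """Injected molecule count: concentration x volume x N_A (2 sig figs)."""
    return round_sig(dose.concentration_m * dose.volume_l * AVOGADRO, 2)


def molecules_per_cell(total: float, n_cycles: int) -> float:
    """Molecules per cell after n synchronous divisions: total / 2^n (1 sig fig)."""
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    if total < 0:
        raise ValueError("total must be non-negative")
    return round_sig(total / 2**n_cycles, 1)


def molar_ratio(c_grna: float, c_protein: float) -> float:
    """gRNA : protein molar ratio."""
    if c_protein <= 0:
        raise ValueError("protein concentration must be positive")
    if c_grna < 0:
        raise ValueError("gRNA concentration must be non-negative")
    return c_grna / c_protein
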