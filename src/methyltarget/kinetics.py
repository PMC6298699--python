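"""Kinetic model of target/non-target methylation specificity.

A methyltransferase tethered near its target site experiences the target CpG
at an elevated effective concentration, while untethered (non-target) sites
remain at a low effective concentration.  With Michaelis-Menten saturation in
effective CpG concentration C,

    v(C) = kcat * C / (Km + C),

raising Km moves both sites out of saturation but suppresses the
low-concentration (non-target) site proportionally more, so affinity-
weakening mutations that increase Km for DNA improve the target/non-target
specificity ratio

    v(C_target) / v(C_nontarget),

which rises monotonically with Km from 1 (both sites saturated) towards the
concentration ratio C_target / C_nontarget (linear regime).  The ratio is
independent of kcat, which is why the argument applies equally to a
catalytically compromised split enzyme.  Units are arbitrary: effective
concentrations are relative quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = ["KineticParams", "velocity", "specificity_ratio", "km_scan"]


@dataclass(frozen=True)
class KineticParams:
    """Michaelis-Menten parameters plus the two effective concentrations."""

    Km: float
    kcat: float = 1.0
    C_target: float = 0.0
    C_nontarget: float = 0.0

    def __post_init__(self):
        if self.Km <= 0 or self.kcat <= 0:
            raise ValueError("Km and kcat must be > 0")
        if self.C_target < 0 or self.C_nontarget < 0:
            raise ValueError("effective concentrations must be >= 0")


def velocity(C: float, params: KineticParams) -> float:
    """Methylation rate at effective CpG concentration C."""
    if np.any(np.asarray(C) < 0):
        raise ValueError("C must be >= 0")
    return params.kcat * C / (params.Km + C)


def specificity_ratio(params: KineticParams) -> float:
    """v(C_target) / v(C_nontarget); kcat cancels.

    >= 1 whenever C_target >= C_nontarget, approaching 1 as Km -> 0 and
    C_target / C_nontarget as Km -> infinity.
    """
    if params.C_nontarget == 0:
        raise ZeroDivisionError("C_nontarget must be > 0 for a specificity ratio")
    ct, cnt, km = params.C_target, params.C_nontarget, params.Km
    return (ct / (km + ct)) * ((km + cnt) / cnt)


def km_scan(C_grid, Km_values, kcat: float = 1.0) -> pd.DataFrame:
    """Activity over a (C, Km) grid, long format for log-scale plotting."""
    C_grid = np.asarray(list(C_grid), dtype=float)
    Km_values = np.asarray(list(Km_values), dtype=float)
    if C_grid.size == 0 or Km_values.size == 0:
        raise ValueError("grids must be non-empty")
    rows = [
        (c, km, velocity(c, KineticParams(Km=km, kcat=kcat)))
        for km, c in product(Km_values, C_grid)
    ]
    return pd.DataFrame(rows, columns=["C", "Km", "activity"])
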