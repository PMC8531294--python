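"""Surface density of covalent ECM anchorage points from co-factor concentration.

The AHA co-factor copolymerised into a polyacrylamide network carries a
terminal carboxyl group that serves as a covalent anchorage point for ECM
proteins.  Treating the anchorage points as uniformly distributed in the gel
volume, the number per unit surface area follows from the volumetric number
density ``N_A * [AHA]`` (sites per litre, i.e. per dm^3) by taking the 2/3
power and converting dm^-2 to um^-2:

    sigma = (N_A * [AHA])**(2/3) * 1e-10   [sites um^-2]

with [AHA] in mol/L.  The interface takes mM (the experimentally used
concentrations are 16, 48 and 80 mM); the 2/3-power scaling means an
increase from 16 to 80 mM raises sigma by 5**(2/3) ~ 2.9, i.e. the density
approximately triples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

__all__ = ["LigandDensity", "ligand_surface_density", "ligand_density_table"]


@dataclass(frozen=True)
class LigandDensity:
    concentration_mM: float
    sigma_per_um2: float

    def __post_init__(self) -> None:
        if self.sigma_per_um2 < 0:
            raise ValueError("sigma must be >= 0")
        if (self.sigma_per_um2 == 0) != (self.concentration_mM == 0):
            raise ValueError("sigma is 0 iff concentration is 0")


def ligand_surface_density(concentration_mM):
    """Anchorage-point surface density (sites um^-2) at the given AHA
    concentration in mM.  Scales as concentration**(2/3)."""
    c = np.asarray(concentration_mM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    molar = c * 1e-3  # mM -> mol/L
    sigma = (Avogadro * molar) ** (2.0 / 3.0) * 1e-10
    return sigma if sigma.ndim else float(sigma)


def ligand_density_table(concentrations_mM) -> pd.DataFrame:
    """Tabulate sigma and the fold change versus the first concentration."""
    c = np.asarray(concentrations_mM, dtype=float)
    sigma = np.asarray(ligand_surface_density(c), dtype=float)
    ref = sigma[0] if sigma.size and sigma[0] > 0 else np.nan
    return pd.DataFrame(
        {
            "concentration_mM": c,
            "sigma_sites_per_um2": sigma,
            "fold_vs_first": sigma / ref,
        }
    )
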