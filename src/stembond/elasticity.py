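"""Hertz-model fitting of approach segments to estimate Young's modulus.

For a rigid sphere of radius :math:`R` indenting an elastic half-space to
depth :math:`\\delta`, the Hertz contact model predicts

.. math::

    F = \\frac{4}{3} \\frac{E}{1 - \\nu^2} \\sqrt{R}\\, \\delta^{3/2}

with Young's modulus :math:`E` and Poisson ratio :math:`\\nu`.  Fitting an
approach force-distance curve requires jointly estimating the contact point
(the piezo height at which the tip first touches the surface) and
:math:`E`.  :class:`HertzModel` scans every sample of the approach segment
as a candidate contact point; for each candidate, the indentation is the
piezo travel past contact minus the cantilever deflection, and :math:`E`
follows from a linear least-squares fit of force against
:math:`\\delta^{3/2}` through the origin.  The candidate minimising the
residual RMS (over pre-contact samples against zero force and in-contact
samples against the Hertz curve) wins.  The search runs on the acquisition
grid: it is deterministic and exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .forcecurve import PN_PER_NM_PER_NEWTON_PER_M, Segment

__all__ = [
    "HertzFit",
    "ModulusSummary",
    "NoContactError",
    "HertzModel",
    "hertz_force",
    "fit_hertz",
    "summarize_modulus",
]


class NoContactError(ValueError):
    """No candidate contact point yields a positive modulus with residual
    improvement over a flat zero-force model."""


def hertz_coefficient(E_Pa: float, poisson_ratio: float, bead_radius_um: float) -> float:
    """Prefactor A such that F_pN = A * delta_nm**1.5 under the Hertz model."""
    R_m = bead_radius_um * 1e-6
    # (nm -> m)**1.5 then N -> pN
    unit = (1e-9) ** 1.5 * 1e12
    return (4.0 / 3.0) * E_Pa / (1.0 - poisson_ratio**2) * np.sqrt(R_m) * unit


def hertz_force(indentation_nm, E_Pa: float, poisson_ratio: float, bead_radius_um: float):
    """Hertz force (pN) of a sphere indenting an elastic half-space.

    Parameters are the indentation depth in nm (>= 0), Young's modulus in
    Pa, the Poisson ratio, and the bead radius in um.
    """
    if E_Pa <= 0:
        raise ValueError("E_Pa must be positive")
    if bead_radius_um <= 0:
        raise ValueError("bead_radius_um must be positive")
    if not 0 <= poisson_ratio <= 0.5:
        raise ValueError("poisson_ratio must be in [0, 0.5]")
    delta = np.asarray(indentation_nm, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    out = hertz_coefficient(E_Pa, poisson_ratio, bead_radius_um) * delta**1.5
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HertzFit:
    """Result of fitting one approach segment."""

    youngs_modulus_Pa: float
    contact_point_nm: float
    poisson_ratio: float
    bead_radius_um: float
    residual_rms_pN: float
    n_points_in_contact: int

    def __post_init__(self) -> None:
        if self.youngs_modulus_Pa <= 0:
            raise ValueError("youngs_modulus_Pa must be positive")
        if self.n_points_in_contact < 5:
            raise ValueError("n_points_in_contact must be >= 5")


@dataclass(frozen=True)
class ModulusSummary:
    """Pooled and per-gel Young's modulus statistics."""

    group: str
    mean_E_Pa: float
    sd_E_Pa: float
    n_indentations: int
    n_gels: int
    per_gel_mean_Pa: dict

    def __post_init__(self) -> None:
        if self.sd_E_Pa < 0:
            raise ValueError("sd_E_Pa must be >= 0")


class HertzModel(BaseEstimator):
    """Sklearn-style estimator for the Hertz contact fit of an approach curve.

    Parameters
    ----------
    bead_radius_um : float
        Radius of the spherical probe in um.
    spring_constant : float
        Cantilever spring constant in N/m, used to convert force to
        deflection when computing indentation.
    poisson_ratio : float, default 0.5
        Poisson ratio of the substrate; 0.5 treats the hydrogel as
        incompressible.
    max_indentation_nm : float or None, default None
        Fit restricted to indentations up to this depth.  ``None`` uses 10%
        of the bead radius (the Hertz small-indentation validity regime).
    min_contact_points : int, default 5
        Candidate contact points must leave at least this many in-contact
        samples.

    Attributes
    ----------
    youngs_modulus_ : float
        Estimated Young's modulus in Pa.
    contact_point_ : float
        Estimated contact piezo height in nm.
    residual_rms_ : float
        RMS of force residuals (pN) at the winning candidate.
    n_points_in_contact_ : int
        Number of in-contact samples used in the winning fit.
    """

    def __init__(
        self,
        bead_radius_um: float = 18.64,
        spring_constant: float = 0.05,
        poisson_ratio: float = 0.5,
        max_indentation_nm: float | None = None,
        min_contact_points: int = 5,
    ):
        self.bead_radius_um = bead_radius_um
        self.spring_constant = spring_constant
        self.poisson_ratio = poisson_ratio
        self.max_indentation_nm = max_indentation_nm
        self.min_contact_points = min_contact_points

    def _resolve_max_indentation(self) -> float:
        if self.max_indentation_nm is not None:
            return float(self.max_indentation_nm)
        return 0.1 * self.bead_radius_um * 1000.0  # um -> nm

    def fit(self, X, y=None):
        """Fit the contact point and modulus.

        ``X`` is either a :class:`~stembond.forcecurve.Segment` or an
        array of shape (n, 2) with columns (piezo_height_nm, force_pN),
        baseline-corrected, with at least 50 samples.
        """
        if isinstance(X, Segment):
            z = X.piezo_height_nm
            f = X.force_pN
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("X must be a Segment or an (n, 2) array")
            z, f = arr[:, 0], arr[:, 1]
        if z.size < 50:
            raise ValueError("approach segment needs >= 50 samples")
        order = np.argsort(z)
        z = z[order]
        f = f[order]

        k_pn_nm = self.spring_constant * PN_PER_NM_PER_NEWTON_PER_M
        deflection = f / k_pn_nm
        max_indent = self._resolve_max_indentation()
        n = z.size
        flat_rms = float(np.sqrt(np.mean(f**2)))

        best = None  # (rms, c, A, n_contact)
        # Candidate contact points on the acquisition grid.  Candidate c puts
        # samples strictly past z[c] in contact.  Only samples within the
        # indentation window inform the least-squares slope, but residuals
        # cover the whole segment (pre-contact against zero, in-contact
        # against the fitted curve, extrapolated past the window), so no
        # candidate can look good by discarding the informative region.
        for c in range(n - self.min_contact_points):
            delta = (z[c + 1 :] - z[c]) - deflection[c + 1 :]
            contact = delta > 0
            use = contact & (delta <= max_indent)
            if int(use.sum()) < self.min_contact_points:
                continue
            x = delta[use] ** 1.5
            y_c = f[c + 1 :][use]
            denom = float(x @ x)
            if denom <= 0:
                continue
            A = float(x @ y_c) / denom
            if A <= 0:
                continue
            model = np.zeros(n - c - 1)
            model[contact] = A * delta[contact] ** 1.5
            rss = float(np.sum(f[: c + 1] ** 2)) + float(np.sum((f[c + 1 :] - model) ** 2))
            rms = np.sqrt(rss / n)
            if best is None or rms < best[0]:
                best = (rms, c, A, int(use.sum()))

        if best is None or best[0] >= flat_rms:
            raise NoContactError(
                "no contact point yields a positive modulus improving on the flat model"
            )
        rms, c, A, n_contact = best
        if c == 0 or c == n - self.min_contact_points - 1:
            warnings.warn(
                "best contact point lies at the edge of the sampling grid",
                RuntimeWarning,
                stacklevel=2,
            )
        coef_unit = hertz_coefficient(1.0, self.poisson_ratio, self.bead_radius_um)
        self.youngs_modulus_ = A / coef_unit
        self.contact_point_ = float(z[c])
        self.residual_rms_ = float(rms)
        self.n_points_in_contact_ = n_contact
        return self

    def result_(self) -> HertzFit:
        """The fitted parameters bundled as a :class:`HertzFit`."""
        return HertzFit(
            youngs_modulus_Pa=self.youngs_modulus_,
            contact_point_nm=self.contact_point_,
            poisson_ratio=self.poisson_ratio,
            bead_radius_um=self.bead_radius_um,
            residual_rms_pN=self.residual_rms_,
            n_points_in_contact=self.n_points_in_contact_,
        )


def fit_hertz(
    approach: Segment,
    bead_radius_um: float,
    spring_constant: float,
    poisson_ratio: float = 0.5,
    max_indentation_nm: float | None = None,
) -> HertzFit:
    """Fit the Hertz model to a baseline-corrected approach segment."""
    model = HertzModel(
        bead_radius_um=bead_radius_um,
        spring_constant=spring_constant,
        poisson_ratio=poisson_ratio,
        max_indentation_nm=max_indentation_nm,
    )
    model.fit(approach)
    return model.result_()


def summarize_modulus(fits: dict[str, list[HertzFit]], group: str = "") -> ModulusSummary:
    """Pool per-indentation Hertz fits grouped by gel id.

    ``fits`` maps gel id to the list of fits on that gel.  The summary
    reports the pooled mean and standard deviation over all indentations
    plus per-gel means, as for "mean +/- sd over 30 indentations/gel".
    A single pooled fit yields sd 0 (flagged by ``n_indentations == 1``).
    """
    if not fits or all(len(v) == 0 for v in fits.values()):
        raise ValueError("summarize_modulus needs at least one fit")
    all_E = np.array(
        [f.youngs_modulus_Pa for gel_fits in fits.values() for f in gel_fits], dtype=float
    )
    per_gel = {
        gel: float(np.mean([f.youngs_modulus_Pa for f in gel_fits]))
        for gel, gel_fits in fits.items()
        if gel_fits
    }
    sd = float(np.std(all_E, ddof=1)) if all_E.size > 1 else 0.0
    return ModulusSummary(
        group=group,
        mean_E_Pa=float(np.mean(all_E)),
        sd_E_Pa=sd,
        n_indentations=int(all_E.size),
        n_gels=len(per_gel),
        per_gel_mean_Pa=per_gel,
    )
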