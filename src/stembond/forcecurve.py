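"""Calibrated force-distance curves and segment-level preprocessing.

A force-distance curve records the vertical force on an AFM cantilever as the
piezo drives the probe toward (approach), holds at (dwell), and pulls away
from (retract) a sample surface.  All analysis in this package works in a
single unit system: piezo height in nm, force in pN, spring constant in N/m
(numerically 1 N/m == 1000 pN/nm).

Sign conventions
----------------
* Forces pushing the cantilever away from the surface (indentation) are
  positive; adhesive/tether forces on retract are negative.  Rupture forces
  are reported downstream as positive magnitudes.
* Piezo height increases toward the surface on approach.  Samples are stored
  in acquisition order, so piezo height is increasing on approach segments
  and decreasing on retract segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Segment",
    "ForceCurve",
    "BaselineModel",
    "SEGMENT_LABELS",
    "PROBE_LABELS",
    "deflection_to_force",
    "baseline_correct",
    "tip_sample_separation",
]

SEGMENT_LABELS = ("approach", "dwell", "retract")
PROBE_LABELS = ("anti_FN", "anti_IgG", "none")

#: 1 N/m expressed in pN/nm.
PN_PER_NM_PER_NEWTON_PER_M = 1000.0


@dataclass(frozen=True)
class Segment:
    """One labelled portion of a force-distance sweep.

    Parameters
    ----------
    label
        One of ``approach``, ``dwell``, ``retract``.
    piezo_height_nm
        Piezo height samples in nm, increasing toward the surface.  Must be
        strictly monotone within approach (increasing) and retract
        (decreasing) segments.
    force_pN
        Cantilever force in pN, same length as ``piezo_height_nm``.
    """

    label: str
    piezo_height_nm: np.ndarray
    force_pN: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        z = np.asarray(self.piezo_height_nm, dtype=float)
        f = np.asarray(self.force_pN, dtype=float)
        if z.ndim != 1 or f.ndim != 1 or z.shape != f.shape:
            raise ValueError("piezo_height_nm and force_pN must be 1-D arrays of equal length")
        if z.size < 2:
            raise ValueError("segments need at least 2 samples")
        if not (np.isfinite(z).all() and np.isfinite(f).all()):
            raise ValueError("non-finite values in segment data")
        dz = np.diff(z)
        if self.label == "approach" and not np.all(dz > 0):
            raise ValueError("approach segment must have strictly increasing piezo height")
        if self.label == "retract" and not np.all(dz < 0):
            raise ValueError("retract segment must have strictly decreasing piezo height")
        object.__setattr__(self, "piezo_height_nm", z)
        object.__setattr__(self, "force_pN", f)

    def __len__(self) -> int:
        return self.piezo_height_nm.size


@dataclass(frozen=True)
class ForceCurve:
    """A calibrated force-distance curve with probe metadata."""

    curve_id: str
    sample_id: str
    probe: str
    substrate: str
    spring_constant: float  # N/m
    segments: tuple = ()
    bead_radius_um: float | None = None  # absent for pyramidal tips

    def __post_init__(self) -> None:
        if self.probe not in PROBE_LABELS:
            raise ValueError(f"unknown probe {self.probe!r}; expected one of {PROBE_LABELS}")
        if not (np.isfinite(self.spring_constant) and self.spring_constant > 0):
            raise ValueError("spring_constant must be positive and finite")
        if self.bead_radius_um is not None and not self.bead_radius_um > 0:
            raise ValueError("bead_radius_um must be positive when present")
        segs = tuple(self.segments)
        labels = [s.label for s in segs]
        if len(labels) != len(set(labels)):
            raise ValueError("at most one segment per label")
        object.__setattr__(self, "segments", segs)

    def segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(f"curve {self.curve_id!r} has no {label!r} segment")

    @property
    def approach(self) -> Segment:
        return self.segment("approach")

    @property
    def retract(self) -> Segment:
        return self.segment("retract")


@dataclass(frozen=True)
class BaselineModel:
    """Linear baseline fitted on the far-from-surface end of a segment."""

    intercept_pN: float
    slope_pN_per_nm: float
    fit_region_fraction: float
    residual_rms_pN: float
    n_fit_points: int = field(default=0)

    def __post_init__(self) -> None:
        if not 0 < self.fit_region_fraction <= 1:
            raise ValueError("fit_region_fraction must be in (0, 1]")
        if self.residual_rms_pN < 0:
            raise ValueError("residual_rms_pN must be >= 0")


def deflection_to_force(deflection_nm, spring_constant: float):
    """Convert cantilever deflection (nm) to force (pN) via Hooke's law.

    ``spring_constant`` is in N/m; 1 N/m corresponds to 1000 pN/nm, so
    10 nm at 0.05 N/m gives 500 pN.  Sign is preserved.
    """
    if not (np.isfinite(spring_constant) and spring_constant > 0):
        raise ValueError("spring_constant must be positive and finite")
    d = np.asarray(deflection_nm, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite deflection")
    out = d * (spring_constant * PN_PER_NM_PER_NEWTON_PER_M)
    return out if out.ndim else float(out)


def _fit_region_slice(segment: Segment, fit_region_fraction: float) -> slice:
    """Samples at the far-from-surface (lowest piezo height) end of a segment."""
    n = len(segment)
    n_fit = int(round(n * fit_region_fraction))
    if segment.label == "retract":
        # retract is stored in acquisition order: far end is the tail
        return slice(n - n_fit, n)
    return slice(0, n_fit)


def baseline_correct(
    segment: Segment, fit_region_fraction: float = 0.3
) -> tuple[Segment, BaselineModel]:
    """Remove a linear force baseline fitted far from the surface.

    A straight line ``force = a + b * piezo_height`` is fitted by least
    squares on the ``fit_region_fraction`` of samples farthest from the
    surface and subtracted from the whole segment, so that the zero-force
    level of the free cantilever is at 0 pN.

    Returns the corrected segment and the fitted :class:`BaselineModel`.

    Raises
    ------
    ValueError
        If the fit region holds fewer than 10 samples or has zero piezo span.
    """
    if not 0 < fit_region_fraction <= 1:
        raise ValueError("fit_region_fraction must be in (0, 1]")
    sl = _fit_region_slice(segment, fit_region_fraction)
    z_fit = segment.piezo_height_nm[sl]
    f_fit = segment.force_pN[sl]
    if z_fit.size < 10:
        raise ValueError(
            f"baseline fit region holds {z_fit.size} samples; at least 10 required"
        )
    if np.ptp(z_fit) == 0:
        raise ValueError("baseline fit region has zero piezo-height span")
    slope, intercept = np.polyfit(z_fit, f_fit, 1)
    corrected_force = segment.force_pN - (intercept + slope * segment.piezo_height_nm)
    residual_rms = float(np.sqrt(np.mean((f_fit - (intercept + slope * z_fit)) ** 2)))
    model = BaselineModel(
        intercept_pN=float(intercept),
        slope_pN_per_nm=float(slope),
        fit_region_fraction=fit_region_fraction,
        residual_rms_pN=residual_rms,
        n_fit_points=int(z_fit.size),
    )
    return replace(segment, force_pN=corrected_force), model


def baseline_is_corrected(
    segment: Segment, fit_region_fraction: float = 0.3, tol_pN: float | None = None
) -> bool:
    """Check that the far-from-surface fit region averages to ~0 force."""
    sl = _fit_region_slice(segment, fit_region_fraction)
    f = segment.force_pN[sl]
    if f.size == 0:
        return False
    if tol_pN is None:
        sd = float(np.std(f))
        tol_pN = max(5.0 * sd / np.sqrt(f.size), 1e-9)
    return abs(float(np.mean(f))) <= tol_pN


def tip_sample_separation(
    segment: Segment, spring_constant: float, contact_point_nm: float | None = None
):
    """Tip-sample separation in nm from piezo height and cantilever deflection.

    The tip sits at ``(contact_point - piezo_height) + force / k`` relative to
    the undeformed surface: retracting the piezo moves the tip away, a
    positive (repulsive) force deflects it further away, and a negative
    (adhesive) force holds it closer.  Negative values are indentation depth
    into the surface: with the piezo advanced ``s`` nm past contact under
    deflection ``d``, the separation is ``-(s - d)`` i.e. indentation
    ``delta = s - d``.

    ``contact_point_nm`` fixes the origin (the piezo height at which an
    undeflected tip touches the surface).  When omitted, the segment's
    highest piezo height is used, which for retract segments that start in
    contact makes the returned values tether extensions.
    """
    if spring_constant is None:
        raise ValueError("spring_constant is required")
    if contact_point_nm is None:
        contact_point_nm = float(segment.piezo_height_nm.max())
    deflection = np.asarray(segment.force_pN, dtype=float) / (
        spring_constant * PN_PER_NM_PER_NEWTON_PER_M
    )
    return (contact_point_nm - segment.piezo_height_nm) + deflection
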