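"""Rupture-event extraction and density-based classification of specific
ECM-tether ruptures.

An antibody-coated probe pressed onto a protein-coated hydrogel and retracted
leaves a retraction curve whose most negative force marks the rupture of the
strongest probe-substrate bond.  Specific antibody-antigen tethers rupture at
higher forces and longer tip-sample separations than the non-specific
adhesion seen with a control (anti-IgG) probe.  The classifier separates the
two populations in four steps:

1. extract a (rupture force, rupture length) pair per curve;
2. threshold both quantities at the medians of the negative-control
   distributions, discarding the bulk of non-specific interactions;
3. build normalised 2-D event-density maps on (rupture length, log10 rupture
   force) for sample and control;
4. mark grid cells where the sample density exceeds ``ratio`` (default 2)
   times the control density, smooth the mask with a median filter, and keep
   the sample events whose cell survives.

Soft and stiff substrates must be analysed separately (the probe-sample
interaction area differs at a fixed 500 pN setpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator

from .forcecurve import PN_PER_NM_PER_NEWTON_PER_M, Segment, baseline_is_corrected

__all__ = [
    "RuptureEvent",
    "EventSet",
    "Thresholds",
    "DensityGrid",
    "SignificanceMask",
    "TetherSummary",
    "TetherConditionResult",
    "TetherSignificanceClassifier",
    "analyze_tether_condition",
    "extract_rupture",
    "control_thresholds",
    "density_map",
    "significant_mask",
    "classify_events",
    "summarize_tethering",
]


@dataclass(frozen=True)
class RuptureEvent:
    rupture_force_pN: float  # positive magnitude of the deepest force dip
    rupture_length_nm: float  # tip-sample separation at that dip
    curve_id: str = ""

    def __post_init__(self) -> None:
        if not self.rupture_force_pN > 0:
            raise ValueError("rupture_force_pN must be positive")
        if self.rupture_length_nm < 0:
            raise ValueError("rupture_length_nm must be >= 0")


@dataclass(frozen=True)
class EventSet:
    """Rupture events from one sample (or one pooled control)."""

    events: tuple
    sample_id: str
    probe: str  # anti_FN (sample) or anti_IgG (negative control)
    substrate: str
    n_curves_total: int = 0

    def __post_init__(self) -> None:
        ev = tuple(self.events)
        if self.probe not in ("anti_FN", "anti_IgG"):
            raise ValueError("probe must be anti_FN or anti_IgG")
        if self.n_curves_total and self.n_curves_total < len(ev):
            raise ValueError("n_curves_total cannot be smaller than the number of events")
        object.__setattr__(self, "events", ev)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def forces_pN(self) -> np.ndarray:
        return np.array([e.rupture_force_pN for e in self.events], dtype=float)

    @property
    def lengths_nm(self) -> np.ndarray:
        return np.array([e.rupture_length_nm for e in self.events], dtype=float)

    @property
    def is_control(self) -> bool:
        return self.probe == "anti_IgG"


@dataclass(frozen=True)
class Thresholds:
    """Medians of the negative-control force and length distributions."""

    force_threshold_pN: float
    length_threshold_nm: float

    def __post_init__(self) -> None:
        for v in (self.force_threshold_pN, self.length_threshold_nm):
            if not (np.isfinite(v) and v >= 0):
                raise ValueError("thresholds must be finite and >= 0")


@dataclass(frozen=True)
class DensityGrid:
    """Normalised 2-D event density on (rupture length, log10 rupture force)."""

    length_bin_edges_nm: np.ndarray
    log10_force_bin_edges: np.ndarray
    density: np.ndarray  # shape (n_length_bins, n_force_bins), sums to 1 (or 0)
    n_events: int = 0

    def __post_init__(self) -> None:
        le = np.asarray(self.length_bin_edges_nm, dtype=float)
        fe = np.asarray(self.log10_force_bin_edges, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if np.any(np.diff(le) <= 0) or np.any(np.diff(fe) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if d.shape != (le.size - 1, fe.size - 1):
            raise ValueError("density shape does not match bin edges")
        if np.any(d < 0):
            raise ValueError("density must be non-negative")
        total = d.sum()
        if not (total == 0 or abs(total - 1.0) < 1e-9):
            raise ValueError("density must sum to 0 (empty) or 1")
        object.__setattr__(self, "length_bin_edges_nm", le)
        object.__setattr__(self, "log10_force_bin_edges", fe)
        object.__setattr__(self, "density", d)

    def same_grid_as(self, other: "DensityGrid") -> bool:
        return (
            self.length_bin_edges_nm.shape == other.length_bin_edges_nm.shape
            and self.log10_force_bin_edges.shape == other.log10_force_bin_edges.shape
            and np.allclose(self.length_bin_edges_nm, other.length_bin_edges_nm)
            and np.allclose(self.log10_force_bin_edges, other.log10_force_bin_edges)
        )


@dataclass(frozen=True)
class SignificanceMask:
    mask: np.ndarray  # boolean, congruent with the density grid
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class TetherSummary:
    """Per-sample and overall mean log10 rupture force of significant events.

    Samples with zero significant events are reported in
    ``empty_sample_ids`` and excluded from the means; when every sample is
    empty the summary is the explicit "no significant binding" result
    (``no_significant_binding`` is True) rather than an exception.
    """

    per_sample_mean_log10_force: dict
    overall_mean_log10_force: float | None
    sem_log10_force: float | None
    n_samples: int
    n_significant_events_per_sample: dict
    empty_sample_ids: tuple = field(default=())

    @property
    def no_significant_binding(self) -> bool:
        return self.n_samples == 0


def extract_rupture(
    retract: Segment,
    spring_constant: float,
    min_force_pN: float = 20.0,
    baseline_tol_pN: float | None = None,
) -> RuptureEvent | None:
    """Extract the rupture event of a baseline-corrected retract segment.

    The rupture force is the magnitude of the most negative force; the
    rupture length is the tip-sample separation at that minimum, measured
    from the contact position at the start of the retraction.  Returns
    ``None`` when the magnitude stays below ``min_force_pN`` (noise-only
    curve).
    """
    if retract.label != "retract":
        raise ValueError("extract_rupture expects a retract segment")
    if not baseline_is_corrected(retract, tol_pN=baseline_tol_pN):
        raise ValueError(
            "retract segment does not look baseline-corrected "
            "(far-from-surface mean force beyond tolerance)"
        )
    f = retract.force_pN
    i_min = int(np.argmin(f))
    force = -float(f[i_min])
    if force < min_force_pN:
        return None
    contact = float(retract.piezo_height_nm.max())
    deflection = f[i_min] / (spring_constant * PN_PER_NM_PER_NEWTON_PER_M)
    length = (contact - float(retract.piezo_height_nm[i_min])) + float(deflection)
    return RuptureEvent(
        rupture_force_pN=force, rupture_length_nm=max(length, 0.0), curve_id=""
    )


def control_thresholds(control: EventSet) -> Thresholds:
    """Force and length thresholds at the medians of the control distributions."""
    if not control.is_control:
        raise ValueError("thresholds must come from an anti_IgG (negative control) set")
    if len(control) == 0:
        raise ValueError(
            "empty control set: pool control events across samples before thresholding"
        )
    return Thresholds(
        force_threshold_pN=float(np.median(control.forces_pN)),
        length_threshold_nm=float(np.median(control.lengths_nm)),
    )


def _retained(events: EventSet, thresholds: Thresholds) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(forces, lengths, keep-mask) of events passing both thresholds."""
    f = events.forces_pN
    length = events.lengths_nm
    keep = (f > thresholds.force_threshold_pN) & (length > thresholds.length_threshold_nm)
    return f[keep], length[keep], keep


def make_grid_edges(
    event_sets: list[EventSet],
    thresholds: Thresholds,
    n_bins: int = 30,
    pad_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared bin edges spanning the pooled retained events, padded 5%."""
    forces = []
    lengths = []
    for es in event_sets:
        f, length, _ = _retained(es, thresholds)
        forces.append(f)
        lengths.append(length)
    forces = np.concatenate(forces) if forces else np.array([])
    lengths = np.concatenate(lengths) if lengths else np.array([])
    if forces.size == 0:
        # degenerate grid covering nothing in particular
        return np.linspace(0, 1, n_bins + 1), np.linspace(0, 1, n_bins + 1)
    if np.any(forces <= 0):
        raise ValueError("rupture forces must be positive to take log10")
    logf = np.log10(forces)

    def padded(lo: float, hi: float) -> tuple[float, float]:
        span = hi - lo
        if span == 0:
            span = max(abs(hi), 1.0)
        return lo - pad_fraction * span, hi + pad_fraction * span

    llo, lhi = padded(float(lengths.min()), float(lengths.max()))
    flo, fhi = padded(float(logf.min()), float(logf.max()))
    return np.linspace(llo, lhi, n_bins + 1), np.linspace(flo, fhi, n_bins + 1)


def density_map(
    events: EventSet,
    thresholds: Thresholds,
    length_edges: np.ndarray,
    log10_force_edges: np.ndarray,
) -> DensityGrid:
    """Normalised 2-D histogram of threshold-passing events.

    Events are retained iff force > force_threshold AND length >
    length_threshold; the histogram is on (rupture length, log10 rupture
    force) and normalised to sum to 1 (all-zero when nothing is retained).
    """
    f, length, _ = _retained(events, thresholds)
    if np.any(f <= 0):
        raise ValueError("rupture forces must be positive to take log10")
    if f.size == 0:
        hist = np.zeros((len(length_edges) - 1, len(log10_force_edges) - 1))
        return DensityGrid(length_edges, log10_force_edges, hist, n_events=0)
    hist, _, _ = np.histogram2d(length, np.log10(f), bins=[length_edges, log10_force_edges])
    n_in = int(hist.sum())
    density = hist / hist.sum() if hist.sum() > 0 else hist
    return DensityGrid(length_edges, log10_force_edges, density, n_events=n_in)


def significant_mask(
    sample: DensityGrid,
    control: DensityGrid,
    ratio: float = 2.0,
    kernel_size: int = 3,
) -> SignificanceMask:
    """Cells where the sample density is more than ``ratio`` times the control's.

    Cells with zero control density use a one-pseudo-event floor: they are
    significant iff the sample density exceeds ``ratio / n_control_retained``
    (the density a single control event would carry).  In addition, no cell
    is significant on the evidence of a single sample event (its density
    must exceed one event's worth, ``1 / n_sample_retained``): when the
    retained sample population is much smaller than the control, one stray
    event would otherwise clear both density ratios on its own, defeating
    the anti-stray purpose of the floor.  The raw mask is then smoothed
    with a 2-D median filter (majority vote over the ``kernel_size`` x
    ``kernel_size`` neighbourhood, edges padded with False).
    """
    if not sample.same_grid_as(control):
        raise ValueError("sample and control grids do not match")
    if kernel_size % 2 != 1:
        raise ValueError("kernel_size must be odd")
    floor = ratio / control.n_events if control.n_events > 0 else np.inf
    raw = np.where(
        control.density > 0,
        sample.density > ratio * control.density,
        sample.density > floor,
    )
    if sample.n_events > 0:
        raw &= sample.density > 1.0 / sample.n_events
    else:
        raw = np.zeros_like(raw, dtype=bool)
    smoothed = median_filter(raw.astype(np.uint8), size=kernel_size, mode="constant", cval=0)
    return SignificanceMask(mask=smoothed.astype(bool), kernel_size=kernel_size)


def _significance_flags(
    events: EventSet,
    thresholds: Thresholds,
    mask: SignificanceMask,
    length_edges: np.ndarray,
    log10_force_edges: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Per-event significance flags plus the count of retained events
    falling outside the grid range (unclassified)."""
    length_edges = np.asarray(length_edges, dtype=float)
    log10_force_edges = np.asarray(log10_force_edges, dtype=float)
    if mask.mask.shape != (length_edges.size - 1, log10_force_edges.size - 1):
        raise ValueError("mask shape does not match the grid")
    flags = np.zeros(len(events), dtype=bool)
    n_outside = 0
    for idx, ev in enumerate(events.events):
        if not (
            ev.rupture_force_pN > thresholds.force_threshold_pN
            and ev.rupture_length_nm > thresholds.length_threshold_nm
        ):
            continue
        logf = np.log10(ev.rupture_force_pN)
        i = int(np.searchsorted(length_edges, ev.rupture_length_nm, side="right")) - 1
        j = int(np.searchsorted(log10_force_edges, logf, side="right")) - 1
        # right bin edge belongs to the last bin, as in numpy.histogram2d
        if i == length_edges.size - 1 and ev.rupture_length_nm == length_edges[-1]:
            i -= 1
        if j == log10_force_edges.size - 1 and logf == log10_force_edges[-1]:
            j -= 1
        if not (0 <= i < mask.mask.shape[0] and 0 <= j < mask.mask.shape[1]):
            n_outside += 1
            continue
        flags[idx] = bool(mask.mask[i, j])
    return flags, n_outside


def classify_events(
    events: EventSet,
    thresholds: Thresholds,
    mask: SignificanceMask,
    length_edges: np.ndarray,
    log10_force_edges: np.ndarray,
) -> tuple[EventSet, int]:
    """Significant subset of ``events``: threshold-passing events whose grid
    cell is True in the mask.

    Returns the subset and the count of retained events falling outside the
    grid range (unclassified, excluded from the subset).
    """
    flags, n_outside = _significance_flags(
        events, thresholds, mask, length_edges, log10_force_edges
    )
    subset = EventSet(
        events=tuple(ev for ev, keep in zip(events.events, flags) if keep),
        sample_id=events.sample_id,
        probe=events.probe,
        substrate=events.substrate,
        n_curves_total=events.n_curves_total,
    )
    return subset, n_outside


def summarize_tethering(significant_sets: list[EventSet]) -> TetherSummary:
    """Per-sample and overall mean log10 rupture force of significant events.

    The overall mean is the mean of per-sample means and the error bar is
    their standard error (sd of sample means / sqrt(n_samples)), matching
    summaries over n = 3 or 4 independent experiments.  All-empty input
    yields the explicit "no significant binding" summary.
    """
    if not significant_sets:
        raise ValueError("summarize_tethering needs at least one sample")
    per_sample = {}
    counts = {}
    empty = []
    for es in significant_sets:
        counts[es.sample_id] = len(es)
        if len(es) == 0:
            empty.append(es.sample_id)
            continue
        per_sample[es.sample_id] = float(np.mean(np.log10(es.forces_pN)))
    if not per_sample:
        return TetherSummary(
            per_sample_mean_log10_force={},
            overall_mean_log10_force=None,
            sem_log10_force=None,
            n_samples=0,
            n_significant_events_per_sample=counts,
            empty_sample_ids=tuple(empty),
        )
    means = np.array(list(per_sample.values()))
    sem = float(np.std(means, ddof=1) / np.sqrt(means.size)) if means.size > 1 else 0.0
    return TetherSummary(
        per_sample_mean_log10_force=per_sample,
        overall_mean_log10_force=float(np.mean(means)),
        sem_log10_force=sem,
        n_samples=int(means.size),
        n_significant_events_per_sample=counts,
        empty_sample_ids=tuple(empty),
    )


@dataclass(frozen=True)
class TetherConditionResult:
    """Full classifier output for one substrate condition."""

    thresholds: Thresholds
    sample_grid: DensityGrid
    control_grid: DensityGrid
    mask: SignificanceMask
    significant_sets: list
    summary: TetherSummary
    n_outside_grid: int


def analyze_tether_condition(
    sample_sets: list[EventSet],
    control: EventSet,
    ratio: float = 2.0,
    kernel_size: int = 3,
    n_bins: int = 30,
    pad_fraction: float = 0.05,
) -> TetherConditionResult:
    """Run the four classification steps for one substrate condition.

    Thresholds come from the control medians; the density grid spans the
    pooled retained events of all samples and the control; the mask is
    shared; classification and counts are per sample.  Soft and stiff
    substrates should each get their own call.
    """
    pooled = EventSet(
        events=tuple(ev for es in sample_sets for ev in es.events),
        sample_id="pooled",
        probe="anti_FN",
        substrate=sample_sets[0].substrate if sample_sets else "",
        n_curves_total=sum(es.n_curves_total for es in sample_sets),
    )
    thresholds = control_thresholds(control)
    length_edges, force_edges = make_grid_edges(
        [pooled, control], thresholds, n_bins=n_bins, pad_fraction=pad_fraction
    )
    sample_grid = density_map(pooled, thresholds, length_edges, force_edges)
    control_grid = density_map(control, thresholds, length_edges, force_edges)
    mask = significant_mask(sample_grid, control_grid, ratio=ratio, kernel_size=kernel_size)
    significant_sets = []
    n_outside = 0
    for es in sample_sets:
        subset, n_out = classify_events(es, thresholds, mask, length_edges, force_edges)
        significant_sets.append(subset)
        n_outside += n_out
    return TetherConditionResult(
        thresholds=thresholds,
        sample_grid=sample_grid,
        control_grid=control_grid,
        mask=mask,
        significant_sets=significant_sets,
        summary=summarize_tethering(significant_sets),
        n_outside_grid=n_outside,
    )


class TetherSignificanceClassifier(BaseEstimator):
    """Density-ratio classifier of specific rupture events.

    Fit on pooled negative-control events; predict on pooled sample events.
    Both are (n, 2) arrays with columns (rupture_force_pN,
    rupture_length_nm).  ``predict`` builds the shared density grid from the
    pooled retained events of the control and the queried sample (the grid
    is study-specific by design) and returns a boolean array marking the
    significant sample events.

    Parameters
    ----------
    ratio : float, default 2.0
        Sample/control density ratio above which a cell is significant.
    kernel_size : int, default 3
        Median-filter kernel (odd).
    n_bins : int, default 30
        Bins per axis of the density grid.
    pad_fraction : float, default 0.05
        Fractional padding of the grid around the pooled retained range.

    Attributes
    ----------
    thresholds_ : Thresholds
        Control-median force and length thresholds.
    control_events_ : EventSet
        The control population seen at fit time.
    mask_, sample_grid_, control_grid_ :
        Set by :meth:`predict` for the most recent sample.
    """

    def __init__(
        self,
        ratio: float = 2.0,
        kernel_size: int = 3,
        n_bins: int = 30,
        pad_fraction: float = 0.05,
    ):
        self.ratio = ratio
        self.kernel_size = kernel_size
        self.n_bins = n_bins
        self.pad_fraction = pad_fraction

    @staticmethod
    def _as_event_set(X, probe: str, sample_id: str) -> EventSet:
        if isinstance(X, EventSet):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("X must be an EventSet or an (n, 2) array of (force_pN, length_nm)")
        events = tuple(
            RuptureEvent(rupture_force_pN=f, rupture_length_nm=length, curve_id=str(i))
            for i, (f, length) in enumerate(arr)
        )
        return EventSet(events=events, sample_id=sample_id, probe=probe, substrate="")

    def fit(self, X, y=None):
        """Learn thresholds from the negative-control event population."""
        control = self._as_event_set(X, probe="anti_IgG", sample_id="control")
        if not control.is_control:
            raise ValueError("fit expects the negative-control events")
        self.control_events_ = control
        self.thresholds_ = control_thresholds(control)
        return self

    def predict(self, X) -> np.ndarray:
        """Boolean significance flag per sample event."""
        if not hasattr(self, "thresholds_"):
            raise ValueError("classifier is not fitted")
        sample = self._as_event_set(X, probe="anti_FN", sample_id="sample")
        length_edges, force_edges = make_grid_edges(
            [sample, self.control_events_],
            self.thresholds_,
            n_bins=self.n_bins,
            pad_fraction=self.pad_fraction,
        )
        self.sample_grid_ = density_map(sample, self.thresholds_, length_edges, force_edges)
        self.control_grid_ = density_map(
            self.control_events_, self.thresholds_, length_edges, force_edges
        )
        self.mask_ = significant_mask(
            self.sample_grid_, self.control_grid_, ratio=self.ratio, kernel_size=self.kernel_size
        )
        flags, _ = _significance_flags(
            sample, self.thresholds_, self.mask_, length_edges, force_edges
        )
        return flags
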