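"""Seeded generators for force curves, rupture-event studies and expression
tables with known ground truth.

Every generator is a pure function of its scenario: the same scenario (seed
included) reproduces the output exactly.  The scenarios encode the study
conditions the analysis modules are validated against:

* indentation curves follow the spherical-probe Hertz model with the
  cantilever-deflection coupling of a calibrated AFM (soft-gel probe:
  37.28 um bead diameter, k = 0.03-0.07 N/m; stiff-gel probe: 10.28 um,
  k = 0.1-0.3 N/m), plus additive Gaussian force noise;
* tether studies mix a non-specific rupture population (low force, short
  length: what an anti-IgG control probe sees) with a specific
  antibody-antigen population (higher force, longer length), per-sample,
  over several independent samples probed a few hundred times each
  (acquisition envelopes: 34-696 measurements and 0-233 significant events
  per sample);
* expression tables plant per-cluster log2 fold-change shifts with
  controlled direction fractions, standing in for differential-expression
  output of a soft-vs-stiff comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elasticity import hertz_coefficient
from .forcecurve import PN_PER_NM_PER_NEWTON_PER_M, ForceCurve, Segment
from .tethering import EventSet, RuptureEvent

__all__ = [
    "IndentationScenario",
    "TetherScenario",
    "ClusterSpec",
    "SignatureScenario",
    "TetherStudy",
    "gen_indentation_curve",
    "gen_retract_curve",
    "gen_tether_events",
    "gen_tether_study",
    "gen_expression_table",
    "DEFAULT_STEMBOND",
    "DEFAULT_SULFO_SOFT",
    "DEFAULT_SULFO_STIFF",
    "DEFAULT_CONTROL",
    "default_signature_scenario",
]


# --------------------------------------------------------------------------
# Indentation (approach) curves


@dataclass(frozen=True)
class IndentationScenario:
    """Forward model for one Hertzian approach curve."""

    E_true_Pa: float = 750.0
    bead_radius_um: float = 18.64  # 37.28 um diameter soft-gel probe
    poisson_ratio: float = 0.5
    spring_constant: float = 0.05  # N/m
    contact_point_nm: float = 500.0
    noise_sd_pN: float = 10.0
    n_points: int = 600
    max_force_pN: float = 1500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("E_true_Pa", "bead_radius_um", "spring_constant", "max_force_pN"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.contact_point_nm <= 0:
            raise ValueError("contact_point_nm must be positive")
        if self.noise_sd_pN < 0:
            raise ValueError("noise_sd_pN must be >= 0")
        if self.n_points < 100:
            raise ValueError("n_points must be >= 100")


def _solve_indentation(s_nm: np.ndarray, A: float, k_pn_nm: float) -> np.ndarray:
    """Solve k (s - delta) = A delta^1.5 for delta, per piezo-past-contact s.

    The residual g(delta) = A delta^1.5 + k delta - k s is monotone, so
    Newton from delta = s converges quadratically; a bisection fallback
    guards the first steps.
    """
    delta = np.clip(s_nm, 0.0, None).astype(float)
    for _ in range(60):
        g = A * delta**1.5 + k_pn_nm * delta - k_pn_nm * s_nm
        dg = 1.5 * A * np.sqrt(delta) + k_pn_nm
        step = g / dg
        delta = np.clip(delta - step, 0.0, None)
        if np.max(np.abs(step)) < 1e-13:
            break
    return delta


def gen_indentation_curve(scenario: IndentationScenario, curve_id: str = "sim") -> ForceCurve:
    """Simulate a calibrated approach curve.

    Before the contact point the noise-free force is zero; past it the force
    and indentation satisfy the Hertz equation exactly once the cantilever
    deflection (force / spring constant) is subtracted from the piezo
    travel.  Gaussian noise of sd ``noise_sd_pN`` is added on top.
    """
    A = hertz_coefficient(scenario.E_true_Pa, scenario.poisson_ratio, scenario.bead_radius_um)
    k_pn_nm = scenario.spring_constant * PN_PER_NM_PER_NEWTON_PER_M
    delta_max = (scenario.max_force_pN / A) ** (2.0 / 3.0)
    s_max = delta_max + scenario.max_force_pN / k_pn_nm
    z = np.linspace(0.0, scenario.contact_point_nm + s_max, scenario.n_points)
    s = z - scenario.contact_point_nm
    force = np.zeros_like(z)
    past = s > 0
    delta = _solve_indentation(s[past], A, k_pn_nm)
    force[past] = A * delta**1.5
    rng = np.random.default_rng(scenario.seed)
    if scenario.noise_sd_pN > 0:
        force = force + rng.normal(0.0, scenario.noise_sd_pN, size=force.size)
    segment = Segment(label="approach", piezo_height_nm=z, force_pN=force)
    return ForceCurve(
        curve_id=curve_id,
        sample_id="sim",
        probe="none",
        substrate="sim",
        spring_constant=scenario.spring_constant,
        bead_radius_um=scenario.bead_radius_um,
        segments=(segment,),
    )


def gen_retract_curve(
    events: list[tuple[float, float]],
    spring_constant: float = 0.05,
    noise_sd_pN: float = 0.0,
    n_points: int = 800,
    travel_nm: float | None = None,
    contact_point_nm: float = 1000.0,
    seed: int = 0,
) -> Segment:
    """Simulate a baseline-corrected retract segment with planted ruptures.

    ``events`` is a list of (rupture_force_pN, rupture_length_nm) pairs.
    Each tether loads as a linear effective spring from the contact
    position: the force ramps to -rupture_force at the piezo displacement
    where the tip-sample separation equals the rupture length, then releases
    instantly.  Tethers engage sequentially in order of rupture
    displacement, so the deepest dip carries the largest rupture force.
    """
    k_pn_nm = spring_constant * PN_PER_NM_PER_NEWTON_PER_M
    ruptures = sorted(
        ((f, length, length + f / k_pn_nm) for f, length in events), key=lambda t: t[2]
    )
    if travel_nm is None:
        travel_nm = 1.5 * (ruptures[-1][2] if ruptures else 100.0) + 100.0
    z = np.linspace(contact_point_nm, contact_point_nm - travel_nm, n_points)
    d = contact_point_nm - z  # piezo displacement away from contact
    force = np.zeros_like(z)
    prev_d = 0.0
    for f_r, _length, d_r in ruptures:
        active = (d > prev_d) & (d <= d_r)
        force[active] = -(f_r / d_r) * d[active]
        prev_d = d_r
    rng = np.random.default_rng(seed)
    if noise_sd_pN > 0:
        force = force + rng.normal(0.0, noise_sd_pN, size=force.size)
    return Segment(label="retract", piezo_height_nm=z, force_pN=force)


# --------------------------------------------------------------------------
# Tether-study event populations


@dataclass(frozen=True)
class TetherScenario:
    """Event-population model for one substrate condition.

    Rupture forces and lengths are lognormal.  ``specific_fraction`` of the
    event-yielding curves carry a specific (antibody-antigen) rupture; the
    rest are non-specific adhesion, as is every event of an anti-IgG
    control probe (``specific_fraction = 0``).
    """

    n_curves: int = 350
    specific_fraction: float = 0.85
    specific_force_median_pN: float = 300.0
    specific_force_sigma_ln: float = 0.07
    specific_length_median_nm: float = 80.0
    specific_length_sigma_ln: float = 0.07
    nonspecific_force_median_pN: float = 30.0
    nonspecific_force_sigma_ln: float = 0.8
    nonspecific_length_median_nm: float = 15.0
    nonspecific_length_sigma_ln: float = 0.8
    no_event_prob: float = 0.3
    setpoint_pN: float = 500.0

    def __post_init__(self) -> None:
        if not 0 <= self.specific_fraction <= 1:
            raise ValueError("specific_fraction must lie in [0, 1]")
        if not 0 <= self.no_event_prob < 1:
            raise ValueError("no_event_prob must lie in [0, 1)")
        for name in (
            "specific_force_median_pN",
            "specific_length_median_nm",
            "nonspecific_force_median_pN",
            "nonspecific_length_median_nm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


#: Default study conditions: StemBond substrates carry a dominant, strong,
#: long specific population; soft sulfo-SANPAH a weaker one; stiff
#: sulfo-SANPAH only short non-specific adhesion (control-like).
DEFAULT_STEMBOND = TetherScenario()
DEFAULT_SULFO_SOFT = TetherScenario(
    specific_fraction=0.6, specific_force_median_pN=100.0, specific_length_median_nm=80.0
)
DEFAULT_SULFO_STIFF = TetherScenario(
    specific_fraction=0.0,
    nonspecific_length_median_nm=6.0,
    nonspecific_length_sigma_ln=0.6,
    nonspecific_force_median_pN=25.0,
)
DEFAULT_CONTROL = TetherScenario(specific_fraction=0.0)


@dataclass(frozen=True)
class TetherStudy:
    """Per-substrate sample event sets, matched controls, and hidden truth."""

    samples: dict  # substrate -> list[EventSet]
    controls: dict  # substrate -> EventSet (pooled anti-IgG events)
    truth: pd.DataFrame  # substrate, sample_id, curve_id, is_specific, force, length


def gen_tether_events(
    scenario: TetherScenario,
    rng: np.random.Generator,
    sample_id: str,
    probe: str,
    substrate: str,
) -> tuple[EventSet, pd.DataFrame]:
    """One sample's event population plus its hidden specific/non-specific labels."""
    records = []
    events = []
    for i in range(scenario.n_curves):
        curve_id = f"{substrate}/{sample_id}/c{i:04d}"
        if rng.random() < scenario.no_event_prob:
            continue
        specific = rng.random() < scenario.specific_fraction
        if specific:
            force = rng.lognormal(
                np.log(scenario.specific_force_median_pN), scenario.specific_force_sigma_ln
            )
            length = rng.lognormal(
                np.log(scenario.specific_length_median_nm), scenario.specific_length_sigma_ln
            )
        else:
            force = rng.lognormal(
                np.log(scenario.nonspecific_force_median_pN), scenario.nonspecific_force_sigma_ln
            )
            length = rng.lognormal(
                np.log(scenario.nonspecific_length_median_nm), scenario.nonspecific_length_sigma_ln
            )
        events.append(
            RuptureEvent(rupture_force_pN=force, rupture_length_nm=length, curve_id=curve_id)
        )
        records.append(
            {
                "substrate": substrate,
                "sample_id": sample_id,
                "curve_id": curve_id,
                "is_specific": specific,
                "rupture_force_pN": force,
                "rupture_length_nm": length,
            }
        )
    event_set = EventSet(
        events=tuple(events),
        sample_id=sample_id,
        probe=probe,
        substrate=substrate,
        n_curves_total=scenario.n_curves,
    )
    columns = [
        "substrate",
        "sample_id",
        "curve_id",
        "is_specific",
        "rupture_force_pN",
        "rupture_length_nm",
    ]
    return event_set, pd.DataFrame(records, columns=columns)


def gen_tether_study(
    stembond: TetherScenario = DEFAULT_STEMBOND,
    sulfosanpah_soft: TetherScenario = DEFAULT_SULFO_SOFT,
    sulfosanpah_stiff: TetherScenario = DEFAULT_SULFO_STIFF,
    control: TetherScenario = DEFAULT_CONTROL,
    n_samples: int = 4,
    seed: int = 0,
) -> TetherStudy:
    """Full synthetic tethering study over three substrate conditions.

    Each substrate gets ``n_samples`` independent sample populations (one
    per replicate experiment) probed with the anti-fibronectin probe, plus a
    pooled anti-IgG control population of the same acquisition size.  Soft
    and stiff substrates are meant to be analysed separately, so each
    substrate carries its own control set.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    scenarios = {
        "stembond_soft": stembond,
        "sulfo_sanpah_soft": sulfosanpah_soft,
        "sulfo_sanpah_stiff": sulfosanpah_stiff,
    }
    root = np.random.SeedSequence(seed)
    samples: dict[str, list[EventSet]] = {}
    controls: dict[str, EventSet] = {}
    truth_frames = []
    for (substrate, scenario), child in zip(
        scenarios.items(), root.spawn(len(scenarios))
    ):
        sub_children = child.spawn(n_samples + 1)
        sets = []
        for j in range(n_samples):
            rng = np.random.default_rng(sub_children[j])
            es, truth = gen_tether_events(
                scenario, rng, sample_id=f"s{j + 1}", probe="anti_FN", substrate=substrate
            )
            sets.append(es)
            truth_frames.append(truth)
        samples[substrate] = sets
        # matched pooled control: same number of probed curves as the samples
        rng = np.random.default_rng(sub_children[n_samples])
        ctrl_scenario = replace(control, n_curves=control.n_curves * n_samples)
        ctrl, truth = gen_tether_events(
            ctrl_scenario, rng, sample_id="control", probe="anti_IgG", substrate=substrate
        )
        controls[substrate] = ctrl
        truth_frames.append(truth)
    return TetherStudy(
        samples=samples, controls=controls, truth=pd.concat(truth_frames, ignore_index=True)
    )


# --------------------------------------------------------------------------
# Expression tables


@dataclass(frozen=True)
class ClusterSpec:
    """Planted effect for one gene cluster.

    ``shift`` is the mean log2fc (soft over stiff).  With ``up_fraction``
    unset, gene log2fc = shift + noise.  With ``up_fraction`` set, each gene
    independently goes up with that probability and the magnitude is
    |shift| + half-normal noise, so the realised direction matches the draw
    exactly (an explicit "X% of cluster genes up/down" structure).
    """

    n_genes: int
    shift: float
    up_fraction: float | None = None
    significant_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.up_fraction is not None and not 0 <= self.up_fraction <= 1:
            raise ValueError("up_fraction must lie in [0, 1]")
        if not 0 <= self.significant_fraction <= 1:
            raise ValueError("significant_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SignatureScenario:
    n_genes: int = 5000
    clusters: tuple = ()  # of (name, ClusterSpec)
    noise_sd: float = 0.3
    background_significant_fraction: float = 0.05
    condition: str = "S+L 48h"
    seed: int = 0
    mirror: bool = False  # generate the exact sign-mirrored table

    def __post_init__(self) -> None:
        total = sum(spec.n_genes for _, spec in self.clusters)
        if total > self.n_genes:
            raise ValueError("cluster sizes exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def reversed(self) -> "SignatureScenario":
        """Scenario with every planted effect reversed in sign.

        At the same seed the generated table is the exact mirror of the
        original (log2fc negated gene by gene), so up/down fractions swap
        exactly.
        """
        flipped = tuple(
            (
                name,
                replace(
                    spec,
                    shift=-spec.shift,
                    up_fraction=None if spec.up_fraction is None else 1.0 - spec.up_fraction,
                ),
            )
            for name, spec in self.clusters
        )
        return replace(self, clusters=flipped, mirror=not self.mirror)


def default_signature_scenario(seed: int = 0) -> SignatureScenario:
    """Study conditions for the signature statistics: pre-implantation genes
    mostly up on soft, post-implantation genes mostly down, ERK-activated
    targets mostly down and ERK-suppressed targets mostly up, with larger
    fold changes for ERK targets than background."""
    return SignatureScenario(
        n_genes=5000,
        clusters=(
            ("pre_implantation", ClusterSpec(n_genes=200, shift=0.5, up_fraction=0.80)),
            ("post_implantation", ClusterSpec(n_genes=200, shift=-0.5, up_fraction=0.15)),
            ("erk_activated", ClusterSpec(n_genes=150, shift=-0.8, up_fraction=0.10)),
            ("erk_suppressed", ClusterSpec(n_genes=150, shift=0.8, up_fraction=0.85)),
        ),
        noise_sd=0.3,
        seed=seed,
    )


def gen_expression_table(scenario: SignatureScenario) -> pd.DataFrame:
    """Per-gene table (gene_id, log2fc, padj, cluster, condition).

    Noise enters in the direction of the planted effect (an antithetic
    construction, distributionally identical to symmetric additive noise)
    so that :meth:`SignatureScenario.reversed` yields the exact mirror
    table at the same seed.
    """
    canonical = scenario.reversed() if scenario.mirror else scenario
    rng = np.random.default_rng(canonical.seed)
    n = canonical.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])
    cluster = np.full(n, "none", dtype=object)
    log2fc = np.zeros(n)
    sig_fraction = np.full(n, canonical.background_significant_fraction)

    z = rng.standard_normal(n) * canonical.noise_sd
    u_dir = rng.random(n)
    u_sig = rng.random(n)
    u_padj = rng.random(n)

    log2fc = z.copy()  # background genes: pure noise around 0
    start = 0
    for name, spec in canonical.clusters:
        rows = slice(start, start + spec.n_genes)
        start += spec.n_genes
        cluster[rows] = name
        sig_fraction[rows] = spec.significant_fraction
        if spec.up_fraction is None:
            sign = 1.0 if spec.shift >= 0 else -1.0
            log2fc[rows] = spec.shift + sign * z[rows]
        else:
            direction = np.where(u_dir[rows] < spec.up_fraction, 1.0, -1.0)
            log2fc[rows] = direction * (abs(spec.shift) + np.abs(z[rows]))

    significant = u_sig < sig_fraction
    padj = np.where(significant, u_padj * 0.05, 0.05 + u_padj * 0.95)
    if canonical is not scenario:  # mirrored request
        log2fc = -log2fc
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "padj": padj,
            "cluster": cluster,
            "condition": scenario.condition,
        }
    )
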