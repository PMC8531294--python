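# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `stembond` package: an analysis pipeline for
characterising polyacrylamide (PAAm) hydrogel culture substrates by AFM
force spectroscopy, and for summarising the transcriptional signature of
substrate stiffness in cells cultured on them.

## Units and conventions

All analysis operates in nm (piezo height, indentation, rupture length),
pN (force) and N/m (cantilever spring constant; 1 N/m = 1000 pN/nm).
Forces pushing the cantilever away from the surface are positive; adhesive
forces on retraction are negative; rupture forces are reported as positive
magnitudes. Piezo height increases toward the surface, and curves are
stored in acquisition order, so approach segments are strictly increasing
and retract segments strictly decreasing in piezo height. Raw-voltage to
deflection conversion (optical-lever sensitivity) is assumed done upstream:
the file reader ingests calibrated nm/pN tables.

## Baseline correction

Any offset or slow drift in the free-cantilever force is removed by fitting
a straight line (force against piezo height) over the fraction of samples
farthest from the surface — default 30%, a compromise between statistical
leverage and contamination by the contact region — and subtracting it from
the whole segment. The fit region must hold at least 10 samples and a
non-zero piezo span. The operation is idempotent up to numerical noise.
Downstream operations that require a corrected baseline verify that the
fit-region mean force is within a few standard errors of zero.

## Substrate stiffness: Hertz contact fit

For a rigid sphere of radius R indenting an elastic half-space to depth
delta, the Hertz model gives

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2).

The probe geometries are those used on the gels: a 37.28 um-diameter bead
on 0.03-0.07 N/m cantilevers for soft gels, a 10.28 um bead on 0.1-0.3 N/m
cantilevers for stiff gels. The Poisson ratio defaults to nu = 0.5
(incompressible hydrogel), the standard choice for PAAm.

Fitting jointly estimates the contact point and E. Every sample of the
approach segment is a candidate contact point (search on the acquisition
grid: deterministic and exactly reproducible; sub-sample contact precision
is irrelevant at the instrument's noise level). For a candidate at piezo
height z_c, the indentation of each later sample is the piezo travel past
contact minus the cantilever deflection, delta = (z - z_c) - F/k; E then
follows from a linear least-squares fit of F against delta^(3/2) through
the origin, restricted to delta <= max_indentation (default 10% of the
bead radius, the Hertz validity regime). The winning candidate minimises
the residual RMS computed over the *whole* segment: pre-contact samples
against zero force, in-contact samples against the fitted curve, with the
model extrapolated beyond the indentation window. Evaluating residuals
only inside the window admits a degenerate solution — a contact point at
the start of the sweep whose near-zero modulus pushes the entire
informative high-force region beyond the window and out of its residual,
leaving it to compete on baseline noise alone; scoring the full segment
removes it. A fit is rejected ("no contact") when no candidate achieves a
positive modulus and a residual improvement over the flat zero-force
model; a winning candidate at the edge of the grid raises a divergence
warning.

Per-gel aggregation reports the pooled mean and standard deviation of E
over all indentations plus per-gel means (e.g. 30 indentations/gel over 5
replicate gels).

## ECM tethering strength: rupture events and the density classifier

A probe coated with an anti-fibronectin antibody is pressed onto the
protein-coated gel (500 pN setpoint) and retracted; the most negative
force on the retract segment marks the rupture of the strongest
probe-substrate bond. Per curve the pipeline extracts the rupture force
(magnitude of that minimum) and the rupture length (tip-sample separation
at the minimum, i.e. (z_contact - z) + F/k, taking the contact position as
the retraction start). Dips shallower than `min_force` (default 20 pN) are
discarded as noise. Rupture length is anchored at the global force
minimum, not at final detachment; with multiple ruptures per curve only
the deepest is kept (multi-rupture decomposition is out of scope).

Specific antibody-antigen ruptures are separated from non-specific
adhesion — measured with an anti-IgG control probe — in four steps:

1. extract one (force, length) pair per curve;
2. threshold both quantities at the medians of the pooled negative-control
   distributions; only events exceeding both thresholds are retained, in
   the analysis of both sample and control (the thresholds exist to strip
   non-specific interactions, so all later steps operate on the filtered
   population);
3. histogram the retained events of sample and control on a shared 30 x 30
   grid over (rupture length, log10 rupture force), spanning the pooled
   retained range padded by 5%, each histogram normalised to unit mass;
4. mark cells where the sample density exceeds twice the control density,
   smooth the mask with a 3 x 3 median filter (majority vote,
   False-padded edges), and keep the sample events whose cell survives.

Two guards govern sparsely populated cells:

* cells with zero control density use a one-pseudo-event floor — the
  sample density must exceed `ratio / n_control_retained`, the density a
  single control event would carry — so an empty control cell is not
  automatically significant;
* no cell is significant on the evidence of a single sample event (its
  density must exceed `1 / n_sample_retained`). Without this, whenever the
  retained sample population is much smaller than the control (as on a
  substrate with essentially no specific binding), one stray event carries
  enough normalised density to clear both the pseudo-event floor and the
  2x ratio on its own, and a handful of strays adjacent in the grid can
  survive the median filter. The guard is symmetric in spirit to the
  control floor, strictly conservative, and irrelevant to genuine
  clusters, whose core cells hold many events.

Soft and stiff substrates are always analysed separately (the
probe-sample interaction area differs at fixed setpoint). The per-sample
summary takes the mean log10 rupture force of the significant events —
the log scale matches how rupture forces are displayed and compared —
then averages sample means and reports their standard error over the 3-4
independent samples. A condition in which every sample has zero
significant events yields an explicit "no significant binding" result, not
an error.

Grid resolution (30 bins/axis), the 2x ratio and the 3 x 3 kernel are
defaults chosen to match event counts of a few hundred per condition;
they are exposed as parameters.

## Ligand surface density

Anchorage points (carboxyl groups of the AHA co-factor) are assumed
uniformly distributed in the gel volume at number density N_A * [AHA]
(per litre = per dm^3). The surface density is the 2/3 power of the
volumetric density converted from dm^-2 to um^-2:

    sigma = (N_A * [AHA])^(2/3) * 1e-10   [sites um^-2],

with [AHA] in mol/L (the interface takes mM). The exact 2/3-power scaling
means raising [AHA] from 16 to 80 mM multiplies sigma by 5^(2/3) = 2.92 —
the anchorage density approximately triples. Incorporation efficiency and
saturation at high co-factor concentration are not modelled.

## Stiffness-signature statistics

Inputs are per-gene differential-expression tables (log2 fold change
soft-over-stiff, adjusted p-value, gene-cluster label); estimating
log2fc/padj themselves is upstream and out of scope. Four statistics:

* **Cumulative log2fc** of a cluster, over genes with |log2fc| > 0.2 (the
  floor removes genes with negligible change). Genes are ordered by
  descending |log2fc| with ties broken by gene id — the order only shapes
  the plotted series; the endpoint, the interpretable quantity, is the
  plain sum and order-free.
* **Direction fractions**: among a cluster's genes with padj < 0.05, the
  percentages with log2fc > 0 (up on soft) and < 0; zero-log2fc genes are
  excluded from the denominator. Defined over significant genes; an empty
  significant set is flagged undefined rather than raised.
* **ERK concordance**: direction fractions of the ERK-activated and
  ERK-suppressed target clusters, plus mean |log2fc| of ERK targets versus
  background genes.
* **Permutation test** for a systematic shift of a gene selection: the
  observed statistic is the set's mean log2fc; the null re-draws gene sets
  of identical size uniformly without replacement from the whole table
  (the natural null for "a selection of genes" against the transcriptome
  background; sign-flipping would instead test symmetry of the set's own
  fold changes). The two-sided p-value uses the add-one correction,
  p = (1 + #{|null| >= |observed|}) / (m + 1), guaranteeing p > 0 and
  super-uniformity under the null. Null sets are sampled by taking the k
  smallest of n i.i.d. uniforms per permutation, which is vectorised and
  exactly reproducible from the seed.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of a scenario (seed included).

**Indentation curves.** The forward model is the Hertz force coupled to
cantilever deflection: past the contact point the piezo travel splits into
indentation plus deflection, k(s - delta) = A delta^(3/2), solved per
sample by a safeguarded Newton iteration; before contact the noise-free
force is exactly zero. Gaussian force noise (default sd 10 pN) is added.
Defaults follow the soft-gel acquisition (bead radius 18.64 um, k = 0.05
N/m, ~600 samples, peak force 1.5 nN). Not modelled: drift, hydrodynamic
drag, tilt, bottom effects, viscoelasticity — so recovery accuracies
measured here are upper bounds on real-data performance.

**Retraction curves.** Planted ruptures load as linear effective springs
from the contact position, reaching -F_rupture exactly where the
tip-sample separation equals the planted rupture length, then release
instantly; multiple tethers engage sequentially. The analysis consumes
only the (force, length) pair at rupture, so this simplest monotone
loading suffices and keeps expected values analytic (worm-like-chain
loading shapes are not modelled).

**Tether studies.** Rupture forces and lengths are lognormal.
Non-specific adhesion (and the anti-IgG control): median 30 pN / 15 nm
with log-sd 0.8. Specific populations are tight (log-sd 0.07), as for a
well-defined molecular bond probed at fixed loading rate. The default
study has four independent samples per substrate, 350 curves per sample
(inside the reported acquisition envelope of 34-696 measurements and
0-233 significant events per sample), 30% of curves yielding no event,
and a pooled control of matching acquisition size. Substrate conditions:
StemBond soft — 85% specific at 300 pN / 80 nm; soft sulfo-SANPAH — 60%
specific at 100 pN / 80 nm (weaker tethering, similar lengths); stiff
sulfo-SANPAH — no specific population and shortened non-specific lengths
(median 6 nm), emulating ECM weakly coupled to the substrate. These
magnitudes are generator conventions consistent with the qualitative
phenomenology (weaker forces on soft sulfo-SANPAH, very short lengths on
stiff), not measured values. The population sizes were chosen by a
Poisson-coverage calculation of the 30 x 30 density grid before any
classifier run: with ~1000 retained sample events the specific cluster's
core cells hold ~10x the significance floor, giving ~90% expected
recovery; recovery of planted events on single studies still varies by a
few percentage points with the seed, so headline recovery numbers average
10 replicate studies.

**Expression tables.** Each cluster plants either a Gaussian-shifted
log2fc (shift + noise) or an explicit direction structure: gene direction
~ Bernoulli(up_fraction), magnitude |shift| + half-normal noise, so the
realised sign always matches the draw. Noise enters in the direction of
the planted effect — an antithetic construction distributionally identical
to symmetric additive noise — so that a sign-reversed scenario generated
at the same seed is the exact mirror of the original table (up/down
percentages swap exactly, a property used in validation). Adjusted
p-values are assigned to hit the requested significant fraction per
cluster (default 90% for planted clusters, 5% for background) and are
independent of the fold changes; real DE tables correlate the two, which
none of the statistics here exploit. The default scenario plants the
study's structure: pre-implantation genes 80% up on soft, post-implantation
85% down, ERK-activated targets 90% down, ERK-suppressed targets 85% up,
with larger magnitudes for ERK targets than background. Tables are
generated at the log2fc level; negative-binomial count simulation is out
of scope.

## Numerical choices and degenerate inputs

* Contact-point search and density binning are grid-based and
  deterministic; ties in the median filter cannot occur (odd vote count)
  and edges are padded with False (conservative).
* Events on the extreme right bin edge belong to the last bin (numpy
  histogram convention); retained events outside the grid are counted as
  unclassified and reported, never silently dropped.
* An empty control set raises an instruction to pool controls; an
  all-empty significant study returns the explicit no-binding result.
* Study outputs carry a provenance header (config hash + seed, no
  timestamps); re-running a study with the same configuration reproduces
  every output byte for byte. Floats in the curve dialect are written at
  repr precision and parsed with round-trip precision.

## Known limitations

* Single-rupture extraction only; loading-rate (Bell-Evans) analysis and
  contour-length fitting are out of scope.
* The Hertz fit assumes a spherical probe on an elastic half-space;
  pyramidal-tip (Sneddon) geometry is not implemented.
* The classifier's recovery depends on grid resolution relative to event
  counts; very sparse studies (tens of events) sit below the density
  floors by construction and will report few or no significant events.
* Synthetic validation bounds real-data performance from above; none of
  the generators emulate instrument drift or correlated noise.
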