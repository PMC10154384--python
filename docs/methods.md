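# Methods

This note records the models, conventions and numerical choices behind each
module, in the order data flows through the package.

## Synthetic data: what is emulated, and what is not

Every generator produces one assay's raw data together with a `GroundTruth`
holding the exact quantities the pipeline should recover. All randomness
flows through a single `numpy.random.Generator` constructed from an explicit
integer seed; no global random state is touched, and identical seeds
reproduce outputs bit-exactly.

**Cohort model.** Published cohort values are available only as mean ± SEM
with n. Per-cell ground truths are drawn from a lognormal with matched
arithmetic mean and SD = SEM·√n (µ = ln m − σ²/2, σ² = ln(1 + s²/m²)). The
lognormal was chosen over a Gaussian because at the published dispersions a
Gaussian would put appreciable mass below zero (e.g. SD ≈ 0.84 nN around a
1.1 nN mean), and forces, moduli and amplitude ratios are strictly positive.
Conditions described only qualitatively ("similar to control") are
control-matched with their own n; conditions with no published number at all
hold `None` and are rejected by the cohort generator.

**Pillar videos** render pillar tops as symmetric 2-D Gaussian spots
(σ = spot diameter / 4, a reasonable stand-in for a diffraction-blurred top)
on a square lattice, with Gaussian pixel noise. Pillars under the cell mask
are displaced along random fixed directions with magnitudes constant in
time. Two anchoring conventions are exposed: `anchor="mean"` rescales the
magnitudes so their *mean* equals force/k (the natural reading of a nominal
force), `anchor="max"` pins the *maximum* (used by the cohort generator,
whose per-cell truth is the mean-maximum traction). Not emulated: optics
point-spread functions, pillar bending shapes beyond the linear spring,
cell-shape dynamics, stage drift.

**Bead trajectories** follow a square-wave-driven creep: during pulse *i*
displacement rises as Aᵢ·(t/t_on)^0.3 and relaxes exponentially
(τ = 0.5 s) during rest, plus Gaussian tracking noise (default 5 nm) and
optional linear drift. Per-pulse amplitudes interpolate linearly from A₁ to
A₁·r₁₂; only the two endpoints are published, so the linear schedule is a
declared assumption. The acquisition frame rate is unpublished; default
10 Hz, configurable. Not emulated: full viscoelastic (power-law) rheology,
bead detachment, out-of-plane motion.

**Indentation curves** are the exact piecewise model — linear baseline
before contact, baseline + Hertz force after — plus Gaussian force noise.
**Invasion stacks** place an axially Gaussian laminin plane (σ_z = 0.4 µm)
and a solid ellipsoidal actin cell (anti-aliased 1-px lateral edge)
positioned so that exactly the requested fraction of its height lies below
the plane. Real f-actin is cortical rather than solid; the solid fill gives
the same axial extent, which is all the readout uses.

Because the generators share the analyses' structural assumptions (linear
springs, exact Hertz form, symmetric spots), passing recovery tests shows
the pipelines are unbiased and correctly implemented — not that they are
robust to model mismatch in real microscopy (uneven illumination, debris,
overlapping cells).

## Micropillar traction

Geometry defaults (the source experiments do not publish theirs): pitch
8 µm, spot diameter 2.4 µm, pixel 0.4 µm/px, 128×128 frames, 60 frames at
1 frame/s, k = 1.36 nN/µm. The pitch was set so the half-pitch assignment
range (4 µm ≙ 5.4 nN) covers beyond the 99th percentile of every preset's
per-cell force distribution; a tighter pitch measurably truncates the
cohort's force tail.

*Detection.* Peaks are found on a spot-scale Gaussian-smoothed copy of the
frame (matched filter) with half-pitch exclusion and a threshold of
background + max(0.3·amplitude, 5·MAD noise). Candidates are refined by an
iterative window-recentred intensity-weighted centroid, then polished by a
vectorized Gauss-Newton fit of a fixed-width Gaussian with free amplitude,
centre and local offset — the Gaussian-noise MLE. At peak-SNR 10 this
reaches ≈ 0.08 px per-axis RMS, essentially the read-noise information
limit (≈ 0.07 px); windowed centroids alone plateau near 0.1–0.13 px.

*Reference lattice.* Undeflected positions come from an affine lattice fit
(origin + integer combinations of two basis vectors, solved by least
squares) to the pillars outside the cell footprint — dilated by half a
pitch, since an edge pillar can be deflected out of the mask. Initial
rotation is the median nearest-neighbour bond angle folded into ±45°;
integer indices are assigned by rounding in the rotated frame and the
affine solve is iterated twice. Fewer than 6 free pillars is an error. Only
the square lattice is implemented; the hexagonal case raises
`NotImplementedError`.

*Tracking and summary.* Per-frame detections attach to the nearest
reference node; assignments farther than half a pitch are recorded as
missing (never interpolated). Forces are F = k·|δ|. The per-cell scalar is
the mean over frames of the per-frame maximum force among pillars whose
*reference* lies under the cell mask — matching a per-cell value reported
with n = cells; the alternative single-global-maximum reduction is a
one-liner on `per_frame_max_force` if wanted. Frames where no pillar is
valid are dropped from the mean.

## Magnetic tweezers

Protocol constants: 6 nN, 3 s on, 4 s rest, 12 pulses (84 s of protocol
inside a ~100 s recording). The amplitude of a pulse is the maximum of the
force-axis projection during the on-window minus the median projection over
the final 1 s of the preceding rest, clipped at zero (motion against the
force is noise). The projection axis is taken from the tweezers geometry
(recorded by the generator); no axis estimation. Pulse-1 onset t₀ is
metadata, not detected. Relative amplitudes Aᵢ/A₁ make the first-vs-twelfth
comparison scale-free; a cell with A₁ = 0 is excluded as unanalysable.
Reinforcement is tested by a paired two-sided Wilcoxon signed-rank on
(A₁, A₁₂); all-zero differences return p = 1 with a degenerate flag.

The peak-minus-baseline estimator slightly undershoots the creep amplitude
(the last sampled point of a pulse sits one frame before the asymptote),
but the bias cancels in the ratio Aᵢ/A₁ because every pulse is sampled at
the same phase — the cohort-recovery tests confirm |bias| < 0.02 across
ratios 0.5–1.0.

## AFM Hertz fitting

ν = 0.5 (incompressible cell) and R = 7.5 µm (half the 15 µm bead) by
default, both configurable. Force in nN with z in µm gives
F = (4/3)·E/(1−ν²)·√R·δ^{3/2}·10⁻³.

*Baseline*: a line fitted to the first 30% of samples (assumed pre-contact)
is subtracted; fewer than 10 pre-contact samples is an error.
*Contact point*: every sampled z is a candidate; E is profiled out in
closed form (the model is linear in E) on the post-candidate window and the
candidate minimising the total residual over the whole curve wins. A
candidate must improve on the flat (no-contact) model by at least 2% of its
RSS, otherwise a no-contact condition is reported — this grid search is
robust at the ~1 nN force set points where derivative thresholding fails.
*Fit window*: indentations up to 10% of the bead radius (0.75 µm), the
usual small-indentation validity bound for the Hertz form; at least 20
post-contact samples are required for a converged fit. Cantilever-deflection
inputs are converted as nN = µm · k[N/m] · 1000 at load time (the nominal
MLCT constant 0.03 N/m).

## Invasion

z increases from the well bottom (invaded side) toward the seeding side, so
"below the bilayer" is z < z_bilayer. The bilayer position is the
intensity-weighted centroid of the background-subtracted laminin z-profile
within ±3 µm of its global maximum; a profile whose maximum does not exceed
the median by 20% of the maximum has no bilayer and is rejected. The cell's
axial extent runs between the outermost crossings of τ·max of the
background-subtracted (minimum-subtracted) actin profile, linearly
interpolated between slices.

τ defaults to 0.02. For a rounded (ellipsoidal) cell the actin z-profile is
parabolic and the τ-crossing pulls each edge inward by (h/2)(1 − √(1−τ)),
biasing percent invasion by (1−√(1−τ))(f−½)/√(1−τ): ≈ 2.7 percentage
points at f = 1 for τ = 0.1, but ≤ 0.5 points anywhere at τ = 0.02. The low
threshold therefore keeps the end-to-end geometry error under 1 percentage
point across the whole range; with noisy real data it should be raised
(and the profile averaged over a larger ROI) at the cost of that bias.

Cumulative counts are per-ROI running sums; a missing day is an error, not
imputed. Slopes come from OLS of cumulative count on day per condition, and
each pair of conditions is tested through the day × condition interaction
of a pooled model. Exact-fit degeneracies (zero residual variance) are
resolved by the interaction coefficient: p = 1 if it vanishes, 0 otherwise.

## Statistics

The gate: Shapiro–Wilk per group at α = 0.05 (the normality test itself is
unnamed in the source protocol; Shapiro–Wilk is the standard choice); all
groups pass → parametric, any failure (or an untestable constant group,
with a warning) → nonparametric. On the parametric branch Levene's test
(median-centred) decides between plain ANOVA/t and the Welch family; the
Welch ANOVA (pingouin) is primary, with the Brown–Forsythe F* computed
alongside. Post-hocs follow the branch: Tukey (all pairs) or Dunnett
(vs a reference) parametric, Dunn's pairwise z-tests nonparametric. Dunn's
test is implemented here (no installed package provides it): mean-rank
differences over the pooled tie-corrected variance, Holm-adjusted — Holm
because the source protocol says only "adjusted for multiple comparisons".
Wilcoxon signed-rank drops zero differences (Wilcoxon's convention) and
uses the exact null distribution when feasible. An explicit
`branch=`/`reference_group=` override exists because published figure
legends sometimes fix the family regardless of the gate.

Known distortion: gating and testing on the same data perturbs the omnibus
level slightly; the type-I simulation (3 normal groups, n = 30, 1000
repeats) stays within [3.5%, 6.5%] at α = 0.05.

## Problem sizes and tolerances used in the tests

Cohort recoveries run at the published cohort sizes (70/53/87 traction,
91/58 stiffness, 41/22 tweezers) on 128×128×60 pillar videos, 0.01 µm-step
force curves and 0.5 µm-step z-stacks; a full acceptance run takes about a
minute on one CPU. Recovered cohort means are accepted within 2 recovered
SEM — at the published dispersions (e.g. SD ≈ 0.84 nN about 1.1 nN) the
cohort mean itself fluctuates by ±SEM ≈ 9% between seeds, so tighter bands
would test the draw, not the pipeline. Deterministic quantities are held to
1% (moduli), 1 percentage point (invasion), one grid step (contact point),
or machine precision (force conversion, forward models).

## Limitations

No cell segmentation (masks and ROIs are inputs), no continuum TFM, no
magnet force calibration, no viscoelastic fitting, no 3-D cell
segmentation, no figure rendering. The generators' fidelity bounds what the
tests can certify about real data; see the synthetic-data section.
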