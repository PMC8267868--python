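# Methods

## Magnetization model

All simulations use the classical Bloch picture of a magnetization vector
per tissue compartment, normalized so thermal equilibrium is (0, 0, 1).
Hard RF pulses are instantaneous rotations by default; the rotation
convention is fixed so that a 90° pulse at phase 0 ("x") takes equilibrium
to (0, 1, 0), and every composite-pulse identity in the package is stated
under this single convention.  A finite-duration mode subdivides a hard
pulse and interleaves nutation (scaled by a B1 factor) with free precession
at a B0 offset; it is used only for the field-robustness analysis, because
at the signal levels of interest sub-millisecond pulse effects do not alter
the sequence-scale evolution.  Relaxation is mono-exponential per
compartment; diffusion, magnetization transfer, exchange and slice profiles
are out of scope.

Tissue defaults are CSF T1/T2 = 4300/2200 ms and vessel wall
T1/T2 = 1200/50 ms (the values the protocols were designed around), plus a
white-matter-like parenchyma placeholder of 850/70 ms for the phantom,
which is config-overridable and not used in any quantitative claim.

## Echo-train engine

The turbo-spin-echo readout is simulated with the extended phase graph
(EPG): configuration states F+(k), F−(k), Z(k) with ideal unit gradient
dephasing per half echo-spacing and relaxation applied per interval.  The
RF mixing matrix is derived numerically from the package's Cartesian
rotation matrix through the (M+, M−, Mz) basis change, so the EPG engine
and the Bloch engines cannot drift apart in convention.  A 256-isochromat
Bloch ensemble with a uniform dephasing grid serves as an independent
oracle: on a uniform grid the ensemble average equals the k = 0 Fourier
coefficient exactly once the isochromat count exceeds the highest populated
order, and the test suite holds the two engines to within 1e-3 on random
flip schedules (they agree to near machine precision).  With all-180°
refocusing the engine reproduces pure e^(−t/T2) echo decay at machine
precision (CPMG limit).

The echo train is excited with a 90° pulse and refocused 90° out of phase
(CPMG condition).  Echo n is read at n·ESP; the scalar "signal" of a
sequence is the amplitude at the effective-TE echo, i.e. the echo encoding
the k-space center under linear reordering, index round(TE/ESP) (21 for
TE 92 ms at ESP 4.4 ms, 28 for TE 123 ms, 78 for TE 345 ms).  k-space
weighting, partial-Fourier and parallel-imaging effects on contrast are
deliberately ignored: the contrast model is single-echo-amplitude.

## Variable flip-angle design

The product "T2 var" schedules of SPACE-type sequences are proprietary and
unpublished, so the package designs its own by prescribed-signal-evolution
inversion of the EPG recursion: for a design tissue (vessel wall by
default) each refocusing angle is solved so the echo amplitude holds a
constant plateau.  Because the amplitude is not monotonic in the angle — a
180° pulse only refocuses the already-decayed previous echo, while
intermediate angles recruit stored longitudinal pathways — each step scans
a coarse angle grid and root-finds on the rising branch, taking the
smallest angle that meets the target (the SAR- and magnetization-conserving
choice).

The default plateau is the maximal one the design tissue can sustain
through the k-space-center echo, found by bisection; after the center the
train tapers linearly back to the schedule's minimum angle, a TRAPS-like
choice that limits RF power and returns magnetization to the longitudinal
axis once the contrast-determining echoes are acquired.  Constant-angle and
explicit user-supplied schedules are available as alternatives, and the
plateau and hold window are exposed as parameters.  Signal levels read at
the effective TE are only moderately sensitive to these conventions, but
absolute levels printed for the unprepared sequence (where the echo train
itself sets the fluid steady state) inherit the uncertainty of the unknown
product schedule; see "Known limitations".

## TR cycle and steady state

One repetition is preparation → inversion-recovery delay → excitation +
echo train → free recovery, with the recovery time derived from
TR − TE_prep − TI − ETL·ESP (negative budgets are rejected with the
deficit).  The engine iterates repetitions from equilibrium and reports the
final one; ten repetitions are the default and the change between the last
two repetitions is reported (all shipped presets converge below 1e-3 well
before rep 10; non-convergence warns rather than fails).

The per-tissue state carried across the TR is the full EPG state, not a
single mz value.  The end-of-train spoiler removes transverse (F) orders
only; longitudinal configuration orders Z(k ≠ 0) survive the recovery
period with plain T1 decay (no regrowth) and re-enter the next excitation.
For prepared sequences this is irrelevant — every preparation module cycles
all orders through the transverse plane and ends in a spoiler, collapsing
the state to Z(0) — but for the unprepared sequence with a long-T1 fluid
the stored orders are a real magnetization reservoir and raise the CSF
steady state by roughly 15%.  Orders beyond 2·ETL are truncated
(physically: crusher-level dephasing).

## Preparation modules

* **T2IR**: 90x excitation, four composite refocusing pulses (90x-180y-90x)
  at uniform CPMG spacing with MLEV-4 phase pattern R,R,R̄,R̄ (the phase
  pattern is configurable because only "alternated" phases are standard,
  not the exact pattern), and a composite tip-down (270−x 360x ≡ −90x at
  nominal field).  T1 recovery during the module is suppressed — the
  longitudinal component is nominally zero throughout — so at nominal field
  the module output is exactly −mz·e^(−TE_prep/T2), the pure-T2 weighting
  law; at TE_prep → 0 it reduces to a plain inversion (the FLAIR limit).
  Refocusing pulses are centered at TE_prep·(2k−1)/(2n).
* **DANTE**: flowing spins are modeled with ideal per-interval transverse
  spoiling (velocity-randomized phase), giving cos(α)^N attenuation
  interleaved with T1 recovery; with the default 20 mT/m gradient over
  1.5 ms interpulse spacing a voxel dephases by many cycles, which
  justifies the idealization.  Static tissue is the voxel average over a
  uniform per-interval phase grid, which largely preserves mz; the narrow
  comb of positions whose gradient phase is a multiple of 2π (where the
  low-flip pulses add coherently) is of measure zero in the average but is
  the mechanism behind spatially heterogeneous fluid suppression.
* **AntiDrive**: a −90° restore at the final echo sends the coherent
  transverse magnetization to −z; the pre-existing longitudinal component
  is tipped into the transverse plane and spoiled.

### Composite-pulse robustness

The efficiency map runs the full preparation with finite-duration pulses
over a (B0 offset, B1 scale) grid and reports the preserved longitudinal
fraction −mz_out/mz_in for the MLEV composite train against a
constant-phase plain-180° train with identical timing.  The composite
shows its advantage at moderate off-resonance (e.g. 200 Hz at nominal B1).
At exactly zero off-resonance a plain CPMG train is transparent to
magnetization parallel to its refocusing axis — a rotation-algebra
identity — so under a pure B1 error nothing outperforms it there; the
composite's known B1 sensitivity at narrow bandwidth is reproduced rather
than idealized away.

## Null-time solvers and parameter search

The cyclic inversion-recovery null solves 1 − 2e^(−TI/T1) + e^(−TR/T1) = 0
in closed form (TI = T1·ln 2 for TR → ∞; 2077 ms for CSF at TR 6250 ms,
matching the FLAIR protocol's rounded 2100 ms).  It deliberately ignores
echo-train saturation; the simulation-consistent counterpart is a grid
search for the TI that nulls the steady-state CSF longitudinal
magnetization at acquisition start, run through the full engine.  The two
bracket the design procedure for the prepared protocols.  The preparation
optimizer is a deterministic, seedless grid sweep over (TE_prep, TI)
maximizing the wall-minus-CSF effective-TE signal under a CSF-residual
constraint, returning the full objective surface; a grid search was chosen
over gradient methods because the objective is cheap and the surfaces
themselves are wanted.

Scan time is TR × ⌈n_lines/ETL⌉ with
n_lines = phase × partitions × partial-Fourier / parallel-factor, plus the
central reference lines counted once at full sampling (switchable off,
since vendor accounting of integrated reference scans is not
standardized — the estimate carries roughly a 10% convention envelope).
With the default 288 × 288 × 224 matrix, 5/8 partial Fourier and factor-2
acceleration this gives 710 s for the TR 2500 ms protocols.

## Digital phantom

A 2D cross-section: concentric lumen / wall / CSF annulus / parenchyma
discs in an air margin, 192² voxels of 0.6 mm by default, wall thickness at
least one voxel.  Simulated steady-state signals are painted per
compartment, the lumen is an ideal flow void (the intrinsic black-blood
assumption of the long echo train; no blood parameters are modeled), and
Gaussian noise of standard deviation σ is added with a fixed seed (a Rician
magnitude mode exists behind a flag; at the SNRs involved the Gaussian
approximation keeps the air-ROI σ estimator unbiased).  ROI statistics
apply SNR = S/σ and CNR = SNR_VW − SNR_CSF verbatim.  The phantom
reproduces the qualitative contrast ordering of the protocols — T2IR
highest wall–CSF CNR, unprepared T2w negative CNR — and that ordering is
stable across a tenfold range of σ.  Absolute in-vivo SNR/CNR magnitudes
are expressly out of scope: coil sensitivity, B1 shading and reconstruction
effects are unmodeled, so only signs and orderings are asserted.

## What the simulations do and do not show

The synthetic conditions are the protocol parameter sets and printed tissue
constants; the phantom adds only geometry and Gaussian noise.  Passing
tests therefore demonstrate internal physical consistency (engine
cross-checks, closed-form limits, steady-state convergence, contrast
orderings) — not agreement with any individual in-vivo measurement, where
flow pulsation, B0/B1 inhomogeneity, coils and reconstruction intervene.

## Known limitations

* The true product flip-angle schedules are unknown.  The prescribed-
  signal-evolution default reproduces the prepared-sequence signal levels
  well, but the unprepared sequence's fluid signal depends strongly on how
  much magnetization the train returns to the longitudinal axis: our
  schedule family yields a steady-state CSF level of ≈ 0.37 of M0, and no
  angle-capped CPMG-type schedule we can construct under this saturation
  model reaches ≈ 0.5 while keeping the other signal levels — the CSF
  level for the unprepared protocol should be read as schedule-dependent.
* Preparation modules assume ideal spoiling and, in instantaneous mode,
  ignore relaxation during pulses; delays are not shortened by pulse
  durations in the finite-duration mode.
* Problem sizes: simulations run 10 repetitions of trains up to ETL 195;
  schedule design dominates runtime (a few seconds per preset) and is
  cached per (tissue, train) geometry.
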