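# Methods

`gelperm` simulates the transport of rigidity-tunable nanoparticles (NPs)
through a cross-linked polymer hydrogel with a coarse-grained bead-spring
model, and provides the statistics used to quantify transport both in
simulation (3D MSD, fitted diffusivity, polymer contacts, particle shape) and
in 2D multi-particle-tracking experiments (per-particle MSD and effective
diffusivity).  All simulation quantities are in reduced Lennard-Jones units:
length sigma, mass m, energy epsilon, time tau; temperature is quoted as kT
in epsilon.

## The model

**Network.**  The hydrogel is a regular cubic lattice of fibers: at every
grid line of an n x n transverse lattice a bead-spring fiber runs parallel to
each axis and closes on itself through the periodic boundary, giving 3 n^2
chains.  With box L and requested mesh a0, n = round(L/a0) and the effective
mesh is a = L/n (98 sigma box with 16 sigma mesh gives n = 6, a = 16.33
sigma, 108 chains).  The three fibers crossing at each lattice point share a
single node bead, and every node is tethered to its initial position by a
harmonic spring (energy k_t |x - x0|^2, k_t = 10 eps/sigma^2), anchoring the
network the way cross-links anchor mucin fibers.  Beads along a fiber are
spaced ~1.75 sigma apart (snapped so an integer number fits each mesh cell,
because nodes must lie on the bead grid) and joined by stiff harmonic bonds
(k = 100 eps/sigma^2, energy k (r - r0)^2).  Fiber-fiber contacts are purely
repulsive (WCA, sigma = 1, cutoff 2^(1/6)): network self-adhesion is not part
of the model.

**Nanoparticles.**  Each NP is a one-particle-thick closed shell: a
deterministic Fibonacci-lattice covering of the sphere (diameter 10 sigma)
with one orientable bead per ~spacing^2 of surface area.  Shell beads carry
an outward unit normal and interact through a soft-core pair potential whose
strength is weighted by the relative orientation of the pair:

    u = u_R(r) + [1 - phi] eps_np              r < r_min
    u = u_A(r) phi                             r_min <= r < r_cut
    u_R = eps_np [ (r_min/r)^4 - 2 (r_min/r)^2 ]
    u_A = -eps_np cos^(2 zeta)( (pi/2)(r - r_min)/(r_cut - r_min) )
    phi = 1 + mu (a - 1)
    a   = (n_i x rhat).(n_j x rhat) + sin(theta0)(n_j - n_i).rhat - sin^2(theta0)

with zeta = 4, mu = 3.  Forces and the generalized forces on the normals are
exact analytic gradients (verified against central finite differences to
1e-5 over thousands of random configurations).  The potential and its first
derivative vanish continuously at r_cut, so no shifting is needed.

`eps_np` is the rigidity dial: bending the shell misaligns neighbor normals
and costs ~mu eps_np per pair.  The calibrated class presets are
soft/semi-elastic/hard = 0.2/1.0/6.0 eps, chosen on the shape taxonomy the
classes are meant to reproduce (see *Calibration*).

**Spontaneous curvature.**  theta0 sets the preferred angle between the
bead-pair axis and the normals.  At the shell discretization used here
(spacing 2.6 sigma on a diameter-10 shell, ~46 beads) the sphere is strongly
curved on the bead scale, and a flat-preferring potential (theta0 = 0) makes
weak shells crumple irreversibly.  The protocols therefore set
sin(theta0) = spacing/diameter, which places two neighboring beads *on the
constructed sphere* exactly at the orientation-weight maximum: the shell's
own curvature is its ground state.  This is the standard role of the
spontaneous-curvature parameter; without it only eps_np >~ 6 shells survive.

**NP-polymer interaction.**  Shell beads are treated as spheres of diameter
~2 sigma (the shell spacing is near the corresponding LJ minimum), so the
polymer-NP Lennard-Jones uses sigma_pn = 1.5 with cutoff 2.5 sigma_pn and
well depth eps_pn = 0.1 eps — the adhesion that makes deformable NPs wrap
fibers.  eps_pn is the documented robustness dial (scans cover 0.02–0.2).
Bonded (1-2) neighbors are excluded from all non-bonded terms.

**Rigid particles.**  Equal-volume prolate spheroids (semi-axes a = r AR^(2/3),
b = r AR^(-1/3)) are built by affinely mapping the Fibonacci sphere, with
outward surface normals.  Rigid bodies are propagated as rigid: velocity-
Verlet for the center of mass and quaternion/body-frame angular-velocity
integration (Euler terms included) for the orientation; per-bead friction
aggregates into a center-of-mass friction N_b*gamma and a body-frame angular
friction gamma*I/m, each with fluctuation-dissipation-matched noise.
Internal geometry is preserved exactly (a rigid AR = 2 spheroid measures
AR = 2.000 throughout any run).

## Dynamics

Velocity-Verlet with time step dt = 0.01 tau, followed each step by a
Langevin kick: v += -gamma v dt/m + xi with Var(xi) = 2 gamma kT dt / m^2 per
component.  The compiled engine draws xi from a uniform distribution with the
matched variance (the standard cheap choice; velocity statistics are Gaussian
by accumulation), while the pure-Python reference operations use Gaussians —
the two are statistically, not bitwise, equivalent.  The engine is
deterministic for a given seed (own xorshift128+ stream).

Shell-bead normals follow a first-order overdamped rotational Langevin
update sharing the thermostat temperature: n += (dt/gamma_n)(-dU/dn)_perp +
noise_perp, renormalized each step, with gamma_n = 10 m/tau.  gamma_n ~ 1
would rotate normals by up to ~0.2 rad per step under typical torques and is
numerically unstable; 10 keeps per-step rotations below ~0.02 rad while the
orientational relaxation (~gamma_n/kT ~ 40 tau) stays far below the
diffusion time scales of interest.

Neighbor search uses linked cells (counting-sorted) with typed Verlet lists
(skin 1.0 sigma), rebuilt when the largest accumulated bead displacement
exceeds half the skin.  A blow-up guard aborts if any bead moves more than
0.5 sigma in one step.  With the thermostat off (gamma = 0) the integrator
conserves energy (drift < 0.1% of the initial potential over 1e4 steps,
shrinking with dt as expected for a symplectic scheme); with it on, the
kinetic temperature equilibrates to the set point within a few percent.

## Protocols

* **Full-length preset** (`paper_protocol`): 98 sigma box, 108 chains,
  27 NPs, kT = 0.23, gamma = 1, 2e6 tau, MSD from 8e5 tau, D fitted over
  1.3e6–1.8e6 tau.  This is hours of CPU and is provided as configuration,
  not run by the test suite.
* **Desk-scale protocol** (`scaled_protocol`, the default): 49 sigma box
  (n = 3, 27 chains) preserving the controlling geometry — effective mesh
  16.33 sigma against NP diameter 10 sigma; 4 NPs of each rigidity class
  co-resident per box (NP volume fraction ~5%, so classes barely interact
  and share the same network realization); 3 seeds; 2e4 tau per run;
  gamma = 0.2 m/tau so that free-NP displacements (D_free = kT/(N_b gamma))
  cross the pore scale within the shortened runs.  MSD uses time origins
  after the first 40% of the run (mirroring the full protocol's 8e5/2e6
  equilibration), lags to 40% of the sampled span, and fits the final 25% of
  the lag range; D = k/6.  Each class's D is the mean over seeds +/- sd, and
  the headline observable is the ratio between class means.

At this problem size a run's root-mean-square NP displacement is a few pore
lengths, so fitted D values carry ~15–20% sampling error per class; ratios
between classes, not absolute D, are the meaningful output.

## Calibration

The rigidity presets were calibrated on the shape taxonomy (not on any
transport observable): in the gel at kT = 0.23,

* hard (eps_np = 6): aspect ratio stays within ~2% of the constructed
  shell's own (discrete) AR — an effectively undeformable sphere;
* semi-elastic (eps_np = 1): transiently buckles into ellipsoids (AR
  excursions to ~1.5–2.5 with large fluctuations);
* soft (eps_np = 0.2): persistently and irregularly deformed (mean AR ~1.3,
  >15% above the constructed shell), conforming to — and wrapping — the
  fibers it adheres to.

Below eps_np ~ 0.5 the shell's shape is adhesion-dominated (further softening
changes it little); above ~3 it is effectively rigid.  The contact observable
(an NP bead counts as contacting if any network bead lies within 3 sigma;
each bead counts once) is reported per NP, so its absolute scale is set by
the shell discretization; the ~46-bead shell makes a single-fiber touch
~8–10 beads and a wrapped soft NP roughly twice that, commensurate with the
full-scale study's per-NP contact scale.

## Tracking pipeline and its synthetic generator

The 2D pipeline computes, per particle, the time-origin-averaged squared
displacement MSD_t = sum[(x_t-x_0)^2 + (y_t-y_0)^2]/n and the effective
diffusivity D_eff = sum[MSD_t/(4t)]/n at a stated time scale (1 s by
convention; the lag snaps to the frame grid and the snapped value is used in
the division, so the estimator is unbiased).  Ensemble averages divide by the
number of particles n.  The distribution stage histograms log10 D_eff and
reports the fraction above a mobility threshold (0.1 um^2/s by convention).

The generator emulates a video-microscopy acquisition: 100 particles, 32.6 ms
frames, 10 s movies, per-particle D drawn from a log-normal mixture spanning
the sub-0.1 to >0.1 um^2/s decade (default: 70% slow, median 0.02 um^2/s,
sigma_log10 0.5; 30% fast, median 0.15, sigma_log10 0.3), Gaussian steps of
per-axis variance 2 D dt, additive Gaussian localization noise (sd 10 nm,
which inflates MSD by the closed-form constant 4 sd^2), and optional
reflective circular confinement.  What it does **not** emulate: static/dynamic
error correlations, motion blur, track splitting/linking errors, spatially
heterogeneous gels, or anything tied to real mucus samples.  Passing tests
therefore validate the estimators and the acquisition geometry, not any
biological claim.

## Numerical choices and degenerate inputs

* Minimum image via branch correction (positions are stored wrapped).
* Pair lists are typed (network-network WCA, network-shell LJ, shell-shell
  orientation-weighted); pairs inside one rigid body are skipped (internal
  forces cannot move a rigid body).
* Gyration shape: beads are made coherent under the minimum image before the
  tensor is formed; AR = sqrt(lambda_max/lambda_min); coplanar or collinear
  bead sets are flagged degenerate and report AR = NaN.
* MSD rejects wrapped-looking input (any single-frame jump > box/2).
* `fit_diffusivity` requires >= 2 lags in the window; empty windows raise.
* Placement rejects candidate NPs within the clearance of any existing bead
  (minimum image, KD-tree) and raises after a configurable attempt cap.

## What the desk-scale experiment does and does not reproduce

Under the desk-scale protocol the model reproduces, from scratch: the
network bookkeeping (108 chains at the full geometry), the deformation
taxonomy of the three rigidity classes, the ~2x diffusivity enhancement of
semi-elastic over hard NPs (measured fold 2.0, seeds 1-3), and the soft
class's elevated polymer contact count (1.9x the semi-elastic mean).

It does **not** reproduce the semi-elastic *optimum* (semi-elastic faster
than soft) or the rigid-ellipsoid speed-up with aspect ratio.  Both failures
trace to the same two desk-scale compromises: (i) runs of 2e4 tau
under-sample the rare, long trapping events that penalize wrapped soft NPs
over a 2e6 tau observation window, so transport is dominated by pore
passage, which deformability always helps — soft comes out fastest
(D soft 0.021 > semi 0.013 > hard 0.0065 sigma^2/tau); and (ii) the coarse
46-bead shells require sigma_pn = 1.5 to stay impermeable to fibers, which
inflates every particle's effective size by ~3 sigma — rigid spheres then
barely clear the pores, and the AR = 3 spheroid's effective major axis
(~19 sigma) exceeds the mesh, so hindered rotation outweighs its slimmer
cross-section (measured D decreases with AR).  Finer shells (~2x the beads)
and ~10x longer runs would lift both compromises at ~20x the compute.

## Known limitations

* No hydrodynamic interactions (Langevin friction is local), no
  electrostatics, no fiber bending stiffness: the gel is an idealized regular
  elastic mesh.
* The desk-scale runs sit at the edge of the diffusive regime (a few pore
  crossings per trajectory); class-mean D ratios carry ~20% sampling error.
* Shell discretization (~46 beads) sets the absolute contact-count scale and
  limits the sharpness of shape statistics.
* The uniform-noise thermostat is exact only in distribution, not per step;
  observables averaged over >> 1 step are unaffected.
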