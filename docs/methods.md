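# Methods

## The model

`condenseq` simulates protein–DNA co-condensation on a double-tethered DNA
molecule with a coarse-grained bead-spring model. DNA is a semiflexible
chain of `Nm` beads, one bead per 10 bp (`sigma = 3.4 nm`), with its two end
beads pinned on the long axis of a fully periodic box at separation
`Re = Re' * s`, where `s` is the contour length and `Re'` the normalized
end-to-end distance familiar from tethered-DNA assays. Proteins are free
beads of the same size.

Interactions:

* **Bonds** — harmonic, `E = kb/2 (l - l0)^2`, `l0 = 1 sigma`,
  `kb = 100 kBT/sigma^2`. The bond constant is a model choice (stiff enough
  that bond stretch under piconewton-scale tension stays far below a bead
  diameter); because the force readout scales with `kb`, it is an explicit
  configuration parameter carried into all outputs.
* **Bending** — discrete worm-like chain, `E = kappa (1 - cos theta)` per
  consecutive bond pair with `kappa = 15 kBT`, targeting a persistence
  length of 15 beads (150 bp). For this Hamiltonian the ideal-chain value
  is `lp = -1/ln(coth kappa - 1/kappa) = 14.5` bonds; weak excluded-volume
  swelling brings the measured value to ~14–16.
* **Nonbonded** — monomer–monomer pairs are purely repulsive (WCA,
  `eps = 1 kBT`). Protein–protein and monomer–protein pairs attract via a
  Lennard-Jones potential cut at `2.5 sigma` and shifted to zero there;
  well depths are `eps_PP` (default 2 kBT) and the per-monomer binding
  affinity `eps_MP(m)` from the sequence model. Directly bonded beads are
  excluded from the nonbonded sum, so the rest bond length stays at `l0`.

Sequence enters only through `eps_MP(m)`: a uniform 2 kBT (homogeneous
null model); a central high-affinity half at 2.25 kBT flanked by 1.75 kBT
quarters (het1, chain-average exactly 2 kBT); five equal blocks alternating
0.1 / 2.25 kBT (het2); or an AT-content mapping of a real sequence, eleven
affinity classes linearly interpolated between 0.1 kBT (0/10 AT) and
4.0 kBT (10/10 AT) over non-overlapping 10-bp windows. The linear
interpolation between the published endpoints is a design choice; the
mapping is monotone and exposed per monomer in TSV form.

Concentrations are intensive: a bulk protein concentration in uM converts
to a particle count through the box volume with Avogadro's number
(`42.25 uM` in the reference 80 x 80 x 600 sigma^3 box is 3840 proteins).
Forces convert as `1 kBT/sigma = 4.11 pN nm / 3.4 nm = 1.209 pN`.

## Dynamics

Underdamped Langevin dynamics at `T = 1 kBT`, damping `gamma = 0.1/tau`,
time step `dt = 0.01 tau`, unit mass, integrated with the BAOAB splitting
(exact Ornstein–Uhlenbeck velocity refresh). Tethered beads are excluded
from integration. An overdamped limit is available by raising `gamma`.
Neighbor lists (cell-linked, `2.5 + 0.8 sigma` list radius, rebuilt every
10 steps) preserve the exact force field within the cutoff. All random
streams — chain shape, protein placement, thermostat noise — are named
substreams of one run seed; repeating a run with the same seed reproduces
the trajectory bit-for-bit.

The experiment protocol mirrors tethered-DNA assays: the bare chain is
equilibrated first (independently per replicate), proteins are then placed
uniformly at random with overlap rejection, the mixed system is
equilibrated — stopping early when both total potential energy and the
largest-cluster size change by less than 2% across two consecutive windows
of 10% of the budget — and production frames are saved at fixed intervals.

## Condensate detection

Condensates are found per frame with DBSCAN over monomers and proteins
jointly (`MinPts = 6`, twice the dimensionality). Monomers are included so
that per-monomer membership — the basis of occupancy and interface
analysis — falls directly out of the clustering; stretched chain segments
are never core points at MinPts 6, so the chain itself does not bridge
separate condensates. With periodic boxes, distances are minimum-image.

The DBSCAN radius is chosen from the data: sort every particle's distance
to its 5th nearest neighbor, smooth the curve with a Savitzky–Golay filter
(degree 3, window 199), and take the curve value at the knee — the index
maximizing the discrete curvature `|y''| / (1 + y'^2)^{3/2}` of the curve
with both axes normalized to [0, 1], ties broken toward smaller epsilon.
The window is clamped to half the curve length (a window spanning the whole
curve reduces the filter to a single cubic and erases the knee), and the
curvature argmax is restricted to the filter's interior, away from the
edge regions where the filter extrapolates.

The knee estimator assumes full-scale particle counts (thousands of
particles, a large condensed fraction). Desk-scale frames are
gas-dominated — a few hundred particles, most of them dilute — and there
the knee lands in the gas ramp of the curve and overestimates epsilon
severely (measured 3–9 sigma against a condensed-phase spacing of
~1.1 sigma). The scaled experiments therefore run the same pipeline with a
fixed `epsilon = 1.5 sigma`, above the condensed-phase spacing and below
the attraction cutoff; `DetectionParams.epsilon` makes this a one-line
switch, and the knee path remains the default elsewhere.

Cluster geometry: per-axis radius = half the maximum pairwise extent,
volume `Vc = 4/3 pi rx ry rz`. Clusters below a minimum size (default 20
particles, scaled with the chain at desk scale) are discarded as transient
oligomers. Across frames, condensates are matched greedily by member-set
Jaccard overlap (threshold 0.3); an equilibrium count requires a track to
be present in at least 80% of the analysis window's frames.

## Observables

* **Occupancy** `Pm`: fraction of analysis frames in which monomer `m`
  belongs to any detected condensate.
* **Interfacial affinity** `Ia`: occupancy-weighted mean binding affinity
  over interface monomers, `Ia = sum eps_MP(m) Pm / sum Pm`. The interface
  set is `0.1 < Pm <= 1` as the default rule; a strict variant
  (`upper = 0.9`) excluding permanently interior monomers is a keyword away,
  since the inclusive upper bound arguably folds the condensate core into
  its interface. Interfaces are split left/right around each contiguous
  core run (`Pm >= 0.9`) and the per-side values averaged.
* **Forces**: the tether force is `F_DNA = kb (lt - l0)` from the mean bond
  lengths of tethered vs free-end bare chains; with proteins,
  `F_DNA,protein = kb (ltp - lt)` uses only bonds whose both endpoint
  monomers lie outside every condensate; the capillary force is their
  difference. Replicates are aggregated as mean ± standard deviation over
  independent initial conditions (default 5).
* **Per-monomer potential energy**: nonbonded pair energies split
  half-and-half between endpoints plus each monomer's bonded terms; the
  profile steps sharply at condensate interfaces.
* **Kymograph**: monomer × time membership matrix.
* **Coarsening**: tracked condensate radii `R = (3 Vc / 4 pi)^(1/3)` vs
  time, scaled by the final largest radius; the growth exponent is the
  log–log slope over frames where the largest radius lies between 20% and
  80% of its final value (the growth regime, excluding the plateau). A
  single desk-scale trajectory grows through a handful of discrete
  coalescence events — a staircase whose apparent slope scatters widely —
  so the quantitative experiment fits the replicate-averaged largest-track
  radius curve, sampled every tau to resolve the early growth.
* **Persistence length**: fit of `A exp(-d/lp)` to the mean
  tangent–tangent correlation over separations up to 30 bonds. The fit is
  nonlinear in correlation space, where sampling noise is roughly
  homoscedastic — a log-linear fit would amplify the noise of the small
  long-separation correlations (it serves only as the starting point).
  Separations beyond ~lp are dominated by slowly relaxing global modes, so
  the quantitative experiment additionally pools correlation curves over
  ten independent chains before fitting.

## Desk-scale experiment design

Production-scale conditions (500-monomer chains, thousands of proteins,
1.5e7 steps, 5 replicates) are cluster-scale. The packaged experiments are
scaled down while keeping the claims being tested scale-invariant:

* chains of 40–100 monomers with block layouts shrunk proportionally
  (het1 keeps 25%/50%/25%, het2 five equal blocks);
* boxes shrunk so that protein counts at the study concentrations stay in
  the low hundreds, with the cross-section kept generous: the condensate
  draws proteins out of a finite reservoir, and too small a box starves it
  (this, not the concentration, is the main finite-size effect);
* equilibration budgets of a few hundred thousand steps — desk-scale
  droplets absorb their DNA over ~2000–6000 tau, and the interface
  position is the slowest observable;
* optionally, a fraction of the proteins initially placed within reach of
  the chain (`protein_near_chain_fraction`): on taut chains the nucleation
  barrier would otherwise consume most of the equilibration budget, and
  pre-seeding changes only the approach to equilibrium, not the state;
* detection with fixed epsilon as discussed above.

Two finite-size effects deserve naming. First, the droplet draws on a
finite protein reservoir, and its DNA *capacity* — how much contour it can
absorb — is the quantity that positions the capillary-force switch: the
switch sits where the absorbed DNA equals the slack, so the force-scan box
is sized to put the capacity near half the contour, the ratio the
full-scale conditions realize at 84.5 uM. Second, the droplet's own
diameter `d` displaces the taut outside DNA, shifting the switch to
`Re' ~ 0.5 + d/s`; at 50 monomers this is a +0.1–0.15 shift, at 100
monomers ~+0.05, which is why the force scan runs at `Nm = 100`.

What the desk-scale runs do show: a homogeneous chain hosts exactly one
equilibrium condensate (at 126.75 uM — nearer the coexistence boundary
the droplet is reservoir-starved and flickers); a two-block chain in the
strong-DNA-binding regime (block affinity 3 kBT above eps_PP = 2 kBT)
holds exactly two stable condensates; the capillary force of the het1
chain switches sharply near `Re' ~ 0.5`, where the condensate interface
crosses from the low- into the high-affinity block; force and interfacial
affinity rise together across the scan; and the largest condensate grows
diffusively, `R ~ t^(1/2)`, before arrest.
What they do not show: absolute force magnitudes comparable to full-scale
runs, nucleation statistics at realistic reservoir sizes, or metastable
multi-droplet lifetimes beyond ~1e4 tau.

The synthetic fixtures (Gaussian blob frames, prescribed membership
patterns, Gaussian bond-length series) exercise the detection and
observable mathematics with exact ground truth; they are geometric
stand-ins and deliberately lack physical droplet interfaces, fluctuating
membership, and chain connectivity, so passing them validates bookkeeping,
not thermodynamics.

## Numerical choices and degenerate inputs

* Knee selection raises a degenerate-curve error on straight or constant
  k-distance curves (no density contrast); detection falls back to a
  configured epsilon if provided.
* Cluster extents use minimum-image coordinates relative to a member seed,
  valid while condensates are smaller than half the box (always, here).
* DBSCAN with periodic boxes uses a dense precomputed distance matrix,
  capped at 5000 points; beyond that, cluster without the box or chunk.
* The growth-exponent fit needs at least 3 frames in the growth window;
  with fewer than two tracked condensates the two-droplet analysis
  downgrades to single-droplet output with a warning.
* Integration raises a named error on non-finite coordinates (time step
  too large for the stiffest mode); the harmonic bond at `kb = 100` limits
  `dt` to well below `0.2 tau`, and the default 0.01 tau has an order of
  magnitude of headroom.
* Protein placement rejects overlaps below 0.9 sigma with a bounded number
  of resampling rounds and raises a density error beyond it.

## Known limitations

Protein binding does not alter DNA mechanics (persistence length is
sequence- and binding-independent); proteins are isotropic single beads
with no valence structure; hydrodynamic interactions are absent; the
potential forms are standard bead-spring choices rather than a published
parameter file, so absolute coexistence concentrations shift accordingly
(the protein-only and co-condensation thresholds land in the right decade
but are not calibrated); and desk-scale reservoirs make droplet sizes
sensitive to box cross-section, which is why the scaled presets fix it.
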