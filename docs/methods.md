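# Model and methods

`gcfb` simulates one germinal center (GC) as a hybrid model: B cells are
discrete agents on a 3-D lattice, while soluble antibody and antibody–antigen
chemistry are deterministic ODE layers advanced on a coarser clock.  The
purpose of the model is to study *antibody feedback*: antibodies secreted by
GC-derived plasma cells mask antigen held on follicular dendritic cells
(FDCs), starving B cells of antigen and feeding back negatively on selection,
output and, ultimately, GC lifetime.

## Spatial substrate

The reaction volume is a sphere of radius 160 µm on a cubic lattice with
5 µm constant (≈137,000 nodes), split into equal dark (DZ) and light (LZ)
zone hemispheres; the equatorial plane is assigned by checkerboard parity so
the two zones differ by <0.01 % of nodes.  Motile B cells obey one-cell-per-
node exclusion and perform a persistent random walk (7.5 µm/min, ~1.5 min
persistence).  Chemotaxis is abstracted as a directional bias applied on
repolarisation: centroblasts outside the DZ bias toward it, centrocytes
outside the LZ toward it, output cells toward the border, with probability
`zone_bias` (default 0.5).  The motion step is 1/90 h — exactly one lattice
constant per step at the default speed, so the move-attempt probability is 1.

FDCs are collapsed to 200 point sites in the LZ, and 250 immobile Tfh are
scattered there.  Each site/Tfh covers a Chebyshev-radius-2 contact
neighbourhood (125 nodes) standing in for FDC dendrites and for active
T–B search; with true point contacts a centrocyte would meet antigen or help
too rarely for any selection to occur at realistic densities.  FDCs and Tfh
do not block B-cell movement.

## B-cell life cycle

Founders enter the DZ as centroblasts at 2 cells/h with a division budget of
6, carrying a shape-space position drawn at Manhattan distance 5–10 from the
optimal clone (the distance shell is drawn uniformly first, then a point on
it; sampling points uniformly would concentrate founders on the far shells).
Influx stops at 96 h: a permanent founder stream, each founder guaranteed
2⁶ descendants regardless of selection, would keep the GC volume at ~10³
cells forever and no reaction could ever terminate.

Centroblasts divide stochastically (mean cycle 6 h).  Each daughter of a
division mutates with probability 0.5 — one ±1 step in one of the four shape-
space dimensions, reflected at the box boundary — but only from day 1 of the
reaction onward.  Affinity is Gaussian in Manhattan distance to the optimum,
`a = exp(−d²/Γ²)`, Γ = 2.8.  A cell that exhausts its budget becomes a
centrocyte and migrates to the LZ.

Centrocytes search FDC sites for up to 10 h.  While in contact they attempt
capture every 0.5 h; an attempt succeeds with probability
`a · G_free/G_initial` (affinity times the unmasked, unconsumed fraction of
site antigen) and removes one 10⁻⁸ M portion from the site.  Tfh help is
polarised: among the centrocytes in contact with a given Tfh, only the one
with the most captured antigen accrues signal (ties at random), and cells
with fewer than `min_collected_portions = 2` portions present too little
pMHC to compete at all.  A centrocyte accumulating 0.75 h of polarised
signal is selected: with probability 0.8 it recycles to a centroblast with 2
further divisions, otherwise it becomes an output cell, drifts to the
border, exits, and differentiates into a plasma cell at rate ln2/24 h⁻¹.
Unselected centrocytes die at the 10 h deadline.  Plasma cells are counted
cumulatively (no death over the 21-day horizon; pool decay handles
turnover).

### Why threshold 0.75 h, refractory 0.5 h, minimum 2 portions

These three parameters are not printed anywhere and jointly set the
selection throughput; they were fixed once so that the default
configuration reproduces the study conditions of the feedback experiments:

* The Tfh pool supports at most `n_tfh / threshold` selections per hour.
  At 0.5 h (with radius-2 contact zones) the GC saturates at ~17,000 cells
  and consumes the entire FDC antigen store within ~9 days; 0.75 h caps the
  GC at a realistic ~10,000 cells.
* A 0.05 h attempt refractory lets a centrocyte take ~10× more antigen per
  lifetime than selection needs, again exhausting antigen by consumption
  alone mid-reaction; 0.5 h keeps cumulative uptake below the store while
  leaving masking as the dominant depletion channel — which is the model's
  mechanism of interest.
* With any captured portion sufficing (≥1), the probability that a starving
  centrocyte still qualifies falls only linearly in antigen availability,
  and a high-affinity remnant of ~30 cells persists for weeks past the
  horizon at strong feedback.  Requiring 2 portions makes qualification
  quadratic in scarcity: starved tails collapse within days while a healthy
  mid-reaction GC (capture probability ~0.2–0.5 per attempt) is barely
  affected.

## Antibody pool and immune complexes

Secreted antibody is resolved into 11 affinity bins with dissociation
constants `K(i) = 10^(−5.5−0.4 i)` M.  Each bin follows

    dA(i)/dt = k1 · n_p(i) − k2 · A(i)

with `k1 = 10⁻¹⁵ M/h` per plasma cell (10⁻¹⁷ mol/h diluted over 10 ml) and
`k2 = ln2/720 h⁻¹` (30-day half-life).  The update is the exact linear-ODE
solution with `n_p` frozen over the chemistry step (0.1 h).

On every FDC site, the effective antibody `A_eff(i) = N·A(i) + A_early(i)`
binds free antigen with a shared `k_on = 10⁶ M⁻¹s⁻¹` and `k_off(i) =
k_on·K(i)`; antibody depletion by complex formation is neglected, so `A_eff`
forces the site chemistry.  `N` is the feedback scaling factor — a proxy for
N synchronous GCs secreting into the same serum pool.  Because
`k_off(0) ≈ 1.1·10⁴ h⁻¹` makes the system stiff, each (G_free, C(i)) pair is
relaxed *analytically* toward its conditional equilibrium (exact for that
pair with the other bins frozen), sweeping bins in randomised order with 10
sub-steps per chemistry step.  Each pair update conserves `G_free + C(i)`
identically, so per-site mass `G_free + ΣC + G_consumed = G_initial` holds
to rounding error; the scheme is verified against a dense stiff ODE solve
(`max |C − C_oracle| / G_initial < 10⁻⁴` over weeks).  Sites start with
`G_initial = 3·10⁻⁵ M` (3000 portions).  B-cell uptake draws from free
antigen only; consumed antigen never returns.

## Readouts

* **GC volume** — centroblasts + centrocytes on the lattice.
* **Termination time** — first hourly sample at which the volume is zero and
  stays zero (leading transient zeros before influx accumulates don't count).
* **IC fraction** — `ΣC / (ΣG_free + ΣC)` over sites: the masked share of
  antigen still displayed; consumed antigen is excluded from both sides.
* **Mean plasma affinity** — arithmetic mean of the continuous shape-space
  affinity of every plasma cell produced so far (a bin-midpoint variant is
  available via `mean_affinity_binned`).
* **Immune power** — `IP = Σᵢ A(i)·G/(K(i)+G) / G` at reference antigen
  `G = 10⁻⁶ M`: the fraction of a probe antigen the GC's own secreted
  antibodies would bind; linear in A and increasing in bin affinity.  IP uses
  the GC's own pool only (no N scaling, no external early antibody).

## Experiment protocols

* **Feedback sweep** — independent GCs at N ∈ {1, 10, 30, 300}.
* **Delayed initialization** — a baseline N = 1 run provides the hourly
  antibody profile `A_ref(i,t)`; a late GC (itself N = 1) then experiences
  `A_early(t) = 300 · A_ref(t + Δ)` for delay Δ, evaluated by linear
  interpolation and extrapolated past the grid by exponential decay at k2.
  The coupling is one-way: the late GC never alters the profile.
* Seeds: `base + condition·10⁴ + replicate`, injective and logged.

## Synthetic-data scope

All inputs are generated in-process; there is no external data.  The
generator emulates a single "representative" GC with a monoclonal antigen,
fixed-size division bursts, and homogeneous well-mixed serum.  It does not
emulate extrafollicular antibody-secreting cells, memory B cells, isotype
classes, explicit chemokine fields, FDC dendrite geometry, or multiple
explicitly interacting GCs (the scaling factor N stands in for those).
Passing tests therefore demonstrate the internal consistency of this model
and the reproduction of its published trends, not quantitative agreement
with any experimental GC.

## Numerical and testing choices

* Motion dt 1/90 h, chemistry dt 0.1 h (10 analytic sub-steps), hourly
  sampling; horizon 504 h.
* Identical (config, seed) runs are bit-identical; every stochastic element
  draws from one `numpy` PCG64 generator.
* Cell bookkeeping (founders + births = alive + apoptosed + exited) and
  per-site antigen mass conservation are asserted at every sample; a
  violation aborts the run.
* The test suite runs full-geometry 21-day replicates for the trend checks
  with 3 seeds per condition; the acceptance script uses 5.  A miniature
  configuration (40 µm sphere, 10 FDC sites, 20 Tfh, 3 days) with identical
  rate constants backs the fast unit and property tests.

## Known limitations

* The selection-throughput parameters above are reconstructed, not printed;
  other (threshold, refractory, minimum-portion) triples can produce the
  same trends with different absolute cell counts.
* The time at which masking becomes essentially complete (IC ≥ 0.99) in the
  zero-delay strong-feedback protocol computes to ~12 days here; pushing it
  earlier requires more antibody per plasma cell or more plasma cells, which
  would overshoot the calibrated day-21 N = 1 masking level of ~65 %.
* Founder influx past 96 h, plasma-cell death, and antigen replenishment are
  all absent; runs beyond ~4 weeks would not be meaningful.
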