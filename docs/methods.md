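# Methods

This note documents the statistical model behind `chialoop`, the numerical
choices made where the mathematics left room, and what the synthetic-data
tests do and do not establish about real data.

## Notation

Read pairs r = ⟨r⁽¹⁾, r⁽²⁾⟩ are stored by the 5′ alignment locations of
their mates, ordered so r⁽¹⁾ ≤ r⁽²⁾ (or by chromosome order across
chromosomes). The orientation is the pair of strand labels of the ordered
mates; d(r) = r⁽²⁾ − r⁽¹⁾ is the span. N with orientation subscripts counts
pairs per orientation; q denotes a protein-occupied genomic location; M is
the mappable genome size (default 0.8 × assembly length when unknown).

## Self-ligation mixture model

Self-ligation pairs always read `-+` and their span is bounded by the
sonication fragment length; inter-ligation pairs occur in all four
orientations with unconstrained spans. Because `++`, `+-` and `--` pairs
can only arise from inter-ligation, and ligation is orientation-symmetric,
the average of those three counts estimates the number of `-+` pairs that
are secretly inter-ligation:

    Pr(z=inter) = min(1, avg(N₊₊, N₊₋, N₋₋) / N₋₊).

The span density of all `-+` pairs, Pr(d), and of the inter-only
orientations, Pr(d|inter), are Gaussian kernel density estimates; the
self-ligation span density follows by mixture subtraction,
Pr(d|self) = (Pr(d) − Pr(inter)·Pr(d|inter)) / Pr(self), clipped at zero
(finite-sample estimates can drive it negative), and Bayes' rule gives each
pair's weight w = Pr(z=self|d), clipped to [0, 1].

*Distance cap.* Spans above 50 kb (configurable) are treated as certainly
inter-ligation, and both KDEs are fitted on capped spans. Strictly this
re-normalizes both densities on [0, cap] while the mixing fraction stays
the global count ratio, which overweights the inter component inside the
cap; the effect is a slightly conservative posterior in the far tail, where
self-ligation mass is negligible anyway. Inter-chromosomal `-+` pairs are
classed as inter-ligation outright (a fragment cannot span chromosomes).

*Bandwidths.* All bandwidths minimize the least-squares cross-validation
(LSCV) criterion ∫f̂² − (2/n)Σᵢ f̂₋ᵢ(xᵢ), evaluated in closed form for the
Gaussian kernel on a log-spaced candidate grid (default 30 points,
10–10,000 bp). The weighted 2D variant renormalizes the leave-one-out
weights over j ≠ i and reduces exactly to the unweighted criterion at equal
weights. The criterion is cheap per candidate and non-convex, so an
exhaustive grid is both simpler and more robust than continuous
optimization. On large inputs LSCV runs on a deterministic subsample
(default 1,000 points); the criterion concentrates fast enough that the
selected bandwidth is stable well below that size.

## Blind deconvolution of the read spread function

The weighted 2D density of self-ligation pair coordinates is modeled as

    Pr(r=⟨x,y⟩|self) = Σᵤ Pr(q=u) · RSF(⟨x−u, y−u⟩),

i.e. a 1D occupancy distribution placed on the plane's diagonal, convolved
with the **read spread function** — the distribution of mate offsets
around an occupied location induced by fragmentation. Both factors are
recovered by alternating multiplicative Richardson–Lucy updates (the
standard blind-RL scheme: the occupancy update correlates the data/model
ratio with the RSF; the RSF update correlates it with the occupancy).

Implementation notes, in decreasing order of consequence:

- **Banded representation.** Data and model live within |y−x| ≤ 2W of the
  diagonal (W = RSF half-width, default 2,000 bp, grid step 10 bp). All 2D
  objects are stored as (span δ, position x) bands; for fixed δ the forward
  model is an ordinary 1D convolution, so one batched FFT convolution per
  update covers the whole band. Span rows carrying no data mass are dropped
  from the updates (exact: they cannot hold RSF mass at the optimum).
- **Sensitivity normalization.** Each correlation is divided by the
  kernel mass that falls inside the observed band (the flat-field term of
  standard RL). Without it, window boundaries bias the estimates and the
  noiseless fixed point (data = exact forward convolution) is only
  approximate; with it, the fixed point is exact to machine precision.
- **Conservation.** Every update clips at zero and renormalizes to the
  input sum, so non-negativity and total mass are preserved exactly at
  every iterate, including at window boundaries.
- **Initialization.** The occupancy starts uniform. The RSF starts with a
  mild Gaussian taper centered on the anti-diagonal (offset −δ/2 within
  each span row) rather than uniform: blind deconvolution has an exact
  diagonal-shift ambiguity (RSF shifted along the diagonal ⇔ occupancy
  shifted oppositely), and a perfectly flat RSF start is a *degenerate
  fixed point* of the multiplicative updates — the update multiplier is
  exactly flat along each span row, so nothing ever concentrates. The
  taper breaks the tie toward the symmetric solution. It is uniform across
  span rows, so it does not bias the recovered peak span and hence not λ.
- **Gauge fixing.** After convergence the remaining shift freedom is
  resolved by translating the RSF so its peak lies on the anti-diagonal,
  with the compensating translation applied to the occupancy — a pure
  re-parameterization that leaves the forward model unchanged.
- **Schedule.** Default: 10 occupancy updates, then 10 RSF updates, for 5
  rounds or until the combined L1 change per round falls below 1e-6;
  non-convergence returns the current state with a warning. λ stabilizes
  within the first round or two; the later rounds sharpen shapes.
- The mirrored-occupancy variant of the RSF update that appears in some
  transcriptions of the blind-RL scheme is not used; the implementation
  follows the standard correlation form, which is the one with the exact
  noiseless fixed point.

The RSF peak ⟨−λ, λ⟩ is read off the maximal cell, projected onto the
anti-diagonal (λ = (dy−dx)/2), ties broken toward smaller λ. λ is the
identifiable quantity of the blind problem (invariant under the shift
ambiguity) and equals half the modal fragment length, because a
self-ligation pair's span *is* its fragment length.

## Fast genome-wide occupancy

Estimated RSFs are unimodal and sharply peaked, so the RSF is approximated
by its peak for genome-wide work: Pr(q=u) ∝ Pr(r=⟨u−λ, u+λ⟩|self). For the
isotropic Gaussian kernel this diagonal slice collapses algebraically to a
1D weighted KDE over pair midpoints with a per-pair factor
exp(−(λ−half-span)²/h²) — evaluated exactly, per 10 bp bin, genome-wide.
Bins farther than 4 bandwidths from every weighted midpoint are exactly
zero (Gaussian tails below ~1e-7 of the peak; configurable). Full blind
deconvolution runs only on a training window (default 5 Mb, chosen as the
window with the most self-ligation weight).

The fast track retains the kernel and fragmentation width that exact RL
deconvolves away: the two agree on *where* occupancy sits and how much,
not on peak sharpness. The test suite therefore compares them on 100 bp
mass aggregates — the estimator's positional-uncertainty scale — where
their correlation exceeds 0.9 on a 1 Mb simulation; at the raw 10 bp grid
the correlation is dominated by spike-vs-bump shape mismatch and is not a
meaningful accuracy measure.

## Anchored joint occupancy

Inter-ligation pairs are treated as independent noisy samples of jointly
occupied location pairs ⟨u, v⟩, with the lower-coordinate mate informing u.
The likelihood of a mate given occupancy at u is the strand-appropriate 1D
marginal of the RSF at offset (mate − u): minus-strand mates marginalize
over dy, plus-strand mates over dx. Marginal values below 1e-9 of their
maximum are treated as exactly zero — multiplicative RL drives unsupported
offsets to underflow-scale positives, and those must not count as read
support. The read-alignment prior is uniform. For pairs used in this step,
every non-`-+` pair qualifies, plus `-+` pairs with self-posterior below
1/2; the binomial sample size N_inter stays the expected count
N − Σw (it is a property of the library, not of the hard assignment).

Each pair contributes end-likelihood × occupancy on both sides, and one
global constant — the sum over *all* pairs of their full-support products —
normalizes everything. Windowed joint densities and per-anchor conditional
profiles therefore share a scale: the conditional profile at anchor v is
exactly the joint-density column through v. Anchors are points; a pair
supports an anchor iff the strand-appropriate marginal is nonzero at the
offset, so resolution comes entirely from the RSF. Anchors in
zero-occupancy bins are retained but flagged (the model forces their
density to zero). Per anchor the profile mass tᵢ and the marginal
occupancy mᵢ (the anchor bin's track value) feed the significance step,
along with an index of which pairs support which bins.

## Significance with missing-mass correction

The basic score is Pr(Y > Z) for independent binomials over N draws:
Y under the uniform background (w/M for marginal regions, the product of
marginal masses for joint regions) and Z under the estimate. It is exact —
a pmf/cdf convolution — up to 10,000 trials, and a normal approximation
with continuity correction beyond (the absolute error of the switch is
below ~1e-3, far from the 0.05 decision boundary at the scales involved).

Sequencing undersamples the joint space, so each anchor's conditional mass
tᵢ is assumed to miss an amount τᵢ, pinned at the heaviest anchor
(τ_imax = (c−1)·t_imax) and elsewhere solved cyclically from

    τᵢ = mᵢ · Σ_{j≠i}(tⱼ+τⱼ) / Σ_{j≠i}mⱼ − tᵢ,  floored at 0,

whose fixed point satisfies (tᵢ+τᵢ)/Σ(tⱼ+τⱼ) = mᵢ/Σmⱼ on every free
coordinate (provably; and on all coordinates when no floor binds). The
`− tᵢ` term is required for that identity to hold and the implementation
includes it. A region's corrected rate is p = (region mass)/(tᵢ+τᵢ),
compared against p′ = its marginal occupancy mass.

Two guards shape the corrected test:

- When p ≤ p′ the reported value is max(score, 0.5): Pr(Y > Z) is small
  whenever both rates are far below 1/N simply because Y is almost surely
  zero, which would let zero-evidence regions through at any correction
  strength. No enrichment, no call.
- Candidate regions are maximal runs of bins with conditional density
  above f (default 0: any positive mass), each carrying its support count —
  the number of distinct pairs whose end likelihood is nonzero somewhere in
  the region.

The scale c is searched (multiplicative bracketing then bisection on
log c, range [1.01, 1e4], ≤ 30 evaluations) so that the fraction of
significant regions supported by a single pair lands in
[target − 0.05, target] (target 0.1). If the fraction jumps across the band
— common when singletons die en masse at some c — the search returns the
conservative side: the smallest c whose singleton fraction does not exceed
the target. Within each significant region the reported interaction point
`eloc` is the midpoint of the maximal-density bin (leftmost on ties). Raw
p-values are used at a 0.05 cutoff by default; Benjamini–Hochberg
adjustment is available behind a flag. RPKM and a read-count enrichment
version of Pr(Y > Z) are provided as utilities for companion ChIP-seq
tracks.

## Synthetic data

The generator emulates the data-generating process the model assumes: an
occupied location u is drawn from a weighted site list; a fragment length
L from a clipped normal (default mean 300 bp, sd 30 bp — sonication
libraries center near 300 bp); a breakpoint fraction β ~ Uniform(0.3, 0.7)
places the minus mate at u − Lβ and the plus mate at u + L(1−β). The span
thus equals L exactly and the implied RSF is a ridge (not a line-delta)
peaking at ⟨−L/2, L/2⟩. Loop pairs draw both endpoints from a planted loop
and fragment each end independently with uniformly random strands;
noise pairs are uniform over the genome, which also supplies short-span
`-+` noise — the mixture model's hard case. Everything derives from one
seed; emission is byte-deterministic and round-trips through the BEDPE
parser losslessly.

The default test scenario: two 1 Mb chromosomes, 25 anchors (TSS-like), 20
of them in loops to distal sites 5–300 kb away, 20,000 self pairs, 12,500
loop pairs, 12,500 noise pairs (half the inter-ligation pairs are noise).
Test runs use an 800 bp RSF grid, a 150 kb training window and a
3-round × 8-update RL schedule — sized to the scenario's 300 bp fragments
and 2 Mb genome.

What passing these tests shows: the estimators recover the quantities the
model is built around (λ, the inter fraction, site positions, planted
loops at ≤ 50 bp eloc error) under the model's own generative assumptions,
and the calibrated test controls false positives on pure ligation noise.
What they do not show: robustness to mappability bias, PCR duplication
structure, chromatin-state-dependent fragmentation, non-uniform read
priors, or anchor sets that are wrong — none of which the simulator
emulates. The uniform read prior and the independence approximation in the
joint model are the places real data will deviate first.

## Defaults at a glance

| Parameter | Default | Meaning |
|---|---|---|
| distance cap | 50 kb | spans above are inter-ligation outright |
| bandwidth grid | 30 log-spaced, 10–10,000 bp | LSCV candidates |
| LSCV subsample | 1,000 | points used for bandwidth selection |
| RSF half-width W | 2,000 bp | offset grid extent |
| grid step / bin size | 10 bp | all tracks and grids |
| training window | 5 Mb | max-weight window for blind RL |
| RL schedule | 10 occ + 10 RSF × 5 rounds, tol 1e-6 | alternation |
| truncation | 4 bandwidths | exact-zero radius for KDE tracks |
| f | 0 | candidate-region density threshold (> f) |
| p cutoff | 0.05 | significance threshold (raw p-values) |
| target single-pair fraction | 0.1 (band −0.05) | c calibration target |
| c range | [1.01, 1e4] | missing-mass scale search |
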