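# Methods

## Duplex model and conventions

Every duplex (imager–barcode, quencher–imager, off-target hybrid) is
treated as two-state: fully formed or fully dissociated, with formation
enthalpy ΔH < 0 (kcal/mol) and entropy ΔS < 0 (cal/(mol·K)). Partial
zipping, ensemble secondary structure, mismatch and dangling-end
corrections are all out of scope; the two-state picture is what makes
the design plane parameterizable by the two domain melting temperatures
alone.

Sequence-derived parameters come from the unified nearest-neighbor table
(ten stack entries, terminal initiation per A·T or G·C end, −1.4
cal/(mol·K) symmetry term for self-complementary sequences) with the
entropic monovalent-salt correction ΔS += 0.368·(N−1)·ln[Na⁺]. The
default salt is 195 mM — a PBS/SSC-scale working buffer — and the
reference strand concentration is 250 nM, the standard thermal-probe
working concentration.

Binding uses the **free-ligand convention**: the imager (or quencher) is
in large excess over its in-situ target, so the occupancy of target
sites is θ = cK/(1+cK) and Tm = ΔH/(ΔS + R ln c) with no factor-of-4
correction. R = 1.987 cal/(mol·K); all interfaces take °C, internals use
K.

## Default domain enthalpies

When a domain is specified only by its melting temperature, ΔS is
back-derived from a default enthalpy, which then sets the *steepness* of
the melting transition (transition width scales as RT²/|ΔH|). The
defaults are **ΔH = −180 kcal/mol for the barcode domain and −150
kcal/mol for the quencher domain**, i.e. roughly 23-nt and 19-nt
duplexes at the NN table's ≈ −8 kcal/mol per stack.

These values are pinned by the published design itself, not fitted to
any dataset: five channels at 39/48/57/65/72 °C (gaps of 9/9/8/7 °C)
with pairwise overlap ≤ 0.12 and yield ≥ 0.8 require spectra whose FWHM
is ≲ 9 °C, which shallow-enthalpy duplexes (e.g. −75/−95 kcal/mol,
~12 °C FWHM) cannot deliver at any grid cell. The chosen defaults
simultaneously reproduce the worked example (quencher Tm 53 °C, barcode
Tm 61 °C → T_s = 57.2 °C, inside the quoted "approximately 57 °C") and
make the five-channel panel feasible. Both enthalpies are configurable
per probe and per scan.

The quencher strand is mixed at a 1.2:1 excess over the imager; this is
modeled through the quencher-domain working concentration. A Tm given
for the quencher domain is interpreted at that working concentration, so
stated melting temperatures are the operative ones. Contact-quenching
efficiency is treated as 1.0 and residual background is not modeled.

## Spectrum and sequential-protocol semantics

The spectrum signal(T) = θ_b(T)·(1−θ_q(T)) is evaluated on a 20–80 °C
grid at 0.1 °C (design scans use a 1 °C grid of (T_mb, T_mq) cells, each
cell's spectrum still at 0.1 °C). T_s is the grid argmax; yield the
maximum; width the FWHM with linearly interpolated half-maximum
crossings (clamped at grid edges). The independent-duplex approximation
(product form) neglects the second-order coupling between barcode and
quencher equilibria; the domains are designed non-overlapping.

Dissociated strands diffuse away and do not rebind at imaging
concentrations, so the fluorescence imaged at ~30 °C after a spike
equals the equilibrium signal at the spike temperature, and spike
sequences must be increasing. `protocol_signal_matrix` implements
exactly this semantics and refuses non-monotone spike lists.

## Crosstalk metric and channel selection

The default crosstalk between channels i and j is
max(s_i(T_s,j)/yield_i, s_j(T_s,i)/yield_j): imaging happens only at the
spike temperatures, so point evaluation there is operationally exact for
the sequential protocol. A Jaccard integral overlap of peak-normalized
spectra is available behind a switch for sensitivity analyses.

Two selection modes exist:

- `select_channels` — greedy floor-up: sweep candidate cells by
  increasing T_s, admit a cell when yield ≥ 0.8 and overlap with every
  admitted channel ≤ 0.12, between the 37 °C wash floor and 75 °C
  ceiling (ties: higher yield, then smaller width, then lower T_mb). On
  the default grid this returns six channels at
  37.6/44.1/50.7/57.1/64.1/71.6 °C. Because modeled spectral width grows
  with temperature (∝ T²), greedy spacing widens with T; the printed
  five-channel set's decreasing spacing is covered within 3 °C but not
  reproduced cell-for-cell.
- `panel_at_signal_temps` — anchored: one channel per requested signal
  temperature (ascending), choosing the *narrowest* cell within 1 °C of
  the target that clears yield and stays compatible with the channels
  already admitted (ties: higher yield, then lower T_mb). Narrow cells
  are the high-yield diagonal of the design plane; selecting by raw
  yield instead would admit wide plateau cells (e.g. T_mb 79/T_mq 35)
  whose overlap with every other channel approaches 1. At the printed
  temperatures this yields cells (41,35), (50,44), (59,53), (67,61),
  (75,68) with max overlap 0.085 and min yield 0.807.

Panel feasibility is always re-verified post hoc from raw spectra
(`verify_panel`); selection cannot self-certify.

## Sequence design and orthogonality screen

`design_domain` draws uniform random sequences under GC-fraction
(0.3–0.7), homopolymer (≤4) and length constraints, then hill-climbs
single-base substitutions toward the target Tm, returning the first
sequence within tolerance; the attempt and step budgets are bounded and
all randomness is behind the spec's seed, so infeasible targets raise
rather than silently returning a weak sequence. This generator is a
simple, auditable stand-in for ensemble-based designers; its outputs are
validated only through the NN screen.

`orthogonality_screen` scores each non-cognate strand pair by the
NN-predicted Tm of the strongest *perfectly complementary contiguous*
segment over all alignments, checking the partner both as given and
reverse-complemented (which also makes the report invariant to
reverse-complementing any input). No internal loops or bulges are
considered — a deliberately conservative, brute-force-verifiable
criterion. The default pass threshold is the 37 °C wash temperature.
Transcriptome-level specificity screening is out of scope; candidate
sequences export to FASTA for external tools.

## Kinetics

dθ/dt = k_on·c·(1−θ) − k_off(T(t))·θ per duplex, with k_on = 1×10⁶
M⁻¹s⁻¹ (a standard oligo association magnitude, configurable; the
temperature dependence sits entirely in k_off = k_on/K(T) by detailed
balance, so ODE fixed points match the equilibrium model exactly).
Temperature protocols are piecewise linear; the stock spike ramps 5 s to
the setpoint and cools 20 s to the 30 °C imaging temperature.
Integration uses LSODA with rtol 1e−8/atol 1e−9 on a fixed ≥10 Hz output
grid; failures raise with the solver message. Rebinding during imaging
uses the pseudo-first-order closed form 1−exp(−k_on·c·t), capped by the
equilibrium occupancy at the imaging temperature; at the femtomolar to
picomolar free-strand range this stays below 1e−4 over 24 h.

## Image quantification

Maximum Z-projection; global threshold (default mean + 5·SD of the
image, absolute override available — the appropriate k depends on spot
density and background structure); 8-connected components of ≥ 2 px;
punctum intensity is the maximum original pixel over the component;
border-touching puncta are kept. Colocalization is greedy global
nearest-pair matching within a 2 px default radius, each punctum used
once, ties broken by distance then row then column — deterministic and
one-to-one. Per-cell counting assigns each punctum to the mask label
under its rounded centroid, label 0 tallied as background so totals are
conserved. Cell exclusion is per target: cells under 5 copies for
high-expression targets, under 2 for low-expression targets
(configurable); exact-boundary counts are retained. Multi-round images
are assumed pre-aligned (acquired on-scope without moving the sample),
so there is no registration stage anywhere.

## Covariation analysis

Counts are normalized within each cell to fractions of the cell's total
(zero-total cells dropped with a warning), correlations are Pearson
across cells on those fractions (not log-transformed), distance is
1 − r, clustering is agglomerative with average linkage, and the group
count is a parameter of the cut (no automatic selection). Constant
columns make correlation undefined and raise unless explicitly dropped.

## Synthetic data

`simulate_images` renders isotropic Gaussian puncta (σ 1.3 px) at
uniform positions with a minimum separation (8 px default; when the
density budget is exhausted placement falls back unconstrained and the
truth table flags the field as crowded) on a Poisson background (100
counts) with Gaussian read noise (SD 3); amplitude 110 gives peak SNR
≈ 10. Colocalized spots share positions to ≤ 0.5 px jitter. Cell masks
are Voronoi tiles. `simulate_counts` plants correlation blocks via one
latent Gaussian factor per group (within-block latent correlation 0.8,
between-block 0 by default — requiring 0 ≤ between ≤ within ≤ 1 for a
valid covariance) pushed through a negative-binomial quantile transform
(mean 30, size 8). Both generators are pure functions of (spec, seed).

What these generators do *not* emulate: Airy PSFs, autofluorescence
structure, optical sectioning, stage drift, segmentation error, or
count-depth artifacts. Passing recovery tests therefore certify the
algorithms against known ground truth under controlled noise, not
robustness to every real-microscopy artifact.

## Problem sizes

Tests and the acceptance script run the design scan at the full 41×41
grid (0.1 °C spectra), detection/colocalization on 512×512 fields with
150–200 spots, and clustering on 200 cells × 15 targets — sizes chosen
to make every recovery check exact while keeping a full run interactive
on a single CPU.

## Known limitations

- The two-state, fixed-enthalpy design plane ignores sequence-specific
  steepness; real panels should re-score selected cells from actual
  sequences (`ThermalProbeSet.from_sequences`).
- The spike-evaluation crosstalk metric is tied to the sequential
  protocol; for steady-state multiplexing an integral metric is more
  appropriate.
- The orthogonality screen bounds only contiguous perfect hybrids;
  bulged or coaxially stacked off-targets are not scored.
- Threshold-based detection has no subpixel localization; centroid
  accuracy is ~0.2 px on clean synthetic data but degrades with
  overlapping spots.
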