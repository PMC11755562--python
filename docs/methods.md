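# Methods

## The assay being modelled

The peptide inhibitor assay (PIA) probes a protein chain for functionally
important, accessible sites by incubating the enzyme with a large molar
excess (standard condition ×500) of short synthetic peptides taken from the
enzyme's own sequence and measuring residual activity. For the EcoRI model
system, activity is the digestion of a plasmid substrate, quantified as the
fluorescence of the excised product band on a gel; reactions are run under
deliberately sub-optimal Mg²⁺ so the control needs about three hours to
reach saturation, and each batch carries a "no peptide" (DMSO-only)
control. A peptide's score is its *relative fluorescence intensity*: the
product-band fluorescence at the 3 h reference time divided by the
simultaneous control's mean.

## Chain reconstruction

The EcoRI chain (M1–K277) is not shipped as a database record; it is
reconstructed by stitching the 25 overlapping original blocking peptides.
Stitching places each peptide at its stated start position, requires exact
letter agreement on every overlap, and fails loudly on conflicts or
coverage gaps; the initiator M, which the peptide tiling starts after, is
supplied as a known prefix. One printed interval (BP22) is 10 wide for a
14-mer; the sequence is treated as authoritative, the start is kept, and
the extension is proven by the overlap with the following peptide. The
packaged FASTA is labelled a reconstruction.

The printed tables carry a handful of further coordinate typos and, in the
staggered table, a four-row block whose molecular weight / pI / GRAVY
values are printed one row out of register (each row shows the next row's
true values, cyclically). All such cells were identified by recomputation
from the sequences and are versioned in `src/piakit/data/anomalies.tsv`;
golden-table comparisons skip exactly those cells and nothing else.

## Panel design rules

* **Original windows** read the chain substring at curated
  secondary-structure windows (6–14 residues in the published panel).
* **Staggered junction peptides** centre on the midpoint
  c = (e_i + s_{i+1})/2 of consecutive windows i, i+1; a length-L window
  starts at round_half_up(c − (L−1)/2), so an even-length window about an
  integer centre takes the C-terminal-shifted choice. Per-junction lengths
  (10–12) come from the published table. The rule regenerates all 22
  published junction sequences, and the printed interval for every row
  outside the known-typo list — notably it uses the *printed* original
  windows (including BP22's wrong end), which is demonstrably what the
  published design did.
* **Short N/M/C fragments** of a parent of length L are residues 1..k,
  o+1..o+k with o = ⌊(L−k)/2⌋, and L−k+1..L (k = 6). Four published
  fragments deviate from this rule (BP12N, BP12M, BP22M, BP22C) and are
  supplied through an explicit override list, each use logged. The BP12
  trio is consistent with applying the rule to parent residues 2–13; the
  BP22 shifts look like design against its mis-printed 10-wide interval.
* **Deletion splits** produce the first `sub_len` residues and a C-side
  window overlapping them by `overlap` residues (the published pair uses
  6 and 2).
* **Randomized controls** are seeded Fisher–Yates shuffles, so composition
  is preserved exactly; derangement is not enforced. The published
  randomized sequences came from manual card drawing and are therefore
  shipped verbatim rather than regenerated; `randomize()` covers new
  designs.

## Descriptors

Computation keeps full precision; reporting mirrors the published tables
(MW/pI/aliphatic index/instability/net charge to 2 dp, GRAVY to 3 dp,
hydrophilic % to the nearest integer), rounding ties away from zero.

* **Molecular weight**: Expasy average residue masses plus one water
  (18.0153 Da). The commonly redistributed biopython mass table differs in
  the last digits and misses the printed 2-dp values at peptide scale,
  which is why the table is fixed here explicitly. Sums are taken over
  residue counts, making the value exactly permutation-invariant in
  floating point.
* **pI**: bisection on pH ∈ [0, 14] of the Henderson–Hasselbalch net
  charge over the Bjellqvist pKa set, with the N-terminal pKa depending on
  the first residue (A 7.59, M 7.0, S 6.93, P 8.36, T 6.82, V 7.44, E 7.7,
  else 7.5) and the C-terminal pKa fixed at 3.55. The first-residue
  dependence is real and visible in the published data: shuffles of the
  same composition print different pIs that track the new first residue.
  C-terminal-residue-dependent pKas (as biopython applies) are ruled out
  by the printed values. The solver bisects to an interval width of 1e-6 —
  a charge-tolerance stop can misplace the root by a printed least count
  where the titration curve is flat. Peptides with no ionizable side chain
  have their root exactly midway between the terminal pKas, which can land
  exactly on a 2-dp rounding boundary (e.g. (7.5+3.55)/2 = 5.525); the
  root is therefore snapped to 4 dp and ties round half-even, which
  matches the reference tool's printed behaviour in both directions.
* **GRAVY**: mean Kyte–Doolittle hydropathy.
* **Aliphatic index**: X(A) + 2.9·X(V) + 3.9·(X(I)+X(L)) on mole percent.
* **Instability index**: (10/L)·Σ DIWV over adjacent pairs, using the
  Guruprasad table with one calibrated correction — the reference web tool
  uses 24.68 for K→Q where the redistributed table has 24.64, detected via
  the only two panel rows containing "KQ", both off by exactly one printed
  least count otherwise.
* **Aromatic count** over {F, H, W, Y}; **hydrophilic percentage** over
  {D, E, K, R, N, Q, S}. The published aromatic column was counted by hand
  and five cells are demonstrably miscounted; they sit on the anomaly
  whitelist while the definition itself is implemented as stated.
* **Net charge at pH 7** (default "bachem" model): +1 per K/R and the free
  N-terminus, −1 per D/E and the free C-terminus, +0.09 per His, −0.05 per
  Cys, 0 for Tyr. The His/Cys increments were calibrated once against the
  printed column, which they reproduce in full. A fully pKa-based charge
  at pH 7 is available behind `model="pka"` for comparison but is not the
  table-matching default.

## Assay simulator

The generator encodes the qualitatively reported kinetics with the simplest
adequate model: single-exponential approach to saturation,
F(t) = f_max·plateau_shift·(1 − e^(−k_eff t)), with competitive-style rate
scaling k_eff = k0/(1 + dose/d50). Defaults are the study conditions:
k0 = 1.0 h⁻¹ (control ≥ 95% saturated at the 3 h reference time), hourly
sampling 0–5 h, three replicates, dose ladder {5, 50, 150, 500} molar
equivalents with ×500 the standard single-dose condition, plateau_shift = 1
(inhibitors delay the rate without changing the saturation level), and 5%
multiplicative Gaussian noise clamped at zero — band densitometry noise
scales with signal. A `no_band` flag reproduces the one observed
nuclease-induction phenotype (no measurable product band at all); the
mechanism behind it is not modelled. What the simulator does *not* emulate:
explicit Michaelis–Menten enzymology, Mg²⁺ dependence, DNA-binding
kinetics, gel imaging artefacts, or between-batch drift — so passing tests
demonstrate the pipeline's statistical behaviour, not fidelity to any
particular wet-lab data set (whose raw values are published only as
figures).

## Statistics

Relative intensity uses the per-replicate-then-average convention: each
replicate is divided by its batch's control mean at the reference time (the
control's own mean is exactly 1 by construction, and the whole analysis is
invariant to rescaling all raw fluorescences). Dunnett's many-to-one
comparison is implemented as a seeded Monte Carlo evaluation of the
max-|t| null with the shared-control correlation structure: group means
z_i ~ N(0, 1/n_i), pooled variance s² ~ χ²(df)/df, and
T_i = (z_i − z_0)/(s·√(1/n_i + 1/n_0)); an observed statistic's adjusted p
is the null tail fraction of max_i |T_i| (default 10⁵ draws), clipped from
below by the raw two-sample p. The standard independent-groups form is
used; a repeated-measures variant was considered and rejected because the
replicates are independent reactions. scipy's multivariate-t-integration
implementation of the same test serves as an independent cross-check in
the test suite, never as the implementation. Correctness is verified three
ways: the k = 1 case collapses to the two-sample t-test, adjusted p-values
agree with scipy's to Monte Carlo precision, and the family-wise error
rate over 10⁴ simulated five-group null experiments (n = 3) is nominal.

Ranking sorts ascending by relative intensity (rank 1 = most inhibitory;
ties break lexicographically by peptide id) and flags means strictly below
0.3 as the "most inhibitory" set. Descriptor correlations are plain Pearson
r with the two-sided t-transform p, computed after dropping an exclusion
list (the analysis convention excludes the nuclease-inducing peptide and
its deletion fragments); no multiple-testing correction is applied across
descriptors, matching the analysis being reproduced. Significance stars:
`*` adjusted p < 0.05, `**` < 0.01.

## Problem sizes and determinism

Golden-table checks cover all 85 peptides and 745 non-whitelisted cells and
run in seconds. Monte Carlo sizes are 10⁵–10⁶ draws for Dunnett nulls, 10⁴
experiments for the family-wise calibration, and 100 shuffles per parent
for composition-invariance checks. Every stochastic component (shuffles,
simulated noise, Monte Carlo nulls) is driven by an explicit integer seed
and is bit-reproducible; CLI outputs carry a provenance header with the
tool version, seed and a config hash.

## Known limitations

* The printed-table anomalies are whitelisted, not "fixed": the toolkit
  reports its computed values and documents the disagreement.
* The net-charge His/Cys increments are an empirical reconstruction of the
  reference calculator's unpublished pKa basis.
* The kinetic model is the minimal one consistent with the reported
  qualitative behaviour; d50 values are free parameters of the simulation,
  not estimates of any real peptide's potency.
* pI is *not* a pure composition descriptor under the implemented (and
  evidently correct) model — it also depends on the first residue. Shuffle
  invariance therefore holds for pI only within an N-terminal pKa class.
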