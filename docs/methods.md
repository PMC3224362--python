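# Methods

## Encoding model

A chain's Cα trace is cut into overlapping four-residue windows; windows
never span a chain break, and a break is declared wherever a consecutive
Cα–Cα distance leaves [2.5, 4.5] Å (distance, not author numbering, governs:
crystallographic renumbering without a physical gap is not a break). Each
window is reduced to (d1, d2, d3, P4); P4 is the signed distance of the
fourth Cα from the plane of the first three, with the sign taken along
(Cα2−Cα1) × (Cα3−Cα2). This convention makes right-handed α-helices project
positively, consistent with the published characterization of the helix
letters as large-P4 conformations. Windows whose first three points are
collinear (triangle area ≤ 1e-6 Å²) have no defined plane; they receive no
letter and split the decoding into independent runs.

Decoding is exact Viterbi in log space under Gaussian emissions (diagonal or
full covariance accepted from a model file) and the model's transition and
initial probabilities; ties break toward the earlier letter in canonical
order A..Z,a so decoding is deterministic. A letter is attributed to the
third residue of its window (residue r carries the letter of fragment
r−2 → r+1), so residues 1, 2 and n of an unbroken n-residue segment carry
none and the letter string has length n−3.

### The default alphabet model is synthetic

The fitted 27-letter alphabet (emission means/covariances and transition
matrix estimated from a structure corpus) is not redistributable here, so
the default model is a prototype library constructed in code: the regular-
structure letters take their descriptor means from parametric helix/strand
geometry (canonical α-helix radius 2.3 Å, rise 1.5 Å/residue, twist
100°/residue; pleated strands with 3.8 Å steps; constant-curvature arc bends
for the curved variants), and the loop/border letters are frozen literals
consistent with the published qualitative ordering (surface loops: long d1,
short d3, low or negative P4; core loops: short d1, positive P4, split into
long- and short-d3 subgroups; borders intermediate). Emission variance is a
shared isotropic 0.5 Å² and transitions are uniform, under which Viterbi
provably reduces to per-window nearest-prototype assignment — the minimal
faithful encoder. Consequences:

* encodings are structurally sensible (straight helices → runs of `A`,
  bent helices → curved letters `a`/`V`, straight strands → `T`/`M`, bent
  strands → `N`) but are **not** letter-exact against published encodings;
* the PCA of the synthetic descriptor table reproduces the qualitative
  structure of the published one (a dominant axis separating extended from
  compact conformations, driven by d2 against P4) but not its printed
  variance percentages exactly;
* supplying a fitted model file restores full fidelity; the JSON schema is
  validated on load (row-stochasticity to 1e-6, positive-definite
  covariances, letter/class consistency).

## Accessibility and compartments

Solvent-accessible areas use the Shrake–Rupley construction with a
deterministic golden-spiral lattice (default 960 points/atom — the
isolated-sphere and two-sphere-cap closed forms are matched well inside
1%/2% at that density, and doubling the density moves areas by <0.5%),
probe 1.4 Å, and NACCESS-style element radii (C 1.87, N 1.65, O 1.40,
S 1.85 Å). Relative accessibility divides a residue's summed atom area by
its area in an extended ALA-X-ALA tripeptide built internally: an idealized
extended backbone (φ = −139°, ψ = +135°, ω = 180°, standard bond geometry)
dressed with idealized residue templates from the chemical component
dictionary bundled with biotite. Values above 100% (possible for terminal
or distorted residues) are capped and flagged.

Compartments follow the accessibility-change definition with A_chain,
A_interf, A_complex computed from three SASA runs. The published rule states
an exact "= 0%" change for surface and core; exact zero is ill-defined in
floating point, so "unchanged" means |A_chain − A_complex| ≤ 0.05 points
(the print precision of classical accessibility output). Burial (5%) and
interface change (1 point) thresholds are strict inequalities on both sides
— a residue at exactly 5% is *undefined* — and all thresholds are surfaced
in `PipelineConfig` rather than hard-coded. Hetero residues and waters are
excluded from every SASA context by default (flag to include). Cα-only
structures (the synthetic generators) use one pseudo-sphere of 3.0 Å per
residue with the isolated sphere as reference: compartment logic depends on
accessibility *changes*, not absolute areas, so coarse spheres suffice
there.

## Preference statistics

The contingency table N(sl, cp) excludes undefined residues. KLd(sl) is the
divergence of the letter's compartment distribution from its own class's;
2·N_sl·KLd is referred to χ²(df = 2), the 3-compartment analogue of the
likelihood-ratio G statistic, with the 0.95 bar at 5.99. Calibration is
checked by simulation (null multinomials at N = 500) rather than assumed.

The printed Z-score formula in the source literature is typographically
garbled; we use the standard Poisson-approximation score
(N_obs − N_exp)/√N_exp, consistent with its stated N_exp > 5 validity rule,
with N_exp = (class total in cp1) × f_cp2(sl) and f_cp2 the letter's
relative frequency within its class in cp2. The Bonferroni family defaults
to (letters in the class) × 3 ordered compartment pairs, two-sided; the
published per-class thresholds (2.5/2.6/2.9) are not exactly recoverable
under any standard convention we tried, so sidedness and family size are
configurable and the convention used is reported with each result.

"MCA" of the letters-by-compartments occurrence table is implemented as
simple correspondence analysis (SVD of standardized residuals): the input
described is a two-way contingency table, and simple CA's axis-inertia
percentages match the published reading of axis variabilities. Descriptor
PCA standardizes columns by default (the descriptors mix three distances
with a signed projection of different spread); a raw-covariance mode is
retained.

The preferential-distribution percentage of a class in a compartment is
Σ_sl max(Obs − Exp, 0) / Σ_sl Obs with Exp(sl, cp) = N_total(sl) × (class
total in cp)/(class total overall); the denominator is the class's observed
count *in that compartment* (the source's wording is ambiguous between
compartment-wise and overall observed counts; compartment-wise keeps the
statistic interpretable as "fraction of this compartment's occurrences in
excess").

## Deformation

Bound/unbound chains are paired by global amino-acid alignment (+1/−1/−2);
only aligned identical residues pair — a letter change at a mutated position
could reflect the mutation, not deformation — and aligned-column identity
below 80% aborts (wrong pairing suspected). The compartment of a transition
is taken from the bound state: the interface exists only there, and unbound
positions inherit it through the pairing. Rows of P with zero deformations
are reported absent, not zero-filled, since P conditions on deformed
letters; in ΔP a row present on only one side uses 0 for the other and is
flagged. Exposure differences D use A_chain (disjoint single chain) in both
states, restricted by default to deformed loop-letters at the bound
interface, and are aggregated by surface-/core-letter transition category
(s/s, s/c, c/s, c/c; letter groups: surface {a,V,L,P,H,Y,D,U,F,B,K}, core
{A,T,M,N,G,R,O,I,S,E,Q,Z,C,J}, non-interface {a,N,D}, interface {F}).
Kabsch superposition enforces a proper rotation via the determinant
correction.

## Synthetic data: what it does and does not emulate

The generators produce Cα-only geometry with exact secondary-structure
control (straight/curved/kinked helices, pleated/twisted/bent strands,
self-avoiding random loops), two-chain complexes whose facing residues
genuinely lose >1 point of accessibility, count tables with planted
compartment preferences, and bound/unbound letter pairs with planted
per-compartment substitution patterns. They are deterministic per seed.

They do **not** emulate: side chains and real packing (no true cores form in
small pseudo-atom complexes, so core-compartment behaviour is exercised
mainly through the rule tests and planted tables), crystallographic noise,
sequence–structure correlation, or realistic loop Ramachandran statistics.
Passing tests therefore demonstrate the correctness and calibration of the
machinery — encoding, compartment rules, statistics, recovery of planted
signal at realistic rates (deformation rate 0.38 at interface vs a low
surface background, matching the scale reported for real complexes) — not
the biological conclusions on real datasets, which require the curated
complex collections that are out of scope here.

## Problem sizes

Default test/acceptance sizes: 10,000 null replicates at N_sl = 500 for KLd
calibration; 100 simulations at N = 2000 per letter for preference power; 50
simulations at 2000 interface + 2000 surface positions for deformation
recovery; 100 toy models (≤5 states, ≤6 windows) for Viterbi-vs-enumeration;
960 sphere points for SASA. These run in seconds to tens of seconds on one
CPU and give binomial error bars comfortably inside the asserted bands.

## Known limitations

* The default alphabet is a stand-in; letter-exact published encodings need
  the fitted model file (JSON schema documented in `sashape.model`).
* SASA is protein-only by default and makes no polar/apolar split; no
  byte-level NACCESS compatibility is attempted.
* mmCIF, assemblies/symmetry expansion and hydrogens are out of scope; NMR
  multi-model files use one selected model.
* Loop generation is a self-avoiding random walk with step/angle sanity
  checks, not a Ramachandran-accurate ensemble.
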