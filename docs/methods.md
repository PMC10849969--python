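# Methods

This note documents the models and numerical choices behind `revmet`, what
the synthetic-data generator does and does not emulate, and the known
limitations. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Mass calculus

Molecular formulas are integer element-count vectors over a bundled table
of IUPAC/CIAAW monoisotopic masses and isotope abundances (C, H, N, O, P,
S, Na, Cl). Condensation products are formula arithmetic only:
`product = left + right − loss`, with loss defaulting to one water per bond
formed. Monoisotopic mass is the count-weighted sum of most-abundant-isotope
masses; additivity and condensation mass conservation hold to 1e−9 Da by
construction and are asserted over all 2,430 bundled-scheme products.

Adduct m/z is `(M + shift)/|z|` with the *proton* mass (1.00727646 Da)
rather than the hydrogen-atom mass for `[M+H]⁺`/`[M−H]⁻`, so the electron
gained or lost by the ion is accounted for; `[M+Na]⁺`/`[M+Cl]⁻` subtract or
add one electron mass explicitly. Multiple-M aggregates are not supported.
The ppm-window test is inclusive (|ppm| ≤ threshold) so boundary behavior
is deterministic.

Isotope envelopes are aggregated by integer neutron shift (A, A+1, …): the
per-element shift distributions are convolved by exponentiation-by-squaring
and the result is truncated and base-peak-normalized. Peak positions use
the ¹³C–¹²C spacing (1.003355 Da), which is adequate for the CHNOS(±Na,Cl)
compounds handled here; fine isotope structure is deliberately out of
scope, matching unit-resolution idotp scoring as used by Skyline-style
workflows. The implementation is verified against a brute-force
isotopologue enumeration on formulas up to ~70 atoms.

Regio- and stereochemistry are ignored: one (rule, left, right) triple is
one record. Distinct block pairs with identical product formulas (Ile/Leu
conjugates; the tri- and dihydroxylated bile-core families) are kept as
separate records linked by a `mass_degenerate_group` label, since MS/MS
cannot distinguish them; analyses that need unambiguous identities should
either collapse on that label or restrict to formula-distinct sub-libraries
(the test suite does the latter for ledger-exact comparisons).

### Building-block fixtures

The bundled tables (46 fatty acyls, 32 amines, 17 hydroxy acids, 8 bile
acids, 22 amino acids) are synthetic fixtures: plausible reagent sets with
correct class formula arithmetic (fatty acids CnH(2n−2d)O₂, hydroxy acids
with one extra oxygen, tri-/dihydroxylated C24 bile cores, proteinogenic
plus Cit/Orn/DOPA amino acids with glycine handled separately). Only the
table sizes and the arithmetic are load-bearing; users substitute their own
reagent tables for real campaigns.

## Spectra and reference-scan selection

Spectra are centroided peak lists kept sorted in m/z (exact duplicate m/z
merged by intensity sum; out-of-order input is re-sorted and flagged). MGF
I/O goes through pyteomics with a light structural pre-scan so malformed
`BEGIN IONS`/`END IONS` blocks fail with a line number. The mzML support is
an intentionally minimal dialect — uncompressed or zlib, little-endian
64/32-bit float arrays, MS1/MS2 with selected-ion records — with an
explicit unsupported-dialect error rather than silent skipping; a paired
fixture writer provides round-trip tests.

Reference-scan selection follows the chooser rule: among MS2 candidates
whose precursor m/z lies within ±10 ppm of the computed adduct m/z, take
the one with the most abundant precursor ion. Ties break on smaller
absolute ppm error, then smaller scan number (deterministic, since the rule
itself does not specify a tie policy). A passing candidate without a
recorded precursor intensity is an error by default; an opt-in degraded
mode ranks by summed fragment intensity instead (used by the CLI for
MGF-only inputs, where precursor intensity is often absent).

Normalization modes: `base_peak` (max 1), `l2` (unit Euclidean norm), and
`sqrt_l2` (square root, then unit norm — the cosine-scoring transform).
`base_peak` and `l2` are idempotent projections; `sqrt_l2` is not (two
applications compose to a fourth-root transform), so its pinned invariant
is that the output is a unit vector, i.e. a fixed point of `l2`.

## Matching

Peak pairing is greedy by descending intensity product among candidate
pairs with |Δm/z| ≤ tolerance, each peak used at most once, ties broken
toward lower query then target m/z. Greedy was chosen over optimal
assignment for repository-scale cost and determinism; on 500+ random
instances with ≤ 8 peaks per side it coincides with the Hungarian
maximum-weight assignment (asserted), and no discrepancy has been observed
on larger random instances, though adversarial weight configurations could
in principle produce one.

The cosine score divides the paired dot product of √-scaled intensities by
the full-spectrum norms, so unmatched peaks penalize the score; it is
symmetric, scale-invariant, bounded in [0, 1], and cross-checked against
matchms' `CosineGreedy` (fed √-scaled intensities) to 1e−9. Plain cosine,
not precursor-shift-aware "modified cosine", because the search targets
identical compounds rather than analogs.

Repository search filters corpus spectra by absolute precursor difference
(0.01 Da Orbitrap / 0.02 Da Q-ToF defaults) using a sorted-precursor binary
search, then applies cosine ≥ 0.7 and ≥ 6 matched ions. The fragment
tolerance defaults to the instrument-class precursor tolerance (it is a
free parameter; no independent value is prescribed by the criteria).
Matched-ion minimum is inclusive (≥ 6) and cosine inclusive (≥ 0.7);
idotp is strict (> 0.8). The drift-time window interprets "IMS resolving
power 40" as FWHM-based: full window = reference drift / Rp, acceptance
±half-window — e.g. 30 ms reference drift gives ±0.375 ms. A feature
lacking drift time (or an envelope) skips that sub-test with a flag rather
than failing, so partial acquisitions degrade explicitly.

## Association statistics

Presence is defined only from criteria-passing spectral matches — no softer
rule. Matches whose source file is missing from the metadata go to an
orphan report instead of being silently dropped. Phenotype labels are
normalized through a small synonym map ("healthy" → "no disease",
"Crohn's disease" → "CD", …); unmapped labels pass through verbatim.

Jaccard distances are computed on boolean sample columns after dropping
samples that detected nothing (Jaccard is undefined for two empty sets; the
dropped census is returned). PCoA is classical scaling: double-center
−½D², eigendecompose (`scipy.linalg.eigh`), scale eigenvectors by the
square roots of positive eigenvalues; eigenvalues within 1e−12 of zero
(relative to the spectral radius) are treated as null, and negative
eigenvalues are reported with their axes omitted. On Euclidean-embeddable
input the embedding reproduces pairwise distances to 1e−8 (asserted to
machine precision in practice).

Wilcoxon rank-sum tests are two-sided, exact by enumeration for untied
samples up to n = 25 per group and normal-approximation with tie correction
otherwise (`scipy.stats.mannwhitneyu`); all-tied data reports p = 1 with a
tie flag. Benjamini–Hochberg runs per group-pair family across compounds
(CD vs non-IBD separately from UC vs non-IBD), via statsmodels, with the
exact small-sample behavior pinned against a full-enumeration oracle in the
tests.

## Quantification

Response ratios are analyte/internal-standard peak areas; calibration is
unweighted OLS of response on concentration (a 1/x-weighted mode exists but
is off by default, as plain linear fits are the stated procedure).
Quantities convert as
mg/kg = µM · 10⁻⁶ mol/L · M g/mol · V_L · 10³ mg/g ÷ (m_g/1000 kg).
Negative back-calculated concentrations report 0 with a below-LOD flag;
values under the lowest standard are flagged, not censored.

## The simulator: what it emulates, and what it does not

Fragmentation templates model which ions appear, not branching ratios:
precursor, sequential water losses (3 for trihydroxylated bile cores, 2 for
dihydroxylated, 1 for acyl amides/esters), the protonated right-hand
fragment (amine / amino acid / hydroxy acid, ± water) and the acylium ion
of the acyl partner (± water). Relative intensities default to uniform —
an explicit, arbitrary choice, since collision-energy-dependent intensities
are not modeled. Every template yields ≥ 6 fragments so a clean match can
satisfy the ion-count criterion.

Noise: Gaussian m/z jitter (default sd 0.002 Da, comfortably inside the
0.02 Da Q-ToF pairing tolerance), multiplicative log-normal intensity noise
(cv 0.2, mean-preserving), and Bernoulli peak dropout (p 0.05) floored so a
planted spectrum never falls below the 6-peak minimum. Decoys keep a real
library spectrum's precursor, peak count and intensities but redraw each
fragment m/z uniformly below the precursor — the hardest negative class for
the precursor filter. (A pure m/z-to-intensity permutation would leave the
peak *set* unchanged and therefore still match; scrambling positions is
what makes the decoy a genuine negative.)

The default study design is two phenotype groups ("CD", "nonIBD") × 100
sample files, occurrence probability 0.5 for enriched compounds in the case
group against a 0.05 background, five decoys per file, and log-normal
abundances (location 5, scale 1 on the natural-log scale) with a +1
log-unit shift for enriched compounds where planted. Each sample file draws
from its own RNG stream derived from the master seed by CRC32 hashing of
the file name, so per-file output is independent of generation order and
everything is bit-reproducible from (seed, config).

What passing these tests shows — and does not. The simulator demonstrates
that the pipeline recovers planted occurrence and enrichment under its own
noise model. Real repository data differ in ways the simulator does not
attempt: chimeric and contaminant spectra, correlated co-eluting
fragments, instrument-specific intensity response, retention/drift-time
drift, batch effects, and heterogeneous metadata quality. Published
repository-scale tallies (tens of thousands of matches across public
files, cohort-specific abundance contrasts, fecal-sample concentrations)
depend on the live public corpus and clinical samples and are therefore not
reproducible at desk scale; the corresponding machinery is exercised on the
synthetic substrate instead.

## Problem sizes used in the checks

Acceptance-level checks run on a 20-compound formula-distinct bile-amidate
sub-library (2 cores × 10 amino acids): the noise-free criteria check uses
20 files/group with occurrence 0.3; the null type-I check uses 100
simulated cohorts of 30 samples/group (≈ 2,000 tests, normal-approximation
regime); parameter recovery uses the full default design (100 files/group,
10 enriched compounds). These sizes make the whole acceptance run complete
in seconds while keeping the binomial/Monte-Carlo error bands meaningful;
the library-size and mass-oracle checks always cover all 2,430 products.

## Known limitations

- No structure generation (SMILES/InChI), reaction feasibility or yield.
- No modified-cosine analog search or molecular networking.
- mzML support is the minimal dialect described above; vendor formats and
  mzXML are out of scope.
- Wilcoxon exactness switches to the normal approximation above n = 25 per
  group or in the presence of ties.
- Drift-time windows assume the FWHM reading of IMS resolving power; other
  conventions (e.g. CCS-based windows) are not implemented.
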