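# revmet

Desk-scale **reverse metabolomics** for Python: instead of collecting a
sample and asking "what molecules are in it?", start from candidate
structures — combinatorial condensation products such as *N*-acyl amides,
fatty-acid esters and amino-acid-conjugated bile acids ("bile amidates") —
compute their masses, select reference MS/MS spectra, search spectral
corpora for them with repository-style match criteria, and aggregate the
hits against sample metadata to learn where the molecules occur and how
they associate with health phenotypes.

The toolkit is aimed at metabolomics researchers who want the computational
half of that strategy as a reproducible, testable library: virtual library
construction, spectral matching, and phenotype association statistics, plus
a synthetic-repository simulator that serves as ground truth for all of it.

## What it computes

**Virtual combinatorial libraries** (`revmet.chemlib`). A condensation
product is pure formula arithmetic, `product = left + right − H₂O`, with
monoisotopic masses from a bundled IUPAC element table. Adduct m/z uses the
proton mass, e.g. `[M+H]⁺ = M + 1.00727646`. The bundled building-block
fixtures enumerate 46 fatty acyls × 32 amines = 1,472 acyl amides,
46 × 17 hydroxy acids = 782 acyl esters and 8 bile acids × 22 amino acids =
176 bile amidates — 2,430 products in total. Aggregated isotope envelopes
(A, A+1, A+2, …) support isotope-dot-product (idotp) scoring.

**Reference-scan selection** (`revmet.spectra`). MGF I/O (via pyteomics), a
minimal mzML dialect with its own reader and fixture writer, and an
MSMS-Chooser-style rule: among MS2 scans whose precursor falls within
10 ppm of the computed adduct m/z, pick the one with the most abundant
precursor ion.

**Repository search** (`revmet.matching`). Fragment peaks are paired
greedily by descending intensity product within a tolerance; the cosine
score is the dot product of √-scaled, L2-normalized intensity vectors:

```
cos(Q, T) = Σ_(i,j)∈pairs √q_i √t_j / (‖√q‖ ‖√t‖)
```

A hit requires |Δprecursor| ≤ 0.01 Da (Orbitrap) or 0.02 Da (Q-ToF),
cosine ≥ 0.7 and ≥ 6 matched fragment ions. LC–IMS feature matching adds
the multi-attribute rule: ≤ 10 ppm mass error, RT within ±0.1 min, drift
time within ±(reference drift)/(2·40) for IMS resolving power 40, and
idotp > 0.8.

**Association** (`revmet.association`). Presence/absence matrices from
criteria-passing matches, per-phenotype detection proportions, log₁₀ match
counts, binary-Jaccard distances with classical-scaling PCoA, and pairwise
two-sided Wilcoxon rank-sum tests (exact for small untied samples) with
Benjamini–Hochberg adjustment per group pair.

**Quantification** (`revmet.quant`). Internal-standard response ratios,
unweighted linear calibration, and conversion of back-calculated µM
concentrations to mg per kg of sample.

**Simulator** (`revmet.synthetic_data`). Rule-based fragmentation templates
(precursor, sequential water losses, bond-cleavage ions), instrument noise
(m/z jitter, log-normal intensity noise, peak dropout), fragment-scrambled
decoys, phenotype-dependent occurrence probabilities and log-normal
abundance tables — all bit-reproducible from a seed, with an exact ledger
of what was planted where.

## Worked example

```python
import revmet as rm
from revmet import chemlib as cl, synthetic_data as sd

ca  = cl.BuildingBlock("CA",  "bile_acid",  cl.parse_formula("C24H40O5"))
gly = cl.BuildingBlock("Gly", "amino_acid", cl.parse_formula("C2H5NO2"))
rec = cl.condense(ca, gly, cl.CONDENSATION_RULES["bile_amidate"],
                  [cl.ADDUCTS["[M+H]+"]])
print(rec.formula.hill(), rec.monoisotopic_mass, rec.adduct_mzs["[M+H]+"])
```

prints

```
C26H43NO6 465.30903810116996 466.31631456117
```

i.e. glycocholic acid: cholic acid (408.28757 Da) plus glycine
(75.03203 Da) minus water (18.01056 Da) gives a neutral mass of
465.30904 Da, observed as the protonated ion at m/z 466.31631. Its
simulated reference spectrum contains the precursor, three sequential
water losses (448.3058, 430.2952, 412.2846) and the protonated glycine
fragment (76.0393).

The same flow from the shell:

```
revmet build-library --left src/revmet/data/bile_acids.tsv \
    --right src/revmet/data/amino_acids.tsv --rule bile_amidate \
    --adducts "[M+H]+" --out library.tsv
revmet simulate --library library.tsv --out corpus/
revmet search --queries refs.mgf --corpus corpus/ --instrument qtof \
    --out matches.tsv
revmet associate --matches matches.tsv --metadata corpus/metadata.tsv \
    --out proportions.tsv
```

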