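# Methods

## Analyte and mass model

The analyte is the histone H3 N-terminal tail released by an engineered
sortase at the APXTG motif between T32 and G33 and ligated to a GGGH
acceptor peptide whose C-terminal residue carries a TMT 6-plex label. The
search space therefore uses 36-residue surrogate sequences

```
H3.1  ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGGH
H3.3  ARTKQTARKSTGGKAPRKQLATKAARKSAPSTGGGH
```

differing only at position 31 (A/S). Because the cleavage site sits at
T32, K36 marks are outside the analyte and cannot be measured.

All masses are monoisotopic. Residue masses are sums of IUPAC atomic
masses over each residue's elemental composition; the proton is
1.007276 Da and the ¹³C–¹²C spacing 1.003355 Da. The modification
registry reproduces the search settings:

| name | Δm (Da) | targets | class | cap |
|---|---|---|---|---|
| Methyl | +14.015650 | K, R | common | 3 |
| Dimethyl | +28.031300 | K, R | common | 3 |
| Trimethyl | +42.046950 | K | common | 3 |
| Phospho | +79.966331 | S, T | common | 2 |
| Acetyl | +42.010565 | K | common | 5 |
| Propionyl | +56.026215 | K | rare | 1 |
| TMT6plex | +229.162932 | H | fixed | — |
| C-term ligation offset | +76.1001 | protein C-term | fixed | — |

All variable deltas and TMT (with its four ¹³C and one ¹⁵N) are computed
from elemental compositions at run time; the C-terminal offset is an
empirical constant (the mass difference between the genome-encoded
continuation of H3 and the ligated K(2,3-diaminopropionamide) acceptor)
and is stored as configured. A proteoform may carry at most 6 common and
1 rare variable modifications, one per position, each within its own cap.
The registry ships as code defaults and can be loaded from YAML.

## Fragment chemistry

EThcD ladders cover a/b/c/y/z ions with optional NH₃/H₂O neutral losses
(a phospho-specific H₃PO₄ loss is registered but off by default), at
charges 1..min(4, precursor charge − 1). Conventions, as neutral masses:

```
b_i = Σ res(1..i)          a_i = b_i − CO       c_i = b_i + NH3
y_j = Σ res(n−j+1..n) + H2O + C-term offset
z_j = y_j − NH2            (z• radical, ETD standard; plain z = z• − H via flag)
m/z = (neutral − loss + z·proton)/z
```

Modifications localize to the side of the cleavage they sit on; the fixed
C-terminal offset (and the TMT on H36) appears in every y/z ion. The b/y
complementarity identity (neutral b_i + y_(n−i) = precursor neutral mass)
holds to < 1e−9 relative error and is enforced by tests.

## Annotation and isotope confirmation

Each peak is matched, per PSM, to the in-tolerance (default 15 ppm)
fragment minimizing |ppm|; ties break deterministically by lower fragment
index, then series order a<b<c<y<z, then lower charge. A peak may carry at
most one match per PSM, so ladder intensity is never double-counted
within one PSM; a peak consistent with several co-isolated PSMs' ladders
carries one match per PSM.

A match is high-confidence only if a companion peak exists at
m/z + 1.003355/z within the same tolerance with intensity > 0 (presence
only; no ratio requirement). Reporter ions are exempt. Two refinements
keep isotopologue intensity from leaking into abundance:

* a peak that sits at the +1 position of another matched peak of the same
  PSM **and is less intense than that parent** is treated as an isotope
  companion, not an independent fragment, and its own match is discarded.
  At this peptide size the +1 isotopologue is always well below the
  monoisotopic peak, so the intensity condition disambiguates true
  fragments that merely happen to sit near a +1 position. A corollary is
  that widening the ppm tolerance widens the exclusion window too, so the
  count of *retained* matches is monotone only at the matching stage.

## Attribution and abundance

Confirmed matches credit their peak's intensity to their PSM; a peak
whose confirmed matches span k PSMs credits intensity/k to each (equal
split; a proportional-to-unique-evidence split is available behind a
flag). Attribution conserves intensity exactly: summed per-PSM credit
equals summed confirmed matched peak intensity per scan. Proteoform
abundance is the proteoform's pooled attributed intensity divided by the
pooled total, so abundances sum to 1 whenever any intensity was
attributed.

## Reporter quantification

Reporters are the nearest peaks within tolerance of the standard TMT6
reporter m/z values (126.1277…131.1382, editable in the run design);
zero-intensity or absent peaks are missing. Label isotopic impurities are
inverted by non-negative least squares against the design's impurity
matrix (identity default; exact inverse in the noiseless case, negative
exact solutions are clipped at zero with a warning). Channel
normalization multiplies every channel by max_c(S_c)/S_channel where S is
the per-channel mean (or median) over all PSM-bearing scans. Scans enter
condition-level statistics only if every condition has ≥ 2 non-missing
reporters, and only if their PSMs identify a single proteoform — chimeric
scans still contribute to abundance and to the normalization statistics,
but their reporter signal cannot be attributed to one proteoform.
Normalized intensities are log2-transformed; zeros/missing are excluded,
never imputed.

## Differential statistics

Per proteoform, log2 signals pool across its eligible scans and channels
by condition; log2FC = mean(treated) − mean(vehicle) and a two-sided
two-sample t-test gives p. Welch's unequal-variance form is the default
(robust when channel variances differ); the pooled-variance form is a
flag. At three observations per side Welch is mildly conservative (true
size ≈ 0.035 at nominal 0.05 under equal variances; the pooled form is
exact there) — the calibration test budgets for this with a ±3 binomial-SE
band. Significance is raw p < 0.05; Benjamini–Hochberg q-values are
reported as an extra column for transparency but do not drive the flag,
matching the convention of flagging on the raw p. Proteoforms with fewer
than 2 observations in either condition are reported as
quantified-but-not-tested.

Site-level marginals sum proteoform abundance over every proteoform
carrying a given positioned mark (linear in the mixture) and are compared
against a bottom-up site table by Pearson correlation over shared labels
(≥ 3 required), per condition.

## Synthetic data

The simulator emulates the acquisition the pipeline targets: charge-8
precursors (typical modified tails fall in the 480–540 m/z selection
window), c/z fragments at charges 1–2 with log-normal intensities
(μ = ln 1000, σ = 0.8), Gaussian m/z jitter (σ = 3 ppm against the 15 ppm
tolerance), +1 isotope companions at 0.45 of the monoisotopic intensity
(envelopes truncated at +1 — sufficient for the confirmation rule), 30
uniform noise peaks per scan (low intensity, 1–50), reporter channels
log-normal around condition means (base 1e5, CV 0.3, 5% dropout) with the
impurity matrix applied forward, a 15% chimera rate, and PSM scores with
10% of rows drawn to fail the confidence filters. The default mixture is
five realistic acetyl/methyl proteoforms at fractions
0.30/0.25/0.20/0.15/0.10. All randomness flows from one seeded generator;
a seed reproduces the output files byte for byte.

Two design choices matter for interpretation:

* **Stratified scan allocation.** Single-PSM scans are apportioned to
  proteoforms by largest remainder rather than iid draws — sampling "∝
  fractions" with minimal variance — so in the zero-noise limit estimated
  abundances equal the input fractions exactly, making the noiseless
  recovery test a sharp correctness check rather than a statistical one.
* **Balanced condition effects.** Channel normalization assumes the bulk
  composition is unchanged between conditions (as in real designs where
  most proteoforms are unaffected). Simulations injecting log2 shifts
  keep channel totals balanced (e.g. +1 on a 0.2 fraction against −1 on a
  0.4 fraction); a strongly unbalanced injection would be partly absorbed
  by normalization, which is a property of the method, not of the
  implementation.

What the simulator does **not** model: chromatographic behavior, MS1
survey scans, full isotope envelopes, correlated noise between fragments,
realistic PEP calibration, or co-isolation of more than two precursors.
Passing tests therefore demonstrate the correctness of the computation
under the stated generative model, not search-engine-level identification
performance on real spectra.

## Problem sizes and numerical choices

Tests and the acceptance script use 30–400 scans per simulated dataset
and 1000 proteoforms for the null-calibration check — sizes at which the
statistical criteria (mixture RMSE < 0.05, |shift bias| < 0.1, type-I rate
within 3 binomial SE of 0.05) are well separated from their thresholds
while the whole suite runs in seconds. Abundance/attribution identities
are checked to 1e−9–1e−12; impurity inversion to 1e−6 relative; registry
masses to 1e−4 Da against printed settings and 1e−9 against compositions.
Ties anywhere (fragment assignment, table ordering) break
deterministically so repeated runs are byte-identical.

## Known limitations

* PEP and delta-mod scores are consumed, never computed; there is no FDR
  estimation or PTM re-localization.
* The impurity treatment is our constrained least-squares reading of
  "processed separately"; vendor lot sheets can be supplied via the run
  design.
* Abundance is computed per run; merging 6-plex runs is left to the
  caller.
* The isotope-companion exclusion assumes the +1 peak is weaker than the
  monoisotopic peak, which holds below roughly 4 kDa fragment mass but
  would need a full envelope model for larger species.
* mzML support covers centroided MS2 with 32/64-bit float arrays (plain
  or zlib); vendor raw formats and mzIdentML are out of scope.
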