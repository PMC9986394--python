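# Methods

## Scope and data flow

The package implements the analysis chain of a high-content
miRNA-inhibitor apoptosis screen and its downstream stages. Raw inputs are
two-channel fluorescence fields (16-bit TIFF, one file per channel) plus a
plate-map CSV (`well, cell_line, inhibitor_id, role, replicate`), or
pre-computed per-well score tables; downstream stages consume DEG tables
(CSV: gene, log2fc, pvalue, fdr), one single-column TSV of genes per
target-evidence source, and dose-response matrices (CSV with doses on the
first row/column). Because no raw screen data are publicly deposited, a
synthetic-data module generates every input with recorded ground truth;
all quantitative claims made by the tests and the acceptance script are
claims about recovery of that planted truth.

## Image quantification

Nuclear segmentation is deliberately a transparent, fully parameterized
standard stack rather than an instrument-specific one: Gaussian smoothing
(default sigma 2 px), global Otsu threshold on the Hoechst channel, binary
hole filling, removal of objects outside [min_area, max_area] (defaults
15–10,000 px), and an optional distance-transform watershed split for
touching nuclei (off by default; the generator's default fields are
non-overlapping). A guard treats a field as empty when the Otsu threshold
does not clear the image median by 5 robust SDs — otherwise Otsu on a
unimodal noise background would hallucinate foreground. An all-constant
channel likewise returns no nuclei rather than an error.

The caspase-3/7 reporter is measured only inside each nucleus mask (mean
intensity). Apoptosis positivity defaults to a fixed intensity threshold
(3000 on the 16-bit scale, matched to the generator's signal levels and
calibratable on control wells in real use) because a fixed cut keeps wells
comparable across a plate; an Otsu-on-nuclei alternative exists and falls
back to the fixed threshold, with a warning, below two nuclei. The field
score is apoptotic nuclei / total nuclei; a field with no cells yields a
missing score. Wells aggregate by the unweighted mean of defined field
scores (not by pooling cells), mirroring a per-field readout averaged
across five fields; wells whose fields are all empty are flagged missing
and excluded downstream with a logged reason.

## Hit-calling statistics

Per inhibitor, replicates collapse by arithmetic mean (median is a config
option) to one score per cell line. The log fold change compares the mean
of the two resistant lines with the parental line; a pseudocount (default
0.001) on both ratio terms guards zero parental scores, and setting it to
0 restores the literal ratio (raising a domain error naming the inhibitor
when the parental score is 0). The log base defaults to 2 and is
configurable; robust Z-scores are invariant to any positive affine
transform of the LFC vector, hence to the base choice — a property the
test suite checks — so only the reported LFC column is base-sensitive.

Robust Z-scores standardize the LFC vector by its median and MAD with the
0.6745 = Φ⁻¹(0.75) consistency constant; |RZ| ≥ 2.5 flags significance
(one-sided standard-normal tail 0.00621). When more than half the LFCs tie
at the median the MAD is zero and the scores are undefined; such screens
are reported with all RZ set to NaN, `significant = False` and a
`mad_degenerate` flag rather than dropped — this arises by construction in
noiseless synthetic screens. Control wells never enter the LFC
distribution.

Phenotype categories are evaluated from per-line scores with priority
pan → resistant_only → responsive_only, with "only" meaning the other
line(s) fall below that criterion's own threshold (thresholds 0.50, 0.20,
0.10). The significance flag and the category are independent outputs;
nothing forces hit counts to match between the two rules. No
plate-position normalization or multiple-testing correction is applied.

## Target intersection

Candidates are genes with raw p-value strictly below the threshold
(default 0.05; an `fdr` column can be selected instead) that are present
in the case-insensitive union of the per-source target lists. Provenance
is reported per gene as a semicolon-joined source list. No gene-alias
resolution is attempted (it would need an external dictionary); this is a
known limitation. Direction of change is carried through but never
filtered on, since direct targets may move in either direction after
inhibition.

## HSA synergy

Dose grids must include dose 0 first on both axes — the single-agent
anchors. Viability readings normalize to inhibition fractions
`clamp(1 − raw/control, 0, 1)` with readings above the untreated control
clamped to zero (logged). The surplus subtracts the highest single agent
cell-wise; the single-agent row/column therefore score exactly zero.
Replicate grids are averaged before scoring; conditional on shared
single-agent anchors the surplus operator is linear, so averaging and
scoring commute (property-tested) — with anchors that differ across
replicates the max in the reference breaks strict commutation, which is
why the implementation reports replicate means with standard errors rather
than claiming an order-free identity in general. No significance surface
or four-parameter curve fitting is computed.

## Assay formulas

ΔΔCt uses the arithmetic mean of the reference-gene Cts (equivalent to a
geometric-mean normalizer on the linear scale) per record; fold change is
2^−ΔΔCt, and no amplification-efficiency correction is applied. Tumour
volume uses the modified-ellipsoid form width² × length / 2, with width
the shorter axis (swapped inputs corrected with a warning). The IHC rubric
maps (intensity, % positive) to scores 1–3; the two combinations the
rubric leaves open — weak staining in > 20 % of cells and strong staining
in ≤ 10 % — are completed to score 2 by nearest-neighbour extension
preserving monotonicity in intensity, and flagged as extrapolated in the
return value. SRB relative growth is the day-t / day-0 absorbance ratio.

## Synthetic-data generator

The generator defines the study conditions: 954 inhibitors × 3 cell lines
× 3 replicates with mock, negative-control and cell-death control wells;
by default 4 parental-only (score 0.20 in MCF7), 9 resistant-only (0.30 in
TamR/LTED) and 13 pan (0.60 everywhere) hits planted over a 0.05 baseline,
with Gaussian replicate noise (sd 0.02 in the noisy condition) clamped —
not resampled — to [0, 1] so boundary behaviour is deterministic.
Microscopy fields are Gaussian-profiled discs (default radius 6 ± 0.8 px,
sigma = radius/2) at ≥ 18 px separation on a 600 × 600 px 16-bit canvas
with additive Gaussian read noise (sd 50 over background 200); the
caspase channel carries an elevated blob only for the apoptotic subset
(exactly round(fraction × n) nuclei). The DEG/target fixture plants a
chosen number of genes that are simultaneously significant and in the
1075-gene target union while all other target genes stay non-significant;
around 200 non-target genes are made significant so the DEG side is
realistically large. Dose-response surfaces are Hill single-agent curves
combined as their cell-wise maximum — the HSA reference itself — so the
null surface has identically zero surplus and planted surplus is the
only signal.

One global integer seed is split into independent per-generator streams
(via seed sequences), so partial reruns reproduce exactly. What the
generator does **not** emulate: optics (PSF, uneven illumination),
cell morphology beyond circular nuclei, plate spatial artefacts (edge
effects), correlated replicate noise, and gene–gene correlation in the DEG
tables. Passing tests therefore demonstrate correctness of the
computations and recovery under idealized imaging, not segmentation
robustness on real microscopy. Per-well cell seeding variability at
imaging time is exposed as a generator parameter without any claim of
fidelity to the original screen.

## Numerical choices and problem sizes

Medians follow the standard even/odd convention (numpy); sorting ties in
hit tables break stably by mergesort. Robust-Z agreement with a
brute-force oracle is asserted to 1e-12; log-base invariance to 1e-12;
the affine-invariance property test excludes near-degenerate spreads
(MAD ≤ 1e-3) where float cancellation dominates. The test suite and the
acceptance script use 50 generated fields of 50–300 nuclei for image
recovery, 20 seeds for noisy planted-hit sensitivity, 1000 random vectors
(n ∈ [3, 50]) for the oracle check, and 10,000 normal draws for
robust-vs-classical z convergence (tolerance 0.05, the scale at which the
two estimators' sampling noise meets at n = 10⁴). These sizes were chosen
as the smallest that exercise each claim convincingly.

## Known limitations

Real screen images would need illumination correction and tuned
segmentation parameters before the recovery guarantees shown on synthetic
fields could be expected. The category rules and the |RZ| rule can
disagree on real data; both are reported and left to the analyst. Gene
symbols are matched literally; alias drift between DEG tables and target
databases will lose candidates.
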