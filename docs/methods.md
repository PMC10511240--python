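# Methods

## Quantification model

One biological sample is 1 mL of culture at 1×10⁷ cells/mL, extracted with
perchloric acid, enriched on TiO₂, and resuspended in 20 µL of water;
15 µL of that extract is spiked with 0.75 µL of the ¹³C₆ internal-standard
mixture (2 µM [¹³C₆]1,5-IP₈, 10 µM [¹³C₆]5-IP₇, 10 µM [¹³C₆]1-IP₇, 40 µM
[¹³C₆]IP₆ → 1.5 / 7.5 / 7.5 / 30 pmol per sample). All amounts are carried
in fmol; per-cell amounts in zmol (10⁻²¹ mol), which divide by a volume in
fL to give µM directly.

The chain, per sample and species:

1. **Assignment.** Peaks map to a transition class by m/z (tolerance
   0.05). Monitored transitions (precursor→product): IP₈ 408.9→359.9,
   [¹³C₆]IP₈ 411.9→362.9, IP₇ 368.9→319.9, [¹³C₆]IP₇ 371.9→322.9, IP₆
   328.9→480.9, [¹³C₆]IP₆ 331.9→486.9 — each heavy precursor +3.0 m/z
   (doubly charged, six ¹³C). The two IP₇ isomers share one transition;
   ¹³C standard peaks are identified with species by migration order
   (5-IP₇ before 1-IP₇ on the CE axis), analytes are aligned to the
   standards by the median (analyte − nearest standard) offset and matched
   within 0.2 min. A median offset above 1 min is treated as spurious
   (drift is physically bounded) and ignored. Two analytes claiming one
   standard, or an exact distance tie, raise an ambiguity error; an
   analyte with no standard in tolerance is flagged unassigned, not fatal.
2. **Isotope dilution.** n = (A_analyte/A_standard)·n_standard /
   response_ratio, response_ratio 1.0 by default (equimolar detector
   response of ¹²C and ¹³C forms; configurable).
3. **Aliquot → extract.** ×(20/15).
4. **Recovery correction.** ÷ r_s with defaults r(1-IP₇)=0.89,
   r(5-IP₇)=0.90, r(1,5-IP₈)=0.75, determined by spiking standards before
   extraction. Corrections are applied by default; `apply_recovery=False`
   reports uncorrected extract amounts instead.
5. **Per cell.** ÷ 1×10⁷ cells (configurable), in zmol.
6. **Concentration.** ÷ V_acc. The accessible volume is
   V_cell·(1 − f_organelles) = 42·0.82 = 34.44 fL: organelle lumina
   (≈18 % of cell volume) are excluded, the nucleus (≈8 %) is included
   because the nuclear envelope is permeable to small molecules. The
   stricter V_cell·(1 − 0.26) alternative is available via
   `VolumeModel(exclude_nucleus=True)`; reported concentrations scale by
   0.82/0.74 ≈ 1.11 between the two conventions.

IP₆ is parsed and quantifiable but excluded from concentration reports by
default — it is not a pyrophosphate endpoint here. "1-IP₇" throughout
labels the 1/3-indistinguishable isomer: the MRM assay cannot separate
pyrophosphorylation at the 1- and 3-positions.

## Synthetic CE-MS fixtures

The generator emits the exact inverse of the chain: analyte peak area =
truth_zmol × N_cells × loss × (15/20) × detector response (50 counts/fmol,
arbitrary — it cancels in the area ratio), ¹³C rows at exactly the spike
amounts. Replicate noise is lognormal and multiplicative on the per-cell
amounts with E[factor]=1 (biological variation between cultures), never on
areas, so the isotope-dilution step stays exact and noise-free fixtures
round-trip to ≤1e-9. Migration times get a per-sample Gaussian shift (sd
0.1 min, shared by analytes and standards) plus per-analyte jitter (sd
0.05 min); defaults 18.0 / 19.5 / 20.1 / 21.5 min for 1,5-IP₈ / 5-IP₇ /
1-IP₇ / IP₆ — only ordering and co-migration carry information.

Default ground truths are chosen so the chain reproduces the measured
biology: wildtype replete concentrations 0.5 / 0.7 / 0.3 µM for 1-IP₇ /
5-IP₇ / 1,5-IP₈ (17.22 / 24.108 / 10.332 zmol/cell at 34.44 fL); declines
of 47 / 40 / 75 % after 30 min of Pi withdrawal; 3 % of 5-IP₇ (≈21 nM)
left at 4 h with the other species depleted; mutant panels with 20× 5-IP₇
(*vip1Δ*), 10× 1-IP₇ (*ddp1Δ*), 5× 5-IP₇ (*siw14Δ*), and near-complete
losses in *kcs1Δ* and *vip1Δ kcs1Δ*. Strain labels are spelled ASCII
(`vip1d`, `vip1d_kcs1d`, …) for CSV friendliness.

## Imaging

The study's segmenter was an unspecified trained ("AI-based") model with
no published weights; this package substitutes a deterministic classical
pipeline with the same output contract: Gaussian smoothing (σ 1.5), Otsu
threshold on the bright-field-like channel, hole filling,
distance-transform watershed (marker minimum distance 7 px) to split
touching cells, label expansion by 2 px to recover the dark cell rim the
threshold excludes, then an area filter (60–3000 px). It is validated
against the ≥90 % detection bar on the synthetic fields (greedy one-to-one
IoU matching, detected at IoU ≥ 0.5).

Nuclei: per-cell Otsu on the marker channel restricted to the cell mask,
largest connected component kept; candidates under 4 px or over 60 % of
the cell area flag the cell `nucleus_free`, a second substantial component
flags `multinucleate`.

I_N/I_C: background is the median reporter intensity outside all cells,
subtracted from both means. The cytosol excludes the nucleus dilated by a
1 px guard ring; symmetrically I_N is measured over the nucleus eroded by
1 px, so the blurred nuclear boundary contaminates neither mean (the
erosion falls back to the full nucleus for very small nuclei). Cells
touching the field border, nucleus-free cells, and cells with
non-positive cytosolic signal are flagged and excluded from population
statistics. Population summaries warn softly when a condition has fewer
than 100 or more than 200 cells, the usual sampling depth per condition.

The synthetic fields place non-overlapping discs (radius 8–14 px, centers
≥3 px apart) in a 768×768 field of 100 cells: bright interior (3000
counts) with a 2 px dark rim (300) on background 1000 for the
bright-field-like channel; nuclear discs covering 8 % of the cell area
(mirroring the nuclear volume fraction), amplitude 3000, blurred σ 0.8;
reporter flat at 800 counts above a 100-count background in the cytosol
and scaled by the cell's true ratio in the nucleus. All channels receive
additive Gaussian noise (sd 100 counts, a moderate sCMOS-like level).
What passing tests show is that the measurement chain is unbiased (<2 %)
and the segmenter exceeds 90 % detection *under these conditions*; real
bright-field images have texture, debris, out-of-focus cells and uneven
illumination that the generator deliberately omits, so performance there
is not implied.

## Kinetics and the threshold

Depletion is modeled as a single exponential C(t) = C₀·e^(−kt) — the
observed decay is monotone and featureless, and one rate is the most
parsimonious description. Fitting is nonlinear least squares initialized
from a log-linear regression on the positive points; values ≤0 are below
detection and excluded from the log-space initialization only. The
relocation curve is a 4-parameter logistic, baseline + amplitude/(1 +
e^(−(t−t_half)/w)), bounded (amplitude ≥ 0, t_half inside the observed
range, w > 0) with up to 5 seeded restarts; a fitted amplitude under 2 %
of the data range is flagged `flat` ("no transition") and cannot anchor a
threshold.

The threshold anchors at the logistic half-maximum: threshold =
C₀·e^(−k·t_half). The half-maximum is the least noise-sensitive landmark
of a sigmoid; an earlier anchor (5 % onset) is exposed via
`infer_threshold(..., anchor="onset")` and necessarily yields a higher
concentration. The fixture ground truth (C₀ 14 µM ≈ 20×0.7 µM, k
0.01716 min⁻¹, t_half 60 min, w 12 min) places the threshold at 5.0 µM.

## Reporter statistics

Normalization: (raw − mean blank)/cell count, blanks matched per
condition (untagged-strain wells; a configurable dark count substitutes
when absent); negative values clip to 0 with a flag. Induction =
mean(−Pi)/mean(+Pi). Group tests are two-sided: Student's t
(pooled variance, as in the source assays), Tukey's HSD over all pairs
(family-wise), Mann-Whitney U. Stars: **** p<10⁻⁴, *** p<10⁻³, ** p<10⁻²,
* p<0.05, else n.s.

## Problem sizes and determinism

Everything is sized for a laptop CPU: quantification fixtures are a few
dozen peaks, segmentation batches use 5–20 fields of 100 cells (seconds
per field), stochastic recovery checks use 8–50 seeds, and the Tukey null
calibration 1000 three-group replicates. All randomness flows through
`numpy.random.default_rng` seeds carried by scenario/spec objects; equal
seeds give byte-identical outputs.

## Known limitations

- No raw electropherogram processing: peak detection/integration is
  upstream, CSV peak tables are the entry point (no vendor/mzML parsing).
- Migration-time assignment assumes the standard set is complete; a
  missing ¹³C standard silently shifts isomer identification to whatever
  standards remain.
- The classical segmenter is tuned to rim-on-bright synthetic morphology;
  dense clumps or low-contrast real images will need the min/max area and
  marker-distance parameters adjusted.
- The threshold estimate inherits both fits' errors multiplicatively
  (via C₀, k and t_half); its quoted precision only holds when the decay
  is well described by a single exponential over the anchored interval.
- 2D imaging only; ratios are area-weighted means, not volume integrals.
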