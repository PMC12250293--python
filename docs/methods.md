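# Methods

This note documents the models, numerical choices and limitations behind
`paralogmeth`, in the order data flows through the package.

## Sequence model

Assay sequences are held as the strand that is bisulfite-converted and
sequenced, written 5'→3'. Genomic coordinates are 1-based inclusive;
NCBI `c`-prefixed ranges are stored as minus strand. In-silico bisulfite
conversion is the idealized substitution-only model: every cytosine
outside a CpG becomes thymine, a CpG cytosine is retained iff the
attached pattern marks it methylated. Incomplete conversion is not
modeled; consequently converted sequences keep their length and all
paralog comparisons stay column-aligned. Fractional per-site methylation
states are representable but cannot be applied to a single molecule; they
must be expanded into a weighted template ensemble (uniform levels are
expanded as mixtures of the all-methylated and all-unmethylated molecule,
which is exactly how wet-lab standards are prepared and preserves the
per-CpG marginal level).

Pairwise identity uses a global, end-gap-penalized alignment
(match +1, mismatch −1, gap open −2, extend −0.5) and reports matched
columns over all alignment columns; for the equal-length, substitution-only
pairs the package targets, this reduces to the fixed-length convention
(e.g. 219/230). Primer matching is a Hamming scan (no indels) with a
default budget of three mismatches — the worst case the assay design
tolerates — with reverse primers reverse-complemented before scanning. An
`N` matches only `N`.

## Pyrogram model

Sequencing-by-synthesis is simulated per template: a pointer starts at
zero, and each dispensed nucleotide incorporates the full homopolymer run
at the pointer (possibly zero). Heights are expected-incorporation units
(1.0 ≡ one base in every template); mixtures are weighted sums of
per-template runs, so heights are exactly linear in template weights. No
light-intensity calibration is modeled because the analysis consumes only
relative peak ratios. Noise is i.i.d. Gaussian per dispensation (seeded
generator recorded in the output) with optional linear signal decay per
dispensation index, default off; heights clip at zero.

Dispensation orders for synthetic assays are designed greedily: repeatedly
dispense the first base (A<C<G<T) needed by the furthest-behind template.
This keeps all four pure templates (paralog × methylation state)
synchronized and guarantees termination; external orders are replayed and
a stall (window not fully consumed) is reported with the offending column.
Quality flags use declared absolute-signal floors (failed < 0.1, check
< 0.3 expected-incorporation units); the vendor's pass/check/fail criteria
are proprietary and these defaults are not a reproduction of them.

## Variable-position map

Sequencing each pure template noiselessly under the assay's dispensation
order yields, per template, the dispensation slot that consumed each read
column. Columns whose expected heights differ across templates become
variable positions: CpG columns (C slot = methylated/retained cytosine,
T slot = converted), classified shared / A-specific / B-specific by which
paralog carries the CpG; marker columns (constant within a paralog,
different between paralogs), attributed to the paralog carrying the
adenine, falling back to the purine carrier; and shifted CpGs (CpG start
offset differing by one base between paralogs). Shifted CpGs sit in
homopolymer context by construction, which is precisely what makes them
poor quantifiers; they are mapped but excluded from proportion estimation
by default (selectable per config).

## Deconvolution

The paralog-A proportion combines the two marker estimates by unweighted
mean: p_A = mean(f_A, 100 − f_B). The mean is symmetric and unbiased when
both markers carry comparable noise; single-marker combinations are
configurable. Marker fractions pass the LLOQ/ULOQ substitution before
combination by default, since the substitution rule covers nucleotide
ratios in general; the raw components and raw p_A are always carried
alongside, and the pre-LOQ corrected values divide by the raw proportion.

Pipeline order is fixed: raw per-CpG quantification → proportion →
correction of paralog-specific CpGs (A-specific by p_A, B-specific by
100 − p_A) → reliability masking of shared CpGs → LOQ substitution as the
final reporting step, making the reported profile a fixed point of the
substitution. Corrected values above 100 (possible under noise) are
clipped and flagged rather than errored. Boundaries 80 and 90 belong to
the moderate band. A B-specific CpG in a sample with zero paralog-B
product has an undefined correction and is reported not-analyzable.

## HRM quantification

Normalization fits linear baselines in pre- and post-melt windows
(defaults: the first and last 1.0 °C of the curve; configurable) and maps
fluorescence to (F − lower)/(upper − lower), clipped to [0, 1] — invariant
under affine transforms of the raw signal. Derivative curves use a
Savitzky–Golay filter, degree 3, default window 11 points at 0.1 °C
spacing, negated so melt peaks point up.

Calibration is temperature-wise over 79.6–81.6 °C: at each grid
temperature the unique cubic through the four standard points
(normalized fluorescence, level) maps fluorescence to methylation. Four
points determine degree 3 exactly, so interpolants reproduce the standards
at machine precision; the direction (fluorescence → methylation) avoids
numeric inversion. Temperatures where two standards share a fluorescence
value are non-invertible and excluded; if all are excluded, calibration
fails. Per-temperature estimates aggregate by median (robust to residual
non-invertible temperatures); mean is available. The melt simulator is a
weighted sum of two-state logistic melts with free Tm parameters plus an
optional linear baseline — it makes no claim to predict real melting
temperatures from sequence. Species attribution assigns observed peaks to
the nearest candidate Tm after excluding candidates ruled out by absent
products, refuses exact ties, and warns when candidate GC ordering
contradicts Tm ordering (GC-richer amplicons melt higher).

## Synthetic study conditions

The shipped preset mirrors the geometry of a CDKN2A/CDKN2B exon-2 style
assay: 230 bp, 24 CpGs in paralog A and 21 in B, identity ≈ 95%
(13 substitutions: six CpG-disrupting C→T transitions, one marker base per
paralog, one B-specific CpG in the sequenced window, one shifted CpG, and
three edits under the reverse primer producing one mismatch on
unmethylated and three on methylated paralog-B product), two sequencing
primers with designed dispensation orders. Markers are engineered as A↔T
swaps flanked by G so every measured slot is homopolymer-isolated in all
four pure templates; this makes noiseless recovery exact (to ~1e-13,
float arithmetic only) rather than merely approximate, which is what the
end-to-end recovery checks exploit. Melt standards use Tm 79.9 °C
(unmethylated) and 81.3 °C (methylated) so the published calibration
window spans the transition; fluorescence is then affine in level and the
cubic calibration recovers held-out levels almost exactly.

What the generator does not emulate: PCR amplification bias between
methylation states (real standards under-recover methylated paralog-B
strands because of reverse-primer mispriming), incomplete bisulfite
conversion, inter-run drift, instrument-specific light calibration, and
indel variation between paralogs. Passing tests therefore demonstrate the
correctness of the quantification arithmetic and pipeline plumbing under
the stated model, not robustness to these wet-lab effects.

Problem sizes used by the test suite and acceptance script — a 230 bp
duplex, a 20-point p_A × methylation grid, 200 random oracle instances,
100-seed noise sweeps — were chosen so the whole suite completes in a few
seconds while exercising every code path.

## Known limitations

* Two paralogs only; multi-paralog deconvolution is out of scope.
* No confidence intervals on proportions or corrected levels.
* Amplicon prediction ignores primer thermodynamics; it is a mismatch
  count scan, not a PCR model.
* The published promoter/exon-2 configs ship primers and dispensation
  orders but no genomic template; sequence-level validation needs a
  user-supplied reference FASTA (`paralogmeth.reference`).
* The discrepancy between panel descriptions counting 21 vs 23 CpGs for
  paralog B in the source assay is resolved in favor of the per-primer
  panel definition (1–21).
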