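# Methods

## The measurement and its statistic

A MAPPIT well reports luciferase counts per second. Interaction strength for
one prey/bait mixture is summarised in three stages:

1. **MAPPIT signal** `s = mean(stimulated counts) / mean(unstimulated counts)`
   over the mixture's 4 + 4 wells on one 384-well plate. The unstimulated arm
   measures the same transfection without cytokine, so the ratio cancels
   transfection efficiency and cell-number effects well by well. A mixture
   whose unstimulated mean is zero has no defined signal and is excluded with
   a log entry. Each arm tolerates one missing well (mean over 3); with fewer
   the mixture is excluded (`MIN_WELLS_PER_ARM = 3`).
2. **Normalized signal** `s / median(s_WT,1..6)` against the six wildtype
   mixtures of the *same* plate. The median (for even n, the mean of the two
   central order statistics — the numpy convention) is robust to one or two
   aberrant wildtype wells and cancels plate-wide multiplicative effects
   exactly. A plate with fewer than 4 wildtype signals, or a zero wildtype
   median, fails QC and is dropped whole. Wildtypes themselves are normalized
   leave-one-out against the median of the 5 others, so their normalized
   values retain sampling variation instead of collapsing onto 1.
3. **Relative signal**: the arithmetic mean of the normalized signals across
   replicate experiments (target 3; fewer is flagged, not dropped). If a prey
   appears on several plates within one experiment, those values are averaged
   *before* the replicate mean, so each experiment contributes equal weight.

**Cut-offs and calls.** The lower/upper cut-off is the minimum/maximum
wildtype relative signal pooled over the whole screen. Calls use strict
inequalities — below the lower cut-off `decreased`, above the upper
`increased`, boundary values `unchanged` — matching the "below/above"
semantics of the decision rule; the wildtype extremes themselves are by
construction unchanged. The assay-level QC gate requires at least 10-fold
wildtype induction (inclusive); the pipeline logs violations per plate rather
than dropping data, since the gate is an assay-optimisation criterion.

**Negative controls** enter no formula; they are reported as a specificity
distribution (their stimulated wells should stay at baseline).

Duplicate clones carrying the same amino-acid substitution are first given
their own relative signal, then averaged into one per-substitution value;
both tables are written. The method is threshold-based by design — no
p-values, no multiple-testing machinery.

## Library accounting

Clones are compared positionally to the reference CDS (Sanger reads of a
fixed-length insert; alignment is unnecessary). Length-discordant clones go
to class `indel` without breakpoint resolution — everything but single
missense is discarded downstream anyway. Consequences are computed per codon
from the jointly mutated codon, so two nucleotide changes in one codon count
as one protein-level event. Silent co-mutations do not disqualify a
single-missense clone (the readout is protein interaction). Any clone
containing an N is `ambiguous` and excluded from screening: an N both is a
mismatch against the reference and can hide one. "Unique single missense
mutants" deduplicate by amino-acid change (codon + alternate residue);
coverage is the fraction of construct codons with at least one such mutant.
The standard genetic code only.

## Layout geometry

One 96-well DNA plate (row A wildtype, row H negative control by default;
configurable) expands into two 384-well plates: source columns 1–6 feed
plate A, 7–12 plate B. Source well (row *r*, column *c*) maps to the 2×4
block at rows 2r…2r+1, columns 4c…4c+3 of its plate, left 2×2 sub-block
stimulated. The assay does not dictate this geometry; a fixed deterministic
block keeps the well→mixture map invertible and auditable, and
`collapse_transfection` is its exact inverse. DNA purity QC (OD 260/280
strictly above 1.8) excludes failing mutant wells from expansion; control
wells are always carried. DNA concentrations are recorded, not converted into
volume calculations.

## Structure mapping

Construct codon *i* is residue `i + residue_offset − 1` of the full-length
protein; an explicit mapping table can override this for structures with
discordant author numbering. Multiple substitutions at one residue reduce to
the **minimum** relative signal by default (the question is whether the
residue *can* matter; `mean` is available). Residues without mutants are
absent from the attribute map — rendered grey/non-mutated downstream — and
residues absent from the structure are reported as unmapped, never silently
dropped.

The attribute file dialect is fixed byte-for-byte (three header lines, then
tab-indented `:resnum<TAB>value` lines, 6 significant digits, ascending
residues) so runs diff cleanly and the file round-trips losslessly.

Threshold colouring: *k* ascending thresholds (1–3) define *k*+1 bands —
band = index of the first threshold ≥ value, with values above every
threshold in an open last band. Intensity interpolates the value's position
between its flanking thresholds linearly, clamped to [0, 1]; the first band
uses 0 as its lower flank and the open last band has intensity 1. A value
equal to a threshold therefore has full intensity for that threshold's
colour. The scheme is this package's own defined contract for the rendering
metadata.

Residue adjacency: an edge joins residues whose minimum heavy-atom distance
is ≤ 5.0 Å (a standard contact definition; configurable), computed with a
k-d tree and verified in tests against an all-pairs scan. Interface patches
are connected components of the affected residues (calls ≠ unchanged) in
that graph; components smaller than `min_patch_size = 3` are flagged
`isolated` and should be interpreted with caution — isolated surface hits are
as consistent with fold/stability damage as with an interface. The patch
report carries an empty stability-annotation column for externally supplied
fold-stability predictions; such predictions annotate, never filter.

## The synthetic generator: what it emulates, and what not

Defaults model a compact screening campaign:

| parameter | default | rationale |
|---|---|---|
| construct | 60 codons, offset 159 | a small interaction domain placed mid-protein |
| clones sequenced | 480 | fills up to two 96-well DNA plates with single-missense mutants |
| per-base substitution rate | 0.0045 (4.5/kb) | the error-prone-PCR regime where ~⅓ of clones carry one missense change |
| spectrum | 12 equal rates | a balanced mutagenesis kit |
| baseline counts | 2000 cps | typical unstimulated luciferase background |
| wildtype fold induction | 25 | comfortably above the 10-fold assay gate |
| well noise σ | 0.10 | log-normal, per well |
| plate effect σ | 0.15 | log-normal, per 384 plate |
| replicates | 3 experiments | the screening design |
| interface | codons 20–27, effect 0.2 | a contiguous surface patch that quenches the interaction |

Stimulated counts are `baseline × fold × effect(prey) × plate × well`,
unstimulated `baseline × plate × well`; negative controls get effect
`1/fold` (no interaction-driven induction). Noise is multiplicative and
per-plate effects are explicit **because the plate-median normalization is
built to cancel exactly such factors** — the generator makes that
cancellation testable, including the exact zero-noise closed form (every
normalized signal equals its configured effect).

What the generator does *not* emulate: Sanger chromatogram noise and mixed
peaks, PCR-cycle mutation-load kinetics, additive background drifts,
position- or residue-specific mutational biases, expression-level differences
between mutants, and structural (fold-destabilising) effects that also move
real MAPPIT signals. Passing tests therefore demonstrate the correctness of
the computations and the self-consistency of the statistic under the stated
noise model — not the biological error rates of a wet-lab screen.

The toy structure is an ideal α-helix Cα+Cβ trace (1.5 Å rise, 100° twist,
2.3 Å Cα radius): consecutive residues sit ~3.8 Å apart, so at the 5 Å cutoff
its contact graph is a simple path — deliberately trivial, making planted
contiguous interfaces form exactly one patch.

All randomness flows from one integer seed through NumPy's PCG64 generator;
stage-level child seeds are drawn from the master so libraries, plates and
readouts are individually reproducible. No hash-ordering dependence.

## Numerical and interface conventions

- CSV floats are written with `%.6g` so reruns are byte-identical.
- Plate IDs embed experiment, source plate and half
  (`E2:DNA01:B`), keeping readouts from different experiments unambiguous in
  one flat table.
- Ties in PCR-condition selection break by single-missense fraction, then
  lexicographic label.
- The wildtype/negative-control replicate tracks are keyed by source well, so
  cut-offs are derived from per-wildtype-prey relative signals exactly as
  mutants are tracked per clone.

## Known limitations

- Equal-length comparison only: clones with real indels are counted but not
  characterised.
- With 24 wildtype tracks, the min/max cut-off rule leaves an expected
  neutral-mutant false-call rate on the order of 2/(n_WT+1) ≈ 8% under pure
  noise; larger screens (more wildtype wells) tighten this. The rule is kept
  as specified — it is the method's decision rule, not an estimator to tune.
- The colour-intensity contract approximates, but is not guaranteed to match,
  any particular external viewer's interpolation.
- Patches are defined on the mutated residues only; an interface residue with
  no mutant in the library cannot appear in a patch (coverage matters).
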