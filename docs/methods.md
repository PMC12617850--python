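# Methods

## Ion chemistry and mass arithmetic

All ion math assumes singly protonated even-electron species ([M+H]⁺),
the charge state under which hydroxamate siderophores are observed in
positive-mode electrospray. Monoisotopic atomic masses are hard-coded
from the AME2020/NIST tables to ≥6 decimals (C 12, H 1.00782503207,
N 14.0030740048, O 15.9949146196, S 31.9720710015, ⁵⁶Fe 55.9349363,
⁵⁴Fe 53.9396090; proton 1.007276466621). The electron mass is carried in
`MassConstants` but not subtracted for [M+H]⁺ — the resulting error is
below 1 ppm for m/z > 100, well inside every tolerance used. ppm is
always 1e6·(observed − theoretical)/theoretical.

The ferric complex is modelled as the tris-deprotonated neutral
M − 3H + Fe(III): three hydroxamate protons are displaced by one iron.
Its protonated ion therefore sits m(⁵⁶Fe) − 3·m(H) = 52.91146 Da above
the apo [M+H]⁺, a constant independent of M; this constant, and the
⁵⁴Fe–⁵⁶Fe spacing 1.99533 Da with abundance ratio
0.05845/0.91754 = 0.0637, drive the whole MS1 screen.

**Formula decomposition** enumerates CHNOS compositions exhaustively
within per-element bounds (defaults C 0–60, H 0–120, N 0–15, O 0–25,
S 0–5), iterating heavy elements and solving the hydrogen count from the
mass residual — algebraically identical to the naive nested loop the
test suite uses as oracle, but linear in the heavy-element grid.
Candidates are filtered to ring-and-double-bond equivalents
RDBE = (2C + 2 + N − H)/2 in [0, 40] (an optional H/C-ratio filter is
off by default) and sorted by |ppm error| then Hill string, so output
order is deterministic. At 750 Da and 5 ppm, dozens of formulas tie
within tolerance; the ranked list, not the top entry, is the result.

## MS1 screen

Stages, in order, on a sample and a blank/control feature table:

1. **Blank subtraction.** Features are matched across runs greedily by
   (|Δm/z in ppm|, |ΔRT|) within 5 ppm and ±0.2 min (each feature used
   once); a sample feature is removed iff its control partner's area
   exceeds 0.01% (1e-4) of the sample area. Partnerless features are
   never removed. The 0.01% rule is deliberately aggressive: medium-borne
   features dominate control extracts.
2. **Iron-pattern detection.** For each feature the screen looks for a
   satellite 1.99533 Da below the monoisotopic peak (tolerance 5 mDa)
   whose relative intensity lies in [0.02, 0.15] — roughly ×/÷2.5 around
   the natural 0.0637, wide enough for counting noise, narrow enough to
   reject Cl/Br-type A+2 patterns and coincidental co-elutions. The
   satellite is sought in the feature's own isotopologue envelope, or,
   for envelope-free tables, among co-eluting features (±0.05 min) using
   areas as intensities. ⁵⁷Fe/⁵⁸Fe satellites (<2.2%) are ignored.
3. **Apo/holo pairing.** Any two features whose m/z difference equals
   52.91146 Da within max(5 ppm at the holo m/z, 0.003 Da), with RT
   shift ≤ ±2.0 min, form a candidate pair. The ppm branch is the active
   one above m/z 600, consistent with the instrument-accuracy rule used
   everywhere else in the pipeline. The ±2 min window spans the
   retention shift an iron complex shows on a reversed-phase gradient
   without pairing unrelated features.
4. **Candidate assembly.** Pairs are consumed in order of mass error,
   each feature at most once; a pair qualifies when the holo member
   carries an iron hit. By default both forms are required
   (`require_apo=True`); a holo-only mode accepts a clean Fe pattern
   alone, for extracts where the apo form is below the detection limit.
   Apo neutral masses are decomposed as above, and ±CH₂ (14.0157 Da) /
   ±O (15.9949 Da) mass relations among accepted candidates are recorded
   as family links — homologous acyl-chain extension and hydroxylation
   are the analog relations expected inside one biosynthetic family.

## MS/MS processing

Spectrum hygiene precedes annotation and networking: product ions within
0.003 Da of the ubiquitous contaminant m/z 202.080 are deleted, then
each spectrum keeps only peaks that (a) rank among the top 5 by
intensity within the 50 Da window centred on them and (b) reach 0.1% of
the base peak. The window is sliding (±25 Da around each peak) rather
than binned, avoiding bin-edge artifacts; ranking uses strictly-greater
comparison so ties survive, which makes the filter idempotent.

Annotation compares every peak with each library block's [B+H]⁺ m/z and
every loss (precursor − peak) with the block's neutral-loss mass, at
max(5 ppm, 0.003 Da). The default library holds N⁵-hydroxyornithine
(C₅H₁₀N₂O₂, fragment 131.0815/loss 130.0742),
N⁵-formyl-N⁵-hydroxyornithine (C₆H₈N₂O₃ fragment 157.0608, loss
C₆H₁₀N₂O₃ 158.0691), the hexanoyl unit C₆H₁₀O₂ (115.0754/114.0681) and
the C₄H₇NO fragment (86.0600). The two ornithine-block formulas are
marked `inferred`: they are assigned from the measured masses and
hydroxamate chemistry, verified numerically to ≤2 mDa, not from isolated
standards. All stored masses are formula-derived; measured reference
values agree within the matching tolerance (the worst case, the
130.073-Da loss, differs from theory by 1.1 mDa — within the 3 mDa
window, and no CHNO composition sits closer). A spectrum is flagged
*hydroxamate-consistent* when ≥2 distinct blocks hit (configurable);
the threshold is an artifact choice — two independent monomer signatures
are already very unlikely by chance at 5 ppm.

## Molecular networking

The modified cosine matches fragment pairs that agree directly in m/z
*or* after shifting by the precursor mass difference, so structural
analogs align; a pair satisfying both conditions is counted once.
Intensities are square-root transformed before the cosine (the common
networking convention; `raw` is available), the one-to-one assignment is
greedy by descending intensity product, and the score is normalised by
the two weight-vector norms, making self-similarity exactly 1. The test
suite checks the greedy assignment against the optimal (Hungarian)
assignment on 1,000 random ≤6-peak pairs and against the independent
matchms implementation.

Networks keep edges with score ≥ 0.7 and ≥ 5 matched ions, then apply
the neighbour cap: an edge survives only if it ranks in the top 10 by
(score, matched ions, partner id) for *both* endpoints — the stricter of
the two readings of "10 neighbours per node", and the one that
guarantees max degree ≤ 10 on any input. Duplicate spectra per feature
are resolved to the most intense. Tie-breaks everywhere are
deterministic (score desc, matched desc, lexicographic ids).

## Synthetic scenarios

The generator emulates what the analysis consumes, not raw profile
spectra: centroided feature tables with isotopologue envelopes, MS/MS
peak lists, and a control run. The default scenario plants five
families at neutral formulas C₃₃H₆₂N₆O₁₃ + {∅, CH₂, O, CH₂+O, 2CH₂+O} —
the offset set under which members 1/2, 3/4, 4/5 differ by CH₂ and 1/3,
2/4 by O — each as an apo ion (25% of the family area) and a ferric
complex (75%, eluting 0.2–0.5 min later) with the ⁵⁴Fe satellite at its
natural ratio. Confounders: 12 plain organic decoys, 4 decoys with the
correct A−2 spacing but ratio 0.5, 4 Cl-like A+2 decoys, 2 near-miss
pairs offset 50 mDa from the ferric shift, 6 blank-shared features
(reproduced in the control at 50–150% area) and 8 control-only features.
Decoy m/z values are rejection-sampled away from every planted ion and
its ±ferric-shift/±CH₂/±O slots so ground truth stays unambiguous.

Noise model: Gaussian m/z error σ = 1 ppm, log-normal area error
σ = 0.1, 5% multiplicative noise on envelope ratios, 0.5 mDa jitter on
envelope and fragment positions — Orbitrap-class full-scan behaviour.
MS/MS spectra superimpose the building-block template (conserved
fragments at fixed m/z, loss peaks riding at precursor − loss, one
0.05%-of-base sub-threshold peak, the 202.080 contaminant) with a few
uniform noise peaks; decoy spectra are random peak lists plus the
contaminant.

What the generator does **not** emulate — chromatographic peak shapes,
co-eluting isomer interference, in-source fragmentation, charge states
≠ 1, negative mode, real fragmentation energetics — bounds what passing
tests show: they validate the screening logic and its thresholds under
the stated noise, not performance on raw instrument data, where feature
detection itself is the harder problem.

## Degenerate inputs and numerical choices

Empty tables and empty spectra flow through every stage and yield empty
results, not errors; malformed CSV schemas and out-of-scan-range
features raise. An empty decomposition result is an empty list. Scores
are clipped to [0, 1] against float round-off. All thresholds live in
one `PipelineConfig`; overriding a published default is legal but
produces an explicit warning from `validate_config`.

## Limitations

- The screen operates on feature tables with isotopologue envelopes;
  peak picking and envelope extraction from raw data are out of scope.
- Positive mode only; the apo/holo arithmetic is not defined here for
  deprotonated species.
- Formula assignment at 750 Da / 5 ppm is set-valued by nature; ranking
  within the tolerance window would need isotope-fine-structure or MS/MS
  formula evidence, both out of scope.
- The neighbour cap's both-endpoint semantics prunes slightly more edges
  than an either-endpoint reading would; cluster membership is
  unaffected in the planted scenarios, but edge counts differ between
  conventions.
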