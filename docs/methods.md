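# Methods

## Screen model

The pipeline analyses tiered ("staggered") RNAi screens on 96-well plates
(8 × 12 by default; geometry is configurable). A *primary* screen measures
per-well percent-positive readouts for IL-6 and IL-8 on pooled siRNAs with
two transfection replicates; a *secondary* screen deconvolutes candidates
into four siRNAs per gene, three replicates, over four SASP channels (IL-6,
IL-8, CCL2, IL-1β); a *killing* screen co-cultures siRNA-transfected
senescent cells with NK effectors and reads the percent change in
target-cell counts across six replicates. Each stage's hit list feeds the
next: secondary candidates come from primary dual hits, and the killing
library is assembled from secondary calls.

## Positivity calling

A cell is scored positive when its intensity strictly exceeds the mean
per-cell intensity of an internal negative control; a well's readout is
100 × the positive fraction. Whether that threshold should ever be adjusted
per experiment is left to the user (`call_percent_positive` takes the raw
control vector); the default is the unadjusted control mean.

## B-score normalization

Per plate/channel/replicate, sample-well values are decomposed by Tukey's
two-way median polish (alternating row/column median sweeps, midpoint
convention for even counts, effect vectors recentred into the overall term
each sweep). Convergence is declared when one full sweep's summed absolute
adjustments fall below `tol` (default 1e-6; `max_iter` 100 — the polish
typically converges in well under 50 sweeps, but tolerances of 1e-9 or
tighter can need a few hundred, so tests use larger budgets). Missing
cells are ignored by the medians and stay missing; rows or columns with no
data at all are excluded from the polish rather than being an error, since
partially filled last plates are routine.

Residuals are scaled by `mad_scale = 1.4826 × median |r|` over sample-well
residuals (the residual median is ~0 after polishing, so this is the
classical MAD with the Gaussian-consistency constant; the constant is a
config knob). Control wells are excluded from the polish so that extreme
controls cannot distort row/column effects; their B-scores are computed
afterwards against the fitted decomposition. A plate with `mad_scale = 0`
(e.g. all sample wells identical) yields all-zero B-scores and a degenerate
flag rather than an error, so one flat plate cannot abort a screen run.
Well-level B-scores are aggregated to one score per (siRNA, replicate) by
an arithmetic mean within each transfection batch; an siRNA absent from a
replicate propagates as missing, never as zero.

### Null behaviour of the B score (known limitation)

On an 8 × 12 grid the MAD of median-polish residuals under-estimates their
standard deviation by roughly a fifth (the polish pulls central residuals
toward zero faster than tail ones), so null B-scores have SD ≈ 1.3–1.4 and
heavier-than-Gaussian tails — *independently of the noise scale*, because
the B score is scale-invariant. Consequently a fixed threshold such as
B ≥ 3.05 sits near 2.2 null SDs and admits a per-well-replicate false-pass
rate of ~2%; with the both-replicates rule this leaves an expected ~0.1
false-positive genes per 420-gene screen even with no spatial artifacts at
all. This is a property of the B score itself, not of a particular noise
setting, and is why screens of this design validate primary hits in a
deconvoluted secondary screen rather than treating primary calls as final.

## NPA scoring

`NPA = (x − C̄neg) / (C̄pos − C̄neg)` with the negative/positive control
means taken per plate (each plate must carry ≥ 2 negative controls and ≥ 1
positive control; equal control means are a hard error naming the plate).
Values are not clipped by default (`clip` is available as config). Because
the formula is invariant to affine rescaling applied to a whole plate, it
absorbs plate, batch and replicate offsets — which is exactly how the
killing screen is normalized across its six replicates. For killing data
the positive control kills more strongly (more negative percent change)
than the negative control, so the unmodified formula already assigns larger
NPA to stronger killing; no sign flip is applied.

## Killing quantification

Killing is read as `100 × (N_end − N_t0) / N_t0` against a separately fixed
time-0 plate count (typically a 48-h coculture; 24 h for OVCAR4 cells).
`nk_specific_effect` reports the difference of percent changes with vs
without effectors, separating NK-dependent killing from cell-intrinsic
(senolytic) effects. `effectors_needed` converts a target count and an E:T
ratio into the number of NK cells to seed. The screen's NPA is computed on
the NK-arm wells directly by default; differencing against no-NK wells
before NPA is supported but not the default, since the plate-level controls
already anchor the NK arm.

## Hit calling

All threshold comparisons are inclusive (≥), matching the printed rules,
and a missing score never counts as a pass. The consensus phrase "at least
*k* siRNAs … in at least *m* replicates" is evaluated per siRNA (each
qualifying siRNA must itself pass in ≥ *m* replicates), the standard
RNAi-screen reading; a stricter joint mode (≥ *m* replicates in which ≥ *k*
siRNAs pass together) is available as `secondary_consensus="joint"` but is
not the default. Primary thresholds default to the fixed published-style
values (IL-6 4.20, IL-8 3.05) and can alternatively be recomputed as the
negative-control mean + 2 SD (`PrimaryHitCaller(from_controls=True)`);
both the thresholds used and the per-siRNA × replicate pass matrices are
recorded in every emitted hit table, so each call is re-derivable from its
own evidence. The killing library takes all genes hit in ≥ 2 of 4 SASP
channels plus up to 8 CCL2-only genes; since no ranking for the CCL2-only
cap is prescribed anywhere, the package ranks by best CCL2 NPA with an
alphabetical tie-break, and both the cap and (implicitly) the ranking are
configurable — a documented assumption, not a published rule.

## Synthetic data generator

Sample wells are generated as
`baseline[channel] + row_amp·r_i + col_amp·c_j + batch + effect + noise`,
truncated to [0, 100] for percent channels and to [−100, ∞) for the killing
percent change. `r, c` are standard-normal row/column profiles drawn once
per physical plate (per plate × replicate); batch offsets are shared by all
plates of a transfection batch (one batch per replicate); noise is i.i.d.
Gaussian per well × channel. The siRNA layout of a plate — including the
positions of the non-targeting negative controls and of positive-control
siRNAs against four known SASP regulators (EPRS, LPAR2, SIRT1, LGMN) — is
drawn once and reused across replicates, as with real pre-plated daughter
plates; control positions are random rather than fixed to plate edges so
that readers of the data cannot assume a layout. All randomness derives
from a single seed through per-plate substreams.

Defaults are scaled-down study conditions chosen to be realistic and fast,
not published values (the source screens publish no noise or effect-size
estimates): baseline 10% positive, well SD 2, spatial amplitudes 3, batch
SD 1, 8 negative + 4 positive controls per plate; spiked hits get +40
percentage points (+50 for CCL2/IL-1β, whose NPA cut of 2 sits above the
+20 positive-control shift); the killing tier uses baseline −10% change,
enhancer effect −50, positive control −60, so enhancer NPA ≈ 0.83 against
the 0.7 cut. Tier sizes are 420 genes × 1 pool (primary; exactly five full
plates — a partially filled plate leaves sparse rows/columns that degrade
the polish MAD, which pre-plated libraries do not exhibit), 156 genes × 4
siRNAs (secondary), 76 genes × 4 siRNAs (killing). A full three-tier
simulated run completes in seconds.

What the generator does *not* emulate: multiplicative or non-additive
spatial artifacts (evaporation gradients interacting with cell density),
heavy-tailed or correlated well noise, transfection-efficiency variation
between siRNAs of a gene, and saturation behaviour near the 0/100 bounds
beyond hard truncation. Passing recovery tests therefore demonstrate
correctness of the pipeline's statistics under its own assumptions, not
performance guarantees on arbitrary real screens.

## Numerical and design choices

- Internal well coordinates are 0-based; readers accept plate-map
  conventions (row letters, 1-based columns) via schema flags, and writers
  emit the plate-map convention.
- Percent values are kept on the 0–100 scale throughout.
- Even-count medians use the midpoint; polish fixed points are then not
  unique in general, which is why cross-implementation comparisons (e.g.
  against R's `medpolish`) are exact only on odd-dimension matrices.
- Hit calling is deterministic and order-independent; gene sets are
  reported sorted where order matters (library selection).
- `evaluate_recovery` reports zero-denominator ratios as undefined (None),
  never as 0.

## Problem sizes in the test suite and acceptance script

Property checks use 200 random 8 × 12 plates (polish/B-score oracles) and
1000 random 4 × 6 score tensors (consensus rule); recovery experiments use
20 seeded screens at the default tier sizes, and the acceptance script uses
10 (primary/null) or 5 (secondary/killing) fresh seeds derived from its
`--seed`. These sizes give stable two-decimal metrics while keeping a full
run in the low minutes on one CPU.
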