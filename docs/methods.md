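# Methods

## Problem and signal model

SNP arrays report, per probe, a log2 intensity ratio (LRR, a copy-number
proxy centred at 0 for two copies) and a B-allele frequency (BAF, the
fraction of signal attributable to the B allele: ~0, 0.5, 1 for AA, AB, BB
in diploid cells).  When a chromosomal rearrangement is *mosaic* — present
in only a fraction `p` of cells — heterozygous probes inside the affected
region split into twin BAF bands at `0.5 ± shift`, where the shift grows
with `p` but the LRR displacement may be small (and is exactly 0 for
copy-neutral events such as mosaic UPD).  Detection therefore works on the
BAF signal; LRR is used only afterwards, to classify the event.

Per probe the **b-deviation** is `b_dev = |BAF − E[BAF | genotype]|` with
the expected level 0, 0.5 or 1 taken from the genotype call when present,
otherwise from the nearest level (ties at 0.25/0.75 break toward 0.5,
favouring sensitivity to allelic imbalance).  Only *informative* probes
enter segmentation — AB calls, or BAF strictly inside (0.1, 0.9) without
genotypes — because homozygous probes carry `b_dev ≈ 0` in every mosaic
state and only dilute the signal (an all-probe mode exists behind
`segment_all_probes`).

`b_dev` is folded (non-negative) and far from Gaussian, while the
segmentation model assumes Gaussian noise, so the signal is the clamped
probit `Φ⁻¹(clip(b_dev, ε, 1−ε))`.  The clamp default is `ε = 5e-3`: at
good-quality noise (σ = 0.03) this leaves the transformed null signal
nearly symmetric (skewness ≈ −0.03, versus −0.9 at ε = 1e-4 and +1.0 for
raw `b_dev`), which is the point of the transform.  Much smaller clamps
re-introduce a long left tail from near-zero deviations.

## Segmentation

Two stages, mirroring the classic sparse-regression-then-prune design.

**Candidate generation** (`sbl_candidates`).  A deterministic multiscale
matched filter: for dyadic windows `w = 4, 8, …, n/2` the t-statistic of
the flanking-mean difference, `t_w(i) = (mean_R − mean_L)/(σ√(2/w))`, is
evaluated at every interior probe boundary.  Local maxima of `|t_w|`
exceeding the sparseness threshold

    τ(a, n) = min( 2 (1 − a) √(2 ln n), 5.5 )

contribute; evidence is aggregated across scales; non-maximum suppression
(radius `clip(n/8, 3, 16)`, strongest first) keeps one candidate per
neighbourhood; each survivor is refined to the exhaustive constrained
maximum-likelihood change-point position within the suppression radius.
The `√(2 ln n)` factor is the null extreme-value scale of such a scan
(standard multiscale change-point calibration), so the sparseness
parameter `a ∈ [0.2, 0.8]` spans "only boundaries beating the null
maximum" to "essentially every local maximum" — the semantics of a sparse
hierarchical prior, under which moderate `a` suppresses null breakpoints
by itself.  The cap 5.5 < 4√2 guarantees recall of any boundary whose
flanking windows differ by ≥ 4 noise SDs, at any `a`.  The second prior
parameter `b` is uninformative (0) and accepted for interface
compatibility, as are `max_iter`/`tol` — the scan is a single
deterministic pass.

**Backward elimination** (`backward_eliminate`).  The boundary t-statistic
between adjacent segments L and R is
`t = (mean_R − mean_L)/(σ√(1/n_L + 1/n_R))`.  The least significant
breakpoint (smallest `|t|`) is removed and its neighbours' statistics
recomputed, until every survivor reaches the threshold `T`.  Because
removal order is fixed, the surviving set for `T₂ > T₁` is nested inside
the set for `T₁`, making `T` a cheap sensitivity/FDR dial.  Afterwards
segments shorter than `MinSegLen` are merged into the neighbour with the
closer mean (ties merge left; ordering of enforcement — merge after
elimination — is a design choice).

The noise scale σ is the median absolute successive difference divided by
`√2 · 0.6745` — robust to the very level shifts being sought.

**Call emission.**  Segments are tested one-sided against a background
reference: the 10%-trimmed mean of the transformed signal, pooled over all
chromosomes of the genome.  A segment is emitted as altered iff its mean
exceeds the background and `t_seg = (mean − background)·√n/σ ≥ T`.  The
genome-wide pooling is what keeps whole-chromosome events (trisomies)
detectable: a fully altered chromosome has no internal breakpoint and can
only be flagged against other chromosomes.  Consequences: (i) a
single-chromosome input in which half the probes are altered has a
contaminated background and loses power for weak shifts (a conservative
failure — visible as near-zero TPR in the noisy/10% benchmark scenario);
(ii) the b-deviation increases under every event type, so the one-sided
test loses nothing.

## FDR control

Under the null a segment's `t_seg` is Student-t with `n − 1` degrees of
freedom (standard normal above n = 200, where the two tails agree to
better than 1e-3).  The genome-wide expected number of false calls at
threshold `T` is bounded by treating the array as `N / MinSegLen` disjoint
minimum-length windows:

    E[false] = (N / MinSegLen) · P(|t_ν| > T),   ν = MinSegLen − 1
    FDR      = min(1, E[false] / n_called)       (0 when nothing is called)

The bound is deliberately conservative (real calls are longer than the
minimum window and correlated); it is monotone non-increasing in both `T`
and `MinSegLen` and is validated against simulated null tracks in the
calibration benchmark.  At `N = 10⁶`, `T = 8`, `MinSegLen = 300` it gives
~4e-12, comfortably below the 1e-4 working bound; the matching empirical
check (200 null chromosomes of 20,000 probes) yields zero calls.

`recommend_settings` scales `MinSegLen` with array density (300 probes per
million, floor 2) and picks the smallest threshold on a coarse documented
ladder `T ∈ {2, 4, 8}` (loose / moderate / strict scan profiles) meeting a
target FDR.  On sparse arrays the Student tail of tiny windows can make a
strict target genuinely unreachable; the function then reports the closest
achievable value rather than silently loosening.

## Classification and cell fraction

The mean LRR of a call is taken *relative* to the mean LRR of all
autosomal probes outside every called segment (X/Y excluded), making the
rule invariant to global intensity offsets.  Thresholds: deletion below
−0.10, duplication above +0.10, copy-neutral (UPD) inside the closed band
[−0.10, +0.10].  A copy-number call covering more than 95% of its
chromosome is promoted to a whole-chromosome event: trisomy for gains,
mosaic monosomy for losses (the extra `monosomy` label is this package's
choice; whole-chromosome losses are otherwise indistinguishable from large
deletions).  Low-fraction gains sit near the +0.10 boundary
(`log2(2.1/2) ≈ 0.07` at p = 0.1) and may be reported as UPD or reflect
constitutional duplications; no constitutional-versus-mosaic discriminator
is attempted.

With fraction `p` of cells altered, allelic dosage gives the heterozygous
band deviation `b` and its inverse:

| event        | B-allele share        | recovered fraction       |
|--------------|-----------------------|--------------------------|
| UPD          | `(1 + p)/2`           | `p = 2b`                 |
| deletion     | `1/(2 − p)`           | `p = 2b/(0.5 + b)`       |
| duplication  | `(1 + p)/(2 + p)`     | `p = 2b/(0.5 − b)`       |

`b` is estimated as the *median* per-probe `b_dev` over the call's
informative probes (original scale, not probit) — robust to band asymmetry
and to background probes swept into a call by `MinSegLen` merging.
Trisomy uses the duplication mapping, monosomy the deletion one; estimates
are clipped to [0, 1].  These mappings and the simulator's forward band
model are exact inverses, which the round-trip benchmark exploits
(median absolute recovery error ≤ 0.03 at p = 0.2, good quality).

## Synthetic data

`simulate_track` emulates the validation arrays: 20,000 probes per
chromosome at uniform 1 kb spacing; genotypes drawn AA/AB/BB at
0.25/0.50/0.25 (configurable); homozygous BAF as a log-normal-shaped
deviation from the 0/1 anchors, `clip(exp(N(ln σ − 0.77, 1)), 0, 1)`,
giving SD = σ and mode ≈ 0.17σ (0.005 at good quality), mirrored for BB;
heterozygous BAF `N(0.5, σ)` clipped to [0, 1].  Noise σ is 0.03 (good) or
0.1 (noisy).  Inside the altered block heterozygous probes are assigned
with probability ½ to each twin band `N(0.5 ± shift, σ)` — real mosaic
data shows symmetric twin bands, and `b_dev` is unaffected by the split.
Shifts of 0.05 / 0.10 correspond to 10% / 20% of cells under the
copy-neutral mapping `shift = p/2`; deletions and duplications use their
dosage mappings above.  LRR is probe noise `N(0, 0.15)` plus a block
offset of 0 (UPD), `log2((2−p)/2)` (deletion) or `log2((2+p)/2)` (gain);
trisomy alters the whole chromosome.

The eight-scenario study grid is {shift 0.05, 0.10} × {block 1,000,
10,000} × {σ 0.03, 0.1}; the proportion series places one 1,000-probe
copy-neutral block in a 20,000-probe track for p = 0, 0.01, …, 0.15.  All
seeds derive from a single master seed via `SeedSequence`; output is
byte-identical per seed.

Not emulated: GC waves, probe-specific bias, genotyping error, raw
two-channel intensities, inhomogeneous probe spacing.  Passing benchmarks
therefore demonstrate the statistical machinery under idealised array
noise, not performance on wave-distorted clinical data.

## Benchmarks and problem sizes

Detection success means a single call covers ≥ 50% of the simulated block
(probe-level, on the raw index scale).  The sensitivity benchmark runs the
caller at `a = 0.5, T = 2, MinSegLen = 900` over the 16-point proportion
grid with 200 replicates per point; the curve area uses the trapezoid rule
and is normalised by the width of the proportion range.  ROC tables use
probe-level TPR/FPR (a segment-level variant was considered and rejected
as under-determined for partial overlaps) over `a ∈ {0.2, 0.8}`,
`T ∈ {2.5 … 5}`; AUC integrates the polyline with (0,0)/(1,1) anchors.
FDR calibration pools calls over replicates and scores a call false when
disjoint from the truth block.  Default replicate counts in the test suite
are scaled to desk hardware (8–200 per point, chosen so Monte-Carlo error
stays well inside each assertion's tolerance); the CLI exposes study-scale
defaults (200 for the sensitivity series, 1,000 for ROC/FDR) with a
`--fast` 1/10 mode.

## Numerical and degenerate-input choices

* Clamping makes every transformed value finite; a constant signal yields
  σ = 0, which is floored at 1e-12 and produces no candidates.
* Heap-based elimination breaks ties deterministically (smaller boundary
  index first); merge ties go to the left neighbour.
* Duplicate probe positions keep the first occurrence with a warning;
  missing BAF/LRR are NaN, never imputed; chromosomes with fewer than
  `MinSegLen` informative probes are skipped with a warning.
* Chromosome labels are strings; X/Y are read and segmented but excluded
  from the diploid LRR baseline.
* Coordinates are 1-based inclusive internally; BED export converts to
  0-based half-open.

## Known limitations

* The candidate scan is a stand-in with contractual behaviour (sparseness
  monotone in `a`, guaranteed 4σ recall, near-linear runtime); it does not
  reproduce any particular hierarchical-prior implementation
  breakpoint-for-breakpoint.
* The FDR bound ignores correlation between overlapping windows and is
  loose at permissive thresholds; calibration by simulation is the
  arbiter.
* Single-chromosome inputs with very large altered fractions weaken the
  background reference (see above).
* Runs of homozygosity from identity-by-descent mimic high-fraction UPD;
  disambiguation needs pedigree or population data and is out of scope.
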