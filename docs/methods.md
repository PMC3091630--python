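# Methods

## Breakpoint detection and resolution

### Model and assumptions

Inserts are modelled as a homogeneous Poisson process on the genome: the
number of inserts spanning a fixed fusion point ζ is Poisson with mean equal
to the clonal coverage c = N·L/G, and the offsets of spanning inserts
relative to ζ are independent and uniform. Insert length is treated as fixed
in every closed form; the length spread σ only enters the simulator. This is
justified empirically by the simulator regression test: at σ/L = 0.1 and
c = 2 the detection frequency moves by less than 2% relative. Edge effects
(fusion points within one insert length of a chromosome end) are ignored by
the closed forms and excluded by the simulator's placement margin.

Detection requires at least `min_inserts` spanning inserts. `min_inserts=1`
is the pure Clarke–Carbon setting and the default for analytic calculations;
`min_inserts=2` matches how empirical paired-end pipelines call breakpoints
(two independent inserts guard against chimeric artifacts) and is the
default for the simulator. Both are exposed everywhere.

### Closed forms

With m = min_inserts and Γ₂(x) = 1 − e^(−x) − x·e^(−x) (the Gamma(2) CDF):

- P_detect(c, m) = P(Pois(c) ≥ m).
- E|Θ|(c, m) = 2L · P(Pois(c) ≥ m+1) / (c · P(Pois(c) ≥ m)). Derivation: the
  spanning inserts localize ζ to the interval between the right-most left
  endpoint and the left-most right endpoint; with k spanning inserts each
  side has expected length L/(k+1), and by symmetry E|Θ| = 2·E(A) with A the
  distance to the nearest right endpoint. Averaging L/(k+1) over the Poisson
  count conditional on k ≥ m gives the form above. Limits: 2L/(m+1) as
  c → 0, 2L/c as c → ∞.
- Resolving to s bp with libraries split at s: short libraries (L ≤ s)
  resolve by spanning alone and contribute only pooled coverage c_short;
  long libraries (L > s) contribute endpoint pairs — their endpoints form a
  Poisson process of rate λ = ΣN_i/G per bp around ζ, so the pair event has
  probability Γ₂(λ·s), independent of the long lengths. For m = 1:
  P = (1 − e^(−c_short)) + e^(−c_short)·Γ₂(λs); for m = 2 the first term
  additionally requires a second spanning insert from any library. This
  reproduces the three classical regimes of a two-length design and reduces
  exactly to P_detect of the pooled coverage when s ≥ L₂.

These expressions are exact under the Poisson model; the Monte-Carlo oracle
(10⁵ trials, three-standard-error bands, sweep over c ∈ {0.2, 1, 5, 16} and
s/L ∈ {0.1, 0.5, 1, 2}, both m values, single and mixed libraries) certifies
them in the test suite, and is the arbiter wherever a transcription of the
algebra could be doubted.

### Optimal mixes

Within the model, an insert shorter than s is dominated by one of length
exactly s (coverage per insert) and an insert between s and the maximum
available length is dominated by the maximum (endpoint density is
length-independent; detection coverage grows with length). The optimal
design therefore mixes exactly two lengths, {s, L_max}. `optimal_mix` grid
searches the split N₁ ∈ [0, N] (default step N/1000, endpoints included,
plus a bounded continuous refinement); the brute-force three-length search
in the acceptance tests confirms no three-length allocation beats it. The
mixing boost is a two-insert-rule phenomenon: under m = 1 a pure s-length
library is already optimal, under m = 2 the theoretical boost at the point
where a single library resolves 15% is ~2.4×, above the ~2× observed on
empirical data (real mapping variation erodes the gain).

### Simulator conventions

Length jitter is Normal(L, σ) truncated at 1 bp by resampling; candidate
inserts are drawn in a window of L + 7σ upstream of ζ so that no spanning
insert is missed. Ambiguity uses the empirical per-insert rule
l − (x_l + x_r) averaged over spanning inserts, which equals the width of
the interval between the right-most left endpoint and the left-most right
endpoint. Comparisons of simulated ambiguity against a target s use an
absolute 10⁻⁶ bp guard for floating-point ties (exactly at s = L a lone
spanning insert resolves by definition). Standard errors are normal
approximations. Planted-SV testbeds flag SVs with l ≤ L as inadmissible for
that library (the insert-size constraint l > L) instead of counting them as
misses.

## Transcript depth planning

### Estimation pipeline

ν values from a pilot are binned into 50 log-spaced bins (per-bin mass =
fraction of observed transcripts). The power-law slope α and intercept
log β are an unweighted OLS fit of log(mass/width) against log(bin center)
over occupied bins above the high-expression threshold, default 10·ν_r —
inside the provably well-sampled regime for any pilot size. For log-spaced
bins the geometric-center density of an exact power law differs from the
bin-average density by a constant factor, so the slope is recovered exactly
and only the intercept carries a (harmless, constant) bias. Weighted
regression was considered and not adopted; recovery of α within ±10% across
seeds at 10⁶-read pilots was verified with the unweighted fit.

The noise model f(ν) ∝ (ν + δ_D)^(−α) flattens below δ_D and matches the
power law above it. Its two free parameters are identified by:

- **Normalization:** continuity with the high-expression fit, C = e^(log β).
  Anchoring C instead to the bins immediately above ν_r was rejected: those
  bins are inflated by Poisson migration of sub-ν_r transcripts, which
  biased δ_D high by ~1.7× and detection predictions high by ~7 points. The
  near-ν_r least-squares anchor remains as a fallback when no intercept is
  available.
- **δ_D:** conservation of total expression. The ν of all transcripts sum
  to 1; the reliably observed transcripts (ν ≥ ν_r) carry a read mass R
  measured directly from the pilot, so the model tail must integrate to
  1 − R. This one-dimensional balance is solved by bracketed root-finding
  in δ_D ∈ [0, 1]. A shallow pilot's ν_r sits above the noise floor, so the
  curvature of the histogram carries no information about δ_D — the read
  mass balance is what identifies it. If the balance is unreachable inside
  the family the nearest boundary is used (pure power law or flat tail)
  with a warning.

The corrected p.d.f. keeps empirical mass at bins ≥ ν_r (the splice
preserves the empirical shape there up to the single renormalization
constant), replaces bins below ν_r with model mass, extends the grid down
to ν_min, and renormalizes. ν_min defaults to 1/(10·target depth) when a
target depth is given — covering everything detectable at the depths under
study — and ν_r/1000 otherwise. Mass below ν_min is genuinely outside the
model's support; predictions at depths approaching 1/ν_min should be read
as slight over-estimates (the package's own validation budgets 5 percentage
points for this).

The reliable point is the closed form ν_r = 1 − 0.05^(1/r). The alternative
of locating the inflection of the log-log histogram is exposed in the CLI
(`--threshold-mode inflection`), implemented as the mode of the log-binned
histogram — undersampling makes the histogram peak where reliability sets
in. The closed form is the default.

At the very low-abundance extreme an empirical full-data histogram can show
a drop-off that may itself be a sampling artifact; the correction trusts
the model there by default, which is the appropriate choice whenever the
pilot cannot rule the artifact out.

### Synthetic transcriptome

The generator draws raw expression values by inverse-transform sampling
from the same (x + δ_D)^(−α) family, truncated to [ν_floor, 1] with
ν_floor = 10⁻⁸ (the pure power law is non-normalizable at 0), then
normalizes the vector to sum 1. Defaults — 20 000 transcripts (a
Refseq-scale catalogue), α = 2 (typical of mammalian expression surveys),
δ_D = 10⁻⁴ pre-normalization (an effective noise floor near 6×10⁻⁶ after
normalization, i.e. between the reliable points of 10⁵- and 10⁶-read
pilots) — are chosen once to emulate a bulk mRNA-seq tissue survey. Reads
are multinomial at the requested depth; subsampling an existing run is
hypergeometric (without replacement). The generator reproduces power-law
abundance with a noise floor and sampling noise but none of the biases of
real library preparation (3'/5' depletion, length and GC effects, platform
preferences for small RNAs), so passing tests demonstrate correctness of
the sampling mathematics, not robustness to such biases; on real data those
biases fold silently into ν.

Normalization makes concentration *decrease* with α in this family: a
shallow slope leaves a heavy high-expression tail whose few transcripts
absorb most of the read mass (Gini falls as α rises).

### Numerical choices

Poisson tails and Γ₂ use the regularized incomplete gamma; detection
probabilities use expm1/log1p throughout, so probabilities stay accurate at
both ends (a coverage beyond ~36 saturates to 1 in double precision).
`required_inserts` inverts the m = 2 detection formula by Brent's method to
one-insert tolerance; `required_depth` bisects on integers after geometric
bracketing. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; equal seeds give bit-identical results.

### Problem sizes

The validation suite runs at desk scale: 10⁵ Monte-Carlo trials per
configuration for oracle certification, 10⁵–10⁶-read pilots of a
20 000-transcript synthetic transcriptome (ten seeds for parameter
recovery), and brute-force mix searches on 21-point allocation grids. These
sizes leave the certification bands (3 SE) far tighter than the effects
being tested.

### Known limitations

- The SV calculus prices breakpoint *detection*, not event calling: paired
  or multi-breakpoint events (inversions, translocations) multiply the
  per-breakpoint answer, and novel-insertion events with no reference
  counterpart are out of scope.
- Mapping ambiguity is a single scalar f; region-specific repeat structure
  is not modelled.
- The noise-model family is one two-parameter choice; it is isolated behind
  `correct_pdf` so an alternative low-abundance law can be swapped in.
- Cross-sample prediction assumes the expression law transfers between
  samples; when the source law has a thinner low-expression tail than the
  target the prediction is systematically optimistic at high depth.
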