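# Methods

## Model

A two-condition enrichment experiment measures, per gene `i` and replicate,
a log2 enrichment value.  The Mock (no specific antibody / untagged strain)
measures non-specific background; the IP superimposes true binding on that
background:

```
Mock replicate:  M_i + c_M
IP replicate:    M_i + T_i + Z_i + c_IP ,   T_i >= 0,  E[Z_i] = 0
```

The per-replicate constants `c` are unobservable additive offsets (dye,
scanner, amplification, library depth).  Only `c_IP − c_Mock` matters for
testing IP against Mock, so the Mocks are anchored by median-centering each
Mock column and all remaining estimation targets the IP constants relative
to that anchor.

Because `T >= 0`, a gene strongly enriched in the Mock *relative to* an IP
replicate is almost surely background for that replicate.  The estimator
therefore ranks the per-gene differences `reference − replicate`
(reference = a Mock average) in descending order, takes the top `k` genes
as the background set `S_k`, and aligns the replicate with the reference on
that set.

## Estimators

Given `S_k`, three variants of the constant are available:

- `set-median` (default): `median(reference on S_k) − median(replicate on
  S_k)` — align the medians of the background set.
- `set-mean` / `orderstat-mean`: `mean over S_k of (reference −
  replicate)`, i.e. the average of the top-`k` difference order statistics.
  (The two names denote the same quantity, since the mean is linear; both
  are kept because users think of it both ways.)

With `S_k` = all genes, `set-median` degenerates to classical pairwise
median normalization — the baseline comparator (`median_normalize`).

## Bias cancellation and the reference policy

Selecting the top `k` order statistics biases any such constant upward
(the selected genes have unusually favorable noise).  The remedy is to push
every Mock replicate through the *identical* machinery against the average
of the other Mocks (its leave-one-out average), producing Mock constants
that carry the same selection bias; the bias cancels in the IP-vs-Mock
comparison a t-test performs.

The cancellation is only exact if the IP and Mock difference profiles have
the same sampling distribution.  Referencing an IP against the average of
all `m` Mocks gives a difference variance of `σ²(1 + 1/m)`, while a Mock
against its leave-one-out average has `σ²(1 + 1/(m−1))`; at `m = 3` that
mismatch leaves a residual background bias of about −0.15 enrichment units
in the simulation conditions below.  The package therefore defaults to the
`matched` reference policy: each IP replicate is fitted against *each*
leave-one-out Mock average and the constants are averaged.  Every IP fit is
then distributed exactly like a Mock control fit (one replicate vs an
average of `m−1` others), and under an all-background null the bias cancels
identically at any replicate count — measured null bias ≈ 0.00 at n ∈
{500, 2000, 6000}.  The `pooled` policy (single fit against the average of
all Mocks) is retained as an option; its reference is slightly less noisy
but its bias cancellation is only asymptotic in `m`.

With targets present the cancellation is intentionally imperfect in one
direction: targets shrink the IP profile's effective background pool, so
the IP constants are selected at a slightly deeper quantile than the Mock
controls and `c_IP − c_Mock` is *under*-estimated.  At 10% targets this
residual is ≈ −0.05 enrichment units; at 50% targets ≈ −0.3.  The sign is
the safe one — enrichment is understated, never overstated — and the
package's conservativeness test verifies it (estimate below truth in 197 of
200 replications at 50% targets).

## Choosing k

The descending difference curve (value vs rank) has a steep nonlinear head
— the extreme order statistics of the background — followed by an
approximately piecewise-linear stretch.  `select_k` slides a linear fit of
width `min_segment` (default 500 ranks, the minimum knot separation that
holds on genome-scale data) along the curve and selects the smallest
candidate rank `k` such that every window starting within `min_segment`
ranks of it reaches `R² ≥ r2_min` (default 0.995).  Properties: the
selection is invariant to shifting and positive scaling of the curve, and a
stricter `r2_min` never selects a smaller `k`.  Defaults for the candidate
range are `k_min = min_segment` and `k_max = 0.9 · n_genes` (keeping a tail
of potential targets out of the background set).  If no candidate
qualifies, the candidate with the best worst-window fit is used and a
warning is logged.  For small panels (`n < 2 · min_segment`) the window is
scaled down to `n/4` with a warning; selection quality degrades gracefully
(the constant estimates remain unbiased under the matched policy — the
choice of `k` affects variance and the contamination bias, not the null
bias).  On simulated normal-background curves with these defaults the
selected `k` lands around ranks 500–900 of 6,000.

Flat windows (zero variance) count as linear: a constant difference profile
is the pure-shift case and any `k` gives the same constant.

## Enrichment testing

`sam_statistic` computes the moderated statistic
`d_i = (mean_IP − mean_Mock) / (s_i + s0)` with `s_i` the pooled two-sample
standard error and `s0 = median(s_i)` (configurable).  This deliberately
simplifies the classical moderated-t machinery — no coefficient-of-variation
tuning of `s0`, no asymmetric cutoffs — because the package's contribution
is the normalization; the moderated structure is what matters for comparing
normalization methods.  Calling is one-sided (IP > Mock), consistent with
`T >= 0`.

`permutation_fdr` sweeps thresholds down the observed statistics.  All
distinct condition-label assignments are enumerated when there are at most
`n_permutations` of them (a 3v3 design has 19 besides the observed one),
otherwise assignments are sampled with the seed.  At threshold `t` the
estimated FDR is (expected false calls)/(observed calls), and a gene is
called when any threshold at or below its statistic meets the requested
FDR.  The expected-false estimator (`numerator`) defaults to `envelope`:
one plus the *largest* per-permutation exceedance count.  Rationale: with
very few distinct assignments, the distribution of a location summary
(median or mean) of the per-permutation counts at the top threshold is
dominated by a single exchangeability event — whether the observed maximum
outranks the permuted maxima — and it collapses to zero for a large
fraction of all-null datasets, calling a spurious single top gene at any
FDR threshold.  The envelope-plus-one estimate can never report zero, which
makes single-gene call sets unreachable at small `B` and leaves multi-gene
call sets essentially unaffected (measured on saturated 5v5 simulations:
envelope calls within a few genes of the pooled estimator and of
Welch+Benjamini–Hochberg).  `median`, `mean`, and `smoothed` (pooled counts
with add-one) are available for users who prefer the textbook estimators.
`welch_t_test` (one-sided Welch + BH) serves as an independent cross-check
route throughout the test suite.

## Simulators

`simulate_ip_experiment` draws the idealized validation experiment:
background genes N(0, 1), targets N(3, 1) (defaults), 6,000 genes, 10%
targets, 3 IP + 3 Mock replicates, and independent Uniform(−2, 2) offsets
per replicate so constant recovery is non-trivial.  These defaults are the
study conditions every headline number in this repository refers to.
`simulate_mock_mock` emulates the false-target control: six background
replicates sharing a per-gene random level (sd 1, so replicates correlate
like biological replicates of one sample), split 3-vs-3 into sham "IP" and
"Mock" groups.  `counts_to_logmatrix` adapts sequencing data: bins with a
zero count in IP, Mock, or the optional total-RNA reference are dropped (no
pseudocounts — zeros carry no usable enrichment information under this
model), reference division absorbs sequencing bias, and values are log2
transformed.

What the simulators do *not* emulate: intensity-dependent (curved) dye
bias, heteroscedastic per-gene variances, correlated gene blocks, and
multiplicative (non-additive) distortions.  Passing tests therefore
demonstrate correctness of the estimator under the additive model, not
robustness to every artifact of real arrays; on real data the rank plots
(`rank_plot`, `constant_vs_k_curve`) are the intended diagnostics.

## Numerical choices

- Ties in the difference ranking are broken by input gene order (stable
  sort) for determinism.
- Window R² uses exact cumulative-sum identities; zero-variance windows are
  defined as R² = 1.
- Degenerate genes with zero mean difference *and* zero scatter get
  `d_i = 0` rather than 0/0.
- Shift invariance of the whole pipeline (adding a constant to one
  replicate, or a common constant to all Mocks, changes no normalized
  value) holds to ~1e-9 rather than bit-exactly: medians of even-sized sets
  average two floats.
- Matrices are written with 6 significant digits; write→read→write is
  byte-idempotent.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use Monte-Carlo replication
counts chosen to make the standard error small relative to each check's
tolerance: 400 replications for the background/target recovery averages
(sem ≈ 0.006 against a ±0.05/±0.1 band), 200 for the conservativeness sign
test, 100 for the Mock-vs-Mock false-positive rate, and 4,000 in the
acceptance script (sem ≈ 0.002).  The background-recovery average is the
one quantity that sits near its band edge (−0.05, the contamination
residual discussed above); all others pass with wide margins.

## Known limitations

- Additive model only; multiplicative distortions must be handled upstream
  (log transformation is assumed, not checked).
- At least two Mock replicates are required; the leave-one-out construction
  is the heart of the method, not an optional extra.
- The permutation FDR needs enough replicates for distinct label
  assignments; a 2v2 design has only 5 usable assignments and the envelope
  estimator will be very conservative there.
- `k` selection assumes genome-scale gene counts; below ~1,000 genes the
  window scaling keeps it running but the piecewise-linearity signal is
  weak and the fallback path (best worst-window fit) is common.
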