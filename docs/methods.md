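# Methods

## Coordinate conventions and the study region

Spot positions are standardized post-alignment pixels in a bounded
rectangle: `x_px` along the proximodistal axis (0 at the wrist, default
extent 1200 px), `y_px` mediolateral (default 300 px). The axis is divided
into `n_segments` (default 4) equal half-open intervals, with `x = L`
closed into the last segment so segment occupancies always sum to the
table size; segment 1 is wrist-adjacent. `px_to_mm` (default 0.33 mm/px)
is a display-only conversion: all analysis is carried out in pixels, the
native unit of the aligned images. (Taken literally, 1200 px × 0.33 mm/px
would be an implausibly long forearm, which is why the pixel axis is
treated as an abstract standardized scale rather than a physical length.)
Forearm curvature and non-rectangular arm silhouettes are ignored; the
region's area and perimeter enter the edge-corrected statistics below, so
results for real data depend on how that rectangle is chosen.

## Confirmation and taxonomy

A candidate spot exists only after a positive identification report
(sweep 0). Up to four confirmation sweeps follow; the loop terminates at
the first positive report, and a positive report of *either* quality
confirms the spot. Classification is over positive reports only
("none" responses are ignored), with cross-block responsiveness dominating:

1. positive reports in both the cooling and warming block, or two positive
   reports that disagree → **inconsistent**;
2. all positive reports agree and match the block polarity → **cold** /
   **warm**;
3. all positive reports agree but contradict the polarity → **incongruous**.

These rules are exhaustive and mutually exclusive over every log the
procedure can produce; the test suite proves this by brute-force
enumeration of all sequences with ≤ 5 trials per block against an
independent rule-by-rule oracle. Category percentages are computed over
confirmed spots and rounded half-away-from-zero to integers. Per-participant
summary SDs use the n−1 denominator; with a single participant the SD is
reported as 0 with a degeneracy flag.

## Uniformity test

The Anderson–Darling statistic is computed in its fully specified ("case
0") form on coordinates affinely rescaled to (0, 1); values landing exactly
on a bound are nudged inward by machine epsilon with a warning. Samples
smaller than 3 are refused; the pipeline additionally excludes participants
with fewer than `exclusion_min_n` (default 10) confirmed spots from this
test only — too few points cannot constrain a distribution — while their
aggregation index is still reported.

p-values default to parametric Monte Carlo (10⁴ seeded uniform replicates,
`p = (1 + #{A²* ≥ A²})/(B+1)`), which is exact up to simulation error at
any n and avoids special-function edge cases. An asymptotic alternative
uses the Marsaglia–Marsaglia approximation to the limiting null CDF with
their finite-n correction; the suite checks the two routes agree to ~0.02
and that null p-values are uniform (KS distance < 0.05 at 2000 replicates).

## Aggregation test

Clark–Evans R compares the mean nearest-neighbour distance r̄_obs with its
expectation under complete spatial randomness. Uncorrected,
r̄_exp = ½√(A/n) and Var(r̄) = (4−π)A/(4πn²); in a bounded region this
overstates regularity because boundary points have artificially distant
neighbours, which makes the uncorrected z test anticonservative (≈ 15%
empirical size at n = 100 in the unit square). The Donnelly correction

    r̄_exp = ½√(A/n) + (0.0514 + 0.0412/√n)·P/n
    Var(r̄) = 0.0703·A/n² + 0.037·P·√A/n^{5/2}

(A area, P perimeter) restores calibration: the suite verifies mean R ∈
[0.98, 1.02] and empirical size 5% ± 2% over 1000 CSR replicates, which is
also what pins down the numerical constants rather than taking them on
trust. Ties in nearest-neighbour distances are unproblematic because only
distances, never neighbour identities, enter the statistic. Coincident
points give r̄_obs = 0 and hence R = 0. The z test is two-sided.

Both spatial tests pool each participant's confirmed spots across all
sessions; unconfirmed spots are excluded from every spatial and
conservation analysis.

## Conservation

All cross-session pairs of confirmed spots (same participant) with
Euclidean distance **strictly** below the threshold (default 6 px = 2 mm,
twice the stimulator wire diameter) are enumerated — by-threshold matching,
not one-to-one assignment, so no tie-breaking is needed. Matched spots form
connected components; the largest component size and the number of
distinct sessions it spans are reported. Because "re-identified" is
ambiguous about whether both members of a pair count, both conventions are
always computed: *component* (every member counts; an isolated pair is 2)
and *reidentification* (later-session members only; a pair is 1).
Category agreement is component-wide: a spot counts as agreeing only if
every spot in its chain carries the same category.

## Synthetic generator

The generator emulates the structure the analysis assumes, with defaults
chosen to resemble the study conditions; each default is a modelling
choice, not a fit:

| parameter | default | rationale |
|---|---|---|
| region | 1200 × 300 px | standard proximodistal extent; plausible arm width |
| n_participants / n_sessions | 8 / 4 | study design |
| process | thomas | standard two-parameter cluster process, smooth and interpretable |
| kappa (parents/px²) | 7 × 10⁻⁶ | with mu below, ≈ 10 spots per participant-session, ≈ 40 pooled |
| mu (offspring/parent) | 4 | few spots per cluster |
| sigma_px (cluster scatter) | 10 px ≈ 3.3 mm | tight aggregation, R ≪ 1 |
| gradient_weight | 1.0 | wrist density ≈ 2× elbow density (linear ramp, a convenience form) |
| persistence_rho | 0.03 | conservation of a few percent |
| jitter_tau_px | 2 px | repositioning error well inside the 6 px criterion |
| birth_rate | 10 | births ≈ deaths: roughly stationary session sizes |
| quality_reliability_q | 0.7 | inconsistent fraction 2q(1−q) ≈ 0.4 of confirmed |
| miss_rate_m | 0.45 | unconfirmed rate m⁴ ≈ 4% |
| p_cold_afferent | 0.73 | cold:warm ≈ 112:41 |

Parent intensity is modulated along x by `1 + w(1 − x/L)`; offspring and
CSR points outside the region are discarded (window simulation — clamping
would pile points on the boundary and bias the edge-corrected statistics),
and between-session jitter resamples until in-region for the same reason.
Each spot is tested in the block matching its true afferent quality (it
was, by construction, discovered during that block's search); the
identification report is always positive but reports the true quality only
with probability q, and the simulated confirmation loop mirrors the
experimental stopping rule, so synthetic logs are structurally identical to
real ones. All randomness derives from the single config seed through fixed
per-participant/session/stream sub-seeds; generated tables are reproducible
byte for byte.

What the generator does **not** emulate: amplitude-dependent detection
(more spots at ±4 °C than ±2 °C), spatially varying skin temperature,
tactile–thermal interactions, inter-participant variability in spot counts
beyond Poisson fluctuation, and non-rectangular arm geometry. Passing the
synthetic calibration suite therefore shows the *machinery* is correct and
calibrated, not that the generative model captures real skin.

## Reference table

`thermospot.studydata` rebuilds a table from the published marginal
summaries: per-participant confirmed totals, category totals, per-condition
totals and per-segment totals. Only these marginals (and statistics derived
from them — the 34/12/49% mix, the 14.00/5.13/20.63 participant means, the
4.3% unconfirmed rate, the 10.44 and 23.25 per-session-condition means) are
faithful; the joint participant × category × session × segment allocation
is not published and is filled by a deterministic north-west-corner
convention. Consequently per-category participant SDs and anything
location-dependent (coordinates are laid out specifically so that no two
cross-session spots fall within the conservation threshold) must not be
read off this table. Participant-level aggregation indices from the
original data are likewise not reproducible from printed summaries alone,
because they require the deposited coordinates and the exact region
geometry.

## Numerical and design notes

- Problem sizes in the calibration suites (e.g. 1000 CSR replicates at
  n = 100, 2000 replicates for p-value uniformity, two-session persistence
  recovery at ≈ 600 spots per arm) were chosen to keep Monte-Carlo error
  well below the asserted tolerances while the full suite runs in seconds.
- The persistence-recovery check uses a two-session design with the birth
  rate set to ρ-compensate session sizes, for which the component-convention
  conservation rate has the closed-form expectation 2ρN₁/(N₁+N₂); with
  more sessions the component convention counts middle-session spots once
  per chain membership and the simple binomial expectation no longer holds.
- CSV round trips write floats with `repr`, so read(write(t)) is exact and
  output is byte-stable under fixed field ordering.
- Unknown category strings are rejected at validation, never coerced.
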