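# Methods

## Scope and data model

The unit of analysis is a (SKU, geography, month) record: nominal pack
price, pack content (sticks for factory-made cigarettes, grams for
roll-your-own tobacco), sticks sold, and the percentage of retailers
stocking the product. Months are 1-based integer indices anchored at a
base calendar month (default May 2015; the standard window is months
1..36). All windows are closed integer intervals, which removes date
arithmetic from the analysis entirely.

## Tax engine

Duty regimes are step functions of the month index. FM excise per 1,000
sticks is `specific + advalorem * retail_price_per_1000`; when a Minimum
Excise Tax is in force the duty is the larger of this and the floor, which
makes FM excise continuous and non-decreasing in price, constant at the
floor below the crossover price `(floor - specific) / advalorem` per 1,000.
RYO duty is the per-kg rate times the stick weight; the same 0.5 g/stick
constant converts pouch prices to per-stick prices, so per-stick duty and
per-stick price are mutually consistent. VAT defaults to the statutory
treatment, `price * r / (1 + r)` of the gross price with r = 0.20; a
`vat_mode="gross"` switch instead takes VAT literally as 20% of the pack
price, since published rate tables sometimes label VAT as a percentage of
pack price and the net-revenue convention used with commercial data is not
always stated. Net revenue is the residual, so
`price = excise + VAT + net revenue` holds to machine precision by
construction.

Mid-month budget changes are snapped to the following full month by
default (`snap="same_month"` applies them from the budget month): with
monthly data the budget month itself is mostly priced under the old
regime. This convention also fixes the semantics of the shifting analysis
(below): the "event month" is the budget month, still under the old duty.

Taxes are computed on nominal prices in the month of sale and the
resulting price and net revenue are each deflated to base-month money by
dividing by a monthly index (base value pinned to exactly 1.0). Deflating
first would be wrong: duty is levied in nominal terms, and in particular
the MET branch depends on the nominal price. A test pins this ordering.
Published inflation tables typically give 12-month percentage changes, not
the monthly index, so the index is a user input;
`InflationIndex.from_annual_rate` builds a geometric stand-in.

## Inclusion rules

Records with missing distribution are excluded first. A (SKU, month) must
reach the 10% distribution threshold (inclusive) both UK-wide and within a
geography: the UK-level figure is the volume-weighted mean of the area
figures (the weighting is an assumption -- sources describing such filters
do not state one), and failing it removes the (SKU, month) everywhere,
while an individual area below the threshold loses only its own row.
Kept + dropped-missing + dropped-below always equals the input count, and
the filter is idempotent. Segment labels come from an exact-string brand
variant map; unmapped variants fall into "no segment".

## Trend model

Response: real price per stick, or real net revenue per stick. The mean is
`alpha + f_k(t) + beta_j + gamma_k` with dummy-coded geography and segment
effects (first level in sort order is the reference, configurable) and one
smooth per segment.

* **Basis.** Cardinal natural cubic splines on `basis_dim` (default 10)
  evenly spaced knots over the segment's observed months, with the exact
  integrated-squared-second-derivative penalty (rank k-2, affine null
  space). If a segment has fewer distinct months than `basis_dim` the
  basis shrinks to that count with a logged warning. Each smooth is
  constrained to sum to zero over the segment's observed months (null
  space reparameterization), so `gamma_k` is the segment's mean level and
  the intercept is identified.
* **Errors.** Stationary AR1 within each SKU-by-geography series
  (configurable to SKU-only grouping, since descriptions of such data
  vary). Records are stably sorted by (sku, geography, month). Whitening
  is exact: the first observation of a series enters as is, later ones as
  `(x_t - rho^g x_{t-g}) / sqrt(1 - rho^{2g})` with g the month gap, the
  natural AR1 treatment of unbalanced series.
* **Estimation.** Penalized least squares on the whitened data. Smoothing
  parameters minimize the Gaussian REML score
  `(n - M_p) log(sigma_hat^2) + log|V_rho| + log|X'X + S_lambda| - sum_k
  r_k log(lambda_k)` (profiled error variance; `M_p` = penalty null-space
  dimension; `log|V_rho|` the AR1 log-determinant), optimized over
  log-lambdas by L-BFGS-B. rho is profiled on top by a bounded scalar
  search of the same score (so values are comparable across rho), bounds
  (-0.5, 0.995), tolerance 1.5e-3 -- comfortably finer than the +-0.02
  accuracy the recovery study asks of rho. Both rho and the lambdas can
  instead be fixed; fixing all lambdas to zero drops to plain (whitened)
  least squares via a numerically safe lstsq path, which is also the
  oracle route used in tests.
* **Uncertainty.** The coefficient covariance is the Bayesian posterior
  `sigma^2 (X'X + S_lambda)^{-1}`. Confidence intervals for every derived
  quantity are computed by drawing coefficients from N(beta_hat, V),
  applying the (linear) summary operator per draw, and taking 2.5/97.5
  percentiles. The covariance factorization tolerates semi-definiteness
  up to a 1e-10 jitter bound and errors beyond it.
* **Model comparison.** AIC is `-2 loglik + 2 (edf + k)` with the GLS
  profile likelihood (including the AR1 log-determinant), `edf = tr((X'X +
  S)^{-1} X'X)`, and k counting sigma and (if estimated) rho. The linear
  variant replaces each smooth with a centred per-segment slope and is
  fitted by the same machinery, so the two AICs are directly comparable.

Degenerate inputs: duplicate months within a series are rejected (no AR1
correlation is defined at zero gap); segments need at least four distinct
months; unknown factor levels at prediction time raise.

## Summaries

Weighted average price for a stratum-month is `sum_i share_i * fitted_i`
with market shares from observed volumes in that month (time-varying
shares; a fixed-weight variant freezes each SKU at its average volume).
Zero-volume stratum-months are omitted with a warning. Gaps difference two
strata per draw, so cross-stratum coefficient correlation propagates and
gap intervals are never wider than independent differencing would give.
Mean monthly growth over a closed window is the endpoint difference over
the window length minus one (identical to the mean of successive
differences); pre/post comparisons difference the two growth draws. The
shifting analysis takes net revenue h = 1..5 months after a budget month
minus the budget month itself (which is still under the old duty, per the
snapping convention), in pence per stick; an interval entirely below zero
is undershifting, entirely above overshifting, otherwise indeterminate.
Default draw count is 10,000.

Default forest-plot windows are months 2-11 and 26-35 (June-March before
and after full implementation); the alternative post-window 14-23
(June 2016 - March 2017) used for RYO comparisons in some presentations is
available via configuration.

## Synthetic data generator

The generator emulates the features of commercial EPOS panels the model
relies on, with every default chosen once:

* 8 segments (25 SKUs each, 200 total) with May-2015-realistic per-stick
  base prices: FM 46.5/40.5/34.5/30.5p, RYO 20.5/18.5/16.5p, "no segment"
  17.5p (RYO combi packs); premium > midprice > value > subvalue ordering
  is validated.
* 11 geographies with fixed level offsets (default evenly spaced over
  +-1p) and a common trend shape -- levels differ, trends do not.
* Segment trends are monotone-cubic (PCHIP) interpolations of
  (month, offset) knots, so they are smooth in the sense the spline model
  assumes; the default is a gentle ~1.5p rise over 36 months.
* Price noise is stationary AR1 per (SKU, geography) with rho = 0.98 and
  innovation sd 0.002 GBP/stick (marginal sd about 1p).
* Volumes are lognormal with a persistent level per (SKU, geography)
  (mu = 10, sd = 1 on the log scale) and month-to-month jitter sd 0.2:
  right-skewed across SKUs, stable in time. Early iterations drew volumes
  independently each month, which made market shares implausibly volatile
  and the weighted series noisy in a way real panels are not. The
  lognormal family itself is an assumption; no distributional form is
  published for such data.
* 10% of SKUs are narrowly distributed (below the 10% threshold), 0.2% of
  distribution values are missing, and 10% of SKUs enter late or exit
  early, so the panel is unbalanced like real EPOS data.
* Tax events add `duty_increase * passthrough(segment)` to per-stick
  prices from the event month onward; pass-through below 1 constructs
  undershifting ground truth, above 1 overshifting.
* Determinism: one root seed; per-SKU substreams are spawned from it, so
  panels are byte-identical across runs and adding a segment leaves
  existing SKUs' draws untouched.

What the generator does *not* emulate: store-sample scale-up, demand
response to price (volumes are independent of price; an elasticity hook is
deliberately not implemented), seasonality in volumes, price-marked packs,
or entry of genuinely new products mid-period. Passing recovery tests on
this generator therefore demonstrates the estimator's correctness under
its stated assumptions, not robustness to those real-data features.

## Simulation study sizes

The test suite runs its studies at sizes chosen to give adequate power on
a single CPU: parameter-recovery coverage uses 25 replicates of the
default 200-SKU panel (425 pooled interval checks; a binomial 95%
interval at that count is about +-2pp wide, well inside the +-5pp
acceptance band), the smooth-vs-linear AIC study 50 replicates of a
smaller two-segment panel with strongly nonlinear trends, and the
whitening diagnostic three seeds of a three-segment panel. The shifting
scenario uses one knot per month (basis_dim 36): a budget event is a
one-month step, and coarser bases visibly ring around it, smearing the
month-after-event deltas the analysis reads off.

## Known limitations

* Smoothing parameters are selected by exact Gaussian REML but the outer
  rho search assumes a unimodal profile; in pathological data a bounded
  grid (the `rho_bounds` argument) should be checked.
* The AIC definition is internally consistent but, like any such choice,
  not comparable across software with different likelihood constants.
* With near-unit-root errors (rho close to 1) level information accrues
  slowly; fixed-effect standard errors on short panels are honest but
  wide.
* The sum-to-zero constraint makes smooths comparable across segments
  only over each segment's own observed months; for segments observed on
  very different month sets the gamma_k comparison inherits that caveat.
* Negative net revenue is possible (and realistic at MET-floor prices);
  it is flagged, not clamped.
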