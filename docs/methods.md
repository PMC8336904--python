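# Methods

## Model

The core is a demographically extended (type-IV) input–output model. Writing
`A` for the domestic technical-coefficient matrix, `w_x` for wages per unit
of output, `l_d` for jobs per million euros of output, `c_E`/`c_U` for the
employed/unemployed consumption-coefficient vectors and `w_U` for the annual
benefit per unemployed person, the closed system matrix is

    M = I − A − c_E w_x + c_U w_U l_d.

The sign on the unemployment term is positive: with a fixed labour force,
an output increase raises employment, *removes* benefit-financed consumption
and replaces it with (larger) employed consumption. The equilibrium
constant term is the algebraically complete `c^D + f^O + c_E y_S + c_U w_U p`
— the `c_E y_S` term (consumption financed by employed households' exogenous
income) is required for the three balances (supply–demand, income,
demographic) to hold simultaneously, which the test suite verifies against a
dense solve of the full `(n+2)×(n+2)` block system. The term cancels in the
shock-impact difference, so `x^D = M⁻¹ c^D` either way.

Linear systems are solved by LU factorisation (`numpy.linalg.solve`); the
extended inverse is exposed only as a diagnostic. Assembly fails loudly if
the condition number of `M` exceeds 1e12. Zero-output sectors get zero
coefficients and ride inertly through every solve. No non-negativity is
imposed on `x^D`: negative sectoral impacts are legitimate consequences of
co-payment offsets.

### Employment decomposition

The direct/indirect/induced split uses the standard telescoping convention:
direct = `diag(l_d) c^D`, indirect = `diag(l_d)((I−A)⁻¹ − I)c^D`, induced =
`diag(l_d)(M⁻¹ − (I−A)⁻¹)c^D`. Other conventions exist (e.g. attributing
first-round consumption effects differently); this one guarantees the three
components sum exactly to the total and reduces correctly in the degenerate
closures (`A = 0` kills indirect, `c_E = c_U = 0` kills induced).

### Benefit shocks

* **In-kind / CBPA**: gross cost (public + co-payment) is injected into the
  care sector; the co-payment is withdrawn from the dependent consumption
  basket using the dependent profile as weights. The purchaser-basis vector
  sums to the public spend. No household budget constraint is imposed on the
  offset (a warning is logged when the co-payment exceeds the public spend).
* **CBIC**: treated as household income; the full cost is spent through the
  dependent profile with no negative offset. A policy flag
  (`include_copay_offset`) switches to the formal-care treatment for
  sensitivity analysis.
* **Price conversion** runs in a fixed order — product taxes off, margins
  stripped and credited to the trade/transport sectors, import share off —
  and is linear, so it commutes with combining shocks. The care-sector
  injection is exempt: personal services carry no trade margins and are
  domestically produced. Only the profile-distributed components pass
  through the bridge.

### Counterfactual

`exclusive_in_kind` rebuilds the entire baseline budget as one in-kind
benefit. The public/co-payment re-split of the cash benefits is not uniquely
determined by the policy question, so it is a flag: `keep_ratio` (default)
preserves the baseline aggregate split; `all_public` treats the whole budget
as public spending. Multiplier normalisation is likewise configurable
between total benefit cost (default) and public spend only — both bases are
meaningful, and published per-million figures for different benefit types
are consistent with different bases.

## Synthetic data

The generator emulates the *structure* of a 16-sector open economy of the
kind the model is applied to, not the magnitudes of any particular country.
Features and defaults:

* **Productive coefficient matrix.** A random positive matrix is rescaled to
  the target spectral radius (default 0.6), so the Hawkins–Simon condition
  holds by construction; a rejection loop guards the (vanishingly rare) case
  of a column sum above 0.92. Columns and rows are sector-typed: the first
  third of sectors are "goods" (intermediate-input-heavy columns,
  materials-dominated rows, ~70% of their inputs from other goods sectors),
  the rest services (input-light); the care sector buys least of all.
* **Consistent accounts.** Gross output solves `x = (I−A)⁻¹ f` from a
  positive final-demand draw, so flows, output, final demand and positive
  value added are mutually consistent. Value added splits into wages (share
  drawn from `wage_share_range`, default 0.45–0.60), employer social
  contributions (0.24 × wages), net production taxes (2% of value added) and
  a strictly positive operating surplus; configurations that would force a
  negative surplus are rejected.
* **Labour intensities** (jobs per million euros) are drawn from
  `labour_intensity_range`, default (2, 20), spanning the realistic range
  from energy/real estate (~2) to hospitality (~20). Goods sectors draw from
  the lower part (capital-intensive), services from the upper. The care
  sector draws 2.1–2.7× the range midpoint and the real-estate analogue
  0.1–0.25×: formal care sustains roughly twice the economy-average jobs per
  euro, while real-estate value added is almost entirely gross operating
  surplus. These two features are what make cash-for-informal-care spending
  (which flows through the household basket, heavily into real estate)
  job-poor and GOS-rich relative to formal-care spending, the central
  contrast of the analysis.
* **Profiles.** The dependent profile places at least `necessity_skew`
  (default 0.5) of its mass on the necessity sectors (trade,
  accommodation/food, real-estate analogues — S6/S8/S11 in the 16-sector
  scheme; the first three sectors in smaller economies, which need at least
  3 sectors). The unemployed profile is a small multiplicative tilt of the
  employed one (lower on accommodation/food, higher on real estate), keeping
  rank correlation high while the two remain distinct.
* **Unemployment benefit** `w_U` is a 0.4–0.6 fraction of the economy-wide
  mean wage, additionally capped at 0.7× the minimum sectoral wage per job.
  The cap enforces the model's monotonicity premise — benefit-financed
  consumption per head below employed consumption in every sector — which is
  the sufficient condition for the multiplier ordering
  open ≤ type-IV ≤ type-II to hold elementwise.
* **Labour force** solves the fixed point `p = slack · l_d x(p)` of the
  closed baseline (slack drawn in 1.08–1.18), leaving a positive baseline
  unemployment rate of roughly 7–15%, so equilibrium solves are feasible and
  shocks of realistic size do not exhaust the labour force.
* **Closure coefficients.** The scenario pipeline converts the
  employed/unemployed profiles through the price bridge and scales them by a
  consumption propensity (default 0.65; the remainder leaks to savings and
  direct taxes), so only the domestic producer-price content of induced
  income re-enters demand. With unit propensity and no leakage the induced
  layer would be implausibly strong.
* **Benefit specs** default to the published 2012 initial costs (CBPA
  €355.42M, CBIC €2,305.12M, in-kind €4,544.85M) with household co-payment
  shares drawn from 45.2–49.1% (the complement of the observed 50.9–54.8%
  public share).
* **Price bridge.** Margin and import rates are drawn from the configured
  ranges; product taxes 2–10%. The care sector is fully domestic with no
  margins; the real-estate analogue is mostly domestic.

What the generator does **not** emulate: the magnitudes of any real economy,
import structure by partner, sectoral detail beyond 16 sectors, or
survey-based heterogeneity within household classes. Passing tests on
synthetic economies therefore validate the model's algebra, accounting
identities and qualitative mechanisms — not country-specific magnitudes,
which in the packaged reference tables come from national accounts and
survey microdata that the package does not ship and validates only by
report arithmetic.

## Numerical choices

* Equilibrium residual tolerance 1e-8 (relative); shock-equivalence and
  telescoping identities asserted at 1e-9; accounting identities in
  generated economies at 1e-6 relative or tighter.
* The Neumann-series cross-check truncates at k = 200 terms; with closure
  kernels of spectral radius ≤ ~0.85 the truncation error is far below the
  1e-8 assertion.
* Percentages and multipliers in reports round half-up at the printed
  precision (1–2 decimals), via `decimal`.
* CSV round-trips use shortest-repr writing and `float_precision="round_trip"`
  parsing, making write→read bit-exact.
* Reference tables are stored exactly as printed; consistency checks carry
  the printed rounding slack (0.05 million euros for euro tables, 1 job for
  integer job tables). The global value-added column intentionally sums to
  5,900.12 against a printed total of 5,900.09, and the in-kind initial cost
  is printed in two variants (4,544.85 / 4,545.85) — both are preserved.

## Problem sizes

Validation batches use 16-sector economies: 200 seeds for generator
feasibility (Hawkins–Simon), 100 seeds for the model-core identities and for
the counterfactual employment property, with the qualifying filter that the
care sector's labour coefficient exceeds the economy mean. These sizes give
stable pass-rate estimates while the whole suite runs in seconds.

## Known limitations

* No supply constraints, fixed technical coefficients, no economies of
  scale — the standard demand-driven IO assumptions.
* No fiscal feedback: taxes and contributions generated are reported, not
  re-spent.
* Administration overheads of the care system are outside the modelled
  spending.
* The all-in-kind counterfactual depends on the co-payment re-split policy;
  both options are provided because the policy question does not determine
  one.
* Single-region, single-year, 16-sector resolution.
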