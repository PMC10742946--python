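# Methods

## Model and assumptions

The package treats sequential information transfer through a noisy channel
as a physical process. A source emits messages `x ∈ {1..n_src}` i.i.d. from
a prior `P_X`. While a message is held, the receiver position `y ∈
{1..n_rcv}` evolves as a continuous-time Markov jump process whose rates
satisfy local detailed balance with respect to the landscape `U_x`; each
message is held long enough for the receiver to re-equilibrate, so the
received message is a draw from the canonical distribution
`q(y|x) = exp(β[F_x − U_x(y)])`. Three consequences of this idealization:

* the coarse-grained kernel `k(y'|y, x) = q(y'|x)` has no memory of the
  previous position — incomplete relaxation (finite holding time) is out of
  scope;
* source and receiver alphabets may differ (`n_src ≠ n_rcv`); nothing ties
  the number of potential wells to the number of messages;
* correlated (non-i.i.d.) sources are out of scope; the trajectory
  estimators and the cancellation ⟨ΔF⟩ = 0 both rely on independence.

All information quantities are computed and stored in natural log units
(nats). This is not cosmetic: the thermodynamic identities `σ = β(w − ΔF)`
hold only in nats; conversion to bits is display-level only.

### Sign and orientation conventions

* Channels are column-stochastic: `q[y, x] = P(y|x)`, columns = sources.
  Files use 1-based labels, the API 0-based.
* The free-energy difference of a message switch is final minus initial,
  `ΔF = F_next − F_prev`. With this convention `σ = β(w − ΔF)` equals the
  channel log-ratio `ln q(y|x_prev)/q(y|x_next)` identically, and a
  landscape shifted by a constant (the equilibrium case) gives `σ = 0`
  exactly. The opposite sign convention breaks both checks; the
  work-accounting unit tests pin this down.
* The error information is oriented as `I_e = Σ_x P_X(x) KL(P_Y ‖ q(·|x))
  ≥ 0` (pointwise `i_e = −ln q/P_Y`), which makes `R = I + I_e` an exact
  algebraic identity rather than an approximation.

## Key quantities and how they are computed

* `recoverability` evaluates the triple sum over `(y, x, x')` as a dense
  log-ratio tensor contraction, summing over **all** ordered pairs
  including `x = x'` (zero terms), so R coincides summand-by-summand with
  the entropy production of the switching process.
* `entropy_production` deliberately takes a different route: a pair-loop of
  `scipy.special.rel_entr` column-to-column KL divergences weighted by
  `P(x)P(x')`. The two agree to 1e−12; the agreement is asserted in tests,
  not assumed.
* Zero handling: `0·ln(0/z) = 0`; a log-ratio with positive weight against
  a zero denominator yields `+inf` (returned, not raised); `0/0` log-ratios
  raise. Canonical channels are strictly positive, so divergences only
  arise for hand-built channels.
* Canonical channels are computed as per-column softmax of `−βU`
  (max-shifted exponentials), so large `β·U` ranges cannot overflow, and
  columns are renormalized to machine precision.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `beta` | 1.0 | 1/energy | inverse temperature; R, I, I_e, Σ are β-free given the channel, only W and the Landauer margin scale as 1/β |
| validation tolerance | 1e−9 | — | column/prior sums accepted as-is below this drift |
| renormalization cap | 1e−6 | — | drift below this is renormalized with a warning, beyond it rejected |
| kernel tolerance | 1e−10 | — | sup-norm column spread at which `exp(Gτ)` is declared converged; τ found by propagator squaring |
| sweep grid | 201×201 | — | resolution of the (d1, d2) surface tables |
| sweep margin ε | 1e−6 | — | shrink of the feasible region to dodge the log divergence of R where a composed entry hits 0 |

The relaxation timescale is arbitrary: only the τ→∞ limit enters the
framework, so rates use unit attempt frequency on a fully connected
position graph. Any irreducible topology gives the same kernel; adaptive
τ-doubling replaces a fixed holding period.

## Synthetic data

There are no external datasets; the study conditions are fully specified by
a channel and a prior. Two generators supply them:

* the bundled worked example — a fixed, strictly positive 3×3 channel with
  a skewed prior, chosen so ML and MAP decoding disagree on one received
  message (exercising the prior's role), used for all worked numbers;
* `generate_random_fixture` — per-column symmetric Dirichlet channels and
  Dirichlet priors (concentration 1 by default, i.e. uniform on the
  simplex), floored at 1e−12 to keep every entry strictly positive, which
  is the regime where all identities are finite.

These emulate arbitrary memoryless discrete channels. They do not emulate
temporally correlated sources, continuous receiver coordinates, or
channels with structural zeros, so passing tests say nothing about those
regimes.

Trajectory simulations default to `t = 10^5` steps for single-run
convergence demonstrations and 200 seeds × `t = 10^4` for unbiasedness
checks — sizes at which the 1/√t estimator error is a few times 10^−3 nats,
an order of magnitude below the example's R ≈ 0.344. One master seed
derives independent streams (source draws, channel noise, shuffling) by
fixed offsets, so each component is reproducible in isolation.

## Numerical choices

* Estimator standard errors include the lag-1 autocovariance of the
  increments (consecutive Σ′ terms share a source draw); traces are stored
  at ~60 logarithmically spaced checkpoints.
* The Σ′ sum has t−1 terms but is divided by t, matching the R′
  normalization; the difference is O(1/t).
* Argmax ties in decoding are broken toward the lowest label and flagged.
* Convexity of the strength surfaces is verified by midpoint tests along
  rows, columns and both diagonals of the grid, and monotonicity along
  random rays from the origin — numerical demonstrations, not symbolic
  proofs.
* Strength decompositions are validated against the box constraints
  (`|d_y| ≤ min(m_y, 1 − m_y)` plus `Σ d_y = 0`) at construction;
  boundary-touching `d` (a zero composed entry) is legal and flagged, since
  R diverges there while I stays finite.

## Known limitations

* Quantities are exact only up to floating point; identities are asserted
  at 1e−10…1e−12 absolute.
* `error_information` and `recoverability` are `+inf` for channels with
  structural zeros under full-support priors; the package returns the
  infinity rather than truncating it.
* The receiver dynamics module makes no claim about absolute timescales or
  finite-τ thermodynamics; it exists to show the canonical channel is the
  long-time limit of any local-detailed-balance relaxation.
* Fluctuation statistics of σ beyond the mean (e.g. detailed fluctuation
  theorems) are not computed.
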