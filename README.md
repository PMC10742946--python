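# recotherm

**Information recoverability of noisy channels and its thermodynamic price.**

A biological receiver — a chemoreceptor, a promoter, any sensor with a finite
memory — reads a sequence of source messages through a noisy channel. Two
questions arise: *how well can the original messages be recovered from what
was received*, and *what does that ability cost energetically*? `recotherm`
implements a framework in which these are literally the same number: the
channel's **recoverability** equals the **entropy production** of the
message-switching dynamics.

## The model

Source messages `x` are drawn i.i.d. from a prior `P_X`. Holding a message
puts the receiver in a potential landscape `U_x(y)` over discrete positions
`y`; after relaxation (local-detailed-balance dynamics, Metropolis or
Glauber) the received message follows the canonical distribution

```
q(y|x) = exp(β [F_x − U_x(y)]),   F_x = −β⁻¹ ln Σ_y exp(−β U_x(y)).
```

The central quantity is the ensemble-averaged log-likelihood ratio between
the true source and an independently drawn alternative,

```
R = Σ_{x,x',y} P_X(x) P_X(x') q(y|x) ln[ q(y|x) / q(y|x') ]   (nats),
```

which obeys two exact identities:

* **R = I + I_e** — mutual information (the useful transfer rate) plus
  *error information*, the spurious correlation between the received message
  and an independent source;
* **R = Σ = β(W − ⟨ΔF⟩)** — the averaged entropy production of switching
  landscapes, with ⟨ΔF⟩ = 0 for an i.i.d. source, giving the generalized
  Landauer bound `W ≥ β⁻¹ I`.

Decomposing two channel columns into equilibrium and nonequilibrium
strengths, `q(·|x) = m ± d`, the point `d = 0` is where messages become
indistinguishable and R = I = Σ = 0; both I and R are convex in `d` and grow
together as the channel is driven out of equilibrium. Both ensemble
quantities are also recovered from single trajectories: `R'` from the
log-probability ratio of the observed sequence to a source-shuffled
surrogate, and `Σ'` from the running sum of stochastic entropy production.

## Worked example

The bundled 3×3 example (a strictly positive channel with a skewed prior):

```python
import recotherm as rt

model = rt.InformationChannelModel.example()
print(model.fit().summary())
```

```
Information channel — ensemble quantities
==============================================
recoverability R             0.3444189962  nats
mutual information I         0.1542094377  nats
error information Ie         0.1902095586  nats
entropy production Sigma     0.3444189962  nats
averaged work W              0.3444189962  1/beta
<dF>                         0.0000000000  1/beta
Landauer margin W - I/beta   0.1902095586  1/beta
==============================================
```

R and Σ agree to machine precision even though they are computed by
independent summation routes, and R = I + I_e exactly: of the 0.344 nats of
dissipation per message, 0.154 nats are useful information transfer and
0.190 nats are noise-induced error. A single simulated trajectory recovers
the same numbers:

```python
print(model.fit_trajectory(100_000, seed=1).summary())
```

```
Trajectory estimators (t=100000)
==============================================
R' (trajectory)       0.3456169970  ± 2.74e-03 nats
Sigma' (trajectory)   0.3433279597  ± 2.72e-03 nats
R (ensemble)          0.3444189962  nats
Sigma (ensemble)      0.3444189962  nats
==============================================
```

Both estimators land within one standard error of the ensemble value. The
same is available from the shell:

```
recotherm fixtures --outdir .
recotherm info --channel worked-example-3x3.channel.csv \
               --prior worked-example-3x3.prior.csv
{
 "R": 0.344418996241,
 "I": 0.154209437688,
 "Ie": 0.190209558554,
 "units": "nats"
}
```

Other subcommands: `thermo` (work, Landauer margin), `decompose`
(equilibrium/nonequilibrium strengths of a column pair), `sweep`
(I and R surfaces over the feasible strength region, presets a–d for the
two-source prior), `simulate` (trajectories and estimator traces), and
`relax` (receiver relaxation under a fixed message).

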