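# crnctrl

A toolkit for building embedded biomolecular reference-tracking controllers
from chemical reaction networks (CRNs):

- **`crnctrl.crn`** — reaction networks with clamped (constant-concentration)
  source species, compilation to generalised mass-action ODE systems
  (`dx/dt = P f(x)`), stiff deterministic simulation and steady-state
  detection by long-horizon integration plus a derivative test.
- **`crnctrl.operators`** — the arithmetic operator motif library: gain (2
  reactions), three-reaction summation, one-sided subtraction (4 reactions;
  output clips at `max(0, a-b)`), division (2), pure integrator (1),
  proportional (2), and the dual-rail summation/subtraction motifs (9 each)
  that encode signed signals as `(+, -)` species pairs with fast
  annihilation. No single-rail motif can settle at a negative output — the
  structural reason the feedback error computation is one-sided.
- **`crnctrl.plant`** — the enzymatic process (binding / catalysis /
  degradation, conserved total enzyme) and its steady-state inversion
  constants `alpha = kr2*kr3`, `beta = kr1*kr2*xT`, `delta = kr1*kr3`.
  Optional retroactivity: the process may consume its input species instead
  of reading a buffered copy.
- **`crnctrl.controller`** — synthesis of the closed loops: full
  inverse-feedforward + PI (26 reactions), simplified feedforward (first
  Taylor coefficient `alpha/beta` only, 18 reactions; a 31% reduction), and
  the PI-only loop (16 reactions) that fails after a reference step-down.
- **`crnctrl.analysis`** — tracking experiments with a piecewise-constant
  reference (default: 4 on [0, 40000), 1 on [40000, 80000]), relative
  steady-state errors, Chernoff-bound Monte Carlo sizing
  (`chernoff_sample_size(0.05, 0.99) == 1060`), split-rate parameter
  perturbation (every rate occurrence in the ODE terms is an independent
  parameter), output envelopes with divergence flags, one-at-a-time
  sensitivity sweeps (factors 0.5–2.0, step 0.1) and the process-parameter
  regime sweep over the literature-range corners.
- **`crnctrl.dsd`** — compilation of uni/bimolecular reactions into DNA
  strand-displacement implementations (2 and 3 steps respectively, with
  auxiliary species at `C_max`), converging to the source kinetics as
  `C_max` grows.
- **`crnctrl.reaction_io` / `crnctrl.config` / `crnctrl.cli`** — a
  plain-text reaction-list format, YAML configuration (empty config =
  nominal experiment), CSV/JSON reports and the command line.

## Command line

```sh
crnctrl count --mode full_ff                 # reaction-count breakdown
crnctrl simulate --mode simplified_ff --out traj.csv
crnctrl robustness --scale 0.1 --n 1060 --seed 1 --out robustness.json
crnctrl sensitivity --mode full_ff --params gSbII1,gSmII1 --out sens.csv
crnctrl sweep --mode full_ff --out regime.csv
crnctrl compile-dsd reactions.txt --out dsd.txt --manifest aux.csv
```

Reaction-list grammar (one reaction per line):

```
# comment
clamp: r, beta
xin + xe -> xi @ kr1=0.005
xo -> empty @ g=1.0
```

Configuration is YAML with sections `process` (kr1, kr2, kr3, xT),
`controller` (gGa, gGd, gSbI, gD, gGKP, KP, KI, gSmI, gSbII, gSmII, gG),
`reference` (`segments: [[0, 4], [40000, 1]]`, `t_end`), `solver`,
`analysis` and `dsd`; any omitted key falls back to the nominal value.

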