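# Methods

This note documents the model implemented by `foragesim`: its equations, the
reasoning behind the shipped default constants, the validation suite, and the
limitations we know about. All symbols match the source; every constant named
here lives in the run configuration and can be overridden from YAML.

## 1. World

The arena is a square grid of unit patches with toroidal boundary conditions
(`world.arena_size = 60` patches per side by default). Items and the forager
occupy continuous coordinates; odors live on the patch grid, one
concentration field per signature: `betaine`, `hermi`, `flab`, `drug`.

Each tick, every live item deposits odor into the patch under it: its own
signature (`signature_deposit`) plus betaine for nutritive prey
(`betaine_deposit`). Fields then diffuse — each cell keeps `1 − f` of its
content and shares `f/8` with each of its 8 toroidal neighbours
(`diffusion_fraction f = 0.5`, implemented as a wrap-mode convolution) — and
evaporate by the factor `1 − e` (`evaporation_fraction e = 0.05`). Diffusion
is exactly mass-conserving (tested to 1e-12); evaporation bounds the
steady-state plume at deposit/e per item.

Species defaults:

| species | signature deposit | betaine | nutrition | reward |
|---------|------------------:|--------:|----------:|-------:|
| hermi   | 0.5               | 0.5     | 0.3       | +0.5   |
| flab    | 0.5               | 0.5     | 0.3       | −0.5   |
| drug    | 5.0               | 0.0     | 0.0       | +4.0   |

The drug is non-nutritive and emits no resource signal, so a naive forager
is indifferent to it; it must learn the association. Its signature deposit is
10× the prey deposit so that, once learned (V⁺ = 1 for both), its sensed
incentive exceeds hermi's despite hermi's betaine bonus: at the presentation
distance the log-compressed drug signal is larger by log₁₀(10) = 1 per
sensor (≈ +2 side-summed), which exceeds the betaine term
`w_betaine · s_bet ≈ 0.05 · 9.4 ≈ 0.5`. This is what makes the addicted
drug-approach region a strict superset of the hermi region. Consumed items
respawn at uniform-random positions (when the protocol enables respawn),
drawing exactly one position from the stream per respawn so trajectories
with different meal timings keep aligned random streams.

## 2. Forager

**Sensing.** Two sensors sit at heading ± 40°, 3 patches from the body
centre. Each samples every field at its patch and log-compresses:
`s = max(0, k_log + log10(c + c_floor))` with `k_log = 7`, `c_floor = 1e−7`,
mapping the usable concentration range (≈1e−7 … 10) onto roughly 0 … 8.

**Somatic map.** Total input per side (all signatures, plus pain routed to
the side of its body-relative bearing) sets the stimulus side and the turn
amplitude `min(max_turn, gain_turn · |L − R|)` (5 °/unit, cap 20 °/tick).
Direction is *not* decided here.

**Incentive.** `I = Σ_k (V⁺_k − V⁻_k) · s_k + w_betaine · s_betaine`, summed
over both sensors. Learned values reweight the same sensory stream; betaine
carries the innate appetitive pull (`w_betaine = 0.05`).

**Appetitive state.** A logistic readout of net drive:

```
drive = I
        + h0 · (1 − S) · (1 + c_w · max(0, −RE))     hunger, amplified in withdrawal
        − c_s · S · (1 + c_re · max(0, RE))          satiation, deepened by reward
        − Q(RE, P)                                   surviving reward/pain suppression
        − theta
AS = sigmoid(beta · drive)
```

`AS ≥ 0.5` (drive ≥ 0) switches the turn from avoidance to approach;
`AS ≥ 0.6` additionally permits biting items within the capture radius
(1.5 patches). Defaults: `beta = 1`, `theta = 1`, `h0 = 16`, `c_s = 12`,
`c_w = 0.5`, `c_re = 0.01`.

**Satiation.** A nutrition store decays multiplicatively
(`N ← N(1 − k_N) + Σ meals`, `k_N = 0.002`) and satiation saturates:
`S = clip(N / (N + K_half), 0.01, 1.0)` with `K_half = 0.3`.

**Locomotion.** Turn, then advance `speed = 0.4` patches/tick (presentation
protocols disable translation).

## 3. Affect

**Homeostatic reward circuit (HRC).** Two rate neurons. R receives a tonic
baseline `r0 = 1` plus a decaying trace `u` of consumption rewards
(`u ← u(1 − 1/tau_u)`, `tau_u = 150`; consumption adds `g_pulse · reward`).
M's activity is `x_M = W · x_R`, and the synapse follows a homeostatic
setpoint rule `W ← clip(W + eta_W (M_set − x_M))` with `M_set = 1`,
`eta_W = 2.5e−4`, `W ∈ [0.05, 2]`. The signed readout is
`RE = k_RE (x_M − M_set)`, `k_RE = 5`.

This single rule yields the opponent-process cycle: a sustained input peaks
RE at onset, W then declines (desensitization/tolerance) so RE falls under
continuing input; at offset the depressed weight on tonic input leaves
`x_M < M_set`, i.e. RE < 0 (withdrawal); W then slowly recovers
(resensitization, time constant `1/eta_W = 4000` ticks).

**Pain and mutual inhibition.** The pain center is a leaky accumulator
(`tau_P = 30`). Pain and positive reward experience inhibit each other
one-for-one (`k_pr = k_rp = 1`), and negative reward experience amplifies
pain (`P · (1 + c_p · |RE⁻|)`, `c_p = 1.0`); the survivor
`Q = P_eff + RE_eff` is what suppresses appetitive state. High reward
experience can therefore mask a strong pain stimulus, and withdrawal makes
the same stimulus dominant.

## 4. Learning

Per consumption, one Rescorla–Wagner step on the consumed item's signature:
`V ← V + α (λ − V)` with `α = 0.3` and asymptote
`λ = min(1, |reward| / r_norm)`, `r_norm = 0.5`. Positive rewards train V⁺,
negative rewards train V⁻, and zero-reward consumption of a signature
extinguishes V⁺ toward 0 (same rate by default). With these defaults both
prey (|r| = 0.5) and the drug (r = 4, capped) train toward 1, and fifteen
rewarded trials reach 1 − 0.7¹⁵ ≈ 0.995, i.e. 1.00 at two-decimal reporting
— the package's single numeric acceptance target.

## 5. Protocols

* **Presentation mode** — forager immobilized (turn only) at the centre of a
  40-patch arena; one item at bearing +45°, distance 5; fields
  pre-equilibrated 200 ticks; S and RE clamped; 300-tick trial; the net turn
  toward the stimulus is classified approach / none / avoid with a 5° dead
  zone. The item is placed off-axis because with symmetric sensors a
  dead-ahead stimulus produces zero left–right difference and hence no turn
  to classify.
* **Selectivity maps** — one presentation per cell of S ∈ {0.01, 0.1, …, 1.0}
  × RE ∈ {−20, −15, …, 20}, per item, under a `drug_free`
  (V⁺[hermi] = V⁻[flab] = 1) or `addicted` (additionally V⁺[drug] = 1)
  preparation.
* **Pain map** — no items; a maintained pain stimulus of strength 10 at the
  right anterior (−45°), with the pain-center output held at the applied
  strength for the trial (a sustained stimulus clamp, rather than letting a
  per-tick application accumulate ~tau_P-fold); grid over S × RE ∈ {−10 … 10}.
* **Addiction cycle** — free-running, four phases: prey only (3 hermi +
  3 flab, respawning; 5 000 ticks), drug introduced (6 drug, respawning;
  10 000), drug removed (5 000), drug reintroduced with unchanged odor but
  zero reward (10 000). Trials are seeded `[root, k]` so adding trials never
  perturbs earlier ones; aggregation reports mean and SEM (sample SD/√n,
  NaN at n = 1).

## 6. Calibration of the shipped defaults

The drive constants cannot be chosen independently; the protocols pin them
from several directions. The shipped set is the solution we found to the
joint system; the binding constraints are listed so the reader can re-derive
them:

1. **Pain map, starving row**: approach at S = 0.01, RE = 0 requires
   `h0 · 0.99 > Q + theta = 11` → `h0 ≳ 11.2`.
2. **Pain map, positive-RE column**: approach at some S ≥ 0.5 when RE = +10
   (reward masks pain, `P_eff = 0`) requires
   `(h0 − c_s(1 + 10·c_re)) · 0.5 ≥ theta + 1` → `h0 ≥ c_s(1 + 10·c_re) + 2`.
   With `c_s = 12`, `c_re = 0.01` this gives `h0 ≥ 15.2`; we ship 16.
3. **Pain map, withdrawal columns**: avoidance at *all* S for RE ≤ −5
   requires amplified pain to beat amplified hunger at S = 0.01:
   `h0 · 0.99 · (1 + 5 c_w) < theta + 10 (1 + 5 c_p)`. With `c_w = 0.5` this
   forces `c_p ≥ 0.9`; we ship 1.0.
4. **Selectivity corner**: avoidance of everything at S = 1, RE = +20 needs
   `c_s (1 + 20 c_re) + theta` to exceed the strongest presentation
   incentive (≈ 11.4 for the learned drug) → `c_s = 12` suffices.
5. **Withdrawal overeating** (cycle phase 3 vs phase 1 prey rate): the
   baseline rate is travel-limited while the withdrawal rate is
   demand-limited, so the contrast is controlled by metabolism and by how
   long withdrawal persists. `k_N = 0.002` makes post-meal idle time short
   during withdrawal, `speed = 0.4` keeps the baseline travel-limited, and
   the slow weight recovery (`eta_W = 2.5e−4`, `tau_u = 150`) keeps RE
   negative across the whole drug-removed phase. With the faster circuit we
   started from, the forager had already resensitized by the time its
   satiation fell below the pursuit threshold and the overeating effect
   vanished.
6. **Mini-withdrawals**: `tau_u = 150` spaces reward troughs so RE
   oscillates through zero many times in the drug phase while still
   decaying fast enough for criterion 2's recovery check.

Changing any of these constants individually is safe for exploration but the
acceptance suite should be re-run; it asserts exactly the patterns above.

## 7. Validation

`tests/test_acceptance.py` holds one test (or test class) per criterion:

1. t1 pre-feeding calibration (15 hermi → V⁺ = 1.00 at 2 d.p.).
2. HRC opponent-process shape on a 10⁴-tick run: onset peak (first 10% of
   the input window), monotone decline under input, negative undershoot at
   offset, terminal |RE| < 5% of peak.
3. Selectivity-map patterns on the default 11 × 9 grid: all-avoid corner at
   max (S, RE); addicted drug ⊃ hermi approach set; RE = −10 at least as
   permissive as RE = 0 for prey; flab/hermi discrimination at RE = 0,
   S ≥ 0.5.
4. Pain-map patterns: starving approach; sated avoidance; masking by high
   positive RE; global avoidance for RE ≤ −5.
5. Addiction-cycle dynamics over 10 seeds: withdrawal prey-overeating
   (phase-mean rates), ≥ 3 RE zero-crossings in the back half of the drug
   phase per seed, faster drug re-engagement than first engagement
   (means), and extinction (first-quarter > last-quarter unrewarded drug
   rate; terminal V⁺[drug] < 0.1 per seed).
6. Closed forms: RW acquisition/extinction vs `1 − (1−α)ⁿ` and
   `v₀(1−α)ⁿ` to 1e−12; HRC fixed-point stationarity to machine precision;
   diffusion mass conservation to 1e−12.
7. Reproducibility: identical (config, seed) → byte-identical CSVs.

The full suite is deterministic and completes in ≈ 3 minutes.

## 8. Numerical and design choices; limitations

* **Scale.** The 60-patch arena, 3 + 3 + 6 items, and the phase lengths are
  desk-scale choices: large enough for plumes to be sparse and encounters
  stochastic, small enough that the 10-seed cycle suite runs in ~2 minutes.
  Rates (not counts) are asserted, so moderate rescaling preserves the
  qualitative results, but encounter statistics do shift with arena size.
* **Determinism.** All randomness flows from `numpy` generators seeded per
  protocol; trial k of root seed r uses `default_rng([r, k])`. Presentation
  protocols are fully deterministic given the seed.
* **Single-cell sensing.** Sensors sample the patch under them rather than
  interpolating; at plume scales ≥ 1 patch this only quantizes the gradient.
* **One forager, one tick order.** The tick order (deposit → transport →
  pain → circuit → decision → move/consume → learn → respawn) is a fixed
  documented convention; results at these time constants are insensitive to
  the alternatives we tried, but the order is asserted by tests, not
  configurable.
* **No compound-stimulus competition.** Learning updates one signature per
  consumption; blocking/overshadowing phenomena are out of scope.
* **Pain map uses a stimulus clamp.** A maintained stimulus holds the pain
  output at its strength; letting a per-tick application accumulate through
  the leaky integrator would scale the effective pain by ~tau_P and has no
  sensible interpretation against the strength-10 protocol.
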