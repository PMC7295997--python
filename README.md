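# foragesim

An agent-based simulator of cost–benefit foraging in which an aesthetic
sense — graded attraction and aversion to stimuli — and, under the right
reward contingencies, addiction, emerge from the interaction of three simple
mechanisms:

* **Rescorla–Wagner reward learning** over odor signatures (what an odor
  predicts),
* an **appetitive-state integrator** that folds incentive, hunger/satiation,
  reward experience, and pain into a single approach/avoid decision variable,
* a **homeostatic reward circuit** whose plastic synapse desensitizes under
  sustained reward, producing opponent-process dynamics: tolerance,
  withdrawal, craving, and recovery.

A single generalist forager, modeled on the predatory sea slug
*Pleurobranchaea*, roams a toroidal arena containing a benign nutritive prey
(**hermi**, small positive reward), a noxious nutritive prey (**flab**,
negative reward), and optionally a high-reward, non-nutritive **drug** item.
All items emit diffusing, evaporating odor plumes; nutritive prey also emit
betaine, an innately attractive resource signal. The forager steers by
comparing two log-compressed odor sensors, learns signature values from
consumption outcomes, and its internal state (satiation, reward experience,
pain) continuously re-weights what the same stimulus is worth.

## Worked example

Presentation mode immobilizes the forager (it can only turn), places one item
at a 45° bearing, clamps satiation S and reward experience RE, and classifies
the net turn. With the standard prey-experienced preparation
(V⁺[hermi] = 1, V⁻[flab] = 1):

```
$ foragesim presentation --item hermi --satiation 0.01 --reward-experience 0
hermi: approach (net turn +41.5 deg)

$ foragesim presentation --item flab --satiation 0.5 --reward-experience 0
flab: avoid (net turn -130.7 deg)

$ foragesim presentation --item hermi --satiation 1.0 --reward-experience 20
hermi: avoid (net turn -130.7 deg)
```

The same prey odor is appetitive to a starving forager and aversive to a
sated, reward-replete one — the aesthetic judgment lives in the observer's
state, not in the stimulus.

The four-phase addiction cycle (prey only → drug introduced → drug removed →
drug without reward) runs free with learning and the reward circuit
unconstrained:

```
$ foragesim addiction-cycle --trials 2 --seed 1 --out results/cycle
wrote 3 artifacts to results/cycle

$ head -6 results/cycle/cycle_summary.csv
phase,ticks,re_mean,hermi_consumed,flab_consumed,drug_consumed
prey_only,5000,0.7092585573,19.5,2,0
drug_introduced,10000,1.115591527,55.5,19,31
drug_removed,5000,-1.481203563,27,1,0
drug_without_reward,10000,-0.3092203577,43.5,6,11
```

Read the story across the rows: removing the drug leaves mean reward
experience negative (withdrawal), during which the forager overeats prey
(28 prey in 5 000 ticks versus 21.5 in the drug-free baseline, noxious flab
included); when the drug returns without reward it is re-engaged quickly but
consumption decays as the association extinguishes.

Other subcommands: `selectivity-map` (approach/avoid grids over S × RE per
item, for the drug-free or addicted preparation), `pain-map` (the same grid
for a maintained pain stimulus), `free-run`, and `presentation`. Every
command accepts `--config <yaml>`, `--seed`, and `--out`; outputs are CSVs,
PNG figures, and a `manifest.json` with SHA-256 digests so reruns are
verifiable. Identical (config, seed) pairs produce byte-identical CSVs.

## Package layout

```
src/foragesim/
  environment.py   toroidal odor world, species, diffusion/evaporation
  forager.py       sensing, somatic map, appetitive state, movement, satiation
  affect.py        homeostatic reward circuit, pain center, mutual inhibition
  learning.py      Rescorla-Wagner updates over odor signatures
  simulation.py    per-tick orchestration
  experiments.py   presentation / selectivity-map / pain-map / cycle protocols
  config.py        YAML config loading, validation, hashing
  io.py            CSV/PNG writers and manifests
  cli.py           command-line interface
docs/methods.md    model description, parameter rationale, validation
```

See `docs/methods.md` for the model equations, the calibration argument
behind the shipped defaults, and known limitations.
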