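# mapkcell

Spatial agent-based simulation of the two lower tiers of the MAPK signalling
cascade (MAPKK → MAPK) in a spherical cell with an explicit nucleus, optional
cytoplasmic subcompartments, nuclear export receptors, re-activation delay
periods, and transient signalosome clusters.

Every molecule is an individual particle performing Brownian motion in 3-D.
An active (phosphorylated) MAPKK that comes within the interaction radius of
an inactive MAPK phosphorylates it; the new pMAPK translocates to the
nucleus, and the MAPKK goes dormant for its **re-activation delay period
(RADP)** — the model's abstraction of phosphatase-mediated negative feedback.
**Export receptors (ExR)** confined to a shell on the inner nuclear membrane
return nuclear pMAPK to the cytoplasm as inactive MAPK, then rest briefly.
The interplay of RADP statistics (deterministic vs stochastic draw, short vs
long bound) and geometry (plain cytoplasm vs ten kinase-confining
subcompartments) produces the model's key qualitative result: sustained
pMAPK oscillations require both compartmentalisation and a long,
low-variance RADP.

## Quick start

```bash
# list the published scenario presets
mapkcell list-scenarios

# run the two-compartment constitutive scenario and analyse it
mapkcell run --scenario fig4A --seed 1 --out fig4A_s1.csv
mapkcell analyze fig4A_s1.csv --out report.json

# robustness sweep: perturb initial MAPK counts by ±20%
mapkcell sweep --scenario fig4B --species MAPK --delta 0.2 --out sweep.csv

# plot a trace
mapkcell plot fig4A_s1.csv --out panel.png
```

Or from Python:

```python
from mapkcell.scenarios import load_scenario
from mapkcell.metrics import dynamics_report, detect_oscillation

ts = load_scenario("fig4A").run(seed=1)
rep = dynamics_report(ts, "pMAPK")
print(rep.equilibrium_ratio, rep.lag_time_s, rep.reduction_at_emax_pct)
```

## Worked example

Three seeded replicates (seeds 1–3) of the two-compartment constitutive
scenario (`fig4A`: 500 MAPKK activated by a stimulus arriving at 80 model-s,
500 MAPK, 180 active + 180 dormant ExR) give, at the calibrated time scale of
1.211 real s per model step:

| quantity (trailing-30-min plateau) | value |
| --- | --- |
| pMAPK : MAPK ratio | 2.26 |
| reduction of cytoplasmic MAPK | 69.4 % |
| activation lag | 96.9 real s |
| max replicate SD of pMAPK (post-lag) | ≈ 4 % |

The multi-compartment deterministic long-RADP scenarios (`fig5F`, `fig5H`)
classify as `sustained_oscillation` (period ≈ RADP bound), while the
constitutive runs are graded. See `docs/methods.md` for the model
definition, the calibration protocol, and a frank account of which published
numbers the calibrated model does and does not reproduce.

## Acceptance measurements

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

writes the eight quantitative acceptance targets (t1–t4, t7, t9–t11) as
`{"<id>": {"value": <number>, "n": <replicates>}}`. The test suite
(`python -m pytest -q tests/`) contains one test per acceptance criterion in
`tests/test_acceptance.py` plus ~160 unit tests of the geometry, matching,
scheduling, metrics, and I/O layers.

## Layout

- `src/mapkcell/geometry.py` — spherical cell/nucleus/subcompartments, specular reflection, uniform region sampling
- `src/mapkcell/agents.py` — agent populations, dormancy clocks, conservation checks
- `src/mapkcell/radp.py` — RADP distributions, phase schedules, plateau/fixed-time triggers, runs test
- `src/mapkcell/clusters.py` — signalosome cluster assembly/disassembly
- `src/mapkcell/engine.py` — the stepping world: binding resolution, export, movement, recording
- `src/mapkcell/metrics.py` — dynamics/oscillation reports, rise-time fitting, replicate SD, statistics wrappers
- `src/mapkcell/scenarios.py` — named presets for all published panels, sensitivity sweeps, the calibrated time constant
- `src/mapkcell/io.py`, `src/mapkcell/cli.py` — config/CSV I/O and the `mapkcell` command
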