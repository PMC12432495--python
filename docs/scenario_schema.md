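# Scenario config schema

Scenario configs are JSON (written and read) or TOML (read) documents
parsed by `fumebox.config.load_scenario`.  Top-level keys:

| key | type | required | meaning |
|---|---|---|---|
| `name` | string | yes | scenario identifier; used in output file names |
| `model_kind` | `"one_box"` \| `"two_box"` \| `"two_box_lev"` | yes | compartment topology |
| `control` | `"none"` \| `"FET"` \| `"LEV"` | no (default `none`) | local-control label |
| `extraction_mode` | `"bulk"` \| `"capture_stream"` | no (default `bulk`) | whether the control flow extracts mixed NF air or is the source-capture stream |
| `emission_mode` | `"factor"` \| `"direct"` \| `"mixture"` | no (default `factor`) | how the emission rate is built per iteration |
| `emission_components` | list of strings | for `mixture` | distribution names averaged into S (equal arc-time split) |
| `process` | table | for `factor` | electrode description (below) |
| `generation` | `"arc_fraction"` or number (min) | no (default `arc_fraction`) | generation-block duration rule |
| `oel` | number, mg/m³ | no (default 5) | limit value for decisions |
| `T_shift` | number, min | no (default 480) | shift duration |
| `window` | `[t1, t2]`, min | no (default whole shift) | worker presence / sampling window |
| `distributions` | table of tables | yes | sampled parameters (below) |

## `distributions`

One sub-table per parameter, keyed by the exact name the engine samples:
`feed_speed` (mm/s), `arc_fraction` (–), `V_room` (m³), `ach` (1/h),
`V_NF` (m³), `beta` (m³/min), `epsilon` (–), `Q_lev` (m³/min), `S_m`
(mg/min) or mixture component names.  Each has:

```toml
[distributions.beta]
kind = "uniform"   # or "point" (then lo == hi)
lo = 9.5
hi = 30.8
```

Completeness is validated at construction: `V_room` and `ach` always;
`V_NF`/`beta` for two-box kinds; `epsilon`/`Q_lev` for `two_box_lev` (and
forbidden for `control = "none"`); `feed_speed` for `factor` emission;
`S_m` for `direct`; every listed component for `mixture`; `arc_fraction`
when `generation = "arc_fraction"`.  A missing key raises an error naming
it.

## `process`

```json
{
  "electrode_name": "ER316LSi",
  "emission_factor": 5.59,
  "wire_diameter": 1.2,
  "wire_density": 7.8,
  "feed_speed_range": [50.0, 250.0],
  "shielding_gas": "99% Ar + 1% O2 16.5 LPM",
  "arc_fraction_range": [0.12, 0.2]
}
```

`emission_factor` is mg fume per g wire; `emission_rate_override`
(`[lo, hi]` mg/min) replaces it for processes characterised by a direct
rate range.

A complete example is produced by
`fumebox simulate --scenario ER316LSi --control FET ...`, which writes the
scenario it ran as `<name>_scenario.json`.
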