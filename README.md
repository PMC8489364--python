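# qctpeep

Quantitative-CT lung aeration analysis and PEEP titration under
intra-abdominal hypertension.

When the abdomen is pressurized (intra-abdominal hypertension, IAH), the
dependent (dorsal, in supine position) lung collapses and the ventilator's
positive end-expiratory pressure (PEEP) must be raised to reopen it — at the
cost of overdistending the non-dependent lung. `qctpeep` is a toolkit for
researchers analyzing this trade-off on CT:

* **Aeration compartments** — classify lung voxels by Hounsfield unit into
  overdistended [−1000, −900), normally aerated [−900, −500), poorly
  aerated [−500, −100) and atelectatic [−100, 200] tissue; compute gas
  volume, tissue mass, and per-segment (ventral/medial/dorsal, left/right)
  breakdowns from the linear air–tissue mixture (gas fraction = −HU/1000).
* **Pressure–volume modeling** — fit each compartment's volume across the
  PEEP ladder with a four-parameter sigmoid V = a + b/(1 + e^−(P−c)/d),
  a saturating exponential and a line; select the smallest-RMS model; derive
  the lower/upper inflection (corner) points P = c ± 2d and the **optimal CT
  inflation PEEP range** — from the atelectatic compartment's lower
  inflection point (recruitment nearly complete) to the overdistended
  compartment's (overdistension about to take off).
* **Respiratory mechanics** — two-point static elastances
  (E_rs = ΔP_aw/V_T, E_W = ΔP_es/V_T, E_L = E_rs − E_W), transpulmonary
  pressures, P/F ratio, best-PEEP selection per titration target (lowest
  elastance, highest P/F, …), ascending/descending hysteresis, and
  relative-difference imputation of missing cells.
* **Synthetic phantoms** — seeded ellipsoidal CT phantoms with a
  gravitational recruitment gradient and IAH coupling, plus sigmoid PV
  datasets and physiology tables, so the entire pipeline is testable with
  no downloads.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Generate a noiseless default phantom (64³ voxels, PEEP 5…27 cmH2O, IAP
27 cmH2O) and quantify aeration at PEEP 5:

```bash
$ qctpeep phantom --out demo --grid 64 --hu-noise-sd 0 --seed 1
wrote 10 volumes + manifest to demo
$ qctpeep aeration demo/ct_peep05.nii.gz demo/mask_peep05.nii.gz \
    --out-csv aer5.csv --out-json aer5.json
$ cat aer5.json
{
  "excluded_volume_ml": 0.0,
  "fraction_pct": {
    "atelectatic": 30.893667390017754,
    "normally_aerated": 28.575655947918722,
    "overdistended": 2.318011442099033,
    "poorly_aerated": 38.21266521996449
  },
  "gas_volume_ml": 440.4041542980671,
  "tissue_mass_g": 826.8458457019328,
  "total_lung_volume_l": 1.26725
}
```

At PEEP 5 under IAH, 31% of this phantom lung is atelectatic and only 2%
overdistended; rerunning on `ct_peep27.nii.gz` shows the trade reversed
(3% atelectatic, 26% overdistended). Fitting the compartment volumes
across all five PEEP levels (`qctpeep pvfit phantom_pv.csv --out
fits.json`) selects the sigmoid for both compartments and reports

```
"optimal_peep_range": { "healthy/descending": {
    "low_cmH2O": 1.0178334962316047,
    "high_cmH2O": 6.318747551235042,
    "well_formed": true } }
```

— i.e. for this severe-IAH phantom, most recruitable volume is regained by
~1 cmH2O above the atelectatic corner pressure while overdistension
accelerates beyond ~6 cmH2O.

The best-PEEP selector runs against the packaged descending-phase median
tables (transcribed from a published porcine IAH titration experiment):

```bash
$ qctpeep bestpeep --target elastance_rs --condition healthy
{"direction": "lowest", "peep_cmH2O": 22.0, "target": "elastance_rs", "tie": false, "value": 81.0}
$ qctpeep bestpeep --target pf_ratio --condition injured
{"direction": "highest", "peep_cmH2O": 22.0, "target": "pf_ratio", "tie": false, "value": 285.0}
```

Both mechanics- and oxygenation-based targets pick PEEP 22 cmH2O — well
above the CT-derived optimal inflation range, which is the central tension
this kind of analysis exposes.

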