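# vwisim

Bloch/EPG simulation and protocol design for CSF-suppressed T2-weighted
intracranial vessel-wall MRI.

High-resolution T2-weighted imaging of the intracranial arterial wall is
hampered by the bright cerebrospinal fluid (CSF) surrounding the vessels:
with CSF T1/T2 ≈ 4300/2200 ms against vessel-wall T1/T2 ≈ 1200/50 ms, the
fluid outshines the wall and hides its outer boundary.  `vwisim` is a
simulator and design tool for the sequence family used to solve this:
3D variable-flip-angle turbo-spin-echo (SPACE-style) readouts combined with

* a **T2IR preparation** — an MLEV composite-pulse T2-preparation whose final
  90° pulse tips the T2-decayed magnetization to the −z axis, weighting the
  longitudinal magnetization by −e^(−TE<sub>prep</sub>/T2) before an
  inversion-recovery delay TI timed to the CSF null;
* a **FLAIR preparation** (plain inversion + long TI, the TE<sub>prep</sub> → 0
  limit);
* no preparation (conventional T2w-SPACE);
* a **DANTE** pulse train (flow-sensitive CSF attenuation); and
* an **AntiDrive** restore pulse at the end of the echo train.

The package provides the elementary magnetization physics (rotations,
relaxation, spoiling), an extended-phase-graph (EPG) echo-train engine
cross-checked against an isochromat Bloch ensemble, the preparation
modules, a steady-state TR-cycle engine with built-in protocol presets,
CSF null-time solvers and preparation-parameter grid search, a scan-time
estimator, and a digital vessel phantom with ROI analysis using
SNR = S/σ and CNR = SNR<sub>VW</sub> − SNR<sub>CSF</sub>.

## Worked example

Steady-state signal levels (fractions of the equilibrium magnetization M0,
read at the effective-TE echo after ten repetitions) for the three
whole-brain 0.6 mm protocols:

```bash
$ vwisim compare-presets --out summary.csv
   sequence      tissue   signal  mz_acq_start  delta_mz
 t2ir-space         csf 0.019745      0.024018  0.000000
 t2ir-space vessel_wall 0.188969      0.542003  0.000000
flair-space         csf 0.013371      0.026642  0.000000
flair-space vessel_wall 0.068859      0.662381  0.000000
  t2w-space         csf 0.372155      0.489013  0.000227
  t2w-space vessel_wall 0.238499      0.843921  0.000227
```

Reading the table: both CSF-suppressed protocols hold CSF below 0.02 — the
T2IR-prepared acquisition enters the echo train with CSF almost exactly at
its null (`mz_acq_start` ≈ 0.024) — while the T2IR protocol keeps roughly
twice the vessel-wall signal of FLAIR (0.189 vs 0.069), because the wall's
short T2 means the T2IR module hands it to the TI delay nearly saturated
rather than fully inverted.  The unprepared T2w protocol has the highest
wall signal (0.238) but a CSF signal beside it (0.372) that destroys the
wall–CSF contrast; on the digital phantom its wall–CSF CNR is negative
while the T2IR protocol's is the highest of the three.

The closed-form cyclic inversion-recovery null for CSF reproduces the
FLAIR protocol's inversion time, and the scan-time estimator the protocol
duration:

```bash
$ vwisim null-ti --t1 4300 --tr 6250
null TI = 2077.3 ms            # protocol uses 2100 ms
$ vwisim scan-time --preset t2ir-space
t2ir-space: 710 s (11.8 min)   # protocol: 11 min 40 s
```

Other entry points: `vwisim simulate` (per-preset signal-evolution traces,
CSV/PNG), `vwisim phantom-report` (phantom SNR/CNR comparison),
`vwisim optimize-prep` (TE<sub>prep</sub> × TI grid search).  Everything is
available as a library (`import vwisim`); see `docs/methods.md` for the
model, its assumptions and parameter choices.

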