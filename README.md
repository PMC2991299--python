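# pcmr — diastolic function analysis of phase-contrast cardiac MR

`pcmr` is a semi-automated analysis pipeline for velocity-encoded
(phase-contrast) cardiovascular MR series acquired at the level of the mitral
valve. From one rough region of interest drawn on a single cardiac phase it

* delineates the **transmitral and aortic flow patterns** on every phase of
  the cycle by tracking the biggest connected component of same-signed
  velocity, propagating its centre of mass toward both ends of the cycle;
* derives **maximal-velocity, mean-velocity and flow-rate curves**
  (flow rate = mean velocity × segmented area) and extracts the standard
  diastolic indices: the early and atrial peak velocities **E** and **A**
  (cm/s) and their ratio, the peak filling and atrial rates **Ef** and **Af**
  (ml/s), the filling volume **FV** (ml), the normalised peak filling rate
  **Ef/FV** (s⁻¹), the deceleration time **DT** (ms) and the isovolumetric
  relaxation time **IVRT** (ms);
* isolates the **myocardium** on tissue-velocity series by k-means clustering
  (k = 7) of per-pixel velocity time-profiles, taking the biggest spatially
  connected cluster, and extracts the early diastolic longitudinal annular
  velocity **E′** and the **E/E′** ratio;
* provides the **evaluation statistics** used to qualify such pipelines:
  Dice overlap between repeated segmentations, paired-measurement
  variability, Mann–Whitney group comparison, Pearson correlation against
  echocardiographic values, and ROC analysis with a Youden-optimal operating
  point.

It is aimed at researchers working on PC-CMR assessment of left-ventricular
diastolic function who need a reproducible, scriptable alternative to manual
per-phase ROI placement.

The two peak detections share one convention: within the diastolic window
(opened by the end of ejection, estimated from the aortic flow-rate curve),
the two highest local peaks at least one sixth of the cardiac cycle apart are
selected, and the **earlier** peak is E (or Ef, or E′) regardless of
magnitude. All wave on/offsets (start/end of filling, end of ejection, end of
the Ef wave for DT) are obtained by a least-squares line through the limb
samples between 40% and 70% of the wave peak, extrapolated to the time axis.
To resist noise, the "maximal" velocity of a region is the mean of the pixels
above 95% of its maximum.

Because no public PC-CMR datasets accompany the method, the package ships a
**phantom generator** (`pcmr.phantom`) producing flow and tissue series with
exactly known ground truth — triangular biphasic transmitral waveforms with a
parabolic jet profile, an opposite-signed systolic aortic jet, tissue annuli
with an S′/E′/A′ longitudinal waveform, seeded Gaussian noise and physical
phase wrapping — so every estimate the pipeline produces can be checked
against an analytic truth.

## Worked example

Generate a flow phantom (ground truth: E = 80 cm/s, A = 60 cm/s,
DT = 185 ms, IVRT = 78 ms, noise σ = 2 cm/s), segment both flows and extract
the diastolic parameters:

```bash
pcmr phantom flow --seed 1 --out demo/flow_series
pcmr segment --series demo/flow_series --roi demo/mitral_roi.json \
     --kind mitral --out demo/mitral
pcmr segment --series demo/flow_series --roi demo/aortic_roi.json \
     --kind aortic --out demo/aortic
pcmr flow-params --series demo/flow_series \
     --mitral-masks demo/mitral/masks.npz \
     --aortic-masks demo/aortic/masks.npz --out demo/flow_out
```

(`mitral_roi.json` / `aortic_roi.json` are rough circles around each jet; see
`pcmr.save_roi` and `pcmr.circular_roi`.) The last command prints

```json
{
  "E_MR_cm_per_s": 78.40129541035498,
  "A_MR_cm_per_s": 60.18939034456686,
  "EA_ratio": 1.3025766661122538,
  "Ef_MR_ml_per_s": 282.5519263512962,
  "Af_MR_ml_per_s": 214.5135146120129,
  "EfAf_ratio": 1.3171754090288588,
  "FV_MR_ml": 48.06010049816593,
  "Ef_over_FV_per_s": 5.879137234889447,
  "DT_MR_ms": 185.3783981640579,
  "IVRT_MR_ms": 76.16968704608007,
  "t_E_ms": 540.0,
  "t_A_ms": 780.0
}
```

E is recovered at 78.4 cm/s — within the expected bias band of the 95% rule
([0.95·80, 80]) — A at 60.2 cm/s, DT within 0.4 ms and IVRT within 1.8 ms of
truth, and FV (48.1 ml vs 47.5 ml analytic truth) within 1.3%. The myocardial
stage then supplies E′ and E/E′:

```bash
pcmr phantom myo --seed 1 --out demo/myo_series
pcmr myo-params --series demo/myo_series --roi demo/lv_roi.json \
     --flow-timings demo/flow_out/timings.json --e-velocity 78.40 \
     --out demo/myo_out
```

```json
{
  "E_prime_MR_cm_per_s": 12.235431956525495,
  "E_over_Eprime": 6.407620121510063,
  "t_E_prime_ms": 560.0
}
```

The tissue truth is E′ = 11.3 cm/s at 560 ms; the ≈ +1 cm/s excess is the
known noise-selection bias of the 95% rule on spatially uniform tissue
(see `docs/methods.md`). Cohort statistics for a per-subject CSV table come
from `pcmr cohort --table cohort.csv --group-col group --out stats/`.

The same pipeline runs on real data: DICOM series directories are read with
`load_pc_series(path, format="dicom", venc=...)` (the encoding velocity must
be given explicitly — vendor venc tags are unreliable and are never guessed).

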