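# lcsync

Linking locus-coeruleus degeneration to levodopa responsiveness in
Parkinson's disease, from neuromelanin-sensitive MRI and resting-state fMRI.

## The problem

The locus coeruleus (LC), the brain's main noradrenergic nucleus, degenerates
in Parkinson's disease alongside the dopaminergic substantia nigra (SN).
Because noradrenergic input facilitates dopaminergic transmission, LC
integrity is a candidate determinant of how well a patient responds to
levodopa.  This package implements the computational chain needed to test
that hypothesis:

1. **NM-MRI contrast quantification** (`lcsync.nm_quant`).  On
   neuromelanin-sensitive scans the LC and SN appear hyperintense.  Integrity
   is measured as a contrast-to-noise ratio against nearby reference tissue,

   CNR_LC = (SI_LC − SI_PT) / SD_PT,  CNR_SN = (SI_SN − SI_CP) / SD_CP,

   with circular ROIs (2 mm² LC, 20 mm² pontine tegmentum, 10 mm² per SN
   subregion, 30 mm² cerebral peduncle), LC ROIs placed at the
   maximal-signal position on three contiguous slices, and the final CNR
   averaged over slices, sides and repeated assessments.  Intra-rater
   reliability is an absolute-agreement ICC.

2. **BOLD conditioning** (`lcsync.bold_preproc`).  Parcellated somatomotor
   time series (33 nodes, 205 volumes at TR = 2 s) are conditioned by
   dropping the first 10 volumes, detrending, nuisance regression
   (WM/CSF + Friston-24 motion expansion) and an ideal 0.04–0.07 Hz
   band-pass; subjects with mean Jenkinson framewise displacement > 0.2 mm
   are excluded.

3. **Phase synchronization** (`lcsync.phase_sync`).  Instantaneous phases
   θ_j(t) come from the Hilbert analytic signal; after trimming 10 border
   points per side (L = 175), network synchrony is the Kuramoto order
   parameter r(t) = (1/n)|Σ_j e^{iθ_j(t)}| and its temporal mean ⟨r(t)⟩.

4. **Response metrics and inference** (`lcsync.response`, `lcsync.stats`).
   Levodopa responsiveness is the rate of change
   (OFF − ON)/OFF of the UPDRS-III motor score and of ⟨r(t)⟩; cohorts split
   into response/resistance groups at the ranked median (57 → 29/28).
   Relationships are tested with covariate-adjusted partial correlations
   (age, medication duration, LEDD) and a stepwise multiple regression of
   the UPDRS-III rate on CNR_LC, CNR_SN and the covariates.

Because the underlying patient data are not public, `lcsync.synthetic`
generates all three input kinds with known ground truth: phantom volumes
with planted contrast, coupled phase-oscillator BOLD whose true synchrony is
controlled by the Kuramoto coupling K, and cohort tables with a planted
partial correlation between CNR_LC and the response rate.

## Worked example

```python
import numpy as np
from lcsync import synthetic, nm_quant, bold_preproc, phase_sync, response, stats

# CNR from a noisy phantom with planted contrast (120-100)/10 = 2.0
truth = synthetic.default_phantom_truth()
volume, rois = synthetic.gen_nm_phantom(truth, seed=1)
lc = {(0, r.label.split("_")[1], r.slice_index): nm_quant.roi_stats(volume, r)
      for r in rois if r.label.startswith("LC")}
pt = {(0, r.slice_index): nm_quant.roi_stats(volume, r) for r in rois if r.label == "PT"}
print(nm_quant.aggregate_cnr_lc(lc, pt).aggregate)   # 2.218 (single noisy phantom)

# synchrony of a weakly vs strongly coupled oscillator network
for coupling in (0.1, 1.5):
    ts = bold_preproc.preprocess(synthetic.gen_oscillator_bold(
        synthetic.OscillatorParams(coupling=coupling, seed=11)))
    res = phase_sync.somatomotor_sync(ts)
    print(coupling, round(res.mean_sync, 3), res.n_nodes, res.n_timepoints_used)
# 0.1 0.441 33 175
# 1.5 0.999 33 175

# cohort inference on a 57-subject table with planted partial r = 0.42
report = stats.run_cohort_analysis(synthetic.gen_cohort(synthetic.CohortParams(seed=1)))
print(report["group_sizes"])                          # {'response': 29, 'resistance': 28}
print(report["correlations"]["cnr_lc~rate_updrs"])    # r = 0.476, p < 0.001 (df = 52)
print(report["stepwise"]["selected"])                 # ['cnr_lc']
```

The single-phantom CNR scatters around the planted 2.0 (the Monte-Carlo mean
over 1000 phantoms is within 2%); the coupled network reaches near-full
synchrony while the subcritical one stays low; and at the planted effect
size, CNR_LC — not CNR_SN — survives the stepwise selection, i.e. the
LC–responsiveness association is independent of SN degeneration.

## The analysis chain

Numbered drivers under `analysis/` run the full study on synthetic data and
write their tables under `results/`:

```
python analysis/01_simulate_inputs.py --seed 1     # phantom, BOLD runs, cohort
python analysis/02_quantify_nm_contrast.py         # ROI stats, CNR, ICC
python analysis/03_network_synchronization.py      # preprocessing + <r(t)> OFF/ON
python analysis/04_cohort_inference.py             # correlations, groups, stepwise
```

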