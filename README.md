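# embryotrace

Analysis toolkit for live CRISPR-dCas13 RNA imaging in developing zebrafish
embryos. Injecting purified dCas13–fluorescent-protein complexes with
modified guide RNAs into the zygote labels endogenous mRNAs at their sites
of transcription, without genetic manipulation, from zygotic genome
activation through early segmentation. This package implements the
computational side of that experiment:

* **Repeat screen** — find transcripts carrying many near-identical ~20-nt
  repeats, so a single guide RNA recruits multiple dCas13 copies to one
  mRNA (`repeat_screen`).
* **Transcription traces** — turn two-ROI intensity measurements of the two
  alleles of a gene into normalized activities, initiation times,
  activation-pattern classes, plateau kinetics, and transcriptional-memory
  statistics comparing de novo transcription with post-mitotic
  re-activation (`trace_quant`).
* **Noise decomposition** — separate extrinsic from intrinsic expression
  noise by correlating cumulative allelic outputs within cells, with
  random-pair controls (`noise_decomp`).
* **Single-particle tracking** — MSD-based classification of mRNP motion
  into stationary, corralled, diffusive, and directed modes, and detection
  of nuclear-export events with dock/release transit times (`spt`).
* **Denoising** — the L1 + gradient-regularized reconstruction applied to
  movies before tracking (`denoise`).
* **Synthetic data** — seeded generators for every input the pipeline
  consumes, with ground truth returned alongside (`synth`).

The microscopy movies behind such experiments are rarely shareable, so the
`synth` module is a first-class citizen: every analysis stage is validated
by recovering the known parameters of synthetic cohorts.

## Models

The mean squared displacement of a track at lag time *t* is fitted with

* directed motion: MSD(*t*) = (*v t*)²
* anomalous diffusion: MSD(*t*) = 2 *m D t*^α, with *m* = 2 dimensions
* confined (corralled) motion: MSD(*t*) = (*L*²/3)(1 − e^(−*t*/τ)),
  with effective *D* = *L*²/(12 τ)

A track whose minor/major principal gyration-radius ratio is below 10⁻³ and
whose span exceeds 2 µm is *directed*; otherwise the anomalous and confined
models compete on weighted residual sum of squares; a track spanning less
than 0.4 µm with fitted *D* < 0.03 µm²/s is *stationary*.

Transcription activity is normalized as
(ROI1_max − ROI2_mean) / ROI2_mean, which cancels photobleaching exactly
because signal and local background share the decay. SNR is
(peak − background mean) / background SD. Extrinsic noise appears as
correlation of the two alleles' cumulative outputs across cells
(*r* → 1, slope → 1 when extrinsic noise dominates); intrinsic noise
scatters cells off the diagonal.

## Worked example

```python
import numpy as np
from embryotrace import synth, spt, trace_quant, noise_decomp

# 50 corralled tracks at nuclear mRNP parameters, then classify them
params = synth.TrajectoryParams("corralled", D_micro=0.2818, L_box=0.5,
                                n_frames=1000, dt=0.01, seed=1)
tracks = synth.gen_trajectories(params, 50)
print(spt.classify_cohort(tracks)["class"].value_counts().to_dict())
fit = spt.classify_motion(tracks[0])
print(f"track 0: class={fit.motion_class}, L={fit.L:.3f} um, "
      f"tau={fit.tau:.4f} s, D=L^2/(12 tau)={fit.D:.4f} um^2/s")

# a de novo transcription cohort: initiation-time memory statistics
cohort = synth.gen_trace_pairs(synth.TracePairParams(
    n_cells=55, offset_mean=44.2, offset_sd=33.5, plateau_time=180.0,
    n_timepoints=130, seed=2))
records = [trace_quant.classify_activation(p, 0.15, same_time_window=2.0)
           for p in cohort.pairs]
summary, _ = trace_quant.memory_statistics(records)
print(summary.to_string(index=False))

outputs = noise_decomp.allele_outputs(cohort.pairs)
print(f"paired alleles: r={noise_decomp.allele_correlation(outputs).r:.2f}")
print(f"random pairs:   r={noise_decomp.random_pair_control(outputs, seed=7).r:.2f}")
```

prints

```
{'corralled': 50}
track 0: class=corralled, L=0.523 um, tau=0.0808 s, D=L^2/(12 tau)=0.2820 um^2/s
  group  n  mean_min    sd_min
de_novo 55 43.236364 30.571085
paired alleles: r=0.72
random pairs:   r=0.09
```

All 50 confined tracks are recognized as corralled, and the fitted
confinement (L ≈ 0.52 µm, τ ≈ 0.081 s) reproduces the generating diffusion
coefficient to 0.1%. The memory statistic recovers the cohort's
inter-allele initiation-time offsets (gamma with mean 44.2 min), and the
shared extrinsic multiplier shows up as a strong allelic output correlation
that collapses when alleles are re-paired across cells.

There is also a CLI for shell use:

```sh
embryotrace simulate traj --seed 1 --out out/
embryotrace screen --fasta transcripts.fasta --k 20 --min-repeats 8 --out out/
embryotrace dose --concentration-um 5.6 --volume-nl 1 --n-cycles 15
```

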