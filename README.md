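# r2tstar

Tissue-specific transverse relaxation (R2t\*) mapping and cohort analysis
for multi-gradient-echo MRI.

The apparent decay rate R2\* of a gradient-echo signal mixes a stable
tissue contribution with a fluctuating blood-oxygenation (BOLD)
contribution and with artifacts from macroscopic field inhomogeneity.
`r2tstar` separates them by fitting, voxel by voxel,

    S(TE) = S0 · exp(−R2t*·TE) · F_BOLD(TE) · F(TE)

where `F_BOLD(TE) = exp(−ζ·f_s(δω·TE))` is the static-dephasing
attenuation of a random venous network (ζ: deoxygenated blood volume
fraction, δω: characteristic frequency shift) and `F(TE) = |sinc(g·Δz·TE)|`
models through-slab dephasing from a local field gradient g. The
tissue-specific rate R2t\* (≈1 s⁻¹ in CSF, 15–20 s⁻¹ in brain tissue)
tracks the cellular/macromolecular environment of tissue water and serves
as a quantitative tissue-integrity marker — complementary to atrophy — in
studies of multiple sclerosis and neurodegeneration.

The package covers the full analysis chain:

* **signal_model** — forward model, including the `f_s` Bessel integral
  (adaptive quadrature + fast monotone lookup table);
* **fitting** — navigator-based phase correction, B0/gradient estimation
  from echo phase, bounded nonlinear least squares per voxel, quality
  masking;
* **roi** — per-region median R2t\* and skull-normalized volumes (NV)
  from FreeSurfer-convention label volumes;
* **stats** — ANCOVA group contrasts, partial Pearson/Spearman
  correlations with clinical scores (lateralized peg-test handling),
  Benjamini–Hochberg FDR;
* **synthetic** — ground-truth phantoms and cohorts with designed effects,
  writing the same NIfTI/TSV formats the real-data path reads;
* **pipeline** / `r2tstar` CLI — simulate → fit → summarize → stats →
  report with checksum-based resume.

## Worked example

`examples/cohort_statistics.py` draws a 111-subject synthetic cohort
(31 healthy controls; 32 relapsing-remitting, 32 secondary-progressive,
16 primary-progressive MS patients) with a designed SPMS R2t\* deficit and
a designed partial correlation of 0.4 between left-hippocampus R2t\* and
the SDMT processing-speed score, then runs the statistics:

```text
cohort: {'RRMS': 32, 'SPMS': 32, 'HC': 31, 'PPMS': 16}

ANCOVA right hippocampus R2t* (age/gender adjusted): F = 4.3, p = 0.0066
  SPMS-HC contrast: -0.64 s^-1 (designed -1.2), p = 0.034

SDMT vs left-hippocampus R2t* (partial Pearson | age, gender, lesion load, treatment):
  r = 0.42 (designed 0.4), p_FDR = 0.0046, n = 80

battery cells tested: 96; FDR-significant: 1
```

The omnibus F rejects equality of the four groups after adjusting for age
and gender; the SPMS deficit is recovered with the designed sign; the
designed SDMT coupling is estimated at r = 0.42 and survives FDR
correction, while the ~90 designed-null cells stay non-significant.

`examples/fit_phantom.py` shows the imaging half — phantom synthesis,
navigator correction, field mapping, voxelwise fitting — and recovers the
CSF/gray-matter class medians (0.99 vs 17.01 s⁻¹ against truths 1.0 and
17.0) and the injected 1 Hz/mm through-slab gradient. The other examples
demo the forward model and the end-to-end pipeline with stage resume.

Real data enter through the same interfaces: a 4D magnitude/phase NIfTI
pair with an `EchoTimes` JSON sidecar, an integer label NIfTI with a TSV
label table, per-subject skull-scaling factors and a cohort TSV.

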