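# cfekit

Quantitative kinetics of **cell-free gene expression** (CFE): simulate a
resource-limited transcription/translation model with translation delay,
fit it to simultaneous mRNA/protein time courses by maximum likelihood,
select among candidate model structures by AIC, quantify parameter
identifiability with profile likelihoods, and analyze expression
variability across populations of liposome-based synthetic cells.

It is written for people who run CFE reactions — bulk plate-reader
titrations of a reconstituted expression mix, or microfluidic
liposome-encapsulated reactions imaged by confocal microscopy — and want
kinetic parameters with honest uncertainty statements out of their
fluorescence time courses.

## The model

Transcription and translation draw on finite, unitless resource pools
(TsR, TlR ∈ [0, 1], proxies for polymerase/ribosome activity, NTPs, amino
acids, energy):

    v_tx = k_r · TsR · DNA / (K_r + DNA)
    v_tl = k_p · TlR · RNA(t − τ_d) / (K_p + RNA(t − τ_d))

    dRNA/dt    = v_tx − δ_r·RNA            dTsR/dt = −a·v_tx − δ_TsR·TsR
    dP_dark/dt = v_tl − k_mat·P_dark       dTlR/dt = −b·v_tl − δ_TlR·TlR/(K_l + TlR)
    dP_mat/dt  = k_mat·P_dark

Translation is delayed by τ_d; a measurement lag τ_l shifts the reported
channels. Seven structural variants (mass-action vs saturating synthesis
laws, alternative resource-decay structures) are fitted and ranked by
AIC = 2k + 2·NLL̂; per-parameter uncertainty comes from profile
likelihoods with chi-squared thresholds, where a profile that never
crosses the threshold within one decade of the estimate reports that
bound as ±∞ (non-identifiable). A synthetic-data module generates bulk
titrations and monodisperse synthetic-cell populations with realistic
noise structure, so the entire pipeline is testable without external
data. See `docs/methods.md` for assumptions, numerics, and limitations.

## Worked example

Fit the full model to a noisy synthetic DNA titration and profile the
transcription rate (`examples/02_fit_and_profile.py`):

```bash
$ python examples/02_fit_and_profile.py
NLL at the optimum: 4226.8  (AIC 8471.5, k=9 free parameters)
  k_r      true       2894   estimate       2831   rel. err   2.2%
  delta_r  true     0.0392   estimate    0.04132   rel. err   5.4%
  k_p      true       2568   estimate       2543   rel. err   1.0%

profile 95% CI for k_r (df=9): [2749, 2966] nM/h
```

The generator produced a triplicate titration (0.94/1.875/3.75 nM DNA, 2%
proportional noise) from known parameters; the multistart fit recovers the
headline rates to a few percent, and the profile-likelihood interval —
using the conservative df = k convention — brackets the generating value
of 2894 nM/h. The other examples cover simulation phenomenology
(`01`: mRNA plateaus ~3 h, protein ~5 h, endpoint protein saturates near
3.75 nM template), AIC model selection (`03`: the generating structure
ranks first among seven), population variability (`04`: radius CV ~0.06,
expression CV ~0.02 preserved from mRNA to protein, batch CV ~0.1), and
unit conversions (`05`: per-polymerase 8.2–11.1 NTP/s, per-ribosome
0.20–0.28 aa/s, ~19.3 min maturation half-time, 1e5–1e8 molecules per
vesicle).

There is also a thin CLI (`cfekit simulate/generate/calibrate/fit/select/
profile/summarize/run`); `cfekit run examples/demo_pipeline.yaml` executes
a seeded generate → fit → profile → summarize pipeline whose reports are
byte-identical across reruns.

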