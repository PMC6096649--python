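# deltabeta

Frontal delta–beta cross-frequency coupling analysis for EEG: debiased
phase–amplitude coupling (dPAC) with an epoch-shuffled surrogate null, the
within-subject delta–beta amplitude-envelope correlation (AAC), and the
nonparametric group-statistics layer used to compare high (HSA) and low
(LSA) socially anxious groups across resting-state and
social-performance-task conditions. Because no raw EEG from the original
study is publicly deposited, the package ships a synthetic-EEG cohort
generator with controllable coupling that stands in for the data and lets
every stage of the pipeline be validated.

## Who this is for

Researchers analyzing phase–amplitude coupling or band-power
co-fluctuations in cleaned, epoched EEG — in particular anyone who needs a
PAC estimator that is robust to non-uniform phase-angle distributions, a
permutation-calibrated effect size (dPACz), and a reproducible
simulation-backed sanity check of the whole chain.

## The estimators

With `φ_t` the instantaneous delta (1–4 Hz) phase and `a_t` the
instantaneous beta (14–30 Hz) amplitude over `n` timepoints:

    PC    = (1/n) Σ_t e^{iφ_t}                      phase clustering
    dPAC  = |(1/n) Σ_t a_t (e^{iφ_t} − PC)|         debiased coupling
    dPACz = (dPAC − mean(dPAC_null)) / std(dPAC_null)

where `dPAC_null` comes from re-pairing whole epochs of phase with intact
amplitude epochs (1,000 random permutations by default). AAC is the
Pearson correlation of the two Hilbert envelopes over all timepoints.
Signals pass through the chain 512 Hz → decimate to 128 Hz → zero-phase
Butterworth band-pass (one-pass order 8 delta / 34 beta, cascaded
second-order sections) → Hilbert transform → trim 16 samples per edge;
metrics are computed per electrode (F3, Fz, F4) over the six concatenated
8-s epochs of a condition and averaged into a frontal composite. Group
statistics are Wilcoxon signed-rank / Mann-Whitney U / Spearman's rho with
Benjamini–Yekutieli FDR correction per family of tests. See
`docs/methods.md` for assumptions, parameter meanings and limitations.

## Worked example

Generate six coupled epochs, run the preprocessing chain, and estimate
coupling:

```python
import numpy as np
from deltabeta import SimulationConfig, synthetic, cfc
from deltabeta.preprocessing import preprocess_epoch_matrix

cfg = SimulationConfig(pac_depth=0.6, aac_rho=0.4, noise_sd=0.5, seed=7)
epochs = synthetic.generate_epochs(cfg, n_epochs=6)
phase, amp_d, amp_b = preprocess_epoch_matrix(
    np.stack([e.samples for e in epochs]), cfg.sampling_rate)

est = cfc.debiased_pac(phase.ravel(), amp_b.ravel())
null = cfc.surrogate_null(list(phase), list(amp_b), n_perm=1000, seed=7)
z = cfc.dpac_z(est, null)
aac = cfc.amplitude_correlation(amp_d.ravel(), amp_b.ravel())
print(f"|PC|  = {est.pc_magnitude:.4f}")
print(f"dPAC  = {est.dpac_magnitude:.4f}  (raw PAC {est.pac_magnitude:.4f})")
print(f"dPACz = {z:.2f}  (null mean {null.mean:.4f}, sd {null.std:.4f})")
print(f"AAC r = {aac.r:.3f} over n = {aac.n_samples} timepoints")
```

prints

```
|PC|  = 0.0039
dPAC  = 0.0629  (raw PAC 0.0640)
dPACz = 4.77  (null mean 0.0170, sd 0.0096)
AAC r = 0.154 over n = 5952 timepoints
```

The phase distribution is essentially uniform (|PC| ≈ 0), so dPAC barely
differs from the raw mean vector; the injected modulation (depth 0.6 of a
0.25-amplitude beta carrier, attenuated by noise and filtering) is
detected at 4.8 null standard deviations, and the injected envelope
correlation (0.4, diluted by in-band noise) appears as AAC ≈ 0.15.

The same analysis is available from the shell. A full synthetic study —
cohort generation, coupling metrics, within/between-group tables with
FDR-corrected p-values — is one command:

```sh
deltabeta run-study --out results/study --seed 7
deltabeta validate --out results/validation.tsv --n-subjects 30 --seed 3
```

`validate` analyzes matched simulations with and without injected
coupling and reports, among others, the one-sided coupled-vs-uncoupled
dPAC contrast and whether AAC is significant only where it was injected:

```
coupling-on > coupling-off dPAC: True; AAC specific to injected coupling: True
```

## Package layout

| module | contents |
|---|---|
| `deltabeta.synthetic` | `SimulationConfig`, epoch/cohort generators, phase-clustering warp |
| `deltabeta.preprocessing` | epoching, clean-epoch selection, decimation, zero-phase band-pass, Hilbert, trimming |
| `deltabeta.cfc` | PC, dPAC, surrogate null, dPACz, AAC, electrode composite |
| `deltabeta.stats` | Wilcoxon, Mann-Whitney, Spearman, BY-FDR, result tables |
| `deltabeta.pipeline` | `run_study`, `validate_with_simulation`, study configs |
| `deltabeta.io` | `.npz` cohort container read/write, EDF reading (MNE) |
| `deltabeta.cli` | `deltabeta simulate / preprocess / cfc / stats / run-study / validate` |
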