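# lysoscan

Analysis pipeline for intravital line-scan fluorescence recordings of kidney
proximal-tubule (PT) cells: singular value decomposition (SVD) of
spatiotemporal intensity waveforms into endo-lysosomal processing
components, together with a compartmental forward simulator, whole-tubule
kinetic metrics and in-silico tryptic-peptide tools.

## The problem

Proteins filtered by the glomerulus are endocytosed in early (S1) PT
segments, trafficked through an endo-lysosomal system (ELS) of early
endosomes (EE), large apical vacuoles (LAV) and lysosomes, degraded, and the
fragments released for reabsorption downstream. In vivo these compartments
overlap spatially within a cell a few micrometers across, and no reliable
in vivo molecular markers exist — so intracellular intensity profiles mix
the signals of several processes. Densely dye-labeled reporter proteins
self-quench; proteolysis relieves the quenching, so fluorescence reports
degradation in real time.

The pipeline disentangles these overlapping processes model-free. Line-scan
profiles drawn across cells (~50 per tubule, apical→basolateral position
rescaled to [0, 1]) are mean-binned per time point into a space × time
waveform matrix **A** (m position bins × n time points) and factorized

    A = U S Vᵀ

where columns of **U** are spatial base vectors, columns of **V** the
matching kinetic time courses, and the singular values in **S** order the
components by their contribution. The number of relevant base vectors is
selected by scanning components in order of decreasing singular value and
retaining those whose singular-value amplitude share s\_i/Σs is above a
noise floor (default 1%) **and** whose spatial and temporal vectors are both
smooth (lag-1 autocorrelation ≥ 0.5); setting the remaining singular values
to zero yields a denoised reconstruction. On healthy-tubule data this yields
three base vectors whose spatial/kinetic signatures localize to the major
ELS structures (broad mid-cell biphasic LAV signal, early sub-apical EE
transient, narrow mid-cell delayed lysosomal signal).

No raw intravital recordings are publicly deposited, so the package ships a
forward simulator that generates waveforms, whole-tubule time series and
axial uptake profiles with the statistical structure the analysis assumes —
including self-quenching photophysics (intact brightness n·q^(n−1),
degraded brightness n, unquenching gain q^(1−n)), cathepsin inhibition,
labeling-density changes and disease-like perturbations (reduced uptake,
delayed apical transit). Every analysis stage is exercised and tested
against this generator; see `docs/methods.md` for what that does and does
not demonstrate about real recordings.

## Worked example

```python
from lysoscan import healthy_s1, decompose, select_rank, simulate_waveform

wf = simulate_waveform(healthy_s1(seed=0))   # 100 bins x 60 min
result = decompose(wf)
print(select_rank(result))
print(result.diagnostics.head(4).to_string(index=False))
```

```
3
 component  singular_value  amplitude_share  autocorr_U  autocorr_V  retained
         0       66.474410         0.653104    0.985614    0.921832      True
         1        8.125327         0.079830    0.991288    0.946288      True
         2        2.584564         0.025393    0.953457    0.942886      True
         3        0.823677         0.008093   -0.059860   -0.185070     False
```

Three components are retained: the first three singular vectors are smooth
in space and time and carry 65%/8.0%/2.5% of the singular-value sum, while
component 4 sits at the noise floor with autocorrelations near zero. The
retained spatial shapes and singular-value-weighted kinetic amplitudes are
the per-component readouts (`component_readouts`), and
`reconstruct(result, 3)` is the denoised waveform.

The numbered scripts under `analysis/` run the full study on the six named
scenarios (healthy-S1, e64-inhibited, low/high-label, OCRL-like,
ClC-5-like): simulation, preprocessing, decomposition, perturbation
contrasts, kinetic metrics and peptide tables, writing results under
`results/`. The same stages are available from the shell via the `lysoscan`
CLI (`simulate`, `preprocess`, `decompose`, `kinetics`, `digest`, `run`).

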