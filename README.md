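# mitool — motor-imagery EEG classification

`mitool` is a toolkit for decoding multi-class motor-imagery EEG: which of K
imagined movements (left hand, right hand, foot, tongue …) produced a given
multichannel epoch. Imagined movement modulates the power of the sensorimotor
µ/β rhythms (event-related de/synchronization), so the discriminative
information lives in the *spatial pattern of band-limited variance*. The
package implements the classical decoding chain as a tested library plus a
small CLI:

* **Preprocessing** — 50 Hz notch, 8–26 Hz bandpass (FIR or zero-phase IIR),
  common average reference, small Laplacian (4-neighbor or distance-weighted).
* **Features** — common spatial patterns (CSP): whiten the summed class
  covariances R̄_A + R̄_B, simultaneously diagonalize them (the per-class
  eigenvalues obey λ_A + λ_B = 1), keep the m most extreme filters per end,
  and form 2m features f_p = log₁₀(var(Z_p)/Σᵢ var(Zᵢ)). Periodogram, STFT
  power spectral density and Mallat wavelet sub-band energies are also
  provided.
* **Classifiers** — soft-margin RBF SVMs (dual: max Σα − ½ΣΣ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ),
  0 ≤ α ≤ C, Σαy = 0) with (C, g) selected by stratified 5-fold grid search
  (ties → smallest C, then first g), arranged into four multi-class
  topologies: one-vs-rest, one-vs-one voting, Platt's decision DAG, and a
  two-layer decision tree over class groups.
* **Synthetic data** — a seeded generator of 4-class epochs whose classes
  differ in band-limited source variance under a fixed mixing matrix, used
  throughout the tests.

Data formats: EDF (read via MNE; a minimal writer is included) or delimited
text, plus a TSV of epoch onsets/labels and an optional YAML montage.

## Worked example

```python
from mitool import easy_preset, generate, train_multiclass, evaluate

train, test = generate(easy_preset(seed=35))        # 160 + 160 labeled epochs
model = train_multiclass(train, scheme="ovo", csp_m=2, svm_config={"seed": 35})
accuracy, confusion = evaluate(model, test)
print(model.n_svms, f"{accuracy:.1f}%")
print(confusion)
```

```
6 100.0%
[[40  0  0  0]
 [ 0 40  0  0]
 [ 0  0 40  0]
 [ 0  0  0 40]]
```

Six pairwise SVMs (K=4 classes → K(K−1)/2 pairs), each on its own CSP
features; the vote recovers every test epoch's class on the easy preset. The
confusion matrix rows are true classes, columns predictions.

The same pipeline from the shell:

```bash
mitool synth --preset easy --seed 7 --out-train train.edf --out-test test.edf \
             --events-train ev_train.tsv --events-test ev_test.tsv
mitool train --data train.edf --events ev_train.tsv --scheme two_layer --out bundle
mitool predict  --model bundle --data test.edf --events ev_test.tsv --out pred.tsv
mitool evaluate --model bundle --data test.edf --events ev_test.tsv --out report.json
```

See `docs/methods.md` for the model, parameter defaults and the generator's
assumptions.

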