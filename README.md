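# entroscan

Kernel-density-estimation (KDE)-based parallelized ultrasound Shannon
entropy imaging, for quantitative ultrasound tissue characterization —
with hepatic steatosis assessment as the driving application.

Ultrasound backscatter envelope statistics carry information about tissue
microstructure: normal liver parenchyma scatters quasi-regularly, while
fat infiltration adds randomly distributed scatterers, increasing the
uncertainty of the backscattered signal. `entroscan` turns a raw
radiofrequency (RF) frame into **entropy parametric images** by sliding a
small gating window (1 pulse length × 1 pulse length, 90% × 90% overlap)
across the envelope image and estimating, per window, the Shannon entropy
of the gated envelope values in two ways:

* **E_hist** (bits): `E = -Σ pᵢ log₂ pᵢ`, with probabilities from a 40-bin
  histogram of the window values — the conventional estimator, bounded by
  `[0, log₂ 40]` and sensitive to histogram settings;
* **E_KDE** (nats): the differential entropy `E = -(1/N) Σᵢ ln f(Zᵢ)`,
  where `f(z) = (1/Nh) Σᵢ K((z-Zᵢ)/h)` is a Gaussian-kernel density
  estimate with the fully data-adaptive bandwidth
  `h = β (4/(3N))^{1/5}`, `β = mean|S - mean S|` (Scott's rule with the
  mean absolute deviation) — parameter-free, exactly scale-equivariant
  (`E(aS) = E(S) + ln a`), and with a much larger imaging dynamic range.

Around the estimators sit: Hilbert-transform envelope detection, B-mode
rendering (40 dB), a block-parallel entropy map whose result is
bit-identical for any worker count, bilinear map interpolation, linear and
convex-array scan conversion, ROI statistics (mean, Emax, Emin,
DR = Emax − Emin), a synthetic speckle-phantom generator spanning
pre-Rayleigh to fully developed speckle (plus a steatosis-graded liver
stand-in), and a diagnostics layer (Pearson r against log₁₀ fat fraction;
ROC/AUC with DeLong 95% CI, Youden cutoff, sensitivity/specificity, LR±,
PPV/NPV per grade split). See `docs/methods.md` for the model details.

## Worked example

Simulate a moderate-steatosis (G2) phantom frame and image it:

```sh
entroscan phantom --out demo --shape 384x32 --grade 2 --seed 7
entroscan image --input demo/rf.npy --meta demo/rf.json --out demo/out
cat demo/out/stats.csv
```

```
estimator,units,roi_mean,roi_max,roi_min,dynamic_range
hist,bits,4.8552886149609815,5.163739628554159,4.352121257847975,0.8116183707061833
kde,nats,0.7359421495669175,1.91587603406973,-0.12501068385687258,2.0408867179266026
```

Reading the numbers: within the central liver ROI the histogram estimator
averages 4.86 bits — high in its bounded `[0, 5.32]` scale, as envelope
histograms of speckle are broad — but spans only 0.81 bits across the ROI.
The KDE estimator averages 0.74 nats and spans 2.04 nats: its value tracks
both the envelope's shape *and* the local signal power (log scale), so
attenuation and parenchymal echogenicity variation spread its map over a
dynamic range ~2.5× the histogram map's, which is the practical advantage
of the KDE route for parametric imaging. The run also writes `bmode.png`,
color-mapped `entropy_{hist,kde}.png`, side-by-side composites, raw map
arrays, and a `manifest.json` capturing the effective configuration.

A cohort-level rehearsal of the diagnostic analysis (ROC per steatosis
grade split on synthetic subjects):

```sh
entroscan eval --grades 10,10,5,5 --seed 3 --out demo/eval
```

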