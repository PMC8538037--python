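# vicmorph

Single-cell morpho-mechanical analysis of aortic valve interstitial cells
(VICs) cultured on flat versus nanostructured, extracellular-matrix-like
substrates.

Healthy valve interstitium mixes smooth-muscle-like cells (SMc),
fibroblasts (Fib) and a small myofibroblast (myFib) fraction; expansion of
the stiff, α-SMA-rich, stress-fiber-laden myofibroblasts marks the
pro-calcific activation seen in calcific aortic valve disease. Fibrous
nanotopographies can hold cultured VICs in a quiescent, fibroblast-like
state. Quantifying that requires a chain of single-cell measurements —
shape morphometry, morphology-based phenotype classification,
immunofluorescence quantification, and AFM stiffness mapping — which this
package implements as a tested, reusable library for image analysts and
mechanobiologists, together with seeded synthetic-data generators so the
entire chain is validated by parameter recovery without any microscope.

## What it computes

* **Morphometry** (`vicmorph.morphometry`) — per-cell area A, Crofton
  perimeter P, degree of circularity DOC = 2√(πA)/P, elongation
  x = 1 − width/length of the minimum-area rotated bounding rectangle,
  axis ratio 1/(1 − x), and an automated cusp (protrusion-tip) count.
* **Classification** (`vicmorph.classify`) — `ElongationKMedoids`, an
  exact 1-D 3-class k-medoids solved by dynamic programming (no restart
  stochasticity), with soft membership and a 90% inclusion rule. Classes
  ordered myFib < Fib < SMc by elongation; reference decision thresholds
  0.551 and 0.817.
* **Fluorescence quantification** (`vicmorph.fluoquant`) — nuclei/mm² from
  DAPI fields, focal-adhesion density (vinculin⁺ area per cell area after
  cytosolic-background subtraction), α-SMA/actin surface ratio, and
  stress-fiber density via multiscale ridge filtering. All in µm²/µm².
* **AFM force spectroscopy** (`vicmorph.afm`) — contact-point estimation
  (change-point scan + forward-model refinement), spherical-indenter Hertz
  fit F = (4/3)·E/(1−ν²)·√R·δ^{3/2} (`HertzModel`, E in kPa, 250 nm
  indentation window), and ISO-style tilt-levelled line roughness R_rms.
* **Statistics** (`vicmorph.stats`) — Shapiro–Wilk-routed t-test /
  Mann–Whitney U, two-way (morphology × substrate) type-II ANOVA with
  Bonferroni post-tests, and the *, **, *** star convention.
* **Synthetic data** (`vicmorph.synth`) — seeded generators for cell
  masks (three morphology classes with independent area/elongation/tip
  control), hard-core Poisson nuclei fields, exactly-painted two-channel
  marker images, Hertz force curves, and height profiles — each recording
  its ground truth.
* **Pipeline** (`vicmorph.pipeline`) — `run(config)` chains all stages
  under one seed; `glass_like_config()` / `cnt_like_config()` encode the
  two substrate conditions; `compare_conditions()` produces routed
  statistics per metric and class.

## Worked example

```python
import numpy as np
from vicmorph import synth, morphometry, classify, afm

# one synthetic myofibroblast, measured
cell, truth = synth.gen_cell_mask(synth.default_shape_params("myFib"), rng_seed=7)
f = morphometry.measure_features(cell)
print(f"area={f.area_um2:.0f} um^2  DOC={f.doc:.3f}  "
      f"elongation={f.elongation:.3f}  cusps={f.n_cusps}")
# area=997 um^2  DOC=0.660  elongation=0.449  cusps=5

# a population, classified
rng = np.random.default_rng(0)
xs, labels = [], []
for _ in range(300):
    cls = ("SMc", "Fib", "myFib")[int(rng.choice(3, p=[0.44, 0.46, 0.10]))]
    c, _ = synth.gen_cell_mask(synth.default_shape_params(cls),
                               rng_seed=int(rng.integers(2**31)))
    xs.append(min(morphometry.elongation(c), 0.999)); labels.append(cls)
model = classify.fit_classifier(xs)
print(np.round(model.boundaries_, 3))     # [0.544 0.823]
acc, sd = classify.evaluate_accuracy(model.predict(xs), labels)
print(f"accuracy {acc:.3f}")              # accuracy 1.000

# an AFM indentation, fitted
p = synth.CurveParams(E_true=5.5, noise_sd=0.05, seed=3)
curve = afm.ForceCurve.from_synthetic(synth.gen_force_curve(p))
fit = afm.analyze_curve(curve)
print(f"E = {fit.E_kPa:.2f} kPa, z0 = {fit.z0_nm:.0f} nm")
# E = 5.51 kPa, z0 = 500 nm
```

The first block renders a ~1000 µm² stellate cell and reads back its
shape: a DOC of 0.66 (well below the circular limit of 1), moderate
elongation, five protrusion tips. The second fits the exact k-medoids
classifier on a mixed population and recovers decision boundaries within
a few thousandths of the reference 0.551/0.817, classifying every cell
correctly against the generator's labels. The third estimates a 5.5 kPa
modulus and a 500 nm contact point from a noisy simulated force curve.

## Layout

```
src/vicmorph/       library modules (synth, morphometry, classify,
                    fluoquant, afm, stats, pipeline)
tests/              pytest suite incl. end-to-end recovery tests
scripts/acceptance.py   recovery-run entry point
docs/methods.md     models, conventions, tolerances, limitations
```
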