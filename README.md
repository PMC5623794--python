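# radiopos

Automatic radiographic position recognition from image frequency and
intensity. Given a single digital radiograph, `radiopos` answers two
questions a PACS/RIS archive pipeline needs answered for every incoming
exposure, without DICOM header metadata:

1. **Which body position was imaged?** (head, lungs, lumbar spine, pelvis,
   knee joint, or limbs)
2. **Which anatomical region does the exposure cover?** — reported as a
   rectangle on an anatomically annotated whole-body phantom template,
   together with the named organs it overlaps.

It is a library first (importable modules, narrative scripts under
`examples/`), with a thin `radiopos` command-line wrapper for shell use.

## Method

**Classification** reduces the 2D image to a 1D spectral curve. After
preprocessing (linear histogram stretch to 16 bit, 5×5 median filter,
optional CLAHE), the normalized Fourier magnitude

```
F(u,v) = (1/MN) · Σₓ Σ_y f(x,y) · e^{-j2π(ux/M + vy/N)}
```

is reduced to ring means over the lowest 2 % of the radial frequency range
(DC excluded) — the *frequency curve* f(w), plus its area under the curve
(AUC). An input curve is compared with six position-labelled reference
curves F(w) by the root-mean-square difference

```
a = sqrt( Σᵢ (fᵢ − Fᵢ)² / n )
```

and, when the two best matches are nearly tied (both a < 0.02 on the
library's normalized amplitude scale), by the cosine of the angle between
the curves, cos θ = f·F / (‖f‖‖F‖), which compares curve *shape*
independently of amplitude.

**Localization** slides the preprocessed input I over the whole-body
template (both downscaled by a common factor, default 0.25) and computes
two score maps per offset: the energy-normalized matrix product
`M = Σ I·W / Σ I²` and the Pearson correlation `R` of I with the template
window W. The recognized region T is the intersection of the input-sized
rectangles at the two maps' maxima (R's rectangle alone if they are
disjoint); the overlapping atlas regions label it anatomically.

Because no phantom radiographs are distributed, the `synth` module
generates the whole-body template (2000×800 pixels for a 165 cm body) with
six structurally distinct zones, plus labelled noisy/exposure-varied crops
— it is the package's data source for libraries, tests and benchmarks.

## Worked example

```python
import radiopos as rp

cfg = rp.SynthConfig(seed=1, template_shape=(2000, 800),
                     n_per_position=12, n_library=10)
template = rp.make_phantom(cfg)
records, samples = rp.make_dataset(template, cfg)
groups = {p: [] for p in rp.POSITIONS}
for rec, s in zip(records, samples):
    if rec.split == "library":
        groups[s.position].append(s.image)
library = rp.build_library(groups)

sample = next(s for r, s in zip(records, samples)
              if r.split == "eval" and s.position == "pelvis")
result = rp.recognize(sample.image, library, template, scale=0.25)
```

Running `python examples/04_locate_and_annotate.py` (the script behind the
snippet) prints:

```
true position: pelvis, true box (1019, 140, 260, 480)
recognized:    pelvis (decided by mean_variance)
matched box:   (1020, 140, 260, 480)  IoU with truth 0.992
score-map agreement (M vs R rectangles): 1.000, fallback=False
anatomical labels covered:
  pelvis   overlap 0.88
```

The noisy pelvis crop (5 % Gaussian noise, exposure gain drawn from
0.8–1.2) is classified by the smallest mean-variance score and localized
to within one pixel of its true source window; 88 % of the matched box
lies inside the atlas's pelvis region. The other scripts in `examples/`
walk through preprocessing invariance, signature curves and AUCs, and the
classifier's audit output.

The same workflow is available from the shell:

```
radiopos simulate --out-dir study --seed 1
radiopos build-library --manifest study/manifest.csv --out study/library.json
radiopos recognize study/images/head_010.png --library study/library.json \
    --template study/atlas.png --regions study/regions.yaml --render overlay.png
radiopos batch --manifest study/manifest.csv --library study/library.json \
    --template study/atlas.png --regions study/regions.yaml --out results.csv
```

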