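# fibrequant

Automated per-fibre quantification of sarcolemmal proteins and regeneration
markers in multiplexed immunofluorescent (IF) whole-slide images of transverse
skeletal-muscle sections.

## The problem

The molecular endpoint of most Duchenne muscular dystrophy (DMD) trials is the
induction of dystrophin at the myofibre membrane (sarcolemma). Quantifying it
objectively is hard: expression is heterogeneous across fibres (trace dystrophin
in DMD, revertant fibres, variable Becker-type expression), background
fluorescence varies across a section, and global intensity thresholds therefore
misclassify low-level signal. `fibrequant` implements a digital analysis of
three-channel IF sections — a laminin α2 membrane mask, a primary sarcolemmal
stain (dystrophin), and a tertiary stain (a dystrophin-associated protein such
as α-sarcoglycan / β-dystroglycan, or fetal/developmental myosin) — that scores
every intact transverse fibre individually.

## The method

For each fibre segmented from the laminin mask and partitioned into a
sarcolemmal ring and sarcoplasm:

* **Per-fibre background threshold.** The cytoplasm carries no functional
  sarcolemmal protein, and its background is taken as equal to the sarcolemmal
  background, so significant membrane staining is anything above

  `T = mean(sarcoplasm) + k · sd(sarcoplasm)`  (default `k = 3`),

  computed independently per fibre — no arbitrary global cut-off, and the
  threshold adapts to local background. Intensities are always reported **raw**
  (no background subtraction).

* **Circumference Positivity.** Supra-threshold ring pixels form connected
  *positive objects*; their summed circumferential extent as a proportion of
  the ring mid-line circumference is the coverage statistic

  `CP = Σ_objects extent / circumference × 100  ∈ [0, 100] %`.

  The default estimator projects object pixels onto the mid-line and measures
  covered arc length; a second estimator computes
  `Σ (border length − 2 × radial width) / 2` in pixel-edge units, and a
  brute-force angular ray sweep serves as an independent cross-check.

* **Coverage classes.** Each fibre falls into 0–25 / 25–50 / 50–75 / 75–100 %
  coverage; `CP > 25 %` defines a protein-positive fibre (exactly 25.0 % stays
  negative).

* **Colocalisation.** For sarcolemmal tertiary stains, the raw tertiary mean is
  reported separately over primary-positive and primary-negative ring regions —
  a direct surrogate for whether dystrophin assembles its associated complex.

* **Regeneration.** For sarcoplasmic f/d-myosin, a fibre is positive when its
  mean sarcoplasmic intensity exceeds a threshold derived from negative control
  sections (99.5th percentile of control fibre means by default).

Morphometrics (areas, minimum-Feret widths, sarcolemma thickness profile,
circumference) are reported in µm/µm², and section summaries include % positive
fibres, mean per-fibre sarcolemmal intensity, class histograms and
cumulative-frequency tables.

Because no public IF muscle WSIs accompany the method, the package ships a
synthetic-section generator (`fibrequant.synthetic_section`) that renders
packed polygonal fibres with laminin rings, dystrophin arcs of exact known
coverage, coupled tertiary staining, noise and injected artefacts — every
pipeline stage is validated against this ground truth.

## Worked example

```python
import fibrequant as fq

spec = fq.SectionSpec(n_fibres=12, primary_coverage_fractions=[0.0, 0.3, 0.6, 1.0], seed=7)
stack, truth, labels = fq.generate_section(spec)
result = fq.analyse_section(stack)

s = result.summary
print(f"fibres analysed : {s.n_fibres_analysed}")
print(f"% positive      : {s.pct_positive:.1f}")
print(f"mean sarcolemmal dystrophin intensity : {s.mean_sarcolemma_intensity:.0f} AU")
print(f"class counts    : {s.class_counts}")
r = result.records[0]
print(f"fibre 1: area {r.fibre_area_um2:.0f} um^2, width {r.fibre_width_um:.1f} um, "
      f"coverage {r.circumference_positivity:.1f}% ({r.coverage_class}), "
      f"threshold {r.primary_threshold:.0f} AU")
```

prints

```
fibres analysed : 12
% positive      : 75.0
mean sarcolemmal dystrophin intensity : 18415 AU
class counts    : {'0-25': 3, '25-50': 3, '50-75': 3, '75-100': 3}
fibre 1: area 748 um^2, width 30.5 um, coverage 100.0% (75-100), threshold 9475 AU
```

The twelve fibres cycle through true coverages 0/30/60/100 %, so three of each
class and 9/12 = 75 % positive is the exact expectation; the section mean
intensity mixes the 30000 AU arcs with the 8000 AU background along each ring.

### Command line

```bash
fibrequant simulate --config config.yaml --out sim/ --seed 3      # synthetic section + truth
fibrequant run --image section.tiff --config config.yaml --out out/
fibrequant myosin-threshold ctrl1/fibres.csv ctrl2/fibres.csv --out threshold.json
fibrequant run --image test.tiff --config config.yaml --out out/ --myosin-threshold threshold.json
fibrequant compare-replicates out1/summary.json out2/summary.json --out report.json
```

`run` writes the per-fibre CSV, the section summary JSON, a Fig.-3-style
classification map PNG (four class colours, yellow for unrecognised tissue) and
the rejected-candidate log.

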