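# cometkit

Automated analysis of comet-assay images — single-cell gel electrophoresis
micrographs in which damaged DNA has migrated out of each nucleus, forming
a comet-shaped fluorescent object whose tail reflects the damage.

High-throughput assays produce images with dozens of arbitrarily placed,
frequently overlapping comets plus debris, and scoring them by hand is the
rate-limiting step. `cometkit` detects every comet in such an image with no
assumptions about count or position, separates overlapping comets, and
characterizes each one, for toxicologists and DNA-repair labs who need
per-cell damage quantification at scale.

## The method

The pipeline runs four stages:

1. **Preprocessing** — median (or moving-average) smoothing to suppress
   shot noise before thresholding.
2. **Binarization** — a gray-level histogram is built and the *first
   valley* after the background peak is used as the threshold. Comet
   histograms always peak at the background intensity; Otsu's
   between-class-variance threshold lands high inside the bright comet
   range and misses faint (typically apoptotic) cells, while the first
   valley sits between the background and Otsu's threshold and keeps them.
   Candidates are labeled by 8-connectivity.
3. **Filtering and overlap correction** — border-touching components are
   removed; components below 0.1% of the image are merged into the closest
   comet. Each remaining component is split by a watershed on its
   Euclidean distance relief, after Haar-wavelet smoothing of the relief
   (shallow pits cause over-segmentation); vertically stacked chunks
   sharing a column span are re-merged, and each chunk must look like a
   cell — the two lowest contour-Fourier frequencies must carry ≥ 70% of
   the spectrum amplitude and the chunk ≥ 3% of its parent mask.
4. **Characterization and classification** — with intensity read as mass,
   each comet's per-column profile gives the head peak CPH, the head
   radius `r` (first column below HT × peak, HT the user-set head
   threshold), the tail from the head's right end to the last positive
   column, and

   ```
   DNA    = Σ_{x∈comet} I(x)              TDNA  = Σ_{x∈tail} I(x) / DNA
   extent moment  = TDNA × tail length    Olive moment = TDNA × (CMT − CPH)
   moment of inertia = Σ_{x∈tail} I(x)(CPH − x)² / DNA
   ```

   where CMT is the tail's intensity-weighted mean column. Optional
   classification into normal / necrosis / apoptosis uses HOG descriptors
   (9 bins, 8×8 cells, 2×2 blocks: 900 features on the 50×50 resize, 360
   on the 25×50 left half) plus the bounding-box width/height ratio, with
   linear-SVM cascade, softmax, AdaBoost and CART back ends.

A seeded synthetic-scene generator (`cometkit.synth`) renders comets of
all three morphology classes with full ground truth — masks, centroids,
and records computed from the noiseless model by the same equations — so
every stage is testable without microscope data, and `cometkit.evaluate`
provides the region-based and centroid-based precision/recall/F1 metrics
(15 px match radius) used to score detection.

## Worked example

```python
import cometkit as ck

image, truth = ck.compose_scene(n_comets=18, overlap_rate=0.2, n_debris=8,
                                seed=41)
result = ck.analyze_image(image)
match = ck.centroid_match([r.centroid for r in result.records],
                          truth.centroids, radius=15)
```

prints (via `python examples/analyze_scene.py`):

```
threshold 28 (valley); stage counts {'candidates': 23, 'after_border_filter': 23,
 'after_fragment_merge': 16, 'after_overlap_correction': 16}
16 comets detected / 18 true
detection: TP=16 FP=0 FN=2 precision=1.00 recall=0.89 F1=0.94
 id   tdna tail_len  extent   olive  inertia
  1  0.503       29   14.60   12.05    311.1
  2  0.135        9    1.22    3.99    118.5
```

The valley threshold (28) sits just above the background peak (~10);
23 candidate components become 16 comets after debris merging and overlap
splitting. Comet 1 carries half its DNA in a 29 px tail (extent moment
14.6); comets 3–5 are nearly undamaged. The two misses are a deeply
overlapping pair the watershed could not separate — the known hard case.

Other runnable walk-throughs live in `examples/`: single-comet
measurement, overlap splitting, damage-state classification, and the
heterogeneity-of-response summary. A thin CLI wraps the same calls:
`cometkit run image.png`, `cometkit synth`, `cometkit evaluate`,
`cometkit classify-train`, `cometkit batch`.

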