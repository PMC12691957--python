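# symstrain

Symmetry-aware two-stage detection of muscle-strain lesions in bilateral
B-mode ultrasound.

Muscle strain appears on B-mode ultrasound as a focal hypoechoic region
that interrupts the bright striated texture of healthy fascicles. Because
speckle and connective-tissue bands produce many lesion look-alikes, a
single texture-based detector run at a recall-oriented operating point
drowns in false positives. Clinicians resolve ambiguous findings by
comparing with the *same anatomical site on the other side of the body*;
`symstrain` implements that strategy as a two-stage cascade for anyone
studying symmetry-aware detection pipelines on paired medical images:

1. **Proposal stage.** An anchor-based single-class detector with three
   heads at strides 32/16/8 (three anchors per location, `3 × (4 + 1 + 1) =
   18` prediction channels per head) proposes scored boxes.
2. **Routing.** With thresholds `T1 < T2`, detections with confidence
   `c < T1` are suppressed, `c ≥ T2` are accepted outright, and the
   ambiguous band `T1 ≤ c < T2` is forwarded for verification
   (defaults `T1 = 0.01`, `T2 = 0.20`).
3. **Verification stage.** For each forwarded box, four candidate
   contralateral reference patches (the exact mirror position plus three
   ±32 px jitters, 128 × 128 px each, re-oriented to the index side) are
   localized with HOG descriptor matching and scored by a Siamese CNN with
   a tanh output in [−1, 1] (−1 = similar = artifact, +1 = dissimilar =
   lesion), trained with MSE against ±1 labels. A forwarded box survives
   only if its reference comparisons vote "dissimilar".

Because clinical bilateral ultrasound data cannot be redistributed, the
package ships a speckle-phantom generator (`symstrain.phantom`) that
emulates the statistical structure the cascade relies on — mirrored
anatomy, multiplicative speckle, striation, unilateral hypoechoic lesions
with known boxes, small inter-side translations, and bilateral symmetric
distractors that are *not* lesions — plus the full paired evaluation
protocol: IoU matching, precision/recall/Fβ, all-point-interpolated mAP,
patient-level k-fold splits with an a-priori hold-out, stratified
patient-level bootstrap CIs, and Cohen's/Fleiss' κ for reader panels.

Both networks train on a compact self-contained numpy layer stack
(`symstrain._nn`) — im2col convolutions with hand-derived backward passes
and an Adam optimizer — so the whole pipeline runs on a single CPU.

## Worked example

```python
import symstrain as ss
from symstrain.detector import DetectorConfig, train_detector, detect
from symstrain.filternet import FilterConfig, train_scnn
from symstrain.symmetry import mine_training_pairs
from symstrain.cascade import CascadeConfig, route, verify
from symstrain.evaluation import MatchResult, match_detections, precision_recall, fbeta

# synthetic bilateral cohort: 15 patients x 2 pairs for detector training
train = ss.generate_dataset(15, 2, ss.PhantomParams(seed=11))
det, trace = train_detector(train, DetectorConfig.desk_scale(), epochs=60, seed=0)

# mine labeled contralateral patch pairs from a lesion-rich cohort
mine_cohort = ss.generate_dataset(
    60, 2, ss.PhantomParams(seed=11, n_lesions=4, lesion_axes_range=(14.0, 34.0)))
mined = [p for i, c in enumerate(mine_cohort)
         for p in mine_training_pairs(c, seed=100 + i)]
scnn, log = train_scnn(mined, FilterConfig.desk_scale(seed=0))

# held-out cohort: plain detector vs cascade at T1=0.01, T2=0.20
test = ss.generate_dataset(15, 2, ss.PhantomParams(seed=999))
cfg = CascadeConfig()
base, casc = MatchResult(0, 0, 0), MatchResult(0, 0, 0)
for pair in test:
    for side in ("left", "right"):
        dets = detect(det, pair.image(side), conf_floor=cfg.T1)
        r = route(dets, cfg)
        kept = r.accepted + verify(r.forwarded, pair, side, scnn, cfg=cfg)
        base = base + match_detections(dets, pair.boxes(side))
        casc = casc + match_detections(kept, pair.boxes(side))
for name, m in (("detector", base), ("cascade", casc)):
    p, r = precision_recall(m)
    print(f"{name}: P={p:.3f} R={r:.3f} F1={fbeta(p, r, 1):.3f} F2={fbeta(p, r, 2):.3f}")
```

On the fixed seeds above this prints (one CPU, ~8 minutes end to end):

```
detector: P=0.029 R=0.817 F1=0.057 F2=0.128
cascade: P=0.054 R=0.800 F1=0.101 F2=0.213
```

Verification against the contralateral side removes about half of the
false positives (1623 → 839 on this cohort) and nearly doubles precision,
while recall drops by less than 0.02: bilateral distractors and speckle
look-alikes proposed at low-to-mid confidence match their mirrored
reference and are discarded, whereas true unilateral lesions do not match
and survive. The recall-oriented floor `T1 = 0.01` intentionally admits a
very large candidate pool, which is why the absolute precision of the
unfiltered detector is so low.

The same pipeline is scriptable from the shell:

```
symstrain --seed 11 simulate --out data/ --n-patients 15 --pairs-per-patient 2
symstrain --seed 0 train-detector --data data/ --out models/det --epochs 60
symstrain --seed 0 mine-pairs --data data/ --out mined/
symstrain --seed 0 train-filter --pairs mined/ --out models/scnn
symstrain evaluate --data data/ --detector models/det --filter models/scnn --out report.json
symstrain sweep --data data/ --detector models/det --filter models/scnn --out sweep.csv
```

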