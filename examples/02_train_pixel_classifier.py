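"""Train the tubule/tissue/background pixel classifier from sparse discs.

Mimics the study protocol: three small annotations per class per image,
over two fully stained scenes and two antibody controls per marker (six
images). Features are Gaussian intensity, gradient magnitude, structure
tensor coherence and Hessian determinant at four scales, fed to a small
MLP. Prints training accuracy and held-out segmentation quality (IoU).
"""

from dataclasses import replace

from tubulopy import pixelclass, synthdata
from tubulopy.synthdata import REGION_CODES

spec = synthdata.SceneSpec(
    size_px=640, n_tubules=2, tubule_radius_um=(40.0, 55.0), seed=7
)

training = []
for i, (img, gt, omitted) in enumerate(synthdata.scene_pair_with_controls(spec)):
    ann = synthdata.sparse_annotations_from_truth(gt, k_per_class=3, seed=100 + i)
    kind = f"control (no {', '.join(omitted)})" if omitted else "fully stained"
    print(f"training image {i}: {kind}, {len(ann)} annotations")
    training.append((img, ann))

model = pixelclass.train_pixel_classifier(training, seed=7)
print(f"trained on {model.meta['n_training_pixels']} annotated pixels, "
      f"training accuracy {model.training_accuracy:.3f}")
model.save("pixel_classifier.json")

img, gt = synthdata.generate_scene(replace(spec, seed=999))
pred = pixelclass.predict_pixels(model, img)
refined = pixelclass.refined_class_map(pred, img.pixel_size_um)
for cls, code in REGION_CODES.items():
    m_pred = refined == pred.class_names.index(cls)
    m_true = gt.region_labels == code
    iou = (m_pred & m_true).sum() / (m_pred | m_true).sum()
    print(f"held-out IoU {cls:10s} {iou:.3f}")
# IoU ~0.9+ per class means the classed ROIs downstream carry the right
# pixels; the model file is portable JSON and refuses other channel sets.
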