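"""Annotation workflow: Labelme -> COCO, augmentation, train/val split.

Exports Labelme-style polygons from a synthetic scene, converts them to
a COCO instances document, applies an annotation-consistent flip and
scale, and splits a small dataset 9:1.
"""

import numpy as np

from podmetrics import random_scene, render_scene
from podmetrics.dataset_io import (
    AugmentationSpec,
    LabeledInstance,
    apply_augmentation,
    split_dataset,
    to_coco,
)
from podmetrics.synthetic import export_annotations

# ten one-scene "images" worth of annotations
instances = []
for i in range(10):
    spec = random_scene(n_pods=2, seed=i)
    _, gt = render_scene(spec)
    doc = export_annotations(gt, "labelme", f"scene_{i:02d}.png")
    for shape in doc["shapes"]:
        instances.append(
            LabeledInstance(shape["label"], np.asarray(shape["points"]),
                            f"scene_{i:02d}.png", spec.height, spec.width)
        )

coco = to_coco(instances, ["coin", "pod"])
print(f"COCO document: {len(coco['images'])} images, "
      f"{len(coco['annotations'])} annotations, "
      f"categories {[c['name'] for c in coco['categories']]}")

# geometric augmentation moves image and polygons through the same map
img, gt = render_scene(random_scene(n_pods=2, seed=0))
insts = [i for i in instances if i.image_path == "scene_00.png"]
flipped_img, flipped = apply_augmentation(img, insts, AugmentationSpec("hflip"))
print(f"hflip: polygon areas unchanged "
      f"({insts[0].area:.0f} -> {flipped[0].area:.0f} px^2)")
_, scaled = apply_augmentation(img, insts, AugmentationSpec("scale", {"factor": 2}))
print(f"scale x2: polygon area x4 exactly "
      f"({insts[0].area:.0f} -> {scaled[0].area:.0f} px^2)")

train, val = split_dataset(coco, train_fraction=0.9, seed=0)
print(f"9:1 split: {len(train['images'])} train / {len(val['images'])} val "
      "images (image-level, no leakage)")
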