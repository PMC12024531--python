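"""Generate a synthetic EUS phantom cohort and look at its composition.

Each patient gets one class (GIST-like vs leiomyoma-like) and one lesion
size from a truncated normal; each frame varies lesion orientation and
offset and carries multiplicative gamma speckle.
"""
import numpy as np

from euslite import phantom

cfg = phantom.CohortConfig(n_patients=30, seed=1)
ds = phantom.generate_cohort(cfg)
man = ds.manifest

per_patient = man.drop_duplicates("patient_id")
print(f"{len(ds)} frames from {cfg.n_patients} patients")
print("class balance:", per_patient["label"].value_counts().to_dict())
sizes = per_patient["lesion_size_mm"]
print(f"lesion sizes: {sizes.mean():.1f} +/- {sizes.std():.1f} mm "
      f"(target 9.3 +/- 5.7); {100 * (sizes < 20).mean():.0f}% under 20 mm")

rec = ds.records[0]
img = rec.frame.pixels
print(f"\nframe 0: {img.shape}, intensities [{img.min():.2f}, {img.max():.2f}], "
      f"label {rec.frame.label}, lesion mask covers "
      f"{100 * rec.lesion_mask.mean():.1f}% of the frame")

# class contrast: GIST-like lesions are internally heterogeneous
kw = dict(image_height=128, image_width=128, px_per_mm=3.5,
          lesion_diameter_mm=12.0, seed=5)
g_img, g_mask = phantom.render_envelope(phantom.PhantomSpec.for_class("GIST_like", **kw))
l_img, l_mask = phantom.render_envelope(
    phantom.PhantomSpec.for_class("leiomyoma_like", **kw)
)
print(f"\nintra-lesion intensity s.d. (noise-free envelope): "
      f"GIST-like {g_img[g_mask].std():.3f} vs leiomyoma-like {l_img[l_mask].std():.3f}")
# The two classes share the same mean lesion brightness; only texture and
# margin structure separate them.

# speckle is multiplicative with unit mean
field = phantom.apply_speckle(np.full((256, 256), 0.5), looks=25.0, seed=0) / 0.5
print(f"speckle field: mean {field.mean():.3f} (1 expected), "
      f"s.d. {field.std():.3f} (~{1 / np.sqrt(25):.3f} expected)")
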