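"""Exact shape and parameter accounting for the lightweight family.

Builds the canonical 7-unit model, prints its layer table and parameter
totals, the 12-member family grid, and the ResNet-18 baseline count.
"""
from euslite import archnet, resnet

spec = archnet.build_canonical()
print("canonical model (C3) at 360x360 input")
print(f"{'unit':6s} {'kernel':>6s} {'ch':>9s} {'pre-pool':>8s} {'post':>5s} {'params':>9s}")
for u, s in zip(spec.units, archnet.shape_chain(spec)):
    print(f"{s.name:6s} {u.kernel_side:>4d}x{u.kernel_side} "
          f"{u.in_channels:>3d}->{u.out_channels:<4d} {s.side_pre_pool:>8d} "
          f"{s.side_post_pool:>5d} {s.conv_param_count:>9,d}")
print(f"classifier: {spec.classifier_in}->{spec.classifier_out} "
      f"({spec.classifier_in * 2 + 2} params)")

print("\ntotal incl. batch-norm:", f"{archnet.count_parameters(spec):,d}")
print("total excl. batch-norm:", f"{archnet.count_parameters(spec, False):,d}")
# The difference (2,048) is the batch-norm scale/shift terms: 2 x sum(channels).

print("\nfamily grid (depth x final width):")
for s in archnet.build_family():
    print(f"  {s.family_code}: {s.depth} units, final width {s.final_width}, "
          f"{archnet.count_parameters(s):,d} params")

print("\nmax units at 360 px input:", archnet.max_units(360))

rn = resnet.build_resnet18_baseline(in_channels=1, num_classes=2)
print(f"\nResNet-18 (1-channel stem, 2-class head): {rn.parameter_count:,d} params")
print("ratio vs lightweight:",
      round(rn.parameter_count / archnet.count_parameters(spec), 2))
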