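"""Receptive-field arithmetic: why tiny objects need small inputs.

R_i = (R_{i+1} - 1) * stride_i + kernel_i, applied backwards from the
output.  Strided layers grow the receptive field multiplicatively; once a
single output unit sees a patch much larger than a ~10 px larva, the larva
contributes almost nothing to that unit — the motivation for tiling.
"""

from larvacount import LayerSpec, receptive_field

# a small strided stack, input -> output
stack = [
    LayerSpec(kernel_size=3, stride=2),
    LayerSpec(kernel_size=3, stride=2),
    LayerSpec(kernel_size=3, stride=2),
    LayerSpec(kernel_size=3, stride=1),
]
trace = receptive_field(stack, r_out=1)
for i, (layer, r) in enumerate(zip(stack, trace), start=1):
    print(f"layer {i} (k={layer.kernel_size}, s={layer.stride}): R{i} = {r}")
print(f"one output unit sees a {trace[0]}x{trace[0]} px patch of the input")
print("a 10x10 px larval head occupies "
      f"{100 / trace[0] ** 2:.1%} of that patch")
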