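"""Inspect the LGDiffNet architecture at full and desk scale.

Prints the layer table of the published configuration (256x256x3 input,
five encoder/decoder stages, 2^(4+i) transition kernels, dense blocks of
4 x 16 kernels) and the desk-scale variant used for CPU end-to-end runs."""

from vortexdiff.nn import DESK_NET, FULL_NET, LGDiffNet, layer_graph, summary

print("Full-scale configuration:")
print(summary(FULL_NET))

rows = layer_graph(FULL_NET)
pools = [r["out_shape"][1] for r in rows if r["kind"] in ("avgpool", "maxpool")]
print(f"\nEncoder spatial trace: 256 -> {' -> '.join(map(str, pools))}")
print(f"Transition kernels per stage: "
      f"{[FULL_NET.transition_kernels(i) for i in range(1, FULL_NET.stages + 1)]}")

desk = LGDiffNet(DESK_NET, seed=0)
print(f"\nDesk preset: input {DESK_NET.input_side}, stages {DESK_NET.stages}, "
      f"{desk.n_parameters():,} parameters "
      f"(full scale: {sum(r['params'] for r in rows):,})")
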