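"""Walk the modified ResNet18 layer by layer.

The network is a standard 18-layer residual classifier with the global
average pool removed and a 3-node output head, so a 64x64 patch shrinks
64 -> 32 -> 16 -> 8 -> 4 -> 2 and the 512x2x2 feature map feeds the final
fully connected layer directly.  That choice makes the network convertible
into a dense scorer with output stride 32.
"""

from he2ihc import NetworkSpec, build_classifier, layer_output_shape, score_map_size

spec = NetworkSpec()
print(f"{'layer':8s} {'input':>14s} -> {'output':14s}")
for name, cin, cout in layer_output_shape(spec, (64, 64)):
    print(f"{name:8s} {'x'.join(map(str, cin)):>14s} -> {'x'.join(map(str, cout)):14s}")

net = build_classifier(spec, seed=0)
print(f"\ntrainable parameters: {net.num_parameters():,}")
for side in (64, 96, 512, 1024):
    print(f"dense score-map side for a {side}px input: {score_map_size(spec, side)}")
print("(the map grows by one position per 32 input pixels beyond 64)")
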