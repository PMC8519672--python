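"""Build the generator and critic and inspect their structure.

Shows the encoder channel plan, per-layer parameter counts of the classic
full-3d layer configurations, and a forward pass of each network.
"""

import numpy as np

from liverseg import nn
from liverseg.discriminator import CriticSpec, build_discriminator, fuse_inputs
from liverseg.generator import ArchSpec, build_generator, count_parameters, series_conv_block

model = build_generator(ArchSpec(), seed=0)
print("encoder channels:", model.encoder_channels)
print("total trainable parameters:", count_parameters(model))

print("conv 3->32 (1x3x3) params:", count_parameters(nn.Conv3d(3, 32, (1, 3, 3))))
print("series block 32->32 params:", count_parameters(series_conv_block(32, 32)))
print("full3d block 128 params:", count_parameters(series_conv_block(128, 128, "full3d")))

x = np.random.default_rng(0).random((1, 3, 64, 64))  # one slice triplet
probs = model(nn.Tensor(x))
print("generator output:", probs.shape, "range",
      f"[{probs.data.min():.3f}, {probs.data.max():.3f}]")

critic = build_discriminator(CriticSpec(), seed=0)
fused = fuse_inputs(probs.data[0, 0], (probs.data[0, 0] > 0.5).astype(float))
score = critic(nn.Tensor(fused))
print("critic score (unbounded scalar):", float(score.data[0]))

# The generator maps a 3-slice stack to center-slice probabilities in [0,1];
# the critic maps a (prediction, annotation) pair to one real-valued score.
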