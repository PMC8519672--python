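"""Generate a synthetic phantom dataset and round-trip it through the readers.

Writes LiTS-style volume/segmentation NIfTI pairs, reads them back, windows
the intensities to [0, 1], and builds the 2.5D slice triplets the network
consumes.
"""

from tempfile import TemporaryDirectory

import numpy as np

from liverseg import data_io, phantom

with TemporaryDirectory() as tmp:
    spec = phantom.PhantomSpec(shape=(8, 64, 64), seed=0)
    manifest = phantom.generate_phantom_dataset(2, spec, tmp)
    print(f"wrote {manifest['n']} phantom pairs:",
          [c["volume"] for c in manifest["cases"]])

    for idx, vol, mask in data_io.load_dataset(tmp):
        normed = data_io.window_normalize(vol, data_io.WindowSpec(-200, 250))
        triplets = data_io.make_triplets(normed)
        print(f"case {idx}: volume {vol.shape}, foreground fraction "
              f"{mask.mean():.3f}, intensities in "
              f"[{normed.voxels.min():.2f}, {normed.voxels.max():.2f}], "
              f"{len(triplets)} slice triplets")

# The foreground fraction is the size of the synthetic liver relative to the
# volume; windowed intensities span [0, 1]; one triplet exists per slice.
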