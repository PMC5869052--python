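"""Train percentile landmarks and standardize intensity histograms.

Landmark (histogram) standardization learns where a training set's
intensity percentiles sit, then remaps any volume so its own percentiles
land on a fixed standard scale — making the mapping invariant to affine
intensity changes such as scanner gain or offset.
"""

import tempfile
from pathlib import Path

import numpy as np

from voxpipe.phantoms import PhantomSpec, write_phantom_dataset
from voxpipe.preprocessing import histogram_standardize, train_landmarks
from voxpipe.volume_io import load_manifest, load_volume

out = Path(tempfile.mkdtemp())
spec = PhantomSpec(shape=(24, 24, 24), n_organs=2, noise_sd=0.1, seed=3)
index = load_manifest(write_phantom_dataset(spec, 3, out))

model = train_landmarks(index)
print("percentile ranks:", model.percentiles.astype(int))
print("trained landmarks:", np.round(model.per_modality_landmarks['modality0'], 2))

vol = load_volume(index.subjects["subject000"]["image"])
standardized = histogram_standardize(vol, model)
shifted = vol.with_data(vol.data * 3.0 + 250.0)        # simulate a rescaled scan
standardized_shifted = histogram_standardize(shifted, model)
gap = np.abs(standardized.data - standardized_shifted.data).max()
print(f"max difference after affine intensity change: {gap:.2e}")
# The standardized volume is essentially independent of the acquisition's
# linear intensity calibration.  The residual (~1e-3 on a 0-100 scale)
# comes from interpolating between nearly coincident percentile knots of
# this strongly clustered phantom histogram; on smooth histograms the gap
# is at rounding level.
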