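"""Synthetic CT-like phantoms with paired liver-like masks.

Every other module in the package is exercised against these phantoms, so
no external imaging data is needed.  A phantom is a randomly oriented
ellipsoid ("liver") whose radius is smoothly perturbed by a low-frequency
angular sinusoid, embedded in a noisy background.  The foreground/background
intensities default to values inside a typical liver CT window so the same
windowing used for real scans applies unchanged.

The generator is a pure function of its :class:`PhantomSpec`: the same spec
always yields bit-identical volumes and masks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "generate_phantom", "generate_phantom_dataset"]

_MASK64 = (1 << 64) - 1


def _splitmix64(state: int) -> int:
    """One splitmix64 step; used to derive independent per-case seeds."""
    state = (state + 0x9E3779B97F4A7C15) & _MASK64
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def case_seed(base_seed: int, index: int) -> int:
    """Deterministic, well-mixed seed for case ``index`` of a dataset."""
    return _splitmix64(_splitmix64(base_seed & _MASK64) ^ (index & _MASK64))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic volume.

    shape:             (depth, height, width) voxel counts, depth >= 3.
    fg_mean/bg_mean:   HU-like mean intensity inside/outside the object.
    noise_sd:          additive Gaussian noise standard deviation (>= 0).
    radius_range:      (lo, hi) semi-axis lengths as fractions of each axis
                       extent; must lie in (0, 0.5].
    deform_amplitude:  boundary perturbation amplitude in voxels (>= 0).
    seed:              RNG seed; identical specs give identical output.
    """

    shape: tuple[int, int, int] = (16, 64, 64)
    fg_mean: float = 100.0
    bg_mean: float = -50.0
    noise_sd: float = 15.0
    radius_range: tuple[float, float] = (0.25, 0.4)
    deform_amplitude: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) != s or s < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if self.shape[0] < 3:
            raise ValueError(f"shape: depth must be >= 3, got {self.shape[0]}")
        lo, hi = self.radius_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"radius_range must satisfy 0 < lo <= hi <= 0.5, got {self.radius_range}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.deform_amplitude < 0:
            raise ValueError(
                f"deform_amplitude must be >= 0, got {self.deform_amplitude}"
            )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random 3x3 rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(volume, mask)`` arrays of shape ``spec.shape``.

    The mask is a single connected {0,1} component; the volume is
    ``bg_mean + (fg_mean - bg_mean) * mask`` plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.shape, dtype=float)
    lo, hi = spec.radius_range

    semi_axes = rng.uniform(lo, hi, size=3) * shape
    center = shape / 2.0 + rng.uniform(-0.05, 0.05, size=3) * shape
    rotation = _random_rotation(rng)
    # angular frequencies and phases of the boundary deformation
    l_azim = int(rng.integers(2, 4))
    l_polar = int(rng.integers(2, 4))
    phase_a, phase_p = rng.uniform(0.0, 2.0 * np.pi, size=2)

    coords = np.indices(spec.shape, dtype=float)  # (3, D, H, W)
    delta = coords - center[:, None, None, None]
    local = np.einsum("ij,jdhw->idhw", rotation, delta)
    u = local / semi_axes[:, None, None, None]
    rho = np.sqrt((u * u).sum(axis=0))

    azim = np.arctan2(local[2], local[1])
    with np.errstate(invalid="ignore"):
        polar = np.arccos(np.clip(local[0] / np.maximum(np.sqrt((local * local).sum(axis=0)), 1e-9), -1, 1))
    rel_amp = spec.deform_amplitude / float(np.mean(semi_axes))
    # keep the perturbed radius positive so the region stays star-shaped
    rel_amp = min(rel_amp, 0.5)
    boundary = 1.0 + rel_amp * np.sin(l_azim * azim + phase_a) * np.sin(l_polar * polar + phase_p)
    mask = (rho <= boundary).astype(np.uint8)

    # discretization can pinch off slivers; keep the largest component
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(mask), labels, index=range(1, n + 1))
        mask = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    if mask.sum() == 0:  # degenerate radii on tiny grids: guarantee one voxel
        mask[tuple(np.round(center).astype(int) % spec.shape)] = 1

    volume = spec.bg_mean + (spec.fg_mean - spec.bg_mean) * mask.astype(float)
    volume = volume + rng.normal(0.0, 1.0, size=spec.shape) * spec.noise_sd
    return volume, mask


def generate_phantom_dataset(n: int, spec: PhantomSpec, out_dir) -> dict:
    """Write ``n`` phantom pairs to ``out_dir`` using LiTS-style naming.

    Files are ``volume-i.nii`` / ``segmentation-i.nii``; per-case seeds are
    derived deterministically from ``spec.seed``.  Returns the manifest,
    which is also written as ``manifest.json`` (paths relative to out_dir,
    so repeated runs with the same spec are byte-identical).
    """
    from . import data_io  # local import: data_io also imports nothing from here

    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write-probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    cases = []
    for i in range(n):
        seed_i = case_seed(spec.seed, i) % (2**63)
        case_spec = PhantomSpec(
            shape=spec.shape,
            fg_mean=spec.fg_mean,
            bg_mean=spec.bg_mean,
            noise_sd=spec.noise_sd,
            radius_range=spec.radius_range,
            deform_amplitude=spec.deform_amplitude,
            seed=seed_i,
        )
        volume, mask = generate_phantom(case_spec)
        vol_name = f"volume-{i}.nii"
        seg_name = f"segmentation-{i}.nii"
        ct = data_io.CTVolume(voxels=volume)
        data_io.write_volume(ct, out_dir / vol_name)
        data_io.write_mask(mask, ct, out_dir / seg_name)
        cases.append({"case": i, "volume": vol_name, "segmentation": seg_name,
                      "seed": seed_i})

    manifest = {"n": n, "spec": asdict(spec), "cases": cases}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %d phantom pairs to %s", n, out_dir)
    return manifest
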