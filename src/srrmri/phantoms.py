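"""Digital phantoms and simulated thick-slice acquisitions.

All validation inputs are generated here: a Shepp-Logan head phantom
(precision experiments), a water-filled cylinder (accuracy
experiments), and low-resolution noisy acquisitions obtained by
applying the sampling model ``y_k = A_k x + eps_k`` to the noiseless
diffusion-weighted phantom signal. Noise is added to the low-resolution
data after sampling -- it models measurement noise, not object
structure -- as independent complex Gaussians rectified to magnitude,
with a standard deviation that does not depend on voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from srrmri.geometry import AcquisitionGeometry, SamplingOperator, build_joint_system
from srrmri.noise import MonoExpParams, RicianNoiseModel

__all__ = [
    "DigitalPhantom",
    "SimulatedAcquisition",
    "shepp_logan",
    "cylinder_phantom",
    "simulate_lowres_acquisition",
]

# Modified (Toft) Shepp-Logan ellipse table:
# (additive value, x semi-axis, y semi-axis, x center, y center, angle deg)
_SHEPP_LOGAN_ELLIPSES = [
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]


@dataclass
class DigitalPhantom:
    """A noiseless high-resolution phantom plane with region labels.

    ``labels``: 0 = background, 1 = the primary homogeneous compartment
    (used for ROI statistics), 2 = other structures. ``diffusivity`` is
    the isotropic diffusion coefficient (um^2/ms) used to generate
    diffusion-weighted signal; None means no diffusion weighting.
    """

    image: np.ndarray
    labels: np.ndarray
    voxel_size_mm: float = 1.6
    diffusivity: float | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.image.shape != self.labels.shape:
            raise ValueError("labels must align with the image")
        if np.any(self.image < 0):
            raise ValueError("phantom image must be nonnegative")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.image.shape

    def signal(self, b: float) -> np.ndarray:
        """Noiseless diffusion-weighted plane ``x exp(-b D)``."""
        if self.diffusivity is None or b == 0:
            return self.image.copy()
        return self.image * np.exp(-b * self.diffusivity)

    def roi(self, label: int = 1) -> np.ndarray:
        return self.labels == label


def _ellipse_mask(n: int, value_tuple) -> np.ndarray:
    _, a, b, x0, y0, phi_deg = value_tuple
    half = n / 2
    c = np.arange(n)
    x = (c - (n - 1) / 2) / half
    y = ((n - 1) / 2 - np.arange(n)) / half  # y axis up
    X, Y = np.meshgrid(x, y)
    phi = np.deg2rad(phi_deg)
    xr = (X - x0) * np.cos(phi) + (Y - y0) * np.sin(phi)
    yr = -(X - x0) * np.sin(phi) + (Y - y0) * np.cos(phi)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def shepp_logan(n: int, s_alpha1: float = 1.0, voxel_size_mm: float = 1.6) -> DigitalPhantom:
    """Shepp-Logan head phantom scaled to a target compartment signal.

    The standard ten-ellipse composition, rescaled so the largest
    homogeneous compartment (the big interior region, playing the role
    of white matter) has value ``s_alpha1`` exactly; that compartment is
    label 1 for ROI statistics.
    """
    if n < 16:
        raise ValueError("grid size must be >= 16")
    image = np.zeros((n, n))
    masks = [_ellipse_mask(n, e) for e in _SHEPP_LOGAN_ELLIPSES]
    for (value, *_), mask in zip(_SHEPP_LOGAN_ELLIPSES, masks):
        image[mask] += value
    # the big interior region: inside the brain ellipse, outside all structures
    largest = masks[1].copy()
    for mask in masks[2:]:
        largest &= ~mask
    image *= s_alpha1 / 0.2  # interior value of the standard table is 0.2
    labels = np.zeros((n, n), dtype=np.int8)
    labels[masks[0]] = 2
    labels[largest] = 1
    return DigitalPhantom(image=np.maximum(image, 0.0), labels=labels,
                          voxel_size_mm=voxel_size_mm)


def cylinder_phantom(
    n: int,
    radius_fraction: float = 0.6,
    params: MonoExpParams | None = None,
    voxel_size_mm: float = 1.6,
) -> DigitalPhantom:
    """Water-cylinder phantom: a uniform disk of value S0 with diffusivity D.

    ``radius_fraction`` is the disk radius as a fraction of the half
    field of view. Label 1 is the disk.
    """
    if not 0 < radius_fraction < 1:
        raise ValueError("radius_fraction must lie in (0, 1)")
    if params is None:
        params = MonoExpParams()
    radius = radius_fraction * n / 2
    idx = np.arange(n) - (n - 1) / 2
    X, Y = np.meshgrid(idx, idx)
    disk = X ** 2 + Y ** 2 <= radius ** 2
    image = np.where(disk, params.s0, 0.0)
    labels = disk.astype(np.int8)
    return DigitalPhantom(image=image, labels=labels, voxel_size_mm=voxel_size_mm,
                          diffusivity=params.diffusivity)


@dataclass
class SimulatedAcquisition:
    """Low-resolution noisy observations of a phantom, per b-value.

    ``data`` has shape ``(n_b, n_repetitions, m)`` where ``m`` counts
    all low-resolution voxels across rotations (the stacked y vector).
    """

    sampling: SamplingOperator
    b_values: np.ndarray
    data: np.ndarray
    sigma: float
    seed: int | None

    def stacks(self, b_index: int = 0, repetition: int = 0) -> list[np.ndarray]:
        """Per-rotation low-resolution images for one b-value/repetition."""
        return self.sampling.split(self.data[b_index, repetition])


def simulate_lowres_acquisition(
    phantom: DigitalPhantom,
    geometry: AcquisitionGeometry,
    b_values,
    noise: RicianNoiseModel,
    seed: int | None = None,
    n_repetitions: int = 1,
    subcells: int = 4,
) -> SimulatedAcquisition:
    """Simulate rotated thick-slice stacks of a phantom with Rician noise.

    For each b-value, the noiseless high-resolution signal is sampled
    through the joint operator (interior low-resolution values scale
    with alpha, reflecting the voxel-volume signal gain), then
    independent complex Gaussian noise of the model's sigma is added to
    every low-resolution voxel and rectified to magnitude. Bit-identical
    under a fixed seed.
    """
    if phantom.grid_shape != geometry.grid_shape:
        raise ValueError(
            f"phantom grid {phantom.grid_shape} does not match geometry grid "
            f"{geometry.grid_shape}"
        )
    b_values = np.atleast_1d(np.asarray(b_values, dtype=float))
    sampling = build_joint_system(geometry, subcells=subcells)
    rng = noise.rng(seed)
    m = sampling.shape[0]
    data = np.empty((b_values.size, n_repetitions, m))
    for i, b in enumerate(b_values):
        y_clean = sampling.apply(phantom.signal(b))
        for r in range(n_repetitions):
            data[i, r] = noise.rectify(y_clean, rng)
    return SimulatedAcquisition(
        sampling=sampling,
        b_values=b_values,
        data=data,
        sigma=noise.sigma,
        seed=seed,
    )
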