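"""NIfTI and sidecar I/O for simulated acquisitions and reconstructions.

Volumetric data travels as NIfTI (the community standard for diffusion
MRI); everything NIfTI cannot express -- aspect factor, per-stack
rotation angles, regularization provenance, noise level, b-values,
seeds -- lives in a JSON sidecar next to the image files. Low-resolution
stacks are stored one file per rotation with the b-value series along
the last axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from srrmri.geometry import AcquisitionGeometry, build_joint_system
from srrmri.phantoms import SimulatedAcquisition

__all__ = [
    "write_acquisition",
    "read_acquisition",
    "write_volume",
    "read_volume",
    "write_json",
    "read_json",
]

SIDECAR_NAME = "geometry.json"


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def write_volume(path, data: np.ndarray, voxel_size_mm: float = 1.6) -> Path:
    """Write an array as NIfTI (spatial axes first)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size_mm))
    nib.save(img, path)
    return path


def read_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_acquisition(outdir, acq: SimulatedAcquisition) -> Path:
    """Write per-rotation stacks plus the geometry sidecar to ``outdir``.

    Each rotation k goes to ``stack_rot{k:02d}.nii.gz`` with shape
    ``(m_u, m_v, n_b)``; repetitions beyond the first extend the last
    axis in repetition-major order.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geo = acq.sampling.geometry
    n_b, n_rep, _ = acq.data.shape
    for k, (offset, (m_u, m_v)) in enumerate(acq.sampling.blocks):
        block = acq.data[:, :, offset:offset + m_u * m_v]
        vol = block.reshape(n_b * n_rep, m_u, m_v).transpose(1, 2, 0)
        write_volume(outdir / f"stack_rot{k:02d}.nii.gz", vol, geo.voxel_size_mm)
    sidecar = geo.to_dict()
    sidecar.update({
        "b_values": acq.b_values.tolist(),
        "sigma": acq.sigma,
        "seed": acq.seed,
        "n_repetitions": n_rep,
        "stack_shapes": [list(shape) for _, shape in acq.sampling.blocks],
    })
    write_json(outdir / SIDECAR_NAME, sidecar)
    return outdir


def read_acquisition(indir) -> SimulatedAcquisition:
    """Read stacks written by :func:`write_acquisition`."""
    indir = Path(indir)
    sidecar_path = indir / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing geometry sidecar {sidecar_path}")
    meta = read_json(sidecar_path)
    geo = AcquisitionGeometry.from_dict(meta)
    sampling = build_joint_system(geo)
    n_b = len(meta["b_values"])
    n_rep = meta.get("n_repetitions", 1)
    parts = []
    for k, (offset, (m_u, m_v)) in enumerate(sampling.blocks):
        path = indir / f"stack_rot{k:02d}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing stack file {path}")
        vol = read_volume(path)
        if vol.shape[:2] != (m_u, m_v) or vol.shape[2] != n_b * n_rep:
            raise ValueError(
                f"stack {path.name} has shape {vol.shape}, expected "
                f"({m_u}, {m_v}, {n_b * n_rep}) for this geometry"
            )
        parts.append(vol.transpose(2, 0, 1).reshape(n_b, n_rep, m_u * m_v))
    return SimulatedAcquisition(
        sampling=sampling,
        b_values=np.asarray(meta["b_values"], dtype=float),
        data=np.concatenate(parts, axis=2),
        sigma=meta.get("sigma", 0.0),
        seed=meta.get("seed"),
    )
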