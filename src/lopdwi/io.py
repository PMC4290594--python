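"""NIfTI + gradient-table readers/writers and dataset concatenation."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DWIVolume
from .sampling import (GradientScheme, KIND_UNKNOWN, read_bvals_bvecs,
                       read_scheme)

__all__ = ["read_dwi", "write_dwi", "concatenate_datasets", "write_manifest"]

logger = logging.getLogger(__name__)

B0_THRESHOLD = 50.0  # s/mm^2; robust to vendor rounding of small b-values


def read_dwi(nifti_path, bval_path, bvec_path, order_path=None,
             b0_threshold: float = B0_THRESHOLD) -> DWIVolume:
    """Read a 4D NIfTI with FSL bval/bvec into a :class:`DWIVolume`.

    Volumes with b < ``b0_threshold`` are treated as unweighted and moved
    to the front of the 4th axis.  If ``order_path`` points to a scheme
    text file, the spiral acquisition order and scheme kind are taken
    from it (matching directions by nearest axis); otherwise the storage
    order is assumed to be the acquisition order and the kind is unknown.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D NIfTI volume")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if bvals.shape[0] != data.shape[3]:
        raise ValueError(
            f"gradient table has {bvals.shape[0]} entries but the volume "
            f"has {data.shape[3]} frames")
    is_b0 = bvals < b0_threshold
    n_b0 = int(is_b0.sum())
    perm = np.concatenate([np.where(is_b0)[0], np.where(~is_b0)[0]])
    if not np.array_equal(perm, np.arange(data.shape[3])):
        logger.info("reordering %d b0 volumes to the front", n_b0)
    data = data[..., perm]
    w_dirs = bvecs[~is_b0]
    w_bvals = bvals[~is_b0]

    kind = KIND_UNKNOWN
    order_index = np.arange(w_dirs.shape[0])
    if order_path is not None:
        ref = read_scheme(order_path)
        if ref.n != w_dirs.shape[0]:
            raise ValueError("order file direction count does not match data")
        kind = ref.kind
        # match stored directions to the reference acquisition order by axis
        cos = np.abs(w_dirs @ ref.directions[ref.acquisition_order()].T)
        assign = np.argmax(cos, axis=1)
        if len(set(assign.tolist())) != w_dirs.shape[0]:
            raise ValueError("could not uniquely match directions to the "
                             "acquisition order file")
        order_index = assign
    scheme = GradientScheme(directions=w_dirs, bvalues=w_bvals,
                            order_index=order_index, kind=kind, n_b0=n_b0)
    return DWIVolume(data=data, scheme=scheme, affine=np.asarray(img.affine))


def write_dwi(vol: DWIVolume, nifti_path, bval_path=None, bvec_path=None) -> None:
    """Write a volume as NIfTI (float32) plus optional FSL bval/bvec."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(nifti_path))
    scheme = vol.scheme
    if bval_path is not None:
        b = np.concatenate([np.zeros(scheme.n_b0), scheme.bvalues])
        np.savetxt(bval_path, b[None, :], fmt="%.6g")
    if bvec_path is not None:
        v = np.vstack([np.zeros((scheme.n_b0, 3)), scheme.directions])
        np.savetxt(bvec_path, v.T, fmt="%.12g")


def concatenate_datasets(datasets: list[DWIVolume]) -> DWIVolume:
    """Concatenate (not average) repeated acquisitions of the same grid.

    b0 volumes of all inputs are gathered at the front; weighted volumes
    and their gradient tables are appended in input order.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    first = datasets[0]
    for d in datasets[1:]:
        if d.data.shape[:3] != first.data.shape[:3]:
            raise ValueError("datasets have different grids")
        if not np.allclose(d.affine, first.affine):
            raise ValueError("datasets have different affines")
    if len(datasets) == 1:
        return first.copy()
    b0 = np.concatenate([d.b0 for d in datasets], axis=-1)
    weighted = np.concatenate([d.weighted for d in datasets], axis=-1)
    dirs = np.concatenate([d.scheme.directions for d in datasets])
    bvals = np.concatenate([d.scheme.bvalues for d in datasets])
    offsets = np.cumsum([0] + [d.scheme.n for d in datasets[:-1]])
    order = np.concatenate([d.scheme.order_index + off
                            for d, off in zip(datasets, offsets)])
    kinds = {d.scheme.kind for d in datasets}
    scheme = GradientScheme(directions=dirs, bvalues=bvals, order_index=order,
                            kind=kinds.pop() if len(kinds) == 1 else KIND_UNKNOWN,
                            n_b0=int(b0.shape[-1]))
    logger.info("concatenated %d datasets: %d weighted + %d b0 volumes",
                len(datasets), weighted.shape[-1], b0.shape[-1])
    return DWIVolume(data=np.concatenate([b0, weighted], axis=-1),
                     scheme=scheme, affine=first.affine.copy())


def write_manifest(path, **entries) -> None:
    """Write a JSON reproducibility manifest (arguments, seeds, versions)."""
    import lopdwi

    payload = {"lopdwi_version": lopdwi.__version__,
               "numpy_version": np.__version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
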