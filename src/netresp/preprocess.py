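"""Post-preprocessing data cleaning: tissue-signal regression and detrending.

Assumes spatially preprocessed input (realigned, normalized).  Cleaning
regresses the mean white-matter and CSF signals plus a linear trend out of
every voxel time-series in a single joint OLS (the residual space of the
joint fit equals that of the sequential steps).  No temporal filtering is
applied, so the full frequency spectrum remains available to the ICA and
to the spectral component classification downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np


class GridError(ValueError):
    pass


class DegenerateMaskError(ValueError):
    pass


@dataclass(frozen=True)
class CleanConfig:
    regress_wm: bool = True
    regress_csf: bool = True
    detrend: bool = True


def load_bold(path) -> np.ndarray:
    """Load a 4D NIfTI as float array (x, y, z, t)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D image, got shape {data.shape}")
    return data


def save_bold(data: np.ndarray, path, tr: float = 1.0) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(tr)))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5


def save_mask(mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))


def mean_tissue_signal(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-volume mean of the in-mask voxels of a 4D image."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:3] != mask.shape:
        raise GridError(
            f"image grid {image.shape[:3]} != mask grid {mask.shape}")
    if not mask.any():
        raise DegenerateMaskError("empty tissue mask")
    return image[mask].mean(axis=0)


def clean_voxelwise(image: np.ndarray, wm_mask=None, csf_mask=None,
                    config: CleanConfig = CleanConfig(),
                    extra_confounds: np.ndarray | None = None) -> np.ndarray:
    """Regress tissue means, linear trend and optional confounds out of
    every voxel time-series (joint OLS with intercept).

    ``extra_confounds`` (volumes x k) accommodates externally supplied
    nuisance regressors such as motion-cleanup outputs.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 4:
        raise ValueError("expected 4D image")
    n_t = image.shape[3]
    if n_t < 4:
        raise ValueError("need at least 4 volumes to clean")
    cols = [np.ones(n_t)]
    if config.regress_wm and wm_mask is not None:
        cols.append(mean_tissue_signal(image, wm_mask))
    if config.regress_csf and csf_mask is not None:
        cols.append(mean_tissue_signal(image, csf_mask))
    if config.detrend:
        cols.append(np.linspace(-1.0, 1.0, n_t))
    if extra_confounds is not None:
        ec = np.asarray(extra_confounds, dtype=float)
        if ec.ndim == 1:
            ec = ec[:, None]
        if ec.shape[0] != n_t:
            raise ValueError("confound rows must match volume count")
        cols.append(ec)
    X = np.column_stack(cols)
    Y = image.reshape(-1, n_t).T          # time x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid.T.reshape(image.shape)
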