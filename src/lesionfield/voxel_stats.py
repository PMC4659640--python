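"""Voxel-wise lesion-frequency testing between improvement groups.

At each voxel, lesion presence across patients is a Bernoulli draw; the
significant- and poor-improvement groups are compared with a pooled
two-proportion z statistic,

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)),
    phat = (k1 + k2) / (n1 + n2),

with a two-sided normal p-value.  Voxels lesioned in no patient carry
no information and are excluded from the tested universe; the
Benjamini-Hochberg step-up procedure controls the FDR at level q over
the tested voxels.  The reported ``z_threshold`` is the smallest |z|
among FDR-significant voxels (the display threshold of a thresholded
z-map).  An exact alternative (Fisher) is available for small groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import GridError, NumericalError, SchemaError
from .lesion_quant import LesionMask


def bernoulli_two_sample_z(k1, n1, k2, n2):
    """Pooled two-proportion z statistic (vectorised over arrays).

    Degenerate voxels where the pooled proportion is 0 or 1 carry no
    between-group evidence and get z = 0.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise NumericalError("both groups must be non-empty")
    if np.any(k1 < 0) or np.any(k1 > n1) or np.any(k2 < 0) or np.any(k2 > n2):
        raise NumericalError("lesion counts must satisfy 0 <= k <= n")
    phat = (k1 + k2) / (n1 + n2)
    var = phat * (1.0 - phat) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (k1 / n1 - k2 / n2) / np.sqrt(var), 0.0)
    return z if z.ndim else float(z)


def two_sided_p(z):
    """Two-sided normal p-value, 2 * (1 - Phi(|z|))."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return p if p.ndim else float(p)


def fdr_select(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up selection at FDR level q.

    Returns ``(selected, p_threshold)`` where ``selected`` is a boolean
    array aligned with the input and ``p_threshold`` is the largest
    selected p-value (NaN when nothing is selected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise NumericalError("empty p-value set")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise NumericalError("p-values must be finite and within [0, 1]")
    selected, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
    p_threshold = float(p[selected].max()) if selected.any() else float("nan")
    return selected, p_threshold


@dataclass
class VoxelTestResult:
    """Thresholded voxel-wise comparison of lesion frequency."""

    z_map: np.ndarray
    p_map: np.ndarray
    significant_mask: np.ndarray
    tested_mask: np.ndarray
    z_threshold: float  # min |z| among FDR-selected voxels; NaN if none
    q: float
    n_tested: int
    n_selected: int

    def summary(self) -> dict:
        return {
            "q": self.q,
            "n_tested": self.n_tested,
            "n_selected": self.n_selected,
            "z_threshold": None
            if np.isnan(self.z_threshold)
            else self.z_threshold,
        }

    def write(self, z_path, mask_path, summary_path, voxel_dims_mm=(1.0, 1.0, 1.0)):
        import nibabel as nib

        affine = np.diag((*voxel_dims_mm, 1.0))
        nib.save(nib.Nifti1Image(self.z_map.astype(np.float32), affine), str(z_path))
        nib.save(
            nib.Nifti1Image(self.significant_mask.astype(np.uint8), affine),
            str(mask_path),
        )
        with open(summary_path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def voxelwise_test(
    group_masks_sig: Sequence[LesionMask],
    group_masks_poor: Sequence[LesionMask],
    q: float = 0.05,
    method: str = "z",
) -> VoxelTestResult:
    """Voxel-wise two-group lesion-frequency test with BH-FDR control.

    ``method="z"`` uses the pooled two-proportion z statistic with a
    normal reference (default); ``method="fisher"`` uses Fisher's exact
    test per voxel (signed z obtained from the two-sided p and the
    direction of the proportion difference).
    """
    sig = [np.asarray(m.data, dtype=bool) for m in group_masks_sig]
    poor = [np.asarray(m.data, dtype=bool) for m in group_masks_poor]
    if not sig or not poor:
        raise SchemaError("both improvement groups must be non-empty")
    shape = sig[0].shape
    if any(a.shape != shape for a in sig + poor):
        raise GridError("group lesion masks do not share a voxel grid")

    k1 = np.sum(sig, axis=0).astype(float)
    k2 = np.sum(poor, axis=0).astype(float)
    n1, n2 = float(len(sig)), float(len(poor))
    tested = (k1 + k2) > 0

    z_map = np.zeros(shape, dtype=float)
    p_map = np.ones(shape, dtype=float)
    if method == "z":
        z = bernoulli_two_sample_z(k1[tested], n1, k2[tested], n2)
        p = two_sided_p(z)
    elif method == "fisher":
        kk1, kk2 = k1[tested].astype(int), k2[tested].astype(int)
        p = np.array(
            [
                stats.fisher_exact(
                    [[a, int(n1) - a], [b, int(n2) - b]], alternative="two-sided"
                )[1]
                for a, b in zip(kk1, kk2)
            ]
        )
        # signed normal quantile consistent with the two-sided p
        direction = np.sign(kk1 / n1 - kk2 / n2)
        z = direction * stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    else:
        raise SchemaError(f"unknown method {method!r}")
    z_map[tested] = z
    p_map[tested] = p

    selected, _ = fdr_select(p, q=q)
    significant = np.zeros(shape, dtype=bool)
    significant[tested] = selected
    z_threshold = (
        float(np.abs(z[selected]).min()) if selected.any() else float("nan")
    )
    return VoxelTestResult(
        z_map=z_map,
        p_map=p_map,
        significant_mask=significant,
        tested_mask=tested,
        z_threshold=z_threshold,
        q=q,
        n_tested=int(tested.sum()),
        n_selected=int(selected.sum()),
    )
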