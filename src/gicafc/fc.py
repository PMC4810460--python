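"""Condition-specific intra- and inter-network functional connectivity.

For working-memory-specific connectivity the 0-back volumes are dropped:
each 1-back block's volume window is shifted forward by a hemodynamic
delay (3 volumes = 6 s by default), the retained volumes are concatenated,
and dual regression is re-run on the restricted data. The z-scored subject
spatial map is the intra-network FC (voxel-wise coupling with the network
timecourse); the Fisher r-to-z transformed Pearson correlation between two
networks' timecourses is the inter-network FC.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .design import TaskDesign, condition_volume_index
from .ica import BOLDRun, GroupSpatialMaps, SubjectDecomposition, dual_regression, zscore_components


def condition_specific_decomposition(run: BOLDRun, group_maps: GroupSpatialMaps,
                                     design: TaskDesign, condition: str = "1-back",
                                     delay_volumes: int = 3) -> SubjectDecomposition:
    """Dual regression on the concatenated volumes of one condition.

    The restricted time x voxel matrix plays the role of X in the
    dual-regression equations; outputs are z-scored.
    """
    idx = condition_volume_index(design, condition, delay_volumes)
    if idx.size == 0:
        raise ValueError("no volumes retained for the requested condition/delay")
    if idx.size < group_maps.order:
        raise ValueError("fewer retained volumes than components")
    restricted = BOLDRun(data=run.data[idx], tr=run.tr, subject=run.subject,
                         mask_index=run.mask_index, shape3d=run.shape3d,
                         affine=run.affine)
    dec = dual_regression(restricted, group_maps)
    return zscore_components(dec)


def fisher_z(r):
    """Fisher r-to-z: atanh, mapping correlations onto an unbounded scale."""
    return np.arctanh(r)


def inter_network_fc(dec: SubjectDecomposition, selected: list[int] | None = None
                     ) -> np.ndarray:
    """Fisher-z'd Pearson correlations between selected temporal components.

    Returns a symmetric (m, m) matrix with NaN on the diagonal.
    """
    tc = dec.temporal if selected is None else dec.temporal[:, list(selected)]
    m = tc.shape[1]
    if m < 2:
        raise ValueError("need at least two selected components")
    sds = tc.std(axis=0)
    if np.any(sds == 0):
        raise ValueError(f"constant timecourse(s): {list(np.where(sds == 0)[0])}")
    r = np.corrcoef(tc.T)
    off = ~np.eye(m, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        i, j = np.argwhere((np.abs(r) >= 1.0) & off)[0]
        raise ValueError(f"perfectly correlated pair ({i}, {j}): Fisher z infinite")
    with np.errstate(divide="ignore"):   # diagonal r=1 is discarded below
        z = fisher_z(r)
    np.fill_diagonal(z, np.nan)
    return z


def intra_fc_group_mask(maps: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Voxels with reliably positive FC across all subjects (Bonferroni FWE).

    One-sample t per voxel on the stacked (n_subjects, V) z-maps; a voxel
    survives when t > 0 and its one-sided p clears alpha / V.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, V) array of maps")
    n, v = maps.shape
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p_one_sided = stats.t.sf(t, df=n - 1)
    mask = (t > 0) & (p_one_sided < alpha / v)
    if not mask.any():
        warnings.warn("no voxel survived the positive-FC mask")
    return mask
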