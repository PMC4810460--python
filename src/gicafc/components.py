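"""Component triage: tissue classification and task-relatedness selection.

Candidate networks must (1) live in gray matter — decided by correlating
each spatial map with the binary indicator of each tissue class from a
maximum-probability map (MPM) — (2) not be cerebellar, and (3) carry the
task: each subject's component timecourse is regressed on the
HRF-convolved 1-back-vs-0-back contrast, and the per-subject slopes are
tested against zero by a one-sample t-test, Bonferroni-corrected over the
candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TISSUE_CLASSES = ("gray", "white", "csf")  # priority order for MPM ties


@dataclass
class TissueAtlas:
    """Per-voxel tissue probabilities plus an optional cerebellum mask.

    ``probabilities`` maps each class name to a flat (V,) probability
    vector over the in-mask voxels; ``cerebellum`` is a flat boolean mask.
    """

    probabilities: dict[str, np.ndarray]
    cerebellum: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, p in self.probabilities.items():
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"probabilities for {name} outside [0, 1]")


def build_mpm(atlas: TissueAtlas) -> np.ndarray:
    """Per-voxel tissue labels by maximum probability.

    Ties break by the fixed priority gray > white > csf (and are logged);
    a voxel with zero probability in every class is an error.
    """
    stack = np.stack([atlas.probabilities[c] for c in TISSUE_CLASSES])
    if np.any(stack.sum(axis=0) == 0):
        raise ValueError("voxel(s) with zero probability in every tissue class")
    labels = np.argmax(stack, axis=0)  # argmax takes the first max -> priority order
    ties = np.sum(stack == stack.max(axis=0), axis=0) > 1
    if np.any(ties):
        logger.info("MPM ties at %d voxel(s) broken by class priority", int(ties.sum()))
    return np.array(TISSUE_CLASSES)[labels]


def classify_component(component_map: np.ndarray, mpm_labels: np.ndarray
                       ) -> tuple[str, float]:
    """Tissue class whose binary indicator best correlates with the map.

    The signed maximum Pearson r decides (an anticorrelated tissue is not
    a match).
    """
    if component_map.shape != mpm_labels.shape:
        raise ValueError("component map and MPM must share the voxel index")
    if np.ptp(component_map) == 0:
        raise ValueError("constant component map")
    best_class, best_r = None, -np.inf
    for cls in TISSUE_CLASSES:
        ind = (mpm_labels == cls).astype(float)
        if np.ptp(ind) == 0:  # class absent or covers everything
            r = 0.0 if ind[0] == 0 else np.nan
        else:
            r = float(np.corrcoef(component_map, ind)[0, 1])
        if np.isnan(r):
            continue
        if r > best_r:
            best_class, best_r = cls, r
    assert best_class is not None
    return best_class, best_r


def component_glm(tc: np.ndarray, regressor: np.ndarray) -> float:
    """OLS slope of a component timecourse on the task contrast regressor.

    The model is ``TC = intercept + beta * regressor``; beta measures the
    component's activation in response to working-memory loading.
    """
    tc = np.asarray(tc, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if tc.shape != regressor.shape:
        raise ValueError("timecourse and regressor lengths differ")
    if np.ptp(regressor) == 0:
        raise ValueError("constant regressor")
    x = np.column_stack([np.ones_like(regressor), regressor])
    coef, *_ = np.linalg.lstsq(x, tc, rcond=None)
    return float(coef[1])


def beta_table(decompositions, regressor: np.ndarray) -> pd.DataFrame:
    """Per-subject, per-component task betas (subjects x components)."""
    rows = {}
    for dec in decompositions:
        rows[dec.subject] = [component_glm(dec.temporal[:, c], regressor)
                             for c in range(dec.temporal.shape[1])]
    return pd.DataFrame.from_dict(rows, orient="index")


def select_wm_components(betas: pd.DataFrame, tissue: list[str],
                         cerebellar: list[bool], alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Gray-matter, non-cerebellar components with Bonferroni-significant beta.

    The one-sample t is computed for every component; Bonferroni adjusts
    over the candidate (gray, non-cerebellar) set, and only candidates can
    be selected.
    """
    if len(betas) < 2:
        raise ValueError("need at least two subjects")
    k = betas.shape[1]
    candidates = [c for c in range(k) if tissue[c] == "gray" and not cerebellar[c]]
    m = max(len(candidates), 1)
    rows = []
    for c in range(k):
        vals = betas.iloc[:, c].to_numpy(dtype=float)
        if np.ptp(vals) == 0 and vals[0] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
        p_adj = min(1.0, float(p) * m)
        selected = (c in candidates) and (p_adj < alpha)
        rows.append({"component": c, "tissue": tissue[c],
                     "cerebellar": bool(cerebellar[c]),
                     "mean_beta": float(np.mean(vals)), "t": float(t),
                     "p": float(p), "p_bonferroni": p_adj,
                     "selected": selected})
    return pd.DataFrame(rows)


def component_report(group_maps, atlas: TissueAtlas, betas: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Full triage: classify each group map, then select task-related ones."""
    mpm = build_mpm(atlas)
    tissue, rvals, cereb = [], [], []
    for c in range(group_maps.order):
        cls, r = classify_component(group_maps.maps[c], mpm)
        tissue.append(cls)
        rvals.append(r)
        if atlas.cerebellum is not None:
            comp = group_maps.maps[c]
            thr = comp > np.percentile(comp, 95)
            overlap = (thr & atlas.cerebellum).sum() / max(thr.sum(), 1)
            cereb.append(bool(overlap > 0.5))
        else:
            cereb.append(False)
    report = select_wm_components(betas, tissue, cereb, alpha=alpha)
    report["tissue_r"] = rvals
    return report
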