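"""Synthetic multi-subject block-design fMRI cohorts with known ground truth.

Each subject's run is generated from the same linear mixing model the
decomposition assumes: ``X = TC @ maps + noise`` where the spatial maps
are shared across subjects and the per-subject timecourses carry the
experimental structure —

* task components ride an HRF-convolved 1-back boxcar whose amplitude is
  multiplied by a per-group activation gain (patients can over-activate);
* a designated component pair shares an AR(1) latent so its timecourse
  correlation hits a per-group target (patients decouple);
* a designated component's contribution inside a small "deficit" region is
  partially replaced by noise for patients (reduced intra-network
  coupling);
* all components carry AR(1) background to mimic BOLD autocorrelation.

Spatial maps are smoothed Gaussian blobs at well-separated centers, which
keeps them near-orthogonal and supergaussian (sparse) — the regime in
which Infomax ICA is identifiable. One component is placed in each
non-gray tissue territory and one in the "cerebellum" so that component
classification has every branch to exercise.

Behavioral records and a demographic covariate table with a mild group
accuracy deficit complete the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import TaskDesign, boxcar, build_nback_design, canonical_hrf, convolve_design
from .ica import BOLDRun

PATIENT = "patient"
CONTROL = "control"


@dataclass(frozen=True)
class BehaviorParams:
    accuracy_mean: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 0.95, PATIENT: 0.90})
    accuracy_sd: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 0.04, PATIENT: 0.05})
    rt_mean_ms: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 620.0, PATIENT: 650.0})
    rt_sd_ms: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 110.0, PATIENT: 120.0})
    n_response_trials: int = 50   # 5 one-back blocks x 10 response trials

    def __post_init__(self) -> None:
        for g, m in self.accuracy_mean.items():
            if not 0 < m <= 1:
                raise ValueError(f"accuracy mean for {g} must be in (0, 1]")
        for g, s in self.rt_sd_ms.items():
            if s < 0:
                raise ValueError(f"RT SD for {g} must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_per_group: tuple[int, int] = (10, 10)       # (control, patient)
    shape: tuple[int, int, int] = (12, 12, 8)
    n_components: int = 6
    design: TaskDesign | None = None              # defaults to the n-back preset
    noise_sd: float = 1.2                         # per-voxel; ~SNR 2 with 6 unit-RMS maps
    task_amplitude: float = 0.7                   # task SD in control units
    activation_gain: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 1.0, PATIENT: 1.3})
    intra_fc_scale: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 1.0, PATIENT: 0.4})
    inter_fc_corr: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 0.5, PATIENT: 0.15})
    ar_phi: float = 0.3
    blob_sigma: float = 1.5
    deficit_region_size: int = 30
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_components < 2:
            raise ValueError("need at least 2 components")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        n_vox = int(np.prod(self.shape))
        if n_vox < 10 * self.n_components:
            raise ValueError("grid too small for the requested component count")

    @property
    def resolved_design(self) -> TaskDesign:
        return self.design if self.design is not None else build_nback_design()

    @property
    def n_volumes(self) -> int:
        t = self.resolved_design.n_volumes
        if t < 2 * self.n_components:
            raise ValueError("need at least 2 volumes per component")
        return t


def tissue_territories(shape: tuple[int, int, int]
                       ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Partition the grid into tissue slabs plus a 'cerebellum' corner.

    Lower z-slabs play CSF and white matter; the upper half is gray
    matter, of which one corner is labeled cerebellum — a cartoon of
    cortical anatomy sufficient to exercise tissue-based component triage.
    """
    nx, ny, nz = shape
    zz = np.arange(nz)
    z3 = np.zeros(shape, dtype=int) + zz[None, None, :]
    csf = z3 < max(1, nz // 4)
    white = (z3 >= max(1, nz // 4)) & (z3 < nz // 2)
    gray = z3 >= nz // 2
    cereb = gray.copy()
    cereb[nx // 2:, :, :] = False
    cereb[:, ny // 2:, :] = False
    return {"gray": gray, "white": white, "csf": csf}, cereb


@dataclass
class GroundTruth:
    spatial_maps: np.ndarray                  # (k, V)
    mixing_timecourses: dict[str, np.ndarray]  # subject -> (T, k)
    activation_gain: dict[str, float]
    intra_fc_scale: dict[str, float]
    inter_fc_corr: dict[str, float]
    behavior_params: BehaviorParams
    task_components: tuple[int, ...]
    fc_pair: tuple[int, int]
    deficit_component: int
    deficit_region: np.ndarray                # flat voxel indices
    tissue_of_component: tuple[str, ...]      # per component: gray/white/csf
    cerebellum_component: int
    territories: dict[str, np.ndarray]        # 3D boolean per tissue class
    cerebellum_region: np.ndarray             # 3D boolean
    seed: int


@dataclass
class SyntheticCohort:
    runs: list[BOLDRun]
    behavior: pd.DataFrame
    covariates: pd.DataFrame
    truth: GroundTruth
    mask: np.ndarray                          # 3D boolean
    config: CohortConfig

    def group_of(self, subject: str) -> str:
        row = self.covariates.loc[self.covariates.subject == subject, "group"]
        return str(row.iloc[0])


# ---------------------------------------------------------------------------
# spatial maps

def _blob_centers(shape, k, rng, min_sep=3.0, regions=None, max_restarts=50):
    """Greedy sequential placement with a minimum center separation.

    ``regions`` optionally gives, per component, a 3D boolean array of
    admissible center locations (e.g. a tissue territory).
    """
    dims = np.array(shape, dtype=float)
    for _ in range(max_restarts):
        centers: list[np.ndarray] = []
        for i in range(k):
            region = None if regions is None else regions[i]
            vox = None if region is None else np.argwhere(region)
            for _ in range(500):
                if vox is None:
                    cand = rng.uniform(low=1.0, high=dims - 1.0)
                else:
                    cand = vox[rng.integers(len(vox))] + rng.uniform(-0.5, 0.5, 3)
                if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                    centers.append(cand)
                    break
            else:
                break
        if len(centers) == k:
            return np.array(centers)
    raise RuntimeError("could not place well-separated blob centers")


def make_spatial_maps(shape: tuple[int, int, int], k: int, sigma: float,
                      rng: np.random.Generator, max_cosine: float = 0.2,
                      regions=None, max_tries: int = 50) -> np.ndarray:
    """k near-orthogonal smoothed-blob maps, unit RMS over the grid."""
    n_vox = int(np.prod(shape))
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    for _ in range(max_tries):
        centers = _blob_centers(shape, k, rng, min_sep=max(3.0, 2.5 * sigma),
                                regions=regions)
        maps = np.empty((k, n_vox))
        for i, c in enumerate(centers):
            d2 = np.sum((grid - c) ** 2, axis=-1)
            blob = np.exp(-d2 / (2 * sigma**2))
            blob[blob < 0.05] = 0.0
            maps[i] = blob.ravel()
        norm = maps / np.linalg.norm(maps, axis=1, keepdims=True)
        cos = norm @ norm.T
        np.fill_diagonal(cos, 0.0)
        if np.max(np.abs(cos)) < max_cosine:
            maps *= np.sqrt(n_vox) / np.linalg.norm(maps, axis=1, keepdims=True)
            return maps
    raise RuntimeError("could not achieve near-orthogonal maps")


def _ar1(t_len: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) series with unit marginal variance."""
    innov_sd = np.sqrt(1 - phi**2)
    x = np.empty(t_len)
    x[0] = rng.standard_normal()
    for t in range(1, t_len):
        x[t] = phi * x[t - 1] + innov_sd * rng.standard_normal()
    return x


# ---------------------------------------------------------------------------
# cohort generation

def _component_roles(k: int) -> tuple[tuple[int, ...], int, int, int, tuple[str, ...]]:
    """Assign roles: task comps first, then white, CSF, cerebellum (if room)."""
    if k < 5:
        n_task = max(1, k - 2)
        tissue = ["gray"] * n_task + ["white", "csf"][: k - n_task]
        cereb = -1
    else:
        n_task = k - 3
        tissue = ["gray"] * n_task + ["white", "csf", "gray"]
        cereb = k - 1
    task = tuple(range(n_task))
    white = n_task if k - n_task >= 1 else -1
    csf = n_task + 1 if k - n_task >= 2 else -1
    return task, white, csf, cereb, tuple(tissue)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a two-group cohort; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    shape = config.shape
    k = config.n_components
    design = config.resolved_design
    t_len = config.n_volumes
    mask = np.ones(shape, dtype=bool)

    task_comps, white_c, csf_c, cereb_c, tissue = _component_roles(k)
    territories, cereb_region = tissue_territories(shape)
    regions = []
    for c in range(k):
        if c == cereb_c:
            regions.append(cereb_region)
        elif tissue[c] == "gray":
            regions.append(territories["gray"] & ~cereb_region)
        else:
            regions.append(territories[tissue[c]])
    maps = make_spatial_maps(shape, k, config.blob_sigma, rng, regions=regions)
    # FC pair: the last two task components (need >= 2 task comps)
    if len(task_comps) >= 2:
        fc_pair = (task_comps[-2], task_comps[-1])
    else:
        fc_pair = (0, 1)
    deficit_comp = task_comps[0]
    deficit_region = np.argsort(maps[deficit_comp])[::-1][: config.deficit_region_size]

    hrf = canonical_hrf(design.tr)
    reg = convolve_design(boxcar(design, "1-back"), hrf)
    reg = (reg - reg.mean()) / reg.std()

    groups = [CONTROL] * config.n_per_group[0] + [PATIENT] * config.n_per_group[1]
    subjects = [f"sub-{i + 1:03d}" for i in range(len(groups))]

    runs: list[BOLDRun] = []
    mixing: dict[str, np.ndarray] = {}
    flat_index = np.arange(int(np.prod(shape)))
    for subj, grp in zip(subjects, groups):
        gain = config.activation_gain[grp]
        rho_target = np.clip(config.inter_fc_corr[grp], -0.99, 0.99)
        tc = np.empty((t_len, k))
        # correlated backgrounds for the FC pair: shared AR(1) latent chosen
        # so the FULL timecourse correlation (task signal included) hits the
        # per-group target.
        a = np.array([config.task_amplitude * gain if c in task_comps else 0.0
                      for c in fc_pair])
        var_full = a**2 + 1.0
        rho_bg = np.clip(rho_target * np.sqrt(var_full[0] * var_full[1]) - a[0] * a[1],
                         -0.99, 0.99)
        shared = _ar1(t_len, config.ar_phi, rng)
        for c in range(k):
            bg = _ar1(t_len, config.ar_phi, rng)
            if c in fc_pair:
                s = np.sign(rho_bg) if c == fc_pair[1] else 1.0
                w = np.sqrt(abs(rho_bg))
                bg = w * s * shared + np.sqrt(1 - abs(rho_bg)) * bg
            amp = config.task_amplitude * gain if c in task_comps else 0.0
            tc[:, c] = amp * reg + bg
        signal = tc @ maps
        # intra-network degradation: inside the deficit region, part of the
        # deficit component's contribution is replaced by matched noise
        scale = config.intra_fc_scale[grp]
        if scale < 1.0:
            contrib = np.outer(tc[:, deficit_comp], maps[deficit_comp, deficit_region])
            repl = np.sqrt(1 - scale**2) * rng.standard_normal(contrib.shape) \
                * np.abs(maps[deficit_comp, deficit_region])[None, :] * tc[:, deficit_comp].std()
            signal[:, deficit_region] += (scale - 1.0) * contrib + repl
        noise = config.noise_sd * rng.standard_normal((t_len, maps.shape[1])) \
            if config.noise_sd > 0 else 0.0
        data = signal + noise
        runs.append(BOLDRun(data=data, tr=design.tr, subject=subj,
                            mask_index=flat_index, shape3d=shape))
        mixing[subj] = tc

    behavior = generate_behavior(config, subjects, groups,
                                 rng=np.random.default_rng(rng.integers(2**31)))
    covariates = _generate_covariates(subjects, groups,
                                      np.random.default_rng(rng.integers(2**31)))

    truth = GroundTruth(
        spatial_maps=maps, mixing_timecourses=mixing,
        activation_gain=dict(config.activation_gain),
        intra_fc_scale=dict(config.intra_fc_scale),
        inter_fc_corr=dict(config.inter_fc_corr),
        behavior_params=config.behavior, task_components=task_comps,
        fc_pair=fc_pair, deficit_component=deficit_comp,
        deficit_region=deficit_region, tissue_of_component=tissue,
        cerebellum_component=cereb_c, territories=territories,
        cerebellum_region=cereb_region, seed=config.seed)
    return SyntheticCohort(runs=runs, behavior=behavior, covariates=covariates,
                           truth=truth, mask=mask, config=config)


def generate_behavior(config: CohortConfig, subjects: list[str] | None = None,
                      groups: list[str] | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-trial 1-back responses: correct flags and reaction times.

    Subject-level accuracy is drawn around the group mean (clipped to
    (0, 1]) and trials are Bernoulli given it; RTs are Gaussian around the
    group mean, floored at 150 ms. Group means therefore converge to the
    configured values as the cohort grows.
    """
    if subjects is None:
        groups = [CONTROL] * config.n_per_group[0] + [PATIENT] * config.n_per_group[1]
        subjects = [f"sub-{i + 1:03d}" for i in range(len(groups))]
    assert groups is not None
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    p = config.behavior
    rows = []
    for subj, grp in zip(subjects, groups):
        acc = p.accuracy_mean[grp]
        if p.accuracy_sd[grp] > 0:
            acc = float(np.clip(rng.normal(acc, p.accuracy_sd[grp]), 1e-3, 1.0))
        for trial in range(p.n_response_trials):
            correct = bool(rng.random() < acc) if acc < 1.0 else True
            rt = p.rt_mean_ms[grp]
            if p.rt_sd_ms[grp] > 0:
                rt = max(150.0, float(rng.normal(rt, p.rt_sd_ms[grp])))
            rows.append({"subject": subj, "group": grp, "trial": trial,
                         "condition": "1-back", "correct": correct,
                         "rt_ms": rt})
    return pd.DataFrame(rows)


def _generate_covariates(subjects, groups, rng) -> pd.DataFrame:
    """Demographics in the range typical of a middle-aged diabetes cohort."""
    spec = {
        CONTROL: dict(age=(52.0, 6.0), edu=(10.7, 2.3), male_p=0.47,
                      hba1c=(5.5, 0.3), fbg=(4.8, 0.5), avlt=(7.0, 1.5)),
        PATIENT: dict(age=(54.0, 8.0), edu=(12.1, 2.7), male_p=0.65,
                      hba1c=(7.9, 2.1), fbg=(7.0, 1.7), avlt=(6.8, 1.6)),
    }
    rows = []
    for subj, grp in zip(subjects, groups):
        s = spec[grp]
        rows.append({
            "subject": subj, "group": grp,
            "age": float(np.clip(rng.normal(*s["age"]), 35, 75)),
            "gender": "M" if rng.random() < s["male_p"] else "F",
            "education": float(np.clip(rng.normal(*s["edu"]), 5, 20)),
            "hba1c": float(max(4.0, rng.normal(*s["hba1c"]))),
            "fbg": float(max(3.5, rng.normal(*s["fbg"]))),
            "avlt": float(np.clip(rng.normal(*s["avlt"]), 1, 10)),
        })
    return pd.DataFrame(rows)


def synthetic_atlas(cohort: "SyntheticCohort"):
    """Tissue probability atlas consistent with the cohort's territories.

    Each territory gets a dominant probability for its tissue; the
    cerebellum mask is the cerebellar territory corner.
    """
    from .components import TissueAtlas
    truth = cohort.truth
    v = truth.spatial_maps.shape[1]
    probs = {"gray": np.full(v, 0.1), "white": np.full(v, 0.1),
             "csf": np.full(v, 0.1)}
    for tis, region in truth.territories.items():
        flat = region.ravel()
        probs[tis][flat] = 0.8
        for other in probs:
            if other != tis:
                probs[other][flat] = 0.1
    return TissueAtlas(probabilities=probs,
                       cerebellum=truth.cerebellum_region.ravel())


# ---------------------------------------------------------------------------
# direct map-level generators for inference calibration

def planted_deficit_maps(n_control: int, n_patient: int,
                         shape: tuple[int, int, int], region_flat: np.ndarray,
                         effect_d: float, fwhm_mm: float, voxel_size_mm: float,
                         seed: int, base_amplitude: float = 5.0,
                         base_region_flat: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject intra-FC maps with a localized patient deficit.

    Every subject's map is ``base + noise`` with unit-SD (smoothed,
    re-standardized) noise; patients lose ``effect_d`` (in noise-SD units,
    i.e. Cohen's d) inside ``region_flat``. Returns ``(maps, groups)`` with
    maps of shape (n_subjects, V) and groups a 0/1 patient indicator.
    """
    from .fields import standardized_noise_field
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(shape))
    mask = np.ones(shape, dtype=bool)
    base = np.zeros(n_vox)
    base[base_region_flat if base_region_flat is not None else slice(None)] = base_amplitude
    maps = np.empty((n_control + n_patient, n_vox))
    groups = np.array([0] * n_control + [1] * n_patient)
    for i, g in enumerate(groups):
        noise = standardized_noise_field(shape, fwhm_mm, voxel_size_mm, mask, rng).ravel()
        m = base + noise
        if g == 1:
            m[region_flat] -= effect_d
        maps[i] = m
    return maps, groups


def correlated_timecourse_pair(t_len: int, rho: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Two white-noise timecourses with population correlation ``rho``."""
    z = rng.standard_normal((t_len, 2))
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    out[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    return out
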