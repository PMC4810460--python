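"""Block design of the 0-back/1-back working-memory task.

The task alternates 0-back (attention control) and 1-back (working-memory)
blocks. Each trial occupies a fixed slot (digit 1000 ms + blank 1000 ms =
2 s); the 2 s instruction screen at the start of a block is counted as that
block's first trial slot, which is what makes the standard design close at
exactly 126 volumes with TR = 2 s: 6 blocks x 11 trials x 2 s + 5 blocks x
12 trials x 2 s = 252 s = 126 TRs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

ZERO_BACK = "0-back"
ONE_BACK = "1-back"


@dataclass(frozen=True)
class TaskDesign:
    """Ordered task blocks with per-trial timing.

    Parameters
    ----------
    blocks
        Ordered ``(condition, n_trials)`` pairs. The instruction trial is
        counted inside ``n_trials``.
    trial_duration
        Seconds per trial slot.
    tr
        Repetition time in seconds.
    instruction_duration
        Seconds of the instruction screen; informational only, it occupies
        the block's first trial slot.
    """

    blocks: tuple[tuple[str, int], ...]
    trial_duration: float = 2.0
    tr: float = 2.0
    instruction_duration: float = 2.0

    def __post_init__(self) -> None:
        if self.trial_duration <= 0 or self.tr <= 0:
            raise ValueError("durations must be positive")
        for cond, n in self.blocks:
            if n <= 0:
                raise ValueError(f"block with non-positive trial count: {cond}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c for c, _ in self.blocks))

    @property
    def total_duration(self) -> float:
        return sum(n * self.trial_duration for _, n in self.blocks)

    @property
    def n_volumes(self) -> int:
        vols = self.total_duration / self.tr
        if abs(vols - round(vols)) > 1e-9:
            raise ValueError("total duration is not an integer number of TRs")
        return int(round(vols))

    def block_volume_spans(self) -> list[tuple[str, int, int]]:
        """Half-open volume spans ``(condition, start, stop)`` per block."""
        spans = []
        t = 0.0
        for cond, n in self.blocks:
            dur = n * self.trial_duration
            start = int(round(t / self.tr))
            stop = int(round((t + dur) / self.tr))
            spans.append((cond, start, stop))
            t += dur
        return spans


def build_nback_design(tr: float = 2.0) -> TaskDesign:
    """The alternating 6 x 0-back / 5 x 1-back block design.

    Six 0-back blocks of 11 trials alternate with five 1-back blocks of
    12 trials; trials last 2 s. At TR = 2 s this yields 126 volumes.
    """
    blocks: list[tuple[str, int]] = []
    for i in range(11):
        blocks.append((ZERO_BACK, 11) if i % 2 == 0 else (ONE_BACK, 12))
    return TaskDesign(blocks=tuple(blocks), trial_duration=2.0, tr=tr)


def boxcar(design: TaskDesign, condition: str) -> np.ndarray:
    """0/1 indicator over volumes: 1 during the condition's blocks."""
    if design.blocks and condition not in design.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    out = np.zeros(design.n_volumes if design.blocks else 0)
    for cond, start, stop in design.block_volume_spans():
        if cond == condition:
            out[start:stop] = 1.0
    return out


@dataclass(frozen=True)
class HRFKernel:
    """Canonical double-gamma hemodynamic response sampled at TR resolution."""

    values: np.ndarray
    tr: float
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        if self.values.sum() <= 0:
            raise ValueError("kernel must have positive integral")


def _double_gamma(t: np.ndarray, peak_delay: float, undershoot_delay: float,
                  ratio: float, dispersion: float = 1.0) -> np.ndarray:
    # shape/scale parametrization with unit dispersion: mode = (a-1)*scale
    peak = gamma_dist.pdf(t, peak_delay / dispersion, scale=dispersion)
    under = gamma_dist.pdf(t, undershoot_delay / dispersion, scale=dispersion)
    return peak - ratio * under


def canonical_hrf(tr: float, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0, ratio: float = 1.0 / 6.0,
                  duration: float = 32.0) -> HRFKernel:
    """Canonical double-gamma HRF (peak ~5 s, undershoot ~15 s, 32 s long).

    The kernel is scaled to unit peak; its exact scale is immaterial for
    GLM t-statistics and for correlation-based connectivity.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0, duration + tr / 2, tr)
    h = _double_gamma(t, peak_delay, undershoot_delay, ratio)
    h = h / np.max(np.abs(h))
    return HRFKernel(values=h, tr=tr, peak_delay=peak_delay,
                     undershoot_delay=undershoot_delay, ratio=ratio,
                     duration=duration)


def convolve_design(box: np.ndarray, kernel: HRFKernel) -> np.ndarray:
    """Discrete convolution of a boxcar with the HRF, truncated to length."""
    if box.size == 0:
        return box.copy()
    return np.convolve(box, kernel.values)[: box.size]


def task_regressor(design: TaskDesign, kernel: HRFKernel | None = None,
                   positive: str = ONE_BACK,
                   negative: str | None = ZERO_BACK) -> np.ndarray:
    """HRF-convolved contrast regressor (1-back minus 0-back by default)."""
    if kernel is None:
        kernel = canonical_hrf(design.tr)
    box = boxcar(design, positive)
    if negative is not None:
        box = box - boxcar(design, negative)
    return convolve_design(box, kernel)


def condition_volume_index(design: TaskDesign, condition: str,
                           delay_volumes: int = 0) -> np.ndarray:
    """Volume indices of a condition's blocks, shifted by an HRF delay.

    Each block's volume window is shifted forward by ``delay_volumes``
    (e.g. 3 volumes = 6 s at TR 2 s to absorb the hemodynamic lag);
    indices past the end of the run are truncated, not wrapped. The
    returned indices are sorted so downstream consumers can concatenate
    the retained volumes contiguously.
    """
    if delay_volumes < 0:
        raise ValueError("delay must be non-negative")
    if not design.blocks:
        return np.array([], dtype=int)
    n = design.n_volumes
    if delay_volumes >= n:
        warnings.warn("delay is at least the run length; no volumes retained")
        return np.array([], dtype=int)
    idx: list[int] = []
    for cond, start, stop in design.block_volume_spans():
        if cond != condition:
            continue
        shifted = np.arange(start + delay_volumes, stop + delay_volumes)
        idx.extend(shifted[shifted < n])
    return np.array(sorted(idx), dtype=int)
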