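"""Block-design task timing and the hemodynamic response function.

The working-memory paradigm is an n-back task with three load levels
(0-back, 1-back, 2-back).  Each load level is presented in three blocks;
a block holds 20 trials of which 5 are targets.  Timing (block length,
instruction periods, inter-trial spacing) is configurable; the counts are
fixed properties of the paradigm.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .errors import DesignError

logger = logging.getLogger(__name__)

CONDITION_NAMES = ("0-back", "1-back", "2-back")

# Canonical double-gamma HRF: response gamma with shape 6, undershoot gamma
# with shape 16, undershoot scaled by 1/6; unit time scale (seconds).
HRF_RESPONSE_SHAPE = 6.0
HRF_UNDERSHOOT_SHAPE = 16.0
HRF_UNDERSHOOT_RATIO = 6.0
HRF_LENGTH_SECONDS = 32.0


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    The response peaks a few seconds after stimulus onset and shows a
    shallow undershoot around 15 s.  The curve is scaled to unit peak so
    that regression amplitudes are in units of the signal.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma_dist.pdf(t, HRF_RESPONSE_SHAPE) - _gamma_dist.pdf(
        t, HRF_UNDERSHOOT_SHAPE
    ) / HRF_UNDERSHOOT_RATIO
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


@dataclass
class TaskDesign:
    """Event timing for one task run.

    ``condition_onsets`` maps an event name to a list of ``(onset, duration)``
    pairs in seconds.  The three load-level conditions must be present; the
    nuisance event types (``instructions``, ``responses``) may be empty.
    """

    condition_onsets: dict[str, list[tuple[float, float]]]
    trials_per_block: int = 20
    targets_per_block: int = 5
    blocks_per_condition: int = 3

    def __post_init__(self) -> None:
        for name in CONDITION_NAMES:
            if name not in self.condition_onsets:
                raise DesignError(f"missing condition {name!r} in design")
        # load-level blocks must not overlap each other
        blocks = []
        for name in CONDITION_NAMES:
            blocks.extend(self.condition_onsets[name])
        blocks.sort()
        for (o1, d1), (o2, _) in zip(blocks, blocks[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise DesignError(
                    f"overlapping task blocks at t={o1:.1f}s and t={o2:.1f}s"
                )

    @property
    def n_targets(self) -> int:
        """Total target trials in the run (all load levels)."""
        return self.targets_per_block * self.blocks_per_condition * len(CONDITION_NAMES)

    @property
    def n_nontargets(self) -> int:
        return (
            (self.trials_per_block - self.targets_per_block)
            * self.blocks_per_condition
            * len(CONDITION_NAMES)
        )

    @property
    def total_seconds(self) -> float:
        end = 0.0
        for events in self.condition_onsets.values():
            for onset, duration in events:
                end = max(end, onset + duration)
        return end

    def to_json(self) -> str:
        payload = {
            "condition_onsets": {
                k: [[float(o), float(d)] for o, d in v]
                for k, v in self.condition_onsets.items()
            },
            "trials_per_block": self.trials_per_block,
            "targets_per_block": self.targets_per_block,
            "blocks_per_condition": self.blocks_per_condition,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        payload = json.loads(text)
        onsets = {
            k: [(float(o), float(d)) for o, d in v]
            for k, v in payload["condition_onsets"].items()
        }
        return cls(
            condition_onsets=onsets,
            trials_per_block=int(payload["trials_per_block"]),
            targets_per_block=int(payload["targets_per_block"]),
            blocks_per_condition=int(payload["blocks_per_condition"]),
        )


def make_nback_design(
    block_seconds: float = 30.0,
    instruction_seconds: float = 10.0,
    trial_seconds: float = 1.5,
    response_duration: float = 0.5,
    seed: int = 0,
) -> TaskDesign:
    """Build a standard n-back run: nine blocks alternating 0/1/2-back,
    each preceded by an instruction period.

    Target positions within each block (and hence response events) are
    drawn reproducibly from ``seed``.  Responses are modeled at target
    onsets, as brief events.
    """
    if trial_seconds * 20 > block_seconds + 1e-9:
        raise DesignError("trials do not fit inside the block duration")
    rng = np.random.default_rng(seed)
    onsets: dict[str, list[tuple[float, float]]] = {
        name: [] for name in CONDITION_NAMES
    }
    onsets["instructions"] = []
    onsets["responses"] = []
    block_period = instruction_seconds + block_seconds
    for b in range(9):
        condition = CONDITION_NAMES[b % 3]
        t0 = b * block_period
        onsets["instructions"].append((t0, instruction_seconds))
        block_onset = t0 + instruction_seconds
        onsets[condition].append((block_onset, block_seconds))
        target_trials = np.sort(rng.choice(20, size=5, replace=False))
        for trial in target_trials:
            onsets["responses"].append(
                (block_onset + float(trial) * trial_seconds, response_duration)
            )
    return TaskDesign(condition_onsets=onsets)


def hrf_regressor(
    events: list[tuple[float, float]],
    n_timepoints: int,
    tr_seconds: float,
    oversample: int = 10,
) -> np.ndarray:
    """Convolve boxcar events with the double-gamma HRF, sampled at the TR.

    Events are rasterized on a grid ``oversample`` times finer than the TR;
    zero-duration events occupy a single fine-grid sample.
    """
    run_seconds = n_timepoints * tr_seconds
    for onset, duration in events:
        if onset < 0 or onset + duration > run_seconds + 1e-9:
            raise DesignError(
                f"event ({onset:.1f}s, {duration:.1f}s) extends beyond the "
                f"{run_seconds:.1f}s run"
            )
    dt = tr_seconds / oversample
    n_fine = n_timepoints * oversample
    box = np.zeros(n_fine)
    for onset, duration in events:
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + duration) / dt)))
        box[i0:min(i1, n_fine)] = 1.0
    hrf = double_gamma_hrf(np.arange(0.0, HRF_LENGTH_SECONDS, dt))
    conv = np.convolve(box, hrf)[:n_fine]
    return conv[::oversample][:n_timepoints].copy()
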