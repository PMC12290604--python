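"""Acquisition timing and stimulus design generation.

The symmetric VASO acquisition cycles through four equally long blocks
(inversion delay, blood-nulled EPI readout, additional delay, BOLD EPI
readout).  One blood-nulled and one BOLD volume are produced per cycle, and
stimulus onsets are jittered over the block grid so that trial averaging
samples the haemodynamic response at the block duration (0.785 s by default)
rather than at the cycle duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_DURATIONS_S = (1.0, 2.0, 4.0, 12.0, 24.0)
#: Rest period following each stimulus, paired to the stimulus duration in
#: sorted order ("stimulus- and corresponding rest durations").
SHORT_ITIS_S = {1.0: 10.0, 2.0: 12.0, 4.0: 14.0, 12.0: 20.0, 24.0: 24.0}
LONG_ITIS_S = {1.0: 20.0, 2.0: 22.0, 4.0: 24.0, 12.0: 30.0, 24.0: 40.0}


@dataclass(frozen=True)
class AcquisitionScheme:
    """Timing of one symmetric VASO acquisition cycle.

    Parameters
    ----------
    block_s
        Length of one block (inversion delay, nulled readout, delay, or BOLD
        readout).  The effective sampling interval of jittered event-related
        averages equals this value.
    blocks_per_cycle
        Number of equally spaced blocks per cycle (4 for the symmetric
        scheme).
    n_jitters
        Number of distinct stimulus-onset phases within one cycle.
    volumes_per_run
        Volumes acquired per contrast per run; ``None`` if set by a design.
    ti1_s, ti2_s, shot_tr_s
        Sequence timing recorded as metadata only; not used in computation.
    """

    block_s: float = 0.785
    blocks_per_cycle: int = 4
    n_jitters: int = 4
    volumes_per_run: int | None = None
    ti1_s: float | None = None
    ti2_s: float | None = None
    shot_tr_s: float | None = None

    def __post_init__(self) -> None:
        if self.block_s <= 0:
            raise ValueError("block_s must be positive")
        if self.blocks_per_cycle < 1 or self.n_jitters < 1:
            raise ValueError("blocks_per_cycle and n_jitters must be >= 1")

    @property
    def cycle_s(self) -> float:
        """Length of one acquisition cycle (pair TR)."""
        return self.blocks_per_cycle * self.block_s

    @property
    def effective_dt_s(self) -> float:
        """Effective sampling interval after jitter interleaving."""
        return self.cycle_s / self.n_jitters

    @property
    def nulled_offset_s(self) -> float:
        """Offset of the blood-nulled readout within the cycle (block 2)."""
        return self.block_s

    @property
    def bold_offset_s(self) -> float:
        """Offset of the BOLD readout within the cycle (block 4)."""
        return 3.0 * self.block_s


@dataclass(frozen=True)
class Trial:
    onset_s: float
    duration_s: float
    jitter_index: int
    iti_s: float

    @property
    def end_s(self) -> float:
        """End of the trial window (stimulus plus its rest period)."""
        return self.onset_s + self.duration_s + self.iti_s


@dataclass
class StimulusDesign:
    """Per-run trial lists for one participant.

    ``target_onsets_s`` holds the onsets of the attention-task targets
    (metadata only; targets occur during stimulation and are not modelled).
    """

    runs: list[list[Trial]]
    iti_class: str
    block_s: float
    cycle_s: float
    run_duration_s: list[float] = field(default_factory=list)
    target_onsets_s: list[list[float]] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def repetition_counts(self) -> dict[tuple[float, int], int]:
        """Number of trials per (duration, jitter) pair across all runs."""
        counts: dict[tuple[float, int], int] = {}
        for run in self.runs:
            for tr in run:
                key = (tr.duration_s, tr.jitter_index)
                counts[key] = counts.get(key, 0) + 1
        return counts

    def validate(self) -> None:
        """Check grid alignment and non-overlap of trial windows."""
        for run in self.runs:
            prev_end = -math.inf
            for tr in sorted(run, key=lambda t: t.onset_s):
                phase = tr.onset_s / self.block_s
                if abs(phase - round(phase)) > 1e-9:
                    raise ValueError(
                        f"onset {tr.onset_s} not on the {self.block_s} s grid"
                    )
                if tr.onset_s < prev_end - 1e-9:
                    raise ValueError("overlapping trial windows")
                prev_end = tr.end_s

    def events_dataframe(self, run: int) -> pd.DataFrame:
        """BIDS-style events table for one run."""
        rows = [
            {
                "onset": tr.onset_s,
                "duration": tr.duration_s,
                "trial_type": f"stim_{tr.duration_s:g}s",
            }
            for tr in self.runs[run]
        ]
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


def trials_from_events(events: pd.DataFrame, iti_class: str = "long",
                       block_s: float = 0.785) -> list[Trial]:
    """Reconstruct :class:`Trial` objects from a BIDS-style events table."""
    itis = LONG_ITIS_S if iti_class == "long" else SHORT_ITIS_S
    cycle = 4 * block_s
    trials = []
    for _, row in events.iterrows():
        onset = float(row["onset"])
        jitter = int(round((onset % cycle) / block_s)) % 4
        dur = float(row["duration"])
        trials.append(Trial(onset, dur, jitter, itis.get(dur, 20.0)))
    return trials


def make_design(
    acq: AcquisitionScheme,
    n_runs: int,
    iti_class: str = "long",
    seed: int = 0,
    durations_s: tuple[float, ...] = DEFAULT_DURATIONS_S,
    lead_in_s: float = 30.0,
    lead_out_s: float = 30.0,
    target_rate: float = 0.5,
) -> StimulusDesign:
    """Generate a jittered stimulation design.

    Each of the stimulus durations occurs exactly once per jitter phase per
    run, in randomized order.  Onsets land on the jitter grid (multiples of
    ``block_s`` relative to cycle starts) and trial windows (stimulus plus
    rest) never overlap.  Following the original acquisition strategy, runs
    with long inter-trial intervals share a single design across runs, while
    short-ITI runs each get a fresh randomization.

    Parameters
    ----------
    n_runs
        Number of runs; must be >= 1.
    iti_class
        ``"short"`` or ``"long"`` rest-duration set.
    lead_in_s, lead_out_s
        Rest before the first onset and after the last trial window; both
        default to the 30 s baseline window of the event-related analysis.
    target_rate
        Expected number of attention-task targets per trial (metadata only).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if iti_class not in ("short", "long"):
        raise ValueError("iti_class must be 'short' or 'long'")
    itis = SHORT_ITIS_S if iti_class == "short" else LONG_ITIS_S
    rng = np.random.default_rng(seed)

    def one_run(run_rng: np.random.Generator) -> tuple[list[Trial], float, list[float]]:
        pairs = [(d, j) for d in durations_s for j in range(acq.n_jitters)]
        run_rng.shuffle(pairs)
        t_min = lead_in_s
        trials: list[Trial] = []
        targets: list[float] = []
        for dur, jit in pairs:
            # earliest cycle whose jitter-phase onset is >= t_min
            k = math.ceil((t_min - jit * acq.block_s) / acq.cycle_s - 1e-12)
            onset = k * acq.cycle_s + jit * acq.block_s
            trials.append(Trial(onset, dur, jit, itis[dur]))
            if run_rng.random() < target_rate:
                targets.append(float(onset + run_rng.uniform(0.0, dur)))
            t_min = onset + dur + itis[dur]
        return trials, t_min + lead_out_s, targets

    runs: list[list[Trial]] = []
    run_durations: list[float] = []
    all_targets: list[list[float]] = []
    if iti_class == "long":
        trials, t_end, targets = one_run(rng)
        for _ in range(n_runs):
            runs.append(list(trials))
            run_durations.append(t_end)
            all_targets.append(list(targets))
    else:
        for _ in range(n_runs):
            trials, t_end, targets = one_run(rng)
            runs.append(trials)
            run_durations.append(t_end)
            all_targets.append(targets)

    design = StimulusDesign(
        runs=runs,
        iti_class=iti_class,
        block_s=acq.block_s,
        cycle_s=acq.cycle_s,
        run_duration_s=run_durations,
        target_onsets_s=all_targets,
    )
    design.validate()
    return design


def n_cycles_for(design: StimulusDesign, run: int) -> int:
    """Number of acquisition cycles needed to cover one run of a design."""
    return int(math.ceil(design.run_duration_s[run] / design.cycle_s))
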