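"""Blocked 2x2x2 task-design generation and DCM input construction.

The protocol crosses *Stimulus Domain* (verbal, spatial) with two forms of
cognitive control — *Contextual Control* (low: Control, Delay; high:
Restart, Dual) and *Temporal Control* (low: Control, Restart; high: Delay,
Dual).  Each block runs a pre phase of the basic sequencing task (2-5
trials), a sub-task phase (3-5 trials), a single return trial, and a post
phase (1-2 trials), i.e. 7-13 trials per block.  Control blocks keep the
same phase structure as a matched epoch but involve no cue change.

Under full counterbalancing every run contains each of the 8 design cells
equally often with phase lengths drawn in complementary pairs, so every run
has an identical trial count (10 per block on average) and every cell
accumulates exactly 4 sub-task trials per block on average.  The default
protocol (2 sessions x 6 runs x 16 blocks) therefore yields 192 blocks,
1920 trials, 160 trials per run, 24 blocks and 96 sub-task trials per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DOMAINS = ("verbal", "spatial")
SUBTASKS = ("Control", "Restart", "Delay", "Dual")
#: subtask name -> (contextual_control, temporal_control)
SUBTASK_FLAGS = {
    "Control": (False, False),
    "Restart": (True, False),
    "Delay": (False, True),
    "Dual": (True, True),
}
PHASES = ("pre", "subtask", "return", "post")

DRIVE_CHANNELS = ("spatial", "verbal", "cue")
MOD_CHANNELS = ("Spatial", "Verbal", "Contextual", "Temporal")

_PRE_PAIRS = ((2, 5), (3, 4), (4, 3), (5, 2))
_SUB_PAIRS = ((3, 5), (4, 4), (5, 3))
_POST_PAIRS = ((1, 2), (2, 1))
_CENTRAL_LENGTHS = (3, 4, 1, 2)  # odd-remainder tuple: pre, subtask, return, post


class DesignConfigurationError(ValueError):
    """Raised when a protocol cannot be counterbalanced."""


@dataclass(frozen=True)
class Condition:
    """One cell of the 2x2x2 design."""

    stimulus_domain: str
    contextual_control: bool
    temporal_control: bool

    def __post_init__(self) -> None:
        if self.stimulus_domain not in DOMAINS:
            raise ValueError(f"unknown stimulus domain {self.stimulus_domain!r}")

    @property
    def subtask_name(self) -> str:
        for name, flags in SUBTASK_FLAGS.items():
            if flags == (self.contextual_control, self.temporal_control):
                return name
        raise AssertionError("unreachable")

    @classmethod
    def from_name(cls, stimulus_domain: str, subtask_name: str) -> "Condition":
        try:
            ctx, tmp = SUBTASK_FLAGS[subtask_name]
        except KeyError:
            raise ValueError(f"unknown sub-task {subtask_name!r}") from None
        return cls(stimulus_domain, ctx, tmp)


#: the 8 design cells in canonical order
CELLS: tuple[Condition, ...] = tuple(
    Condition.from_name(d, s) for d in DOMAINS for s in SUBTASKS
)


@dataclass(frozen=True)
class BlockPlan:
    """Phase lengths (in trials) for one block."""

    condition: Condition
    pre_len: int
    subtask_len: int
    return_len: int
    post_len: int
    run_index: int
    session_index: int

    def __post_init__(self) -> None:
        if not (2 <= self.pre_len <= 5 and 3 <= self.subtask_len <= 5):
            raise ValueError("phase lengths out of protocol bounds")
        if self.return_len != 1 or self.post_len not in (1, 2):
            raise ValueError("phase lengths out of protocol bounds")

    @property
    def n_trials(self) -> int:
        return self.pre_len + self.subtask_len + self.return_len + self.post_len


@dataclass(frozen=True)
class TrialEvent:
    onset_index: int  # global trial index across the whole design
    phase: str
    subtask: str
    domain: str
    run_index: int
    session_index: int
    block_index: int


@dataclass
class Design:
    """An ordered block list plus its trial-level event expansion."""

    blocks: list[BlockPlan] = field(default_factory=list)
    events: list[TrialEvent] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.events)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def run_trial_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for ev in self.events:
            key = (ev.session_index, ev.run_index)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def cell_subtask_counts(self) -> dict[tuple[str, str], int]:
        counts = {(d, s): 0 for d in DOMAINS for s in SUBTASKS}
        for ev in self.events:
            if ev.phase == "subtask":
                counts[(ev.domain, ev.subtask)] += 1
        return counts


DEFAULT_PROTOCOL = {
    "sessions": 2,
    "runs_per_session": 6,
    "blocks_per_run": 16,
    "counterbalance": "full",
}


def _sample_lengths(rng: np.random.Generator, n_blocks: int) -> list[tuple[int, int, int, int]]:
    """Phase-length tuples for the blocks of one cell within one run.

    Lengths come in complementary pairs (pre sums to 7, sub-task to 8, post
    to 3) so the per-run totals are exact; an odd remainder takes the
    central tuple.
    """
    out: list[tuple[int, int, int, int]] = []
    for _ in range(n_blocks // 2):
        pre = _PRE_PAIRS[rng.integers(len(_PRE_PAIRS))]
        sub = _SUB_PAIRS[rng.integers(len(_SUB_PAIRS))]
        post = _POST_PAIRS[rng.integers(len(_POST_PAIRS))]
        out.append((pre[0], sub[0], 1, post[0]))
        out.append((pre[1], sub[1], 1, post[1]))
    if n_blocks % 2:
        out.append(_CENTRAL_LENGTHS)
    return out


def generate_design(seed: int = 0, protocol: dict | None = None) -> Design:
    """Generate a counterbalanced blocked design.

    Parameters
    ----------
    seed:
        Controls block ordering and phase-length sampling.
    protocol:
        Mapping with keys ``sessions``, ``runs_per_session``,
        ``blocks_per_run`` and ``counterbalance``; missing keys take the
        defaults of the full two-session protocol.

    Raises
    ------
    DesignConfigurationError
        If ``blocks_per_run`` is not divisible by the 8 design cells.
    """
    cfg = dict(DEFAULT_PROTOCOL)
    cfg.update(protocol or {})
    sessions = int(cfg["sessions"])
    runs = int(cfg["runs_per_session"])
    blocks_per_run = int(cfg["blocks_per_run"])
    if sessions < 0 or runs < 0 or blocks_per_run < 0:
        raise DesignConfigurationError("protocol counts must be nonnegative")
    design = Design()
    if sessions == 0 or runs == 0 or blocks_per_run == 0:
        return design
    if blocks_per_run % len(CELLS) != 0:
        raise DesignConfigurationError(
            f"blocks_per_run={blocks_per_run} is not divisible by the {len(CELLS)} design cells"
        )
    per_cell = blocks_per_run // len(CELLS)
    rng = np.random.default_rng(seed)

    trial_counter = 0
    block_counter = 0
    for ses in range(sessions):
        for run in range(runs):
            run_blocks: list[BlockPlan] = []
            for cell in CELLS:
                for lengths in _sample_lengths(rng, per_cell):
                    run_blocks.append(
                        BlockPlan(cell, lengths[0], lengths[1], lengths[2], lengths[3], run, ses)
                    )
            order = rng.permutation(len(run_blocks))
            for idx in order:
                block = run_blocks[idx]
                design.blocks.append(block)
                for phase, length in zip(PHASES, (block.pre_len, block.subtask_len, block.return_len, block.post_len)):
                    for _ in range(length):
                        design.events.append(
                            TrialEvent(
                                onset_index=trial_counter,
                                phase=phase,
                                subtask=block.condition.subtask_name,
                                domain=block.condition.stimulus_domain,
                                run_index=run,
                                session_index=ses,
                                block_index=block_counter,
                            )
                        )
                        trial_counter += 1
                block_counter += 1
    return design


def design_from_blocks(blocks: list[BlockPlan]) -> Design:
    """Expand an explicit block list into a Design (no counterbalancing)."""
    design = Design()
    trial_counter = 0
    for bi, block in enumerate(blocks):
        design.blocks.append(block)
        for phase, length in zip(PHASES, (block.pre_len, block.subtask_len, block.return_len, block.post_len)):
            for _ in range(length):
                design.events.append(
                    TrialEvent(trial_counter, phase, block.condition.subtask_name,
                               block.condition.stimulus_domain, block.run_index, block.session_index, bi)
                )
                trial_counter += 1
    return design


@dataclass
class InputTimeline:
    """DCM input functions on a microtime grid.

    ``drive`` holds three impulse channels (spatial stimulus, verbal
    stimulus, sub-task cue) as unit-weight Dirac events assigned to the bin
    of their onset; ``mod`` holds four 0/1 modulatory epoch channels
    (Spatial, Verbal, Contextual, Temporal) that are 1 exactly during the
    sub-task phases of blocks loading the factor.
    """

    dt: float
    drive: np.ndarray  # (T, 3) impulse weights
    mod: np.ndarray  # (T, 4) epoch indicators
    trial_soa: float = 2.0
    drive_names: tuple[str, ...] = DRIVE_CHANNELS
    mod_names: tuple[str, ...] = MOD_CHANNELS

    @property
    def n_steps(self) -> int:
        return self.drive.shape[0]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def resample(self, dt: float) -> "InputTimeline":
        """Return the same inputs on a coarser or finer grid.

        The ratio between grids must be an integer.  Impulse weights are
        conserved (summed into the enclosing coarse bin / placed at the
        first sub-bin); epochs are piecewise constant.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if abs(dt - self.dt) < 1e-12:
            return self
        if dt > self.dt:
            ratio = dt / self.dt
            r = int(round(ratio))
            if abs(ratio - r) > 1e-9:
                raise ValueError("coarse dt must be an integer multiple of timeline dt")
            T = self.n_steps // r
            drive = self.drive[: T * r].reshape(T, r, -1).sum(axis=1)
            mod = self.mod[: T * r].reshape(T, r, -1).max(axis=1)
            return replace(self, dt=dt, drive=drive, mod=mod)
        ratio = self.dt / dt
        r = int(round(ratio))
        if abs(ratio - r) > 1e-9:
            raise ValueError("fine dt must divide timeline dt")
        T = self.n_steps * r
        drive = np.zeros((T, self.drive.shape[1]))
        drive[::r] = self.drive
        mod = np.repeat(self.mod, r, axis=0)
        return replace(self, dt=dt, drive=drive, mod=mod)


def _loaded_factors(subtask: str, domain: str) -> list[int]:
    """Modulatory channels loaded during a block's sub-task phase.

    Control blocks are the unmodulated baseline (their matched epoch loads
    nothing); other blocks load their stimulus-domain channel plus the
    control factors of the sub-task.
    """
    if subtask == "Control":
        return []
    loaded = [MOD_CHANNELS.index("Spatial" if domain == "spatial" else "Verbal")]
    ctx, tmp = SUBTASK_FLAGS[subtask]
    if ctx:
        loaded.append(MOD_CHANNELS.index("Contextual"))
    if tmp:
        loaded.append(MOD_CHANNELS.index("Temporal"))
    return loaded


def build_input_timeline(design: Design, dt: float = 0.125, trial_soa: float = 2.0) -> InputTimeline:
    """Translate a Design into DCM driving impulses and modulatory epochs.

    Every trial contributes one stimulus impulse on its block's domain
    channel.  Non-Control blocks add cue impulses at the sub-task onset and
    the return-trial onset, and switch their loaded modulatory channels to
    1 for the duration of the sub-task phase.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    steps = trial_soa / dt
    spt = int(round(steps))
    if abs(steps - spt) > 1e-9 or spt < 1:
        raise ValueError("dt must divide trial_soa")
    T = design.n_trials * spt
    drive = np.zeros((T, len(DRIVE_CHANNELS)))
    mod = np.zeros((T, len(MOD_CHANNELS)))
    if T == 0:
        return InputTimeline(dt, drive, mod, trial_soa)

    i_spatial = DRIVE_CHANNELS.index("spatial")
    i_verbal = DRIVE_CHANNELS.index("verbal")
    i_cue = DRIVE_CHANNELS.index("cue")

    prev_phase_by_block: dict[int, str] = {}
    for ev in design.events:
        t0 = ev.onset_index * spt
        drive[t0, i_spatial if ev.domain == "spatial" else i_verbal] += 1.0
        first_of_phase = prev_phase_by_block.get(ev.block_index) != ev.phase
        prev_phase_by_block[ev.block_index] = ev.phase
        if ev.subtask != "Control":
            if first_of_phase and ev.phase in ("subtask", "return"):
                drive[t0, i_cue] += 1.0
            if ev.phase == "subtask":
                for j in _loaded_factors(ev.subtask, ev.domain):
                    mod[t0 : t0 + spt, j] = 1.0
    return InputTimeline(dt, drive, mod, trial_soa)


_EVENT_COLUMNS = ("onset", "duration", "trial_type", "phase", "domain", "run", "session", "block")


def events_frame(design: Design, trial_soa: float = 2.0) -> pd.DataFrame:
    """Trial events as a BIDS-style table (onset/duration in seconds)."""
    rows = [
        (
            ev.onset_index * trial_soa,
            trial_soa,
            ev.subtask,
            ev.phase,
            ev.domain,
            ev.run_index,
            ev.session_index,
            ev.block_index,
        )
        for ev in design.events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_events(design: Design, path, trial_soa: float = 2.0) -> None:
    """Write the trial events of a design to a BIDS-style events TSV."""
    try:
        events_frame(design, trial_soa).to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"could not write events file {path!r}: {exc}") from exc


def read_events(path, trial_soa: float = 2.0) -> list[TrialEvent]:
    """Read an events TSV back into the trial-event list of a Design."""
    df = pd.read_csv(path, sep="\t")
    return [
        TrialEvent(
            onset_index=int(round(row.onset / trial_soa)),
            phase=row.phase,
            subtask=row.trial_type,
            domain=row.domain,
            run_index=int(row.run),
            session_index=int(row.session),
            block_index=int(row.block),
        )
        for row in df.itertuples()
    ]
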