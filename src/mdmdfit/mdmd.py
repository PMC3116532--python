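"""Maxwell's-demon molecular dynamics (MdMD) driver.

The demon iterates short unbiased "sprints" of a propagator and keeps
only those that improve a global progress variable — here, by default,
the cross-correlation between the simulated density of the current model
and a target experimental map.  Selection, not added forces, does the
driving: no gradient of the progress variable ever enters the potential.

One iteration:

1. propagate one sprint (duration bounded by [min_sprint, max_sprint]);
2. evaluate the progress variable on the resulting structure;
3. accept iff it strictly exceeds the best of the last ``archive_depth``
   archived values (ties reject).  On accept the state is archived and
   the next sprint grows (x grow_factor); on reject the last archived
   state is restored, velocities are re-thermalized from a fresh
   deterministic substream, and the next sprint shrinks (x shrink_factor).

The run ends when the progress variable reaches ``goal``, the iteration
budget is exhausted, or ``max_consecutive_rejections`` sprints in a row
fail (stalled).  The accepted states form the fitting trajectory; the
progress trace is strictly increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .density import (DensityMap, KernelParams, cross_correlation, resample,
                      simulate_density)
from .model_io import Structure, Trajectory, superpose
from .propagator import Engine, PropagatorState

STATUS_GOAL = "goal_reached"
STATUS_MAX_ITER = "max_iterations"
STATUS_STALLED = "stalled"
STATUS_ERROR = "error"


@dataclass
class MdmdConfig:
    """Demon schedule parameters.

    Sprint durations are in ps; the 0.05-5 ps default window spans the
    50 fs - 5 ps range typical for MD sprints.  ``archive_depth`` is how
    many previous archived progress values the acceptance test consults.
    """

    goal: float = 0.98
    min_sprint: float = 0.05
    max_sprint: float = 5.0
    initial_sprint: float = 0.5
    grow_factor: float = 1.5
    shrink_factor: float = 0.5
    max_iterations: int = 500
    max_consecutive_rejections: int = 50
    archive_depth: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_sprint <= self.initial_sprint <= self.max_sprint):
            raise ValueError(
                "require 0 < min_sprint <= initial_sprint <= max_sprint")
        if not (0 < self.shrink_factor < 1 < self.grow_factor):
            raise ValueError("require 0 < shrink_factor < 1 < grow_factor")
        if self.archive_depth < 1:
            raise ValueError("archive_depth must be >= 1")


@dataclass
class IterationRecord:
    iteration: int
    accepted: bool
    progress: float
    sprint: float
    consecutive_rejections: int


@dataclass
class FittingResult:
    """Archive of an MdMD run: accepted frames and traces."""

    accepted_frames: Trajectory
    cc_trace: np.ndarray            # progress value at each accepted state
    sprint_trace: np.ndarray        # sprint duration (ps) of each accepted sprint
    rejection_counts: np.ndarray    # rejections preceding each acceptance
    status: str
    initial_progress: float
    n_iterations: int
    iteration_log: list[IterationRecord] = field(default_factory=list)
    error: str | None = None

    @property
    def final_progress(self) -> float:
        if len(self.cc_trace):
            return float(self.cc_trace[-1])
        return self.initial_progress

    @property
    def final_structure(self) -> Structure:
        if self.accepted_frames.n_frames:
            return self.accepted_frames.frame(self.accepted_frames.n_frames - 1)
        return self.accepted_frames.topology


def run_mdmd(
    initial: Structure,
    progress: Callable[[Structure], float],
    engine: Engine,
    config: MdmdConfig,
) -> FittingResult:
    """Drive ``initial`` uphill in ``progress`` by sprint selection."""
    seed_seq = np.random.SeedSequence(config.seed)
    main_stream, *_ = seed_seq.spawn(1)
    reject_streams = iter(_substreams(seed_seq))

    state = PropagatorState.from_structure(initial, main_stream)
    try:
        p0 = float(progress(initial))
    except Exception as exc:
        return _error_result(initial, str(exc))
    if not np.isfinite(p0):
        return _error_result(initial, "initial progress value is not finite")

    archive_states: list[PropagatorState] = [state.clone()]
    archive_values: list[float] = [p0]
    frames: list[np.ndarray] = []
    cc_trace: list[float] = []
    sprint_trace: list[float] = []
    rejection_counts: list[int] = []
    log: list[IterationRecord] = []

    status = STATUS_MAX_ITER
    error = None
    if p0 >= config.goal:
        status = STATUS_GOAL
        return _make_result(initial, frames, cc_trace, sprint_trace,
                            rejection_counts, status, p0, 0, log)

    sprint = config.initial_sprint
    consec_rej = 0
    iteration = 0
    while iteration < config.max_iterations:
        iteration += 1
        used_sprint = sprint
        try:
            candidate = engine.propagate(state, used_sprint)
            value = float(progress(initial.with_coords(candidate.coords)))
        except Exception as exc:  # propagator or progress failure: partial result
            status = STATUS_ERROR
            error = f"{type(exc).__name__}: {exc}"
            break
        best_recent = max(archive_values[-config.archive_depth:])
        accepted = np.isfinite(value) and value > best_recent
        if accepted:
            state = candidate
            post = getattr(engine, "postprocess_accepted", None)
            if post is not None:
                state = post(state)
            archive_states.append(state.clone())
            archive_values.append(value)
            frames.append(state.coords.copy())
            cc_trace.append(value)
            sprint_trace.append(used_sprint)
            rejection_counts.append(consec_rej)
            consec_rej = 0
            sprint = min(sprint * config.grow_factor, config.max_sprint)
        else:
            state = archive_states[-1].clone()
            state.rng = np.random.default_rng(next(reject_streams))
            state = engine.thermalize(state, state.rng)
            consec_rej += 1
            sprint = max(sprint * config.shrink_factor, config.min_sprint)
        log.append(IterationRecord(iteration, bool(accepted), value,
                                   used_sprint, consec_rej))
        if accepted and value >= config.goal:
            status = STATUS_GOAL
            break
        if consec_rej >= config.max_consecutive_rejections:
            status = STATUS_STALLED
            break

    return _make_result(initial, frames, cc_trace, sprint_trace,
                        rejection_counts, status, p0, iteration, log, error)


def _substreams(seed_seq: np.random.SeedSequence):
    """Endless deterministic stream of child SeedSequences for retries."""
    while True:  # SeedSequence.spawn advances its child counter each call
        yield seed_seq.spawn(1)[0]


def _error_result(initial: Structure, message: str) -> FittingResult:
    return _make_result(initial, [], [], [], [], STATUS_ERROR, np.nan, 0, [],
                        message)


def _make_result(initial, frames, cc_trace, sprint_trace, rejection_counts,
                 status, p0, iteration, log, error=None) -> FittingResult:
    frame_arr = (np.array(frames) if frames
                 else np.empty((0, initial.n_atoms, 3)))
    return FittingResult(
        accepted_frames=Trajectory(initial, frame_arr,
                                   metadata=list(range(len(frames)))),
        cc_trace=np.asarray(cc_trace, dtype=float),
        sprint_trace=np.asarray(sprint_trace, dtype=float),
        rejection_counts=np.asarray(rejection_counts, dtype=int),
        status=status, initial_progress=float(p0),
        n_iterations=iteration, iteration_log=log, error=error,
    )


# ---------------------------------------------------------------------------
# Progress variables
# ---------------------------------------------------------------------------

def cc_progress(target_map: DensityMap, kernel: KernelParams,
                grid: DensityMap | None = None) -> Callable[[Structure], float]:
    """Progress variable: map cross-correlation against a target map.

    The structure's density is synthesized on ``grid`` (default: the
    target's own geometry) and resampled onto the target grid if the two
    differ.  A model entirely outside the map support scores 0.
    """
    if grid is None:
        grid = target_map.geometry()

    def progress(structure: Structure) -> float:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # fully-outside structures score 0
            sim = simulate_density(structure, grid, kernel)
        if not sim.same_geometry(target_map):
            sim = resample(sim, target_map.geometry())
        if float(np.sum(sim.values ** 2)) == 0.0:
            return 0.0
        return cross_correlation(sim, target_map)

    return progress


def rmsd_progress(reference: Structure,
                  selection: dict | None = None) -> Callable[[Structure], float]:
    """Progress variable: negative RMSD to a reference, so higher = closer."""

    def progress(structure: Structure) -> float:
        _, r = superpose(structure, reference, selection)
        return -r

    return progress
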