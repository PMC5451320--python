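"""Central integration controller.

The meta-algorithm: at each step every submodel is integrated from the same
immutable snapshot of the global state (the "arrow of time" contract) and
proposes its species changes as a request; a central controller arbitrates
the requests — production is always accepted, and when total requested
consumption of a species exceeds what is available the consumers are scaled
proportionally with largest-remainder apportionment — and commits the
result.  A step that needed scaling is normally *redone* at half the time
step (scaling distorts kinetics, so it is reserved for the floor ``dt_min``);
runs of clean steps let the step grow back.  Boolean-rule effects are
applied at the commit boundary and take effect in the next snapshot.

Randomness: each stochastic submodel draws from its own counter-based
stream keyed by (master seed, submodel id, step index, retry index), so the
order in which submodels are invoked can never perturb the draws, and a
redone step is an independent draw.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import engine_boolean, engine_fba, engine_ode, engine_ssa
from .model_core import Formalism, Submodel, WCModel, validate_model
from .state import ChangeRequest, StateSnapshot

logger = logging.getLogger("wcsim")


@dataclass
class CommitDecision:
    """Arbitration outcome for one step.

    ``accepted`` maps submodel id → accepted deltas; ``scaling`` records the
    applied consumption fraction per (species, submodel) where it differs
    from 1; ``scaled_species`` is the set of species whose consumers were
    scaled; ``committed_counts`` is the resulting global pool.
    """

    accepted: dict[str, dict[str, int]]
    scaling: dict[tuple[str, str], float]
    scaled_species: set[str]
    committed_counts: dict[str, int]


@dataclass
class SimulationConfig:
    """Controller configuration.

    All times are seconds.  ``clean_steps_to_grow`` (K) is the number of
    consecutive scale-free committed steps after which dt doubles (capped at
    ``dt_max``); any step that needed scaling and is above ``dt_min`` is
    redone at dt/2, up to ``max_retries`` times per step.
    """

    t_max: float
    dt_init: float = 1.0
    dt_min: float = 0.125
    dt_max: float = 1.0
    clean_steps_to_grow: int = 3
    seed: int = 0
    output_stride: int = 1
    max_retries: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.dt_min <= self.dt_init <= self.dt_max):
            raise ValueError("require 0 < dt_min <= dt_init <= dt_max")
        if self.clean_steps_to_grow < 1:
            raise ValueError("clean_steps_to_grow must be >= 1")


@dataclass
class Trajectory:
    """Committed states at the output stride, plus per-step diagnostics."""

    species_ids: list[str]
    times: np.ndarray  # (n_rows,)
    counts: np.ndarray  # (n_rows, n_species), integer
    diagnostics: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=self.species_ids)
        df.insert(0, "time", self.times)
        return df

    def final_counts(self) -> dict[str, int]:
        return dict(zip(self.species_ids, self.counts[-1].tolist()))


def submodel_stream(master_seed: int, submodel_id: str, step: int, retry: int = 0):
    """Independent per-(submodel, step, retry) random stream.

    The submodel id enters through a CRC32 hash so streams are a pure
    function of the id string, not of invocation order.
    """
    key = zlib.crc32(submodel_id.encode())
    ss = np.random.SeedSequence((int(master_seed) % (2**31), key, step, retry))
    return np.random.default_rng(ss)


def collect_requests(
    snapshot: StateSnapshot,
    submodels: Sequence[Submodel],
    dt: float,
    rng_streams: Mapping[str, np.random.Generator],
    carries: Mapping[str, object],
) -> tuple[list[ChangeRequest], dict[str, object]]:
    """Invoke every non-Boolean submodel's engine on the identical snapshot.

    Returns the requests plus the updated per-submodel carries (for ODE/FBA
    integerization residuals).  Engine failures propagate with the submodel
    id attached.  Invocation order is unobservable: engines are isolated on
    the snapshot and draw from per-submodel streams.
    """
    requests: list[ChangeRequest] = []
    new_carries: dict[str, object] = dict(carries)
    for sm in submodels:
        try:
            if sm.formalism is Formalism.SSA:
                result = engine_ssa.ssa_advance(snapshot, sm, dt, rng_streams[sm.id])
                requests.append(result.request)
            elif sm.formalism is Formalism.ODE:
                req, carry = engine_ode.ode_advance(snapshot, sm, dt, carries.get(sm.id))
                requests.append(req)
                new_carries[sm.id] = carry
            elif sm.formalism is Formalism.FBA:
                req, carry = engine_fba.fba_advance(snapshot, sm, dt, carries.get(sm.id))
                requests.append(req)
                new_carries[sm.id] = carry
            elif sm.formalism is Formalism.BOOLEAN:
                continue  # evaluated separately at commit time
        except Exception as exc:
            raise type(exc)(f"[submodel {sm.id}] {exc}") from exc
    return requests, new_carries


def arbitrate(requests: Sequence[ChangeRequest], counts: Mapping[str, int]) -> CommitDecision:
    """Accept, scale, or pass through the submodels' requests.

    Production (positive deltas) is always accepted in full.  For each
    species whose total requested consumption ``C`` exceeds the available
    pool ``A`` (current count plus total production), each consumer's
    request ``r_i`` is scaled to ``floor(r_i · A / C)`` and the remaining
    units are distributed by largest fractional remainder, ties broken by
    ascending submodel id.  All arithmetic is exact (integers), and the
    committed pool is never negative.  With no conflicts, requests are
    committed verbatim.
    """
    accepted: dict[str, dict[str, int]] = {
        r.submodel_id: dict(r.deltas) for r in requests
    }
    scaling: dict[tuple[str, str], float] = {}
    scaled_species: set[str] = set()

    species = sorted({sid for r in requests for sid in r.deltas})
    for sid in species:
        consumers = [r for r in requests if r.deltas.get(sid, 0) < 0]
        if not consumers:
            continue
        production = sum(r.production(sid) for r in requests)
        available = counts.get(sid, 0) + production
        total_consumption = sum(r.consumption(sid) for r in consumers)
        if total_consumption <= available:
            continue
        scaled_species.add(sid)
        # exact largest-remainder apportionment of `available` units
        shares = []
        for r in consumers:
            c_i = r.consumption(sid)
            floor_i = (c_i * available) // total_consumption
            rem_i = (c_i * available) % total_consumption
            shares.append([r.submodel_id, floor_i, rem_i, c_i])
        leftover = available - sum(s[1] for s in shares)
        for s in sorted(shares, key=lambda s: (-s[2], s[0]))[:leftover]:
            s[1] += 1
        for smid, granted, _, c_i in shares:
            accepted[smid][sid] = -granted
            scaling[(sid, smid)] = granted / c_i if c_i else 1.0

    committed = dict(counts)
    for smid, deltas in accepted.items():
        for sid, d in deltas.items():
            committed[sid] = committed.get(sid, 0) + d
    for sid, n in committed.items():
        if n < 0:  # pragma: no cover - guarded by construction
            raise AssertionError(f"arbitration committed negative count for '{sid}'")
    return CommitDecision(
        accepted=accepted,
        scaling=scaling,
        scaled_species=scaled_species,
        committed_counts=committed,
    )


@dataclass(frozen=True)
class DtDecision:
    next_dt: float
    redo: bool
    clean_counter: int
    warn: bool


def adapt_dt(
    decision: CommitDecision,
    dt: float,
    config: SimulationConfig,
    clean_counter: int,
    retries: int = 0,
) -> DtDecision:
    """Adaptive time-step policy driven by arbitration diagnostics.

    Scaling at ``dt > dt_min`` (with retry budget left) → redo the step at
    ``dt/2`` from the same snapshot.  Scaling at the floor, or with the
    retry budget exhausted, commits anyway with a warning.  After
    ``clean_steps_to_grow`` consecutive scale-free commits, dt doubles
    (capped at ``dt_max``) and the counter resets.
    """
    scaled = bool(decision.scaled_species)
    if scaled and dt > config.dt_min and retries < config.max_retries:
        return DtDecision(max(dt / 2.0, config.dt_min), True, clean_counter, False)
    if scaled:
        return DtDecision(dt, False, 0, True)
    clean_counter += 1
    if clean_counter >= config.clean_steps_to_grow:
        return DtDecision(min(2.0 * dt, config.dt_max), False, 0, False)
    return DtDecision(dt, False, clean_counter, False)


def simulate(model: WCModel, config: SimulationConfig, mode: str = "controller") -> Trajectory:
    """Run the multi-algorithm simulation to ``t_max``.

    ``mode="controller"`` is the arbitrated same-snapshot scheme described in
    the module docstring.  ``mode="sequential"`` is the rejected sequential
    alternative kept for reference and comparison: submodels are integrated
    one after another within each step, each seeing the previous one's
    committed output; no redo logic.  Both modes are fully reproducible from
    ``(model, config)``.

    Raises
    ------
    ValueError
        If validation fails (before any stepping).
    """
    report = validate_model(model)
    if not report.ok:
        raise ValueError(f"model validation failed:\n{report}")
    if mode not in ("controller", "sequential"):
        raise ValueError(f"unknown mode {mode!r}")

    species_ids = sorted(model.global_species)
    counts = {sid: model.global_species[sid].initial_count for sid in species_ids}
    parameters = dict(model.parameters)
    enabled_overrides: dict[str, bool] = {}
    carries: dict[str, object] = {}
    boolean_rules = [rule for sm in model.submodels if sm.formalism is Formalism.BOOLEAN for rule in sm.rules]
    kinetic_submodels = sorted(
        (sm for sm in model.submodels if sm.formalism is not Formalism.BOOLEAN),
        key=lambda sm: sm.id,
    )

    times = [0.0]
    rows = [[counts[sid] for sid in species_ids]]
    diagnostics: list[dict] = []
    time = 0.0
    dt = config.dt_init
    clean_counter = 0
    step_index = 0
    eps = 1e-12

    while time < config.t_max - eps:
        dt_step = min(dt, config.t_max - time)
        retry = 0
        while True:
            snapshot = StateSnapshot(time, counts, parameters, enabled_overrides)
            streams = {
                sm.id: submodel_stream(config.seed, sm.id, step_index, retry)
                for sm in kinetic_submodels
                if sm.formalism is Formalism.SSA
            }
            if mode == "controller":
                requests, new_carries = collect_requests(
                    snapshot, kinetic_submodels, dt_step, streams, carries
                )
                decision = arbitrate(requests, counts)
                verdict = adapt_dt(decision, dt_step, config, clean_counter, retry)
                if verdict.redo:
                    dt_step = verdict.next_dt
                    retry += 1
                    continue
            else:  # sequential reference mode
                running = dict(counts)
                accepted: dict[str, dict[str, int]] = {}
                scaled: set[str] = set()
                new_carries = dict(carries)
                for sm in kinetic_submodels:
                    sub_snap = StateSnapshot(time, running, parameters, enabled_overrides)
                    reqs, new_carries = collect_requests(
                        sub_snap, [sm], dt_step, streams, new_carries
                    )
                    d = arbitrate(reqs, running)
                    running = d.committed_counts
                    scaled |= d.scaled_species
                    accepted.update(d.accepted)
                decision = CommitDecision(accepted, {}, scaled, running)
                verdict = DtDecision(dt_step, False, clean_counter, bool(scaled))
            break

        if verdict.warn:
            logger.warning(
                "step %d at t=%.6g committed with scaling on %s (dt=%g at floor/retry limit)",
                step_index,
                time,
                sorted(decision.scaled_species),
                dt_step,
            )
        if decision.scaled_species and mode == "controller":
            logger.info(
                "step %d: scaled species %s at dt=%g (retry %d)",
                step_index,
                sorted(decision.scaled_species),
                dt_step,
                retry,
            )

        counts = decision.committed_counts
        carries = new_carries
        time += dt_step
        # Boolean rules see the step's input snapshot; effects apply from the
        # next snapshot on (one-step-delayed observers).
        if boolean_rules:
            for upd in engine_boolean.evaluate_rules(snapshot, boolean_rules):
                if upd.kind == "parameter":
                    parameters[upd.target] = upd.value
                else:
                    enabled_overrides[upd.target] = upd.enabled
        dt = min(max(verdict.next_dt, config.dt_min), config.dt_max)
        clean_counter = verdict.clean_counter
        step_index += 1
        if step_index % config.output_stride == 0 or time >= config.t_max - eps:
            times.append(time)
            rows.append([counts[sid] for sid in species_ids])
        diagnostics.append(
            {
                "step": step_index - 1,
                "time": time,
                "dt": dt_step,
                "n_scaled_species": len(decision.scaled_species),
                "retries": retry,
                "warned": verdict.warn,
            }
        )

    return Trajectory(
        species_ids=species_ids,
        times=np.asarray(times, dtype=float),
        counts=np.asarray(rows, dtype=np.int64),
        diagnostics=diagnostics,
    )
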