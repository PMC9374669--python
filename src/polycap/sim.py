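"""Capsule session simulation: transmission policy, modality switching,
over-the-air network replacement and the power/energy budget.

Policy: a frame with at least one surviving detection is significant — it
is transmitted, the frame rate rises to 2 fps, and an NBI capture of the
same scene is scheduled.  Insignificant frames are deleted except every
5th consecutive one, which is transmitted for localization; the counter
resets on a significant frame.  The frame rate decays back to 1 fps after
a configurable run of insignificant frames.

Power: a two-point static + dynamic clock model calibrated from the
printed operating points (300 mW at full clock, 50 mW at a tenfold-reduced
clock); battery energy is calibrated so a fully active session at reduced
clock lasts one hour, and operating time grows with the sparsity (idle
fraction) of the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .head import HeadConfig, ProposalSet, classify_frame, confidence_filter, decode_grid, nms
from .net.network import Network
from .net.spec import SpecError
from .records import WLI, AnnotatedImage
from .synth import render_nbi

__all__ = [
    "CapsuleState",
    "PowerModel",
    "SessionOver",
    "step",
    "run_session",
    "power_at_clock",
    "operating_time",
    "otap_update",
]

TRANSMIT_EVERY = 5  # every 5th consecutive insignificant frame is kept


class SessionOver(Exception):
    """Raised when the energy budget is exhausted."""


@dataclass(frozen=True)
class PowerModel:
    p_active_full_clock: float = 300.0     # mW at full clock
    p_active_reduced_clock: float = 50.0   # mW at clock / clock_divisor
    clock_divisor: float = 10.0
    p_idle: float = 5.0                    # mW; <= p_active/8 so 8-10 h sessions exist
    battery_energy: float = 50.0 * 3600.0  # mJ; default: 1 h fully active at reduced clock
    transmit_cost: float = 0.0             # optional per-transmission surcharge, mJ

    def __post_init__(self) -> None:
        if not (0 < self.p_idle < self.p_active_reduced_clock < self.p_active_full_clock):
            raise ValueError("require 0 < p_idle < p_reduced < p_full")
        if self.battery_energy <= 0:
            raise ValueError("battery_energy must be positive")


@dataclass
class CapsuleState:
    mode: str = "active"            # "active" | "hibernate" (externally triggered)
    frame_rate: int = 1             # fps, 1 or 2
    modality: str = WLI
    frames_seen: int = 0
    insignificant_streak: int = 0
    transmitted: list[str] = field(default_factory=list)
    deleted: list[str] = field(default_factory=list)
    energy_remaining: float = 50.0 * 3600.0
    network_version: str = "v0"
    rate_decay_after: int = 10      # insignificant frames before returning to 1 fps

    def __post_init__(self) -> None:
        if self.frame_rate not in (1, 2):
            raise ValueError("frame_rate must be 1 or 2")
        if self.energy_remaining < 0:
            raise ValueError("energy_remaining must be non-negative")


def power_at_clock(power: PowerModel, divisor: float) -> float:
    """Static + dynamic power at a given clock divisor, two-point calibrated.

    ``P(d) = s + p_dyn / d`` with ``s`` and ``p_dyn`` solved from
    ``P(1) = p_full`` and ``P(clock_divisor) = p_reduced``.
    """
    if divisor < 1:
        raise ValueError("clock divisor must be >= 1")
    d0 = power.clock_divisor
    p_dyn = (power.p_active_full_clock - power.p_active_reduced_clock) / (1.0 - 1.0 / d0)
    static = power.p_active_full_clock - p_dyn
    return static + p_dyn / divisor

def operating_time(power: PowerModel, sparsity: float) -> float:
    """Session duration in hours as a function of the idle fraction.

    ``T(s) = E / (s * p_idle + (1 - s) * p_active_reduced)``; strictly
    increasing in sparsity, with T(0) = 1 h under the default calibration.
    """
    if not (0.0 <= sparsity <= 1.0):
        raise ValueError("sparsity must lie in [0, 1]")
    mean_power = sparsity * power.p_idle + (1.0 - sparsity) * power.p_active_reduced_clock
    return power.battery_energy / mean_power / 3600.0


def step(state: CapsuleState, frame: AnnotatedImage, detections: ProposalSet,
         power: PowerModel | None = None) -> tuple[CapsuleState, dict]:
    """Advance the session by one already-classified frame.

    ``detections`` must be confidence-filtered.  Returns the new state and
    an action record (transmit/delete, frame-rate, scheduled NBI capture).
    Raises :class:`SessionOver` when the energy budget is already exhausted.
    """
    power = power or PowerModel()
    if state.energy_remaining <= 0:
        raise SessionOver("energy budget exhausted")
    frame_id = frame.frame_id or f"frame{state.frames_seen}"
    significant = classify_frame(detections) == "significant"

    new = replace_dataclass(state)
    new.frames_seen += 1
    cost = power.p_active_reduced_clock * (1.0 / new.frame_rate)
    actions: dict = {"frame_id": frame_id, "significant": significant,
                     "modality": frame.modality, "schedule_nbi": False}

    if significant:
        new.transmitted.append(frame_id)
        new.insignificant_streak = 0
        new.frame_rate = 2
        actions["action"] = "transmit"
        if frame.modality == WLI:
            actions["schedule_nbi"] = True
        cost += power.transmit_cost
    else:
        new.insignificant_streak += 1
        if new.insignificant_streak % TRANSMIT_EVERY == 0:
            new.transmitted.append(frame_id)
            actions["action"] = "transmit"
            cost += power.transmit_cost
        else:
            new.deleted.append(frame_id)
            actions["action"] = "delete"
        if new.insignificant_streak >= new.rate_decay_after:
            new.frame_rate = 1

    new.energy_remaining = max(state.energy_remaining - cost, 0.0)
    actions["energy_spent"] = min(cost, state.energy_remaining)
    actions["frame_rate"] = new.frame_rate
    actions["energy_remaining"] = new.energy_remaining
    return new, actions


def replace_dataclass(state: CapsuleState) -> CapsuleState:
    return CapsuleState(
        mode=state.mode, frame_rate=state.frame_rate, modality=state.modality,
        frames_seen=state.frames_seen, insignificant_streak=state.insignificant_streak,
        transmitted=list(state.transmitted), deleted=list(state.deleted),
        energy_remaining=state.energy_remaining, network_version=state.network_version,
        rate_decay_after=state.rate_decay_after,
    )


def detect(network: Network, frame: AnnotatedImage, head: HeadConfig) -> ProposalSet:
    """Forward -> decode -> confidence filter -> NMS for one frame."""
    raw = network.forward_batch(frame.pixels[None], training=False)[0]
    proposals = decode_grid(raw, head, source_frame_id=frame.frame_id)
    kept = confidence_filter(proposals, head.score_threshold)
    return nms(kept, head.nms_iou)


def run_session(frames, network: Network, head: HeadConfig,
                power: PowerModel | None = None,
                state0: CapsuleState | None = None,
                nbi_followup: bool = True) -> tuple[CapsuleState, list[dict]]:
    """Iterate detector + policy over a frame stream until it (or energy) runs out.

    A significant WLI frame schedules an NBI re-capture of the same scene,
    which is processed before the next stream frame.  Deterministic for
    fixed inputs; the log records one row per processed frame.
    """
    power = power or PowerModel()
    state = state0 or CapsuleState(energy_remaining=power.battery_energy)
    log: list[dict] = []
    queue: list[AnnotatedImage] = []
    stream = iter(frames)
    while True:
        if queue:
            frame = queue.pop(0)
        else:
            frame = next(stream, None)
            if frame is None:
                break
        detections = detect(network, frame, head)
        try:
            state, actions = step(state, frame, detections, power)
        except SessionOver:
            break
        actions["network_version"] = state.network_version
        log.append(actions)
        if nbi_followup and actions["schedule_nbi"]:
            nbi_frame = render_nbi(frame)
            nbi_frame.frame_id = f"{frame.frame_id}/nbi" if frame.frame_id else "nbi"
            queue.append(nbi_frame)
        if state.energy_remaining <= 0:
            break
    return state, log


def otap_update(state: CapsuleState, current: Network, new_network: Network
                ) -> tuple[CapsuleState, Network]:
    """Replace the onboard network mid-session.

    The replacement must match the deployed architecture contract (input
    and output shapes); an incompatible network is rejected and the old one
    retained.  Counters and the energy ledger are unaffected.
    """
    if new_network.spec.input_shape != current.spec.input_shape or \
            new_network.spec.output_shape != current.spec.output_shape:
        raise SpecError(
            f"over-the-air update rejected: network maps "
            f"{new_network.spec.input_shape} -> {new_network.spec.output_shape}, "
            f"deployed contract is {current.spec.input_shape} -> "
            f"{current.spec.output_shape}"
        )
    new_state = replace_dataclass(state)
    try:
        version = int(state.network_version.lstrip("v")) + 1
    except ValueError:
        version = 1
    new_state.network_version = f"v{version}"
    new_network.version = new_state.network_version
    return new_state, new_network
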