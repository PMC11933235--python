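"""Turn-transition extraction, classification, timing, and tabulation.

A turn transition is an ordered pair of units produced by the two
*different* interactants (role reversal), where the second unit begins
within 30 s of the end of the first.  Signed timing follows the
convention that negative values mean a gap between the turns (overlap
avoidance) and positive values mean the response began before the first
unit ended (overlap)::

    timing = first.offset - second.onset

The pairing rule is greedy-earliest: scanning units in temporal order,
each produced unit's candidate response is the earliest-onset unit by
the other interactant that starts no earlier than it and has not already
been claimed as a response.  Each unit is the first element of at most
one transition and the second element of at most one; units whose
candidate fails the 30 s gap rule (or that have no candidate) yield no
transition — these are the "no response" rows of the unit-level model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from turntaking.event_model import Interaction, UnitAnnotation, ValidationError

TRANSITION_TYPES = ("action_action", "action_signal", "signal_action", "signal_signal")

DEFAULT_WINDOW = 30.0


@dataclass(frozen=True)
class TurnTransition:
    interaction_id: str
    first_unit: UnitAnnotation
    second_unit: UnitAnnotation

    def __post_init__(self) -> None:
        if self.first_unit.actor_id == self.second_unit.actor_id:
            raise ValidationError("turn transition requires role reversal")

    @property
    def type(self) -> str:
        return classify_type(self)

    @property
    def timing(self) -> float:
        return timing(self)

    @property
    def overlap(self) -> bool:
        # Simultaneity (timing == 0) counts as the limit of avoidance.
        return timing(self) > 0


def classify_type(t: TurnTransition) -> str:
    """Map the (first, second) modalities to one of the four types."""
    m1, m2 = t.first_unit.modality, t.second_unit.modality
    for m in (m1, m2):
        if m not in ("action", "signal"):
            raise ValidationError(f"unit modality unset or invalid: {m!r}")
    return f"{m1}_{m2}"


def timing(t: TurnTransition) -> float:
    """Signed offset-to-onset timing: negative = gap (overlap avoidance),
    positive = overlap."""
    return t.first_unit.offset - t.second_unit.onset


def extract_transitions(
    interaction: Interaction, window: float = DEFAULT_WINDOW
) -> list[TurnTransition]:
    """Extract all turn transitions from one interaction.

    See the module docstring for the pairing rule.  ``window`` bounds
    the *gap* (second.onset − first.offset ≤ window); overlapping
    responses always qualify.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    units = interaction.units  # sorted by (onset, offset, actor)
    claimed_as_second: set[int] = set()
    out: list[TurnTransition] = []
    for i, u in enumerate(units):
        candidate = None
        for j, v in enumerate(units):
            if j == i or j in claimed_as_second:
                continue
            if v.actor_id == u.actor_id or v.onset < u.onset:
                continue
            candidate = j
            break  # units sorted: first hit is earliest-onset
        if candidate is None:
            continue
        v = units[candidate]
        if v.onset - u.offset <= window:
            claimed_as_second.add(candidate)
            out.append(
                TurnTransition(
                    interaction_id=interaction.interaction_id,
                    first_unit=u,
                    second_unit=v,
                )
            )
    return out


@dataclass
class TransitionSummary:
    n_units: int
    n_transitions: int
    counts_by_type: dict[str, int]
    proportion_by_type: dict[str, float]
    overlap_avoidance_fraction: float
    median_timing_by_type: dict[str, float | None]
    n_interactions_with_transition: int

    def as_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "n_transitions": self.n_transitions,
            "counts_by_type": dict(self.counts_by_type),
            "proportion_by_type": dict(self.proportion_by_type),
            "overlap_avoidance_fraction": self.overlap_avoidance_fraction,
            "median_timing_by_type": dict(self.median_timing_by_type),
            "n_interactions_with_transition": self.n_interactions_with_transition,
        }


def summarize_transitions(
    interactions: Iterable[Interaction], window: float = DEFAULT_WINDOW
) -> TransitionSummary:
    """Aggregate transition counts, type mixture, overlap avoidance, and
    per-type median signed timings over a set of interactions."""
    n_units = 0
    counts = {t: 0 for t in TRANSITION_TYPES}
    timings: dict[str, list[float]] = {t: [] for t in TRANSITION_TYPES}
    n_with = 0
    n_avoid = 0
    for inter in interactions:
        n_units += len(inter.units)
        trans = extract_transitions(inter, window=window)
        if trans:
            n_with += 1
        for t in trans:
            tt = t.type
            counts[tt] += 1
            timings[tt].append(t.timing)
            if t.timing < 0:
                n_avoid += 1
    n_trans = sum(counts.values())
    props = {
        t: (counts[t] / n_trans if n_trans else 0.0) for t in TRANSITION_TYPES
    }
    medians = {
        t: (float(np.median(timings[t])) if timings[t] else None)
        for t in TRANSITION_TYPES
    }
    return TransitionSummary(
        n_units=n_units,
        n_transitions=n_trans,
        counts_by_type=counts,
        proportion_by_type=props,
        overlap_avoidance_fraction=(n_avoid / n_trans if n_trans else 0.0),
        median_timing_by_type=medians,
        n_interactions_with_transition=n_with,
    )


def transition_table(
    interactions: Iterable[Interaction], window: float = DEFAULT_WINDOW
) -> pd.DataFrame:
    """One row per turn transition: ids, type, signed timing, overlap."""
    rows = []
    for inter in interactions:
        for t in extract_transitions(inter, window=window):
            rows.append(
                {
                    "interaction_id": inter.interaction_id,
                    "initiator_id": t.first_unit.actor_id,
                    "recipient_id": t.second_unit.actor_id,
                    "dyad_id": "--".join(inter.dyad),
                    "community": inter.community,
                    "type": t.type,
                    "timing_s": t.timing,
                    "overlap": t.overlap,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "interaction_id",
            "initiator_id",
            "recipient_id",
            "dyad_id",
            "community",
            "type",
            "timing_s",
            "overlap",
        ],
    )


def unit_response_table(
    interactions: Iterable[Interaction], window: float = DEFAULT_WINDOW
) -> pd.DataFrame:
    """One row per produced unit, for the unit-level response model.

    ``response`` is 1 iff the unit is the first element of some turn
    transition.  The unit's actor is the initiator slot; the other
    interactant is the recipient slot.  The row count therefore equals
    the total number of produced units.
    """
    rows = []
    for inter in interactions:
        firsts = {
            id(t.first_unit) for t in extract_transitions(inter, window=window)
        }
        for u in inter.units:
            rows.append(
                {
                    "interaction_id": inter.interaction_id,
                    "initiator_id": u.actor_id,
                    "recipient_id": inter.partner_of(u.actor_id),
                    "dyad_id": "--".join(inter.dyad),
                    "community": inter.community,
                    "modality": u.modality,
                    "response": int(id(u) in firsts),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "interaction_id",
            "initiator_id",
            "recipient_id",
            "dyad_id",
            "community",
            "modality",
            "response",
        ],
    )


def interaction_tally_table(
    interactions: Sequence[Interaction], window: float = DEFAULT_WINDOW
) -> pd.DataFrame:
    """One row per interaction: transition tally plus duration (the
    offset term of the frequency model).  The interaction-level
    initiator is the actor of the earliest unit."""
    rows = []
    for inter in interactions:
        if inter.duration <= 0:
            raise ValidationError(
                f"interaction {inter.interaction_id}: duration must be > 0 "
                "(log-duration offset undefined)"
            )
        trans = extract_transitions(inter, window=window)
        initiator = inter.units[0].actor_id if inter.units else inter.dyad[0]
        rows.append(
            {
                "interaction_id": inter.interaction_id,
                "initiator_id": initiator,
                "recipient_id": inter.partner_of(initiator),
                "dyad_id": "--".join(inter.dyad),
                "community": inter.community,
                "n_transitions": len(trans),
                "duration_s": inter.duration,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "interaction_id",
            "initiator_id",
            "recipient_id",
            "dyad_id",
            "community",
            "n_transitions",
            "duration_s",
        ],
    )
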