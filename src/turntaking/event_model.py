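"""Domain types, tabular readers/writers, and inter-rater agreement.

The atom of the pipeline is the :class:`UnitAnnotation`: one produced
signal (gesture) or action with an actor and an onset/offset in seconds
relative to the start of its interaction.  Interactions are strictly
dyadic.  All intervals are half-open ``[onset, offset)`` so overlap
arithmetic is unambiguous.

Interchange format is plain delimited text (TSV by default); the readers
validate every row and either warn (default) or raise (``strict=True``)
on records referencing individuals missing from a roster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

COMMUNITIES = ("central", "western")
MODALITIES = ("signal", "action")
AGONISTIC_KINDS = ("aggression", "pant_grunt", "pant_bark")

EVENT_LOG_COLUMNS = [
    "interaction_id",
    "actor_id",
    "partner_id",
    "community",
    "modality",
    "label",
    "onset_s",
    "offset_s",
    "interaction_duration_s",
]


class FormatError(ValueError):
    """A table is missing required columns or is otherwise malformed."""


class ValidationError(ValueError):
    """A row or record violates a domain invariant."""


@dataclass(frozen=True)
class Individual:
    """A study subject.

    Ages are years at the study midpoint; the inclusion rule admits
    males of 13 years and older (independent of their mothers).
    """

    id: str
    community: str
    age: float
    observation_time: float = 0.0

    def __post_init__(self) -> None:
        if self.community not in COMMUNITIES:
            raise ValidationError(
                f"community must be one of {COMMUNITIES}, got {self.community!r}"
            )
        if self.age < 13:
            raise ValidationError(f"age must be >= 13 (inclusion rule), got {self.age}")
        if self.observation_time < 0:
            raise ValidationError("observation_time must be >= 0")


@dataclass(frozen=True)
class UnitAnnotation:
    """One produced signal or action unit within an interaction."""

    interaction_id: str
    actor_id: str
    modality: str
    label: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        if self.onset > self.offset:
            raise ValidationError(
                f"onset ({self.onset}) must be <= offset ({self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _unit_sort_key(u: UnitAnnotation) -> tuple:
    # Tie-break identical onsets by offset, then actor id (documented).
    return (u.onset, u.offset, u.actor_id)


@dataclass
class Interaction:
    """A dyadic grooming interaction with its ordered unit stream."""

    interaction_id: str
    dyad: tuple[str, str]
    community: str
    duration: float
    units: list[UnitAnnotation] = field(default_factory=list)
    phases: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        a, b = self.dyad
        if a == b:
            raise ValidationError(f"interaction {self.interaction_id}: dyad must be two distinct ids")
        self.dyad = tuple(sorted((a, b)))
        if self.community not in COMMUNITIES:
            raise ValidationError(
                f"community must be one of {COMMUNITIES}, got {self.community!r}"
            )
        for u in self.units:
            if u.actor_id not in self.dyad:
                raise ValidationError(
                    f"interaction {self.interaction_id}: actor {u.actor_id!r} "
                    f"is not one of the interactants {self.dyad}"
                )
        self.units = sorted(self.units, key=_unit_sort_key)
        if self.units:
            max_off = max(u.offset for u in self.units)
            if self.duration < max_off:
                raise ValidationError(
                    f"interaction {self.interaction_id}: duration {self.duration} "
                    f"< max unit offset {max_off}"
                )

    def partner_of(self, actor_id: str) -> str:
        a, b = self.dyad
        return b if actor_id == a else a


@dataclass(frozen=True)
class AgonisticRecord:
    """A decided agonistic event: an aggression with a clear winner, or a
    submissive signal (pant-grunt / pant-bark) whose producer is the
    subordinate and whose recipient is credited as dominant."""

    kind: str
    dominant_id: str
    subordinate_id: str
    community: str

    def __post_init__(self) -> None:
        if self.kind not in AGONISTIC_KINDS:
            raise ValidationError(
                f"kind must be one of {AGONISTIC_KINDS}, got {self.kind!r}"
            )
        if self.dominant_id == self.subordinate_id:
            raise ValidationError("dominant_id must differ from subordinate_id")


@dataclass(frozen=True)
class ScanRecord:
    """One 15-minute proximity scan: which individuals were within ~1 m
    of the focal."""

    focal_id: str
    timestamp: float
    partner_ids_within_1m: frozenset[str]

    def __post_init__(self) -> None:
        if self.focal_id in self.partner_ids_within_1m:
            raise ValidationError("focal cannot be its own proximity partner")


@dataclass(frozen=True)
class GroomingRecord:
    """One focal grooming bout (episode of unidirectional grooming)."""

    actor_id: str
    recipient_id: str

    def __post_init__(self) -> None:
        if self.actor_id == self.recipient_id:
            raise ValidationError("grooming actor and recipient must differ")


class RelatednessTable:
    """Symmetric binary map: 1 iff the pair are maternal siblings."""

    def __init__(self, related_pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[frozenset[str]] = set()
        for a, b in related_pairs:
            if a == b:
                raise ValidationError("self-pairs are not allowed in relatedness table")
            self._pairs.add(frozenset((a, b)))

    def related(self, a: str, b: str) -> int:
        return int(frozenset((a, b)) in self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path, required: Sequence[str], sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_event_log(path, sep: str = "\t") -> list[Interaction]:
    """Read a unit-level annotation table into validated Interactions.

    The table has one row per unit with columns
    ``interaction_id, actor_id, partner_id, community, modality, label,
    onset_s, offset_s, interaction_duration_s``.  Rows are grouped by
    interaction id; units are sorted by (onset, offset, actor id).
    """
    df = _read_table(path, EVENT_LOG_COLUMNS, sep)
    if df.empty:
        logger.warning("event log %s is empty", path)
        return []

    interactions: list[Interaction] = []
    for iid, grp in df.groupby("interaction_id", sort=False):
        actors = sorted(set(grp["actor_id"]) | set(grp["partner_id"]))
        if len(actors) > 2:
            raise ValidationError(
                f"interaction {iid!r}: more than two interactants: {actors}"
            )
        units = []
        for idx, row in grp.iterrows():
            onset, offset = float(row["onset_s"]), float(row["offset_s"])
            if offset < onset:
                raise ValidationError(
                    f"row {idx}: offset_s ({offset}) < onset_s ({onset})"
                )
            units.append(
                UnitAnnotation(
                    interaction_id=str(iid),
                    actor_id=row["actor_id"],
                    modality=row["modality"],
                    label=row["label"],
                    onset=onset,
                    offset=offset,
                )
            )
        interactions.append(
            Interaction(
                interaction_id=str(iid),
                dyad=(actors[0], actors[1]),
                community=grp["community"].iloc[0],
                duration=float(grp["interaction_duration_s"].iloc[0]),
                units=units,
            )
        )
    return interactions


def write_event_log(interactions: Iterable[Interaction], path, sep: str = "\t") -> None:
    """Write interactions back to the unit-level table (round-trips
    :func:`read_event_log` bit-exactly)."""
    rows = []
    for inter in interactions:
        for u in inter.units:
            rows.append(
                {
                    "interaction_id": inter.interaction_id,
                    "actor_id": u.actor_id,
                    "partner_id": inter.partner_of(u.actor_id),
                    "community": inter.community,
                    "modality": u.modality,
                    "label": u.label,
                    "onset_s": repr(u.onset),
                    "offset_s": repr(u.offset),
                    "interaction_duration_s": repr(inter.duration),
                }
            )
    pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS).to_csv(path, sep=sep, index=False)


def _check_roster(ids: Iterable[str], roster, path, strict: bool) -> None:
    if roster is None:
        return
    roster = set(roster)
    unknown = sorted(set(ids) - roster)
    if unknown:
        if strict:
            raise ValidationError(f"{path}: unknown individual id(s): {unknown}")
        logger.warning("%s: %d unknown individual id(s): %s", path, len(unknown), unknown)


def read_agonistic_records(
    path, roster: Iterable[str] | None = None, strict: bool = False, sep: str = "\t"
) -> list[AgonisticRecord]:
    """Read agonistic events.

    Columns: ``kind, dominant_id, subordinate_id, community``.  For
    submissive signals (pant_grunt, pant_bark) the *recipient* of the
    signal is entered as ``dominant_id``.
    """
    df = _read_table(path, ["kind", "dominant_id", "subordinate_id", "community"], sep)
    records = []
    for idx, row in df.iterrows():
        if row["kind"] not in AGONISTIC_KINDS:
            raise ValidationError(
                f"row {idx}: unknown kind {row['kind']!r}; allowed: {AGONISTIC_KINDS}"
            )
        records.append(
            AgonisticRecord(
                kind=row["kind"],
                dominant_id=row["dominant_id"],
                subordinate_id=row["subordinate_id"],
                community=row["community"],
            )
        )
    ids = list(df["dominant_id"]) + list(df["subordinate_id"])
    _check_roster(ids, roster, path, strict)
    return records


def read_scan_records(
    path, roster: Iterable[str] | None = None, strict: bool = False, sep: str = "\t"
) -> list[ScanRecord]:
    """Read proximity scans.  Columns: ``focal_id, timestamp,
    partner_ids_within_1m`` (comma-separated ids, empty for none)."""
    df = _read_table(path, ["focal_id", "timestamp", "partner_ids_within_1m"], sep)
    records = []
    for _, row in df.iterrows():
        raw = row["partner_ids_within_1m"]
        partners = frozenset(p for p in str(raw).split(",") if p) if pd.notna(raw) else frozenset()
        records.append(
            ScanRecord(
                focal_id=row["focal_id"],
                timestamp=float(row["timestamp"]),
                partner_ids_within_1m=partners,
            )
        )
    ids = [r.focal_id for r in records] + [p for r in records for p in r.partner_ids_within_1m]
    _check_roster(ids, roster, path, strict)
    return records


def read_grooming_records(
    path, roster: Iterable[str] | None = None, strict: bool = False, sep: str = "\t"
) -> list[GroomingRecord]:
    """Read focal grooming bouts.  Columns: ``actor_id, recipient_id``."""
    df = _read_table(path, ["actor_id", "recipient_id"], sep)
    records = [
        GroomingRecord(actor_id=row["actor_id"], recipient_id=row["recipient_id"])
        for _, row in df.iterrows()
    ]
    ids = [r.actor_id for r in records] + [r.recipient_id for r in records]
    _check_roster(ids, roster, path, strict)
    return records


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------

UNMATCHED = "<unmatched>"


def _overlap(a: UnitAnnotation, b: UnitAnnotation) -> float:
    return max(0.0, min(a.offset, b.offset) - max(a.onset, b.onset))


def interrater_agreement(
    tier_a: Sequence[UnitAnnotation],
    tier_b: Sequence[UnitAnnotation],
    overlap_threshold: float = 0.60,
    bidirectional: bool = True,
) -> dict:
    """Segment-matching inter-rater agreement with Cohen's kappa.

    Segments from the two raters are greedily linked by maximal temporal
    overlap (each segment links at most once).  A linked pair counts as
    an agreement cell (label_a, label_b) only if the overlap covers at
    least ``overlap_threshold`` of both segments' durations (of the
    first segment only if ``bidirectional=False``).  Segments that fail
    the overlap rule, and unlinked segments, fall in an explicit
    "unmatched" category, so missed annotations penalise agreement.

    Returns ``{"kappa", "linked_pairs", "unmatched_a", "unmatched_b"}``;
    ``kappa`` is ``None`` when either tier is empty (no-data result).
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    if not tier_a or not tier_b:
        return {
            "kappa": None,
            "linked_pairs": 0,
            "unmatched_a": len(tier_a),
            "unmatched_b": len(tier_b),
        }

    candidates = []
    for i, ua in enumerate(tier_a):
        for j, ub in enumerate(tier_b):
            ov = _overlap(ua, ub)
            if ov > 0:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for ov, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, ov))

    def _qualifies(i: int, j: int, ov: float) -> bool:
        da, db = tier_a[i].duration, tier_b[j].duration
        if da <= 0 or db <= 0:
            return False
        ok_a = ov / da >= overlap_threshold
        ok_b = ov / db >= overlap_threshold
        return (ok_a and ok_b) if bidirectional else ok_a

    cells: list[tuple[str, str]] = []
    linked = 0
    for i, j, ov in pairs:
        if _qualifies(i, j, ov):
            cells.append((tier_a[i].label, tier_b[j].label))
            linked += 1
        else:
            cells.append((tier_a[i].label, UNMATCHED))
            cells.append((UNMATCHED, tier_b[j].label))
    for i in range(len(tier_a)):
        if i not in used_a:
            cells.append((tier_a[i].label, UNMATCHED))
    for j in range(len(tier_b)):
        if j not in used_b:
            cells.append((UNMATCHED, tier_b[j].label))

    kappa = _cohens_kappa(cells)
    return {
        "kappa": kappa,
        "linked_pairs": linked,
        "unmatched_a": len(tier_a) - linked,
        "unmatched_b": len(tier_b) - linked,
    }


def _cohens_kappa(cells: Sequence[tuple[str, str]]) -> float:
    labels = sorted({a for a, _ in cells} | {b for _, b in cells})
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    conf = [[0] * n for _ in range(n)]
    for a, b in cells:
        conf[index[a]][index[b]] += 1
    total = len(cells)
    po = sum(conf[k][k] for k in range(n)) / total
    row = [sum(conf[k]) / total for k in range(n)]
    col = [sum(conf[r][k] for r in range(n)) / total for k in range(n)]
    pe = sum(r * c for r, c in zip(row, col))
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)
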