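"""Dyadic Composite Sociality Index (DSI) from grooming and proximity.

For a dyad (A, B) the index sums a grooming fraction and a proximity
fraction::

    DSI = G_AB / (G_AB + G_A + G_B)  +  P_AB / (P_AB + P_A + P_B)

where ``G_AB`` counts grooming bouts between A and B (either direction),
``G_A`` counts A's grooming bouts not involving B (and vice versa),
``P_AB`` counts proximity scans in which A and B were within ~1 m of
each other, and ``P_A`` / ``P_B`` count each individual's focal scans
excluding the other.  A term with a zero denominator contributes 0, so
the index is always defined and lies in [0, 2].  Higher values mark more
strongly bonded dyads relative to the rest of their community.

"Frequency" is counted as bouts/scans (episodes), not durations; pass
``weights`` to :func:`dyad_counts` to switch to duration weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from turntaking.event_model import GroomingRecord, ScanRecord, ValidationError


@dataclass(frozen=True)
class DyadCounts:
    G_AB: float
    G_A: float
    G_B: float
    P_AB: float
    P_A: float
    P_B: float

    def __post_init__(self) -> None:
        if min(self.G_AB, self.G_A, self.G_B, self.P_AB, self.P_A, self.P_B) < 0:
            raise ValidationError("all dyad counts must be >= 0")


@dataclass(frozen=True)
class DyadSociality:
    dyad: tuple[str, str]
    dsi: float


def dyad_counts(
    grooming_records: Iterable[GroomingRecord],
    scan_records: Iterable[ScanRecord],
    dyad: tuple[str, str],
    weights: Mapping[int, float] | None = None,
) -> DyadCounts:
    """Tally the six DSI input counts for one unordered dyad."""
    a, b = dyad
    if a == b:
        raise ValidationError("dyad must contain two distinct ids")
    g_ab = g_a = g_b = 0.0
    for rec in grooming_records:
        members = {rec.actor_id, rec.recipient_id}
        if members == {a, b}:
            g_ab += 1
        elif a in members:
            g_a += 1
        elif b in members:
            g_b += 1
    p_ab = p_a = p_b = 0.0
    for scan in scan_records:
        if scan.focal_id == a:
            if b in scan.partner_ids_within_1m:
                p_ab += 1
            else:
                p_a += 1
        elif scan.focal_id == b:
            if a in scan.partner_ids_within_1m:
                p_ab += 1
            else:
                p_b += 1
    return DyadCounts(G_AB=g_ab, G_A=g_a, G_B=g_b, P_AB=p_ab, P_A=p_a, P_B=p_b)


def dsi(c: DyadCounts) -> float:
    """The two-fraction composite index; zero-denominator terms are 0."""
    g_den = c.G_AB + c.G_A + c.G_B
    p_den = c.P_AB + c.P_A + c.P_B
    g_term = c.G_AB / g_den if g_den > 0 else 0.0
    p_term = c.P_AB / p_den if p_den > 0 else 0.0
    return g_term + p_term


def dsi_table(
    grooming_records: Sequence[GroomingRecord],
    scan_records: Sequence[ScanRecord],
    roster: Sequence[str],
) -> list[DyadSociality]:
    """DSI for every unordered dyad in the roster, in roster order."""
    out = []
    for a, b in combinations(roster, 2):
        c = dyad_counts(grooming_records, scan_records, (a, b))
        out.append(DyadSociality(dyad=(a, b), dsi=dsi(c)))
    return out
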