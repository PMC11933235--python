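"""Independent oracles and random-input generators shared by the tests.

Everything here re-derives expected results from first principles
(explicit double loops, exhaustive enumeration, direct formula
transcription) so the package implementation is checked against code
that shares none of its structure.
"""

from __future__ import annotations

import itertools

import numpy as np

from turntaking.event_model import Interaction, UnitAnnotation


def random_event_log(
    rng: np.random.Generator,
    n_units: int,
    interaction_id: str = "I0",
    t_max: float = 120.0,
) -> Interaction:
    """A random two-actor unit stream with arbitrary overlaps and gaps."""
    units = []
    for k in range(n_units):
        onset = float(np.round(rng.uniform(0, t_max), 3))
        dur = float(np.round(rng.uniform(0.1, 25.0), 3))
        units.append(
            UnitAnnotation(
                interaction_id=interaction_id,
                actor_id=rng.choice(["A", "B"]),
                modality=rng.choice(["action", "signal"]),
                label="u",
                onset=onset,
                offset=onset + dur,
            )
        )
    duration = max(u.offset for u in units) + 1.0
    return Interaction(
        interaction_id=interaction_id,
        dyad=("A", "B"),
        community="central",
        duration=duration,
        units=units,
    )


def brute_force_transition_pairs(
    interaction: Interaction, window: float = 30.0
) -> list[tuple[UnitAnnotation, UnitAnnotation]]:
    """Exhaustive re-derivation of the pairing rule.

    For every unit, scan *all* other units for role-reversed candidates
    starting no earlier, take the earliest-onset unclaimed one, and
    admit the pair when the gap respects the window.
    """
    key = lambda u: (u.onset, u.offset, u.actor_id)
    units = sorted(interaction.units, key=key)
    claimed: list[int] = []
    pairs = []
    for i, u in enumerate(units):
        best = None
        for j, v in enumerate(units):
            if j == i or j in claimed:
                continue
            if v.actor_id == u.actor_id:
                continue
            if v.onset < u.onset:
                continue
            if best is None or key(v) < key(units[best]):
                best = j
        if best is None:
            continue
        v = units[best]
        if v.onset - u.offset <= window:
            claimed.append(best)
            pairs.append((u, v))
    return pairs


def brute_force_david_scores(wins: np.ndarray, variant: str = "Pij"):
    """Direct loop transcription of David's method: w, w2, l, l2."""
    n = wins.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            nij = wins[i, j] + wins[j, i]
            if nij == 0:
                continue
            pij = wins[i, j] / nij
            if variant == "Dij":
                pij = pij - (pij - 0.5) / (nij + 1)
            p[i, j] = pij
    w = np.array([sum(p[i, j] for j in range(n)) for i in range(n)])
    l = np.array([sum(p[j, i] for j in range(n)) for i in range(n)])
    w2 = np.array([sum(p[i, j] * w[j] for j in range(n)) for i in range(n)])
    l2 = np.array([sum(p[j, i] * l[j] for j in range(n)) for i in range(n)])
    ds = w + w2 - l - l2
    norm = (ds + n * (n - 1) / 2) / n
    return ds, norm


def exhaustive_isi(wins: np.ndarray) -> tuple[int, int]:
    """Minimal (I, SI) over every ordering, counted independently."""
    n = wins.shape[0]
    best = None
    for perm in itertools.permutations(range(n)):
        inc = 0
        strength = 0
        for a in range(n):
            for b in range(a + 1, n):
                hi, lo = perm[a], perm[b]
                if wins[lo, hi] > wins[hi, lo]:
                    inc += 1
                    strength += b - a
        if best is None or (inc, strength) < best:
            best = (inc, strength)
    return best


def make_interaction(
    spans: list[tuple[str, str, float, float]], iid: str = "I0"
) -> Interaction:
    """Compact constructor: (actor, modality, onset, offset) tuples."""
    units = [
        UnitAnnotation(
            interaction_id=iid,
            actor_id=a,
            modality=m,
            label="groom" if m == "action" else "gesture",
            onset=on,
            offset=off,
        )
        for a, m, on, off in spans
    ]
    return Interaction(
        interaction_id=iid,
        dyad=("A", "B"),
        community="central",
        duration=max(u.offset for u in units) + 1.0,
        units=units,
    )
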