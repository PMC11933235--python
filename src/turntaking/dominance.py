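"""Dominance hierarchy construction and metrics.

From pooled decided agonistic interactions (aggressions with a clear
winner, plus pant-grunt / pant-bark submissive signals whose producer is
subordinate) a winner-by-loser count matrix is built, and from it:

* David's scores from dyadic win proportions (raw ``Pij`` or the
  chance-corrected ``Dij`` variant), with the usual normalisation
  ``normDS = (DS + n(n-1)/2) / n`` so that scores sum to n(n-1)/2;
* hierarchy steepness — the absolute OLS slope of normDS against ordinal
  rank position — with a permutation test that reallocates each dyad's
  outcomes at random while keeping its interaction count;
* the improved linearity index h' (Landau's h corrected for tied and
  unknown relationships by randomly directing them) with a
  randomization test;
* an I&SI ordinal ranking minimising first the number of
  inconsistencies (dyads where the lower-ranked individual holds the
  winning record) and then their summed strength (rank distance),
  exactly for small groups and by seeded local search above.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from turntaking.event_model import AgonisticRecord, ValidationError


@dataclass
class DominanceMatrix:
    """Square count matrix; ``wins[i, j]`` = times ids[i] dominated ids[j]."""

    ids: list[str]
    wins: np.ndarray

    def __post_init__(self) -> None:
        self.wins = np.asarray(self.wins, dtype=float)
        n = len(self.ids)
        if self.wins.shape != (n, n):
            raise ValidationError("wins must be n x n for n ids")
        if (self.wins < 0).any():
            raise ValidationError("win counts must be non-negative")
        if np.diag(self.wins).any():
            raise ValidationError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)


def build_dominance_matrix(
    records: Iterable[AgonisticRecord],
    ids: Sequence[str],
    strict: bool = True,
) -> DominanceMatrix:
    """Pool aggression and submissive records into one count matrix."""
    index = {x: k for k, x in enumerate(ids)}
    wins = np.zeros((len(ids), len(ids)))
    for r in records:
        if r.dominant_id not in index or r.subordinate_id not in index:
            if strict:
                raise ValidationError(
                    f"record references id(s) outside roster: "
                    f"{r.dominant_id!r}, {r.subordinate_id!r}"
                )
            continue
        wins[index[r.dominant_id], index[r.subordinate_id]] += 1
    return DominanceMatrix(ids=list(ids), wins=wins)


# ---------------------------------------------------------------------------
# David's scores
# ---------------------------------------------------------------------------


def _dyadic_proportions(m: DominanceMatrix, variant: str) -> np.ndarray:
    w = m.wins
    nij = w + w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        pij = np.where(nij > 0, w / np.where(nij > 0, nij, 1), 0.0)
    if variant == "Dij":
        # de Vries chance correction; unknown dyads stay 0.
        dij = pij - (pij - 0.5) / (nij + 1)
        pij = np.where(nij > 0, dij, 0.0)
    elif variant != "Pij":
        raise ValueError(f"variant must be 'Pij' or 'Dij', got {variant!r}")
    np.fill_diagonal(pij, 0.0)
    return pij


def david_scores(m: DominanceMatrix, variant: str = "Dij") -> dict:
    """David's scores DS = w + w2 - l - l2 and their normalised form.

    ``w`` is the row sum of dyadic win proportions, ``w2`` weights each
    proportion by the opponent's ``w`` (and symmetrically for losses),
    so scores discount wins against weak opponents.  Unknown dyads
    contribute zero.
    """
    if m.n < 2:
        raise ValidationError("David's scores need at least 2 individuals")
    p = _dyadic_proportions(m, variant)
    w = p.sum(axis=1)
    l = p.sum(axis=0)
    w2 = p @ w
    l2 = p.T @ l
    ds = w + w2 - l - l2
    n = m.n
    norm = (ds + n * (n - 1) / 2) / n
    return {
        "ids": list(m.ids),
        "DS": ds,
        "normDS": norm,
        "variant": variant,
    }


# ---------------------------------------------------------------------------
# Steepness
# ---------------------------------------------------------------------------


@dataclass
class SteepnessResult:
    steepness: float
    p_value: float
    n_permutations: int
    dyadic_index_variant: str
    degenerate: bool = False


def _steepness_value(normds: np.ndarray) -> float:
    n = len(normds)
    ranks = np.arange(1, n + 1, dtype=float)
    y = np.sort(normds)[::-1]
    slope = np.polyfit(ranks, y, 1)[0]
    return abs(float(slope))


def _random_matrix_like(rng: np.random.Generator, nij: np.ndarray) -> np.ndarray:
    """Reallocate each dyad's outcomes uniformly, keeping its total count."""
    n = nij.shape[0]
    w = np.zeros_like(nij, dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    counts = nij[iu, ju].astype(int)
    wins_i = rng.binomial(counts, 0.5)
    w[iu, ju] = wins_i
    w[ju, iu] = counts - wins_i
    return w


def steepness_test(
    m: DominanceMatrix,
    variant: str = "Dij",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> SteepnessResult:
    """Steepness of the normDS-vs-rank line, with a right-tail
    permutation test (random dyadic outcome reallocation under the
    observed per-dyad interaction counts)."""
    if m.n < 3:
        raise ValidationError("steepness needs at least 3 individuals")
    if not m.wins.any():
        return SteepnessResult(
            steepness=float("nan"),
            p_value=float("nan"),
            n_permutations=0,
            dyadic_index_variant=variant,
            degenerate=True,
        )
    observed = _steepness_value(david_scores(m, variant)["normDS"])
    rng = np.random.default_rng(seed)
    nij = m.wins + m.wins.T
    ge = 0
    for _ in range(n_permutations):
        wperm = _random_matrix_like(rng, nij)
        perm = _steepness_value(
            david_scores(DominanceMatrix(list(m.ids), wperm), variant)["normDS"]
        )
        if perm >= observed:
            ge += 1
    p = (ge + 1) / (n_permutations + 1)
    return SteepnessResult(
        steepness=observed,
        p_value=p,
        n_permutations=n_permutations,
        dyadic_index_variant=variant,
    )


# ---------------------------------------------------------------------------
# Linearity h'
# ---------------------------------------------------------------------------


@dataclass
class LinearityResult:
    h_prime: float
    p_value: float
    n_randomizations: int
    n_unknown_dyads: int
    n_tied_dyads: int


def _landau_h(v: np.ndarray) -> float:
    n = len(v)
    return float(12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2))


def _dominance_counts(
    rng: np.random.Generator,
    known_v: np.ndarray,
    undirected: np.ndarray,
) -> np.ndarray:
    """Row dominance counts with tied/unknown dyads directed at random."""
    v = known_v.copy()
    if undirected.size:
        flips = rng.random(undirected.shape[0]) < 0.5
        v_add = np.zeros_like(v)
        winners = np.where(flips, undirected[:, 0], undirected[:, 1])
        np.add.at(v_add, winners, 1)
        v = v + v_add
    return v


def linearity_h_prime(
    m: DominanceMatrix,
    n_randomizations: int = 10000,
    seed: int | None = None,
) -> LinearityResult:
    """Improved linearity index h' with randomization p-value.

    h' is the expected Landau h after randomly directing every tied or
    unknown dyad (estimated over ``n_randomizations`` seeded draws; it
    equals plain h exactly when no dyad is tied or unknown).  The
    p-value is the right-tail probability of h' under matrices whose
    every dyad is directed at random.
    """
    if m.n < 3:
        raise ValidationError("linearity is undefined for fewer than 3 individuals")
    n = m.n
    w = m.wins
    iu, ju = np.triu_indices(n, k=1)
    wi, wj = w[iu, ju], w[ju, iu]
    unknown = (wi == 0) & (wj == 0)
    tied = (wi == wj) & ~unknown
    known_v = np.zeros(n)
    np.add.at(known_v, iu[wi > wj], 1)
    np.add.at(known_v, ju[wj > wi], 1)
    undirected = np.column_stack([iu[tied | unknown], ju[tied | unknown]])

    rng = np.random.default_rng(seed)
    if undirected.size == 0:
        h_prime = _landau_h(known_v)
    else:
        hs = [
            _landau_h(_dominance_counts(rng, known_v, undirected))
            for _ in range(n_randomizations)
        ]
        h_prime = float(np.mean(hs))

    # Null: every dyad directed uniformly at random.
    all_dyads = np.column_stack([iu, ju])
    zero_v = np.zeros(n)
    null_ge = 0
    for _ in range(n_randomizations):
        h_null = _landau_h(_dominance_counts(rng, zero_v, all_dyads))
        if h_null >= h_prime:
            null_ge += 1
    p = (null_ge + 1) / (n_randomizations + 1)
    return LinearityResult(
        h_prime=h_prime,
        p_value=p,
        n_randomizations=n_randomizations,
        n_unknown_dyads=int(unknown.sum()),
        n_tied_dyads=int(tied.sum()),
    )


# ---------------------------------------------------------------------------
# I&SI ranking
# ---------------------------------------------------------------------------


@dataclass
class RankOrder:
    ids: list[str]
    ranks: dict[str, int]
    inconsistencies: int
    strength: int


def _isi_cost(order: Sequence[int], w: np.ndarray) -> tuple[int, int]:
    """(I, SI) of an order: an inconsistency is a pair where the
    individual ranked lower holds the winning record; its strength is
    the rank distance."""
    inc = 0
    strength = 0
    n = len(order)
    for p in range(n):
        for q in range(p + 1, n):
            i, j = order[p], order[q]
            if w[j, i] > w[i, j]:
                inc += 1
                strength += q - p
    return inc, strength


def isi_ranking(
    m: DominanceMatrix,
    max_iter: int = 200,
    n_restarts: int = 20,
    seed: int | None = None,
    exact_limit: int = 8,
) -> RankOrder:
    """Ordinal ranking minimising (I, SI) lexicographically.

    Exhaustive for ``n <= exact_limit``; otherwise seeded pairwise-swap
    local search from the normDS order with random restarts.  Ties
    between optimal orders are broken by descending normDS, then id.
    """
    if m.n < 2:
        raise ValidationError("ranking needs at least 2 individuals")
    n = m.n
    w = m.wins
    norm = david_scores(m, "Dij")["normDS"]
    # tie-break key per individual: higher normDS first, then id
    base_key = {i: (-norm[i], m.ids[i]) for i in range(n)}

    def order_key(order: Sequence[int]) -> tuple:
        return tuple(base_key[i] for i in order)

    if n <= exact_limit:
        best = None
        for perm in itertools.permutations(range(n)):
            cost = _isi_cost(perm, w)
            cand = (cost, order_key(perm), perm)
            if best is None or cand < best:
                best = cand
        (inc, strength), _, order = best
    else:
        rng = np.random.default_rng(seed)
        start = sorted(range(n), key=lambda i: base_key[i])
        best_order = list(start)
        best_cost = _isi_cost(best_order, w)
        for restart in range(n_restarts):
            order = list(start)
            if restart:
                rng.shuffle(order)
            cost = _isi_cost(order, w)
            for _ in range(max_iter):
                improved = False
                for p in range(n - 1):
                    order[p], order[p + 1] = order[p + 1], order[p]
                    c2 = _isi_cost(order, w)
                    if c2 < cost:
                        cost = c2
                        improved = True
                    else:
                        order[p], order[p + 1] = order[p + 1], order[p]
                if not improved:
                    break
            if (cost, order_key(order)) < (best_cost, order_key(best_order)):
                best_cost, best_order = cost, list(order)
        order, (inc, strength) = best_order, best_cost

    ranks = {m.ids[i]: r + 1 for r, i in enumerate(order)}
    return RankOrder(
        ids=[m.ids[i] for i in order],
        ranks=ranks,
        inconsistencies=inc,
        strength=strength,
    )
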