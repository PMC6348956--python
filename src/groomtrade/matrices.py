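"""Aggregation of grooming bouts into actor-by-actor interaction matrices.

Two directed summaries are used throughout: *effort* (total seconds the row
individual groomed the column individual) and *frequency* (number of bouts
in which she groomed that partner at least once).  Directed matrices are
symmetrised by summing the two directions, binarised for partner-choice
analyses, and filtered to exclude bouts of immediately reciprocated
grooming for the across-bout reciprocity tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .obslog import GroomingBout


def _square_frame(data: pd.DataFrame) -> pd.DataFrame:
    if list(data.index) != list(data.columns):
        raise AnalysisError("matrix index and columns must list the same actors")
    return data.astype(float)


@dataclass
class DirectedInteractionMatrix:
    """Square actor x actor matrix; ``x[i, j]`` flows from row i to column j."""

    data: pd.DataFrame
    kind: str  # effort | frequency | agonism | binary

    def __post_init__(self) -> None:
        self.data = _square_frame(self.data)
        vals = self.data.to_numpy()
        if np.any(np.diag(vals) != 0):
            raise AnalysisError("diagonal of an interaction matrix must be zero")
        if np.any(vals < 0):
            raise AnalysisError("interaction counts must be non-negative")

    @property
    def actors(self) -> list[str]:
        return list(self.data.index)

    def restrict(self, actors: Sequence[str]) -> "DirectedInteractionMatrix":
        actors = [a for a in self.actors if a in set(actors)]
        return DirectedInteractionMatrix(self.data.loc[actors, actors], self.kind)

    def transpose(self) -> "DirectedInteractionMatrix":
        return DirectedInteractionMatrix(self.data.T, self.kind)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)


@dataclass
class SymmetricAffinityMatrix:
    """Undirected dyadic totals, ``w = x + x.T``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _square_frame(self.data)
        if not np.allclose(self.data.to_numpy(), self.data.to_numpy().T):
            raise AnalysisError("affinity matrix must be symmetric")

    @property
    def actors(self) -> list[str]:
        return list(self.data.index)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)


@dataclass
class DyadClassification:
    mutual: int
    unidirectional: int
    none: int

    @property
    def possible_dyads(self) -> int:
        return self.mutual + self.unidirectional + self.none

    @property
    def grooming_dyads(self) -> int:
        return self.mutual + self.unidirectional

    @property
    def percent_grooming(self) -> float:
        return round(100.0 * self.grooming_dyads / self.possible_dyads, 2)


def _empty_square(actors: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(0.0, index=list(actors), columns=list(actors))


def _actors_from_bouts(bouts: Iterable[GroomingBout]) -> list[str]:
    actors: set[str] = set()
    for b in bouts:
        actors.update(b.pair)
    return sorted(actors)


def effort_matrix(
    bouts: Sequence[GroomingBout], actors: Sequence[str] | None = None
) -> DirectedInteractionMatrix:
    """Total grooming seconds per directed pair, summed over bouts."""
    actors = list(actors) if actors is not None else _actors_from_bouts(bouts)
    df = _empty_square(actors)
    for bout in bouts:
        for (a, r), dur in bout.duration_by_direction.items():
            df.loc[a, r] += dur
    return DirectedInteractionMatrix(df, "effort")


def frequency_matrix(
    bouts: Sequence[GroomingBout], actors: Sequence[str] | None = None
) -> DirectedInteractionMatrix:
    """Bout participations per directed pair: a mutual bout counts once in each direction."""
    actors = list(actors) if actors is not None else _actors_from_bouts(bouts)
    df = _empty_square(actors)
    for bout in bouts:
        for a, r in bout.duration_by_direction:
            df.loc[a, r] += 1
    return DirectedInteractionMatrix(df, "frequency")


def symmetrize(m: DirectedInteractionMatrix) -> SymmetricAffinityMatrix:
    """Dyadic totals: grooming traded in both directions summed per pair."""
    return SymmetricAffinityMatrix(m.data + m.data.T)


def binary_partner_matrix(m: DirectedInteractionMatrix) -> DirectedInteractionMatrix:
    """Directed 0/1 partner-choice matrix: 1 iff the row individual groomed the column one."""
    return DirectedInteractionMatrix((m.data > 0).astype(float), "binary")


def classify_dyads(m: DirectedInteractionMatrix) -> DyadClassification:
    """Count mutual, unidirectional and non-grooming dyads."""
    x = m.data.to_numpy()
    n = x.shape[0]
    mutual = unidirectional = none = 0
    for i in range(n):
        for j in range(i + 1, n):
            ab, ba = x[i, j] > 0, x[j, i] > 0
            if ab and ba:
                mutual += 1
            elif ab or ba:
                unidirectional += 1
            else:
                none += 1
    return DyadClassification(mutual=mutual, unidirectional=unidirectional, none=none)


def exclude_immediate_reciprocation(
    bouts: Sequence[GroomingBout], actors: Sequence[str] | None = None
) -> tuple[DirectedInteractionMatrix, DirectedInteractionMatrix]:
    """Effort and frequency matrices built only from unreciprocated bouts.

    Whole bouts in which grooming was immediately reciprocated are dropped,
    leaving the grooming traded across bouts.
    """
    actors = list(actors) if actors is not None else _actors_from_bouts(bouts)
    kept = [b for b in bouts if not b.reciprocated]
    return effort_matrix(kept, actors), frequency_matrix(kept, actors)


def agonism_matrix(log, period_id: str | None = None) -> DirectedInteractionMatrix:
    """Directed counts of aggression, supplant and avoidance events.

    Rows are the individual displaying agonism toward the column individual:
    the actor for aggression and supplants; for an avoidance the *recipient*
    (the individual avoided) is the one displaying dominance, so the count
    is credited to her.
    """
    df_all = log.records if period_id is None else log.for_period(period_id)
    actors = sorted(log.individuals)
    df = _empty_square(actors)
    for r in df_all.itertuples():
        if r.event_type in ("aggression", "supplant"):
            df.loc[r.actor_id, r.recipient_id] += 1
        elif r.event_type == "avoidance":
            df.loc[r.recipient_id, r.actor_id] += 1
    return DirectedInteractionMatrix(df, "agonism")


def from_binary_partner_lists(
    partners: dict[str, Sequence[str]], actors: Sequence[str] | None = None
) -> DirectedInteractionMatrix:
    """Build a directed binary matrix from per-individual partner lists."""
    actors = list(actors) if actors is not None else sorted(
        set(partners) | {p for v in partners.values() for p in v}
    )
    df = _empty_square(actors)
    for groomer, groomed in partners.items():
        for p in groomed:
            df.loc[groomer, p] = 1.0
    return DirectedInteractionMatrix(df, "binary")
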