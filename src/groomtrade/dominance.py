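"""Dominance hierarchy, rank distances, and pedigree kinship.

The hierarchy is ordered by each individual's *average dominance index*
(ADI): the mean, over opponents she actually interacted with, of the
proportion of decided dyadic agonistic interactions she won.  Under a fully
consistent linear hierarchy with every dyad observed, the individual at
rank ``i`` of ``n`` has ADI ``(n - i) / (n - 1)`` exactly.

Relatedness is computed from a maternal pedigree by the recursive tabular
(numerator relationship) method; unknown parents are treated as unrelated
founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .obslog import EventLog

#: event_type -> which side is credited the win ("actor" or "recipient").
#: Supplants and aggression are won by the actor; an avoidance is recorded by
#: the retreating individual, so the recipient (the one avoided) wins;
#: submission is displayed by the loser toward the winner.
WIN_CREDIT = {
    "supplant": "actor",
    "aggression": "actor",
    "avoidance": "recipient",
    "submission": "recipient",
}


@dataclass
class WinLossMatrix:
    """wins.loc[i, j] counts decided interactions i won against j."""

    wins: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.wins.index) != list(self.wins.columns):
            raise AnalysisError("win/loss matrix must be square with matching labels")
        vals = self.wins.to_numpy()
        if np.any(np.diag(vals) != 0) or np.any(vals < 0):
            raise AnalysisError("win counts must be non-negative with a zero diagonal")

    @property
    def actors(self) -> list[str]:
        return list(self.wins.index)


@dataclass
class DominanceResult:
    """ADI per individual and the derived linear rank order (rank 1 = highest)."""

    table: pd.DataFrame  # index: individual; columns: adi, rank
    ties: list[tuple[str, str]] = field(default_factory=list)

    @property
    def individuals(self) -> list[str]:
        return list(self.table.index)

    def rank_of(self, individual: str) -> int:
        return int(self.table.loc[individual, "rank"])

    def adi_of(self, individual: str) -> float:
        return float(self.table.loc[individual, "adi"])

    @property
    def by_rank(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


def win_loss_from_log(log: EventLog, period_id: str) -> WinLossMatrix:
    """Tally decided agonistic outcomes for one period; grooming rows are ignored."""
    df = log.for_period(period_id)
    actors = sorted(log.individuals)
    wins = pd.DataFrame(0, index=actors, columns=actors)
    for r in df.itertuples():
        credit = WIN_CREDIT.get(r.event_type)
        if credit is None:
            continue
        if credit == "actor":
            wins.loc[r.actor_id, r.recipient_id] += 1
        else:
            wins.loc[r.recipient_id, r.actor_id] += 1
    return WinLossMatrix(wins)


def average_dominance_index(m: WinLossMatrix) -> DominanceResult:
    """ADI per individual, ranked descending; ties broken by total wins then label order.

    Only opponents with at least one decided interaction enter an
    individual's mean.  An individual with no decided interaction at all has
    an undefined index and is rejected (callers may exclude her first).
    """
    w = m.wins.to_numpy(dtype=float)
    total = w + w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, w / np.where(total > 0, total, 1.0), np.nan)
    np.fill_diagonal(share, np.nan)
    n_opponents = np.sum(~np.isnan(share), axis=1)
    if np.any(n_opponents == 0):
        missing = [a for a, k in zip(m.actors, n_opponents) if k == 0]
        raise AnalysisError(
            f"no decided interactions for {missing}; exclude before ranking"
        )
    adi = np.nanmean(share, axis=1)
    total_wins = w.sum(axis=1)
    order = sorted(
        range(len(adi)), key=lambda i: (-adi[i], -total_wins[i], m.actors[i])
    )
    rank = np.empty(len(adi), dtype=int)
    for pos, i in enumerate(order):
        rank[i] = pos + 1
    ties = [
        (m.actors[order[k]], m.actors[order[k + 1]])
        for k in range(len(order) - 1)
        if np.isclose(adi[order[k]], adi[order[k + 1]])
    ]
    table = pd.DataFrame({"adi": adi, "rank": rank}, index=m.actors)
    return DominanceResult(table=table, ties=ties)


def rank_distance(result: DominanceResult) -> pd.DataFrame:
    """Symmetric matrix of absolute rank differences."""
    ranks = result.table["rank"].to_numpy()
    d = np.abs(ranks[:, None] - ranks[None, :])
    return pd.DataFrame(d, index=result.individuals, columns=result.individuals)


def kinship_from_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Coefficients of relatedness from a parent table.

    ``pedigree`` needs columns ``id``, ``mother_id``, ``father_id`` (empty or
    NaN for unknown).  The numerator relationship matrix A is built
    recursively:

        A[i, i] = 1 + 0.5 * A[sire_i, dam_i]
        A[i, j] = 0.5 * (A[j, sire_i] + A[j, dam_i])   (j older than i)

    so mother x daughter and full-sister dyads come out at 0.5,
    grandmother x granddaughter and aunt x niece at 0.25, and
    cousins-who-are-also-paternal-half-sibs at 0.375.  The diagonal is
    returned as NaN since self-relatedness is excluded from all analyses.
    """
    ped = pedigree.copy()
    ped["id"] = ped["id"].astype(str)
    ids = list(ped["id"])
    if len(set(ids)) != len(ids):
        raise AnalysisError("duplicate ids in pedigree")
    parents: dict[str, tuple[str | None, str | None]] = {}
    for r in ped.itertuples():
        mother = None if pd.isna(r.mother_id) or r.mother_id == "" else str(r.mother_id)
        father = None if pd.isna(r.father_id) or r.father_id == "" else str(r.father_id)
        parents[str(r.id)] = (mother, father)
    for child, (mo, fa) in list(parents.items()):
        for p in (mo, fa):
            if p is not None and p not in parents:
                parents[p] = (None, None)  # implicit founder

    order = _topological_order(parents)
    idx = {v: k for k, v in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for i, ind in enumerate(order):
        mo, fa = parents[ind]
        mi = idx[mo] if mo is not None else None
        fi = idx[fa] if fa is not None else None
        f_par = a[mi, fi] if (mi is not None and fi is not None) else 0.0
        a[i, i] = 1.0 + 0.5 * f_par
        for j in range(i):
            contrib = 0.0
            if mi is not None:
                contrib += 0.5 * a[j, mi]
            if fi is not None:
                contrib += 0.5 * a[j, fi]
            a[i, j] = a[j, i] = contrib
    out = pd.DataFrame(a, index=order, columns=order).loc[ids, ids]
    np.fill_diagonal(out.values, np.nan)
    return out


def _topological_order(parents: dict[str, tuple[str | None, str | None]]) -> list[str]:
    order: list[str] = []
    state: dict[str, int] = {}  # 0 in progress, 1 done

    def visit(node: str, stack: list[str]) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            raise AnalysisError(f"cycle in pedigree involving {node!r}")
        state[node] = 0
        for p in parents[node]:
            if p is not None:
                visit(p, stack + [node])
        state[node] = 1
        order.append(node)

    for node in sorted(parents):
        visit(node, [])
    return order
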