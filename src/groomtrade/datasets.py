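"""Bundled example data: a captive matrilineal mandrill group, two periods.

The published descriptive tables of a zoo-housed matriline of female
mandrills observed in two separate periods provide a convenient desk-scale
fixture: directed grooming partner lists for every female (who groomed
whom), the linear dominance rank order of each period, and the pedigree.
From the partner lists alone the binary directed networks — and hence
degree, reach and betweenness centralities, and dyad accounting — can be
reconstructed exactly; grooming durations are not bundled, so weighted
quantities (eigenvector centrality, modularity values) need the raw logs.

Period one covers six mature females; in period two a seventh female
(Tania) had matured into the hierarchy and the lowest-ranking female
(Nefertari) had been excluded from all grooming.
"""

from __future__ import annotations

import pandas as pd

from .dominance import DominanceResult
from .matrices import DirectedInteractionMatrix, from_binary_partner_lists

#: Directed partner lists: groomer -> tuple of females she groomed.
PERIOD_ONE_PARTNERS: dict[str, tuple[str, ...]] = {
    "Camila": ("Lisala", "Limbe"),
    "Lisala": ("Camila", "Limbe", "Lolaya"),
    "Limbe": ("Camila", "Lisala"),
    "Lolaya": ("Lisala", "Mirinda", "Nefertari"),
    "Mirinda": ("Lolaya", "Nefertari"),
    "Nefertari": ("Mirinda",),
}

PERIOD_TWO_PARTNERS: dict[str, tuple[str, ...]] = {
    "Camila": ("Tania", "Lisala", "Limbe"),
    "Tania": ("Camila", "Lisala", "Lolaya"),
    "Lisala": ("Camila", "Tania", "Lolaya"),
    "Limbe": ("Camila", "Tania", "Lisala"),
    "Lolaya": ("Lisala", "Tania"),
    "Mirinda": ("Camila",),
    "Nefertari": (),
}

#: Dominance rank order per period, highest first.
PERIOD_ONE_RANKS: tuple[str, ...] = (
    "Camila", "Lisala", "Limbe", "Lolaya", "Mirinda", "Nefertari",
)
PERIOD_TWO_RANKS: tuple[str, ...] = (
    "Camila", "Tania", "Lisala", "Limbe", "Mirinda", "Lolaya", "Nefertari",
)

#: Maternal pedigree of the matriline (fathers unrecorded).  Camila heads
#: the high-ranking branch, Mirinda the low-ranking one; both descend from
#: the (unobserved) founder of the matriline.
PEDIGREE_ROWS: tuple[tuple[str, str, str], ...] = (
    ("Mirinda", "", ""),
    ("Nefertari", "Mirinda", ""),
    ("Camila", "", ""),
    ("Limbe", "Camila", ""),
    ("Lisala", "Camila", ""),
    ("Lolaya", "Nefertari", ""),
    ("Tania", "Camila", ""),
)


def partner_matrix(period: str) -> DirectedInteractionMatrix:
    """Directed binary partner-choice matrix for ``period`` ("one" or "two")."""
    if period == "one":
        return from_binary_partner_lists(PERIOD_ONE_PARTNERS, sorted(PERIOD_ONE_PARTNERS))
    if period == "two":
        return from_binary_partner_lists(PERIOD_TWO_PARTNERS, sorted(PERIOD_TWO_PARTNERS))
    raise ValueError(f"unknown period {period!r}")


def rank_table(period: str) -> DominanceResult:
    """Dominance order for ``period`` as a DominanceResult.

    The bundled tables publish the rank order; the indices attached here are
    the closed-form values of a fully consistent hierarchy, (n - i)/(n - 1),
    sufficient for every rank-based analysis.
    """
    order = PERIOD_ONE_RANKS if period == "one" else PERIOD_TWO_RANKS
    if period not in ("one", "two"):
        raise ValueError(f"unknown period {period!r}")
    n = len(order)
    table = pd.DataFrame(
        {
            "adi": [(n - r) / (n - 1) for r in range(1, n + 1)],
            "rank": list(range(1, n + 1)),
        },
        index=list(order),
    ).sort_index()
    return DominanceResult(table=table)


def pedigree() -> pd.DataFrame:
    return pd.DataFrame(PEDIGREE_ROWS, columns=["id", "mother_id", "father_id"])
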