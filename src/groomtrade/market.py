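"""Biological-markets statistics for grooming trade.

Covers the battery of partner-choice and trade analyses: the standardised
Shannon-Weaver diversity of grooming partners (H'), the dyadic grooming
reciprocity index (gRI), the weighted log-log within-bout reciprocity
regression, the grooming-up-the-hierarchy test, the received/given ratio
against rank, grooming-for-tolerance and gRI-versus-rank-distance matrix
correlations, and cross-period partner-choice stability.

Key definitions:

    H'  = -sum_i p_i ln p_i / ln(n - 1)

with ``p_i`` the proportion of a groomer's grooming frequency directed to
partner i and ``n`` the number of mature females; H' is 0 for a single
partner and 1 for grooming spread uniformly over all n - 1 partners.

    gRI = 1 - | gAB/(gAB + gBA) - gBA/(gAB + gBA) |

with gAB the seconds A groomed B: 1 is a perfectly balanced partnership,
0 a unidirectional one; dyads that never groomed are undefined (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata, spearmanr, wilcoxon

from .dominance import DominanceResult
from .errors import AnalysisError
from .matrices import DirectedInteractionMatrix
from .obslog import GroomingBout
from .taukr import TauKrResult, tau_kr_test

#: Familywise-adjusted alpha when the reciprocity tests are run on both the
#: full data and the reciprocation-excluded data (two tests per hypothesis).
RECIPROCITY_FAMILY_ALPHA = 0.025


@dataclass
class DiversityResult:
    table: pd.DataFrame  # index: groomer; columns: h_prime, n_partners
    proportions: dict[str, pd.Series]
    n_females: int

    def h_prime(self, groomer: str) -> float:
        return float(self.table.loc[groomer, "h_prime"])


def grooming_diversity(
    freq: DirectedInteractionMatrix, n_females: int | None = None
) -> DiversityResult:
    """Standardised Shannon-Weaver partner diversity per groomer.

    ``n_females`` defaults to the matrix size; a groomer with zero given
    grooming, or exactly one partner, scores 0.
    """
    df = freq.data
    n = int(n_females) if n_females is not None else len(df.index)
    if n < 3:
        raise AnalysisError("H' needs at least 3 mature females")
    log_denom = math.log(n - 1)
    rows = []
    props: dict[str, pd.Series] = {}
    for groomer in df.index:
        out = df.loc[groomer].drop(groomer)
        given = out[out > 0]
        if given.sum() == 0:
            h = 0.0
            props[groomer] = given
        else:
            p = given / given.sum()
            props[groomer] = p
            h = float(-(p * np.log(p)).sum() / log_denom)
            if h == 0.0:
                h = 0.0  # normalise -0.0
        rows.append({"groomer": groomer, "h_prime": h, "n_partners": int((out > 0).sum())})
    table = pd.DataFrame(rows).set_index("groomer")
    return DiversityResult(table=table, proportions=props, n_females=n)


def gri(effort: DirectedInteractionMatrix) -> pd.DataFrame:
    """Symmetric grooming reciprocity index per dyad; NaN where no grooming traded."""
    x = effort.data.to_numpy()
    total = x + x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, x / np.where(total > 0, total, 1.0), np.nan)
    g = 1.0 - np.abs(share - share.T)
    g[total == 0] = np.nan
    np.fill_diagonal(g, np.nan)
    return pd.DataFrame(g, index=effort.actors, columns=effort.actors)


@dataclass
class WlsResult:
    slope: float
    intercept: float
    f_stat: float
    df: tuple[int, int]
    s2: float
    p: float
    weights: pd.Series = field(repr=False)
    degenerate: bool = False


def within_bout_regression(bouts: Sequence[GroomingBout]) -> WlsResult:
    """Weighted log-log regression of reciprocated on initial grooming within bouts.

    Only bouts where grooming was immediately reciprocated enter.  The
    response is ln(seconds the Reciprocator groomed the Groomer), the
    predictor ln(seconds the Groomer groomed the Reciprocator), and each
    bout is weighted by the inverse of its dyad's reciprocated-bout count so
    every dyad contributes equally in total.
    """
    recip = [b for b in bouts if b.reciprocated]
    if len(recip) < 3:
        raise AnalysisError("fewer than 3 reciprocated bouts: regression undefined")
    per_dyad: dict[tuple[str, str], int] = {}
    for b in recip:
        per_dyad[b.pair] = per_dyad.get(b.pair, 0) + 1
    x = np.array([math.log(b.duration(b.groomer_id, b.reciprocator_id)) for b in recip])
    y = np.array([math.log(b.duration(b.reciprocator_id, b.groomer_id)) for b in recip])
    w = np.array([1.0 / per_dyad[b.pair] for b in recip])
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    s2 = float(model.scale)
    degenerate = not np.isfinite(model.fvalue) or s2 < 1e-12
    return WlsResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        f_stat=float(model.fvalue) if np.isfinite(model.fvalue) else float("inf"),
        df=(1, len(recip) - 2),
        s2=s2,
        p=float(model.f_pvalue) if not degenerate else float("nan"),
        weights=pd.Series(w, index=[f"{b.pair[0]}|{b.pair[1]}" for b in recip]),
        degenerate=degenerate,
    )


@dataclass
class UpHierarchyResult:
    table: pd.DataFrame  # per female x measure: observed, expected, difference
    percent_up: dict[str, float]
    wilcoxon_w: dict[str, float]
    wilcoxon_p: dict[str, float]
    n_nonzero: dict[str, int]
    excluded: list[str] = field(default_factory=list)


def _signed_rank(diff: np.ndarray) -> tuple[float, float, int]:
    """W+ (sum of positive-difference ranks) and exact two-sided p; zeros dropped."""
    d = diff[diff != 0]
    if len(d) == 0:
        return 0.0, 1.0, 0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    try:
        res = wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
        p = float(res.pvalue)
    except ValueError:
        res = wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="approx")
        p = float(res.pvalue)
    return w_plus, p, len(d)


def up_hierarchy_test(
    effort: DirectedInteractionMatrix,
    freq: DirectedInteractionMatrix,
    dom: DominanceResult,
    exclude: Sequence[str] = (),
) -> UpHierarchyResult:
    """Observed versus expected grooming directed up the dominance hierarchy.

    For each female the expected up-hierarchy grooming is her total given
    grooming times the proportion of females ranked above her; the observed
    value is her grooming to strictly higher-ranking partners.  The
    observed-minus-expected differences are tested against zero with an
    exact Wilcoxon signed-rank test (zero differences dropped), separately
    for effort and frequency.  ``exclude`` removes named individuals (and
    all their grooming) before the computation, compressing ranks.
    """
    excluded = [e for e in exclude if e in effort.actors]
    keep = [a for a in effort.actors if a not in set(excluded)]
    if len(keep) < 4:
        raise AnalysisError("up-hierarchy test needs at least 4 females")
    ranks = dom.table.loc[keep, "rank"].rank(method="dense")
    matrices = {"effort": effort.restrict(keep), "freq": freq.restrict(keep)}
    n = len(keep)
    rows = []
    percent_up: dict[str, float] = {}
    ww: dict[str, float] = {}
    wp: dict[str, float] = {}
    nn: dict[str, int] = {}
    for measure, m in matrices.items():
        x = m.data
        observed = {}
        expected = {}
        for female in keep:
            above = [o for o in keep if ranks[o] < ranks[female]]
            observed[female] = float(x.loc[female, above].sum())
            total = float(x.loc[female].sum())
            expected[female] = total * len(above) / (n - 1)
        total_groom = float(x.to_numpy().sum())
        percent_up[measure] = (
            round(100.0 * sum(observed.values()) / total_groom, 2) if total_groom else float("nan")
        )
        diff = np.array([observed[f] - expected[f] for f in keep])
        w_plus, p, n_nonzero = _signed_rank(diff)
        ww[measure], wp[measure], nn[measure] = w_plus, p, n_nonzero
        for f in keep:
            rows.append(
                {
                    "female": f, "measure": measure,
                    "observed_up": observed[f], "expected_up": expected[f],
                    "difference": observed[f] - expected[f],
                }
            )
    table = pd.DataFrame(rows).set_index(["female", "measure"])
    return UpHierarchyResult(
        table=table, percent_up=percent_up,
        wilcoxon_w=ww, wilcoxon_p=wp, n_nonzero=nn, excluded=excluded,
    )


@dataclass
class RatioRankResult:
    ratios: pd.Series
    rho: float
    p: float
    n: int
    excluded: list[str]
    tied: bool = False


def received_given_vs_rank(
    effort: DirectedInteractionMatrix,
    dom: DominanceResult,
    zero_convention: str = "exclude",
) -> RatioRankResult:
    """Spearman correlation of the received/given grooming ratio with rank.

    The ratio GR/GG is computed per female; rank is inverted internally so a
    positive rho means higher-ranking females receive relatively more.  A
    female who neither gave nor received grooming has an undefined ratio:
    ``zero_convention="exclude"`` drops her (logged in ``excluded``) while
    ``"zero"`` scores her 0, keeping the full sample.  A female who received
    but never gave gets an infinite ratio, which is safe under ranking.
    """
    if zero_convention not in {"exclude", "zero"}:
        raise ValueError(f"unknown zero_convention {zero_convention!r}")
    x = effort.data
    given = x.sum(axis=1)
    received = x.sum(axis=0)
    ratios = {}
    excluded = []
    for f in effort.actors:
        if given[f] == 0 and received[f] == 0:
            if zero_convention == "exclude":
                excluded.append(f)
            else:
                ratios[f] = 0.0
        elif given[f] == 0:
            ratios[f] = float("inf")
        else:
            ratios[f] = float(received[f] / given[f])
    if not ratios:
        raise AnalysisError("every ratio is undefined")
    series = pd.Series(ratios)
    inv_rank = (len(dom.individuals) + 1) - dom.table.loc[series.index, "rank"].astype(float)
    tied = series.nunique() <= 1
    if tied:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = spearmanr(series, inv_rank)
    return RatioRankResult(
        ratios=series, rho=float(rho), p=float(p), n=len(series),
        excluded=excluded, tied=tied,
    )


def reciprocity_vs_rank_distance(
    g: pd.DataFrame, d: pd.DataFrame, n_perm: int = 10_000, seed: int | None = None
) -> TauKrResult:
    """tau-Kr between dyadic gRI and rank distance (undefined dyads excluded pairwise)."""
    offdiag = ~np.eye(len(g.index), dtype=bool)
    defined_per_row = (~g.isna().to_numpy() & offdiag).sum(axis=1)
    if defined_per_row.max() < 3:
        raise AnalysisError("too few defined gRI cells for a rowwise correlation")
    return tau_kr_test(g, d, n_perm=n_perm, seed=seed)


def tolerance_correlation(
    groom: DirectedInteractionMatrix,
    agonism: DirectedInteractionMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TauKrResult:
    """tau-Kr between directed grooming effort and directed agonism counts.

    A negative, significant statistic indicates that dyads who groom more
    display less aggression / supplanting / avoidance toward each other,
    i.e. grooming is associated with social tolerance.
    """
    common = [a for a in groom.actors if a in set(agonism.actors)]
    return tau_kr_test(
        groom.restrict(common).data, agonism.restrict(common).data,
        n_perm=n_perm, seed=seed,
    )


def partner_choice_stability(
    b1: DirectedInteractionMatrix,
    b2: DirectedInteractionMatrix,
    common: Sequence[str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TauKrResult:
    """Cross-period tau-Kr between binary partner-choice matrices.

    Both matrices are restricted to the individuals present in both periods
    before correlating, so the test asks whether pre-existing partnerships
    were maintained.
    """
    common = [c for c in b1.actors if c in set(common) and c in set(b2.actors)]
    if len(common) < 3:
        raise AnalysisError("need at least 3 common individuals across periods")
    return tau_kr_test(
        b1.restrict(common).data, b2.restrict(common).data, n_perm=n_perm, seed=seed
    )


def reciprocity_family(
    bouts: Sequence[GroomingBout],
    actors: Sequence[str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict[str, dict]:
    """Given-vs-received reciprocity on full and reciprocation-excluded data.

    Runs the tau-Kr reciprocity test for grooming effort and frequency, on
    the full bout set and again with immediately reciprocated bouts
    excluded.  Because each hypothesis is tested twice, every result carries
    the familywise-adjusted alpha of 0.025.
    """
    from .matrices import effort_matrix, exclude_immediate_reciprocation, frequency_matrix
    from .taukr import reciprocity_test

    eff = effort_matrix(bouts, actors)
    freq = frequency_matrix(bouts, actors)
    eff_x, freq_x = exclude_immediate_reciprocation(bouts, actors)
    out = {}
    for name, m in {
        "effort_full": eff, "frequency_full": freq,
        "effort_excluded": eff_x, "frequency_excluded": freq_x,
    }.items():
        res = reciprocity_test(m, n_perm=n_perm, seed=seed)
        out[name] = {"result": res, "alpha_adjusted": RECIPROCITY_FAMILY_ALPHA}
    return out
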