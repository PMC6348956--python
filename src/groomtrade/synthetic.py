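"""Seeded generator of focal-observation event logs for a matrilineal group.

The generator emulates the statistical structure the downstream analyses
assume in a small captive matriline of female primates: a near-linear
dominance hierarchy (a configurable probability ``c`` that the higher-ranked
female wins any agonistic interaction), concentrated grooming preferences
(each female grooms ``k`` preferred partners), a tunable up-hierarchy
grooming bias, tunable within-bout reciprocity, a negative grooming-agonism
coupling (tolerance), and an optional mother-with-dependent-infant effect
under which other females direct extra unreciprocated grooming at the
mother.

Events are laid down on a continuous clock and sliced into fixed-length
focal samples rotating round-robin across individuals, emulating partial
observability under focal sampling: a grooming bout is kept iff one of its
participants is the focal individual of the sample in which the bout
starts (the observer follows an ongoing interaction to its end), and a
point agonistic event is kept iff a participant is focal when it occurs.
Each
(period, dyad) pair draws from its own deterministically derived random
stream, so adding a dyad never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigError
from .obslog import EventLog, build_event_log

#: Minimum spacing (s) enforced between generated bouts of one dyad so that
#: segmentation at the 30 s criterion recovers them unambiguously.
_BOUT_SPACING_S = 35.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model; defaults emulate the study group.

    Rates are per *clock* hour (the continuous timeline later sliced into
    focal samples); with ``n`` females only ``2/n`` of dyadic events fall in
    a sample of one of their participants, so observed counts are roughly
    ``2/n`` of the generated ones.
    """

    n_females: int = 7
    obs_hours_per_female: float = 16.0
    sample_length_min: float = 15.0
    latent_ranks: tuple[str, ...] | None = None  # highest first; None -> seeded shuffle
    hierarchy_consistency: float = 0.95  # P(higher-ranked wins)
    preference_partners: int = 2
    preference_concentration: float = 1.0  # Dirichlet concentration across partners
    up_bias: float = 0.5  # multiplier exp(up_bias) on higher-ranked recipients
    within_bout_recip: float = 0.1  # P(bout immediately reciprocated)
    recip_balance: float = 0.7  # expected reciprocated/initial duration ratio
    recip_noise_sigma: float = 0.2
    agonism_base: float = 1.0  # agonistic events per clock hour per dyad
    tolerance_coupling: float = 1.0  # rate decay per unit grooming affinity
    infant_mother: str | None = None
    infant_groom_rate: float = 0.3  # extra bouts/h toward the mother, per other female
    bout_rate_per_h: float = 1.0  # grooming bout initiations per female per clock hour
    episode_dur_lognormal: tuple[float, float] = (3.5, 0.8)  # (mu, sigma) of ln-seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 3:
            raise ConfigError("need at least 3 females")
        if not 1 <= self.preference_partners < self.n_females:
            raise ConfigError("preference_partners must be in 1..n_females-1")
        if not 0.5 <= self.hierarchy_consistency <= 1.0:
            raise ConfigError("hierarchy_consistency must be in [0.5, 1]")
        if not 0.0 <= self.within_bout_recip <= 1.0:
            raise ConfigError("within_bout_recip must be in [0, 1]")
        for name in ("up_bias", "agonism_base", "tolerance_coupling",
                     "infant_groom_rate", "bout_rate_per_h", "recip_balance",
                     "obs_hours_per_female"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class DemographicChange:
    kind: Literal["add_maturing_female", "withdraw_individual", "infant_independence"]
    target: str | None = None
    rank: int | None = None  # for add_maturing_female


@dataclass
class GroupState:
    """Latent state of the simulated group."""

    individuals: tuple[str, ...]  # stable label order (round-robin order)
    ranks: dict[str, int]  # 1 = highest
    pedigree: pd.DataFrame  # id, mother_id, father_id
    preference: pd.DataFrame  # row-stochastic grooming preference over partners
    infant_mother: str | None = None
    withdrawn: set[str] = field(default_factory=set)
    seed: int = 0

    @property
    def by_rank(self) -> list[str]:
        return sorted(self.ranks, key=self.ranks.get)


def _stream(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-context RNG; string keys are hashed stably."""
    ints = [seed & 0x7FFFFFFF]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(ints))


def generate_group(config: SyntheticConfig) -> GroupState:
    """Draw the latent group: ranks, one-matriline pedigree, preference weights."""
    n = config.n_females
    rng = _stream(config.seed, "group")
    if config.latent_ranks is not None:
        individuals = tuple(config.latent_ranks)
        if len(set(individuals)) != n:
            raise ConfigError("latent_ranks must be a permutation of n_females labels")
        ranks = {ind: r + 1 for r, ind in enumerate(individuals)}
        individuals = tuple(sorted(individuals))
    else:
        individuals = tuple(f"F{i + 1}" for i in range(n))
        order = rng.permutation(n)
        ranks = {individuals[i]: int(r + 1) for r, i in enumerate(order)}

    # One matriline: every female descends from the first-listed founder.
    # All births of one generation share a founder sire, which reproduces the
    # field's kinship classes (0.5 full sisters, 0.375 cousin-siblings, 0.25
    # grandmother/granddaughter and aunt/niece).
    age_order = [individuals[0], *(individuals[i] for i in rng.permutation(np.arange(1, n)))]
    generation = {age_order[0]: 0}
    mothers: dict[str, str | None] = {age_order[0]: None}
    for child in age_order[1:]:
        mother = age_order[: age_order.index(child)][int(rng.integers(0, age_order.index(child)))]
        mothers[child] = mother
        generation[child] = generation[mother] + 1
    rows = []
    for ind in individuals:
        mo = mothers[ind]
        fa = f"M{generation[ind]}" if mo is not None else ""
        rows.append({"id": ind, "mother_id": mo or "", "father_id": fa})
    pedigree = pd.DataFrame(rows)

    pref = pd.DataFrame(0.0, index=list(individuals), columns=list(individuals))
    for ind in individuals:
        others = [o for o in individuals if o != ind]
        chosen = rng.choice(others, size=config.preference_partners, replace=False)
        weights = rng.dirichlet(
            np.full(config.preference_partners, config.preference_concentration)
        )
        for partner, wgt in zip(chosen, weights):
            pref.loc[ind, partner] = float(wgt)
    return GroupState(
        individuals=individuals, ranks=ranks, pedigree=pedigree,
        preference=pref, infant_mother=config.infant_mother, seed=config.seed,
    )


def apply_change(group: GroupState, change: DemographicChange) -> GroupState:
    """Return a new group state with one demographic change applied."""
    if change.kind == "add_maturing_female":
        label = change.target or f"F{len(group.individuals) + 1}"
        if label in group.individuals:
            raise ConfigError(f"{label!r} already present")
        at = change.rank if change.rank is not None else len(group.individuals) + 1
        ranks = {
            ind: (r + 1 if r >= at else r) for ind, r in group.ranks.items()
        }
        ranks[label] = at
        rng = _stream(group.seed, "maturation", label)
        individuals = tuple([*group.individuals, label])
        pref = group.preference.reindex(index=list(individuals), columns=list(individuals), fill_value=0.0)
        k = max(1, int((pref.loc[list(group.individuals)] > 0).sum(axis=1).median()))
        chosen = rng.choice([o for o in group.individuals], size=k, replace=False)
        weights = rng.dirichlet(np.full(k, 1.0))
        for partner, wgt in zip(chosen, weights):
            pref.loc[label, partner] = float(wgt)
        mother = group.individuals[int(rng.integers(0, len(group.individuals)))]
        gen_guess = 1
        pedigree = pd.concat(
            [group.pedigree,
             pd.DataFrame([{"id": label, "mother_id": mother, "father_id": f"M{gen_guess}"}])],
            ignore_index=True,
        )
        return GroupState(
            individuals=individuals, ranks=ranks, pedigree=pedigree, preference=pref,
            infant_mother=group.infant_mother, withdrawn=set(group.withdrawn),
            seed=group.seed,
        )
    if change.kind == "withdraw_individual":
        if change.target not in group.individuals:
            raise ConfigError(f"unknown individual {change.target!r}")
        withdrawn = set(group.withdrawn) | {change.target}
        return replace(group, withdrawn=withdrawn)
    if change.kind == "infant_independence":
        if group.infant_mother is None:
            raise ConfigError("no dependent infant to mature")
        if change.target is not None and change.target != group.infant_mother:
            raise ConfigError(f"unknown target {change.target!r}")
        return replace(group, infant_mother=None)
    raise ConfigError(f"unknown change kind {change.kind!r}")


def _grooming_rates(group: GroupState, config: SyntheticConfig) -> pd.DataFrame:
    """Per-directed-pair bout initiation rates (events per clock hour)."""
    inds = list(group.individuals)
    pref = group.preference.loc[inds, inds].to_numpy().copy()
    ranks = np.array([group.ranks[i] for i in inds])
    up = (ranks[None, :] < ranks[:, None]).astype(float)  # recipient higher-ranked
    raw = pref * np.exp(config.up_bias * up)
    row_sum = raw.sum(axis=1, keepdims=True)
    lam = np.where(row_sum > 0, raw / np.where(row_sum > 0, row_sum, 1.0), 0.0)
    lam *= config.bout_rate_per_h
    for w in group.withdrawn:
        i = inds.index(w)
        lam[i, :] = 0.0
        lam[:, i] = 0.0
    return pd.DataFrame(lam, index=inds, columns=inds)


def simulate_period(
    group: GroupState,
    config: SyntheticConfig,
    period_id: str,
    return_ledger: bool = False,
) -> EventLog | tuple[EventLog, pd.DataFrame]:
    """Simulate one observation period and return the resulting event log.

    With ``return_ledger=True`` a per-directed-pair ground-truth tally of
    the grooming seconds and episode counts actually written to the log is
    returned alongside, accumulated independently of any downstream
    aggregation (for oracle tests).
    """
    inds = list(group.individuals)
    n = len(inds)
    sample_len = config.sample_length_min * 60.0
    total_s = config.obs_hours_per_female * 3600.0 * n
    lam = _grooming_rates(group, config).to_numpy()
    idx = {ind: i for i, ind in enumerate(inds)}
    ranks = np.array([group.ranks[i] for i in inds])
    pcrc = zlib.crc32(str(period_id).encode())

    def focal_of(t: float) -> tuple[str, float]:
        s = int(t // sample_len)
        return inds[s % n], s * sample_len

    records: list[dict] = []
    ledger: dict[tuple[str, str], dict[str, float]] = {}

    def log_grooming(
        actor: str, recipient: str, start: float, dur: float,
        focal: str, sample_start: float,
    ) -> None:
        # observability is decided per bout (the observer follows an ongoing
        # interaction to its end), so focal/sample come from the bout start
        records.append(
            {
                "period_id": period_id, "focal_id": focal,
                "sample_start_s": sample_start, "event_type": "grooming",
                "actor_id": actor, "recipient_id": recipient,
                "start_s": round(start, 3), "duration_s": round(dur, 3),
            }
        )
        acc = ledger.setdefault((actor, recipient), {"seconds": 0.0, "episodes": 0})
        acc["seconds"] += round(dur, 3)
        acc["episodes"] += 1

    # --- grooming, one stream per unordered pair -------------------------
    for a in range(n):
        for b in range(a + 1, n):
            rng = _stream(config.seed, pcrc, a, b, "groom")
            initiations: list[tuple[float, int, int, bool]] = []
            for i, j in ((a, b), (b, a)):
                rate = lam[i, j] / 3600.0
                extra = 0.0
                if (
                    group.infant_mother is not None
                    and inds[j] == group.infant_mother
                    and inds[i] not in group.withdrawn
                    and inds[j] not in group.withdrawn
                ):
                    extra = config.infant_groom_rate / 3600.0
                for stream_rate, infant_flag in ((rate, False), (extra, True)):
                    if stream_rate <= 0:
                        continue
                    count = rng.poisson(stream_rate * total_s)
                    times = np.sort(rng.uniform(0.0, total_s, size=count))
                    initiations.extend((float(t), i, j, infant_flag) for t in times)
            initiations.sort()
            last_end = -np.inf
            for t, i, j, infant_flag in initiations:
                if t < last_end + _BOUT_SPACING_S:
                    continue  # drop colliding initiation: keeps bouts separable
                mu, sigma = config.episode_dur_lognormal
                d1 = float(rng.lognormal(mu, sigma))
                end = t + d1
                reciprocate = (
                    not infant_flag
                    and inds[j] not in group.withdrawn
                    and rng.random() < config.within_bout_recip
                )
                d2 = gap = 0.0
                if reciprocate:
                    gap = float(rng.uniform(1.0, 25.0))
                    noise = float(rng.lognormal(0.0, config.recip_noise_sigma)) \
                        if config.recip_noise_sigma > 0 else 1.0
                    d2 = d1 * config.recip_balance * noise
                    end = end + gap + d2
                last_end = end
                focal, sample_start = focal_of(t)
                if focal not in (inds[i], inds[j]):
                    continue  # bout falls outside its participants' focal samples
                log_grooming(inds[i], inds[j], t, d1, focal, sample_start)
                if reciprocate:
                    log_grooming(inds[j], inds[i], t + d1 + gap, d2, focal, sample_start)

    # --- agonism, one stream per unordered dyad --------------------------
    pair_aff = group.preference.to_numpy() + group.preference.to_numpy().T
    max_aff = pair_aff.max() if pair_aff.max() > 0 else 1.0
    for a in range(n):
        for b in range(a + 1, n):
            rng = _stream(config.seed, pcrc, a, b, "agonism")
            affinity = pair_aff[a, b] / max_aff
            rate = config.agonism_base * np.exp(-config.tolerance_coupling * affinity) / 3600.0
            count = rng.poisson(rate * total_s)
            times = np.sort(rng.uniform(0.0, total_s, size=count))
            hi, lo = (a, b) if ranks[a] < ranks[b] else (b, a)
            for t in times:
                winner, loser = (hi, lo) if rng.random() < config.hierarchy_consistency else (lo, hi)
                as_supplant = rng.random() < 0.5
                if as_supplant:
                    actor, recipient, etype = inds[winner], inds[loser], "supplant"
                else:
                    actor, recipient, etype = inds[loser], inds[winner], "avoidance"
                focal, sample_start = focal_of(float(t))
                if focal not in (actor, recipient):
                    continue
                records.append(
                    {
                        "period_id": period_id, "focal_id": focal,
                        "sample_start_s": sample_start, "event_type": etype,
                        "actor_id": actor, "recipient_id": recipient,
                        "start_s": round(float(t), 3), "duration_s": 0.0,
                    }
                )

    columns = ["period_id", "focal_id", "sample_start_s", "event_type",
               "actor_id", "recipient_id", "start_s", "duration_s"]
    df = pd.DataFrame(records, columns=columns)
    log = build_event_log(df, sample_length_s=sample_len)
    if not return_ledger:
        return log
    led = pd.DataFrame(
        [
            {"actor_id": a_, "recipient_id": r_, **acc}
            for (a_, r_), acc in sorted(ledger.items())
        ],
        columns=["actor_id", "recipient_id", "seconds", "episodes"],
    )
    return log, led
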