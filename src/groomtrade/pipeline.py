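"""Orchestration of the full grooming-market analysis.

The pipeline runs four stages per observation period — event log (read or
simulated), dominance hierarchy, grooming network, market statistics — and
a cross-period comparison, collecting everything into one JSON-serialisable
report.  Every stochastic test records its seed and permutation count, and
every familywise-corrected test carries its adjusted alpha, so any single
number in the report can be recomputed in isolation.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import dominance as dom_mod
from . import market, matrices, network, obslog, synthetic, taukr
from .errors import AnalysisError, ConfigError

DEFAULT_N_PERM = 10_000


def _subseed(seed: int, *keys) -> int:
    h = seed & 0x7FFFFFFF
    for k in keys:
        h = zlib.crc32(str(k).encode(), h) & 0x7FFFFFFF
    return h


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, taukr.TauKrResult):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return {str(k): _jsonable(v) for k, v in obj.to_dict(orient="index").items()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.to_dict().items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return [_jsonable(v) for v in sorted(obj, key=str)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def analyze_period(
    log: obslog.EventLog,
    period_id: str,
    pedigree: pd.DataFrame | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    exclude: Sequence[str] = (),
    gap_s: float = 30.0,
) -> dict:
    """Run dominance, network and market stages for one period."""
    bouts = [b for b in obslog.segment_bouts(log, gap_s=gap_s) if b.period_id == period_id]
    actors = sorted(log.individuals)

    # --- dominance -------------------------------------------------------
    wl = dom_mod.win_loss_from_log(log, period_id)
    dom = dom_mod.average_dominance_index(wl)
    rdist = dom_mod.rank_distance(dom)
    kinship = dom_mod.kinship_from_pedigree(pedigree) if pedigree is not None else None

    # --- matrices --------------------------------------------------------
    effort = matrices.effort_matrix(bouts, actors)
    freq = matrices.frequency_matrix(bouts, actors)
    sym = matrices.symmetrize(effort)
    binary = matrices.binary_partner_matrix(effort)
    dyads = matrices.classify_dyads(effort)
    agonism = matrices.agonism_matrix(log, period_id)

    # --- network ---------------------------------------------------------
    cent = network.centrality_table(sym)
    try:
        partition = network.modularity_partition(sym)
        partition_out = {
            "clusters": [sorted(c) for c in partition.clusters],
            "q": partition.q,
            "has_structure": partition.has_structure,
            "excluded": sorted(partition.excluded),
        }
        n_clusters = partition.n_clusters
    except AnalysisError as exc:
        partition, partition_out, n_clusters = None, {"error": str(exc)}, None
    clustering = network.hierarchical_clustering(sym, n_clusters=n_clusters)
    rank_tests = network.centrality_rank_tests(cent, dom)

    membership_tests = {}
    if partition is not None and len(actors) >= 3:
        member = partition.membership_matrix(actors)
        if kinship is not None:
            kin_sub = kinship.loc[actors, actors]
            membership_tests["vs_kinship"] = taukr.tau_kr_test(
                member, kin_sub, n_perm=n_perm, seed=_subseed(seed, period_id, "member_kin")
            )
        membership_tests["vs_rank_distance"] = taukr.tau_kr_test(
            member, rdist.loc[actors, actors],
            n_perm=n_perm, seed=_subseed(seed, period_id, "member_rank"),
        )

    # --- market ----------------------------------------------------------
    diversity = market.grooming_diversity(freq)
    gri_m = market.gri(effort)
    recip = market.reciprocity_family(
        bouts, actors, n_perm=n_perm, seed=_subseed(seed, period_id, "recip")
    )
    try:
        wls = market.within_bout_regression(bouts)
        wls_out = {
            "slope": wls.slope, "intercept": wls.intercept, "f_stat": wls.f_stat,
            "df": list(wls.df), "s2": wls.s2, "p": wls.p, "degenerate": wls.degenerate,
        }
    except AnalysisError as exc:
        wls_out = {"error": str(exc)}
    try:
        up = market.up_hierarchy_test(effort, freq, dom, exclude=())
        up_out = _up_to_dict(up)
        if exclude:
            up_out["sensitivity_excluding"] = _up_to_dict(
                market.up_hierarchy_test(effort, freq, dom, exclude=exclude)
            )
    except AnalysisError as exc:
        up_out = {"error": str(exc)}
    ratio = market.received_given_vs_rank(effort, dom)
    try:
        gri_vs_rd = market.reciprocity_vs_rank_distance(
            gri_m, rdist, n_perm=n_perm, seed=_subseed(seed, period_id, "gri_rd")
        )
    except AnalysisError as exc:
        gri_vs_rd = {"error": str(exc)}
    tol = market.tolerance_correlation(
        effort, agonism, n_perm=n_perm, seed=_subseed(seed, period_id, "tolerance")
    )

    return {
        "period_id": period_id,
        "n_individuals": len(actors),
        "bout_summary": {
            "n_bouts": len(bouts),
            "n_reciprocated": sum(b.reciprocated for b in bouts),
            "total_grooming_s": float(effort.data.to_numpy().sum()),
        },
        "dominance": {
            "table": dom.table,
            "ties": [list(t) for t in dom.ties],
        },
        "dyads": {
            "mutual": dyads.mutual, "unidirectional": dyads.unidirectional,
            "possible": dyads.possible_dyads,
            "percent_grooming": dyads.percent_grooming,
        },
        "matrices": {
            "effort": effort.data, "frequency": freq.data,
            "affinity": sym.data, "binary": binary.data, "agonism": agonism.data,
        },
        "centrality": cent,
        "centrality_rank_tests": rank_tests,
        "partition": partition_out,
        "clustering": {
            "ccc": clustering.ccc, "faithful": clustering.faithful,
            "n_clusters": clustering.n_clusters,
        },
        "membership_tests": membership_tests,
        "diversity": diversity.table,
        "gri": gri_m,
        "reciprocity": {
            k: {"result": v["result"], "alpha_adjusted": v["alpha_adjusted"]}
            for k, v in recip.items()
        },
        "within_bout_regression": wls_out,
        "up_hierarchy": up_out,
        "received_given_vs_rank": {
            "rho": ratio.rho, "p": ratio.p, "n": ratio.n,
            "excluded": ratio.excluded, "ratios": ratio.ratios,
        },
        "gri_vs_rank_distance": gri_vs_rd,
        "tolerance": tol,
    }


def _up_to_dict(up: market.UpHierarchyResult) -> dict:
    return {
        "percent_up": up.percent_up,
        "wilcoxon_w": up.wilcoxon_w,
        "wilcoxon_p": up.wilcoxon_p,
        "n_nonzero": up.n_nonzero,
        "excluded": up.excluded,
        "table": up.table.reset_index().to_dict(orient="records"),
    }


def compare_periods(
    period_results: Mapping[str, dict],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> dict:
    """Cross-period comparison: centrality correlations and partner stability."""
    ids = sorted(period_results)
    if len(ids) < 2:
        raise AnalysisError("cross-period comparison needs at least 2 periods")
    first, second = ids[0], ids[1]
    c1 = period_results[first]["centrality"]
    c2 = period_results[second]["centrality"]
    common = [i for i in c1.index if i in set(c2.index)]
    out: dict = {"periods": [first, second], "common_individuals": common,
                 "unreliable": len(common) < 4}
    cors = {}
    for measure in network.CENTRALITY_MEASURES:
        a = c1.loc[common, measure].astype(float)
        b = c2.loc[common, measure].astype(float)
        if a.nunique() <= 1 or b.nunique() <= 1:
            cors[measure] = {"rho": None, "p": None, "tied": True, "n": len(common)}
        else:
            rho, p = spearmanr(a, b)
            cors[measure] = {"rho": float(rho), "p": float(p), "tied": False, "n": len(common)}
    out["centrality_correlations"] = cors
    b1 = matrices.DirectedInteractionMatrix(period_results[first]["matrices"]["binary"], "binary")
    b2 = matrices.DirectedInteractionMatrix(period_results[second]["matrices"]["binary"], "binary")
    out["partner_stability"] = market.partner_choice_stability(
        b1, b2, common, n_perm=n_perm, seed=_subseed(seed, "stability")
    )
    return out


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "periods" not in cfg:
        raise ConfigError("config must be a mapping with a 'periods' list")
    return cfg


def run_analysis(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline described by a configuration mapping or YAML path.

    Each entry of ``periods`` names a period and either points at an
    event-log CSV (``log``) or asks for a simulation (``simulate: true``
    with a shared top-level ``simulation`` parameter block and an optional
    per-period ``changes`` list).  Returns the full report; when
    ``output_dir`` (or the config's ``output_dir``) is set, the report and
    every derived matrix are also written to disk.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    n_perm = int(config.get("n_perm", DEFAULT_N_PERM))
    gap_s = float(config.get("gap_s", 30.0))
    exclude = list(config.get("exclude", []))
    out_dir = output_dir or config.get("output_dir")

    sim_params = dict(config.get("simulation", {}))
    group = None
    if any(p.get("simulate") for p in config["periods"]):
        sim_params.setdefault("seed", seed)
        sim_cfg = synthetic.SyntheticConfig(**sim_params)
        group = synthetic.generate_group(sim_cfg)

    period_results: dict[str, dict] = {}
    pedigree = None
    if config.get("pedigree"):
        ped_path = Path(config["pedigree"])
        if not ped_path.exists():
            raise FileNotFoundError(ped_path)
        pedigree = pd.read_csv(ped_path).fillna("")
    elif group is not None:
        pedigree = group.pedigree

    for spec_p in config["periods"]:
        pid = str(spec_p["id"])
        try:
            if spec_p.get("simulate"):
                for ch in spec_p.get("changes", []):
                    group = synthetic.apply_change(group, synthetic.DemographicChange(**ch))
                log = synthetic.simulate_period(group, sim_cfg, pid)
            else:
                log = obslog.read_event_log(spec_p["log"])
            period_results[pid] = analyze_period(
                log, pid, pedigree=pedigree, n_perm=n_perm,
                seed=seed, exclude=exclude, gap_s=gap_s,
            )
        except Exception as exc:
            raise AnalysisError(f"period {pid!r} failed: {exc}") from exc

    report: dict = {
        "seed": seed,
        "n_perm": n_perm,
        "periods": {pid: _jsonable(res) for pid, res in period_results.items()},
    }
    if len(period_results) >= 2:
        report["cross_period"] = _jsonable(
            compare_periods(period_results, n_perm=n_perm, seed=seed)
        )

    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, res in period_results.items():
            for name, df in res["matrices"].items():
                df.to_csv(out_dir / f"{pid}_{name}.csv")
            res["centrality"].to_csv(out_dir / f"{pid}_centrality.csv")
            res["dominance"]["table"].to_csv(out_dir / f"{pid}_dominance.csv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
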