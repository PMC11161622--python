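"""End-to-end study replica on synthetic data.

``run_all`` wires every stage together in the order of the study's
results: simulate a cohort -> score behavior (forward flow, stop-signal,
composites) -> dissociation GLMs -> connectome-based prediction of
novelty and appropriateness (cross-validation, permutation null,
consensus masks) -> network-pair decomposition (with the
threshold/partial robustness variants) -> external validation on an
independent resting cohort and on block-wise task connectivity ->
mediation.  One config, one seed, one report; every stage's seed derives
from the global seed, so re-running a config reproduces the report
bit-identically.
"""

from __future__ import annotations

import copy
import os

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import behavior as bhv
from . import cpm as cpmmod
from . import networks as netmod
from . import synthetic as synth
from ._utils import spawn_seeds
from .connectome import block_fc, edge_vector
from .mediation import mediate
from .semantic import associative_ability

__all__ = ["DEFAULT_CONFIG", "run_all"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_participants": 150,
        "beta_assoc_nov": 0.12,
        "beta_ef_app": -0.09,
        "beta_assoc_app": -0.09,
        "noise_sd": 1.0,
    },
    "semantic": {
        "vocab_size": 120,
        "dim": 50,
        "stream_length": 8,
    },
    "ef": {
        "n_participants": 20,
        "true_ssrt": 250.0,
        "go_rt_mean": 500.0,
        "go_rt_sd": 80.0,
    },
    "connectome": {
        "n_nodes": 30,
        "n_planted_per_sign": 10,
        "effect_size": 0.4,
        "base_noise_sd": 0.3,
    },
    "cpm": {
        "threshold_p": 0.01,
        "k": 10,
        "repetitions": 10,
        "n_perm": 50,
        "perm_repetitions": 1,
        "retention": 0.8,
    },
    "variants": {
        "enabled": True,
        "thresholds": [0.05, 0.01, 0.005],
        "repetitions": 3,
    },
    "ev1": {"n_participants": 50},
    "ev2": {
        "n_participants": 12,
        "n_blocks": 4,
        "n_trials_per_block": 2,
        "window_length": 16,
        "coupling": 1.0,
        "n_perm": 200,
    },
    "mediation": {"n_boot": 1000},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def _planted_edges(n_nodes: int, n_per_sign: int, rng) -> tuple[list, list]:
    """Distinct random node pairs, split into positive and negative sets."""
    from .connectome import EdgeIndex

    index = EdgeIndex(n_nodes)
    ids = rng.choice(index.n_edges, size=2 * n_per_sign, replace=False)
    pairs = index.pairs()[ids]
    pos = [tuple(map(int, p)) for p in pairs[:n_per_sign]]
    neg = [tuple(map(int, p)) for p in pairs[n_per_sign:]]
    return pos, neg


def run_all(config: dict | None = None, outdir: str | None = None) -> dict:
    """Run the full synthetic study replica; returns the report dict.

    ``config`` overrides :data:`DEFAULT_CONFIG` (nested merge).  When
    ``outdir`` is given the config snapshot (YAML), report (YAML) and the
    main per-stage tables (CSV) are written there.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    seeds = spawn_seeds(seed, 16)
    report: dict = {"seed": seed}

    # --- stage 1: semantic scoring demo -------------------------------
    sem = cfg["semantic"]
    coh = cfg["cohort"]
    space = synth.make_embedding_space(
        sem["vocab_size"], sem["dim"], seed=int(seeds[0])
    )
    n = int(coh["n_participants"])
    rng = np.random.default_rng(int(seeds[1]))
    flow_levels = rng.permutation(np.linspace(0.05, 0.95, n))
    streams = synth.make_thought_streams(
        space, n, flow_levels, stream_length=int(sem["stream_length"]),
        seed=int(seeds[2]),
    )
    assoc_scores = associative_ability(streams, space)
    rho = stats.spearmanr(flow_levels, assoc_scores.to_numpy()).statistic
    report["semantic"] = {
        "n_streams": len(streams),
        "flow_level_vs_score_spearman": float(rho),
    }

    # --- stage 2: cohort, outlier screen, dissociation GLMs -----------
    spec = synth.CohortSpec(
        n_participants=n,
        beta_assoc_nov=float(coh["beta_assoc_nov"]),
        beta_ef_app=float(coh["beta_ef_app"]),
        beta_assoc_app=float(coh["beta_assoc_app"]),
        noise_sd=float(coh["noise_sd"]),
        seed=int(seeds[3]),
    )
    table = synth.make_cohort(spec)
    table, exclusions = bhv.exclude_outliers(table)
    glms = {}
    for outcome in ("novelty", "appropriateness"):
        for model in ("1", "2"):
            res = bhv.dissociation_glm(table, outcome, model=model)
            glms[f"{outcome}_model{model}"] = {
                term: {
                    "beta": float(row["beta"]),
                    "se": float(row["se"]),
                    "t": float(row["t"]),
                    "p_bonferroni": float(row["p_bonferroni"]),
                }
                for term, row in res.table.iterrows()
            }
    report["behavior"] = {
        "n_after_exclusion": int(len(table)),
        "n_excluded": int(len(exclusions["participant"].unique()) if len(exclusions) else 0),
        "glm": glms,
    }

    # --- stage 3: stop-signal recovery demo ---------------------------
    ef = cfg["ef"]
    trials = synth.make_ef_trials(
        int(ef["n_participants"]), true_ssrt=float(ef["true_ssrt"]),
        go_rt_mean=float(ef["go_rt_mean"]), go_rt_sd=float(ef["go_rt_sd"]),
        seed=int(seeds[4]),
    )
    ssrts = []
    for pid in trials["participant_id"].unique():
        go, by_ssd = synth.ef_trials_to_ssrt_inputs(trials, pid)
        ssrts.append(bhv.ssrt_integration(go, by_ssd))
    report["stop_signal"] = {
        "true_ssrt": float(ef["true_ssrt"]),
        "mean_estimated_ssrt": float(np.nanmean(ssrts)),
    }

    # --- stage 4: CPM per outcome -------------------------------------
    con, cp = cfg["connectome"], cfg["cpm"]
    n_nodes = int(con["n_nodes"])
    edge_rng = np.random.default_rng(int(seeds[5]))
    cpm_results, masks, net_tables = {}, {}, {}
    conn_specs = {}
    for idx, outcome in enumerate(("novelty", "appropriateness")):
        pos, neg = _planted_edges(
            n_nodes, int(con["n_planted_per_sign"]), edge_rng
        )
        cspec = synth.ConnectomeSpec(
            n_nodes=n_nodes, planted_pos_edges=tuple(pos),
            planted_neg_edges=tuple(neg),
            effect_size=float(con["effect_size"]),
            base_noise_sd=float(con["base_noise_sd"]),
            seed=int(seeds[6 + idx]),
        )
        conn_specs[outcome] = cspec
        y = table[f"{outcome}_z"].to_numpy()
        mats = synth.make_connectomes(cspec, y)
        X = np.stack([edge_vector(m) for m in mats])
        config_sel = cpmmod.SelectionConfig(threshold_p=float(cp["threshold_p"]))
        res = cpmmod.cpm_cross_validate(
            X, y, config_sel, k=int(cp["k"]),
            repetitions=int(cp["repetitions"]), seed=int(seeds[8 + idx]),
        )
        _, p_pt = cpmmod.permutation_null(
            X, y, config_sel, n_perm=int(cp["n_perm"]),
            seed=int(seeds[10 + idx]), observed_r=res.prediction_r,
            k=int(cp["k"]), repetitions=int(cp["perm_repetitions"]),
        )
        res.p_pt = p_pt
        mask = cpmmod.consensus_mask(res, retention=float(cp["retention"]))
        atlas = cspec.atlas()
        net_pos = netmod.edges_to_network_pairs(mask.positive_edges, atlas)
        net_neg = netmod.edges_to_network_pairs(mask.negative_edges, atlas)
        cpm_results[outcome] = res
        masks[outcome] = mask
        net_tables[outcome] = {"positive": net_pos, "negative": net_neg}
        report.setdefault("cpm", {})[outcome] = {
            "prediction_r": res.prediction_r,
            "p_pt": p_pt,
            "mask_pos_edges": int(mask.positive_edges.size),
            "mask_neg_edges": int(mask.negative_edges.size),
            "X_edges": int(X.shape[1]),
        }
        report.setdefault("_internal", {})[outcome] = {
            "X": X, "y": y, "result": res, "mask": mask, "spec": cspec,
        }

    # --- stage 5: robustness variants + network-pair similarity -------
    var = cfg["variants"]
    if var.get("enabled", True):
        sim_report = {}
        for outcome in ("novelty", "appropriateness"):
            X = report["_internal"][outcome]["X"]
            y = report["_internal"][outcome]["y"]
            atlas = conn_specs[outcome].atlas()
            cov_table = table[["age", "gender", "handedness"]].copy()
            variant_tables_pos, variant_tables_neg = [], []
            for thr in var["thresholds"]:
                for kind in ("plain", "partial"):
                    scfg = cpmmod.SelectionConfig(
                        threshold_p=float(thr), correlation_kind=kind,
                        partial_covariates=("age", "gender", "handedness")
                        if kind == "partial" else (),
                    )
                    vres = cpmmod.cpm_cross_validate(
                        X, y, scfg, k=int(cp["k"]),
                        repetitions=int(var["repetitions"]),
                        seed=int(seeds[12]),
                        covariate_table=cov_table if kind == "partial" else None,
                    )
                    vmask = cpmmod.consensus_mask(
                        vres, retention=float(cp["retention"])
                    )
                    variant_tables_pos.append(
                        netmod.edges_to_network_pairs(vmask.positive_edges, atlas)
                    )
                    variant_tables_neg.append(
                        netmod.edges_to_network_pairs(vmask.negative_edges, atlas)
                    )
            sims = {}
            for sign, tabs in (
                ("positive", variant_tables_pos),
                ("negative", variant_tables_neg),
            ):
                try:
                    mean_r, pairwise = netmod.pair_vector_similarity(tabs)
                    sims[sign] = {
                        "mean_r": mean_r, "n_pairwise": int(len(pairwise))
                    }
                except ValueError:
                    sims[sign] = {"mean_r": None, "n_pairwise": 0}
            sim_report[outcome] = sims
        report["variant_similarity"] = sim_report

    # --- stage 6: external validation, resting (EV1) ------------------
    ev1 = cfg["ev1"]
    ev1_report = {}
    for idx, outcome in enumerate(("novelty", "appropriateness")):
        internal = report["_internal"][outcome]
        cspec = conn_specs[outcome]
        rng1 = np.random.default_rng(int(seeds[13]) + idx)
        n_new = int(ev1["n_participants"])
        y_new = rng1.standard_normal(n_new)
        cspec_new = synth.ConnectomeSpec(
            n_nodes=cspec.n_nodes,
            planted_pos_edges=cspec.planted_pos_edges,
            planted_neg_edges=cspec.planted_neg_edges,
            effect_size=cspec.effect_size,
            base_noise_sd=cspec.base_noise_sd,
            seed=int(seeds[14]) + idx,
        )
        mats_new = synth.make_connectomes(cspec_new, y_new)
        X_new = np.stack([edge_vector(m) for m in mats_new])
        covs = pd.DataFrame(
            {
                "fd": rng1.uniform(0.05, 0.2, n_new),
                "age": rng1.normal(21.7, 1.9, n_new),
                "gender": (rng1.random(n_new) < 0.8).astype(int),
            }
        )
        r, p_one = cpmmod.external_validate_rest(
            internal["X"], internal["y"],
            cpmmod.SelectionConfig(threshold_p=float(cp["threshold_p"])),
            X_new, y_new, covs,
        )
        ev1_report[outcome] = {"partial_r": r, "p_one_tailed": p_one}
    report["ev1"] = ev1_report

    # --- stage 7: external validation, task blocks (EV2) --------------
    ev2 = cfg["ev2"]
    ev2_report = {}
    for idx, outcome in enumerate(("novelty", "appropriateness")):
        internal = report["_internal"][outcome]
        model, sel = cpmmod.fit_full_model(
            internal["X"], internal["y"],
            cpmmod.SelectionConfig(threshold_p=float(cp["threshold_p"])),
        )
        windows, labels, scores = synth.make_task_blocks(
            model, sel, n_nodes, int(ev2["n_participants"]),
            n_blocks=int(ev2["n_blocks"]),
            n_trials_per_block=int(ev2["n_trials_per_block"]),
            window_length=int(ev2["window_length"]),
            coupling=float(ev2["coupling"]), seed=int(seeds[15]) + idx,
        )
        block_X = []
        for p in range(int(ev2["n_participants"])):
            per_block = block_fc(windows[p], labels[p])
            block_X.append(
                [edge_vector(per_block[b]) for b in sorted(per_block)]
            )
        block_X = np.asarray(block_X)
        rhos, null_means, group_p = cpmmod.external_validate_task(
            model, sel, block_X, scores, n_perm=int(ev2["n_perm"]),
            seed=int(seeds[15]) + 100 + idx,
        )
        ev2_report[outcome] = {
            "mean_rho": float(np.mean(rhos)),
            "mean_null_rho": float(np.mean(null_means)),
            "group_p_one_tailed": float(group_p),
        }
    report["ev2"] = ev2_report

    # --- stage 8: mediation -------------------------------------------
    med = cfg["mediation"]
    med_report = {}
    chains = [
        ("assoc_to_novelty", "assoc_z", "novelty", "novelty_z"),
        ("ef_to_appropriateness", "ef_rt_z", "appropriateness", "appropriateness_z"),
        ("assoc_to_appropriateness", "assoc_z", "appropriateness", "appropriateness_z"),
    ]
    for name, xcol, mediator_outcome, ycol in chains:
        m_vals = cpm_results[mediator_outcome].predicted
        res = mediate(
            table[xcol].to_numpy(), m_vals, table[ycol].to_numpy(),
            n_boot=int(med["n_boot"]), seed=int(seeds[15]) + 200,
        )
        med_report[name] = {
            "a": res.a, "b": res.b, "c": res.c, "c_prime": res.c_prime,
            "indirect": res.indirect,
            "ci95": list(res.ci[0.95]), "ci90": list(res.ci[0.90]),
        }
    report["mediation"] = med_report

    # --- stage 9: specificity profile ---------------------------------
    rng_spec = np.random.default_rng(int(seeds[15]) + 300)
    battery = pd.DataFrame(
        {
            "novelty_score": table["novelty_z"].to_numpy(),
            "appropriateness_score": table["appropriateness_z"].to_numpy(),
            **{
                f"unrelated_{i + 1:02d}": rng_spec.standard_normal(len(table))
                for i in range(10)
            },
        },
        index=table.index,
    )
    spec_report = {}
    for outcome, target in (
        ("novelty", "novelty_score"),
        ("appropriateness", "appropriateness_score"),
    ):
        preds = pd.Series(cpm_results[outcome].predicted, index=table.index)
        prof = cpmmod.specificity_profile(preds, battery, target)
        spec_report[outcome] = {
            "target_ranks_first": bool(prof.attrs["target_ranks_first"]),
            "top_outcome": str(prof.index[0]),
            "target_r": float(prof.loc[target, "r"]),
            "target_eta_sq": float(prof.loc[target, "eta_sq"]),
        }
    report["specificity"] = spec_report

    internal = report.pop("_internal")
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "config.yaml"), "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)
        with open(os.path.join(outdir, "report.yaml"), "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
        for outcome in ("novelty", "appropriateness"):
            res = cpm_results[outcome]
            pd.DataFrame(
                {"observed": res.observed, "predicted": res.predicted},
                index=table.index,
            ).to_csv(os.path.join(outdir, f"predictions_{outcome}.csv"))
            for sign in ("positive", "negative"):
                net_tables[outcome][sign].to_csv(
                    os.path.join(outdir, f"network_pairs_{outcome}_{sign}.csv")
                )
    report["_tables"] = {"behavior": table, "net": net_tables}
    report["_models"] = {"cpm": cpm_results, "masks": masks}
    return report
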