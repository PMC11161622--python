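"""Validation studies on synthetic cohorts.

Each function runs a self-contained simulation study against the
package's own generators: type-I-error calibration of the permutation
test, power and mask recovery on planted connectome effects, recovery of
the planted behavioral regression structure, bootstrap coverage of the
mediation interval, and the stop-signal recovery error.  They exist so
that the same experiment can be run from the test suite, the acceptance
script and the examples without duplicating the study definitions.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._utils import spawn_seeds
from .behavior import dissociation_glm, ssrt_integration
from .connectome import EdgeIndex, edge_vector
from .cpm import SelectionConfig, consensus_mask, cpm_cross_validate, permutation_null
from .mediation import mediate
from .synthetic import (
    CohortSpec,
    ConnectomeSpec,
    ef_trials_to_ssrt_inputs,
    make_cohort,
    make_connectomes,
    make_ef_trials,
)

__all__ = [
    "exact_moment_mediation",
    "worked_mediation_paths",
    "permutation_calibration_study",
    "cpm_recovery_study",
    "glm_recovery_study",
    "mediation_coverage_study",
    "selection_fpr_study",
    "ssrt_recovery_study",
]


def exact_moment_mediation(n, a, b, c_prime, n_boot=1000, seed=0):
    """Mediation on vectors with exact sample moments.

    Builds x, m, y from an orthonormal mean-zero basis so that the three
    OLS path fits return exactly the requested standardized coefficients
    (a for M~X; b and c' for Y~X+M), then runs :func:`flowcpm.mediate`.
    Used to reproduce printed path tables: the indirect effect equals
    a*b by the product rule, free of sampling error.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n, 3))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    basis = q * np.sqrt(n - 1)  # exact unit sample SD, zero correlation
    b1, b2, b3 = basis.T
    x = b1
    m = a * b1 + np.sqrt(1 - a**2) * b2
    var_y = c_prime**2 + b**2 + 2 * a * b * c_prime
    if var_y >= 1:
        raise ValueError("path coefficients imply variance >= 1")
    y = c_prime * x + b * m + np.sqrt(1 - var_y) * b3
    return mediate(x, m, y, n_boot=n_boot, seed=seed)


#: the three brain-mediated pathways: (name, a, b, c') on standardized scales
WORKED_PATHS = (
    ("assoc_to_novelty", 0.055, 0.472, 0.081),
    ("ef_to_appropriateness", -0.045, 0.525, -0.065),
    ("assoc_to_appropriateness", -0.061, 0.525, -0.046),
)


def worked_mediation_paths(n=1455, n_boot=1000, seed=0):
    """The three mediation chains at their estimated path coefficients.

    Returns {name: MediationResult}; each indirect effect is the product
    of its a and b paths.
    """
    return {
        name: exact_moment_mediation(n, a, b, c_prime, n_boot=n_boot, seed=seed + i)
        for i, (name, a, b, c_prime) in enumerate(WORKED_PATHS)
    }


def permutation_calibration_study(
    n_replicates=50,
    n_participants=100,
    n_nodes=20,
    k=5,
    n_perm=100,
    repetitions=2,
    seed=0,
):
    """Permutation p values under a fully null cohort.

    Generates connectomes with zero planted effect and an independent
    behavioral score, runs the cross-validated CPM plus its permutation
    null, and collects one p_pt per replicate.  Under the null the p
    values should be uniform; returns (p array, KS-test p against the
    uniform distribution).
    """
    seeds = spawn_seeds(seed, n_replicates)
    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng(int(seeds[r]))
        spec = ConnectomeSpec(
            n_nodes=n_nodes, effect_size=0.0, seed=int(seeds[r]) ^ 0x5A5A
        )
        y = rng.standard_normal(n_participants)
        X = np.stack([edge_vector(m) for m in make_connectomes(spec, y)])
        res = cpm_cross_validate(
            X, y, SelectionConfig(), k=k, repetitions=repetitions,
            seed=int(seeds[r]) + 1,
        )
        _, p = permutation_null(
            X, y, SelectionConfig(), n_perm=n_perm, seed=int(seeds[r]) + 2,
            observed_r=res.prediction_r, k=k, repetitions=1,
        )
        ps[r] = p
    ks_p = float(stats.kstest(ps, "uniform").pvalue)
    return ps, ks_p


def cpm_recovery_study(
    n_replicates=10,
    n_participants=200,
    n_nodes=30,
    n_planted_per_sign=10,
    effect_size=0.4,
    k=10,
    repetitions=20,
    n_perm=99,
    seed=0,
):
    """Power and mask recovery on planted-signal cohorts.

    Per replicate: a cohort with 2 x ``n_planted_per_sign`` planted edges
    coupling to behavior at +/-``effect_size``; the cross-validated CPM;
    a permutation p_pt (reduced repetitions); and the consensus mask.
    Returns a dict of per-replicate arrays: p_pt, mask sensitivity
    (fraction of planted edges recovered with the correct sign) and
    false-positive fraction among non-planted edges.
    """
    seeds = spawn_seeds(seed, n_replicates)
    index = EdgeIndex(n_nodes)
    out = {"p_pt": [], "sensitivity": [], "false_positive_rate": []}
    for r in range(n_replicates):
        rng = np.random.default_rng(int(seeds[r]))
        ids = rng.choice(index.n_edges, size=2 * n_planted_per_sign, replace=False)
        pairs = index.pairs()[ids]
        pos = tuple(map(tuple, pairs[:n_planted_per_sign]))
        neg = tuple(map(tuple, pairs[n_planted_per_sign:]))
        spec = ConnectomeSpec(
            n_nodes=n_nodes, planted_pos_edges=pos, planted_neg_edges=neg,
            effect_size=effect_size, seed=int(seeds[r]) ^ 0x3C3C,
        )
        y = rng.standard_normal(n_participants)
        X = np.stack([edge_vector(m) for m in make_connectomes(spec, y)])
        res = cpm_cross_validate(
            X, y, SelectionConfig(), k=k, repetitions=repetitions,
            seed=int(seeds[r]) + 1,
        )
        _, p = permutation_null(
            X, y, SelectionConfig(), n_perm=n_perm, seed=int(seeds[r]) + 2,
            observed_r=res.prediction_r, k=k, repetitions=1,
        )
        mask = consensus_mask(res)
        planted_pos = {index.edge_id(i, j) for i, j in pos}
        planted_neg = {index.edge_id(i, j) for i, j in neg}
        hits = len(planted_pos & set(mask.positive_edges)) + len(
            planted_neg & set(mask.negative_edges)
        )
        noise_hits = (set(mask.positive_edges) | set(mask.negative_edges)) - (
            planted_pos | planted_neg
        )
        n_noise_edges = index.n_edges - 2 * n_planted_per_sign
        out["p_pt"].append(p)
        out["sensitivity"].append(hits / (2 * n_planted_per_sign))
        out["false_positive_rate"].append(len(noise_hits) / n_noise_edges)
    return {key: np.asarray(val) for key, val in out.items()}


def glm_recovery_study(n_replicates=100, n_participants=2000, seed=0):
    """95%-CI coverage of the planted dissociation betas.

    The generator plants raw-scale betas; after marginal standardization
    the true standardized coefficients are attenuated by the outcome SD,
    which is computed analytically (independent predictors).  Returns
    per-path coverage fractions over the replicates.
    """
    spec0 = CohortSpec()
    sd_nov = np.sqrt(spec0.beta_assoc_nov**2 + spec0.noise_sd**2)
    sd_app = np.sqrt(
        spec0.beta_ef_app**2 + spec0.beta_assoc_app**2 + spec0.noise_sd**2
    )
    truth = {
        ("novelty", "assoc_z"): spec0.beta_assoc_nov / sd_nov,
        ("appropriateness", "ef_rt_z"): spec0.beta_ef_app / sd_app,
        ("appropriateness", "assoc_z"): spec0.beta_assoc_app / sd_app,
    }
    seeds = spawn_seeds(seed, n_replicates)
    covered = {key: 0 for key in truth}
    betas = {key: [] for key in truth}
    for r in range(n_replicates):
        table = make_cohort(
            CohortSpec(n_participants=n_participants, seed=int(seeds[r]))
        )
        for outcome in ("novelty", "appropriateness"):
            res = dissociation_glm(table, outcome, model="1")
            tcrit = stats.t.ppf(0.975, res.table["df"].iloc[0])
            for (out_name, term), true_beta in truth.items():
                if out_name != outcome:
                    continue
                beta, se = res[term]["beta"], res[term]["se"]
                betas[(out_name, term)].append(beta)
                if beta - tcrit * se <= true_beta <= beta + tcrit * se:
                    covered[(out_name, term)] += 1
    return {
        "coverage": {k: v / n_replicates for k, v in covered.items()},
        "mean_beta": {k: float(np.mean(v)) for k, v in betas.items()},
        "true_beta": truth,
    }


def mediation_coverage_study(
    n_replicates=200, n=500, a=0.5, b=0.5, n_boot=1000, seed=0
):
    """Coverage of the 95% percentile bootstrap interval for a*b.

    Data follow x -> m -> y with standardized path coefficients a and b;
    the true standardized indirect effect is computed analytically from
    the generative scaling.  Returns the fraction of replicates whose
    interval covers it.
    """
    # m = a x + e has SD sqrt(a^2 + 1); y = b m + e has SD sqrt(b^2 s_m^2 + 1)
    s_m = np.sqrt(a**2 + 1.0)
    s_y = np.sqrt(b**2 * s_m**2 + 1.0)
    true_indirect = (a / s_m) * (b * s_m / s_y)
    seeds = spawn_seeds(seed, n_replicates)
    hits = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(int(seeds[r]))
        x = rng.standard_normal(n)
        m = a * x + rng.standard_normal(n)
        y = b * m + rng.standard_normal(n)
        res = mediate(x, m, y, n_boot=n_boot, seed=int(seeds[r]) + 1)
        lo, hi = res.ci[0.95]
        hits += lo <= true_indirect <= hi
    return hits / n_replicates, true_indirect


def selection_fpr_study(n_participants=300, n_edges=4000, threshold=0.01, seed=0):
    """Edge-selection false-positive rate on pure noise."""
    from .cpm import select_edges

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_participants, n_edges))
    y = rng.standard_normal(n_participants)
    pos, neg = select_edges(X, y, SelectionConfig(threshold_p=threshold))
    return (len(pos) + len(neg)) / n_edges


def ssrt_recovery_study(n_seeds=50, true_ssrt=250.0, seed=0):
    """Mean signed error of the integration-method SSRT on race-model
    staircase data."""
    seeds = spawn_seeds(seed, n_seeds)
    errors = []
    for s in seeds:
        trials = make_ef_trials(1, true_ssrt=true_ssrt, seed=int(s))
        go, by_ssd = ef_trials_to_ssrt_inputs(trials, "p0001")
        errors.append(ssrt_integration(go, by_ssd) - true_ssrt)
    return float(np.mean(errors))
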