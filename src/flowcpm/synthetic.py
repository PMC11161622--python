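"""Synthetic study generators with planted ground truth.

The human data behind this analysis (behavior, resting and task fMRI)
are not publicly deposited, so every input the pipeline consumes can be
simulated here with known structure:

* embedding spaces drawn uniformly on the unit sphere;
* thought streams whose expected forward flow rises monotonically with a
  per-participant ``flow_level``;
* behavioral cohorts from the linear-Gaussian model that the dissociation
  GLMs assume, with the study's sign structure (novelty increases with
  associative ability; appropriateness increases with executive function,
  i.e. decreases with the RT composite, and decreases with associative
  ability);
* connectomes with a sparse set of planted edges whose Fisher-z weight
  covaries with a behavioral target;
* race-model stop-signal trials with the staircase SSD procedure;
* block-wise task time series carrying a planted coupling between a
  fitted model's prediction and the observed block score.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import rng_from
from .connectome import Atlas, EdgeIndex, edge_matrix
from .semantic import EmbeddingSpace, ThoughtStream

__all__ = [
    "CohortSpec",
    "ConnectomeSpec",
    "make_embedding_space",
    "make_thought_streams",
    "make_cohort",
    "make_connectomes",
    "make_ef_trials",
    "ef_trials_to_ssrt_inputs",
    "make_task_blocks",
]

#: staircase ladder start values (ms) for the stop-signal generator
DEFAULT_SSD_LADDER = (140.0, 180.0, 220.0, 260.0)
#: extension step (ms) beyond the top/bottom ladder
SSD_STEP = 60.0


@dataclass(frozen=True)
class CohortSpec:
    """Linear-Gaussian behavioral cohort.

    Defaults plant the study's standardized effect pattern: associative
    ability raises novelty (0.12); a faster EF-RT composite raises
    appropriateness (−0.09 on the RT scale, where lower is better); and
    associative ability lowers appropriateness (−0.09).
    """

    n_participants: int = 200
    beta_assoc_nov: float = 0.12
    beta_ef_app: float = -0.09
    beta_assoc_app: float = -0.09
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 10:
            raise ValueError("need at least 10 participants")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class ConnectomeSpec:
    """Planted-edge connectome cohort.

    ``planted_pos_edges`` / ``planted_neg_edges`` are unordered node
    pairs (i < j, 0-based) whose Fisher-z weight correlates with the
    behavioral target at +/−``effect_size``; all other edges are noise.
    Nodes are assigned to ``n_networks`` networks in contiguous blocks.
    """

    n_nodes: int = 60
    n_networks: int = 7
    planted_pos_edges: tuple = ()
    planted_neg_edges: tuple = ()
    effect_size: float = 0.4
    base_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not abs(self.effect_size) < 1:
            raise ValueError("|effect_size| must be < 1")
        seen = set()
        for (i, j) in tuple(self.planted_pos_edges) + tuple(self.planted_neg_edges):
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(
                    f"planted edge ({i}, {j}) must satisfy 0 <= i < j < n_nodes"
                )
            if (i, j) in seen:
                raise ValueError(f"duplicate planted edge ({i}, {j})")
            seen.add((i, j))

    def atlas(self) -> Atlas:
        from .connectome import YEO7_NETWORKS

        if self.n_networks == 7:
            names = list(YEO7_NETWORKS)
        else:
            names = [f"N{i + 1}" for i in range(self.n_networks)]
        per = int(np.ceil(self.n_nodes / self.n_networks))
        labels = [names[min(i // per, self.n_networks - 1)] for i in range(self.n_nodes)]
        return Atlas(labels, name=f"synthetic-{self.n_nodes}")


def make_embedding_space(vocab_size: int, dim: int, seed: int = 0) -> EmbeddingSpace:
    """Uniform unit-sphere embedding space with words w0001, w0002, ...

    Sampling a standard Gaussian and normalizing gives the uniform
    distribution on the sphere, the simplest space with well-behaved
    cosine geometry.
    """
    if vocab_size < 2 or dim < 2:
        raise ValueError("vocab_size and dim must both be at least 2")
    rng = rng_from(seed)
    vecs = rng.standard_normal((vocab_size, dim))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    width = max(4, len(str(vocab_size)))
    words = [f"w{i + 1:0{width}d}" for i in range(vocab_size)]
    return EmbeddingSpace(dict(zip(words, vecs)))


def make_thought_streams(
    space: EmbeddingSpace,
    n_participants: int,
    flow_level,
    stream_length: int = 8,
    seed: int = 0,
    items: tuple[str, ...] = ("cake", "snowflake"),
    jump_concentration: float = 4.0,
) -> list[ThoughtStream]:
    """Free-association streams whose expected forward flow increases with
    ``flow_level``.

    At each step the stream repeats the previous word with probability
    ``1 − flow_level`` and otherwise jumps to a word sampled with
    probability proportional to exp(jump_concentration * distance from
    the previous word), tilting jumps toward semantically distant words.
    ``flow_level`` may be a scalar or one value per participant, each in
    [0, 1]; 0 forces pure repetition (forward flow exactly 0).
    """
    if stream_length < 2:
        raise ValueError("stream_length must be at least 2")
    flow = np.broadcast_to(
        np.asarray(flow_level, dtype=float), (n_participants,)
    ).copy()
    if np.any((flow < 0) | (flow > 1)):
        raise ValueError("flow_level values must lie in [0, 1]")
    rng = rng_from(seed)
    words = sorted(space.vocabulary)
    vecs = np.stack([space[w] for w in words])
    # pairwise cosine distances once; vocab sizes here are small
    dmat = 1.0 - vecs @ vecs.T

    streams = []
    for p in range(n_participants):
        for item in items:
            current = int(rng.integers(len(words)))
            seq = [words[current]]
            for _ in range(stream_length - 1):
                if rng.random() < 1.0 - flow[p]:
                    seq.append(words[current])
                    continue
                logits = jump_concentration * dmat[current]
                w = np.exp(logits - logits.max())
                w[current] = 0.0
                w /= w.sum()
                current = int(rng.choice(len(words), p=w))
                seq.append(words[current])
            streams.append(
                ThoughtStream(
                    participant_id=f"p{p + 1:04d}", item_id=item,
                    cue=item, responses=seq,
                )
            )
    return streams


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Behavioral cohort under the planted linear-Gaussian model.

    Predictors (associative ability, EF-RT composite, EF-ACC composite)
    are independent standard normals; outcomes follow the planted betas
    plus Gaussian residuals of SD ``noise_sd``; all five analysis columns
    are then standardized marginally.  Age, gender (1 = female, rate
    0.67) and handedness (1 = right, rate 0.9) are cosmetic covariates.
    """
    rng = rng_from(spec.seed)
    n = spec.n_participants
    assoc = rng.standard_normal(n)
    ef_rt = rng.standard_normal(n)
    ef_acc = rng.standard_normal(n)
    novelty = spec.beta_assoc_nov * assoc + spec.noise_sd * rng.standard_normal(n)
    approp = (
        spec.beta_ef_app * ef_rt
        + spec.beta_assoc_app * assoc
        + spec.noise_sd * rng.standard_normal(n)
    )

    def _z(v):
        return (v - v.mean()) / v.std(ddof=1)

    table = pd.DataFrame(
        {
            "novelty_z": _z(novelty),
            "appropriateness_z": _z(approp),
            "assoc_z": _z(assoc),
            "ef_rt_z": _z(ef_rt),
            "ef_acc_z": _z(ef_acc),
            "age": np.round(rng.normal(21.1, 0.97, size=n), 1),
            "gender": (rng.random(n) < 0.67).astype(int),
            "handedness": (rng.random(n) < 0.9).astype(int),
        },
        index=pd.Index([f"p{i + 1:04d}" for i in range(n)], name="participant_id"),
    )
    return table


def make_connectomes(spec: ConnectomeSpec, behavior) -> np.ndarray:
    """Cohort of symmetric Fisher-z connectivity matrices with planted
    behavior-coupled edges.

    Each planted edge carries weight
    ``base_noise_sd * (effect_size * z_behavior +/- sqrt(1-effect_size^2) * noise)``
    so its across-participant correlation with the behavioral target is
    +/-``effect_size`` in expectation; non-planted edges are pure noise.
    Returns an (n_participants, n_nodes, n_nodes) array with zero
    diagonals.
    """
    behavior = np.asarray(behavior, dtype=float).ravel()
    n = behavior.size
    if behavior.std() == 0:
        raise ValueError("behavioral target must vary across participants")
    z_beh = (behavior - behavior.mean()) / behavior.std()
    rng = rng_from(spec.seed)
    index = EdgeIndex(spec.n_nodes)
    n_edges = index.n_edges

    edges = spec.base_noise_sd * rng.standard_normal((n, n_edges))
    mix = np.sqrt(1.0 - spec.effect_size**2)
    for pairs, sign in ((spec.planted_pos_edges, 1.0), (spec.planted_neg_edges, -1.0)):
        for (i, j) in pairs:
            e = index.edge_id(i, j)
            noise = rng.standard_normal(n)
            edges[:, e] = spec.base_noise_sd * (
                sign * spec.effect_size * z_beh + mix * noise
            )
    return np.stack([edge_matrix(edges[s], spec.n_nodes) for s in range(n)])


def make_ef_trials(
    n_participants: int,
    true_ssrt: float = 250.0,
    go_rt_mean: float = 500.0,
    go_rt_sd: float = 80.0,
    ssd_ladder: tuple[float, ...] = DEFAULT_SSD_LADDER,
    n_go: int = 192,
    n_stop: int = 64,
    seed: int = 0,
) -> pd.DataFrame:
    """Race-model stop-signal trials with staircase SSD tracking.

    Go RTs are Gaussian (truncated at 50 ms); on stop trials the
    participant responds iff the go process finishes before SSD + SSRT.
    The SSD starts at the third ladder value; successful inhibition moves
    it one ladder up (or +60 ms beyond the top), failure one ladder down
    (or −60 ms below the bottom, floored at 0).  Returns a trial table
    with columns participant_id, trial_type, ssd, responded, rt.
    """
    if true_ssrt <= 0:
        raise ValueError("true_ssrt must be positive")
    ssrt_arr = np.broadcast_to(
        np.asarray(true_ssrt, dtype=float), (n_participants,)
    )
    rng = rng_from(seed)
    ladder = sorted(ssd_ladder)
    rows = []
    for p in range(n_participants):
        pid = f"p{p + 1:04d}"
        # interleave stop trials uniformly among go trials
        kinds = np.array(["go"] * n_go + ["stop"] * n_stop)
        rng.shuffle(kinds)
        ssd = ladder[min(2, len(ladder) - 1)]
        for kind in kinds:
            go_rt = max(rng.normal(go_rt_mean, go_rt_sd), 50.0)
            if kind == "go":
                rows.append((pid, "go", np.nan, True, go_rt))
                continue
            responded = go_rt < ssd + ssrt_arr[p]
            rows.append((pid, "stop", ssd, responded, go_rt if responded else np.nan))
            if responded:  # failure to stop: make inhibition easier
                if ssd > ladder[0]:
                    below = [x for x in ladder if x < ssd]
                    ssd = max(below) if below else max(ssd - SSD_STEP, 0.0)
                else:
                    ssd = max(ssd - SSD_STEP, 0.0)
            else:  # successful stop: make it harder
                if ssd < ladder[-1]:
                    above = [x for x in ladder if x > ssd]
                    ssd = min(above) if above else ssd + SSD_STEP
                else:
                    ssd = ssd + SSD_STEP
        # off-ladder SSDs from the +/-60 extension stay in their own pools
    return pd.DataFrame(
        rows, columns=["participant_id", "trial_type", "ssd", "responded", "rt"]
    )


def ef_trials_to_ssrt_inputs(
    trials: pd.DataFrame, participant_id: str
) -> tuple[np.ndarray, dict[float, tuple[int, int]]]:
    """Aggregate one participant's trial table into the inputs of the
    integration-method SSRT: the go-RT distribution and per-SSD
    (n stop trials, n responded) counts."""
    sub = trials[trials["participant_id"] == participant_id]
    go = sub[sub["trial_type"] == "go"]["rt"].dropna().to_numpy()
    stop = sub[sub["trial_type"] == "stop"]
    by_ssd = {
        float(ssd): (len(grp), int(grp["responded"].sum()))
        for ssd, grp in stop.groupby("ssd")
    }
    return go, by_ssd


def make_task_blocks(
    model,
    selected_edges: np.ndarray,
    n_nodes: int,
    n_participants: int,
    n_blocks: int = 4,
    n_trials_per_block: int = 3,
    window_length: int = 16,
    coupling: float = 1.0,
    seed: int = 0,
):
    """Block-wise task time series with a planted prediction-score coupling.

    For each participant, block scores are standard normal; the target
    Fisher-z pattern of a block shifts along the fitted model's prediction
    gradient by ``coupling * score``, so the model's predicted block
    score is monotonically related to the observed one (``coupling=0``
    plants no relation).  Each trial window is Gaussian noise with the
    block's correlation structure (eigenvalue-clipped to stay positive
    definite); no hemodynamics or spatial autocorrelation are simulated.

    Returns (trial_windows, block_assignment, scores) where
    ``trial_windows[p]`` is the list of T x N arrays for participant p,
    ``block_assignment`` the matching block labels, and ``scores`` the
    (n_participants, n_blocks) observed block scores.
    """
    if n_blocks < 3:
        raise ValueError("need at least 3 blocks for rank correlation")
    rng = rng_from(seed)
    index = EdgeIndex(n_nodes)

    # prediction gradient of the linear-kernel model in edge space
    grad_sel = np.zeros(model.n_features_in_)
    for w, m in zip(model.weights_, model.active_):
        if m > 0:
            grad_sel += w * model._X_train[m - 1]
    grad = np.zeros(index.n_edges)
    grad[np.asarray(selected_edges, dtype=int)] = grad_sel
    norm = np.linalg.norm(grad)
    if norm > 0:
        grad = grad / norm

    all_windows, assignments = [], []
    scores = np.empty((n_participants, n_blocks))
    for p in range(n_participants):
        windows, labels = [], []
        base = 0.05 * rng.standard_normal(index.n_edges)
        for b in range(n_blocks):
            s = rng.standard_normal()
            scores[p, b] = s
            z_target = base + coupling * s * grad
            r_target = np.tanh(edge_matrix(z_target, n_nodes))
            np.fill_diagonal(r_target, 1.0)
            # project to the positive-definite cone
            vals, vecs = np.linalg.eigh(r_target)
            vals = np.clip(vals, 1e-3, None)
            cov = (vecs * vals) @ vecs.T
            d = np.sqrt(np.diag(cov))
            cov = cov / np.outer(d, d)
            chol = np.linalg.cholesky(cov)
            for _ in range(n_trials_per_block):
                windows.append(
                    rng.standard_normal((window_length, n_nodes)) @ chol.T
                )
                labels.append(b)
        all_windows.append(windows)
        assignments.append(labels)
    return all_windows, assignments, scores
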