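"""Decompose edge masks onto within-/between-network pairs.

With 7 cortical networks there are 28 unordered network pairs (7 within-
network plus 21 between-network).  Each mask edge maps to the pair formed
by the networks of its two endpoint nodes; the table reports counts and
percentages of the mask, and model variants are compared by correlating
their 28-length count vectors.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import IntegrityError
from .connectome import Atlas, EdgeIndex

logger = logging.getLogger(__name__)

__all__ = ["network_pair_labels", "edges_to_network_pairs", "pair_vector_similarity"]


def network_pair_labels(networks: list[str]) -> list[str]:
    """Canonical unordered pair labels: within-network pairs first, then
    between-network pairs, in network order."""
    labels = [f"{n}-{n}" for n in networks]
    labels += [f"{a}-{b}" for a, b in combinations(networks, 2)]
    return labels


def edges_to_network_pairs(
    edge_ids: np.ndarray, atlas: Atlas, n_nodes: int | None = None
) -> pd.DataFrame:
    """Count mask edges per network pair.

    ``edge_ids`` are ids into the canonical edge order for ``atlas``.
    Returns a table indexed by pair label with columns ``count`` and
    ``percent`` (count / mask size x 100; NaN for an empty mask, with the
    table flagged via ``attrs['empty']``).  Counts always sum to the mask
    size, and for a nonempty mask percentages sum to 100.
    """
    if n_nodes is not None and n_nodes != atlas.n_nodes:
        raise IntegrityError(
            f"edge index built for {n_nodes} nodes but atlas has {atlas.n_nodes}"
        )
    index = EdgeIndex(atlas.n_nodes)
    edge_ids = np.asarray(edge_ids, dtype=int)
    if edge_ids.size and (edge_ids.min() < 0 or edge_ids.max() >= index.n_edges):
        raise IntegrityError("edge id outside the atlas edge range")

    networks = atlas.networks
    labels = network_pair_labels(networks)
    counts = pd.Series(0, index=pd.Index(labels, name="pair"), dtype=int)
    pairs = index.pairs()
    for e in edge_ids:
        i, j = pairs[e]
        a, b = atlas.network_of(int(i)), atlas.network_of(int(j))
        a, b = sorted((a, b), key=networks.index)
        key = f"{a}-{a}" if a == b else f"{a}-{b}"
        counts[key] += 1

    table = counts.to_frame("count")
    total = counts.sum()
    if total == 0:
        logger.warning("empty mask: percentages undefined")
        table["percent"] = np.nan
        table.attrs["empty"] = True
    else:
        table["percent"] = counts / total * 100.0
        table.attrs["empty"] = False
    return table


def pair_vector_similarity(
    tables: list[pd.DataFrame], use: str = "count"
) -> tuple[float, pd.DataFrame]:
    """Mean pairwise Pearson correlation between network-pair vectors.

    Given m tables over the identical pair ordering, computes the
    m(m-1)/2 pairwise correlations of their ``use`` columns ('count' by
    default, 'percent' optionally) and returns (mean r, the pairwise
    table).  Constant vectors make a pair's correlation undefined; such
    pairs are excluded with a warning.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    base = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(base):
            raise IntegrityError("tables disagree on the network-pair ordering")
    vectors = [t[use].to_numpy(dtype=float) for t in tables]
    rows = []
    for a, b in combinations(range(len(vectors)), 2):
        va, vb = vectors[a], vectors[b]
        if np.std(va) == 0 or np.std(vb) == 0:
            logger.warning("pair (%d, %d) skipped: constant vector", a, b)
            continue
        rows.append(
            {"i": a, "j": b, "r": float(stats.pearsonr(va, vb).statistic)}
        )
    pairwise = pd.DataFrame(rows, columns=["i", "j", "r"])
    if pairwise.empty:
        raise ValueError("no defined pairwise correlations")
    return float(pairwise["r"].mean()), pairwise
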