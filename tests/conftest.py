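"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phyloclock.dating import RootPrior, TreeIndex
from phyloclock.trees import PhyloTree
from phyloclock.synth import simulate_time_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quartet():
    return PhyloTree.from_newick("((A:1,B:1):2,C:1,D:1);")


def random_metric_tree(n_tips: int, rng: np.random.Generator) -> PhyloTree:
    """Random topology with Gamma-perturbed branch lengths (not clock-like)."""
    tree = simulate_time_tree(n_tips, 1.0, seed=rng)
    for node in tree.postorder():
        node.age = None
        if node.parent is not None:
            node.length = float(rng.gamma(2.0, 0.5)) + 1e-3
    return tree


# ---------------------------------------------------------------------------
# Brute-force MAD oracle: exhaustive branch x rho-grid search built only on
# tip-to-root-point distances (no closed-form rho*).
# ---------------------------------------------------------------------------


def mad_grid_oracle(tree: PhyloTree, grid_step_frac: float = 1e-4):
    """Return (best_tipset, best_rho, best_mad) by grid search.

    For a candidate root r on a branch, each tip pair's ancestor deviation is
    |2*d(a,i)/d_ij - 1| with d(a,i) = (d(r,i) + d_ij - d(r,j)) / 2, evaluated
    on a dense rho grid per branch.
    """
    from phyloclock.trees import _unrooted_edges, _distances_from, _tipset_side

    labels, dmat = tree.tip_distance_matrix()
    tip_nodes = tree.tips()
    tip_index = {t.label: i for i, t in enumerate(tip_nodes)}
    adjacency, edges, _ = _unrooted_edges(tree)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    order = {l: i for i, l in enumerate(labels)}

    best = None
    for child, other, t in edges:
        side = _tipset_side(child, other, adjacency)
        dc = _distances_from(child, adjacency)
        do = _distances_from(other, adjacency)
        in_side = np.zeros(n, dtype=bool)
        d_child_end = np.zeros(n)
        d_other_end = np.zeros(n)
        for tip in tip_nodes:
            i = order[tip.label]
            if id(tip) in side:
                in_side[i] = True
                d_child_end[i] = dc[id(tip)]
            else:
                d_other_end[i] = do[id(tip)]
        if t > 0:
            rhos = np.arange(0.0, t + grid_step_frac * t / 2, grid_step_frac * t)
        else:
            rhos = np.array([0.0])
        # d(r, i) for every tip and rho
        d_r = np.where(
            in_side[None, :],
            d_child_end[None, :] + rhos[:, None],
            d_other_end[None, :] + (t - rhos)[:, None],
        )  # (n_rho, n_tips)
        di = d_r[:, iu[0]]
        dj = d_r[:, iu[1]]
        dij = dmat[iu][None, :]
        d_ai = 0.5 * (di + dij - dj)
        r = np.abs(2.0 * d_ai / dij - 1.0)
        mads = np.sqrt(np.mean(r * r, axis=1))
        k = int(np.argmin(mads))
        if best is None or mads[k] < best[2] - 1e-15:
            tipset = frozenset(labels[i] for i in np.flatnonzero(in_side))
            best = (tipset, float(rhos[k]), float(mads[k]))
    return best


# ---------------------------------------------------------------------------
# Direct prior sampler: truncated-normal root + uniform order statistics,
# with rejection for tree order constraints and calibration bounds.
# ---------------------------------------------------------------------------


def prior_age_oracle(
    tree: PhyloTree,
    root_prior: RootPrior,
    calibrations=(),
    n: int = 2000,
    rng=None,
    batch: int = 50_000,
    max_batches: int = 400,
):
    """Draw node-age vectors directly from the dating prior.

    Returns dict mapping internal node names to arrays of n sampled ages.
    Independent of the MCMC code path: plain rejection sampling from
    root ~ truncated normal, internal ages i.i.d. uniform(0, root).
    """
    from scipy.stats import truncnorm

    rng = rng if rng is not None else np.random.default_rng(0)
    idx = TreeIndex(tree)
    free = list(idx.free_internal)
    m = len(free)
    cal_bounds = []
    for cal in calibrations:
        node = idx.mrca_index(cal.tip_a, cal.tip_b)
        cal_bounds.append((node, cal.min_age, cal.max_age))

    a = -root_prior.mean / root_prior.sd
    tn = truncnorm(a, np.inf, loc=root_prior.mean, scale=root_prior.sd)
    col = {node: j for j, node in enumerate([idx.root] + free)}

    out = []
    for _ in range(max_batches):
        roots = tn.rvs(size=batch, random_state=rng)
        ages = np.zeros((batch, idx.n))
        ages[:, idx.root] = roots
        if m:
            ages[:, free] = rng.random((batch, m)) * roots[:, None]
        ok = np.ones(batch, dtype=bool)
        for i in idx.nonroot:
            ok &= ages[:, idx.parent[i]] >= ages[:, i]
        for node, lo, hi in cal_bounds:
            ok &= (ages[:, node] >= lo) & (ages[:, node] <= hi)
        out.append(ages[ok])
        if sum(len(o) for o in out) >= n:
            break
    ages = np.vstack(out)
    if len(ages) < n:
        raise RuntimeError("prior oracle: not enough accepted draws")
    ages = ages[:n]
    return {
        idx.node_names[node]: ages[:, node] for node in [idx.root] + free
    }
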