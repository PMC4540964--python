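"""Independent oracles used by the test suite.

Each oracle deliberately re-derives its quantity by a different route from
the implementation it checks: exhaustive enumeration for the cluster score
and the hypergeometric tail, and node-by-node moment propagation (rather
than closed-form path sums) for the OU tip distribution.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.special import comb

from crmou.crmscore import _BASE_INDEX, _background_freqs, _site_log_odds
from crmou.phylo import PhyloTree, RegimePainting


def brute_force_crm_score(seq: str, pwm, gap: float, background) -> float:
    """log2 best-subsegment cluster score by exhaustive enumeration of all
    (start, end) segments and all non-overlapping site placements."""
    seq = seq.upper()
    bg = _background_freqs(seq, background)
    idx = np.array([_BASE_INDEX.get(b, 4) for b in seq])
    L, n = pwm.length, len(seq)
    q = 1.0 / (1.0 + gap)
    odds_f = np.exp(_site_log_odds(idx, pwm, bg))
    odds_r = np.exp(_site_log_odds(idx, pwm.reverse_complement(), bg))
    w = (q / 2.0) * (odds_f + odds_r)

    best = 1.0
    for a in range(n + 1):
        for b in range(a, n + 1):
            total = 0.0

            def rec(pos, prod, covered):
                nonlocal total
                if pos > b - L:
                    total += prod * (1.0 - q) ** (b - a - covered)
                    return
                rec(pos + 1, prod, covered)
                rec(pos + L, prod * w[pos], covered + L)

            rec(a, 1.0, 0)
            best = max(best, total)
    return math.log2(best)


def ou_moments_by_propagation(tree: PhyloTree, painting: RegimePainting,
                              alpha: float, sigma_sq: float,
                              theta: dict[str, float], x0: float):
    """Tip mean vector and covariance matrix by per-branch moment
    propagation down the tree (E, Var, Cov recursions), independent of the
    closed-form path construction used by the implementation."""
    n_nodes = len(tree.preorder)
    mean = np.zeros(n_nodes)
    cov = np.zeros((n_nodes, n_nodes))
    mean[tree.root.index] = x0
    for node in tree.preorder:
        if node is tree.root:
            continue
        i, p = node.index, node.parent.index
        t = node.length
        decay = math.exp(-alpha * t)
        th = theta[painting.regime_of(tree.branch_id(node))]
        mean[i] = mean[p] * decay + th * (1.0 - decay)
        # Cov(child, any previously realized node) scales by decay
        cov[i, :] = cov[p, :] * decay
        cov[:, i] = cov[i, :]
        cov[i, i] = cov[p, p] * decay ** 2 \
            + sigma_sq * (-math.expm1(-2.0 * alpha * t)) / (2.0 * alpha)
    tips = [tree.tip(lab).index for lab in tree.tip_labels]
    return (tree.tip_labels, mean[tips], cov[np.ix_(tips, tips)])


def brute_force_hypergeom_sf(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by direct summation of hypergeometric pmf terms."""
    total = comb(N, n, exact=True)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += comb(K, j, exact=True) * comb(N - K, n - j, exact=True)
    return acc / total


def random_tree_newick(rng: np.random.Generator, n_tips: int,
                       min_bl: float = 0.05, max_bl: float = 1.5) -> str:
    """A random rooted binary tree with uniform random branch lengths."""
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(min_bl, max_bl, size=2)
        merged = f"({a}:{la:.4f},{b}:{lb:.4f})"
        nodes = [x for idx, x in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return nodes[0] + ";"
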