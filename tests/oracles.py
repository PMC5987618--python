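"""Independent brute-force oracles shared across test modules.

Each oracle re-derives an expected value from first principles
(enumeration, dense-matrix algebra, direct summation) without touching
the implementation paths it checks.
"""

import itertools

import numpy as np
from scipy import stats


def chain_score_oracle(hsps):
    """Best colinear chain weight by exhaustive permutation search."""
    best = 0.0
    for k in range(1, len(hsps) + 1):
        for combo in itertools.permutations(hsps, k):
            ok = all(
                a.qend < b.qstart and a.send < b.sstart
                for a, b in zip(combo, combo[1:])
            )
            if ok:
                best = max(best, sum(h.bits for h in combo))
    return best


def cluster_oracle(genes, edges, min_weight=5.0, min_ratio=0.33, max_size=10**5):
    """Naive agglomeration re-derivation: every average recomputed from
    the weight table at every step."""
    w = {tuple(sorted(k)): v for k, v in edges.items() if v >= min_weight}

    def pairw(a, b):
        return w.get((a, b) if a < b else (b, a), 0.0)

    clusters = [{g} for g in sorted(set(genes))]
    while True:
        scored = []
        for c1, c2 in itertools.combinations(clusters, 2):
            ab = sum(pairw(a, b) for a in c1 for b in c2) / (len(c1) * len(c2))
            if ab > 0:
                lo, hi = sorted((min(c1), min(c2)))
                scored.append((-ab, lo, hi, c1, c2))
        scored.sort(key=lambda t: t[:3])
        done = True
        for neg_ab, _, _, c1, c2 in scored:
            if len(c1) + len(c2) > max_size:
                continue
            if len(c1) != len(c2):
                small = c1 if len(c1) < len(c2) else c2
            else:
                small = c1 if min(c1) < min(c2) else c2
            if len(small) > 1:
                pairs = list(itertools.combinations(sorted(small), 2))
                internal = sum(pairw(a, b) for a, b in pairs) / len(pairs)
                if -neg_ab < min_ratio * internal:
                    continue
            clusters.remove(c1)
            clusters.remove(c2)
            clusters.append(c1 | c2)
            done = False
            break
        if done:
            return sorted(map(sorted, clusters))


def signed_rank_oracle(diffs):
    """Two-sided exact signed-rank p by explicit 2^n sign enumeration."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = float(ranks[np.array(diffs) > 0].sum())
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    lower = np.mean(ws <= w_obs + 1e-12)
    upper = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(lower, upper))


def dense_cov_oracle(tree, painting, s2f, s2b, focal_label="focal"):
    """Tip covariance by per-branch indicator sums: V[i,j] accumulates
    rate * length over branches lying on both tips' root paths."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    ancestors = []
    for leaf in leaves:
        path = set()
        node = leaf
        while node.parent_node is not None:
            path.add(id(node))
            node = node.parent_node
        ancestors.append(path)
    n = len(leaves)
    v = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        rate = s2f if painting[node] == focal_label else s2b
        term = rate * node.edge.length
        on_path = [id(node) in anc for anc in ancestors]
        for i in range(n):
            for j in range(n):
                if on_path[i] and on_path[j]:
                    v[i, j] += term
    return [lf.taxon.label for lf in leaves], v


def gls_profiled_loglik_oracle(x, v):
    """MVN log density with the mean profiled by GLS, via dense algebra."""
    ones = np.ones(len(x))
    vi = np.linalg.inv(v)
    mu = (ones @ vi @ x) / (ones @ vi @ ones)
    return float(
        stats.multivariate_normal(mean=mu * ones, cov=v).logpdf(x)
    )
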