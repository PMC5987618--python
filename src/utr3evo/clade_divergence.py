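"""Per-gene comparative statistics of 3'UTR length on a painted phylogeny.

A time-calibrated, rooted, ultrametric tree is "painted" into two rate
regimes: the focal clade (its crown branches plus the stem leading to it)
and the background (everything else).  For each gene, the vector of
per-species 3'UTR lengths is modelled as Brownian motion whose variance
accrues at rate ``sigma2_focal`` on focal branches and
``sigma2_background`` on background branches.  Tip covariance is

    V[i, j] = sigma2_focal * T_f[i, j] + sigma2_background * T_b[i, j]

where ``T_r[i, j]`` is the root-to-MRCA(i, j) path length spent in regime
``r``.  The root state is profiled analytically by generalized least
squares, and the two rates are estimated by maximum likelihood (or REML)
over the rate ratio with the scale profiled out, so the numerical search
is one-dimensional.

The module also provides the clade mean-length log-ratio and the
one-sample t-test used to ask whether the focal clade's 3'UTRs are, on
average, longer or faster-evolving than the background's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats

FOCAL = "focal"
BACKGROUND = "background"

# Rate ratio is searched on a natural-log scale within these bounds; a
# fit ending on a bound is flagged rather than trusted.
_LOG_RATIO_BOUND = math.log(1e6)

__all__ = [
    "FOCAL",
    "BACKGROUND",
    "BMFit",
    "TwoRegimeBM",
    "read_tree",
    "check_ultrametric",
    "paint_regimes",
    "regime_path_matrices",
    "bm_loglik",
    "fit_bm_rates",
    "length_log_ratio",
    "one_sample_t",
]


def read_tree(source: str, *, is_path: bool = True) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths in Myr."""
    kwargs = {"path": source} if is_path else {"data": source}
    tree = dendropy.Tree.get(
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
        **kwargs,
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            raise ValueError(
                f"branch above {edge.head_node} lacks a positive length"
            )
    return tree


def check_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> None:
    """Raise ValueError if root-to-tip depths differ by > rel_tol * depth."""
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    depth = max(depths)
    if depth <= 0:
        raise ValueError("tree has zero depth")
    if max(depths) - min(depths) > rel_tol * depth:
        raise ValueError(
            f"tree is not ultrametric: tip depths span "
            f"[{min(depths):.6g}, {max(depths):.6g}]"
        )


def paint_regimes(tree: dendropy.Tree, focal_tips: set[str]) -> dict:
    """Label every branch focal or background.

    The focal regime is the crown of the monophyletic ``focal_tips`` clade
    plus its stem branch; every other branch is background.  Returns a
    mapping from each non-root node (standing for the branch above it) to
    the regime label.

    Raises ValueError if ``focal_tips`` is not monophyletic on the tree.
    """
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(focal_tips) - taxa
    if missing:
        raise ValueError(f"focal tips absent from tree: {sorted(missing)}")
    if focal_tips == taxa:
        return {
            node: FOCAL
            for node in tree.preorder_node_iter()
            if node.parent_node is not None
        }
    mrca = tree.mrca(taxon_labels=sorted(focal_tips))
    clade_tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if clade_tips != set(focal_tips):
        raise ValueError(
            f"focal tips are not monophyletic: their MRCA also contains "
            f"{sorted(clade_tips - set(focal_tips))}"
        )
    painting = {}
    focal_nodes = set(mrca.preorder_iter())
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        painting[node] = FOCAL if node in focal_nodes else BACKGROUND
    return painting


def regime_path_matrices(
    tree: dendropy.Tree, painting: dict
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-regime shared-path matrices T_f and T_b over the tips.

    Entry [i, j] is the branch length in that regime on the path from the
    root to MRCA(tip_i, tip_j); the diagonal uses the full root-to-tip
    path.  ``T_f + T_b`` is the usual BM phylogenetic covariance
    structure of the tree.
    """
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    t_f = np.zeros((n, n))
    t_b = np.zeros((n, n))

    # Accumulate regime-split depths root->node, then fill each internal
    # node's entry for all tip pairs whose MRCA it is (preorder, so deeper
    # nodes overwrite shallower ones).
    depth_f: dict[int, float] = {id(tree.seed_node): 0.0}
    depth_b: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        f = depth_f[id(node.parent_node)]
        b = depth_b[id(node.parent_node)]
        if painting[node] == FOCAL:
            f += node.edge.length
        else:
            b += node.edge.length
        depth_f[id(node)] = f
        depth_b[id(node)] = b

    for node in tree.preorder_node_iter():
        under = [index[id(leaf)] for leaf in node.leaf_iter()]
        f = depth_f[id(node)]
        b = depth_b[id(node)]
        idx = np.array(under)
        t_f[np.ix_(idx, idx)] = f
        t_b[np.ix_(idx, idx)] = b
    for leaf in leaves:
        i = index[id(leaf)]
        t_f[i, i] = depth_f[id(leaf)]
        t_b[i, i] = depth_b[id(leaf)]
    return labels, t_f, t_b


@dataclass
class BMFit:
    """Result of a per-gene two-regime Brownian-motion fit."""

    sigma2_focal: float
    sigma2_background: float
    root_state: float
    loglik: float
    rate_ratio: float = field(default=math.nan)
    log10_ratio: float = field(default=math.nan)
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags


class TwoRegimeBM:
    """Two-regime BM likelihood machinery for one (tree, painting) pair.

    Precomputes the per-regime path matrices once so that thousands of
    genes can be fit against the same painted tree cheaply.
    """

    def __init__(self, tree: dendropy.Tree, painting: dict):
        check_ultrametric(tree)
        self.tip_labels, self.t_f, self.t_b = regime_path_matrices(tree, painting)
        self.n = len(self.tip_labels)
        if self.n < 2:
            raise ValueError("need at least two tips")
        self._ones = np.ones(self.n)

    # -- likelihood -------------------------------------------------------

    def loglik(self, x: np.ndarray, sigma2_f: float, sigma2_b: float) -> float:
        """Log density of tip values under given rates, root profiled by GLS."""
        if sigma2_f < 0 or sigma2_b < 0 or (sigma2_f == 0 and sigma2_b == 0):
            raise ValueError("rates must be >= 0 and not both zero")
        x = np.asarray(x, dtype=float)
        v = sigma2_f * self.t_f + sigma2_b * self.t_b
        try:
            cho = np.linalg.cholesky(v)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular tip covariance") from exc
        logdet = 2.0 * np.sum(np.log(np.diag(cho)))
        sol = np.linalg.solve(cho, np.column_stack([x, self._ones]))
        xTVix = sol[:, 0] @ sol[:, 0]
        oTVio = sol[:, 1] @ sol[:, 1]
        oTVix = sol[:, 1] @ sol[:, 0]
        mu = oTVix / oTVio
        quad = xTVix - mu * oTVix
        return -0.5 * (self.n * math.log(2.0 * math.pi) + logdet + quad)

    def _profile(self, u: float, x: np.ndarray, reml: bool):
        """Profiled negative criterion at log rate ratio ``u``.

        With r = exp(u), W = r*T_f + T_b; the background rate and root
        state are profiled analytically.  Returns (criterion, sigma2_b,
        mu) where criterion is -2 * profiled log-likelihood up to a
        constant.
        """
        r = math.exp(u)
        w = r * self.t_f + self.t_b
        cho = np.linalg.cholesky(w)
        logdet = 2.0 * np.sum(np.log(np.diag(cho)))
        sol = np.linalg.solve(cho, np.column_stack([x, self._ones]))
        xTWix = sol[:, 0] @ sol[:, 0]
        oTWio = sol[:, 1] @ sol[:, 1]
        oTWix = sol[:, 1] @ sol[:, 0]
        mu = oTWix / oTWio
        quad = max(xTWix - mu * oTWix, 0.0)
        k = self.n - 1 if reml else self.n
        s2b = quad / k
        if s2b <= 0.0:
            return -math.inf, 0.0, mu
        crit = k * math.log(s2b) + logdet
        if reml:
            crit += math.log(oTWio)
        return crit, s2b, mu

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        *,
        reml: bool = True,
        boundary_tol: float = 1e-9,
    ) -> BMFit:
        """Estimate (sigma2_focal, sigma2_background) for one gene.

        The search is a deterministic coarse grid over the log rate ratio
        followed by bounded Brent refinement, which makes it robust to the
        occasional multimodal profile without random restarts.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"expected {self.n} tip values, got {x.shape}")
        n_focal = int(np.sum(np.diag(self.t_f) > 0))
        if n_focal < 2 or self.n - n_focal < 2:
            raise ValueError("rate fitting needs at least two tips per regime")
        if np.ptp(x) == 0.0:
            return BMFit(
                sigma2_focal=0.0,
                sigma2_background=0.0,
                root_state=float(x[0]),
                loglik=math.inf,
                flags=("degenerate_constant",),
            )

        grid = np.linspace(-_LOG_RATIO_BOUND, _LOG_RATIO_BOUND, 25)
        crit = np.array([self._profile(u, x, reml)[0] for u in grid])
        u0 = grid[int(np.argmin(crit))]
        lo = max(u0 - 1.5, -_LOG_RATIO_BOUND)
        hi = min(u0 + 1.5, _LOG_RATIO_BOUND)
        res = optimize.minimize_scalar(
            lambda u: self._profile(u, x, reml)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        u_hat = float(res.x)
        _, s2b, mu = self._profile(u_hat, x, reml)
        r_hat = math.exp(u_hat)
        s2f = r_hat * s2b

        flags = []
        if abs(u_hat) >= _LOG_RATIO_BOUND - 1e-3:
            flags.append("ratio_at_bound")
        scale = float(np.var(x)) / max(np.max(self.t_f + self.t_b), 1.0)
        if s2f <= boundary_tol * max(scale, 1e-300) or s2b <= boundary_tol * max(
            scale, 1e-300
        ):
            flags.append("boundary_rate")
        ll = self.loglik(x, s2f, s2b) if s2f > 0 and s2b > 0 else -math.inf
        return BMFit(
            sigma2_focal=s2f,
            sigma2_background=s2b,
            root_state=mu,
            loglik=ll,
            rate_ratio=r_hat,
            log10_ratio=math.log10(r_hat),
            flags=tuple(flags),
        )

    def fit_many(self, traits: np.ndarray, **kwargs) -> list[BMFit]:
        """Fit each row of a (genes x tips) trait matrix."""
        traits = np.atleast_2d(np.asarray(traits, dtype=float))
        return [self.fit(row, **kwargs) for row in traits]


def bm_loglik(
    x: np.ndarray,
    tree: dendropy.Tree,
    painting: dict,
    sigma2_f: float,
    sigma2_b: float,
) -> float:
    """Two-regime BM log-likelihood (convenience wrapper)."""
    return TwoRegimeBM(tree, painting).loglik(x, sigma2_f, sigma2_b)


def fit_bm_rates(
    x: np.ndarray,
    tree: dendropy.Tree,
    painting: dict,
    *,
    reml: bool = True,
) -> BMFit:
    """Fit two-regime BM rates for one gene (convenience wrapper).

    REML is the default because with nine tips the ML rate estimates are
    noticeably biased downward by the profiled root state; see the
    package methods note.
    """
    return TwoRegimeBM(tree, painting).fit(x, reml=reml)


def length_log_ratio(
    x: dict[str, float] | np.ndarray,
    focal_tips: list[str],
    background_tips: list[str],
    tip_labels: list[str] | None = None,
) -> float:
    """log10(mean focal 3'UTR length / mean background 3'UTR length).

    Raises ValueError when either clade mean is not positive (such genes
    are excluded upstream).
    """
    if isinstance(x, dict):
        values = x
    else:
        if tip_labels is None:
            raise ValueError("tip_labels required when x is an array")
        values = dict(zip(tip_labels, np.asarray(x, dtype=float)))
    mean_f = float(np.mean([values[t] for t in focal_tips]))
    mean_b = float(np.mean([values[t] for t in background_tips]))
    if mean_f <= 0 or mean_b <= 0:
        raise ValueError("clade mean length must be positive")
    return math.log10(mean_f / mean_b)


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float]:
    """Classic one-sample t-test of mean(values) == mu0, two-sided."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(values) == 0.0:
        raise ValueError("zero sample variance")
    res = stats.ttest_1samp(values, popmean=mu0)
    return float(res.statistic), float(res.pvalue)
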