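"""Phylogenetic signal (Pagel's lambda) and lambda-PGLS regression.

Under Brownian motion on a rooted tree, a continuous trait across the
tips is multivariate normal with covariance proportional to C, the matrix
of shared root-to-ancestor path lengths. Pagel's lambda rescales the
off-diagonal of C: lambda = 0 removes all phylogenetic covariance (tips
independent), lambda = 1 is full Brownian motion. Both the signal test
(ML lambda for one trait) and lambda-PGLS (regression whose residual
covariance is sigma^2 C(lambda), with lambda estimated jointly) profile
the mean/coefficients and sigma^2 analytically and search lambda on [0, 1]
by bounded scalar optimization.

Branch lengths can be used as given (divergence times) or set to unity,
which forces change onto branching events (a punctuated view of change).

Trees are handled through dendropy; only rooted trees with positive
branch lengths are accepted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy import optimize, stats

__all__ = [
    "Phylogeny",
    "LambdaEstimate",
    "PGLSFit",
    "read_newick",
    "write_newick",
    "normalize_name",
    "bm_covariance",
    "lambda_transform",
    "fit_lambda_ml",
    "residual_signal_test",
    "pgls_lambda_regression",
    "set_branch_lengths_unity",
]

logger = logging.getLogger(__name__)

_PROFILE_CUTOFF = stats.chi2.ppf(0.95, 1) / 2.0  # 1.92 log-likelihood units


def normalize_name(name: str) -> str:
    """Canonical species-name key: lowercase, whitespace -> underscore."""
    return "_".join(name.strip().lower().split())


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and a branch-length mode flag."""

    tree: dendropy.Tree
    mode: str = "divergence_times"  # or "unity"

    def __post_init__(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None or edge.length <= 0:
                raise ValueError(
                    f"non-positive or missing branch length on edge to "
                    f"{edge.head_node.taxon or 'internal node'}"
                )
        labels = self.taxon_labels
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate taxa after normalization: {sorted(dupes)}")
        if not self.is_ultrametric() and self.mode == "divergence_times":
            logger.warning("tree is not ultrametric in divergence-time mode")

    @property
    def taxon_labels(self) -> List[str]:
        return [normalize_name(leaf.taxon.label) for leaf in self.tree.leaf_node_iter()]

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = [leaf.distance_from_root() for leaf in self.tree.leaf_node_iter()]
        return (max(depths) - min(depths)) <= rel_tol * max(depths)


@dataclass(frozen=True)
class LambdaEstimate:
    """Maximum-likelihood Pagel's lambda for one trait or residual vector."""

    lam: float
    ci: Tuple[float, float]
    log_likelihood: float
    method: str = "profile"
    at_boundary: bool = False


@dataclass(frozen=True)
class PGLSFit:
    """lambda-PGLS regression of y on x with jointly estimated lambda."""

    slope: float
    intercept: float
    slope_ci: Tuple[float, float]
    lambda_estimate: LambdaEstimate
    log_likelihood: float
    sigma2: float


def read_newick(path: str) -> Phylogeny:
    """Read a rooted Newick tree, validating taxa and branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="default-rooted")
    return Phylogeny(tree=tree)


def write_newick(phylogeny: Phylogeny, path: str) -> None:
    phylogeny.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def set_branch_lengths_unity(phylogeny: Phylogeny) -> Phylogeny:
    """Return a copy with every branch length set to 1 (idempotent)."""
    tree = phylogeny.tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = 1.0
    return Phylogeny(tree=tree, mode="unity")


def bm_covariance(phylogeny: Phylogeny) -> Tuple[List[str], np.ndarray]:
    """Brownian-motion covariance: shared root-to-MRCA path lengths.

    Returns the tip labels (normalized, in tree leaf order) and the
    symmetric PSD matrix whose diagonal holds root-to-tip distances.
    """
    tree = phylogeny.tree
    leaves = list(tree.leaf_node_iter())
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    tree.calc_node_root_distances(return_leaf_distances_only=False)

    def collect(node) -> List[int]:
        if node.is_leaf():
            i = index[id(node)]
            C[i, i] = node.root_distance
            return [i]
        depth = node.root_distance or 0.0
        child_sets = [collect(ch) for ch in node.child_nodes()]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        C[i, j] = C[j, i] = depth
        return [i for s in child_sets for i in s]

    collect(tree.seed_node)
    labels = [normalize_name(leaf.taxon.label) for leaf in leaves]
    return labels, C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal covariances by lambda, keep the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def _align(values: Dict[str, float] | Sequence[float], labels: List[str]) -> np.ndarray:
    """Order trait values to the tree's tip labels; hard error on mismatch."""
    if isinstance(values, dict):
        keyed = {normalize_name(k): v for k, v in values.items()}
        missing = [l for l in labels if l not in keyed]
        extra = [k for k in keyed if k not in labels]
        if missing or extra:
            raise ValueError(
                f"taxon mismatch: missing from data {missing}; not in tree {extra}"
            )
        arr = np.array([keyed[l] for l in labels], dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        if len(arr) != len(labels):
            raise ValueError(
                f"{len(arr)} trait values for {len(labels)} tips; pass a dict "
                "keyed by species to align by name"
            )
    if not np.isfinite(arr).all():
        raise ValueError("non-finite trait values")
    return arr


def _gls_profile_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Profile (beta, sigma^2) analytically; return (logL, beta, sigma2_ml)."""
    n = len(y)
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        raise ValueError("degenerate (zero-residual) GLS problem")
    sigma2 = rss / n
    logl = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return logl, beta, sigma2


def _lambda_profile(y, X, C):
    """Return f(lambda) = profile log-likelihood, and the ML point on [0,1]."""

    def logl(lam: float) -> float:
        V = lambda_transform(C, lam)
        return _gls_profile_loglik(y, X, V)[0]

    res = optimize.minimize_scalar(
        lambda lam: -logl(lam), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(logl(0.0), 0.0), (logl(1.0), 1.0), (-res.fun, float(res.x))]
    best_logl, best_lam = max(candidates)
    return logl, best_lam, best_logl


def _profile_ci(logl, lam_hat: float, logl_hat: float) -> Tuple[float, float]:
    """Profile-likelihood CI at the chi2(1) cutoff, clipped to [0, 1]."""
    target = logl_hat - _PROFILE_CUTOFF

    def f(lam: float) -> float:
        return logl(lam) - target

    lo = 0.0
    if lam_hat > 0 and f(0.0) < 0:
        lo = optimize.brentq(f, 0.0, lam_hat, xtol=1e-8)
    hi = 1.0
    if lam_hat < 1 and f(1.0) < 0:
        hi = optimize.brentq(f, lam_hat, 1.0, xtol=1e-8)
    return (lo, hi)


def fit_lambda_ml(
    trait: Dict[str, float] | Sequence[float], phylogeny: Phylogeny
) -> LambdaEstimate:
    """ML Pagel's lambda for one trait on a tree, with profile CI.

    The likelihood is multivariate normal with mean equal to the GLS
    ancestral state and covariance sigma^2 C(lambda); both nuisance
    parameters are profiled analytically at each lambda. Boundary optima
    (0 or 1) are reported as such.
    """
    labels, C = bm_covariance(phylogeny)
    if len(labels) < 4:
        raise ValueError("need at least 4 tips to estimate lambda")
    y = _align(trait, labels)
    if np.ptp(y) == 0:
        raise ValueError("constant trait: lambda is unidentifiable")
    X = np.ones((len(y), 1))
    logl, lam_hat, logl_hat = _lambda_profile(y, X, C)
    ci = _profile_ci(logl, lam_hat, logl_hat)
    return LambdaEstimate(
        lam=lam_hat, ci=ci, log_likelihood=logl_hat,
        at_boundary=lam_hat in (0.0, 1.0),
    )


def residual_signal_test(
    y: Dict[str, float] | Sequence[float],
    x: Dict[str, float] | Sequence[float],
    phylogeny: Phylogeny,
) -> LambdaEstimate:
    """Phylogenetic signal in the residuals of a non-phylogenetic fit.

    Fits ordinary least squares of y on x across species, then estimates
    lambda for the residual vector. Signal is significant when the CI
    excludes 0.
    """
    labels, _ = bm_covariance(phylogeny)
    yv = _align(y, labels)
    xv = _align(x, labels)
    X = np.column_stack([np.ones_like(xv), xv])
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    if np.ptp(resid) < 1e-12:
        raise ValueError("residuals are constant; signal test is degenerate")
    return fit_lambda_ml(dict(zip(labels, resid)), phylogeny)


def pgls_lambda_regression(
    y: Dict[str, float] | Sequence[float],
    x: Dict[str, float] | Sequence[float],
    phylogeny: Phylogeny,
    lam: Optional[float] = None,
) -> PGLSFit:
    """Regression of y on x with residual covariance sigma^2 C(lambda).

    lambda is estimated by ML jointly with the coefficients unless pinned
    via ``lam`` (``lam=0`` reduces exactly to OLS, ``lam=1`` to Brownian
    GLS). The slope CI is t-based from the GLS coefficient covariance at
    the estimated lambda, with n - 2 degrees of freedom.
    """
    labels, C = bm_covariance(phylogeny)
    yv = _align(y, labels)
    xv = _align(x, labels)
    n = len(yv)
    X = np.column_stack([np.ones_like(xv), xv])
    if np.ptp(xv) == 0:
        raise ValueError("singular design: x is constant")

    if lam is not None:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        lam_hat = float(lam)
        V = lambda_transform(C, lam_hat)
        logl_hat = _gls_profile_loglik(yv, X, V)[0]
        lam_ci = (lam_hat, lam_hat)
        at_boundary = lam_hat in (0.0, 1.0)
    else:
        logl, lam_hat, logl_hat = _lambda_profile(yv, X, C)
        lam_ci = _profile_ci(logl, lam_hat, logl_hat)
        at_boundary = lam_hat in (0.0, 1.0)

    V = lambda_transform(C, lam_hat)
    _, beta, sigma2_ml = _gls_profile_loglik(yv, X, V)
    # unbiased residual variance for the coefficient covariance
    sigma2 = sigma2_ml * n / (n - 2)
    L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, X)
    cov_beta = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se_slope = math.sqrt(cov_beta[1, 1])
    tcrit = stats.t.ppf(0.975, n - 2)
    slope = float(beta[1])
    return PGLSFit(
        slope=slope,
        intercept=float(beta[0]),
        slope_ci=(slope - tcrit * se_slope, slope + tcrit * se_slope),
        lambda_estimate=LambdaEstimate(
            lam=lam_hat, ci=lam_ci, log_likelihood=logl_hat,
            at_boundary=at_boundary,
        ),
        log_likelihood=logl_hat,
        sigma2=sigma2_ml,
    )
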