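"""Semiparametric Gaussian copula graphical model estimation.

The latent Gaussian correlation matrix is estimated from ranks via the
nonparanormal "skeptic" sine transforms — 2 sin(pi rho / 6) of Spearman's
rho, or sin(pi tau / 2) of Kendall's tau-b — then a sparse precision matrix
is fitted by the graphical lasso with the penalty chosen by k-fold
cross-validated held-out Gaussian log-likelihood. Edges of the resulting
network are partial correlations -w_ij / sqrt(w_ii w_jj).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import warnings

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

STRONG_PCOR = 0.30  # |partial correlation| at or above this counts as strong
MIN_NETWORK_SIZE = 3  # a "network" is a connected component of >= 3 groups

__all__ = [
    "SkepticCorrelation",
    "GlassoFit",
    "CVPath",
    "PartialCorrelationNetwork",
    "Edge",
    "rank_correlation_matrix",
    "skeptic_transform",
    "nearest_psd_correlation",
    "glasso_fit",
    "cv_select_lambda",
    "partial_correlations",
    "estimate_network",
    "GlassoConvergenceError",
]


class GlassoConvergenceError(RuntimeError):
    def __init__(self, residual: float, lam: float):
        self.residual = residual
        self.lam = lam
        super().__init__(
            f"graphical lasso did not reach the KKT tolerance at lambda={lam:g} "
            f"(residual {residual:.3e})"
        )


@dataclass
class SkepticCorrelation:
    """Rank-based latent correlation estimate, PSD-corrected if needed."""

    matrix: np.ndarray
    method: str
    n_obs: int
    psd_corrected: bool
    min_eigenvalue_before_correction: float
    constant_columns: tuple[int, ...] = ()


@dataclass
class GlassoFit:
    precision: np.ndarray
    covariance: np.ndarray
    lam: float
    objective: float
    kkt_residual: float
    n_iter: int


@dataclass
class CVPath:
    lambdas: np.ndarray  # strictly decreasing
    fold_losses: np.ndarray  # k x len(lambdas)
    mean_losses: np.ndarray
    lambda_star: float  # selected penalty (per the selection rule)
    seed: int
    n_folds: int
    selection_rule: str = "1se"
    lambda_min: float = float("nan")  # argmin of the mean loss
    edge_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.lambdas) < 0):
            raise ValueError("lambda grid must be strictly decreasing")


@dataclass(frozen=True)
class Edge:
    u: str
    v: str
    pcor: float
    strong: bool


@dataclass
class PartialCorrelationNetwork:
    """Signed weighted conditional-dependence graph over food groups."""

    nodes: tuple[str, ...]
    pcor_matrix: np.ndarray
    edges: tuple[Edge, ...]
    components: tuple[frozenset[str], ...]
    networks: tuple[frozenset[str], ...]  # components with >= MIN_NETWORK_SIZE nodes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def network_nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for comp in self.networks:
            out |= comp
        return frozenset(out)

    def to_graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        for e in self.edges:
            G.add_edge(e.u, e.v, pcor=float(e.pcor), strong=bool(e.strong))
        return G


def rank_correlation_matrix(X: np.ndarray, method: str = "spearman"
                            ) -> tuple[np.ndarray, tuple[int, ...]]:
    """Raw rank correlation matrix with tie handling.

    Spearman uses mid-ranks; Kendall uses tie-adjusted tau-b. Columns with
    zero variance are flagged and given correlation 0 with all others.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d matrix with at least 2 rows")
    n, p = X.shape
    const = tuple(int(j) for j in range(p) if np.ptp(X[:, j]) == 0)
    if len(const) == p:
        raise ValueError("all columns are constant; no correlation estimable")
    if method == "spearman":
        ranks = stats.rankdata(X, axis=0)  # mid-ranks under ties
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(ranks, rowvar=False)
        R = np.where(np.isfinite(R), R, 0.0)
    elif method == "kendall":
        R = np.eye(p)
        live = [j for j in range(p) if j not in const]
        for a_idx, j in enumerate(live):
            for k in live[a_idx + 1:]:
                tau = stats.kendalltau(X[:, j], X[:, k]).statistic  # tau-b
                if not np.isfinite(tau):
                    tau = 0.0
                R[j, k] = R[k, j] = tau
    else:
        raise ValueError(f"unknown rank method {method!r}")
    np.fill_diagonal(R, 1.0)
    return R, const


def nearest_psd_correlation(S: np.ndarray, eigenvalue_floor: float = 1e-4
                            ) -> np.ndarray:
    """Clip eigenvalues at the floor and rescale to unit diagonal.

    Returned unchanged when the floor is already satisfied. Rescaling can
    nudge the spectrum, so clipping is repeated until the floor holds.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    out = (S + S.T) / 2.0
    for _ in range(100):
        w = np.linalg.eigvalsh(out)
        if w[0] >= eigenvalue_floor * (1.0 - 1e-9):
            return out if _ > 0 else S
        w_full, V = np.linalg.eigh(out)
        out = (V * np.maximum(w_full, eigenvalue_floor)) @ V.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 1.0)
    return out


def spearman_to_latent(rho):
    """Sine map 2 sin(pi rho / 6): Spearman's rho -> latent Gaussian correlation."""
    return 2.0 * np.sin(np.pi * np.asarray(rho, dtype=float) / 6.0)


def kendall_to_latent(tau):
    """Sine map sin(pi tau / 2): Kendall's tau -> latent Gaussian correlation."""
    return np.sin(np.pi * np.asarray(tau, dtype=float) / 2.0)


def skeptic_transform(R: np.ndarray, method: str, n_obs: int = 0,
                      constant_columns: tuple[int, ...] = (),
                      eigenvalue_floor: float = 1e-4) -> SkepticCorrelation:
    """Sine maps of rank correlations onto the latent Gaussian scale."""
    R = np.asarray(R, dtype=float)
    if method == "spearman":
        S = spearman_to_latent(R)
    elif method == "kendall":
        S = kendall_to_latent(R)
    else:
        raise ValueError(f"unknown rank method {method!r}")
    np.fill_diagonal(S, 1.0)
    min_eig = float(np.linalg.eigvalsh((S + S.T) / 2.0)[0])
    corrected = min_eig < eigenvalue_floor
    if corrected:
        S = nearest_psd_correlation(S, eigenvalue_floor)
    return SkepticCorrelation(
        matrix=S, method=method, n_obs=int(n_obs),
        psd_corrected=corrected, min_eigenvalue_before_correction=min_eig,
        constant_columns=constant_columns,
    )


def skeptic_from_data(X: np.ndarray, method: str = "spearman",
                      eigenvalue_floor: float = 1e-4) -> SkepticCorrelation:
    R, const = rank_correlation_matrix(X, method)
    return skeptic_transform(R, method, n_obs=X.shape[0],
                             constant_columns=const,
                             eigenvalue_floor=eigenvalue_floor)


def _kkt_residual(S: np.ndarray, precision: np.ndarray,
                  covariance: np.ndarray, lam: float) -> float:
    """Max violation of the off-diagonal-penalty stationarity conditions."""
    p = S.shape[0]
    diff = covariance - S
    off = ~np.eye(p, dtype=bool)
    active = (precision != 0) & off
    inactive = (~active) & off
    res = 0.0
    if active.any():
        res = max(res, float(np.max(np.abs(
            diff[active] - lam * np.sign(precision[active])))))
    if inactive.any():
        res = max(res, float(np.max(np.abs(diff[inactive]) - lam)))
    res = max(res, float(np.max(np.abs(np.diag(diff)))))
    return max(res, 0.0)


_CDBreakdown = FloatingPointError  # raised by coordinate descent on non-SPD iterates


def _cd_glasso(Smat: np.ndarray, lam: float, solver_tol: float = 1e-10,
               max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, int]:
    """Coordinate-descent glasso; raises ``_CDBreakdown`` when the solver
    cannot keep its iterates positive definite."""
    with warnings.catch_warnings():
        # the solver's own stopping diagnostics are advisory here: the KKT
        # residual is the binding convergence contract
        warnings.simplefilter("ignore", ConvergenceWarning)
        cov, prec, costs, n_iter = _sk_graphical_lasso(
            Smat, alpha=lam, tol=solver_tol, enet_tol=1e-12,
            max_iter=max_iter, return_costs=True, return_n_iter=True,
        )
    return cov, prec, n_iter


def _admm_glasso(S: np.ndarray, lam: float, rho: float = 1.0,
                 max_iter: int = 20000, kkt_stop: float = 5e-6,
                 warm: tuple[np.ndarray, np.ndarray, float] | None = None
                 ) -> tuple[np.ndarray, np.ndarray, int, tuple]:
    """Glasso by ADMM with residual-balancing rho; eigen-decomposition
    based, so it stays stable on near-singular input matrices where
    coordinate descent can fail. Stops once the KKT residual of the
    sparse iterate drops below ``kkt_stop``. ``warm`` carries (Z, U, rho)
    from a neighbouring penalty for path-wise warm starts."""
    p = len(S)
    if warm is not None:
        Z, U, rho = warm[0].copy(), warm[1].copy(), warm[2]
    else:
        Z = np.linalg.inv(S + 0.1 * np.eye(p))
        U = np.zeros((p, p))
    for it in range(max_iter):
        d, Q = np.linalg.eigh(rho * (Z - U) - S)
        om = (d + np.sqrt(d * d + 4.0 * rho)) / (2.0 * rho)
        Omega = (Q * om) @ Q.T
        Z_old = Z
        A = Omega + U
        Z = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(A))
        U = U + Omega - Z
        r = np.linalg.norm(Omega - Z)
        s = rho * np.linalg.norm(Z - Z_old)
        if (it + 1) % 25 == 0 or (r < 1e-10 and s < 1e-10):
            prec = (Z + Z.T) / 2.0
            if np.linalg.eigvalsh(prec)[0] > 0:
                cov = np.linalg.inv(prec)
                if _kkt_residual(S, prec, cov, lam) < kkt_stop:
                    return cov, prec, it + 1, (Z, U, rho)
        if r > 10.0 * s and rho < 1e6:
            rho *= 2.0
            U /= 2.0
        elif s > 10.0 * r and rho > 1e-6:
            rho /= 2.0
            U *= 2.0
    prec = (Z + Z.T) / 2.0
    cov = np.linalg.inv((Omega + Omega.T) / 2.0)
    return cov, prec, it + 1, (Z, U, rho)


def glasso_fit(S: SkepticCorrelation | np.ndarray, lam: float,
               max_iter: int = 500, solver_tol: float = 1e-10,
               kkt_tol: float = 1e-5) -> GlassoFit:
    """L1-penalised precision estimation (off-diagonal penalty).

    Maximises log det(O) - tr(S O) - lam * sum_{i != j} |o_ij|. The
    contract checked is the KKT system: |sigma_ij - s_ij| <= lam off the
    support and = lam with consistent sign on it. Coordinate descent is
    used first; if it breaks down (tiny penalty on a near-singular
    matrix), the ADMM solver of the same objective takes over.
    """
    if lam <= 0:
        raise ValueError("penalty must be positive")
    Smat = S.matrix if isinstance(S, SkepticCorrelation) else np.asarray(S, float)
    try:
        cov, prec, n_iter = _cd_glasso(Smat, float(lam), solver_tol, max_iter)
    except _CDBreakdown:
        cov, prec, n_iter, _ = _admm_glasso(Smat, float(lam))
    prec = (prec + prec.T) / 2.0
    residual = _kkt_residual(Smat, prec, cov, lam)
    if residual > kkt_tol:
        raise GlassoConvergenceError(residual, lam)
    sign, logdet = np.linalg.slogdet(prec)
    off = ~np.eye(len(Smat), dtype=bool)
    objective = float(logdet - np.trace(Smat @ prec) - lam * np.abs(prec[off]).sum())
    return GlassoFit(precision=prec, covariance=cov, lam=float(lam),
                     objective=objective, kkt_residual=residual, n_iter=n_iter)


def default_lambda_grid(S: np.ndarray, n_lambda: int = 30,
                        min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced descending grid from lambda_max = max off-diagonal |s|."""
    off = ~np.eye(len(S), dtype=bool)
    lam_max = float(np.max(np.abs(S[off])))
    if lam_max <= 0:
        lam_max = 1e-2
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _holdout_loss(S_test: np.ndarray, precision: np.ndarray) -> float:
    """Gaussian negative log-likelihood (up to constants) of held-out data."""
    sign, logdet = np.linalg.slogdet(precision)
    return float(np.trace(S_test @ precision) - logdet)


def cv_select_lambda(X: np.ndarray, method: str = "spearman",
                     lambdas: np.ndarray | None = None, k: int = 10,
                     seed: int = 0, n_lambda: int = 30,
                     lambda_min_ratio: float = 0.01,
                     eigenvalue_floor: float = 1e-4,
                     selection_rule: str = "1se") -> CVPath:
    """Tenfold (by default) cross-validated penalty selection.

    Per fold the skeptic matrix is re-estimated on the training rows, a
    glasso path is fitted over the descending grid, and the held-out loss
    tr(S_test O) - log det O is scored on the fold's own skeptic matrix.
    Losses tie toward the larger (sparser) penalty: under the default
    "1se" rule, losses within one standard error of the minimum count as
    tied, so the selected penalty is the largest one statistically
    indistinguishable from the optimum (plain CV-min of the Gaussian
    likelihood is known to overselect edges); ``selection_rule="min"``
    gives the exact-argmin variant.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k > n:
        raise ValueError(f"cannot split n={n} rows into k={k} folds")
    if k < 2:
        raise ValueError("need at least 2 folds")
    if lambdas is None:
        S_full = skeptic_from_data(X, method, eigenvalue_floor).matrix
        lambdas = default_lambda_grid(S_full, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    fold_losses = np.zeros((k, len(lambdas)))
    edge_counts = np.zeros((k, len(lambdas)), dtype=int)
    off = ~np.eye(p, dtype=bool)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        S_train = skeptic_from_data(X[train_idx], method, eigenvalue_floor)
        if S_train.constant_columns:
            logger.warning("fold %d: constant columns %s; using corrected matrix",
                           f, S_train.constant_columns)
        S_test = skeptic_from_data(X[test_idx], method, eigenvalue_floor)
        # ADMM state carried down the path; once coordinate descent breaks
        # on a fold (ill-conditioning only worsens as lambda shrinks) the
        # remaining path is fitted by warm-started ADMM directly
        warm, cd_alive = None, True
        for li, lam in enumerate(lambdas):
            prec = None
            if cd_alive:
                try:
                    cov, prec, _ = _cd_glasso(S_train.matrix, float(lam),
                                              solver_tol=1e-8, max_iter=200)
                    if _kkt_residual(S_train.matrix, prec, cov, float(lam)) > 1e-5:
                        prec = None
                except _CDBreakdown:
                    pass
                if prec is None:
                    cd_alive = False
                else:
                    warm = (prec, cov - S_train.matrix, 1.0)
            if prec is None:
                cov, prec, _, warm = _admm_glasso(S_train.matrix, float(lam),
                                                  warm=warm)
            fold_losses[f, li] = _holdout_loss(S_test.matrix, prec)
            edge_counts[f, li] = int((prec[off] != 0).sum() // 2)
    mean_losses = fold_losses.mean(axis=0)
    best = int(np.argmin(mean_losses))  # first = largest lambda on exact ties
    if selection_rule == "min":
        chosen = best
    elif selection_rule == "1se":
        se = float(fold_losses[:, best].std(ddof=1)) / np.sqrt(k)
        within = np.nonzero(mean_losses <= mean_losses[best] + se)[0]
        chosen = int(within.min())  # grid descends: min index = largest lambda
    else:
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    return CVPath(lambdas=lambdas, fold_losses=fold_losses,
                  mean_losses=mean_losses, lambda_star=float(lambdas[chosen]),
                  seed=seed, n_folds=k, selection_rule=selection_rule,
                  lambda_min=float(lambdas[best]), edge_counts=edge_counts)


def partial_correlations(fit: GlassoFit, nodes: tuple[str, ...] | list[str],
                         zero_tol: float = 1e-8,
                         strong_threshold: float = STRONG_PCOR
                         ) -> PartialCorrelationNetwork:
    """Network extraction: pcor_ij = -w_ij / sqrt(w_ii w_jj).

    Edges exist wherever the precision entry is nonzero beyond the exact
    zero tolerance; |pcor| >= 0.30 flags a strong relation; connected
    components with >= 3 food groups count as networks.
    """
    omega = fit.precision
    nodes = tuple(nodes)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    edges = []
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if abs(pcor[i, j]) > zero_tol:
                val = float(pcor[i, j])
                edges.append(Edge(nodes[i], nodes[j], val,
                                  abs(val) >= strong_threshold))
                G.add_edge(nodes[i], nodes[j])
    components = tuple(frozenset(c) for c in
                       sorted(nx.connected_components(G), key=lambda c: sorted(c)[0]))
    networks = tuple(c for c in components if len(c) >= MIN_NETWORK_SIZE)
    return PartialCorrelationNetwork(
        nodes=nodes, pcor_matrix=pcor, edges=tuple(edges),
        components=components, networks=networks,
    )


@dataclass
class NetworkEstimate:
    """Bundle of every estimation stage for one intake table."""

    skeptic: SkepticCorrelation
    cv: CVPath
    fit: GlassoFit
    network: PartialCorrelationNetwork


def estimate_network(X: np.ndarray, nodes: tuple[str, ...] | list[str],
                     method: str = "spearman", k: int = 10, seed: int = 0,
                     lambdas: np.ndarray | None = None,
                     n_lambda: int = 30, lambda_min_ratio: float = 0.01,
                     eigenvalue_floor: float = 1e-4,
                     selection_rule: str = "1se") -> NetworkEstimate:
    """Full SGCGM pass on one observation matrix."""
    skeptic = skeptic_from_data(X, method, eigenvalue_floor)
    cv = cv_select_lambda(X, method, lambdas=lambdas, k=k, seed=seed,
                          n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
                          eigenvalue_floor=eigenvalue_floor,
                          selection_rule=selection_rule)
    fit = glasso_fit(skeptic, cv.lambda_star)
    network = partial_correlations(fit, nodes)
    return NetworkEstimate(skeptic=skeptic, cv=cv, fit=fit, network=network)
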