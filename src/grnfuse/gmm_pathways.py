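"""Soft-clustering of genes into regulatory pathways with a Gaussian mixture.

Genes are treated as i.i.d. draws from a finite mixture of multivariate
Gaussians over the J experiments; a pathway is one mixture component, and a
gene's posterior responsibilities tau[i, l] are its soft pathway
memberships.  The number of pathways L is selected automatically by
component-wise EM under a minimum-message-length (MML) criterion: fitting
starts at L_max and repeatedly annihilates the smallest mixture component,
keeping the model with the smallest message length.

The same EM engine accepts an optional Markov-random-field prior over gene
assignments (a score matrix C coupling neighbouring genes), which turns the
plain mixture into the hidden-Markov-model variant used for fusing
protein-interaction evidence; see :mod:`grnfuse.ghmm_fusion`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .io_formats import ExpressionMatrix, ScoredNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GmmParameters",
    "MembershipMatrix",
    "MmlTrace",
    "e_step",
    "m_step",
    "fit_gmm_cem",
    "co_membership",
]

#: smallest variance allowed on any coordinate of a diagonal covariance
VAR_FLOOR = 1e-6
#: pseudo-observations of the global variance blended into each component's
#: variance (a weakly supported component cannot collapse its variance)
VAR_PSEUDO_OBS = 1.0
#: fraction of raw mass a starving component keeps while awaiting its turn
STARVE_FLOOR = 0.1
#: additive ridge lambda*I applied to full covariances
FULL_COV_SHRINKAGE = 1e-3


@dataclass
class GmmParameters:
    """Mixture weights, means and (diagonal or full) covariances for L pathways.

    ``covariances`` is (L, J) for diagonal covariances and (L, J, J) for
    full ones. ``dirichlet_alphas`` are the (uniform) Dirichlet prior
    weights on the mixture proportions; with alpha = 1 they add no
    smoothing beyond the MML penalty.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    covariance_type: str = "diag"
    dirichlet_alphas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.dirichlet_alphas is None:
            self.dirichlet_alphas = np.ones(self.L)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError(f"mixture weights sum to {self.weights.sum()}, not 1")
        if self.covariance_type not in ("diag", "full"):
            raise ValueError("covariance_type must be 'diag' or 'full'")
        diag = self.covariances if self.covariance_type == "diag" else np.array(
            [np.diag(S) for S in self.covariances]
        )
        if np.any(diag <= 0):
            raise ValueError("every covariance must have strictly positive diagonal")

    @property
    def L(self) -> int:
        return len(self.weights)

    @property
    def J(self) -> int:
        return self.means.shape[1]


@dataclass
class MembershipMatrix:
    """Soft pathway memberships tau (genes x pathways); rows sum to one."""

    tau: np.ndarray
    gene_ids: list[str]
    pathway_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if not self.pathway_ids:
            self.pathway_ids = [f"pathway_{l}" for l in range(self.tau.shape[1])]
        if self.tau.shape != (len(self.gene_ids), len(self.pathway_ids)):
            raise ValueError("tau shape does not match labels")
        if np.any(self.tau < -1e-12) or np.any(self.tau > 1 + 1e-9):
            raise ValueError("memberships must lie in [0, 1]")
        if not np.allclose(self.tau.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("membership rows must sum to 1")

    @property
    def L(self) -> int:
        return self.tau.shape[1]

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.tau, axis=1)


@dataclass
class MmlTrace:
    """(L, message length, log-likelihood) per outer component-annihilation step."""

    records: list[tuple[int, float, float]] = field(default_factory=list)

    def append(self, L: int, mml: float, loglik: float) -> None:
        self.records.append((int(L), float(mml), float(loglik)))

    def best(self) -> tuple[int, float, float]:
        return min(self.records, key=lambda r: r[1])

    def visited_L(self) -> list[int]:
        return [r[0] for r in self.records]


def _log_gaussian(X: np.ndarray, params: GmmParameters) -> np.ndarray:
    """log N(x_i; mu_l, Sigma_l) for all genes and components, shape (I, L)."""
    I, J = X.shape
    out = np.empty((I, params.L))
    if params.covariance_type == "diag":
        for l in range(params.L):
            var = params.covariances[l]
            if np.any(var <= 0):
                raise np.linalg.LinAlgError(
                    "singular diagonal covariance; raise the variance floor"
                )
            diff = X - params.means[l]
            out[:, l] = -0.5 * (
                J * np.log(2 * np.pi) + np.sum(np.log(var)) + np.sum(diff**2 / var, axis=1)
            )
    else:
        for l in range(params.L):
            S = params.covariances[l]
            try:
                chol = np.linalg.cholesky(S)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "singular covariance matrix; increase the shrinkage ridge"
                ) from err
            diff = X - params.means[l]
            sol = np.linalg.solve(chol, diff.T)
            logdet = 2 * np.sum(np.log(np.diag(chol)))
            out[:, l] = -0.5 * (J * np.log(2 * np.pi) + logdet + np.sum(sol**2, axis=0))
    return out


def _log_responsibilities(X: np.ndarray, params: GmmParameters) -> tuple[np.ndarray, float]:
    """Normalized log tau and the observed-data log-likelihood."""
    logp = _log_gaussian(X, params) + np.log(params.weights)
    norm = logsumexp(logp, axis=1, keepdims=True)
    return logp - norm, float(np.sum(norm))


def e_step(X: ExpressionMatrix, params: GmmParameters) -> MembershipMatrix:
    """Posterior pathway responsibilities under the current parameters.

    Computed in log space so that genes far from every component never
    underflow to an all-zero row.
    """
    log_tau, _ = _log_responsibilities(X.values, params)
    return MembershipMatrix(tau=np.exp(log_tau), gene_ids=list(X.gene_ids))


def m_step(
    X: ExpressionMatrix,
    tau: MembershipMatrix,
    covariance_type: str = "diag",
) -> GmmParameters:
    """Weighted reestimation of mixture weights, means and covariances.

    A component whose total responsibility is zero is flagged by returning a
    zero weight for it (the caller annihilates it); it never produces NaNs.
    """
    T = tau.tau
    Xv = X.values
    I, J = Xv.shape
    L = T.shape[1]
    mass = T.sum(axis=0)
    weights = mass / I
    means = np.zeros((L, J))
    if covariance_type == "diag":
        covs = np.ones((L, J))
    else:
        covs = np.stack([np.eye(J)] * L)
    for l in range(L):
        if mass[l] <= 0:
            logger.warning("component %d has zero responsibility; flagged for annihilation", l)
            weights[l] = 0.0
            continue
        means[l] = T[:, l] @ Xv / mass[l]
        diff = Xv - means[l]
        if covariance_type == "diag":
            covs[l] = np.maximum(T[:, l] @ diff**2 / mass[l], VAR_FLOOR)
        else:
            S = (T[:, l, None] * diff).T @ diff / mass[l]
            covs[l] = S + FULL_COV_SHRINKAGE * np.eye(J)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all components empty")
    return GmmParameters(
        weights=weights / total, means=means, covariances=covs,
        covariance_type=covariance_type,
    )


def _free_params_per_component(J: int, covariance_type: str) -> int:
    return 2 * J if covariance_type == "diag" else J + J * (J + 1) // 2


def mml_criterion(loglik: float, weights: np.ndarray, I: int, J: int,
                  covariance_type: str = "diag") -> float:
    """Message length of the fitted mixture (smaller is better).

    Standard component-wise-EM form: the data log-likelihood penalized by
    (P/2) sum_l log(I*theta_l/12) + (L/2) log(I/12) + L(P+1)/2 with P free
    parameters per component.
    """
    w = weights[weights > 0]
    L = len(w)
    P = _free_params_per_component(J, covariance_type)
    penalty = (P / 2) * np.sum(np.log(I * w / 12.0)) + (L / 2) * np.log(I / 12.0) + L * (P + 1) / 2
    return float(penalty - loglik)


def _init_params(Xv: np.ndarray, L: int, seed: int, covariance_type: str) -> GmmParameters:
    """k-means seeding; all stochastic behaviour flows from the one seed."""
    I, J = Xv.shape
    km = KMeans(n_clusters=L, n_init=10, random_state=seed).fit(Xv)
    labels = km.labels_
    weights = np.array([max(np.sum(labels == l), 1) for l in range(L)], dtype=float)
    weights /= weights.sum()
    means = km.cluster_centers_.copy()
    gvar = np.maximum(Xv.var(axis=0), VAR_FLOOR)
    cvars = []
    for l in range(L):
        pts = Xv[labels == l]
        cvars.append(np.maximum(pts.var(axis=0), VAR_FLOOR) if len(pts) >= 2 else gvar)
    if covariance_type == "diag":
        covs = np.stack(cvars)
    else:
        covs = np.stack([np.diag(v) + FULL_COV_SHRINKAGE * np.eye(J) for v in cvars])
    return GmmParameters(weights=weights, means=means, covariances=covs,
                         covariance_type=covariance_type)


def _drop_component(params: GmmParameters, idx: int) -> GmmParameters:
    keep = [l for l in range(params.L) if l != idx]
    w = params.weights[keep]
    return GmmParameters(
        weights=w / w.sum(),
        means=params.means[keep],
        covariances=params.covariances[keep],
        covariance_type=params.covariance_type,
    )


def _field_penalty(C: np.ndarray, tau_prev: np.ndarray) -> np.ndarray:
    """Log-domain MRF term sum_{j != i} -C_ij (1 - tau_jl), shape (I, L).

    C must have a zero diagonal so the i = j term vanishes.
    """
    row_mass = C.sum(axis=1, keepdims=True)
    return C @ tau_prev - row_mass


def _cem_fit(
    Xv: np.ndarray,
    gene_ids: list[str],
    L_max: int,
    L_min: int,
    seed: int,
    tol: float,
    covariance_type: str,
    field_C: np.ndarray | None,
    max_em_iter: int = 300,
) -> tuple[GmmParameters, MembershipMatrix, MmlTrace]:
    """Component-wise EM with MML model selection, optionally field-regularized.

    Runs EM to convergence at the current L, records the message length,
    annihilates the smallest component, and repeats until the message
    length stabilizes or L falls below L_min; returns the best model seen.
    """
    I, J = Xv.shape
    if L_min < 1 or L_max < L_min:
        raise ValueError("need 1 <= L_min <= L_max")
    if L_max > I:
        raise ValueError(f"L_max={L_max} exceeds the number of genes I={I}")

    params = _init_params(Xv, L_max, seed, covariance_type)
    tau_prev = None  # previous-iteration memberships for the field term
    trace = MmlTrace()
    best: tuple[float, GmmParameters, np.ndarray] | None = None
    prev_mml = np.inf
    P = _free_params_per_component(J, covariance_type)
    prior_var = np.maximum(Xv.var(axis=0), VAR_FLOOR)

    def _responsibilities(p: GmmParameters) -> tuple[np.ndarray, float]:
        nonlocal tau_prev
        with np.errstate(divide="ignore"):
            log_tau, ll = _log_responsibilities(Xv, p)
        if field_C is not None:
            prev = (np.exp(log_tau) if tau_prev is None or tau_prev.shape[1] != p.L
                    else tau_prev)
            log_u = log_tau + _field_penalty(field_C, prev)
            log_tau = log_u - logsumexp(log_u, axis=1, keepdims=True)
        tau = np.exp(log_tau)
        tau_prev = tau
        return tau, ll

    def _cem_sweep(p: GmmParameters, penalize: bool) -> GmmParameters:
        """One component-wise sweep: per component, E-step then its M-step
        with the MML-penalized weight update; a component whose penalized
        weight vanishes at its own turn is annihilated on the spot."""
        nonlocal tau_prev
        l = 0
        killed = False  # at most one starvation kill per sweep, smallest first
        while l < p.L:
            tau, _ = _responsibilities(p)
            mass = tau.sum(axis=0)
            if mass[l] <= 0 and p.L > max(L_min, 1):
                logger.info("annihilating empty component %d", l)
                p = _drop_component(p, l)
                tau_prev = None
                continue
            means = p.means.copy()
            covs = p.covariances.copy()
            means[l] = tau[:, l] @ Xv / mass[l]
            diff = Xv - means[l]
            if covariance_type == "diag":
                s2 = tau[:, l] @ diff**2 / mass[l]
                # MAP variance with one pseudo-observation of the global
                # variance: a weakly supported component cannot collapse
                # its variance and fake a likelihood gain
                covs[l] = np.maximum(
                    (mass[l] * s2 + VAR_PSEUDO_OBS * prior_var)
                    / (mass[l] + VAR_PSEUDO_OBS), VAR_FLOOR)
            else:
                S = (tau[:, l, None] * diff).T @ diff / mass[l]
                S = (mass[l] * S + VAR_PSEUDO_OBS * np.diag(prior_var)) / (
                    mass[l] + VAR_PSEUDO_OBS)
                covs[l] = S + FULL_COV_SHRINKAGE * np.eye(J)
            # penalized weights: a component's mass is discounted by P/2
            # (the message cost of its parameters); a component whose
            # discounted mass hits zero at its own turn is annihilated.
            # Inapplicable when every component starves (I small vs P):
            # plain weights apply and selection rests on the criterion.
            adj = np.maximum(mass - P / 2.0, 0.0)
            if penalize and adj.sum() > 0 and np.count_nonzero(adj) >= max(L_min, 1):
                if (adj[l] <= 0 and p.L > max(L_min, 1) and not killed
                        and mass[l] <= mass.min() + 1e-9):
                    logger.info("annihilating starved component %d (mass %.2f)",
                                l, mass[l])
                    p = _drop_component(p, l)
                    tau_prev = None
                    killed = True
                    continue
                # other starving components are suppressed, not zeroed:
                # their mass drains gradually until their own turn comes
                weights = np.maximum(adj, STARVE_FLOOR * mass)
            else:
                weights = mass
            p = GmmParameters(weights=weights / weights.sum(), means=means,
                              covariances=covs, covariance_type=covariance_type)
            l += 1
        return p

    warmup_sweeps = 3  # plain EM sweeps before the weight penalty engages
    first_round = True
    while True:
        prev_ll = -np.inf
        for sweep in range(max_em_iter):
            penalize = not (first_round and sweep < warmup_sweeps)
            params = _cem_sweep(params, penalize)
            _, ll = _log_responsibilities(Xv, params)
            if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
                break
            prev_ll = ll
        first_round = False

        tau, ll = _responsibilities(params)
        mml = mml_criterion(ll, params.weights, I, J, covariance_type)
        trace.append(params.L, mml, ll)
        if best is None or mml < best[0]:
            best = (mml, params, tau)

        if abs(mml - prev_mml) < tol * max(1.0, abs(mml)) or params.L <= L_min:
            break
        prev_mml = mml
        # force exploration of a smaller L: annihilate the smallest component
        params = _drop_component(params, int(np.argmin(params.weights)))
        tau_prev = None

    _, best_params, best_tau = best
    # polish at the selected L with plain (unpenalized) EM: the discounted
    # weight normalization used during annihilation biases assignment
    # boundaries slightly and is not part of the final model
    params = best_params
    tau_prev = best_tau if field_C is not None else None
    prev_ll = -np.inf
    for _ in range(max_em_iter):
        tau, ll = _responsibilities(params)
        mass = tau.sum(axis=0)
        if np.any(mass <= 0):
            break  # degenerate polish step; keep the pre-polish model
        means = (tau.T @ Xv) / mass[:, None]
        if covariance_type == "diag":
            covs = np.empty_like(params.covariances)
            for l in range(params.L):
                diff = Xv - means[l]
                s2 = tau[:, l] @ diff**2 / mass[l]
                covs[l] = np.maximum(
                    (mass[l] * s2 + VAR_PSEUDO_OBS * prior_var)
                    / (mass[l] + VAR_PSEUDO_OBS), VAR_FLOOR)
        else:
            covs = np.empty_like(params.covariances)
            for l in range(params.L):
                diff = Xv - means[l]
                S = (tau[:, l, None] * diff).T @ diff / mass[l]
                S = (mass[l] * S + VAR_PSEUDO_OBS * np.diag(prior_var)) / (
                    mass[l] + VAR_PSEUDO_OBS)
                covs[l] = S + FULL_COV_SHRINKAGE * np.eye(J)
        params = GmmParameters(weights=mass / mass.sum(), means=means,
                               covariances=covs, covariance_type=covariance_type)
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            break
        prev_ll = ll
    best_tau, _ = _responsibilities(params)
    membership = MembershipMatrix(tau=best_tau, gene_ids=list(gene_ids))
    logger.info("CEM selected L=%d (MML %.3f) over visited L=%s",
                params.L, best[0], trace.visited_L())
    return params, membership, trace


def fit_gmm_cem(
    X: ExpressionMatrix,
    L_max: int | None = None,
    L_min: int = 1,
    seed: int = 0,
    tol: float = 1e-6,
    covariance_type: str = "diag",
) -> tuple[GmmParameters, MembershipMatrix, MmlTrace]:
    """Fit the pathway mixture, selecting L by MML component annihilation.

    Parameters
    ----------
    X : expression matrix (genes x experiments).
    L_max, L_min : bracket for the pathway count; ``L_max`` defaults to
        ``min(I, 15)``.
    seed : RNG seed controlling the k-means initialisation; the whole fit
        is deterministic given it.
    tol : relative convergence tolerance for both the inner EM
        log-likelihood and the outer message-length sequence.
    """
    if L_max is None:
        L_max = min(X.n_genes, 15)
    return _cem_fit(X.values, list(X.gene_ids), L_max, L_min, seed, tol,
                    covariance_type, field_C=None)


def co_membership(tau: MembershipMatrix, zero_diagonal: bool = True) -> ScoredNetwork:
    """Pairwise same-pathway probability G = tau tau^T.

    G[i, i'] = sum_l tau[i, l] tau[i', l] is the probability that genes i
    and i' fall in the same pathway (genes treated as independent).  The
    diagonal is zeroed for network use.
    """
    G = tau.tau @ tau.tau.T
    if zero_diagonal:
        np.fill_diagonal(G, 0.0)
    G = np.clip(G, 0.0, 1.0)
    return ScoredNetwork(gene_ids=list(tau.gene_ids), scores=G,
                         symmetric=True, score_range=(0.0, 1.0))
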