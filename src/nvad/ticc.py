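"""Toeplitz Inverse Covariance-based Clustering (TICC).

Each of the K clusters is a Gaussian Markov random field over a window of
``w`` (possibly dilated) feature frames, parameterized by a mean and a sparse
block-Toeplitz precision matrix: the C x C sub-block coupling layers i and j
depends only on i - j, making cross-lag dependencies time-invariant.

Fitting alternates, EM-style, between

* an assignment step: the minimum-cost label path under per-frame Gaussian
  negative log-likelihoods plus a switching penalty ``beta`` for adjacent
  frames changing cluster, solved exactly by dynamic programming; and
* an update step: per cluster, the block-Toeplitz-constrained sparse inverse
  covariance ``argmin_Theta  (n_k/2)(-logdet Theta + tr(S_k Theta)) +
  lam * ||Theta||_1(off-diag)``, solved by ADMM with a combined
  soft-threshold / Toeplitz block-averaging proximal step.

With this parameterization both steps are exact coordinate descent on the
joint objective ``sum_t NLL(x_t; Theta_{c_t}) + beta * #switches +
sum_k lam * ||Theta_k||_1``, so the recorded objective trace is
non-increasing.  Convergence is declared when the assignment is stationary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .types import FrameSequence, LabelSequence

__all__ = [
    "TICCHyperparams",
    "MRFCluster",
    "TICCModel",
    "window_embed",
    "gmm_initialize",
    "cluster_nll",
    "estep_assign",
    "mstep_update",
    "fit_ticc",
]

logger = logging.getLogger(__name__)


@dataclass
class TICCHyperparams:
    """Hyperparameters: K clusters, switching penalty beta, L1 weight lam,
    w block-Toeplitz layers spaced ``dilation_frames`` apart."""

    K: int = 2
    beta: float = 50.0
    lam: float = 11e-4
    n_layers: int = 1
    dilation_frames: int = 5
    max_iter: int = 100
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_layers < 1 or self.beta < 0 or self.lam < 0:
            raise ValueError("invalid TICC hyperparameters")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class MRFCluster:
    """One cluster: Gaussian mean plus block-Toeplitz sparse precision."""

    mean: np.ndarray
    precision: np.ndarray
    log_det: float
    n_assigned: int = 0

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class TICCModel:
    clusters: list[MRFCluster]
    hyper: TICCHyperparams
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def K(self) -> int:
        return len(self.clusters)


def window_embed(frames: FrameSequence, n_layers: int, dilation_frames: int) -> FrameSequence:
    """Per-frame observation (x_t, x_{t-d}, ..., x_{t-(w-1)d}), zero-filled
    before the sequence start.  ``w=1`` returns the input unchanged."""
    if n_layers < 1 or dilation_frames < 1:
        raise ValueError("n_layers and dilation_frames must be >= 1")
    if n_layers == 1:
        return frames
    x = frames.values
    T, C = x.shape
    out = np.zeros((T, C * n_layers), dtype=np.float64)
    for layer in range(n_layers):
        lag = layer * dilation_frames
        if lag < T:
            out[lag:, layer * C:(layer + 1) * C] = x[:T - lag]
    return frames.with_values(out)


def gmm_initialize(embedded: FrameSequence, K: int, seed: int, max_retries: int = 5,
                   init_params: str = "random_from_data") -> LabelSequence:
    """Hard assignments from a K-component full-covariance Gaussian mixture.

    A fit that leaves a component empty is retried with a bumped seed, a
    bounded number of times.  ``init_params`` defaults to random-from-data
    responsibilities: k-means-style initialization cannot separate clusters
    that differ in covariance but not mean.
    """
    X = embedded.values
    T, D = X.shape
    if T <= K * D:
        logger.warning("few frames (%d) relative to K*D = %d; GMM init may be unstable", T, K * D)
    for attempt in range(max_retries):
        gmm = GaussianMixture(n_components=K, covariance_type="full",
                              random_state=seed + attempt, n_init=5,
                              init_params=init_params, reg_covar=1e-6)
        labels = gmm.fit_predict(X)
        if len(np.unique(labels)) == K or K == 1:
            return LabelSequence(labels, frame_shift_ms=embedded.frame_shift_ms,
                                 start_time=embedded.start_time,
                                 classes={k: f"cluster{k}" for k in range(K)})
    raise RuntimeError(f"GMM initialization left empty components after {max_retries} retries")


def _nll_matrix(X: np.ndarray, clusters: list[MRFCluster]) -> np.ndarray:
    """(T, K) Gaussian negative log-likelihoods."""
    T, D = X.shape
    out = np.empty((T, len(clusters)))
    for k, c in enumerate(clusters):
        diff = X - c.mean
        quad = np.einsum("ti,ij,tj->t", diff, c.precision, diff)
        out[:, k] = 0.5 * (quad - c.log_det + D * np.log(2 * np.pi))
    return out


def cluster_nll(observation: np.ndarray, cluster: MRFCluster) -> float:
    """0.5 * [(x-mu)' Theta (x-mu) - logdet Theta + D log 2pi]."""
    x = np.asarray(observation, dtype=np.float64)
    if x.shape != cluster.mean.shape:
        raise ValueError("observation dimension does not match cluster")
    return float(_nll_matrix(x[None, :], [cluster])[0, 0])


def estep_assign(embedded: FrameSequence, model: TICCModel) -> LabelSequence:
    """Minimum-cost label path under NLL + beta-per-switch, by forward DP.

    Ties are broken toward the lower cluster index, both in the transition
    choice and in the final state, so the output is deterministic.
    """
    X = embedded.values
    K = model.K
    beta = model.hyper.beta
    nll = _nll_matrix(X, model.clusters)
    T = X.shape[0]
    if T == 0:
        return LabelSequence(np.empty(0, np.int64), frame_shift_ms=embedded.frame_shift_ms,
                             start_time=embedded.start_time,
                             classes={k: f"cluster{k}" for k in range(K)})

    back = np.zeros((T, K), dtype=np.int64)
    cost = nll[0].copy()
    ks = np.arange(K)
    for t in range(1, T):
        best_prev = int(np.argmin(cost))  # argmin -> first (lowest) index on ties
        switch_cost = cost[best_prev] + beta
        stay = cost
        # prefer staying on exact ties unless switching to a LOWER index ties
        take_switch = (switch_cost < stay) | ((switch_cost == stay) & (best_prev < ks))
        back[t] = np.where(take_switch, best_prev, ks)
        cost = nll[t] + np.where(take_switch, switch_cost, stay)

    labels = np.empty(T, dtype=np.int64)
    labels[-1] = int(np.argmin(cost))
    for t in range(T - 1, 0, -1):
        labels[t - 1] = back[t, labels[t]]
    return LabelSequence(labels, frame_shift_ms=embedded.frame_shift_ms,
                         start_time=embedded.start_time,
                         classes={k: f"cluster{k}" for k in range(K)})


# ---------------------------------------------------------------------------
# M-step: block-Toeplitz sparse inverse covariance by ADMM

#: ADMM settings: penalty rho, absolute/relative stopping tolerances, cap
ADMM_RHO = 1.0
ADMM_ABSTOL = 1e-6
ADMM_RELTOL = 1e-4
ADMM_MAX_ITER = 1000
#: diagonal loading added to empirical covariances
COV_LOADING = 1e-6
#: eigenvalue floor when restoring positive definiteness after projection
PD_FLOOR = 1e-8


def _toeplitz_prox(A: np.ndarray, w: int, C: int, thresh: float) -> np.ndarray:
    """Projection onto symmetric block-Toeplitz matrices combined with
    entrywise soft-thresholding (matrix diagonal unpenalized).

    Each Toeplitz equivalence class {(a, a+m, i, j)} (plus its transpose
    images) shares one value; the exact prox of the summed L1 + quadratic
    terms over a class is soft-threshold applied to the class mean.
    """
    Asym = (A + A.T) / 2.0
    blocks = Asym.reshape(w, C, w, C).transpose(0, 2, 1, 3)  # (w, w, C, C)
    Z = np.zeros_like(A)
    idx = np.arange(w)
    for m in range(w):
        rows, cols = idx[: w - m], idx[m:]
        mean_block = blocks[rows, cols].mean(axis=0)  # (C, C)
        z = np.sign(mean_block) * np.maximum(np.abs(mean_block) - thresh, 0.0)
        if m == 0:
            z = (z + z.T) / 2.0
            np.fill_diagonal(z, np.diag(mean_block))  # diagonal unpenalized
        for a in range(w - m):
            Z[a * C:(a + 1) * C, (a + m) * C:(a + m + 1) * C] = z
            if m > 0:
                Z[(a + m) * C:(a + m + 1) * C, a * C:(a + 1) * C] = z.T
    return Z


def _solve_toeplitz_glasso(S: np.ndarray, w: int, C: int, lam_eff: float) -> np.ndarray:
    """ADMM for  -logdet(Theta) + tr(S Theta) + lam_eff ||Theta||_1(off-diag)
    over symmetric block-Toeplitz positive definite matrices."""
    p = S.shape[0]
    rho = ADMM_RHO
    Z = np.diag(1.0 / np.maximum(np.diag(S), COV_LOADING))
    U = np.zeros_like(S)
    for it in range(ADMM_MAX_ITER):
        # Theta-update: eigenvalue proximal step for the log-det term
        M = rho * (Z - U) - S
        M = (M + M.T) / 2.0
        d, Q = np.linalg.eigh(M)
        theta_eigs = (d + np.sqrt(d * d + 4.0 * rho)) / (2.0 * rho)
        Theta = (Q * theta_eigs) @ Q.T

        Z_old = Z
        Z = _toeplitz_prox(Theta + U, w, C, lam_eff / rho)
        U = U + Theta - Z

        r = np.linalg.norm(Theta - Z)
        s = rho * np.linalg.norm(Z - Z_old)
        eps_pri = ADMM_ABSTOL * p + ADMM_RELTOL * max(np.linalg.norm(Theta), np.linalg.norm(Z))
        eps_dual = ADMM_ABSTOL * p + ADMM_RELTOL * rho * np.linalg.norm(U)
        if r <= eps_pri and s <= eps_dual:
            break
        # residual balancing keeps rho matched to the problem's scale
        if it % 10 == 9:
            if r > 10.0 * s:
                rho *= 2.0
                U /= 2.0
            elif s > 10.0 * r:
                rho /= 2.0
                U *= 2.0
    else:
        raise RuntimeError(
            f"Toeplitz graphical-lasso ADMM did not converge in {ADMM_MAX_ITER} "
            f"iterations (primal residual {r:.3e}, dual residual {s:.3e})")

    # Z is exactly symmetric block-Toeplitz; restore PD with diagonal loading
    min_eig = float(np.linalg.eigvalsh(Z)[0])
    if min_eig < PD_FLOOR:
        Z = Z + (PD_FLOOR - min_eig) * np.eye(p)
    return Z


def min_cluster_frames(n_layers: int, n_features: int) -> int:
    """Minimum assigned frames before a cluster's covariance is re-estimated."""
    return max(20, (n_layers * n_features) // 10)


def mstep_update(embedded: FrameSequence, labels: LabelSequence, lam: float,
                 n_layers: int = 1,
                 previous: list[MRFCluster] | None = None,
                 K: int | None = None) -> list[MRFCluster]:
    """Re-estimate every cluster's mean and block-Toeplitz sparse precision.

    ``lam`` is the per-cluster L1 weight of the joint objective; the
    per-cluster subproblem handed to the ADMM solver is the standard form
    ``-logdet + tr(S Theta) + (2 lam / n_k) ||Theta||_1``.  Clusters with
    fewer than :func:`min_cluster_frames` assigned frames keep their previous
    parameters (or raise, if there are none to keep).
    """
    X = embedded.values
    D = X.shape[1]
    if D % n_layers != 0:
        raise ValueError("embedded dimension is not a multiple of n_layers")
    C = D // n_layers
    K = K if K is not None else int(labels.labels.max()) + 1
    min_n = min_cluster_frames(n_layers, C)

    clusters: list[MRFCluster] = []
    for k in range(K):
        members = X[labels.labels == k]
        n_k = members.shape[0]
        if n_k < max(2, min_n):
            if previous is not None and k < len(previous):
                logger.warning("cluster %d has %d frames (< %d); keeping previous parameters",
                               k, n_k, min_n)
                prev = previous[k]
                clusters.append(MRFCluster(prev.mean, prev.precision, prev.log_det, n_k))
                continue
            raise ValueError(f"cluster {k} has too few frames ({n_k}) and no fallback")
        mean = members.mean(axis=0)
        diff = members - mean
        S = diff.T @ diff / n_k + COV_LOADING * np.eye(D)
        lam_eff = 2.0 * lam / n_k
        precision = _solve_toeplitz_glasso(S, n_layers, C, lam_eff)
        sign, log_det = np.linalg.slogdet(precision)
        if sign <= 0:
            raise RuntimeError("estimated precision is not positive definite")
        clusters.append(MRFCluster(mean=mean, precision=precision,
                                   log_det=float(log_det), n_assigned=n_k))
    return clusters


def _joint_objective(X: np.ndarray, labels: np.ndarray, clusters: list[MRFCluster],
                     beta: float, lam: float) -> float:
    nll = _nll_matrix(X, clusters)
    data_term = float(nll[np.arange(X.shape[0]), labels].sum())
    switches = int(np.count_nonzero(labels[1:] != labels[:-1]))
    penalty = sum(
        lam * (np.abs(c.precision).sum() - np.abs(np.diag(c.precision)).sum())
        for c in clusters)
    return data_term + beta * switches + float(penalty)


def _rescue_empty_clusters(labels: np.ndarray, nll: np.ndarray, K: int) -> np.ndarray:
    """Reassign the worst-fitting 1% of frames to any empty cluster."""
    labels = labels.copy()
    for k in range(K):
        if np.any(labels == k):
            continue
        fit = nll[np.arange(labels.shape[0]), labels]
        n_move = max(20, labels.shape[0] // 100)
        worst = np.argsort(fit)[-n_move:]
        labels[worst] = k
        logger.warning("cluster %d empty; reassigned %d worst-fit frames", k, n_move)
    return labels


def fit_ticc(frames: FrameSequence, hyper: TICCHyperparams) -> tuple[TICCModel, LabelSequence]:
    """Fit the clustering, restarting from ``n_restarts`` different mixture
    initializations and keeping the run with the lowest final objective.

    EM-style alternation is sensitive to its starting point (a poor start
    can collapse one cluster); restarts with objective selection are the
    standard, fully deterministic remedy.
    """
    best: tuple[TICCModel, LabelSequence] | None = None
    for r in range(hyper.n_restarts):
        init = "random_from_data" if r % 2 == 0 else "random"
        model, labels = _fit_ticc_once(frames, hyper, hyper.seed + 7919 * r, init)
        if best is None or model.objective_trace[-1] < best[0].objective_trace[-1]:
            best = (model, labels)
    return best


def _fit_ticc_once(frames: FrameSequence, hyper: TICCHyperparams,
                   init_seed: int, init_params: str = "random_from_data"
                   ) -> tuple[TICCModel, LabelSequence]:
    """One EM run: alternate assignment and update steps from a GMM
    initialization until the assignment is stationary (or ``max_iter``)."""
    emb = window_embed(frames, hyper.n_layers, hyper.dilation_frames)
    X = emb.values
    T = X.shape[0]
    if T < 2 * hyper.K:
        raise ValueError("too few frames to cluster")

    labels = gmm_initialize(emb, hyper.K, init_seed, init_params=init_params)
    clusters = mstep_update(emb, labels, hyper.lam, hyper.n_layers, K=hyper.K)
    model = TICCModel(clusters=clusters, hyper=hyper)

    prev = labels.labels
    for iteration in range(1, hyper.max_iter + 1):
        assigned = estep_assign(emb, model)
        lab = assigned.labels
        missing = [k for k in range(hyper.K) if not np.any(lab == k)]
        if missing:
            lab = _rescue_empty_clusters(lab, _nll_matrix(X, model.clusters), hyper.K)
            assigned = assigned.with_labels(lab, classes=assigned.classes)
        model.objective_trace.append(
            _joint_objective(X, lab, model.clusters, hyper.beta, hyper.lam))
        model.n_iter = iteration
        if np.array_equal(lab, prev):
            model.converged = True
            break
        prev = lab
        model.clusters = mstep_update(emb, assigned, hyper.lam, hyper.n_layers,
                                      previous=model.clusters, K=hyper.K)

    final = LabelSequence(prev, frame_shift_ms=frames.frame_shift_ms,
                          start_time=frames.start_time,
                          classes={k: f"cluster{k}" for k in range(hyper.K)})
    return model, final
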