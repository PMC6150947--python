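"""Empirical-Bayes source inversion with exchangeable covariance priors.

The sensor data (reduced to a few orthonormal temporal modes) are modelled
as zero-mean Gaussian with covariance

    Sigma_y = h_0 * Q_noise + sum_k h_k * L C_k L'

where L is the lead-field matrix, Q_noise a diagonal sensor-noise
component and the C_k are source-covariance components. The choice of
C_k is the only thing that differs between the four inversion schemes:

* MMN - a single identity component (classical unweighted minimum norm);
* LOR - a single surface-smoothed component G G' with G a graph heat
  kernel on the cortical mesh (LORETA-like);
* EBB - a single diagonal component whose variances are beamformer power
  estimates 1/(l_i' Cy^-1 l_i) from the sensor covariance;
* MSP - many rank-1 patch components g_k g_k' at quasi-uniform seed
  vertices, mixed by the hyperparameter optimization with ARD-style
  pruning.

Hyperparameters are optimized on the log scale by Fisher-scored ReML
(variational Laplace) under weak Gaussian hyperpriors; the variational
free energy is the model-comparison metric. All four priors run through
the identical ``reml_fit``/``map_sources`` path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import scipy.sparse as sp

from .synthgen import CorticalMesh, _rng

__all__ = [
    "TemporalModes",
    "CovariancePriorSet",
    "InversionResult",
    "temporal_reduce",
    "prior_mmn",
    "prior_lor",
    "prior_ebb",
    "prior_msp",
    "reml_fit",
    "map_sources",
    "predict_heldout",
    "gaussian_log_evidence",
]

# Weak Gaussian hyperpriors on log-scale hyperparameters (SPM-style).
HP_MEAN = -32.0
HP_VAR = 256.0


# ---------------------------------------------------------------------------
# Temporal reduction
# ---------------------------------------------------------------------------


@dataclass
class TemporalModes:
    """Orthonormal temporal basis and the data projected onto it.

    ``modes`` is S x R with orthonormal columns (eigenvectors of the
    epoch-averaged temporal covariance); ``reduced_data`` concatenates the
    per-epoch projections, giving C x (E*R) columns.
    """

    modes: np.ndarray  # (S, R)
    reduced_data: np.ndarray  # (C, E*R)
    variance_retained: float
    n_epochs: int

    @property
    def R(self) -> int:
        return self.modes.shape[1]


def temporal_reduce(epochs: np.ndarray, R: int = 16) -> TemporalModes:
    """Project epochs onto the top-R temporal eigenmodes.

    ``epochs`` is (E, C, S). The S x S temporal covariance is averaged over
    epochs, its leading R eigenvectors form the (orthonormal) mode basis,
    and each epoch is projected onto it. If the data support fewer than R
    modes the available rank is kept with a warning.
    """
    epochs = np.asarray(epochs, float)
    E, C, S = epochs.shape
    if R > S:
        raise ValueError(f"R={R} exceeds samples per epoch S={S}")
    tcov = np.einsum("ecs,ect->st", epochs, epochs) / max(E, 1)
    evals, evecs = np.linalg.eigh(tcov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    rank = int(np.sum(evals > 1e-12 * max(evals[0], 1e-300)))
    if rank < R:
        warnings.warn(f"data support only {rank} temporal modes (requested {R})")
        R_eff = max(rank, 1)
    else:
        R_eff = R
    modes = evecs[:, :R_eff]
    reduced = np.concatenate([ep @ modes for ep in epochs], axis=1)
    total = float(evals.sum())
    retained = float(evals[:R_eff].sum() / total) if total > 0 else 0.0
    return TemporalModes(
        modes=modes, reduced_data=reduced, variance_retained=retained, n_epochs=E
    )


# ---------------------------------------------------------------------------
# Source-covariance priors
# ---------------------------------------------------------------------------


@dataclass
class CovariancePriorSet:
    """Source-covariance components C_k, each PSD, in factored or dense form.

    Component encodings:
      ("scaled_identity", alpha)  -> alpha * I_N
      ("diag", v)                 -> diag(v)
      ("factor", F)               -> F F'   (F is N x r)
      ("vec", g)                  -> g g'   (rank 1)
    """

    components: list
    kind: str
    n_sources: int

    def __len__(self) -> int:
        return len(self.components)

    def sensor_components(self, L: np.ndarray) -> list:
        """Project each C_k to the sensor level: L C_k L'.

        Returns a list of ("dense", Q) / ("vec", a) entries used by ReML.
        """
        out = []
        for enc, payload in self.components:
            if enc == "scaled_identity":
                out.append(("dense", payload * (L @ L.T)))
            elif enc == "diag":
                A = L * np.sqrt(np.clip(payload, 0.0, None))[None, :]
                out.append(("dense", A @ A.T))
            elif enc == "factor":
                A = L @ payload
                out.append(("dense", A @ A.T))
            elif enc == "vec":
                out.append(("vec", L @ payload))
            else:  # pragma: no cover
                raise ValueError(f"unknown component encoding {enc}")
        return out

    def source_cov_times(self, L_T: np.ndarray, h: np.ndarray) -> np.ndarray:
        """(sum_k h_k C_k) @ L_T without forming N x N matrices.

        ``L_T`` is N x C (the transposed lead field); ``h`` the natural-
        scale component weights.
        """
        N = self.n_sources
        out = np.zeros((N, L_T.shape[1]))
        for hk, (enc, payload) in zip(h, self.components):
            if hk == 0.0:
                continue
            if enc == "scaled_identity":
                out += hk * payload * L_T
            elif enc == "diag":
                out += hk * payload[:, None] * L_T
            elif enc == "factor":
                out += hk * (payload @ (payload.T @ L_T))
            elif enc == "vec":
                out += hk * np.outer(payload, payload @ L_T)
        return out


def prior_mmn(n_sources: int) -> CovariancePriorSet:
    """IID minimum-norm prior: a single identity source covariance."""
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    return CovariancePriorSet(
        components=[("scaled_identity", 1.0)], kind="MMN", n_sources=n_sources
    )


def _mesh_graph(mesh: CorticalMesh) -> sp.csr_matrix:
    """Row-normalized vertex adjacency (random-walk operator)."""
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    W = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(mesh.n_vertices,) * 2
    )
    W.data[:] = 1.0  # collapse duplicate entries
    W = sp.csr_matrix((W > 0).astype(float))
    deg = np.asarray(W.sum(axis=1)).ravel()
    return sp.diags(1.0 / np.maximum(deg, 1.0)) @ W


def _heat_kernel_apply(
    A: sp.spmatrix, s: float, V: np.ndarray, tol: float = 1e-12, max_terms: int = 60
) -> np.ndarray:
    """exp(s*A) @ V by truncated Taylor series (converges fast: ||A||<=1)."""
    acc = V.copy()
    term = V.copy()
    for j in range(1, max_terms):
        term = (s / j) * (A @ term)
        acc += term
        if np.max(np.abs(term)) < tol * max(np.max(np.abs(acc)), 1e-300):
            break
    return acc


def prior_lor(mesh: CorticalMesh, smooth_s: float = 0.6) -> CovariancePriorSet:
    """LORETA-like prior: Q = G G' with G = exp(s*A) a surface heat kernel.

    ``A`` is the row-normalized vertex adjacency; ``s`` controls the
    smoothing extent (s=0 reduces to the identity, i.e. the MMN prior).
    """
    A = _mesh_graph(mesh)
    n_comp, labels = sp.csgraph.connected_components(A, directed=False)
    G = _heat_kernel_apply(A, smooth_s, np.eye(mesh.n_vertices))
    if n_comp > 1:
        warnings.warn(f"mesh has {n_comp} components: kernel is block-diagonal")
        mask = labels[:, None] == labels[None, :]
        G = G * mask
    return CovariancePriorSet(
        components=[("factor", G)], kind="LOR", n_sources=mesh.n_vertices
    )


def prior_ebb(gain, reduced_data: np.ndarray) -> CovariancePriorSet:
    """Empirical Bayesian beamformer prior from the sensor covariance.

    Source variance_i is proportional to 1/(l_i' Cy^-1 l_i) — the
    beamformer power estimate with zero regularization of Cy — normalized
    to unit trace. Zero-norm lead-field columns get zero variance.
    """
    L = np.asarray(getattr(gain, "values", gain), float)
    Y = np.asarray(reduced_data, float)
    Cy = Y @ Y.T / Y.shape[1]
    # symmetric (pseudo-)inverse: clip numerically zero/negative eigenvalues
    # so beamformer powers stay positive; no diagonal loading is applied
    evals, evecs = np.linalg.eigh(Cy)
    tol = max(evals.max(), 0.0) * 1e-12
    if evals.min() <= tol:
        warnings.warn("rank-deficient sensor covariance: using pseudo-inverse")
    keep = evals > tol
    iCy = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    denom = np.einsum("cn,cd,dn->n", L, iCy, L)
    v = np.zeros(L.shape[1])
    ok = denom > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-power sources set to zero variance")
    v[ok] = 1.0 / denom[ok]
    v /= v.sum()
    return CovariancePriorSet(components=[("diag", v)], kind="EBB", n_sources=L.shape[1])


def _farthest_point_seeds(
    mesh: CorticalMesh, n_patches: int, seed: int
) -> np.ndarray:
    """Quasi-uniform seed vertices by farthest-point sampling on the
    edge-weighted mesh graph (geodesic approximated by shortest paths)."""
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    lens = np.linalg.norm(mesh.vertices[rows] - mesh.vertices[cols], axis=1)
    W = sp.csr_matrix((lens, (rows, cols)), shape=(mesh.n_vertices,) * 2)
    W = W.maximum(W.T)
    rng = _rng(seed, "prior_msp")
    first = int(rng.integers(mesh.n_vertices))
    seeds = [first]
    dist = sp.csgraph.dijkstra(W, indices=first, directed=False)
    for _ in range(n_patches - 1):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, sp.csgraph.dijkstra(W, indices=nxt, directed=False))
    return np.array(seeds)


def prior_msp(
    mesh: CorticalMesh,
    n_patches: int = 512,
    smooth_s: float = 0.6,
    seed: int = 0,
) -> CovariancePriorSet:
    """Multiple sparse priors: rank-1 patch components at even seed vertices.

    Component k is g_k g_k' where g_k is the surface heat-kernel column at
    seed vertex k; seeds are placed by seed-deterministic farthest-point
    sampling so patches tile the surface approximately evenly.
    """
    if n_patches > mesh.n_vertices:
        warnings.warn(
            f"n_patches={n_patches} exceeds vertex count; capped at {mesh.n_vertices}"
        )
        n_patches = mesh.n_vertices
    seeds = _farthest_point_seeds(mesh, n_patches, seed)
    A = _mesh_graph(mesh)
    V = np.zeros((mesh.n_vertices, n_patches))
    V[seeds, np.arange(n_patches)] = 1.0
    G_cols = _heat_kernel_apply(A, smooth_s, V)
    comps = [("vec", G_cols[:, k].copy()) for k in range(n_patches)]
    return CovariancePriorSet(components=comps, kind="MSP", n_sources=mesh.n_vertices)


# ---------------------------------------------------------------------------
# ReML / free energy
# ---------------------------------------------------------------------------


@dataclass
class InversionResult:
    """Fitted hyperparameters, free energy and model covariance."""

    lambdas: np.ndarray  # log-scale weights, original units; [0] = noise
    free_energy: float  # nats (Laplace evidence approximation)
    model_cov: np.ndarray  # Sigma_y, C x C, original units
    prior_kind: str
    mesh_id: str = ""
    converged: bool = True
    f_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    h_source: np.ndarray = field(default_factory=lambda: np.empty(0))
    h_noise: float = 0.0
    n_samples: int = 0
    priors: Optional[CovariancePriorSet] = None

    def save_h5(self, path, J_hat: Optional[np.ndarray] = None) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("lambdas", data=self.lambdas)
            f.create_dataset("model_cov", data=self.model_cov)
            if J_hat is not None:
                f.create_dataset("J_hat", data=J_hat)
            f.attrs["free_energy"] = self.free_energy
            f.attrs["prior_kind"] = self.prior_kind
            f.attrs["mesh_id"] = self.mesh_id
            f.attrs["converged"] = self.converged


def gaussian_log_evidence(Y: np.ndarray, Sigma: np.ndarray) -> float:
    """Exact log density of zero-mean Gaussian columns: sum_t log N(y_t; 0, Sigma)."""
    C, n = Y.shape
    chol = np.linalg.cholesky(Sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    sol = np.linalg.solve(chol, Y)
    quad = float(np.sum(sol**2))
    return -0.5 * (quad + n * logdet + n * C * np.log(2.0 * np.pi))


def _accuracy(Cy: np.ndarray, n: int, Sigma: np.ndarray) -> float:
    """ReML accuracy term -n/2 [tr(Sigma^-1 Cy) + log|Sigma| + C log 2pi].

    For a fixed model covariance this equals the exact Gaussian log
    evidence of the data whose sample covariance is ``Cy``.
    """
    C = Cy.shape[0]
    chol = np.linalg.cholesky(Sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    tr_term = float(np.trace(np.linalg.solve(Sigma, Cy)))
    return -0.5 * n * (tr_term + logdet + C * np.log(2.0 * np.pi))


def reml_accuracy(Y: np.ndarray, Sigma: np.ndarray) -> float:
    """The ReML objective's data-fit term evaluated at a fixed covariance."""
    C, n = Y.shape
    return _accuracy(Y @ Y.T / n, n, Sigma)


def _trace_terms(Qs, active, h, Sigma, Cy, n):
    """Gradient and expected (Fisher) curvature of the ReML accuracy term."""
    iS = np.linalg.inv(Sigma)
    Rm = iS @ (Cy - Sigma) @ iS
    idx = np.flatnonzero(active)
    K = len(idx)
    grad = np.zeros(K)
    PQ = []  # iS @ Q_k for dense, iS @ a for vec
    for j, k in enumerate(idx):
        enc, payload = Qs[k]
        if enc == "dense":
            grad[j] = 0.5 * n * h[k] * float(np.sum(Rm * payload))
            PQ.append(("dense", iS @ payload))
        else:
            grad[j] = 0.5 * n * h[k] * float(payload @ Rm @ payload)
            PQ.append(("vec", payload, iS @ payload))
    H = np.zeros((K, K))
    for j in range(K):
        for l in range(j, K):
            ej, el = PQ[j], PQ[l]
            if ej[0] == "dense" and el[0] == "dense":
                t = float(np.sum(ej[1] * el[1].T))
            elif ej[0] == "dense" and el[0] == "vec":
                t = float(el[1] @ ej[1] @ el[2])
            elif ej[0] == "vec" and el[0] == "dense":
                t = float(ej[1] @ el[1] @ ej[2])
            else:
                t = float(ej[1] @ el[2]) ** 2
            H[j, l] = H[l, j] = 0.5 * n * h[idx[j]] * h[idx[l]] * t
    return grad, H


def reml_fit(
    gain,
    reduced_data: np.ndarray,
    priors: CovariancePriorSet,
    noise: Optional[np.ndarray] = None,
    max_iter: int = 128,
    tol: float = 1e-7,
    prune_log_ratio: float = -16.0,
    hp_mean: float = HP_MEAN,
    hp_var: float = HP_VAR,
    mesh_id: str = "",
) -> InversionResult:
    """Fisher-scored ReML over log-scale covariance hyperparameters.

    Maximizes the variational-Laplace objective

        F(lambda) = -n/2 [tr(Sigma^-1 Cy) + log|Sigma| + C log 2pi]
                    - sum_k (lambda_k - mu)^2 / (2 v)  + const

    with Sigma = sum_k exp(lambda_k) Q_k (Q_0 the sensor-noise component),
    backtracking on the Newton step so the objective never decreases. Data
    and components are trace-normalized internally (hyperpriors, mean
    ``hp_mean`` and variance ``hp_var``, act on the normalized scale);
    reported hyperparameters and free energy are on the original scale.
    Components whose normalized log-weight falls ``prune_log_ratio`` below
    the current maximum are pruned (ARD behaviour, relevant for MSP).

    The reported ``free_energy`` adds the Laplace volume term
    ``K/2 log 2pi - 1/2 log|H|``; the per-iteration objective trace (which
    is non-decreasing) is kept in ``f_trace``.
    """
    L = np.asarray(getattr(gain, "values", gain), float)
    Y = np.asarray(reduced_data, float)
    C, n = Y.shape
    if L.shape[0] != C:
        raise ValueError("gain row count must match data channel count")

    Qs_raw = [("dense", np.eye(C) if noise is None else np.diag(np.asarray(noise)))]
    Qs_raw += priors.sensor_components(L)
    K = len(Qs_raw)

    # trace-normalize components and data
    def _tr(entry):
        enc, payload = entry
        return float(np.trace(payload)) if enc == "dense" else float(payload @ payload)

    scales = np.array([C / max(_tr(q), 1e-300) for q in Qs_raw])
    Qs = []
    for (enc, payload), s in zip(Qs_raw, scales):
        Qs.append((enc, payload * s if enc == "dense" else payload * np.sqrt(s)))
    Cy_raw = Y @ Y.T / n
    data_scale = C / max(float(np.trace(Cy_raw)), 1e-300)
    Cy = Cy_raw * data_scale

    lam = np.full(K, -np.log(K))
    active = np.ones(K, dtype=bool)
    prior_prec = 1.0 / hp_var

    def objective(lam_vec, act):
        h = np.where(act, np.exp(lam_vec), 0.0)
        Sigma = np.zeros((C, C))
        for hk, (enc, payload) in zip(h, Qs):
            if hk == 0.0:
                continue
            Sigma += hk * (payload if enc == "dense" else np.outer(payload, payload))
        try:
            acc = _accuracy(Cy, n, Sigma)
        except np.linalg.LinAlgError:
            return -np.inf, None
        pen = -0.5 * prior_prec * float(np.sum((lam_vec[act] - hp_mean) ** 2))
        return acc + pen, Sigma

    f_trace = []
    obj, Sigma = objective(lam, active)
    converged = False
    H_last = np.eye(int(active.sum())) * prior_prec
    for _ in range(max_iter):
        h = np.where(active, np.exp(lam), 0.0)
        grad_acc, H_acc = _trace_terms(Qs, active, h, Sigma, Cy, n)
        idx = np.flatnonzero(active)
        grad = grad_acc - prior_prec * (lam[idx] - hp_mean)
        H = H_acc + prior_prec * np.eye(len(idx))
        H_last = H
        try:
            step = np.linalg.solve(H + 1e-8 * np.eye(len(idx)), grad)
        except np.linalg.LinAlgError:
            step = grad / (np.diag(H) + 1e-8)
        step = np.clip(step, -8.0, 8.0)  # trust region on log scale
        alpha = 1.0
        for _bt in range(40):
            lam_try = lam.copy()
            lam_try[idx] = lam[idx] + alpha * step
            obj_try, Sigma_try = objective(lam_try, active)
            if obj_try >= obj - 1e-12:
                break
            alpha *= 0.5
        else:
            converged = True
            break
        improved = obj_try - obj
        lam, obj, Sigma = lam_try, obj_try, Sigma_try
        f_trace.append(obj)
        # ARD pruning: drop components far below the leading weight
        if K > 2:
            rel = lam[idx] - lam[idx].max()
            drop = idx[rel < prune_log_ratio]
            drop = drop[drop != 0]  # never prune the noise component
            if drop.size:
                active[drop] = False
                obj, Sigma = objective(lam, active)
        if improved < tol * max(1.0, abs(obj)) and np.max(np.abs(alpha * step)) < 1e-5:
            converged = True
            break
    if not converged:
        warnings.warn("ReML did not converge in max_iter; returning best iterate")

    # Laplace volume term and rescale to original units
    sign, logdet_H = np.linalg.slogdet(H_last)
    Kact = int(active.sum())
    occam = 0.5 * Kact * np.log(2.0 * np.pi) - 0.5 * (logdet_H if sign > 0 else 0.0)
    free_energy = (
        obj
        + occam
        - 0.5 * Kact * np.log(2.0 * np.pi * hp_var)
        + 0.5 * n * C * np.log(data_scale)
    )

    h_norm = np.where(active, np.exp(lam), 0.0)
    h_orig = h_norm * scales / data_scale  # Sigma_raw = sum h_orig * Q_raw
    Sigma_orig = np.zeros((C, C))
    for hk, (enc, payload) in zip(h_orig, Qs_raw):
        if hk:
            Sigma_orig += hk * (payload if enc == "dense" else np.outer(payload, payload))
    with np.errstate(divide="ignore"):
        lam_orig = np.log(h_orig)
    return InversionResult(
        lambdas=lam_orig,
        free_energy=float(free_energy),
        model_cov=Sigma_orig,
        prior_kind=priors.kind,
        mesh_id=mesh_id,
        converged=converged,
        f_trace=np.array(f_trace),
        h_source=h_orig[1:],
        h_noise=float(h_orig[0]),
        n_samples=n,
        priors=priors,
    )


# ---------------------------------------------------------------------------
# MAP sources and held-out prediction
# ---------------------------------------------------------------------------


def map_sources(result: InversionResult, gain, reduced_data: np.ndarray) -> np.ndarray:
    """MAP source coefficients J = Q_s L' Sigma_y^-1 Y (N x n)."""
    L = np.asarray(getattr(gain, "values", gain), float)
    Y = np.asarray(reduced_data, float)
    Sigma = result.model_cov
    try:
        chol = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("model covariance is not positive definite") from e
    iSY = np.linalg.solve(chol.T, np.linalg.solve(chol, Y))
    return result.priors.source_cov_times(L.T @ iSY, result.h_source)


def predict_heldout(
    result: InversionResult,
    gain_heldout,
    J_hat: np.ndarray,
    modes: Optional[np.ndarray] = None,
    fit_labels=None,
    heldout_labels=None,
) -> np.ndarray:
    """Predict held-out channels from the source estimate.

    Returns ``L_out @ J_hat`` in reduced (temporal-mode) space, or — when
    ``modes`` is given — mapped back to sample space as (E, C_out, S)
    epochs. Raises if fitted and held-out channel label sets overlap.
    """
    if fit_labels is not None and heldout_labels is not None:
        overlap = set(fit_labels) & set(heldout_labels)
        if overlap:
            raise ValueError(f"held-out channels overlap fitted set: {sorted(overlap)}")
    L_out = np.asarray(getattr(gain_heldout, "values", gain_heldout), float)
    Yp = L_out @ J_hat  # (C_out, E*R)
    if modes is None:
        return Yp
    R = modes.shape[1]
    C_out = Yp.shape[0]
    E = Yp.shape[1] // R
    return np.einsum("cer,sr->ecs", Yp.reshape(C_out, E, R), modes)
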