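"""De novo signature extraction by consensus non-negative matrix
factorization.

The catalog V (categories x samples) is modelled as V = P S + E with a
column-stochastic signature matrix P (M x K) and a non-negative exposure
matrix S (K x N). Extraction proceeds in five stages:

1.  random column-normalized starting matrices;
2.  a bootstrap of the catalog (Dirichlet-multinomial per sample) and
    refinement of the start by minimizing a penalized least-squares
    objective on the vectorized variables;
3.  several such refined starts, of which the five lowest-error ones are
    pooled and condensed by k-means into consensus starting matrices;
4.  multiplicative-update NMF from the consensus start;
5.  many independent repetitions per candidate K, summarized into a
    solution space whose silhouette widths and error gradients drive the
    choice of K.

Defaults for the penalty weights alpha (signature orthogonality), beta
(exposure sparsity) and gamma (update regularizer) are 0, i.e. plain NMF;
they are exposed for users who want accelerated convergence behaviour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import normalize as _l2_normalize

from .catalog import MutationCatalog

logger = logging.getLogger("sigcca")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class NMFConfig:
    """Settings for the extraction pipeline.

    ``inner_runs`` (I) is the number of refined starts per consensus
    initialization (minimum 5, since the 5 lowest-error ones are pooled);
    ``outer_runs`` (Î, default 20) is the number of independent repetitions
    per K in the solution space.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    init_iters: int = 20_000
    max_iters: int = 100_000
    inner_runs: int = 5
    outer_runs: int = 20
    tol: float = 1e-8
    seed: int = 0
    k_range: tuple[int, ...] = (2, 3, 4, 5)

    def __post_init__(self):
        if self.inner_runs < 5:
            raise ValueError("inner_runs must be >= 5 (five lowest-error runs are pooled)")
        if self.outer_runs < 1:
            raise ValueError("outer_runs must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("alpha, beta, gamma must be non-negative")


@dataclass
class SignatureMatrix:
    """P: column-stochastic signature profiles (M x K)."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("signature matrix must be non-negative")
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("signature columns must sum to 1 (within 1e-9)")

    @property
    def n_signatures(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


@dataclass
class ExposureMatrix:
    """S: per-sample signature loadings (K x N).

    ``normalized`` distinguishes absolute mutation loads from per-sample
    fractions (columns summing to 1).
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("exposure matrix must be non-negative")
        if self.normalized:
            sums = self.values.sum(axis=0)
            nonzero = sums > 0
            if not np.allclose(sums[nonzero], 1.0, atol=1e-9):
                raise ValueError("normalized exposure columns must sum to 1")

    def to_fractions(self) -> "ExposureMatrix":
        if self.normalized:
            return self
        sums = self.values.sum(axis=0)
        frac = np.divide(self.values, np.where(sums > 0, sums, 1.0))
        return ExposureMatrix(frac, list(self.row_labels), list(self.col_labels), True)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


@dataclass
class FactorizationResult:
    P: SignatureMatrix
    S: ExposureMatrix
    error: float          # squared Frobenius reconstruction error ||V - PS||^2
    iterations: int
    converged: bool
    error_trace: np.ndarray | None = None   # per-iteration E when requested


@dataclass
class SolutionSpace:
    """Per-K collections of factorization runs with stability summaries."""

    runs: dict[int, list[FactorizationResult]]
    silhouette: dict[int, float]
    error_mean: dict[int, float]
    error_std: dict[int, float]
    config: NMFConfig

    def summary(self) -> pd.DataFrame:
        ks = sorted(self.runs)
        return pd.DataFrame(
            {
                "K": ks,
                "silhouette": [self.silhouette[k] for k in ks],
                "error_mean": [self.error_mean[k] for k in ks],
                "error_std": [self.error_std[k] for k in ks],
                "n_runs": [len(self.runs[k]) for k in ks],
            }
        )

    def best_run(self, K: int) -> FactorizationResult:
        return min(self.runs[K], key=lambda r: r.error)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _as_matrix(V) -> np.ndarray:
    if isinstance(V, MutationCatalog):
        return np.asarray(V.values, dtype=float)
    return np.asarray(V, dtype=float)


def reconstruction_error(V, P: np.ndarray, S: np.ndarray) -> float:
    """Squared Frobenius norm ||V - PS||^2."""
    Vm = _as_matrix(V)
    R = Vm - P @ S
    return float(np.sum(R * R))


def _normalize_columns(P: np.ndarray, S: np.ndarray | None = None):
    """Scale P columns to sum 1; absorb the scale into S rows (PS preserved)."""
    scale = P.sum(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Pn = P / scale
    if S is None:
        return Pn
    return Pn, S * scale[:, None]


# ---------------------------------------------------------------------------
# Step 2: bootstrap + penalized refinement
# ---------------------------------------------------------------------------

def resample_catalog(V: MutationCatalog, seed=None) -> MutationCatalog:
    """Dirichlet-multinomial bootstrap of the catalog, column by column.

    Each sample's category weights are drawn from a Dirichlet whose
    concentration equals the observed counts (so zero categories stay
    zero), then counts are redrawn multinomially with the sample's total
    preserved. The expected resampled column equals the original.
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(V.values)
    out = values.copy()
    for n in range(values.shape[1]):
        col = values[:, n]
        total = int(col.sum())
        if total == 0:
            warnings.warn(f"sample {V.col_labels[n]!r} has no mutations; left unchanged")
            continue
        support = col > 0
        weights = rng.dirichlet(col[support].astype(float))
        draw = rng.multinomial(total, weights)
        newcol = np.zeros_like(col)
        newcol[support] = draw
        out[:, n] = newcol
    return MutationCatalog(out, list(V.row_labels), list(V.col_labels), V.scheme)


def penalized_objective(V, P: np.ndarray, S: np.ndarray,
                        alpha: float = 0.0, beta: float = 0.0) -> float:
    """0.5 ||V - PS||^2 + alpha * sum_{i != j} P_i . P_j + beta * sum(S).

    The orthogonality term runs over ordered pairs of distinct signature
    columns; the sparsity term is the plain sum of exposures.
    """
    Vm = _as_matrix(V)
    P = np.asarray(P, dtype=float)
    S = np.asarray(S, dtype=float)
    if (P < 0).any() or (S < 0).any():
        raise ValueError("P and S must be non-negative")
    R = Vm - P @ S
    G = P.T @ P
    ortho = float(G.sum() - np.trace(G))
    return 0.5 * float(np.sum(R * R)) + alpha * ortho + beta * float(S.sum())


def _objective_and_grad(x, V, M, K, N, alpha, beta):
    P = x[: M * K].reshape(M, K, order="F")
    S = x[M * K :].reshape(K, N, order="F")
    R = P @ S - V
    G = P.T @ P
    f = 0.5 * np.sum(R * R) + alpha * (G.sum() - np.trace(G)) + beta * S.sum()
    gP = R @ S.T
    if alpha:
        gP = gP + 2.0 * alpha * (P.sum(axis=1, keepdims=True) - P)
    gS = P.T @ R + beta
    return f, np.concatenate([gP.ravel(order="F"), gS.ravel(order="F")])


def _random_start(V: np.ndarray, K: int, rng) -> tuple[np.ndarray, np.ndarray]:
    M, N = V.shape
    P = rng.random((M, K)) + _EPS
    P /= P.sum(axis=0)
    frac = rng.random((K, N)) + _EPS
    frac /= frac.sum(axis=0)
    S = frac * V.sum(axis=0)
    return P, S


def refine_initialization(
    V: MutationCatalog | np.ndarray,
    K: int,
    config: NMFConfig,
    rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Refined starting matrices (P0, S0) for one bootstrap replicate.

    The two matrices are vectorized column-wise into one solution vector
    and the penalized objective is minimized with a bounded (non-negative)
    quasi-Newton method, capped at ``config.init_iters`` iterations. The
    smoothed solution is projected back to the feasible set: P columns are
    rescaled to sum 1 (the scale moving into S), and the result is only
    accepted if it does not worsen the objective of the random start.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    Vm = _as_matrix(V)
    M, N = Vm.shape
    for _attempt in range(5):
        P, S = _random_start(Vm, K, rng)
        f_start = penalized_objective(Vm, P, S, config.alpha, config.beta)
        x0 = np.concatenate([P.ravel(order="F"), S.ravel(order="F")])
        res = minimize(
            _objective_and_grad,
            x0,
            args=(Vm, M, K, N, config.alpha, config.beta),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * x0.size,
            options={"maxiter": config.init_iters},
        )
        if not np.isfinite(res.fun):
            logger.warning("non-finite objective in initialization; restarting")
            continue
        P1 = np.maximum(res.x[: M * K].reshape(M, K, order="F"), 0.0)
        S1 = np.maximum(res.x[M * K :].reshape(K, N, order="F"), 0.0)
        P1, S1 = _normalize_columns(P1 + _EPS, S1)
        f_end = penalized_objective(Vm, P1, S1, config.alpha, config.beta)
        if f_end <= f_start:
            return P1, S1
        return P, S  # descent contract: never worse than the random start
    raise RuntimeError("initialization failed to produce a finite objective")


# ---------------------------------------------------------------------------
# Step 3: consensus initialization
# ---------------------------------------------------------------------------

def consensus_initialization(
    V: MutationCatalog | np.ndarray,
    K: int,
    config: NMFConfig,
    rng=None,
    return_details: bool = False,
):
    """Pool the 5 lowest-error refined starts and condense them by k-means.

    Each of ``config.inner_runs`` starts is refined on a fresh bootstrap of
    V; the five with the smallest reconstruction error against the
    original V contribute their 5K signature columns, which are clustered
    (k-means++ with 10 restarts on L2-normalized columns, i.e. cosine
    geometry) into K groups. Consensus signatures are the cluster means of
    the raw columns renormalized to sum 1; the matched exposure rows are
    averaged with the same assignments.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    Vm = _as_matrix(V)
    runs = []
    for _ in range(config.inner_runs):
        if isinstance(V, MutationCatalog):
            Vboot = resample_catalog(V, rng)
        else:
            Vboot = _bootstrap_matrix(Vm, rng)
        P0, S0 = refine_initialization(Vboot, K, config, rng)
        err = reconstruction_error(Vm, P0, S0)
        runs.append((err, P0, S0))
    runs.sort(key=lambda t: t[0])
    best = runs[:5]

    cols = np.hstack([P for _, P, _ in best])          # M x 5K
    rows = np.vstack([S for _, _, S in best])          # 5K x N
    X = _l2_normalize(cols.T)                          # unit-norm columns
    km = KMeans(n_clusters=K, n_init=10,
                random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(X)
    M = Vm.shape[0]
    P_cons = np.zeros((M, K))
    S_cons = np.zeros((K, Vm.shape[1]))
    for k in range(K):
        members = labels == k
        if not members.any():  # sklearn relocates empty clusters, but be safe
            far = np.argmax(((X - km.cluster_centers_[k]) ** 2).sum(axis=1))
            members = np.zeros_like(members)
            members[far] = True
            logger.warning("empty consensus cluster re-seeded from farthest column")
        P_cons[:, k] = cols[:, members].mean(axis=1)
        S_cons[k, :] = rows[members, :].mean(axis=0)
    P_cons, S_cons = _normalize_columns(P_cons + _EPS, S_cons)
    if return_details:
        details = {"pooled_columns": cols, "cluster_labels": labels,
                   "errors": [e for e, _, _ in best]}
        return P_cons, S_cons, details
    return P_cons, S_cons


def _bootstrap_matrix(Vm: np.ndarray, rng) -> np.ndarray:
    out = Vm.copy()
    for n in range(Vm.shape[1]):
        col = Vm[:, n]
        total = col.sum()
        if total <= 0:
            continue
        support = col > 0
        weights = rng.dirichlet(col[support])
        draw = rng.multinomial(int(round(total)), weights)
        newcol = np.zeros_like(col)
        newcol[support] = draw
        out[:, n] = newcol
    return out


# ---------------------------------------------------------------------------
# Step 4: multiplicative updates
# ---------------------------------------------------------------------------

def multiplicative_nmf(
    V: MutationCatalog | np.ndarray,
    P0: np.ndarray,
    S0: np.ndarray,
    config: NMFConfig,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
    signature_names: Sequence[str] | None = None,
    track_errors: bool = False,
) -> FactorizationResult:
    """Alternating multiplicative updates from a given start.

    P <- P * (V S^T) / (P S S^T),  S <- S * (P^T V) / (P^T P S + gamma).
    Stops when the relative change of E = ||V - PS||^2 over a 10-iteration
    window falls below ``config.tol`` or after ``config.max_iters``
    iterations. The returned P is column-stochastic with the scale absorbed
    into S (PS unchanged).
    """
    Vm = _as_matrix(V)
    P = np.asarray(P0, dtype=float).copy()
    S = np.asarray(S0, dtype=float).copy()
    gamma = config.gamma
    err_prev = reconstruction_error(Vm, P, S)
    trace: list[float] | None = [err_prev] if track_errors else None
    it = 0
    converged = False
    floored = False
    while it < config.max_iters:
        for _ in range(10):
            num = Vm @ S.T
            den = P @ (S @ S.T)
            if (den < _EPS).any():
                den = np.maximum(den, _EPS)
                if not floored:
                    logger.info("multiplicative update denominator floored at %g", _EPS)
                    floored = True
            P *= num / den
            num = P.T @ Vm
            den = P.T @ P @ S + gamma
            if (den < _EPS).any():
                den = np.maximum(den, _EPS)
                if not floored:
                    logger.info("multiplicative update denominator floored at %g", _EPS)
                    floored = True
            S *= num / den
            it += 1
            if trace is not None:
                trace.append(reconstruction_error(Vm, P, S))
            if it >= config.max_iters:
                break
        err = reconstruction_error(Vm, P, S)
        if abs(err_prev - err) <= config.tol * max(err_prev, _EPS):
            converged = True
            err_prev = err
            break
        err_prev = err

    P, S = _normalize_columns(P + _EPS, S)
    if row_labels is None and isinstance(V, MutationCatalog):
        row_labels = list(V.row_labels)
    if col_labels is None and isinstance(V, MutationCatalog):
        col_labels = list(V.col_labels)
    K = P.shape[1]
    sig_names = list(signature_names) if signature_names else [f"Sig{k+1}" for k in range(K)]
    row_labels = list(row_labels) if row_labels else [f"cat{i}" for i in range(P.shape[0])]
    col_labels = list(col_labels) if col_labels else [f"s{j}" for j in range(S.shape[1])]
    return FactorizationResult(
        P=SignatureMatrix(P, row_labels, sig_names),
        S=ExposureMatrix(S, sig_names, col_labels, normalized=False),
        error=reconstruction_error(Vm, P, S),
        iterations=it,
        converged=converged,
        error_trace=None if trace is None else np.asarray(trace),
    )


def extract_signatures(
    V: MutationCatalog | np.ndarray,
    K: int,
    config: NMFConfig,
    rng=None,
) -> FactorizationResult:
    """One full de novo run: consensus initialization + multiplicative NMF."""
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    P0, S0 = consensus_initialization(V, K, config, rng)
    return multiplicative_nmf(V, P0, S0, config)


# ---------------------------------------------------------------------------
# Step 5: solution space and K selection
# ---------------------------------------------------------------------------

def build_solution_space(
    V: MutationCatalog | np.ndarray,
    config: NMFConfig,
) -> SolutionSpace:
    """Run ``outer_runs`` independent extractions per candidate K.

    Per-K stability is the mean silhouette width of all pooled signature
    columns clustered into K groups under cosine distance; reconstruction
    errors are summarized by mean and standard deviation.
    """
    if not config.k_range:
        raise ValueError("k_range must be nonempty")
    master = np.random.default_rng(config.seed)
    runs: dict[int, list[FactorizationResult]] = {}
    silhouette: dict[int, float] = {}
    err_mean: dict[int, float] = {}
    err_std: dict[int, float] = {}
    for K in config.k_range:
        results = [
            extract_signatures(V, K, config, rng=master.spawn(1)[0])
            for _ in range(config.outer_runs)
        ]
        runs[K] = results
        errors = np.array([r.error for r in results])
        err_mean[K] = float(errors.mean())
        err_std[K] = float(errors.std(ddof=1)) if len(errors) > 1 else 0.0
        cols = np.hstack([r.P.values for r in results])  # M x (outer_runs*K)
        if K == 1:
            silhouette[K] = 1.0  # a single cluster is trivially stable
            continue
        X = _l2_normalize(cols.T)
        km = KMeans(n_clusters=K, n_init=10, random_state=config.seed)
        labels = km.fit_predict(X)
        if len(set(labels)) < 2:
            silhouette[K] = 0.0
        else:
            sil = silhouette_score(cols.T, labels, metric="cosine")
            silhouette[K] = float(np.clip(sil, -1.0, 1.0))
    return SolutionSpace(runs, silhouette, err_mean, err_std, config)


def select_k(
    space: SolutionSpace,
    silhouette_threshold: float = 0.9,
    flat_fraction: float = 0.05,
) -> tuple[int, pd.DataFrame, bool]:
    """Choose K from the solution space.

    Returns the largest K whose mean silhouette meets the stability
    threshold and whose error gradient to K+1 has flattened. Error drops
    are normalized scree-style by the mean error at the smallest K, so the
    flattening judgement is not inflated as the per-K error approaches the
    noise floor; a drop below ``flat_fraction`` of that scale counts as
    flat. The largest K examined has no K+1 evidence and can only be
    chosen through the fallback. If no K qualifies, the argmax-silhouette
    K is returned flagged as unstable. The full diagnostic table is always
    returned.
    """
    ks = sorted(space.runs)
    if len(ks) < 2:
        raise ValueError("solution space must cover at least two values of K")
    table = space.summary()
    scale = max(space.error_mean[ks[0]], _EPS)
    grad = []
    for i, k in enumerate(ks):
        if i + 1 < len(ks):
            e0, e1 = space.error_mean[k], space.error_mean[ks[i + 1]]
            grad.append((e0 - e1) / scale)
        else:
            grad.append(np.nan)
    table["error_drop_to_next"] = grad
    table["stable"] = [
        space.silhouette[k] >= silhouette_threshold
        and not np.isnan(g)
        and g < flat_fraction
        for k, g in zip(ks, grad)
    ]
    stable_ks = [k for k, ok in zip(ks, table["stable"]) if ok]
    if stable_ks:
        return max(stable_ks), table, True
    fallback = max(ks, key=lambda k: space.silhouette[k])
    logger.warning("no stable solution; falling back to argmax-silhouette K=%d", fallback)
    return fallback, table, False
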