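"""Exposure refitting against a fixed signature set (inverse NMF).

Given a catalog V and a known column-stochastic signature matrix P (for
example a COSMIC release), the per-sample exposures S are the non-negative
solution of V ~ P S, obtained by iterating the multiplicative update

    S <- S * (P^T V) / (P^T P S + gamma)

from a uniform start. Because P is fixed the problem is convex in S, so
any positive start converges to the same fixed point; this also works for
a single tumor (N = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .catalog import MutationCatalog
from .nmf import ExposureMatrix, SignatureMatrix, _EPS

logger = logging.getLogger("sigcca")


class AlignmentError(ValueError):
    """Catalog and signature category spaces do not match."""


@dataclass
class RefitResult:
    S: ExposureMatrix            # absolute loadings (columns sum to sample totals)
    fractions: ExposureMatrix    # per-sample normalized view
    residual: np.ndarray         # per-sample squared reconstruction error
    iterations: int
    zero_samples: list[str]      # samples with no mutations (zero exposures)


def _align(V: MutationCatalog | np.ndarray, P: SignatureMatrix | np.ndarray):
    if isinstance(V, MutationCatalog) and isinstance(P, SignatureMatrix):
        if list(V.row_labels) != list(P.row_labels):
            v_only = set(V.row_labels) - set(P.row_labels)
            p_only = set(P.row_labels) - set(V.row_labels)
            if v_only or p_only:
                raise AlignmentError(
                    f"category mismatch; catalog-only: {sorted(v_only)[:5]}, "
                    f"signatures-only: {sorted(p_only)[:5]}"
                )
            # same set, different order: reorder P to the catalog order
            df = P.to_dataframe().loc[list(V.row_labels)]
            P = SignatureMatrix(df.to_numpy(), list(df.index), list(df.columns))
    Vm = np.asarray(V.values if isinstance(V, MutationCatalog) else V, dtype=float)
    Pm = np.asarray(P.values if isinstance(P, SignatureMatrix) else P, dtype=float)
    if Vm.shape[0] != Pm.shape[0]:
        raise AlignmentError(
            f"catalog has {Vm.shape[0]} categories but signatures have {Pm.shape[0]}"
        )
    return Vm, Pm, P


def inverse_nmf(
    V: MutationCatalog | np.ndarray,
    P: SignatureMatrix | np.ndarray,
    gamma: float = 0.0,
    tol: float = 1e-10,
    max_iters: int = 100_000_000,
    check_every: int = 50,
) -> RefitResult:
    """Estimate exposures for fixed signatures by multiplicative updates.

    Iterates until the relative change of the total squared residual drops
    below ``tol`` (checked every ``check_every`` iterations) or the
    iteration ceiling is reached. Samples without mutations get zero
    exposures and are flagged.
    """
    Vm, Pm, P_aligned = _align(V, P)
    M, N = Vm.shape
    K = Pm.shape[1]
    totals = Vm.sum(axis=0)
    zero_cols = totals == 0

    S = np.tile((np.where(zero_cols, 0.0, totals) / K), (K, 1))
    PtV = Pm.T @ Vm
    PtP = Pm.T @ Pm
    err_prev = np.inf
    it = 0
    while it < max_iters:
        for _ in range(check_every):
            den = np.maximum(PtP @ S + gamma, _EPS)
            S *= PtV / den
            it += 1
            if it >= max_iters:
                break
        R = Vm - Pm @ S
        err = float(np.sum(R * R))
        if abs(err_prev - err) <= tol * max(err_prev if np.isfinite(err_prev) else err, _EPS):
            break
        err_prev = err

    S[:, zero_cols] = 0.0
    sig_names = (list(P_aligned.col_labels) if isinstance(P_aligned, SignatureMatrix)
                 else [f"Sig{k+1}" for k in range(K)])
    col_labels = (list(V.col_labels) if isinstance(V, MutationCatalog)
                  else [f"s{j}" for j in range(N)])
    residual = ((Vm - Pm @ S) ** 2).sum(axis=0)
    zero_samples = [col_labels[j] for j in np.flatnonzero(zero_cols)]
    if zero_samples:
        logger.warning("zero-mutation samples got zero exposures: %s", zero_samples)
    S_abs = ExposureMatrix(S, sig_names, col_labels, normalized=False)
    return RefitResult(
        S=S_abs,
        fractions=S_abs.to_fractions(),
        residual=residual,
        iterations=it,
        zero_samples=zero_samples,
    )


def presence_calls(fractions: ExposureMatrix | np.ndarray,
                   threshold: float = 0.20) -> np.ndarray:
    """Signature presence per sample: fraction >= threshold (inclusive).

    A signature is considered present in a sample when it explains at
    least 20% (by default) of the sample's mutations.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if isinstance(fractions, ExposureMatrix):
        if not fractions.normalized:
            fractions = fractions.to_fractions()
        values = fractions.values
    else:
        values = np.asarray(fractions, dtype=float)
    return values >= threshold
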