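"""Cosine-similarity comparison of signatures against a reference set."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nmf import SignatureMatrix
from .refit import AlignmentError


def cosine_similarity(a, b) -> float:
    """a . b / (||a|| ||b||); errors on zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(a @ b / (na * nb))


@dataclass
class MatchResult:
    similarity: pd.DataFrame   # extracted x reference cosine matrix
    best: pd.DataFrame         # per extracted signature: best match + renaming


def similarity_matrix(P: SignatureMatrix, ref: SignatureMatrix) -> pd.DataFrame:
    if list(P.row_labels) != list(ref.row_labels):
        if set(P.row_labels) != set(ref.row_labels):
            raise AlignmentError("signature sets are over different category spaces")
        ref_df = ref.to_dataframe().loc[list(P.row_labels)]
        ref = SignatureMatrix(ref_df.to_numpy(), list(ref_df.index), list(ref_df.columns))
    A = P.values / np.linalg.norm(P.values, axis=0)
    B = ref.values / np.linalg.norm(ref.values, axis=0)
    return pd.DataFrame(A.T @ B, index=list(P.col_labels), columns=list(ref.col_labels))


def match_to_reference(
    P: SignatureMatrix,
    ref: SignatureMatrix,
    display_threshold: float = 0.6,
    rename_threshold: float = 0.8,
) -> MatchResult:
    """Best reference match per extracted signature.

    Matches at or above ``display_threshold`` are listed alongside the
    best one; ties on the best score are broken by reference column order.
    An extracted signature whose best score reaches ``rename_threshold``
    is renamed after its reference match with a ``*`` suffix (e.g.
    ``SBS2*``); the rest are labelled ``New``, ``New2``, ... in order.
    """
    sim = similarity_matrix(P, ref)
    rows = []
    new_count = 0
    for name in sim.index:
        scores = sim.loc[name]
        best_ref = scores.idxmax()  # first column on ties
        best_score = float(scores[best_ref])
        above = [f"{r}:{scores[r]:.3f}" for r in sim.columns if scores[r] >= display_threshold]
        if best_score >= rename_threshold:
            assigned = f"{best_ref}*"
        else:
            new_count += 1
            assigned = "New" if new_count == 1 else f"New{new_count}"
        rows.append(
            {
                "extracted": name,
                "best_match": best_ref,
                "cosine": best_score,
                "assigned_name": assigned,
                "matches_above_threshold": ";".join(above),
            }
        )
    return MatchResult(similarity=sim, best=pd.DataFrame(rows).set_index("extracted"))
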