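"""Gene-level cumulative contribution abundance (CCA).

Given a factorization V ~ P S, each mutation category m in each tumor n is
attributed probabilistically to the K signatures:

    phi_mn   = sum_k P_mk S_kn                 (total modelled intensity)
    rho_smn  = P_ms S_sn / phi_mn              (attribution probability)

Per-gene mutation counts N_mgn (the tensor Gamma) define gene impact
factors rho_mgn = N_mgn / sum_i N_min, and their gene-length-scaled
variant rho'_mgn with each count divided by the gene length l_g. The
contribution of signature s through category m of gene g in tumor n is

    theta_sgmn = rho_smn * rho_mgn * w_mn

with w_mn = 1 (plain) or w_mn = (sum_g N_mgn) / (sum_mg N_mgn)
(count-weighted, the default, which makes the per-sample total over s, g
and m equal 1). Cohort abundances accumulate over categories and samples:

    alpha_sg = sum_m sum_n theta_sgmn          (cumulative abundance)
    eta_sg   = sum_m sum_n gamma_sgmn          (length-normalized variant)

The per-sample gene CCA is the count-weighted mean attribution

    c(s, g, n) = sum_m N_mgn rho_smn / sum_m N_mgn,

a proper fraction over signatures for every mutated gene. Association of a
gene's mutation status with a signature is scored by a two-sided rank-sum
test on per-sample contributions and a permutation test on the difference
in median CCA, with Benjamini-Hochberg correction per signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import fisher_exact, ranksums
from statsmodels.stats.multitest import multipletests

from .catalog import (
    ClassificationSkip,
    MutationCatalog,
    MutationRecord,
    ReferenceGenome,
    SCHEME_CATEGORIES,
    _SCHEME_CLASSES,
    classify,
)
from .nmf import ExposureMatrix, SignatureMatrix

logger = logging.getLogger("sigcca")


# ---------------------------------------------------------------------------
# Gene annotation and count tensor
# ---------------------------------------------------------------------------

class GeneAnnotation(dict):
    """gene symbol -> length in bp (positive)."""

    def __init__(self, lengths: Mapping[str, int]):
        for g, l in lengths.items():
            if l <= 0:
                raise ValueError(f"gene {g!r} has non-positive length {l}")
        super().__init__(lengths)

    @classmethod
    def from_table(cls, path: str | Path, sep: str = "\t") -> "GeneAnnotation":
        df = pd.read_csv(path, sep=sep)
        if df.shape[1] < 2:
            raise ValueError("gene table needs symbol and length columns")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int))))


@dataclass
class GeneCountTensor:
    """Gamma: per-category, per-gene, per-sample mutation counts (M x G x N)."""

    counts: np.ndarray
    categories: list[str]
    genes: list[str]
    samples: list[str]
    unassigned: int = 0   # records whose gene was absent from the gene list

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.categories), len(self.genes), len(self.samples)):
            raise ValueError("tensor shape does not match labels")

    def per_sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=(0, 1))


def build_gene_tensor(
    records: Iterable[MutationRecord],
    genome: ReferenceGenome,
    scheme: str,
    gene_list: Sequence[str],
    samples: Sequence[str] | None = None,
    nonsilent_only: bool = False,
) -> GeneCountTensor:
    """Count gene-labelled mutations into the Gamma tensor.

    Only mutations whose gene is in ``gene_list`` are counted
    (intersection semantics); the rest go into the ``unassigned`` tally.
    With ``nonsilent_only`` records flagged silent (or without a
    classification) are dropped.
    """
    if not gene_list:
        raise ValueError("gene_list must be nonempty")
    categories = SCHEME_CATEGORIES[scheme]
    cat_index = {c: i for i, c in enumerate(categories)}
    gene_index = {g: i for i, g in enumerate(gene_list)}
    wanted = _SCHEME_CLASSES[scheme]

    sample_order: list[str] = list(samples) if samples is not None else []
    sample_index = {s: i for i, s in enumerate(sample_order)}
    triples: list[tuple[int, int, int]] = []
    unassigned = 0
    for rec in records:
        if rec.variant_class not in wanted:
            continue
        if nonsilent_only and not rec.is_nonsilent:
            continue
        try:
            cat = classify(rec, genome, scheme)
        except ClassificationSkip:
            continue
        if rec.sample_id not in sample_index:
            if samples is not None:
                continue
            sample_index[rec.sample_id] = len(sample_order)
            sample_order.append(rec.sample_id)
        if rec.gene is None or rec.gene not in gene_index:
            unassigned += 1
            continue
        triples.append((cat_index[cat], gene_index[rec.gene], sample_index[rec.sample_id]))

    counts = np.zeros((len(categories), len(gene_list), len(sample_order)), dtype=np.int64)
    for i, j, k in triples:
        counts[i, j, k] += 1
    return GeneCountTensor(counts, list(categories), list(gene_list), sample_order,
                           unassigned=unassigned)


# ---------------------------------------------------------------------------
# Signature attribution and gene impact
# ---------------------------------------------------------------------------

@dataclass
class SignatureAttribution:
    """phi (M x N) and rho (K x M x N); rho sums to 1 over s where phi > 0."""

    phi: np.ndarray
    rho: np.ndarray
    defined: np.ndarray          # (M x N) mask where phi > 0
    signatures: list[str]
    categories: list[str]
    samples: list[str]


def signature_attribution(P: SignatureMatrix, S: ExposureMatrix) -> SignatureAttribution:
    """Per-category, per-sample attribution probabilities.

    rho is scale-invariant in each sample's exposures, so absolute or
    normalized S give identical probabilities. Cells with phi = 0 carry
    rho = 0 and are flagged undefined.
    """
    Pm = np.asarray(P.values, dtype=float)
    Sm = np.asarray(S.values, dtype=float)
    if Pm.shape[1] != Sm.shape[0]:
        raise ValueError("P and S have incompatible signature dimensions")
    phi = Pm @ Sm                                      # M x N
    defined = phi > 0
    denom = np.where(defined, phi, 1.0)
    rho = Pm[:, :, None].transpose(1, 0, 2) * Sm[:, None, :] / denom[None, :, :]
    rho[:, ~defined] = 0.0
    return SignatureAttribution(
        phi=phi,
        rho=rho,
        defined=defined,
        signatures=list(P.col_labels),
        categories=list(P.row_labels),
        samples=list(S.col_labels),
    )


@dataclass
class GeneImpact:
    """Impact factors rho_mgn (and length-scaled rho'_mgn when lengths given)."""

    tensor: GeneCountTensor
    rho: np.ndarray                       # M x G x N, sums to 1 over g where defined
    rho_length: np.ndarray | None = None  # length-scaled variant
    lengths: np.ndarray | None = None


def gene_impact(tensor: GeneCountTensor,
                lengths: GeneAnnotation | None = None) -> GeneImpact:
    """Share of each gene in each (category, sample) mutation count."""
    N = tensor.counts.astype(float)
    totals = N.sum(axis=1)                              # M x N
    denom = np.where(totals > 0, totals, 1.0)
    rho = N / denom[:, None, :]
    rho_len = None
    lvec = None
    if lengths is not None:
        mutated = np.flatnonzero(tensor.counts.sum(axis=(0, 2)) > 0)
        missing = [tensor.genes[g] for g in mutated if tensor.genes[g] not in lengths]
        if missing:
            raise KeyError(f"gene length missing for mutated gene(s): {missing}")
        lvec = np.array([float(lengths.get(g, np.nan)) for g in tensor.genes])
        weighted = N / lvec[None, :, None]
        weighted = np.nan_to_num(weighted)
        wt = weighted.sum(axis=1)
        wdenom = np.where(wt > 0, wt, 1.0)
        rho_len = weighted / wdenom[:, None, :]
    return GeneImpact(tensor=tensor, rho=rho, rho_length=rho_len, lengths=lvec)


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

@dataclass
class CCAResult:
    alpha: pd.DataFrame                 # K x G cohort cumulative abundance
    eta: pd.DataFrame | None            # K x G length-normalized variant
    cca: np.ndarray                     # K x G x N per-sample gene CCA
    signatures: list[str]
    genes: list[str]
    samples: list[str]
    weighting: str
    attribution: SignatureAttribution = field(repr=False)
    impact: GeneImpact = field(repr=False)

    def per_sample_frame(self, signature: str) -> pd.DataFrame:
        s = self.signatures.index(signature)
        return pd.DataFrame(self.cca[s], index=self.genes, columns=self.samples)

    def theta(self) -> np.ndarray:
        """Full contribution tensor theta_sgmn (K x G x M x N); large."""
        w = _weights(self.impact.tensor, self.weighting)
        return np.einsum("smn,mgn,mn->sgmn", self.attribution.rho,
                         self.impact.rho, w)


def _weights(tensor: GeneCountTensor, weighting: str) -> np.ndarray:
    if weighting == "plain":
        return np.ones((len(tensor.categories), len(tensor.samples)))
    if weighting == "count_weighted":
        per_cat = tensor.counts.sum(axis=1).astype(float)      # M x N
        per_sample = per_cat.sum(axis=0)                       # N
        denom = np.where(per_sample > 0, per_sample, 1.0)
        return per_cat / denom[None, :]
    raise ValueError(f"unknown weighting {weighting!r}")


def compute_cca(
    attribution: SignatureAttribution,
    impact: GeneImpact,
    weighting: str = "count_weighted",
) -> CCAResult:
    """Cohort alpha/eta and per-sample gene CCA from attribution and impact.

    With the default count weighting the theta contributions of a sample
    sum to 1 over signatures, genes and categories, so alpha accumulates
    one unit per sample with gene-annotated mutations.
    """
    tensor = impact.tensor
    if list(attribution.categories) != list(tensor.categories):
        raise ValueError("attribution and tensor use different category spaces")
    if list(attribution.samples) != list(tensor.samples):
        raise ValueError("attribution and tensor use different sample sets")
    w = _weights(tensor, weighting)
    alpha = np.einsum("smn,mgn,mn->sg", attribution.rho, impact.rho, w)
    eta = None
    if impact.rho_length is not None:
        eta = np.einsum("smn,mgn,mn->sg", attribution.rho, impact.rho_length, w)

    counts = tensor.counts.astype(float)                       # M x G x N
    gene_totals = counts.sum(axis=0)                           # G x N
    denom = np.where(gene_totals > 0, gene_totals, 1.0)
    cca = np.einsum("smn,mgn->sgn", attribution.rho, counts) / denom[None, :, :]

    sig = attribution.signatures
    alpha_df = pd.DataFrame(alpha, index=sig, columns=tensor.genes)
    eta_df = None if eta is None else pd.DataFrame(eta, index=sig, columns=tensor.genes)
    return CCAResult(
        alpha=alpha_df,
        eta=eta_df,
        cca=cca,
        signatures=list(sig),
        genes=list(tensor.genes),
        samples=list(tensor.samples),
        weighting=weighting,
        attribution=attribution,
        impact=impact,
    )


def flag_low_cca(cca: CCAResult, threshold: float = 0.06) -> np.ndarray:
    """Boolean (K x G x N): gene has little effect on the signature in the
    sample when its CCA is strictly below the threshold (default 6%)."""
    return cca.cca < threshold


# ---------------------------------------------------------------------------
# Association statistics
# ---------------------------------------------------------------------------

def associate_gene_signature(
    cca: CCAResult,
    mutation_status: pd.DataFrame | np.ndarray,
    exposures: ExposureMatrix | None = None,
    min_mutated_fraction: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = 0,
    bh_per_signature: bool = True,
) -> pd.DataFrame:
    """Gene x signature association battery.

    For every gene mutated in more than ``min_mutated_fraction`` of
    samples and every signature:

    * a two-sided rank-sum test compares per-sample signature
      contributions (exposure fractions when given, otherwise the gene's
      per-sample CCA) between mutant and wild-type samples;
    * a permutation test shuffles mutation-status labels ``n_perm`` times
      and scores the difference in median per-sample gene CCA, with
      add-one correction;
    * Benjamini-Hochberg q-values are computed per signature (or globally
      with ``bh_per_signature=False``).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    status = _status_matrix(mutation_status, cca.genes, cca.samples)
    N = len(cca.samples)
    rng = np.random.default_rng(seed)

    if exposures is not None:
        expo = exposures.to_fractions().values
    else:
        expo = None

    rows = []
    for gi, gene in enumerate(cca.genes):
        mut = status[gi]
        n_mut = int(mut.sum())
        if n_mut / N <= min_mutated_fraction:
            continue
        # one shared set of label permutations across the signatures
        perm_idx = np.argsort(rng.random((n_perm, N)), axis=1)[:, :n_mut]
        c_gene = cca.cca[:, gi, :]                      # K x N
        for si, signame in enumerate(cca.signatures):
            vals = c_gene[si]
            contrib = expo[si] if expo is not None else vals
            flagged = n_mut == 0 or n_mut == N
            if flagged:
                stat = pval = obs = perm_p = np.nan
            else:
                res = ranksums(contrib[mut], contrib[~mut])
                stat, pval = float(res.statistic), float(res.pvalue)
                obs = float(np.median(vals[mut]) - np.median(vals[~mut]))
                med_mut = np.median(vals[perm_idx], axis=1)   # n_perm x n_mut
                med_wt = _median_complement(vals, perm_idx)
                diffs = med_mut - med_wt
                perm_p = (1 + np.sum(np.abs(diffs) >= abs(obs))) / (n_perm + 1)
            rows.append({
                "gene": gene,
                "signature": signame,
                "n_mutant": n_mut,
                "n_wildtype": N - n_mut,
                "ranksum_stat": stat,
                "ranksum_p": pval,
                "median_cca_diff": obs,
                "perm_p": perm_p,
                "flagged": flagged,
            })
    result = pd.DataFrame(rows)
    if result.empty:
        result["q"] = []
        return result
    result["q"] = np.nan
    ok = ~result["flagged"] & result["perm_p"].notna()
    if bh_per_signature:
        for signame in result["signature"].unique():
            m = ok & (result["signature"] == signame)
            if m.any():
                result.loc[m, "q"] = multipletests(result.loc[m, "perm_p"],
                                                   method="fdr_bh")[1]
    elif ok.any():
        result.loc[ok, "q"] = multipletests(result.loc[ok, "perm_p"], method="fdr_bh")[1]
    return result


def _median_complement(vals: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
    """Median of the non-selected entries for each permutation row."""
    n = vals.size
    mask = np.ones((perm_idx.shape[0], n), dtype=bool)
    rows = np.repeat(np.arange(perm_idx.shape[0]), perm_idx.shape[1])
    mask[rows, perm_idx.ravel()] = False
    out = np.empty(perm_idx.shape[0])
    for i in range(perm_idx.shape[0]):
        out[i] = np.median(vals[mask[i]])
    return out


def _status_matrix(mutation_status, genes: list[str], samples: list[str]) -> np.ndarray:
    if isinstance(mutation_status, pd.DataFrame):
        return mutation_status.loc[genes, samples].to_numpy(dtype=bool)
    arr = np.asarray(mutation_status, dtype=bool)
    if arr.shape != (len(genes), len(samples)):
        raise ValueError("mutation_status shape does not match genes x samples")
    return arr


def fisher_presence_test(
    presence: np.ndarray,
    mutation_status: pd.DataFrame | np.ndarray,
    signatures: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Fisher exact test of signature presence vs gene mutation.

    Degenerate 2x2 margins yield p = 1 with the odds ratio flagged
    undefined; an infinite odds ratio is flagged separately.
    """
    pres = np.asarray(presence, dtype=bool)
    if isinstance(mutation_status, pd.DataFrame):
        genes = list(mutation_status.index) if genes is None else list(genes)
        status = mutation_status.to_numpy(dtype=bool)
    else:
        status = np.asarray(mutation_status, dtype=bool)
        genes = [f"gene{i}" for i in range(status.shape[0])] if genes is None else list(genes)
    signatures = ([f"Sig{k+1}" for k in range(pres.shape[0])]
                  if signatures is None else list(signatures))
    rows = []
    for gi, gene in enumerate(genes):
        for si, signame in enumerate(signatures):
            a = int(np.sum(status[gi] & pres[si]))
            b = int(np.sum(status[gi] & ~pres[si]))
            c = int(np.sum(~status[gi] & pres[si]))
            d = int(np.sum(~status[gi] & ~pres[si]))
            degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
            if degenerate:
                odds, p = np.nan, 1.0
            else:
                odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({
                "gene": gene, "signature": signame,
                "table": (a, b, c, d),
                "odds_ratio": float(odds) if np.isfinite(odds) else np.nan,
                "odds_ratio_infinite": bool(np.isinf(odds)),
                "p": float(p),
                "degenerate": degenerate,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Image-matrix export
# ---------------------------------------------------------------------------

def hclust_gene_order(cca: CCAResult) -> list[str]:
    """Gene order from agglomerative clustering (average linkage,
    Euclidean) of cohort CCA profiles (alpha columns)."""
    profiles = cca.alpha.to_numpy().T        # G x K
    if profiles.shape[0] < 3:
        return list(cca.genes)
    Z = linkage(profiles, method="average", metric="euclidean")
    return [cca.genes[i] for i in leaves_list(Z)]


def image_matrix(
    cca: CCAResult,
    signature: str,
    sample: str,
    gene_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Square image of one sample's gene CCA vector under one signature.

    Genes are laid out row-major in the given (or clustering-derived)
    order into the smallest square grid holding all genes, padded with
    zeros.
    """
    order = list(gene_order) if gene_order is not None else hclust_gene_order(cca)
    if set(order) != set(cca.genes):
        raise ValueError("gene_order must be a permutation of the CCA gene set")
    s = cca.signatures.index(signature)
    n = cca.samples.index(sample)
    idx = [cca.genes.index(g) for g in order]
    vec = cca.cca[s, idx, n]
    side = math.isqrt(len(vec) - 1) + 1 if len(vec) > 0 else 0
    if side * side < len(vec):  # pragma: no cover - isqrt guard
        side += 1
    grid = np.zeros(side * side)
    grid[: len(vec)] = vec
    return grid.reshape(side, side)
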