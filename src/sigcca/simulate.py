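"""Truth-known synthetic data: catalogs, signatures and MAF+FASTA fixtures.

Two generators cover the pipeline. ``simulate_catalog`` draws a catalog
V = P S (+ multinomial sampling noise) from known sparse signatures so
extraction and refitting can be scored against the truth.
``simulate_maf_reference`` goes one level deeper: it writes a miniature
reference genome (one contig per gene) and a MAF whose substitutions sit
at positions whose trinucleotide context realizes a category drawn from a
known signature mixture, with configurable per-gene signature preference;
engineered homopolymer/repeat/microhomology templates supply indels for
every ID-83 bin family. The generator records every intended category so
catalog construction can be checked for exact agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    BASES,
    ID83_CATEGORIES,
    MutationCatalog,
    SBS96_CATEGORIES,
    SCHEME_CATEGORIES,
    revcomp,
)
from .nmf import ExposureMatrix, SignatureMatrix


# ---------------------------------------------------------------------------
# Signature / catalog simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Ground truth behind a simulated data set."""

    P_true: SignatureMatrix
    S_true: ExposureMatrix                 # absolute loadings (K x N)
    seed: int | None
    gene_preferences: dict = field(default_factory=dict)
    intended_counts: dict[str, pd.DataFrame] = field(default_factory=dict)
    records: list = field(default_factory=list)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.P_true.to_dataframe().to_csv(directory / "P_true.tsv", sep="\t")
        self.S_true.to_dataframe().to_csv(directory / "S_true.tsv", sep="\t")
        for scheme, df in self.intended_counts.items():
            df.to_csv(directory / f"intended_{scheme}.tsv", sep="\t")
        meta = {"seed": self.seed,
                "gene_preferences": {g: list(map(float, np.atleast_1d(w)))
                                     for g, w in self.gene_preferences.items()}}
        (directory / "truth.json").write_text(json.dumps(meta, indent=2))


def random_signatures(
    M: int,
    K: int,
    rng,
    concentration: float = 0.1,
    max_pairwise_cosine: float = 0.3,
    max_tries: int = 200,
) -> np.ndarray:
    """K sparse, well-separated signature columns over M categories.

    Columns are Dirichlet draws with a sparse concentration; the whole set
    is redrawn until all pairwise cosines fall below the separation bound.
    """
    for _ in range(max_tries):
        P = rng.dirichlet(np.full(M, concentration), size=K).T
        U = P / np.linalg.norm(P, axis=0)
        G = U.T @ U
        np.fill_diagonal(G, 0.0)
        if G.max() < max_pairwise_cosine:
            return P
    raise RuntimeError("could not draw well-separated signatures; "
                       "lower K or raise max_pairwise_cosine")


def simulate_catalog(
    M: int = 96,
    N: int = 50,
    K: int = 3,
    mutations_per_sample: int = 1000,
    noise: str = "multinomial",
    seed: int | None = 0,
) -> tuple[MutationCatalog, SimulationTruth]:
    """Catalog V = P S with optional multinomial sampling noise.

    Per-sample signature fractions are log-normal (so activity varies
    across tumors) scaled to ``mutations_per_sample`` total mutations.
    ``noise='none'`` rounds the exact product; ``'multinomial'`` draws each
    sample's counts from its expected category distribution.
    """
    scheme = {96: "SBS96", 78: "DBS78", 83: "ID83"}.get(M)
    if scheme is None:
        raise ValueError("M must be one of 96, 78, 83 (a catalog scheme size)")
    if K > min(M, N):
        raise ValueError("K must be <= min(M, N)")
    if mutations_per_sample <= 0:
        raise ValueError("mutations_per_sample must be positive")
    rng = np.random.default_rng(seed)
    P = random_signatures(M, K, rng)
    mix = np.exp(rng.normal(0.0, 0.5, size=(K, N)))
    mix /= mix.sum(axis=0)
    S = mix * mutations_per_sample

    expected = P @ mix  # per-category probabilities per sample
    if noise == "none":
        V = np.rint(P @ S).astype(np.int64)
    elif noise == "multinomial":
        V = np.stack(
            [rng.multinomial(mutations_per_sample, expected[:, n] / expected[:, n].sum())
             for n in range(N)],
            axis=1,
        ).astype(np.int64)
    else:
        raise ValueError(f"unknown noise model {noise!r}")

    cats = list(SCHEME_CATEGORIES[scheme])
    samples = [f"S{n+1:03d}" for n in range(N)]
    signames = [f"TrueSig{k+1}" for k in range(K)]
    catalog = MutationCatalog(V, cats, samples, scheme)
    truth = SimulationTruth(
        P_true=SignatureMatrix(P, cats, signames),
        S_true=ExposureMatrix(S, signames, samples, normalized=False),
        seed=seed,
    )
    return catalog, truth


# ---------------------------------------------------------------------------
# Indel templates (engineered contexts, one per ID-83 bin family)
# ---------------------------------------------------------------------------

#: each template is (pattern, kind, offset, sequence, intended category);
#: offsets are 0-based into the pattern: first deleted base for deletions,
#: the base 5' of the event for insertions. Guard bases inside each pattern
#: stop run/repeat/homology scans, so templates can be concatenated.
INDEL_TEMPLATES: tuple[tuple[str, str, int, str, str], ...] = (
    ("GTTTTTTG", "del", 1, "T", "1:Del:T:5"),        # 6-T homopolymer
    ("CAAAAC", "del", 1, "A", "1:Del:T:3"),          # A-run, complemented
    ("GACAG", "del", 2, "C", "1:Del:C:0"),           # lone C deletion
    ("GAGG", "ins", 1, "C", "1:Ins:C:0"),            # C into non-C context
    ("GTTTTG", "ins", 4, "T", "1:Ins:T:4"),          # extend 4-T run
    ("TCACACAT", "del", 1, "CA", "2:Del:R:2"),       # CA x3 repeat
    ("ACTG", "del", 1, "CT", "2:Del:R:0"),           # non-repeat 2bp del
    ("GTCTATCGG", "del", 1, "TCTA", "4:Del:M:2"),    # 2bp microhomology
    ("TACGTCG", "del", 1, "ACGTC", "5:Del:R:0"),     # plain 5bp deletion
    ("ACGTA", "ins", 3, "CGT", "3:Ins:R:1"),         # duplicate CGT unit
    ("GTA", "ins", 0, "AC", "2:Ins:R:0"),            # novel 2bp insertion
)

_SPACER = "ACGT"


# ---------------------------------------------------------------------------
# MAF + mini-FASTA generation
# ---------------------------------------------------------------------------

def _parse_category(cat: str) -> tuple[str, str]:
    """SBS-96 label -> (pyrimidine-strand trinucleotide, alt base)."""
    five, rest = cat.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    return five + ref + three, alt


def simulate_maf_reference(
    n_samples: int,
    genes: Mapping[str, int] | Sequence[tuple[str, int]],
    signature_mix: Sequence[float] | None = None,
    seed: int | None = 0,
    out_dir: str | Path = ".",
    mutations_per_sample: int = 30,
    P_true: SignatureMatrix | None = None,
    gene_preferences: Mapping[str, Sequence[float] | int] | None = None,
    indels_per_sample: int = 0,
    silent_fraction: float = 0.0,
    mix_concentration: float = 10.0,
) -> tuple[Path, Path, SimulationTruth]:
    """Write a mini-FASTA (one contig per gene) and a matching MAF.

    Substitutions are placed at reference positions whose trinucleotide
    context (on either strand) realizes a category drawn from the active
    signature; when a gene lacks the context it is injected into the
    sequence before the FASTA is written, so the emitted reference is
    always consistent with the records. Per-sample signature activities
    are Dirichlet draws around ``signature_mix``; ``gene_preferences``
    re-weights (or pins, when given an index) the signature choice for
    mutations falling in a gene. ``indels_per_sample`` indel records are
    drawn from engineered context templates appended to each contig.

    Returns the MAF path, the FASTA path and the generator truth, which
    includes the intended per-sample category counts for every scheme
    touched.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    gene_items = list(genes.items()) if isinstance(genes, Mapping) else list(genes)
    if not gene_items:
        raise ValueError("genes must be nonempty")
    gene_names = [g for g, _ in gene_items]
    gene_lengths = np.array([l for _, l in gene_items], dtype=float)

    if P_true is None:
        K = len(signature_mix) if signature_mix is not None else 3
        P = random_signatures(96, K, rng)
        P_true = SignatureMatrix(P, list(SBS96_CATEGORIES),
                                 [f"TrueSig{k+1}" for k in range(K)])
    else:
        K = P_true.n_signatures
    mix = (np.asarray(signature_mix, dtype=float)
           if signature_mix is not None else np.full(K, 1.0 / K))
    mix = mix / mix.sum()

    prefs: dict[str, np.ndarray] = {}
    if gene_preferences:
        for g, w in gene_preferences.items():
            if isinstance(w, (int, np.integer)):
                v = np.zeros(K)
                v[int(w)] = 1.0
            else:
                v = np.asarray(w, dtype=float)
                v = v / v.sum()
            prefs[g] = v

    # build contig sequences; indel playground appended after the gene body
    seqs: dict[str, list[str]] = {}
    indel_anchor: dict[str, int] = {}
    for g, l in gene_items:
        body = rng.choice(list(BASES), size=int(l)).tolist()
        indel_anchor[g] = int(l)
        tail: list[str] = []
        if indels_per_sample > 0:
            for pattern, *_ in INDEL_TEMPLATES:
                tail.extend(_SPACER)
                tail.extend(pattern)
            tail.extend(_SPACER)
        seqs[g] = body + tail
    template_offsets: dict[int, int] = {}
    if indels_per_sample > 0:
        off = len(_SPACER)
        for ti, (pattern, *_rest) in enumerate(INDEL_TEMPLATES):
            template_offsets[ti] = off
            off += len(pattern) + len(_SPACER)

    locked: dict[str, set[int]] = {g: set() for g in gene_names}
    samples = [f"S{n+1:03d}" for n in range(n_samples)]
    sample_mix = (rng.dirichlet(mix * mix_concentration, size=n_samples).T
                  if n_samples else np.zeros((K, 0)))

    maf_rows: list[dict] = []
    truth_records: list[dict] = []
    S_counts = np.zeros((K, n_samples))
    cat_index = {c: i for i, c in enumerate(SBS96_CATEGORIES)}
    sbs_counts = np.zeros((96, n_samples), dtype=np.int64)
    id_counts = np.zeros((83, n_samples), dtype=np.int64)
    id_index = {c: i for i, c in enumerate(ID83_CATEGORIES)}

    gene_probs = gene_lengths / gene_lengths.sum()
    for n, sample in enumerate(samples):
        for _ in range(mutations_per_sample):
            gi = int(rng.choice(len(gene_names), p=gene_probs))
            gene = gene_names[gi]
            w = sample_mix[:, n] * prefs.get(gene, np.ones(K))
            if w.sum() == 0:
                w = prefs.get(gene, sample_mix[:, n])
            w = w / w.sum()
            k = int(rng.choice(K, p=w))
            cat = str(rng.choice(SBS96_CATEGORIES, p=P_true.values[:, k]))
            placed = _place_sbs(seqs[gene], locked[gene], indel_anchor[gene],
                                cat, rng)
            if placed is None:
                continue  # gene body too crowded; drop the mutation
            pos0, ref, alt = placed
            nonsilent = bool(rng.random() >= silent_fraction)
            maf_rows.append({
                "Hugo_Symbol": gene,
                "Chromosome": gene,
                "Start_Position": pos0 + 1,
                "End_Position": pos0 + 1,
                "Variant_Classification": "Missense_Mutation" if nonsilent else "Silent",
                "Variant_Type": "SNP",
                "Reference_Allele": ref,
                "Tumor_Seq_Allele1": ref,
                "Tumor_Seq_Allele2": alt,
                "Tumor_Sample_Barcode": sample,
            })
            truth_records.append({"sample": sample, "gene": gene,
                                  "scheme": "SBS96", "category": cat,
                                  "signature": k})
            S_counts[k, n] += 1
            sbs_counts[cat_index[cat], n] += 1
        for _ in range(indels_per_sample):
            ti = int(rng.integers(len(INDEL_TEMPLATES)))
            pattern, kind, offset, seq, cat = INDEL_TEMPLATES[ti]
            gi = int(rng.choice(len(gene_names), p=gene_probs))
            gene = gene_names[gi]
            base0 = indel_anchor[gene] + template_offsets[ti]
            pos0 = base0 + offset
            if kind == "del":
                row = {
                    "Start_Position": pos0 + 1,
                    "End_Position": pos0 + len(seq),
                    "Variant_Type": "DEL",
                    "Reference_Allele": seq,
                    "Tumor_Seq_Allele1": seq,
                    "Tumor_Seq_Allele2": "-",
                }
            else:
                row = {
                    "Start_Position": pos0 + 1,
                    "End_Position": pos0 + 2,
                    "Variant_Type": "INS",
                    "Reference_Allele": "-",
                    "Tumor_Seq_Allele1": "-",
                    "Tumor_Seq_Allele2": seq,
                }
            row.update({
                "Hugo_Symbol": gene,
                "Chromosome": gene,
                "Variant_Classification": "Frame_Shift_Del" if kind == "del" else "Frame_Shift_Ins",
                "Tumor_Sample_Barcode": sample,
            })
            maf_rows.append(row)
            truth_records.append({"sample": sample, "gene": gene,
                                  "scheme": "ID83", "category": cat,
                                  "signature": None})
            id_counts[id_index[cat], n] += 1

    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w") as fh:
        for g in gene_names:
            fh.write(f">{g}\n")
            s = "".join(seqs[g])
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")

    maf_path = out_dir / "mutations.maf"
    columns = ["Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
               "Variant_Classification", "Variant_Type", "Reference_Allele",
               "Tumor_Seq_Allele1", "Tumor_Seq_Allele2", "Tumor_Sample_Barcode"]
    pd.DataFrame(maf_rows, columns=columns).to_csv(maf_path, sep="\t", index=False)

    intended = {"SBS96": pd.DataFrame(sbs_counts, index=list(SBS96_CATEGORIES),
                                      columns=samples)}
    if indels_per_sample > 0:
        intended["ID83"] = pd.DataFrame(id_counts, index=list(ID83_CATEGORIES),
                                        columns=samples)
    truth = SimulationTruth(
        P_true=P_true,
        S_true=ExposureMatrix(S_counts, list(P_true.col_labels), samples,
                              normalized=False),
        seed=seed,
        gene_preferences={g: v for g, v in prefs.items()},
        intended_counts=intended,
        records=truth_records,
    )
    return maf_path, fasta_path, truth


def _place_sbs(seq: list[str], locked: set[int], limit: int,
               category: str, rng) -> tuple[int, str, str] | None:
    """Find or inject a position realizing an SBS-96 category.

    Returns (0-based position, ref base, alt base) on the forward strand,
    or None when the gene body has no room left. The +/-1 neighbourhood of
    every used site is locked so later placements cannot disturb a
    recorded context.
    """
    tri, alt = _parse_category(category)
    rc_tri, rc_alt = revcomp(tri), revcomp(alt)
    usable = [p for p in range(1, limit - 1)
              if not ({p - 1, p, p + 1} & locked)]
    if not usable:
        return None
    candidates = []
    for p in usable:
        ctx = seq[p - 1] + seq[p] + seq[p + 1]
        if ctx == tri:
            candidates.append((p, tri[1], alt))
        elif ctx == rc_tri:
            candidates.append((p, rc_tri[1], rc_alt))
    if candidates:
        choice = candidates[int(rng.integers(len(candidates)))]
    else:  # inject the context deterministically at a random free site
        p = usable[int(rng.integers(len(usable)))]
        seq[p - 1], seq[p], seq[p + 1] = tri[0], tri[1], tri[2]
        choice = (p, tri[1], alt)
    p = choice[0]
    locked.update({p - 1, p, p + 1})
    return choice
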