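"""Mutation catalogs: parse somatic variants and classify them into the
standard COSMIC category schemes.

Single-base substitutions are classified into the 96 trinucleotide-context
types (SBS-96), doublet substitutions into the 78 strand-agnostic types
(DBS-78) and small insertions/deletions into the 83 indel types (ID-83).
Counts are assembled into a category x sample catalog matrix ``V`` which is
the input of signature extraction.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sigcca")

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CatalogError(Exception):
    """Base class for catalog construction problems."""


class FormatError(CatalogError):
    """A file does not conform to the named standard."""


class ConsistencyError(CatalogError):
    """A record contradicts the reference genome."""


class ClassificationSkip(CatalogError):
    """Record cannot be classified (e.g. ambiguous flanking base); it is
    skipped and counted in the classification report."""


# ---------------------------------------------------------------------------
# Category spaces
# ---------------------------------------------------------------------------

SBS_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical SBS-96 category order: substitution-major, flanks in A,C,G,T order
SBS96_CATEGORIES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SBS_SUBSTITUTIONS
    for five in BASES
    for three in BASES
)


def _build_dbs78() -> tuple[tuple[str, ...], dict[tuple[str, str], str]]:
    """Enumerate the 78 canonical doublet classes and the 144 -> 78 map.

    Every doublet event (ref XY -> alt X'Y' with both bases substituted) is
    equivalent to its reverse-complement representation; COSMIC fixes one
    canonical member per pair. The canonical reference doublets are the ten
    listed below; everything else maps through reverse complement.
    """
    canonical_refs = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")
    categories: list[str] = []
    lookup: dict[tuple[str, str], str] = {}
    for ref in canonical_refs:
        rc_ref = revcomp(ref)
        alts = []
        for a0 in BASES:
            for a1 in BASES:
                if a0 == ref[0] or a1 == ref[1]:
                    continue
                alt = a0 + a1
                if ref == rc_ref:
                    # palindromic ref: event and its revcomp share the ref;
                    # keep the lexicographically smaller alt as canonical
                    if revcomp(alt) < alt:
                        continue
                alts.append(alt)
        for alt in sorted(alts):
            label = f"{ref}>{alt}"
            categories.append(label)
            lookup[(ref, alt)] = label
            lookup[(rc_ref, revcomp(alt))] = label
    return tuple(categories), lookup


DBS78_CATEGORIES, _DBS_LOOKUP = _build_dbs78()


def _build_id83() -> tuple[str, ...]:
    cats: list[str] = []
    for base in ("C", "T"):
        cats.extend(f"1:Del:{base}:{i}" for i in range(6))
    for base in ("C", "T"):
        cats.extend(f"1:Ins:{base}:{i}" for i in range(6))
    for length in (2, 3, 4, 5):
        cats.extend(f"{length}:Del:R:{i}" for i in range(6))
    for length in (2, 3, 4, 5):
        cats.extend(f"{length}:Ins:R:{i}" for i in range(6))
    # microhomology bins: homology 1..length-1, except the 5+ length class
    # which also holds longer deletions and so runs to homology 5
    for length in (2, 3, 4):
        cats.extend(f"{length}:Del:M:{i}" for i in range(1, length))
    cats.extend(f"5:Del:M:{i}" for i in range(1, 6))
    return tuple(cats)


ID83_CATEGORIES = _build_id83()

SCHEME_CATEGORIES: dict[str, tuple[str, ...]] = {
    "SBS96": SBS96_CATEGORIES,
    "DBS78": DBS78_CATEGORIES,
    "ID83": ID83_CATEGORIES,
}

assert len(SBS96_CATEGORIES) == 96
assert len(DBS78_CATEGORIES) == 78
assert len(ID83_CATEGORIES) == 83


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class VariantClass(str, Enum):
    SBS = "SBS"
    DBS = "DBS"
    INS = "INS"
    DEL = "DEL"
    OTHER = "OTHER"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant in one sample.

    Coordinates are 1-based. For insertions ``pos`` is the reference base
    immediately 5' of the inserted sequence and ``ref`` is empty; for
    deletions ``pos`` is the first deleted base and ``alt`` is empty.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    is_nonsilent: bool | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical: {self.ref!r}")

    @property
    def variant_class(self) -> VariantClass:
        ref, alt = self.ref, self.alt
        valid = all(b in BASES for b in ref + alt)
        if not valid:
            return VariantClass.OTHER
        if len(ref) == 1 and len(alt) == 1:
            return VariantClass.SBS
        if len(ref) == 2 and len(alt) == 2:
            return VariantClass.DBS
        if len(ref) == 0 and len(alt) >= 1:
            return VariantClass.INS
        if len(alt) == 0 and len(ref) >= 1:
            return VariantClass.DEL
        return VariantClass.OTHER


class ReferenceGenome:
    """1-based, inclusive-coordinate accessor over a set of contigs.

    Wraps either an in-memory ``{contig: sequence}`` mapping or a
    ``pyfaidx.Fasta`` handle. Out-of-range access raises; a zero-length
    window returns the empty string.
    """

    def __init__(self, source: Mapping[str, str] | str | Path):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source), sequence_always_upper=True)
            self._mem = None
        else:
            self._mem = {k: v.upper() for k, v in source.items()}
            self._fasta = None

    def contigs(self) -> list[str]:
        if self._mem is not None:
            return list(self._mem)
        return list(self._fasta.keys())

    def contig_length(self, chrom: str) -> int:
        if self._mem is not None:
            return len(self._mem[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence from ``start`` to ``end`` inclusive, 1-based, uppercase."""
        if end < start:
            return ""
        if chrom not in self.contigs():
            raise KeyError(f"unknown contig {chrom!r}")
        n = self.contig_length(chrom)
        if start < 1 or end > n:
            raise IndexError(
                f"window {chrom}:{start}-{end} outside contig of length {n}"
            )
        if self._mem is not None:
            return self._mem[chrom][start - 1 : end]
        return str(self._fasta[chrom][start - 1 : end]).upper()


@dataclass
class MutationCatalog:
    """The observation matrix V: category x sample counts."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    scheme: str

    def __post_init__(self):
        self.values = np.asarray(self.values)
        expected = SCHEME_CATEGORIES.get(self.scheme)
        if expected is None:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if list(self.row_labels) != list(expected):
            raise ValueError(
                f"row labels are not the canonical {self.scheme} categories"
            )
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        if (self.values < 0).any():
            raise ValueError("catalog entries must be non-negative")

    @property
    def n_categories(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass
class ClassificationReport:
    """Bookkeeping for records that could not be counted."""

    n_classified: int = 0
    skipped: Counter = field(default_factory=Counter)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def classify_sbs96(rec: MutationRecord, genome: ReferenceGenome) -> str:
    """Trinucleotide-context class of a single-base substitution.

    The pyrimidine-strand convention applies: when the reference base is a
    purine the mutation and its flanks are reverse complemented, so the 96
    categories are ``X[R>A]Y`` with R in {C, T}.
    """
    if rec.variant_class is not VariantClass.SBS:
        raise ValueError("classify_sbs96 requires a single-base substitution")
    ref_base = genome.fetch(rec.chrom, rec.pos, rec.pos)
    if ref_base != rec.ref:
        raise ConsistencyError(
            f"{rec.chrom}:{rec.pos} genome has {ref_base!r}, record says {rec.ref!r}"
        )
    try:
        tri = genome.fetch(rec.chrom, rec.pos - 1, rec.pos + 1)
    except IndexError as exc:
        raise ClassificationSkip(f"no flanking context at {rec.chrom}:{rec.pos}") from exc
    if any(b not in BASES for b in tri):
        raise ClassificationSkip(f"ambiguous flanking base in {tri!r}")
    alt = rec.alt
    if rec.ref in "AG":
        tri = revcomp(tri)
        alt = revcomp(alt)
    return f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"


def classify_dbs78(rec: MutationRecord, genome: ReferenceGenome | None = None) -> str:
    """Strand-agnostic doublet-substitution class (78-way lookup)."""
    if rec.variant_class is not VariantClass.DBS:
        raise ValueError("classify_dbs78 requires a doublet substitution")
    if genome is not None:
        obs = genome.fetch(rec.chrom, rec.pos, rec.pos + 1)
        if obs != rec.ref:
            raise ConsistencyError(
                f"{rec.chrom}:{rec.pos} genome has {obs!r}, record says {rec.ref!r}"
            )
    key = (rec.ref, rec.alt)
    if key not in _DBS_LOOKUP:
        # shares a base with the reference at the same position: not a true
        # doublet substitution under the 78-type scheme
        raise ClassificationSkip(f"{rec.ref}>{rec.alt} is not a doublet substitution")
    return _DBS_LOOKUP[key]


def _run_left(seq_get, pos: int, base: str) -> int:
    """Number of consecutive `base` at pos, pos-1, ... (1-based walk left)."""
    n = 0
    p = pos
    while p >= 1 and seq_get(p) == base:
        n += 1
        p -= 1
    return n


def _tandem_copies(genome: ReferenceGenome, chrom: str, unit: str,
                   left_end: int, right_start: int) -> tuple[int, int]:
    """Count full tandem copies of ``unit`` immediately left of ``left_end``
    (inclusive) and starting at ``right_start`` (1-based)."""
    m = len(unit)
    n = genome.contig_length(chrom)
    right = 0
    p = right_start
    while p + m - 1 <= n and genome.fetch(chrom, p, p + m - 1) == unit:
        right += 1
        p += m
    left = 0
    p = left_end
    while p - m + 1 >= 1 and genome.fetch(chrom, p - m + 1, p) == unit:
        left += 1
        p -= m
    return left, right


def classify_id83(rec: MutationRecord, genome: ReferenceGenome) -> str:
    """COSMIC-style 83-way indel class.

    1 bp indels are binned by the pyrimidine identity of the base (A/G runs
    are complemented into T/C) and the homopolymer run length in the
    reference — for deletions the run includes the deleted base, for
    insertions it is the pre-existing run. Longer indels are binned by
    length and tandem-repeat-unit count; deletions that are not tandem
    repeats but share flanking homology are binned as microhomology
    deletions by homology length.
    """
    vclass = rec.variant_class
    if vclass not in (VariantClass.INS, VariantClass.DEL):
        raise ValueError("classify_id83 requires an insertion or deletion")
    chrom = rec.chrom
    contig_len = genome.contig_length(chrom)

    if vclass is VariantClass.DEL:
        seq = rec.ref
        d = len(seq)
        if rec.pos + d - 1 > contig_len:
            raise ClassificationSkip(f"deletion at {chrom}:{rec.pos} overlaps contig end")
        obs = genome.fetch(chrom, rec.pos, rec.pos + d - 1)
        if obs != seq:
            raise ConsistencyError(
                f"{chrom}:{rec.pos} genome has {obs!r}, record deletes {seq!r}"
            )
        if d == 1:
            base = seq
            get = lambda p: genome.fetch(chrom, p, p)
            left = _run_left(get, rec.pos - 1, base)
            right = 0
            p = rec.pos + 1
            while p <= contig_len and get(p) == base:
                right += 1
                p += 1
            run = left + 1 + right  # including the deleted base
            pyr = base if base in "CT" else revcomp(base)
            return f"1:Del:{pyr}:{min(run, 6) - 1}"
        # >= 2 bp deletion: repeat units first, then microhomology
        left, right = _tandem_copies(genome, chrom, seq, rec.pos - 1, rec.pos + d)
        units = left + 1 + right  # including the deleted copy
        dlab = min(d, 5)
        if units >= 2:
            return f"{dlab}:Del:R:{min(units, 6) - 1}"
        # microhomology: longest shared prefix with the 3' flank or suffix
        # with the 5' flank, necessarily < d here (else it would be a repeat)
        hom = 0
        for i in range(1, d):
            p = rec.pos + d + i - 1
            if p > contig_len or genome.fetch(chrom, p, p) != seq[i - 1]:
                break
            hom = i
        hom_left = 0
        for i in range(1, d):
            p = rec.pos - i
            if p < 1 or genome.fetch(chrom, p, p) != seq[d - i]:
                break
            hom_left = i
        hom = max(hom, hom_left)
        if hom >= 1:
            return f"{dlab}:Del:M:{min(hom, 5)}"
        return f"{dlab}:Del:R:0"

    # insertion: rec.pos is the base 5' of the inserted sequence
    seq = rec.alt
    d = len(seq)
    if rec.pos > contig_len:
        raise ClassificationSkip(f"insertion anchor {chrom}:{rec.pos} beyond contig end")
    if d == 1:
        base = seq
        get = lambda p: genome.fetch(chrom, p, p)
        left = _run_left(get, rec.pos, base)
        right = 0
        p = rec.pos + 1
        while p <= contig_len and get(p) == base:
            right += 1
            p += 1
        run = left + right  # pre-existing copies adjacent to the site
        pyr = base if base in "CT" else revcomp(base)
        return f"1:Ins:{pyr}:{min(run, 5)}"
    left, right = _tandem_copies(genome, chrom, seq, rec.pos, rec.pos + 1)
    units = left + right
    return f"{min(d, 5)}:Ins:R:{min(units, 5)}"


_SCHEME_CLASSES = {
    "SBS96": (VariantClass.SBS,),
    "DBS78": (VariantClass.DBS,),
    "ID83": (VariantClass.INS, VariantClass.DEL),
}


def classify(rec: MutationRecord, genome: ReferenceGenome, scheme: str) -> str:
    if scheme == "SBS96":
        return classify_sbs96(rec, genome)
    if scheme == "DBS78":
        return classify_dbs78(rec, genome)
    if scheme == "ID83":
        return classify_id83(rec, genome)
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Catalog assembly
# ---------------------------------------------------------------------------

def build_catalog(
    records: Iterable[MutationRecord],
    genome: ReferenceGenome,
    scheme: str,
    samples: Sequence[str] | None = None,
) -> tuple[MutationCatalog, ClassificationReport]:
    """Count classified records into a category x sample matrix.

    Records whose variant class does not belong to ``scheme`` are ignored
    silently (they belong in another catalog); records of the right class
    that cannot be classified are skipped and tallied in the report. When
    ``samples`` is given the column set and order are fixed even for samples
    without mutations.
    """
    categories = SCHEME_CATEGORIES[scheme]
    cat_index = {c: i for i, c in enumerate(categories)}
    wanted = _SCHEME_CLASSES[scheme]
    report = ClassificationReport()

    col_order: list[str] = list(samples) if samples is not None else []
    col_index = {s: i for i, s in enumerate(col_order)}
    counts: list[tuple[int, int]] = []

    for rec in records:
        if rec.variant_class not in wanted:
            continue
        try:
            cat = classify(rec, genome, scheme)
        except ClassificationSkip as exc:
            report.skipped[str(exc)] += 1
            continue
        if rec.sample_id not in col_index:
            if samples is not None:
                report.skipped[f"sample {rec.sample_id!r} not in declared sample list"] += 1
                continue
            col_index[rec.sample_id] = len(col_order)
            col_order.append(rec.sample_id)
        counts.append((cat_index[cat], col_index[rec.sample_id]))
        report.n_classified += 1

    values = np.zeros((len(categories), len(col_order)), dtype=np.int64)
    for i, j in counts:
        values[i, j] += 1
    if report.n_skipped:
        logger.info("build_catalog skipped %d records: %s", report.n_skipped,
                    dict(report.skipped))
    return MutationCatalog(values, list(categories), col_order, scheme), report


def write_catalog(catalog: MutationCatalog, path: str | Path, sep: str = "\t") -> None:
    df = catalog.to_dataframe()
    df.index.name = "MutationType"
    df.to_csv(path, sep=sep)


def read_catalog(path: str | Path, sep: str = "\t") -> MutationCatalog:
    """Read a delimited catalog; rows are restored to canonical order."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    labels = set(df.index.astype(str))
    scheme = None
    for name, cats in SCHEME_CATEGORIES.items():
        if labels == set(cats):
            scheme = name
            break
    if scheme is None:
        raise FormatError(
            "row labels do not match any of the SBS96/DBS78/ID83 category sets"
        )
    df = df.loc[list(SCHEME_CATEGORIES[scheme])]
    values = df.to_numpy()
    if (values < 0).any():
        raise FormatError("catalog contains negative entries")
    if np.allclose(values, np.round(values)):
        values = np.round(values).astype(np.int64)
    return MutationCatalog(values, list(df.index), [str(c) for c in df.columns], scheme)


# ---------------------------------------------------------------------------
# MAF / VCF readers
# ---------------------------------------------------------------------------

_MAF_SILENT = {
    "Silent", "Synonymous", "3'UTR", "5'UTR", "3'Flank", "5'Flank",
    "Intron", "IGR", "RNA", "lincRNA",
}

_MAF_START_COLS = ("Start_Position", "Start_position")


def _read_maf(path: str | Path, sample_field: str | None) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    sample_col = sample_field or "Tumor_Sample_Barcode"
    start_col = next((c for c in _MAF_START_COLS if c in df.columns), None)
    required = {"Chromosome": "Chromosome" in df.columns,
                "Start_Position": start_col is not None,
                "Reference_Allele": "Reference_Allele" in df.columns,
                sample_col: sample_col in df.columns}
    alt_col = next(
        (c for c in ("Tumor_Seq_Allele2", "Tumor_Seq_Allele1") if c in df.columns),
        None,
    )
    required["Tumor_Seq_Allele2"] = alt_col is not None
    missing = [name for name, ok in required.items() if not ok]
    if missing:
        raise FormatError(f"MAF is missing mandatory column(s): {', '.join(missing)}")

    records: list[MutationRecord] = []
    for row in df.to_dict("records"):
        ref = row["Reference_Allele"].strip().upper()
        alt = row[alt_col].strip().upper()
        pos = int(row[start_col])
        if ref in ("-", ""):
            ref = ""  # MAF insertion start is already the base 5' of the event
        if alt in ("-", ""):
            alt = ""
        gene = row.get("Hugo_Symbol") or None
        vc = row.get("Variant_Classification")
        nonsilent = None if not vc else vc not in _MAF_SILENT
        if ref == alt:
            continue
        records.append(
            MutationRecord(
                sample_id=row[sample_col],
                chrom=str(row["Chromosome"]),
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                is_nonsilent=nonsilent,
            )
        )
    return records


def _normalize_vcf_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared flanking bases from a VCF ref/alt pair.

    Returns 1-based coordinates under the internal convention: for pure
    insertions ``pos`` is the base 5' of the insertion and ref is empty; for
    pure deletions ``pos`` is the first deleted base.
    """
    # trim common suffix first, then common prefix
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    trimmed = 0
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        trimmed += 1
    pos += trimmed
    if ref == alt:
        raise ValueError("alleles identical after normalization")
    if len(alt) > len(ref) and len(ref) == 0:
        pos -= 1  # anchor on the base 5' of the insertion
    return pos, ref, alt


def _read_vcf(path: str | Path, sample_field: str | None) -> list[MutationRecord]:
    import pysam

    records: list[MutationRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        default_sample = sample_field or Path(path).stem
        for var in vcf:
            if var.alts is None:
                continue
            for ai, alt in enumerate(var.alts, start=1):
                if alt is None or not alt or alt[0] in "<*.":
                    continue
                try:
                    pos, ref, a = _normalize_vcf_alleles(
                        var.pos, var.ref.upper(), alt.upper()
                    )
                except ValueError:
                    continue
                gene = None
                if "GENE" in var.info:
                    g = var.info["GENE"]
                    gene = g[0] if isinstance(g, tuple) else g
                if vcf_samples:
                    carriers = [
                        s for s in vcf_samples
                        if ai in (var.samples[s].get("GT") or ())
                    ]
                else:
                    carriers = [default_sample]
                for s in carriers:
                    records.append(
                        MutationRecord(sample_id=s, chrom=var.chrom, pos=pos,
                                       ref=ref, alt=a, gene=gene)
                    )
    return records


def read_mutations(
    path: str | Path,
    format: str,
    sample_field: str | None = None,
) -> list[MutationRecord]:
    """Read somatic variants from a MAF or VCF file.

    ``sample_field`` names the MAF sample column (default
    ``Tumor_Sample_Barcode``); for a VCF without sample columns it provides
    the sample id.
    """
    fmt = format.upper()
    if fmt == "MAF":
        return _read_maf(path, sample_field)
    if fmt == "VCF":
        return _read_vcf(path, sample_field)
    raise ValueError(f"unknown format {format!r}; expected 'MAF' or 'VCF'")
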