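"""The 96 strand-collapsed trinucleotide substitution categories.

Somatic single-base substitutions are classified by the substituted
pyrimidine (C or T), the alternate base, and the two flanking reference
bases, giving 6 substitution types x 16 flanking contexts = 96 categories.
Mutations reported on the purine strand are reverse-complemented so the
central reference base is always a pyrimidine.

The canonical column order is the COSMIC convention: substitution types in
the order C>A, C>G, C>T, T>A, T>C, T>G; within each type the 16 flanking
combinations sorted alphabetically by 5' then 3' base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 category labels, e.g. "A[C>A]A", in canonical COSMIC order.
CATEGORIES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in BASES
    for three in BASES
)

#: label -> column index (bijection over the 96 labels).
CATEGORY_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CATEGORIES)}


class ClassificationError(ValueError):
    """Raised for records that cannot be placed in the 96-category scheme."""


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ClassificationError(f"non-ACGT base {exc.args[0]!r} in {seq!r}") from exc


def classify_mutation(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Classify a single-base substitution into one of the 96 categories.

    Parameters are the reference base, the alternate base, and the 5' and 3'
    flanking reference bases, all on the reported strand. If ``ref`` is a
    purine (A/G) the trinucleotide and the alternate base are
    reverse-complemented first, so the returned label always carries a
    pyrimidine as the central reference base.
    """
    for name, b in (("ref", ref), ("alt", alt), ("flank5", flank5), ("flank3", flank3)):
        if b not in BASES:
            raise ClassificationError(
                f"{name}={b!r} is not a single base in A/C/G/T "
                f"(record ref={ref!r} alt={alt!r} context={flank5!r}_{flank3!r})"
            )
    if alt == ref:
        raise ClassificationError(
            f"alt equals ref ({ref!r}) — not a substitution "
            f"(context={flank5!r}_{flank3!r})"
        )
    if ref not in PYRIMIDINES:
        flank5, ref, flank3 = (
            _COMPLEMENT[flank3],
            _COMPLEMENT[ref],
            _COMPLEMENT[flank5],
        )
        alt = _COMPLEMENT[alt]
    return f"{flank5}[{ref}>{alt}]{flank3}"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant call.

    ``pos`` is 1-based; ``ref`` and ``alt`` are single bases. Indels and
    multi-nucleotide variants are rejected at construction.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ClassificationError(
                f"{self.sample_id} {self.chrom}:{self.pos} "
                f"{self.ref}>{self.alt}: only single-base substitutions are supported"
            )
        if self.ref == self.alt:
            raise ClassificationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: alt equals ref ({self.ref})"
            )
        if self.pos < 2:
            raise ClassificationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: no 5' flank exists"
            )


@dataclass
class CountMatrix:
    """N samples x 96 mutation-category count matrix (the matrix M)."""

    counts: np.ndarray  # (N, 96) non-negative
    sample_ids: list[str]
    categories: tuple[str, ...] = field(default=CATEGORIES)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.categories):
            raise ValueError(
                f"counts must be N x {len(self.categories)}, got {self.counts.shape}"
            )
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValueError("sample_ids length does not match counts rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="sample"),
            columns=list(self.categories),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        missing = [c for c in CATEGORIES if c not in frame.columns]
        if missing:
            raise ValueError(f"count table is missing categories, e.g. {missing[:3]}")
        ordered = frame[list(CATEGORIES)]
        return cls(ordered.to_numpy(dtype=float), [str(s) for s in frame.index])

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


class _ContextAccessor:
    """Uniform chrom/pos -> trinucleotide access over pyfaidx or dict-of-str."""

    def __init__(self, reference):
        self.reference = reference

    def contigs(self) -> set[str]:
        return set(self.reference.keys())

    def trinucleotide(self, chrom: str, pos: int) -> str:
        seq = self.reference[chrom]
        # pyfaidx FastaRecord supports len() and 0-based slicing like str
        if pos + 1 > len(seq):
            raise ClassificationError(
                f"{chrom}:{pos}: 3' flank outside contig bounds (len {len(seq)})"
            )
        tri = seq[pos - 2 : pos + 1]
        return str(tri).upper()


def build_count_matrix(
    records: Iterable[MutationRecord],
    reference,
    strict: bool = True,
) -> CountMatrix:
    """Tally mutations into a sample x 96-category count matrix.

    ``reference`` is a genome-sequence accessor: a ``pyfaidx.Fasta`` or any
    mapping of contig name to sequence string. The reference base at each
    position must match the record's ref allele; in strict mode a mismatch is
    an error, otherwise the record is skipped with a logged warning. Records
    whose trinucleotide context contains N or other ambiguity codes are
    always skipped with a warning.
    """
    accessor = _ContextAccessor(reference)
    contigs = accessor.contigs()
    per_sample: dict[str, np.ndarray] = {}
    n_accepted = 0
    n_skipped = 0
    for rec in records:
        if rec.chrom not in contigs:
            raise ClassificationError(
                f"{rec.sample_id} {rec.chrom}:{rec.pos}: contig {rec.chrom!r} "
                "not present in the reference"
            )
        tri = accessor.trinucleotide(rec.chrom, rec.pos)
        if any(b not in BASES for b in tri):
            logger.warning(
                "skipping %s %s:%d — ambiguous context %r",
                rec.sample_id, rec.chrom, rec.pos, tri,
            )
            n_skipped += 1
            continue
        if tri[1] != rec.ref:
            msg = (
                f"{rec.sample_id} {rec.chrom}:{rec.pos}: reference base {tri[1]} "
                f"does not match record ref {rec.ref}"
            )
            if strict:
                raise ClassificationError(msg)
            logger.warning("skipping %s", msg)
            n_skipped += 1
            continue
        label = classify_mutation(rec.ref, rec.alt, tri[0], tri[2])
        row = per_sample.setdefault(rec.sample_id, np.zeros(96))
        row[CATEGORY_INDEX[label]] += 1
        n_accepted += 1
    if n_skipped:
        logger.warning("skipped %d of %d records", n_skipped, n_accepted + n_skipped)
    if not per_sample:
        raise ClassificationError("no mutations could be classified")
    sample_ids = list(per_sample)
    return CountMatrix(np.vstack([per_sample[s] for s in sample_ids]), sample_ids)


def filter_samples(
    matrix: CountMatrix, min_mutations: int
) -> tuple[CountMatrix, list[str]]:
    """Drop samples with fewer than ``min_mutations`` total mutations.

    The published pipeline removes tumors with fewer than 1000 point
    mutations before factorization. Returns the filtered matrix and the
    removed sample ids; raises if nothing survives.
    """
    if min_mutations < 0:
        raise ValueError("min_mutations must be >= 0")
    keep = matrix.row_sums() >= min_mutations
    removed = [s for s, k in zip(matrix.sample_ids, keep) if not k]
    if not keep.any():
        raise ValueError(
            f"all {matrix.n_samples} samples fall below {min_mutations} mutations; "
            "no factorization is possible"
        )
    kept = CountMatrix(
        matrix.counts[keep], [s for s, k in zip(matrix.sample_ids, keep) if k]
    )
    return kept, removed


# ---------------------------------------------------------------------------
# Variant-file readers


def read_tsv_records(path) -> Iterator[MutationRecord]:
    """Five-column TSV: sample, chrom, pos, ref, alt (header required)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = list(table.columns[:5])
    if len(required) < 5:
        raise ValueError("variant TSV needs 5 columns: sample, chrom, pos, ref, alt")
    for row in table.itertuples(index=False):
        yield MutationRecord(
            sample_id=str(row[0]), chrom=str(row[1]), pos=int(row[2]),
            ref=str(row[3]).upper(), alt=str(row[4]).upper(),
        )


MAF_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)


def read_maf_records(path) -> Iterator[MutationRecord]:
    """MAF reader using the minimal column subset; non-SNV rows are skipped."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in MAF_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"MAF is missing required columns: {missing}")
    n_skipped = 0
    for row in table[list(MAF_COLUMNS)].itertuples(index=False):
        sample, chrom, pos, ref, alt = row
        ref, alt = str(ref).upper(), str(alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            n_skipped += 1
            continue
        yield MutationRecord(str(sample), str(chrom), int(pos), ref, alt)
    if n_skipped:
        logger.warning("MAF: skipped %d non-SNV rows", n_skipped)


def read_vcf_records(path, sample_id: str | None = None) -> Iterator[MutationRecord]:
    """VCF reader (plain or bgzipped, via cyvcf2).

    Multi-allelic records are split into one record per SNV alternate
    allele; non-SNV alleles are skipped. The sample id is the single VCF
    sample column, or ``sample_id`` for sample-less VCFs.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_id is None:
        if len(vcf.samples) == 1:
            sample_id = vcf.samples[0]
        elif not vcf.samples:
            raise ValueError(f"{path}: VCF has no sample column; pass sample_id")
        else:
            raise ValueError(
                f"{path}: multi-sample VCFs are not supported; split per sample"
            )
    for variant in vcf:
        ref = variant.REF.upper()
        if len(ref) != 1 or ref not in BASES:
            continue
        for alt in variant.ALT:
            alt = alt.upper()
            if len(alt) != 1 or alt not in BASES or alt == ref:
                continue
            yield MutationRecord(sample_id, variant.CHROM, variant.POS, ref, alt)
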