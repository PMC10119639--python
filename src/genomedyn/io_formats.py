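"""Readers and writers for the formats every pipeline stage touches.

Coordinate convention: every on-disk format keeps its native convention
(1-based inclusive for the LTR element table and VCF, 0-based half-open for
BED); the conversion to the internal 0-based half-open representation happens
exactly once, here at the I/O boundary.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

__all__ = [
    "SequenceRecord",
    "LtrElementRow",
    "GenotypeTable",
    "KmerHistogram",
    "read_fasta",
    "write_fasta",
    "read_ltr_table",
    "write_ltr_table",
    "read_vcf_genotypes",
    "write_vcf",
    "read_kmer_histogram",
    "write_kmer_histogram",
    "read_bed",
    "write_bed",
]

_ALPHABET = set("ACGTN")

LTR_TABLE_COLUMNS = [
    "element_id",
    "chrom",
    "element_start",
    "element_end",
    "ltr5_start",
    "ltr5_end",
    "ltr3_start",
    "ltr3_end",
    "superfamily",
]

_SUPERFAMILY_ALIASES = {
    "gypsy": "Gypsy",
    "ty3/gypsy": "Gypsy",
    "ty3": "Gypsy",
    "copia": "Copia",
    "ty1/copia": "Copia",
    "ty1": "Copia",
    "unknown": "unknown",
}


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record has an empty id")
        if not self.sequence:
            raise ValidationError(f"sequence record {self.id!r} is empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValidationError(
                f"sequence record {self.id!r} contains non-ACGTN symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LtrElementRow:
    """One full-length LTR retrotransposon with both terminal repeats.

    All intervals are 0-based half-open (internal convention); the on-disk
    TSV is 1-based inclusive.
    """

    element_id: str
    chrom: str
    element_start: int
    element_end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    superfamily: str = "unknown"

    def __post_init__(self) -> None:
        eid = self.element_id
        if not eid:
            raise ValidationError("LTR element row without an element_id")
        for name in ("element", "ltr5", "ltr3"):
            s = getattr(self, f"{name}_start")
            e = getattr(self, f"{name}_end")
            if e - s < 1 or s < 0:
                raise ValidationError(
                    f"element {eid!r}: {name} interval [{s}, {e}) has length < 1"
                )
        if not self.ltr5_end <= self.ltr3_start:
            raise ValidationError(
                f"element {eid!r}: 5'-LTR must precede the 3'-LTR "
                f"(got [{self.ltr5_start}, {self.ltr5_end}) vs "
                f"[{self.ltr3_start}, {self.ltr3_end}))"
            )
        if self.ltr5_start < self.element_start or self.ltr3_end > self.element_end:
            raise ValidationError(
                f"element {eid!r}: LTR intervals fall outside the element interval"
            )
        if self.superfamily not in ("Gypsy", "Copia", "unknown"):
            raise ValidationError(
                f"element {eid!r}: unrecognised superfamily {self.superfamily!r}"
            )

    @property
    def length(self) -> int:
        return self.element_end - self.element_start

    @property
    def ltr_lengths(self) -> tuple[int, int]:
        return (self.ltr5_end - self.ltr5_start, self.ltr3_end - self.ltr3_start)


def normalize_superfamily(label: str) -> str:
    """Map a free-form superfamily label onto {Gypsy, Copia, unknown}."""
    try:
        return _SUPERFAMILY_ALIASES[label.strip().lower()]
    except KeyError:
        raise ValidationError(f"unrecognised superfamily label {label!r}") from None


@dataclass
class GenotypeTable:
    """Individuals x sites diploid genotype matrix with per-call metadata.

    Genotypes are coded 0/1/2 (count of alternate alleles) with -1 for
    missing; ``depth`` and ``gq`` use -1 where the call carries no annotation.
    Positions are stored 0-based internally. ``biallelic`` flags records that
    are biallelic SNPs; multi-allelic records are kept (flagged) so the filter
    stage can count them rather than losing them silently.
    """

    individuals: list[str]
    chrom: np.ndarray          # object, per site
    pos: np.ndarray            # int64, 0-based, per site
    ref: np.ndarray            # object
    alt: np.ndarray            # object (comma-joined for multi-allelic)
    qual: np.ndarray           # float64 (nan when absent)
    biallelic: np.ndarray      # bool
    genotypes: np.ndarray      # int8  (n_sites, n_ind), -1 missing
    depth: np.ndarray          # int32 (n_sites, n_ind), -1 absent
    gq: np.ndarray             # int32 (n_sites, n_ind), -1 absent

    def __post_init__(self) -> None:
        n_sites, n_ind = self.genotypes.shape
        if n_ind != len(self.individuals):
            raise ValidationError("genotype matrix width != number of individuals")
        for arr_name in ("chrom", "pos", "ref", "alt", "qual", "biallelic"):
            if len(getattr(self, arr_name)) != n_sites:
                raise ValidationError(f"per-site array {arr_name!r} has wrong length")
        # positions strictly increasing within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValidationError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def take_sites(self, index: np.ndarray) -> "GenotypeTable":
        """Return a new table restricted to the given site selection."""
        return GenotypeTable(
            individuals=list(self.individuals),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            qual=self.qual[index],
            biallelic=self.biallelic[index],
            genotypes=self.genotypes[index],
            depth=self.depth[index],
            gq=self.gq[index],
        )


@dataclass
class KmerHistogram:
    """k-mer depth histogram: number of distinct k-mers per depth."""

    depth: np.ndarray   # int64, strictly increasing, positive
    count: np.ndarray   # int64, non-negative
    k: int = 17

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if self.depth.shape != self.count.shape or self.depth.ndim != 1:
            raise ValidationError("depth and count must be 1-D arrays of equal length")
        if len(self.depth) == 0:
            raise ValidationError("empty k-mer histogram")
        if np.any(self.depth <= 0):
            raise ValidationError("depths must be positive")
        if np.any(np.diff(self.depth) <= 0):
            raise ValidationError("depths must be strictly increasing")
        if np.any(self.count < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def total_instances(self) -> int:
        """Total number of k-mer instances, sum(depth * count)."""
        return int(np.sum(self.depth * self.count))


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into SequenceRecords.

    Sequences are uppercased and U is mapped to T. Malformed headers and
    empty sequences raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    # Pre-scan so errors can name lines; parsing itself is Bio.SeqIO's job.
    current_header_line = None
    seen_seq = False
    first_content = True
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            if not line[1:].strip():
                raise FormatError(f"{path}:{lineno}: FASTA header without an id")
            if current_header_line is not None and not seen_seq:
                raise FormatError(
                    f"{path}:{current_header_line}: record has an empty sequence"
                )
            current_header_line = lineno
            seen_seq = False
            first_content = False
        else:
            if first_content:
                raise FormatError(
                    f"{path}:{lineno}: expected a '>' header before sequence data"
                )
            seen_seq = True
    if current_header_line is None:
        raise FormatError(f"{path}: no FASTA records found")
    if not seen_seq:
        raise FormatError(f"{path}:{current_header_line}: record has an empty sequence")

    records = []
    with io.StringIO("\n".join(lines)) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            try:
                records.append(SequenceRecord(id=rec.id, sequence=seq))
            except ValidationError as exc:
                raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# LTR element table (bespoke TSV, 1-based inclusive on disk)


def read_ltr_table(path) -> list[LtrElementRow]:
    """Read the nine-column LTR element TSV (1-based inclusive coordinates)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in LTR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    rows = []
    for _, r in df.iterrows():
        eid = str(r["element_id"])
        try:
            coords = {
                c: int(r[c])
                for c in LTR_TABLE_COLUMNS
                if c.endswith(("_start", "_end"))
            }
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: element {eid!r}: non-integer coordinate") from exc
        try:
            rows.append(
                LtrElementRow(
                    element_id=eid,
                    chrom=str(r["chrom"]),
                    # 1-based inclusive -> 0-based half-open
                    element_start=coords["element_start"] - 1,
                    element_end=coords["element_end"],
                    ltr5_start=coords["ltr5_start"] - 1,
                    ltr5_end=coords["ltr5_end"],
                    ltr3_start=coords["ltr3_start"] - 1,
                    ltr3_end=coords["ltr3_end"],
                    superfamily=normalize_superfamily(str(r["superfamily"])),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return rows


def write_ltr_table(path, rows: Sequence[LtrElementRow]) -> None:
    df = pd.DataFrame(
        {
            "element_id": [r.element_id for r in rows],
            "chrom": [r.chrom for r in rows],
            "element_start": [r.element_start + 1 for r in rows],
            "element_end": [r.element_end for r in rows],
            "ltr5_start": [r.ltr5_start + 1 for r in rows],
            "ltr5_end": [r.ltr5_end for r in rows],
            "ltr3_start": [r.ltr3_start + 1 for r in rows],
            "ltr3_end": [r.ltr3_end for r in rows],
            "superfamily": [r.superfamily for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


def read_vcf_genotypes(path) -> GenotypeTable:
    """Load a VCF 4.x into a GenotypeTable via cyvcf2.

    Multi-allelic records are flagged (``biallelic=False``) rather than
    dropped; the filter stage accounts for them. Missing genotypes map to -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    header = vcf.raw_header
    if "##FORMAT=<ID=GT" not in header:
        raise FormatError(f"{path}: VCF has no GT FORMAT definition")
    individuals = list(vcf.samples)
    n_ind = len(individuals)
    chroms, poss, refs, alts, quals, bial = [], [], [], [], [], []
    gts, dps, gqs = [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)  # 1-based VCF -> 0-based internal
        refs.append(var.REF)
        alts.append(",".join(var.ALT) if var.ALT else ".")
        quals.append(var.QUAL if var.QUAL is not None else math.nan)
        bial.append(
            len(var.ALT) == 1 and len(var.REF) == 1 and len(var.ALT[0]) == 1
        )
        row = np.full(n_ind, -1, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            # cyvcf2 genotype entry: [allele_1, allele_2, phased]
            a, b = int(g[0]), int(g[1])
            if a >= 0 and b >= 0:
                row[i] = min(a, 1) + min(b, 1)
        gts.append(row)
        dp = var.format("DP")
        if dp is None:
            dps.append(np.full(n_ind, -1, dtype=np.int32))
        else:
            d = dp.astype(np.int64).ravel()[:n_ind]
            dps.append(np.where(d < 0, -1, d).astype(np.int32))
        gq = var.format("GQ")
        if gq is None:
            gqs.append(np.full(n_ind, -1, dtype=np.int32))
        else:
            g = gq.astype(np.int64).ravel()[:n_ind]
            gqs.append(np.where(g < 0, -1, g).astype(np.int32))
    if not chroms:
        raise FormatError(f"{path}: VCF contains no variant records")
    return GenotypeTable(
        individuals=individuals,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        qual=np.array(quals, dtype=np.float64),
        biallelic=np.array(bial, dtype=bool),
        genotypes=np.vstack(gts),
        depth=np.vstack(dps),
        gq=np.vstack(gqs),
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(path, table: GenotypeTable) -> None:
    """Write a GenotypeTable as a minimal plain-text VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genomedyn\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        for c in dict.fromkeys(table.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.individuals)
            + "\n"
        )
        for s in range(table.n_sites):
            qual = table.qual[s]
            qual_str = "." if math.isnan(qual) else f"{qual:g}"
            calls = []
            for i in range(table.n_individuals):
                gt = _GT_STRINGS[int(table.genotypes[s, i])]
                dp = table.depth[s, i]
                gq = table.gq[s, i]
                calls.append(
                    f"{gt}:{dp if dp >= 0 else '.'}:{gq if gq >= 0 else '.'}"
                )
            fh.write(
                f"{table.chrom[s]}\t{table.pos[s] + 1}\t.\t{table.ref[s]}\t"
                f"{table.alt[s]}\t{qual_str}\t.\t.\tGT:DP:GQ\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# k-mer histogram (two-column whitespace text)


def read_kmer_histogram(path, k: int = 17) -> KmerHistogram:
    """Read a two-column (depth, count) whitespace-delimited histogram."""
    depths, counts = [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            try:
                d, c = int(parts[0]), int(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer field in {parts!r}"
                ) from None
            depths.append(d)
            counts.append(c)
    if not depths:
        raise FormatError(f"{path}: empty histogram")
    order = np.argsort(depths, kind="stable")
    depth = np.asarray(depths, dtype=np.int64)[order]
    count = np.asarray(counts, dtype=np.int64)[order]
    if np.any(np.diff(depth) == 0):
        raise FormatError(f"{path}: duplicate depth values")
    try:
        return KmerHistogram(depth=depth, count=count, k=k)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_kmer_histogram(path, hist: KmerHistogram) -> None:
    with open(path, "w") as fh:
        for d, c in zip(hist.depth, hist.count):
            fh.write(f"{d} {c}\n")


# ---------------------------------------------------------------------------
# BED (repeat masks), 0-based half-open on disk and in memory


def read_bed(path) -> list[tuple[str, int, int]]:
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with < 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty or reversed BED interval")
            intervals.append((parts[0], start, end))
    return intervals


def write_bed(path, intervals: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
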