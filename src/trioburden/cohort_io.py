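"""Readers and writers for cohort artifacts, plus the domain records they carry.

All on-disk interval coordinates follow BED conventions (0-based, half-open);
point variants are 1-based (VCF convention). Chromosome names are normalized
to the ``chr``-prefixed form on read. Unknown extra columns are preserved by
the TSV round trip but ignored by the analysis.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "ChildRecord",
    "DeNovoVariant",
    "DeNovoCNV",
    "GeneModelTranscript",
    "GeneSet",
    "FormatError",
    "read_pedigree",
    "write_pedigree",
    "read_variant_table",
    "write_variant_table",
    "read_gene_model",
    "write_gene_model",
    "read_gene_set",
    "write_gene_set",
    "read_config",
    "get_logger",
    "normalize_chrom",
]

PEDIGREE_COLUMNS = [
    "child_id",
    "family_id",
    "collection",
    "affected",
    "sex",
    "dna_source",
    "mother_age",
    "father_age",
    "mean_coverage",
]

SMALL_VARIANT_COLUMNS = ["child_id", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads"]
CNV_COLUMNS = ["chrom", "start", "end", "child_id", "change"]


class FormatError(ValueError):
    """A file did not conform to the declared on-disk format."""


def get_logger(name: str = "trioburden") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


_log = get_logger(__name__)


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed convention."""
    c = str(chrom).strip()
    if not c.startswith("chr"):
        c = "chr" + c
    return c


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChildRecord:
    """One sequenced child of a trio with the covariates the analysis uses."""

    child_id: str
    family_id: str
    collection: str  # SSC | AGRE | OTHER
    affected: bool
    sex: str  # M | F
    dna_source: str  # WB | LCL
    mother_age_years: float
    father_age_years: float
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.collection not in {"SSC", "AGRE", "OTHER"}:
            raise ValueError(f"unknown collection {self.collection!r} for child {self.child_id}")
        if self.sex not in {"M", "F"}:
            raise ValueError(f"unknown sex {self.sex!r} for child {self.child_id}")
        if self.dna_source not in {"WB", "LCL"}:
            raise ValueError(f"unknown dna_source {self.dna_source!r} for child {self.child_id}")
        if self.mean_coverage < 0:
            raise ValueError(f"negative coverage for child {self.child_id}")
        for label, age in (("mother", self.mother_age_years), ("father", self.father_age_years)):
            if age is not None and not (10.0 <= age <= 80.0):
                raise ValueError(
                    f"{label} age {age} out of range [10, 80] for child {self.child_id}"
                )


@dataclass(frozen=True)
class DeNovoVariant:
    """A de novo substitution or small indel called in one child.

    ``pos`` is 1-based; ``var_type`` is inferred from the allele lengths
    (SUB iff both alleles are single bases).
    """

    child_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_reads: int = 0
    alt_reads: int = 0
    effect: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def var_type(self) -> str:
        return "SUB" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def alt_ratio(self) -> float:
        """Alternative allele ratio: fraction of reads supporting the alt allele."""
        total = self.ref_reads + self.alt_reads
        if total == 0:
            raise ValueError(f"no reads recorded for variant at {self.chrom}:{self.pos}")
        return self.alt_reads / total


@dataclass(frozen=True)
class DeNovoCNV:
    """A de novo copy-number event on a 0-based half-open interval."""

    child_id: str
    chrom: str
    start: int
    end: int
    change: str  # DEL | DUP
    cnv_effect: str | None = None
    single_gene_subclass: str | None = None
    n_genes_hit: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CNV interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.change not in {"DEL", "DUP"}:
            raise ValueError(f"unknown CNV change {self.change!r}")

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModelTranscript:
    """One transcript model: exon structure plus CDS extent (half-open).

    ``cds_start == cds_end`` marks a noncoding transcript. Exons are sorted,
    disjoint (start, end) tuples within the transcript span.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon ({s},{e}) in {self.transcript_id}")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"exon ({s},{e}) outside transcript span in {self.transcript_id}")
            if s <= prev_end:
                raise ValueError(f"exons overlap or are unsorted in {self.transcript_id}")
            prev_end = e
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"CDS outside transcript span in {self.transcript_id}")

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exonic intervals intersected with the CDS extent."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return tuple(out)


@dataclass(frozen=True)
class GeneSet:
    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> list[ChildRecord]:
    """Read a pedigree TSV into validated :class:`ChildRecord` objects.

    Raises :class:`FormatError` on missing columns, duplicated child ids, or
    unparseable numeric fields (the error names the offending row/id).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pedigree {path}: missing columns {missing}")
    dup = df["child_id"][df["child_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"pedigree {path}: duplicated child_id {dup.iloc[0]!r}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ChildRecord(
                    child_id=row["child_id"],
                    family_id=row["family_id"],
                    collection=row["collection"],
                    affected=bool(int(row["affected"])),
                    sex=row["sex"],
                    dna_source=row["dna_source"],
                    mother_age_years=float(row["mother_age"]),
                    father_age_years=float(row["father_age"]),
                    mean_coverage=float(row["mean_coverage"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"pedigree {path} row {i} (child {row['child_id']!r}): {exc}") from exc
    return records


def write_pedigree(cohort: Iterable[ChildRecord], path: str | Path) -> None:
    rows = [
        {
            "child_id": c.child_id,
            "family_id": c.family_id,
            "collection": c.collection,
            "affected": int(c.affected),
            "sex": c.sex,
            "dna_source": c.dna_source,
            "mother_age": c.mother_age_years,
            "father_age": c.father_age_years,
            "mean_coverage": c.mean_coverage,
        }
        for c in cohort
    ]
    pd.DataFrame(rows, columns=PEDIGREE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant tables (small variants: TSV or VCF; CNVs: BED-like TSV)
# ---------------------------------------------------------------------------


def _is_vcf(path: Path) -> bool:
    if path.suffix in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
        return True
    try:
        with open(path, "rt") as fh:
            return fh.readline().startswith("##fileformat=VCF")
    except (OSError, UnicodeDecodeError):
        return False


def read_variant_table(path: str | Path, kind: str = "SMALL"):
    """Read de novo calls: ``kind='SMALL'`` small variants, ``kind='CNV'`` CNVs.

    Small variants may come as a TSV (child_id, chrom, pos, ref, alt,
    ref_reads, alt_reads [, effect]) or a VCF 4.x with per-sample GT and AD;
    every sample carrying a non-reference genotype yields one record. CNVs
    are a BED-like TSV (chrom, start, end, child_id, change). CNV rows with
    end <= start raise a record-level error; unknown chromosome labels are
    accepted after normalization.
    """
    path = Path(path)
    if kind == "SMALL":
        if _is_vcf(path):
            return _read_small_vcf(path)
        return _read_small_tsv(path)
    if kind == "CNV":
        return _read_cnv_tsv(path)
    raise ValueError(f"unknown variant table kind {kind!r}")


def _read_small_tsv(path: Path) -> list[DeNovoVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SMALL_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table {path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                DeNovoVariant(
                    child_id=row["child_id"],
                    chrom=normalize_chrom(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    ref_reads=int(row["ref_reads"]),
                    alt_reads=int(row["alt_reads"]),
                    effect=row["effect"] if "effect" in df.columns and pd.notna(row["effect"]) else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"variant table {path} row {i}: {exc}") from exc
    return out


def _read_small_vcf(path: Path) -> list[DeNovoVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"VCF {path}: no sample columns")
    out = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(f"VCF {path}: AD field missing at {rec.CHROM}:{rec.POS}")
        for si, sample in enumerate(samples):
            gt = rec.genotypes[si]
            if not any(a == 1 for a in gt[:-1]):
                continue
            ref_reads, alt_reads = int(ad[si][0]), int(ad[si][1])
            out.append(
                DeNovoVariant(
                    child_id=sample,
                    chrom=normalize_chrom(rec.CHROM),
                    pos=int(rec.POS),
                    ref=rec.REF,
                    alt=rec.ALT[0],
                    ref_reads=max(ref_reads, 0),
                    alt_reads=max(alt_reads, 0),
                )
            )
    return out


def _read_cnv_tsv(path: Path) -> list[DeNovoCNV]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CNV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"CNV table {path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                DeNovoCNV(
                    child_id=row["child_id"],
                    chrom=normalize_chrom(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    change=row["change"],
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"CNV table {path} row {i}: {exc}") from exc
    return out


def write_variant_table(events, path: str | Path, kind: str = "SMALL") -> None:
    if kind == "SMALL":
        rows = [
            {
                "child_id": v.child_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "ref_reads": v.ref_reads,
                "alt_reads": v.alt_reads,
                "effect": v.effect if v.effect is not None else "",
            }
            for v in events
        ]
        pd.DataFrame(rows, columns=SMALL_VARIANT_COLUMNS + ["effect"]).to_csv(
            path, sep="\t", index=False
        )
    elif kind == "CNV":
        rows = [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "child_id": c.child_id,
                "change": c.change,
            }
            for c in events
        ]
        pd.DataFrame(rows, columns=CNV_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown variant table kind {kind!r}")


# ---------------------------------------------------------------------------
# Gene models (BED12) and gene sets
# ---------------------------------------------------------------------------


def read_gene_model(path: str | Path) -> list[GeneModelTranscript]:
    """Read transcript models from BED12.

    The ``name`` field encodes ``gene_symbol/transcript_id`` (a bare name is
    used for both). Exons are reconstructed from blockStarts/blockSizes and
    thickStart/thickEnd is taken as the CDS extent, clipped to the transcript.
    """
    transcripts = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path} line {ln + 1}: expected 12 BED fields, got {len(fields)}")
            chrom = normalize_chrom(fields[0])
            tx_start, tx_end = int(fields[1]), int(fields[2])
            name = fields[3]
            strand = fields[5]
            thick_start = max(int(fields[6]), tx_start)
            thick_end = min(int(fields[7]), tx_end)
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"{path} line {ln + 1}: blockCount {block_count} does not match "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = tuple((tx_start + s, tx_start + s + sz) for s, sz in zip(starts, sizes))
            if "/" in name:
                gene_symbol, transcript_id = name.split("/", 1)
            else:
                gene_symbol = transcript_id = name
            if thick_end < thick_start:
                thick_start = thick_end = tx_start
            transcripts.append(
                GeneModelTranscript(
                    gene_symbol=gene_symbol,
                    transcript_id=transcript_id,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=exons,
                    cds_start=thick_start,
                    cds_end=thick_end,
                )
            )
    return transcripts


def write_gene_model(transcripts: Sequence[GeneModelTranscript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.tx_start) for s, _ in t.exons)
            name = f"{t.gene_symbol}/{t.transcript_id}"
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.tx_start),
                        str(t.tx_end),
                        name,
                        "0",
                        t.strand,
                        str(t.cds_start),
                        str(t.cds_end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a newline-delimited gene symbol list (``#`` comments allowed)."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                symbols.add(sym)
    if not symbols:
        raise FormatError(f"gene set file {path} contains no symbols")
    return GeneSet(name=name or Path(path).stem, symbols=frozenset(symbols))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(gene_set.symbols):
            fh.write(sym + "\n")


def read_config(path: str | Path) -> dict:
    """Read a YAML key/value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path}: expected a mapping at top level")
    return cfg
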