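"""Readers and writers for direct-to-consumer genotype files and the SNP reference VCF.

Two raw dialects are supported: the 23andme export (4 tab-separated columns:
rsid, chromosome, position, genotype) and the AncestryDNA export (5 columns:
rsid, chromosome, position, allele1, allele2). AncestryDNA rows are merged
into a single genotype string ``allele1 + allele2`` so every profile is
structurally a 23andme profile. The SNP reference panel (rsid, REF, ALT) is
read from VCF through cyvcf2.

Genotype strings that cannot be compared to a single-base reference allele —
the ``--`` no-call marker, AncestryDNA ``0`` placeholder alleles, and calls
containing insertion/deletion codes (I/D) or any character outside
{A, C, G, T} — are stored as missing.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
#: characters a raw genotype call may contain (I/D are indel codes)
CALL_CHARS = frozenset("ACGTID")
MISSING_GENOTYPE = "--"

FORMAT_23ANDME = "23andme"
FORMAT_ANCESTRYDNA = "ancestrydna"


class GenotypeParseError(ValueError):
    """A raw genotype file could not be parsed at all (wrong structure)."""


@dataclass(frozen=True)
class GenotypeRecord:
    """One SNP call for one person.

    ``genotype`` is ``None`` when the site is a no-call or contains characters
    that cannot be compared to a single-base reference allele.
    """

    rsid: str
    chromosome: str
    position: int
    genotype: Optional[str]

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"position must be positive, got {self.position}")
        if self.genotype is not None and not (
            1 <= len(self.genotype) <= 2 and set(self.genotype) <= CALL_CHARS
        ):
            raise ValueError(f"invalid genotype string {self.genotype!r}")


@dataclass
class ParseReport:
    """Line-level bookkeeping for one raw genotype file."""

    path: str = ""
    n_lines: int = 0
    n_comments: int = 0
    n_records: int = 0
    n_no_calls: int = 0
    n_duplicates: int = 0
    n_errors: int = 0
    error_lines: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "path": self.path,
            "n_lines": self.n_lines,
            "n_comments": self.n_comments,
            "n_records": self.n_records,
            "n_no_calls": self.n_no_calls,
            "n_duplicates": self.n_duplicates,
            "n_errors": self.n_errors,
            "error_lines": list(self.error_lines),
        }


@dataclass
class GenotypeProfile:
    """All SNP calls for one person, keyed by rsid (first occurrence wins)."""

    sample_id: str
    records: dict[str, GenotypeRecord]
    source_format: str
    parse_report: Optional[ParseReport] = None

    def __len__(self) -> int:
        return len(self.records)

    def same_records(self, other: "GenotypeProfile") -> bool:
        """Record-for-record equality, ignoring sample id and provenance."""
        return self.records == other.records


@dataclass(frozen=True)
class SnpReference:
    """REF/ALT information for one SNP from the reference panel."""

    rsid: str
    chromosome: str
    position: int
    ref_allele: Optional[str]
    alt_allele: Optional[str]

    @property
    def complete(self) -> bool:
        return (
            self.ref_allele in VALID_BASES and self.alt_allele in VALID_BASES
        )


def _chromosome_sort_key(chrom: str) -> tuple[int, str]:
    """Order 1..22 numerically, then X, Y, MT, then anything else."""
    c = chrom.upper()
    if c.isdigit():
        return (int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return (special.get(c, 26), c)


@dataclass
class ReferencePanel:
    """Ordered SNP reference entries with an rsid index (first entry wins)."""

    entries: list[SnpReference]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.index: dict[str, SnpReference] = {}
        for entry in self.entries:
            self.index.setdefault(entry.rsid, entry)

    def __len__(self) -> int:
        return len(self.entries)

    def sorted(self) -> "ReferencePanel":
        """Deterministic (chromosome, position, rsid) ordering."""
        ordered = sorted(
            self.entries,
            key=lambda e: (_chromosome_sort_key(e.chromosome), e.position, e.rsid),
        )
        return ReferencePanel(ordered, list(self.warnings))


def _normalise_genotype(raw: str) -> Optional[str]:
    """Map a raw genotype string to a stored call or missing (None)."""
    g = raw.strip().upper()
    if not (1 <= len(g) <= 2):
        return None
    if set(g) <= CALL_CHARS:
        return g
    return None


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _parse_lines(
    lines: Iterable[str], n_columns: int, report: ParseReport
) -> Iterator[tuple[list[str], int]]:
    for lineno, line in enumerate(lines, start=1):
        report.n_lines += 1
        stripped = line.rstrip("\n").rstrip("\r")
        if not stripped or stripped.startswith("#"):
            report.n_comments += 1
            continue
        fields = stripped.split("\t")
        if len(fields) != n_columns:
            report.n_errors += 1
            report.error_lines.append(lineno)
            logger.warning("line %d: expected %d columns, got %d", lineno, n_columns, len(fields))
            continue
        yield fields, lineno


def _finish_profile(
    rows: Iterator[tuple[str, str, str, Optional[str]]],
    sample_id: str,
    source_format: str,
    report: ParseReport,
) -> GenotypeProfile:
    records: dict[str, GenotypeRecord] = {}
    for rsid, chrom, pos, genotype in rows:
        try:
            record = GenotypeRecord(rsid, _strip_chr(chrom), int(pos), genotype)
        except (ValueError, TypeError):
            report.n_errors += 1
            continue
        if rsid in records:
            report.n_duplicates += 1
            continue
        records[rsid] = record
        report.n_records += 1
        if genotype is None:
            report.n_no_calls += 1
    return GenotypeProfile(sample_id, records, source_format, report)


def parse_23andme(path: str | Path) -> GenotypeProfile:
    """Parse a 4-column 23andme raw file into a :class:`GenotypeProfile`.

    ``--`` and any genotype containing characters outside {A,C,G,T,I,D} are
    stored as missing; genotypes with I/D are stored verbatim but coded as
    missing downstream. Duplicate rsids keep the first occurrence.
    """
    path = Path(path)
    report = ParseReport(path=str(path))

    def rows() -> Iterator[tuple[str, str, str, Optional[str]]]:
        with path.open() as fh:
            for fields, _ in _parse_lines(fh, 4, report):
                rsid, chrom, pos, raw = fields
                genotype = None if raw.strip() == MISSING_GENOTYPE else _normalise_genotype(raw)
                # indel codes can't be compared to a single-base reference
                if genotype is not None and set(genotype) & {"I", "D"}:
                    genotype = None
                yield rsid.strip(), chrom.strip(), pos.strip(), genotype

    return _finish_profile(rows(), path.stem, FORMAT_23ANDME, report)


def parse_ancestrydna(path: str | Path) -> GenotypeProfile:
    """Parse a 5-column AncestryDNA raw file, merging allele1+allele2.

    A ``0`` in either allele column marks a no-call; the merged profile is
    structurally identical to a 23andme parse.
    """
    path = Path(path)
    report = ParseReport(path=str(path))

    def rows() -> Iterator[tuple[str, str, str, Optional[str]]]:
        with path.open() as fh:
            for fields, _ in _parse_lines(fh, 5, report):
                rsid, chrom, pos, a1, a2 = (f.strip() for f in fields)
                if a1 == "0" or a2 == "0":
                    genotype: Optional[str] = None
                else:
                    genotype = _normalise_genotype(a1 + a2)
                    if genotype is not None and set(genotype) & {"I", "D"}:
                        genotype = None
                yield rsid, chrom, pos, genotype

    return _finish_profile(rows(), path.stem, FORMAT_ANCESTRYDNA, report)


def write_23andme(profile: GenotypeProfile, path: str | Path) -> None:
    """Write a profile as a 4-column 23andme file in (chromosome, position) order."""
    path = Path(path)
    ordered = sorted(
        profile.records.values(),
        key=lambda r: (_chromosome_sort_key(r.chromosome), r.position, r.rsid),
    )
    with path.open("w") as fh:
        fh.write("# rsid\tchromosome\tposition\tgenotype\n")
        for rec in ordered:
            genotype = rec.genotype if rec.genotype is not None else MISSING_GENOTYPE
            fh.write(f"{rec.rsid}\t{rec.chromosome}\t{rec.position}\t{genotype}\n")


def load_reference_vcf(path: str | Path) -> ReferencePanel:
    """Load the SNP reference panel (ID, REF, ALT) from a VCF file.

    ``.`` in REF or ALT leaves the corresponding allele missing (entry
    incomplete, removed later by QC); a multi-allelic ALT keeps the first
    allele and records a warning. Entries are returned in deterministic
    (chromosome, position, rsid) order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[SnpReference] = []
    warnings: list[str] = []
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises plain OSError/Exception on bad headers
        raise GenotypeParseError(f"not a readable VCF: {path}: {exc}") from exc
    for variant in vcf:
        rsid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ref = variant.REF if variant.REF and variant.REF in VALID_BASES else None
        alts = [a for a in (variant.ALT or []) if a and a != "."]
        if len(alts) > 1:
            warnings.append(f"{rsid}: multi-allelic ALT {alts}, keeping {alts[0]}")
        alt = alts[0] if alts and alts[0] in VALID_BASES else None
        entries.append(
            SnpReference(rsid, _strip_chr(variant.CHROM), variant.POS, ref, alt)
        )
    vcf.close()
    for msg in warnings:
        logger.warning("%s", msg)
    return ReferencePanel(entries, warnings).sorted()


def sniff_format(path: str | Path) -> str:
    """Guess the dialect of a raw genotype file from its first data line.

    Returns ``"23andme"``, ``"ancestrydna"`` or ``"unknown"``. Binary or
    encrypted files (e.g. ftdna-illumina exports) come back ``"unknown"``
    and should be skipped with a warning.
    """
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                n = len(stripped.split("\t"))
                if n == 4:
                    return FORMAT_23ANDME
                if n == 5:
                    return FORMAT_ANCESTRYDNA
                return "unknown"
    except (UnicodeDecodeError, OSError):
        return "unknown"
    return "unknown"


def parse_any(path: str | Path) -> Optional[GenotypeProfile]:
    """Parse a raw file in whichever supported dialect it is in.

    Returns ``None`` (with a logged warning) for unrecognised or unreadable
    formats such as encrypted ftdna-illumina exports.
    """
    fmt = sniff_format(path)
    if fmt == FORMAT_23ANDME:
        return parse_23andme(path)
    if fmt == FORMAT_ANCESTRYDNA:
        return parse_ancestrydna(path)
    logger.warning("skipping %s: unrecognised or unreadable format", path)
    return None
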