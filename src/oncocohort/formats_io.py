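"""Readers and writers for the plain-text formats the toolkit exchanges.

Dialects handled here:

* ``chrom.sizes`` — two tab-separated columns (name, length), or SAM header
  text from which ``@SQ`` lines are harvested.
* MAF — GDC-style tab-separated mutation annotation format.  Only the seven
  structural columns are required; any further columns are carried through
  opaquely so that ``write_maf(read_maf(t))`` round-trips.
* SEG — IGV segmented copy-number tables, 5- or 6-column variants.
* BED3 gene tables and one-symbol-per-line gene lists.
* Sites-only VCFv4.2 (no FORMAT/sample columns).

Coordinate conventions: MAF, SEG and VCF are 1-based inclusive **on disk**;
gene tables are BED (0-based half-open) on disk.  Everything internal is
0-based half-open; conversion happens here at the I/O boundary and nowhere
else.  ``MafRecord``/``SegRecord``/``VcfSite`` mirror their on-disk 1-based
fields verbatim; use :meth:`MafRecord.interval` etc. for half-open views.

Chromosome names are matched exactly; :func:`normalize_chrom_names` offers an
opt-in ``chr``-prefix normalizer (off by default, since silent aliasing hides
data errors).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ParseError, SchemaError, ValidationError

# ---------------------------------------------------------------------------
# Enumerations

VARIANT_CLASSIFICATIONS = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Nonstop_Mutation",
    "Translation_Start_Site",
    "Silent",
    "3'UTR",
    "5'UTR",
    "Intron",
    "RNA",
    "IGR",
)

VARIANT_TYPES = ("SNP", "INS", "DEL", "DNP", "TNP")

_BASES = frozenset("ACGT")
_ALLELE_CHARS = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class ChromTable:
    """Ordered chromosome names and lengths; the planner's universe.

    Input order is preserved and defines the canonical chromosome sort order
    used downstream (VCF merging, gene ordering, circos layout).
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate chromosome name(s): {', '.join(dup)}")
        for name, length in self.entries:
            if length < 1:
                raise ValidationError(f"chromosome {name}: length {length} < 1")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def length(self, name: str) -> int:
        for n, ln in self.entries:
            if n == name:
                return ln
        raise KeyError(name)

    def index(self, name: str) -> int:
        """Rank of a chromosome in the canonical order."""
        for i, (n, _) in enumerate(self.entries):
            if n == name:
                return i
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.entries)


@dataclass(frozen=True)
class MafRecord:
    """One annotated somatic mutation (one MAF data row).

    ``start``/``end`` are 1-based inclusive, as on disk.  ``extra`` holds any
    additional MAF columns verbatim, keyed by their header names, so records
    round-trip through :func:`write_maf`.
    """

    gene_symbol: str
    chrom: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    variant_classification: str
    variant_type: str
    sample_id: str
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.variant_classification not in VARIANT_CLASSIFICATIONS:
            raise ValidationError(
                f"unknown Variant_Classification {self.variant_classification!r}"
            )
        if self.variant_type not in VARIANT_TYPES:
            raise ValidationError(f"unknown Variant_Type {self.variant_type!r}")
        if self.end < self.start:
            raise ValidationError(f"end {self.end} < start {self.start}")
        if self.variant_type == "SNP":
            ref, alt = self.ref_allele, self.alt_allele
            if not (ref in _BASES and alt in _BASES and ref != alt):
                raise ValidationError(
                    f"SNP alleles must be distinct single bases, got {ref!r}>{alt!r}"
                )

    def interval(self) -> tuple[int, int]:
        """0-based half-open genomic interval."""
        return (self.start - 1, self.end)


@dataclass(frozen=True)
class SegRecord:
    """One copy-number segment of one sample (1-based inclusive on disk)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_markers: int | None = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(f"segment end {self.end} < start {self.start}")

    def interval(self) -> tuple[int, int]:
        return (self.start - 1, self.end)


@dataclass(frozen=True)
class GeneRecord:
    """Gene coordinates, BED-style 0-based half-open."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"gene {self.symbol}: end {self.end} must exceed start {self.start}"
            )


@dataclass(frozen=True)
class VcfSite:
    """One sites-only VCF record (single ALT after multiallelic split)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    filter: str = "."
    info: tuple[tuple[str, str], ...] = ()
    id: str = "."
    qual: str = "."

    def __post_init__(self):
        # ALT may hold comma-separated alleles until split_multiallelic runs.
        alleles = [(self.ref, "REF")] + [(a, "ALT") for a in self.alt.split(",")]
        for allele, label in alleles:
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValidationError(
                    f"{label} must be nonempty uppercase over ACGTN, got {allele!r}"
                )

    def info_dict(self) -> dict[str, str]:
        return dict(self.info)


@dataclass
class VcfDocument:
    """A sites-only VCF: header lines (without trailing newlines) + records."""

    header: list[str] = field(default_factory=list)
    sites: list[VcfSite] = field(default_factory=list)


# ---------------------------------------------------------------------------
# chrom.sizes / SAM header


def read_chrom_sizes(stream: str | io.TextIOBase, dialect: str = "two_column") -> ChromTable:
    """Parse a chromosome-size table.

    ``dialect="two_column"`` expects ``name<TAB>length`` lines;
    ``dialect="sam_header"`` harvests ``@SQ`` lines (``SN:``/``LN:`` tags)
    from SAM header text, ignoring all other header lines.
    """
    text = stream if isinstance(stream, str) else stream.read()
    if dialect not in ("two_column", "sam_header"):
        raise ValueError(f"unknown dialect {dialect!r}")
    entries: list[tuple[str, int]] = []
    saw_line = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        saw_line = True
        if dialect == "sam_header":
            if not line.startswith("@SQ"):
                continue
            tags = dict(
                t.split(":", 1) for t in line.split("\t")[1:] if ":" in t
            )
            if "SN" not in tags or "LN" not in tags:
                raise ParseError("@SQ line lacks SN: or LN: tag", lineno)
            name, length_s = tags["SN"], tags["LN"]
        else:
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"expected 2 tab-separated columns, got {len(parts)}", lineno
                )
            name, length_s = parts
        try:
            length = int(length_s)
        except ValueError:
            raise ParseError(f"non-integer length {length_s!r}", lineno) from None
        if length < 1:
            raise ParseError(f"length {length} < 1", lineno)
        entries.append((name, length))
    if not saw_line:
        raise ParseError("empty chromosome-size input")
    if dialect == "sam_header" and not entries:
        raise ParseError("no @SQ lines found in SAM header input")
    return ChromTable(tuple(entries))


def write_chrom_sizes(table: ChromTable) -> str:
    return "".join(f"{n}\t{ln}\n" for n, ln in table)


def normalize_chrom_names(names: Iterable[str], *, add_prefix: bool = False) -> list[str]:
    """Optional ``chr``-prefix normalizer (exact matching is the default policy)."""
    out = []
    for n in names:
        bare = n[3:] if n.lower().startswith("chr") else n
        out.append(f"chr{bare}" if add_prefix else bare)
    return out


# ---------------------------------------------------------------------------
# MAF

MAF_REQUIRED = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
)


def _split_tsv_header(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_maf(stream: str | io.TextIOBase) -> list[MafRecord]:
    """Parse a GDC-style MAF.  Leading ``#`` comment lines are skipped; column
    names are matched case-insensitively; unrecognized columns are preserved in
    ``MafRecord.extra`` for round-trip."""
    text = stream if isinstance(stream, str) else stream.read()
    lines = text.splitlines()
    header: list[str] | None = None
    header_lineno = 0
    records: list[MafRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            continue
        if header is None:
            header = _split_tsv_header(line)
            header_lineno = lineno
            lower = [h.lower() for h in header]
            missing = [c for c in MAF_REQUIRED if c.lower() not in lower]
            if missing:
                raise SchemaError(
                    "MAF header missing required column(s): " + ", ".join(missing)
                )
            col = {c: lower.index(c.lower()) for c in MAF_REQUIRED}
            extra_cols = [
                (i, header[i])
                for i in range(len(header))
                if i not in col.values()
            ]
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} columns (header at line {header_lineno}), "
                f"got {len(fields)}",
                lineno,
            )
        try:
            rec = MafRecord(
                gene_symbol=fields[col["Hugo_Symbol"]],
                chrom=fields[col["Chromosome"]],
                start=int(fields[col["Start_Position"]]),
                end=int(fields[col["End_Position"]]),
                ref_allele=fields[col["Reference_Allele"]],
                alt_allele=fields[col["Tumor_Seq_Allele2"]],
                variant_classification=fields[col["Variant_Classification"]],
                variant_type=fields[col["Variant_Type"]],
                sample_id=fields[col["Tumor_Sample_Barcode"]],
                extra=tuple((name, fields[i]) for i, name in extra_cols),
            )
        except ValueError as e:
            raise ParseError(f"bad numeric field: {e}", lineno) from None
        except ValidationError as e:
            raise ValidationError(f"row at line {lineno}: {e}") from None
        records.append(rec)
    if header is None:
        raise SchemaError("MAF input has no header line")
    return records


def write_maf(records: Sequence[MafRecord]) -> str:
    """Emit a MAF with the required columns first, then any extra columns seen
    on the first record (all records must share the same extra-column set)."""
    extra_names = [k for k, _ in records[0].extra] if records else []
    header = list(MAF_REQUIRED) + extra_names
    out = ["\t".join(header)]
    for rec in records:
        extras = dict(rec.extra)
        if list(extras) != extra_names:
            raise ValidationError(
                f"inconsistent extra columns on record {rec.gene_symbol}/{rec.sample_id}"
            )
        row = [
            rec.gene_symbol,
            rec.chrom,
            str(rec.start),
            str(rec.end),
            rec.ref_allele,
            rec.alt_allele,
            rec.variant_classification,
            rec.variant_type,
            rec.sample_id,
        ] + [extras[k] for k in extra_names]
        out.append("\t".join(row))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# SEG

_SEG_HEADER_HINTS = ("id", "sample", "track")


def read_seg(stream: str | io.TextIOBase) -> list[SegRecord]:
    """Parse an IGV SEG table (5 columns, or 6 with a num-markers column).

    An optional header line is detected by a non-numeric start column.
    """
    text = stream if isinstance(stream, str) else stream.read()
    records: list[SegRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (5, 6):
            raise ParseError(f"expected 5 or 6 columns, got {len(parts)}", lineno)
        # Header detection: start column not an integer on the first row.
        if not records and not _is_int(parts[2]):
            if parts[0].strip().lower().startswith(_SEG_HEADER_HINTS) or lineno == 1:
                continue
            raise ParseError(f"non-integer start {parts[2]!r}", lineno)
        try:
            if len(parts) == 6:
                sample, chrom, s, e, nm, lr = parts
                n_markers = int(nm)
            else:
                sample, chrom, s, e, lr = parts
                n_markers = None
            rec = SegRecord(
                sample_id=sample,
                chrom=chrom,
                start=int(s),
                end=int(e),
                n_markers=n_markers,
                log2_ratio=float(lr),
            )
        except ValueError as e:
            raise ParseError(f"bad numeric field: {e}", lineno) from None
        except ValidationError as e:
            raise ValidationError(f"row at line {lineno}: {e}") from None
        records.append(rec)
    return records


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_seg(records: Sequence[SegRecord]) -> str:
    """Emit an IGV SEG table.  6-column when any record carries n_markers."""
    with_markers = any(r.n_markers is not None for r in records)
    cols = ["ID", "chrom", "loc.start", "loc.end"]
    if with_markers:
        cols.append("num.mark")
    cols.append("seg.mean")
    out = ["\t".join(cols)]
    for r in records:
        row = [r.sample_id, r.chrom, str(r.start), str(r.end)]
        if with_markers:
            row.append("" if r.n_markers is None else str(r.n_markers))
        row.append(_fmt_float(r.log2_ratio))
        out.append("\t".join(row))
    return "\n".join(out) + "\n"


def _fmt_float(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


def validate_segments(records: Sequence[SegRecord]) -> None:
    """Reject overlapping segments of one sample on one chromosome."""
    by_key: dict[tuple[str, str], list[SegRecord]] = {}
    for r in records:
        by_key.setdefault((r.sample_id, r.chrom), []).append(r)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda r: r.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:  # 1-based inclusive overlap
                raise ValidationError(
                    f"sample {sample} chrom {chrom}: segments "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}] overlap"
                )


# ---------------------------------------------------------------------------
# Gene tables (BED3+name) and gene lists


def read_gene_table(stream: str | io.TextIOBase) -> list[GeneRecord]:
    """Parse a BED-like gene table: chrom, start, end, symbol (0-based half-open)."""
    text = stream if isinstance(stream, str) else stream.read()
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise ParseError(f"expected ≥4 columns (chrom start end name), got {len(parts)}", lineno)
        chrom, s, e, symbol = parts[0], parts[1], parts[2], parts[3]
        try:
            gene = GeneRecord(symbol=symbol, chrom=chrom, start=int(s), end=int(e))
        except ValueError as err:
            raise ParseError(f"bad numeric field: {err}", lineno) from None
        except ValidationError as err:
            raise ValidationError(f"row at line {lineno}: {err}") from None
        if symbol in seen:
            raise ValidationError(f"line {lineno}: duplicate gene symbol {symbol!r}")
        seen.add(symbol)
        genes.append(gene)
    return genes


def write_gene_table(genes: Sequence[GeneRecord]) -> str:
    return "".join(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\n" for g in genes)


def read_gene_list(stream: str | io.TextIOBase) -> set[str]:
    """One symbol per line; ``#`` comments and blank lines ignored."""
    text = stream if isinstance(stream, str) else stream.read()
    out: set[str] = set()
    for line in text.splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            out.add(sym)
    return out


def write_gene_list(genes: Iterable[str]) -> str:
    return "".join(f"{g}\n" for g in sorted(genes))


# ---------------------------------------------------------------------------
# Sites-only VCF

_VCF_FIXED_HEADER = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"


def read_vcf_sites(stream: str | io.TextIOBase) -> VcfDocument:
    """Parse a sites-only VCF (no FORMAT/sample columns).

    Multiallelic ALT fields are split into one :class:`VcfSite` per allele,
    INFO copied verbatim to each.
    """
    text = stream if isinstance(stream, str) else stream.read()
    doc = VcfDocument()
    saw_columns = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("##"):
            doc.header.append(line)
            continue
        if line.startswith("#CHROM"):
            saw_columns = True
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 8:
            raise ParseError(f"expected ≥8 VCF columns, got {len(parts)}", lineno)
        chrom, pos_s, vid, ref, alt_field, qual, filt, info_s = parts[:8]
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(f"non-integer POS {pos_s!r}", lineno) from None
        info = _parse_info(info_s)
        for alt in alt_field.split(","):
            try:
                doc.sites.append(
                    VcfSite(
                        chrom=chrom,
                        pos=pos,
                        ref=ref.upper(),
                        alt=alt.upper(),
                        filter=filt,
                        info=info,
                        id=vid,
                        qual=qual,
                    )
                )
            except ValidationError as e:
                raise ValidationError(f"line {lineno}: {e}") from None
    if not saw_columns and not doc.header:
        raise ParseError("input has no VCF header")
    return doc


def _parse_info(info_s: str) -> tuple[tuple[str, str], ...]:
    if info_s in (".", ""):
        return ()
    pairs = []
    for item in info_s.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
        else:
            k, v = item, ""
        pairs.append((k, v))
    return tuple(pairs)


def _format_info(info: tuple[tuple[str, str], ...]) -> str:
    if not info:
        return "."
    return ";".join(k if v == "" else f"{k}={v}" for k, v in info)


def write_vcf_sites(
    doc: VcfDocument,
    *,
    contigs: ChromTable | None = None,
    info_declarations: Mapping[str, tuple[str, str]] | None = None,
) -> str:
    """Emit a sites-only VCFv4.2 document.

    ``info_declarations`` maps INFO key → (Type, Description) and produces
    ``##INFO`` header lines; ``contigs`` produces ``##contig`` lines.  Existing
    header lines from ``doc.header`` are kept (fileformat added if absent).
    """
    header = list(doc.header)
    if not any(h.startswith("##fileformat") for h in header):
        header.insert(0, "##fileformat=VCFv4.2")
    if contigs is not None:
        present = {re.match(r"##contig=<ID=([^,>]+)", h).group(1)
                   for h in header if h.startswith("##contig=")}
        for name, length in contigs:
            if name not in present:
                header.append(f"##contig=<ID={name},length={length}>")
    if info_declarations:
        declared = {m.group(1) for h in header
                    if (m := re.match(r"##INFO=<ID=([^,>]+)", h))}
        for key, (vtype, desc) in info_declarations.items():
            if key not in declared:
                header.append(
                    f'##INFO=<ID={key},Number=.,Type={vtype},Description="{desc}">'
                )
    lines = header + [_VCF_FIXED_HEADER]
    for s in doc.sites:
        lines.append(
            "\t".join(
                [s.chrom, str(s.pos), s.id, s.ref, s.alt, s.qual, s.filter,
                 _format_info(s.info)]
            )
        )
    return "\n".join(lines) + "\n"
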