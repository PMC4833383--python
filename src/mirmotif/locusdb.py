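"""Local miRNA locus database: annotation parsing, window extraction,
genomic-context classification, and coordinate-frame mapping.

A *locus* is one annotated pre-miRNA gene (UCSC-style 1-based inclusive
genomic coordinates, strand, optional transcription start site).  A
*window* is the extracted genomic sequence around it — by default 60 kb
upstream of the pre-miRNA 5' end and 5 kb downstream of its 3' end — stored
in transcript (5'→3') orientation so that "upstream/downstream" means the
same thing on both strands.  Within a window, positions are 0-based string
offsets; anchor-relative positions (vs TSS or pre-miRNA boundaries) are
signed base pairs, negative upstream.

The on-disk database is deliberately flat: ``loci.tsv`` (annotation +
context), ``windows.tsv`` (spans, anchor offsets, clipping) and
``windows.fa`` (one record per accession, transcript orientation).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import reverse_complement_str

__all__ = [
    "MirnaLocus",
    "LocusWindow",
    "RegionSpec",
    "LocusDB",
    "LocusDbError",
    "FormatError",
    "UnknownChromosomeError",
    "WindowError",
    "MissingAnchorError",
    "load_annotation",
    "load_gene_bed",
    "extract_window",
    "classify_context",
    "annotate_context",
    "offset_to_relative",
    "relative_to_offset",
]

DEFAULT_UP = 60_000
DEFAULT_DOWN = 5_000

ANNOTATION_COLUMNS = ("name", "accession", "chrom", "strand", "pre_start", "pre_end")
OPTIONAL_COLUMNS = ("tss", "cluster", "host_gene")

ANCHORS = ("tss", "pre5", "pre3")


class LocusDbError(ValueError):
    """Base class for locus-database errors."""


class FormatError(LocusDbError):
    """Malformed annotation or interval file."""


class UnknownChromosomeError(LocusDbError):
    """Locus references a contig absent from the genome."""


class WindowError(LocusDbError):
    """Requested window lies entirely outside its contig."""


class MissingAnchorError(LocusDbError):
    """An anchor (typically the TSS) is absent for this locus."""


@dataclass
class MirnaLocus:
    """One annotated miRNA gene."""

    name: str
    accession: str
    chrom: str
    strand: str
    pre_start: int  # 1-based inclusive
    pre_end: int  # 1-based inclusive
    tss: int | None = None
    cluster: str | None = None
    host_gene: str | None = None
    context: str = "unknown"  # intragenic / intergenic / unknown

    def __post_init__(self) -> None:
        if self.strand == "−":  # unicode minus in some exports
            self.strand = "-"
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"locus {self.accession}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.pre_start < 1:
            raise FormatError(f"locus {self.accession}: pre_start must be >= 1")
        if self.pre_end < self.pre_start:
            raise FormatError(f"locus {self.accession}: pre_end < pre_start")

    @property
    def pre_length(self) -> int:
        return self.pre_end - self.pre_start + 1


@dataclass
class LocusWindow:
    """Extracted window in transcript orientation with anchor offsets.

    ``seq`` always reads 5'→3' along the direction of transcription: for a
    minus-strand locus it is the reverse complement of the genomic slice.
    ``pre5_offset`` is the 0-based offset of the pre-miRNA's first (5')
    base; equal to the upstream span actually obtained (requested_up minus
    clipped_up).
    """

    locus: MirnaLocus
    seq: str
    chrom: str
    start: int  # genomic span, 1-based inclusive
    end: int
    pre5_offset: int
    pre3_offset: int
    tss_offset: int | None
    clipped_up: int
    clipped_down: int
    requested_up: int
    requested_down: int

    @property
    def genomic_span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return len(self.seq)

    def offset_to_genomic(self, offset: int) -> int:
        """Window offset -> 1-based genomic coordinate (strand-aware)."""
        self._check_offset(offset)
        if self.locus.strand == "+":
            return self.start + offset
        return self.end - offset

    def genomic_to_offset(self, pos: int) -> int:
        """1-based genomic coordinate -> window offset (strand-aware)."""
        if not self.start <= pos <= self.end:
            raise LocusDbError(
                f"genomic position {pos} outside window span "
                f"[{self.start}, {self.end}]"
            )
        if self.locus.strand == "+":
            return pos - self.start
        return self.end - pos

    def anchor_offset(self, anchor: str) -> int:
        a = anchor.lower()
        if a == "pre5":
            return self.pre5_offset
        if a == "pre3":
            return self.pre3_offset
        if a == "tss":
            if self.tss_offset is None:
                raise MissingAnchorError(
                    f"locus {self.locus.accession} has no TSS"
                )
            return self.tss_offset
        raise LocusDbError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")

    def _check_offset(self, offset: int) -> None:
        if not 0 <= offset < self.length:
            raise LocusDbError(
                f"offset {offset} outside window of length {self.length}"
            )


@dataclass(frozen=True)
class RegionSpec:
    """Anchor-relative region, e.g. (tss, -500, +500).

    Signed base pairs in transcript orientation: negative = upstream of the
    anchor, 0 = the anchor base itself.  Regions are clipped to the window
    before use.
    """

    anchor: str
    from_bp: int
    to_bp: int

    def __post_init__(self) -> None:
        if self.anchor.lower() not in ANCHORS:
            raise LocusDbError(
                f"unknown anchor {self.anchor!r}; expected one of {ANCHORS}"
            )
        if self.from_bp > self.to_bp:
            raise LocusDbError("region from_bp must be <= to_bp")


def offset_to_relative(window: LocusWindow, offset: int, anchor: str) -> int:
    """Signed anchor-relative position of a window offset (negative = upstream)."""
    window._check_offset(offset)
    return offset - window.anchor_offset(anchor)


def relative_to_offset(window: LocusWindow, rel: int, anchor: str) -> int:
    """Inverse of :func:`offset_to_relative` (result may lie outside the window)."""
    return window.anchor_offset(anchor) + rel


# ---------------------------------------------------------------------------
# annotation / interval input


def load_annotation(path: str | os.PathLike) -> list[MirnaLocus]:
    """Parse a locus annotation TSV (miRBase/miRStart-like).

    Mandatory header columns: name, accession, chrom, strand, pre_start,
    pre_end.  Optional: tss (may be empty), cluster, host_gene.  Row order
    is preserved; duplicate accessions are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation is missing mandatory column(s): {missing}")
    loci: list[MirnaLocus] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        acc = d["accession"].strip()
        if acc in seen:
            raise FormatError(f"row {i}: duplicate accession {acc!r}")
        seen.add(acc)
        try:
            pre_start = int(d["pre_start"])
            pre_end = int(d["pre_end"])
        except ValueError as e:
            raise FormatError(f"row {i}: non-integer pre-miRNA coordinate: {e}") from None
        tss_cell = d.get("tss", "").strip()
        try:
            locus = MirnaLocus(
                name=d["name"].strip(),
                accession=acc,
                chrom=d["chrom"].strip(),
                strand=d["strand"].strip(),
                pre_start=pre_start,
                pre_end=pre_end,
                tss=int(tss_cell) if tss_cell else None,
                cluster=d.get("cluster", "").strip() or None,
                host_gene=d.get("host_gene", "").strip() or None,
            )
        except FormatError as e:
            raise FormatError(f"row {i}: {e}") from None
        loci.append(locus)
    return loci


def load_gene_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """Load gene intervals from BED3+name.

    BED is 0-based half-open on disk; intervals are converted to 1-based
    inclusive on load to match the annotation convention.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, dtype=str, comment="#", keep_default_na=False
    )
    if df.shape[1] < 3:
        raise FormatError("gene BED needs at least 3 columns (chrom, start, end)")
    out: list[tuple[str, int, int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        vals = list(row)
        try:
            start0, end0 = int(vals[1]), int(vals[2])
        except ValueError:
            raise FormatError(f"gene BED row {i}: non-integer coordinates") from None
        name = str(vals[3]) if len(vals) > 3 and str(vals[3]) else f"gene_{i}"
        out.append((str(vals[0]), start0 + 1, end0, name))
    return out


def classify_context(
    locus: MirnaLocus, genes: Sequence[tuple[str, int, int, str]]
) -> tuple[str, str | None]:
    """(context, host_gene) for one locus against 1-based inclusive gene intervals.

    Intragenic iff the pre-miRNA interval overlaps any gene by >= 1 bp; the
    host is the first overlapping interval in input order.  An empty gene
    list yields intergenic.
    """
    for chrom, gstart, gend, gname in genes:
        if chrom == locus.chrom and locus.pre_start <= gend and gstart <= locus.pre_end:
            return "intragenic", gname
    return "intergenic", None


def annotate_context(
    loci: Sequence[MirnaLocus], genes: Sequence[tuple[str, int, int, str]]
) -> None:
    """Set context/host_gene in place for every locus."""
    for locus in loci:
        ctx, host = classify_context(locus, genes)
        locus.context = ctx
        if host is not None:
            locus.host_gene = host


# ---------------------------------------------------------------------------
# genome access and window extraction


def _open_genome(genome):
    """Accept a path (FASTA, opened with pyfaidx), a pyfaidx.Fasta, or a
    plain mapping of contig name -> sequence string."""
    if isinstance(genome, (str, os.PathLike)):
        from pyfaidx import Fasta

        return Fasta(str(genome))
    return genome


def _contig_length(genome, chrom: str) -> int:
    try:
        contig = genome[chrom]
    except KeyError:
        raise UnknownChromosomeError(f"unknown chromosome {chrom!r}") from None
    return len(contig)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of a contig, uppercased."""
    contig = genome[chrom]
    if isinstance(contig, str):
        return contig[start - 1 : end].upper()
    # pyfaidx FastaRecord supports 0-based python slicing
    return str(contig[start - 1 : end]).upper()


def _sanitize(seq: str) -> str:
    """Map any non-ACGT genome character (ambiguity codes, gaps) to N."""
    return "".join(c if c in "ACGTN" else "N" for c in seq)


def extract_window(
    genome,
    locus: MirnaLocus,
    up: int = DEFAULT_UP,
    down: int = DEFAULT_DOWN,
) -> LocusWindow:
    """Extract the strand-aware window around one locus.

    Plus strand: genomic span [pre_start - up, pre_end + down], sequence as
    sliced.  Minus strand: genomic span [pre_start - down, pre_end + up],
    sequence reverse complemented, so in both cases ``seq`` reads 5'→3'
    along transcription and ``pre5_offset`` marks the pre-miRNA 5' base.
    Spans are truncated at contig edges with the lost bases recorded in
    ``clipped_up`` / ``clipped_down``.
    """
    if up < 0 or down < 0:
        raise LocusDbError("window extents must be non-negative")
    genome = _open_genome(genome)
    clen = _contig_length(genome, locus.chrom)
    if locus.pre_end > clen:
        raise WindowError(
            f"locus {locus.accession}: pre-miRNA [{locus.pre_start}, "
            f"{locus.pre_end}] extends past contig end ({clen})"
        )
    if locus.strand == "+":
        raw_start, raw_end = locus.pre_start - up, locus.pre_end + down
    else:
        raw_start, raw_end = locus.pre_start - down, locus.pre_end + up
    if raw_end < 1 or raw_start > clen:
        raise WindowError(
            f"locus {locus.accession}: window [{raw_start}, {raw_end}] lies "
            f"entirely outside contig of length {clen}"
        )
    start = max(1, raw_start)
    end = min(clen, raw_end)
    seq = _sanitize(_fetch(genome, locus.chrom, start, end))
    if locus.strand == "+":
        clipped_up = start - raw_start
        clipped_down = raw_end - end
        pre5_offset = locus.pre_start - start
        tss_offset = None if locus.tss is None else locus.tss - start
    else:
        seq = reverse_complement_str(seq)
        clipped_up = raw_end - end
        clipped_down = start - raw_start
        pre5_offset = end - locus.pre_end
        tss_offset = None if locus.tss is None else end - locus.tss
    if tss_offset is not None and not 0 <= tss_offset < len(seq):
        tss_offset = None  # annotated TSS falls outside the extracted window
    return LocusWindow(
        locus=locus,
        seq=seq,
        chrom=locus.chrom,
        start=start,
        end=end,
        pre5_offset=pre5_offset,
        pre3_offset=pre5_offset + locus.pre_length - 1,
        tss_offset=tss_offset,
        clipped_up=clipped_up,
        clipped_down=clipped_down,
        requested_up=up,
        requested_down=down,
    )


# ---------------------------------------------------------------------------
# flat-file database


_WINDOW_INDEX_COLUMNS = (
    "accession",
    "chrom",
    "start",
    "end",
    "pre5_offset",
    "pre3_offset",
    "tss_offset",
    "clipped_up",
    "clipped_down",
    "requested_up",
    "requested_down",
)


@dataclass
class LocusDB:
    """The built database: loci in input order plus one window per accession."""

    loci: list[MirnaLocus]
    windows: dict[str, LocusWindow]
    up: int = DEFAULT_UP
    down: int = DEFAULT_DOWN

    @classmethod
    def build(
        cls,
        genome,
        loci: Sequence[MirnaLocus],
        up: int = DEFAULT_UP,
        down: int = DEFAULT_DOWN,
        genes: Sequence[tuple[str, int, int, str]] | None = None,
    ) -> "LocusDB":
        loci = list(loci)
        if genes is not None:
            annotate_context(loci, genes)
        genome = _open_genome(genome)
        windows = {
            locus.accession: extract_window(genome, locus, up, down) for locus in loci
        }
        return cls(loci=loci, windows=windows, up=up, down=down)

    def get(self, accession: str) -> LocusWindow:
        try:
            return self.windows[accession]
        except KeyError:
            raise LocusDbError(f"unknown accession {accession!r}") from None

    def save(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for locus in self.loci:
            rows.append(
                {
                    "name": locus.name,
                    "accession": locus.accession,
                    "chrom": locus.chrom,
                    "strand": locus.strand,
                    "pre_start": locus.pre_start,
                    "pre_end": locus.pre_end,
                    "tss": "" if locus.tss is None else locus.tss,
                    "cluster": locus.cluster or "",
                    "host_gene": locus.host_gene or "",
                    "context": locus.context,
                }
            )
        pd.DataFrame(rows).to_csv(out / "loci.tsv", sep="\t", index=False)
        idx_rows = []
        for locus in self.loci:
            w = self.windows[locus.accession]
            idx_rows.append(
                {
                    "accession": locus.accession,
                    "chrom": w.chrom,
                    "start": w.start,
                    "end": w.end,
                    "pre5_offset": w.pre5_offset,
                    "pre3_offset": w.pre3_offset,
                    "tss_offset": "" if w.tss_offset is None else w.tss_offset,
                    "clipped_up": w.clipped_up,
                    "clipped_down": w.clipped_down,
                    "requested_up": w.requested_up,
                    "requested_down": w.requested_down,
                }
            )
        pd.DataFrame(idx_rows, columns=_WINDOW_INDEX_COLUMNS).to_csv(
            out / "windows.tsv", sep="\t", index=False
        )
        records = [
            SeqRecord(Seq(self.windows[l.accession].seq), id=l.accession, description="")
            for l in self.loci
        ]
        SeqIO.write(records, out / "windows.fa", "fasta")

    @classmethod
    def load(cls, db_dir: str | os.PathLike) -> "LocusDB":
        db = Path(db_dir)
        loci = load_annotation(db / "loci.tsv")
        # context column round-trips through the same TSV
        ctx = pd.read_csv(db / "loci.tsv", sep="\t", dtype=str, keep_default_na=False)
        if "context" in ctx.columns:
            for locus, c in zip(loci, ctx["context"]):
                locus.context = c or "unknown"
        idx = pd.read_csv(db / "windows.tsv", sep="\t", dtype=str, keep_default_na=False)
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(db / "windows.fa"), "fasta")
        }
        by_acc = {l.accession: l for l in loci}
        windows: dict[str, LocusWindow] = {}
        up = down = None
        for row in idx.itertuples(index=False):
            d = row._asdict()
            acc = d["accession"]
            if acc not in by_acc:
                raise FormatError(f"windows.tsv references unknown accession {acc!r}")
            if acc not in seqs:
                raise FormatError(f"windows.fa lacks a record for {acc!r}")
            w = LocusWindow(
                locus=by_acc[acc],
                seq=seqs[acc],
                chrom=d["chrom"],
                start=int(d["start"]),
                end=int(d["end"]),
                pre5_offset=int(d["pre5_offset"]),
                pre3_offset=int(d["pre3_offset"]),
                tss_offset=int(d["tss_offset"]) if d["tss_offset"] else None,
                clipped_up=int(d["clipped_up"]),
                clipped_down=int(d["clipped_down"]),
                requested_up=int(d["requested_up"]),
                requested_down=int(d["requested_down"]),
            )
            windows[acc] = w
            up, down = w.requested_up, w.requested_down
        return cls(
            loci=loci,
            windows=windows,
            up=up if up is not None else DEFAULT_UP,
            down=down if down is not None else DEFAULT_DOWN,
        )
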