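"""Aggregation and export of scan results.

Per-locus summary tables, the frequency distribution of per-locus hit
counts, positional (anchor-relative) distributions, and round-trip-safe
TSV/CSV export.  Histograms use half-open bins [lo, hi) and always
conserve totals: every aggregated item lands in exactly one bin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, is_dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scan import ScanHit, ScanResult

__all__ = [
    "SummaryRow",
    "Histogram",
    "summarize",
    "hit_count_frequency",
    "hit_count_extremes",
    "position_distribution",
    "hits_to_dataframe",
    "summary_to_dataframe",
    "histogram_to_dataframe",
    "export",
    "read_table",
]

HIT_COLUMNS = (
    "accession",
    "name",
    "offset",
    "strand",
    "matched",
    "rel_pre5",
    "rel_tss",
    "flank_identity",
)


@dataclass
class SummaryRow:
    """One locus in the results overview table."""

    name: str
    accession: str
    n_hits: int
    positions: tuple[int, ...]  # anchor-relative, signed bp
    matrix_length: int
    elapsed_ms: int


@dataclass(frozen=True)
class Histogram:
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    what: str  # per_locus_hit_count | hit_position

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if any(c < 0 for c in self.counts):
            raise ValueError("histogram counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def _hit_rel(hit: ScanHit, anchor: str) -> int | None:
    a = anchor.lower()
    if a == "pre5":
        return hit.rel_pre5
    if a == "tss":
        return hit.rel_tss
    if a == "offset":
        return hit.offset
    raise ValueError(f"unknown summary anchor {anchor!r}")


def summarize(
    results: Sequence[ScanResult],
    names: Mapping[str, str] | None = None,
    anchor: str = "pre5",
) -> list[SummaryRow]:
    """One row per scan result, in input order.

    ``positions`` are the hits' signed distances from the chosen anchor
    ('pre5', 'tss', or raw window 'offset').  ``names`` maps accession to a
    display name; missing names fall back to the accession.
    """
    rows: list[SummaryRow] = []
    for r in results:
        positions = []
        for h in r.hits:
            rel = _hit_rel(h, anchor)
            if rel is None:
                raise ValueError(
                    f"hit in {r.accession} lacks anchor {anchor!r} (no TSS?)"
                )
            positions.append(rel)
        rows.append(
            SummaryRow(
                name=(names or {}).get(r.accession, r.accession),
                accession=r.accession,
                n_hits=r.n_hits,
                positions=tuple(positions),
                matrix_length=r.matrix_length,
                elapsed_ms=r.elapsed_ms,
            )
        )
    return rows


def hit_count_frequency(
    results: Sequence[ScanResult], bin_width: int = 10
) -> Histogram:
    """Distribution of per-locus hit counts across loci (half-open bins from 0)."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts = [r.n_hits for r in results]
    top = max(counts, default=0)
    edges = np.arange(0, (top // bin_width + 1) * bin_width + 1, bin_width)
    hist, _ = np.histogram(counts, bins=edges)
    return Histogram(tuple(float(e) for e in edges), tuple(int(c) for c in hist), "per_locus_hit_count")


def hit_count_extremes(
    results: Sequence[ScanResult],
) -> tuple[int, list[str], int, list[str]]:
    """(min_count, loci at min, max_count, loci at max) in one pass."""
    if not results:
        raise ValueError("no results")
    lo = min(r.n_hits for r in results)
    hi = max(r.n_hits for r in results)
    return (
        lo,
        [r.accession for r in results if r.n_hits == lo],
        hi,
        [r.accession for r in results if r.n_hits == hi],
    )


def position_distribution(
    results: Sequence[ScanResult], anchor: str = "pre5", bin_width: int = 100
) -> Histogram:
    """Histogram of anchor-relative hit positions, bins aligned to bin_width."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    rels: list[int] = []
    for r in results:
        for h in r.hits:
            rel = _hit_rel(h, anchor)
            if rel is None:
                raise ValueError(
                    f"hit in {r.accession} lacks anchor {anchor!r} (no TSS?)"
                )
            rels.append(rel)
    if not rels:
        return Histogram((0.0, float(bin_width)), (0,), "hit_position")
    lo = (min(rels) // bin_width) * bin_width
    hi = (max(rels) // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + 1, bin_width)
    hist, _ = np.histogram(rels, bins=edges)
    return Histogram(tuple(float(e) for e in edges), tuple(int(c) for c in hist), "hit_position")


# ---------------------------------------------------------------------------
# tabular views and export


def hits_to_dataframe(
    results: Sequence[ScanResult], names: Mapping[str, str] | None = None
) -> pd.DataFrame:
    rows = []
    for r in results:
        for h in r.hits:
            rows.append(
                {
                    "accession": r.accession,
                    "name": (names or {}).get(r.accession, r.accession),
                    "offset": h.offset,
                    "strand": h.strand,
                    "matched": h.matched,
                    "rel_pre5": h.rel_pre5,
                    "rel_tss": "" if h.rel_tss is None else h.rel_tss,
                    "flank_identity": round(h.flank_identity, 6),
                }
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def summary_to_dataframe(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "accession": r.accession,
                "n_hits": r.n_hits,
                "positions": ",".join(str(p) for p in r.positions),
                "matrix_length": r.matrix_length,
                "elapsed_ms": r.elapsed_ms,
            }
            for r in rows
        ],
        columns=("name", "accession", "n_hits", "positions", "matrix_length", "elapsed_ms"),
    )


def histogram_to_dataframe(h: Histogram) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_lo": [h.bin_edges[i] for i in range(len(h.counts))],
            "bin_hi": [h.bin_edges[i + 1] for i in range(len(h.counts))],
            "count": list(h.counts),
        }
    )


def _as_dataframe(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    if isinstance(table, Histogram):
        return histogram_to_dataframe(table)
    seq = list(table)
    if seq and isinstance(seq[0], SummaryRow):
        return summary_to_dataframe(seq)
    if seq and is_dataclass(seq[0]):
        return pd.DataFrame([asdict(r) for r in seq])
    return pd.DataFrame(seq)


def export(table, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write a table as TSV or CSV, atomically (temp file + rename).

    TSV fields may not contain tabs or newlines (validated; TSV has no
    quoting).  CSV quotes as needed, so reading the file back reproduces
    the table exactly in both dialects.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown export format {format!r}")
    df = _as_dataframe(table)
    if format == "tsv":
        bad = df.select_dtypes(include="object").apply(
            lambda col: col.astype(str).str.contains("\t|\n|\r", regex=True).any()
        )
        if bool(bad.any()):
            cols = list(bad[bad].index)
            raise ValueError(f"tabs/newlines not allowed inside TSV fields: {cols}")
    tmp = path.with_name(path.name + ".tmp")
    df.to_csv(tmp, sep="\t" if format == "tsv" else ",", index=False)
    os.replace(tmp, path)
    return path


def read_table(path: str | os.PathLike, format: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`export` (all cells as strings)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    return pd.read_csv(
        path, sep="\t" if format == "tsv" else ",", dtype=str, keep_default_na=False
    )
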