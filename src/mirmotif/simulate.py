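"""Synthetic genomes and locus sets with planted matrix occurrences.

The generator builds desk-scale stand-ins for a real miRNA locus database:
one contig per locus, loci on both strands, a configurable fraction
without an annotated TSS, and an i.i.d. background at a chosen GC content
from which every occurrence of the matrix core (in either orientation) has
been rejection-resampled away.  Planted occurrences are therefore the
*only* possible hits, so scans can be checked against exact ground truth
(precision = recall = 1).

Everything is deterministic under a seed.  Defaults are scaled down
(600 bp upstream / 50 bp downstream) so an end-to-end
simulate → build → scan → report cycle stays fast; full-size windows
(60 kb / 5 kb) are a parameter away.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locusdb import MirnaLocus
from .matrix import reverse_complement_str

__all__ = [
    "PlantedSite",
    "SyntheticTruth",
    "SimulationError",
    "generate_background",
    "plant",
    "generate_locus_set",
    "DEFAULT_PLANT_STRINGS",
]

#: Strings that satisfy the default CCAAT policy (5/6 or 6/6 flank identity)
#: and contain exactly one core occurrence each; used for random planting.
DEFAULT_PLANT_STRINGS = ("agcccaatcag", "gggccaatcgg", "cggccaatgag")

_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    """Constraint could not be satisfied (e.g. impossible GC/forbidden-core combo)."""


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted occurrence."""

    offset: int  # 0-based window offset of the first base
    strand: str
    string: str  # the motif string as planted (matrix orientation)
    rel_pre5: int | None = None
    rel_tss: int | None = None


@dataclass
class SyntheticTruth:
    accession: str
    planted: list[PlantedSite]


def _find_all(text: str, sub: str) -> list[int]:
    out = []
    i = text.find(sub)
    while i != -1:
        out.append(i)
        i = text.find(sub, i + 1)
    return out


def _forbidden_set(forbidden_cores: Sequence[str]) -> set[str]:
    out: set[str] = set()
    for c in forbidden_cores:
        cu = c.upper()
        out.add(cu)
        out.add(reverse_complement_str(cu))
    return out


def generate_background(
    length: int,
    gc: float = 0.41,
    seed: int | None = None,
    forbidden_cores: Sequence[str] = ("CCAAT",),
    rng: np.random.Generator | None = None,
    max_iter: int = 500,
) -> str:
    """i.i.d. background at the given GC, free of the forbidden cores.

    Bases are drawn independently with P(G) = P(C) = gc/2.  Any occurrence
    of a forbidden core or its reverse complement is resampled in place and
    the string rescanned, up to ``max_iter`` sweeps; an unsatisfiable
    constraint (e.g. gc = 1 with a G/C-only core) raises
    :class:`SimulationError`.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    forb = _forbidden_set(forbidden_cores)
    for _ in range(max_iter):
        s = "".join(arr)
        spans: set[int] = set()
        for f in forb:
            for i in _find_all(s, f):
                spans.update(range(i, i + len(f)))
        if not spans:
            return s
        idx = np.array(sorted(spans))
        arr[idx] = rng.choice(_BASES, size=len(idx), p=p)
    raise SimulationError(
        f"could not produce a core-free background of length {length} at "
        f"gc={gc} within {max_iter} resampling sweeps"
    )


def plant(
    background: str, items: Sequence[tuple[int, str, str]]
) -> tuple[str, list[PlantedSite]]:
    """Write motif strings into a background sequence.

    ``items`` are (position, strand, string) with positions 0-based in the
    background; for strand '-', the reverse complement of the string is
    written so that a both-strand scan reports the site on '-' at the same
    first-base offset.  Items must be in bounds and mutually non-overlapping.
    """
    seq = list(background)
    occupied: list[tuple[int, int]] = []
    truth: list[PlantedSite] = []
    for pos, strand, string in items:
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        s = string.upper()
        if pos < 0 or pos + len(s) > len(background):
            raise ValueError(
                f"planted item at {pos} (length {len(s)}) out of bounds for "
                f"background of length {len(background)}"
            )
        for a, b in occupied:
            if pos < b and a < pos + len(s):
                raise ValueError(f"planted items overlap at position {pos}")
        occupied.append((pos, pos + len(s)))
        written = s if strand == "+" else reverse_complement_str(s)
        seq[pos : pos + len(s)] = written
        truth.append(PlantedSite(offset=pos, strand=strand, string=s))
    return "".join(seq), truth


def _core_positions(seq: str, core: str = "CCAAT") -> set[int]:
    rc = reverse_complement_str(core)
    return set(_find_all(seq, core)) | set(_find_all(seq, rc))


def generate_locus_set(
    n_loci: int = 10,
    seed: int = 0,
    up: int = 600,
    down: int = 50,
    gc: float = 0.41,
    pre_length: int = 80,
    tss_fraction: float = 0.79,
    max_sites: int = 3,
    plant_strings: Sequence[str] = DEFAULT_PLANT_STRINGS,
    planted_sites: Sequence[tuple[str, int, str, str]] | None = None,
    core: str = "CCAAT",
    out_dir: str | os.PathLike | None = None,
) -> tuple[dict[str, str], list[MirnaLocus], list[SyntheticTruth]]:
    """Generate a synthetic locus set with exact planted ground truth.

    Each locus occupies its own contig sized exactly to the requested
    window (``up`` + pre-miRNA + ``down``), with strand assigned at random
    and a TSS present with probability ``tss_fraction`` (placed upstream of
    the pre-miRNA 5' end).  Unless ``planted_sites`` pins the layout, each
    locus receives 0..``max_sites`` non-overlapping occurrences drawn from
    ``plant_strings`` at uniform window positions and random strands.

    ``planted_sites`` entries are (anchor, rel_pos, strand, string) applied
    to *every* locus, anchor in {pre5, pre3, tss} (tss_fraction is forced
    to 1 when a tss anchor is used); rel_pos is the signed position of the
    site's first base.

    After planting, the window is checked to contain core occurrences at
    exactly the planted positions (junction artefacts are re-rolled), so
    recovered hits equal planted sites exactly.

    Returns (genome mapping contig->sequence, loci, truths); when
    ``out_dir`` is given, also writes genome.fa, loci.tsv and truth.tsv.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if planted_sites and any(a.lower() == "tss" for a, *_ in planted_sites):
        tss_fraction = 1.0
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    loci: list[MirnaLocus] = []
    truths: list[SyntheticTruth] = []
    wlen = up + pre_length + down
    for i in range(n_loci):
        accession = f"MISYN{i:04d}"
        name = f"mir-s{i}"
        chrom = f"ctg{i}"
        strand = "+" if rng.random() < 0.5 else "-"
        has_tss = rng.random() < tss_fraction
        # TSS upstream of the pre-miRNA 5' end, within the window
        lo_rel = -min(up - 1, 450)
        hi_rel = -80 if up > 80 else lo_rel
        lo_off, hi_off = up + lo_rel, up + hi_rel
        if planted_sites:
            # keep every TSS-anchored planted site inside the window
            tss_rels = [
                (rel, len(s))
                for a, rel, _st, s in planted_sites
                if a.lower() == "tss"
            ]
            if tss_rels:
                need_lo = max(0, -min(rel for rel, _ in tss_rels))
                need_hi = wlen - max(rel + ln for rel, ln in tss_rels)
                lo_off, hi_off = max(lo_off, need_lo), min(hi_off, need_hi)
                if lo_off > hi_off:
                    lo_off, hi_off = need_lo, need_hi
                if lo_off > hi_off:
                    raise SimulationError(
                        "planted TSS-anchored sites cannot fit in the window"
                    )
        tss_off = int(rng.integers(lo_off, hi_off + 1)) if has_tss else None
        for attempt in range(60):
            background = generate_background(
                wlen, gc=gc, forbidden_cores=(core,), rng=rng
            )
            if planted_sites is not None:
                items = []
                for anchor, rel, s_strand, string in planted_sites:
                    a = anchor.lower()
                    if a == "pre5":
                        base = up
                    elif a == "pre3":
                        base = up + pre_length - 1
                    elif a == "tss":
                        base = tss_off if tss_off is not None else up
                    else:
                        raise ValueError(f"unknown anchor {anchor!r}")
                    items.append((base + rel, s_strand, string))
            else:
                n_sites = int(rng.integers(0, max_sites + 1))
                items = []
                taken: list[tuple[int, int]] = []
                for _ in range(n_sites):
                    string = str(rng.choice(list(plant_strings)))
                    s_strand = "+" if rng.random() < 0.5 else "-"
                    for _try in range(100):
                        pos = int(rng.integers(0, wlen - len(string) + 1))
                        if all(
                            pos >= b or pos + len(string) <= a for a, b in taken
                        ):
                            taken.append((pos, pos + len(string)))
                            items.append((pos, s_strand, string))
                            break
            try:
                window_seq, truth_sites = plant(background, items)
            except ValueError:
                continue  # explicit layout clashed; re-roll background/positions
            expected_cores = set()
            for site in truth_sites:
                w = site.string if site.strand == "+" else reverse_complement_str(site.string)
                expected_cores.update(
                    site.offset + j for j in _core_positions(w, core)
                )
            if _core_positions(window_seq, core) == expected_cores:
                break
        else:
            raise SimulationError(
                f"locus {accession}: could not realise a junction-clean planted "
                "window in 60 attempts"
            )
        # lay the window onto its contig
        if strand == "+":
            contig = window_seq
            pre_start, pre_end = up + 1, up + pre_length
            tss = None if tss_off is None else tss_off + 1
        else:
            contig = reverse_complement_str(window_seq)
            pre_start, pre_end = down + 1, down + pre_length
            tss = None if tss_off is None else wlen - tss_off
        genome[chrom] = contig
        loci.append(
            MirnaLocus(
                name=name,
                accession=accession,
                chrom=chrom,
                strand=strand,
                pre_start=pre_start,
                pre_end=pre_end,
                tss=tss,
            )
        )
        truths.append(
            SyntheticTruth(
                accession=accession,
                planted=[
                    PlantedSite(
                        offset=s.offset,
                        strand=s.strand,
                        string=s.string,
                        rel_pre5=s.offset - up,
                        rel_tss=None if tss_off is None else s.offset - tss_off,
                    )
                    for s in truth_sites
                ],
            )
        )
    if out_dir is not None:
        _write_locus_set(Path(out_dir), genome, loci, truths)
    return genome, loci, truths


def _write_locus_set(
    out: Path,
    genome: dict[str, str],
    loci: list[MirnaLocus],
    truths: list[SyntheticTruth],
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, out / "genome.fa", "fasta")
    pd.DataFrame(
        [
            {
                "name": l.name,
                "accession": l.accession,
                "chrom": l.chrom,
                "strand": l.strand,
                "pre_start": l.pre_start,
                "pre_end": l.pre_end,
                "tss": "" if l.tss is None else l.tss,
                "cluster": "",
                "host_gene": "",
            }
            for l in loci
        ]
    ).to_csv(out / "loci.tsv", sep="\t", index=False)
    rows = []
    for t in truths:
        for s in t.planted:
            rows.append(
                {
                    "accession": t.accession,
                    "offset": s.offset,
                    "strand": s.strand,
                    "string": s.string,
                    "rel_pre5": s.rel_pre5,
                    "rel_tss": "" if s.rel_tss is None else s.rel_tss,
                }
            )
    pd.DataFrame(
        rows, columns=("accession", "offset", "strand", "string", "rel_pre5", "rel_tss")
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
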