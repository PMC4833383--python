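"""Curated worked-example data for the CCAAT/NF-Y survey.

Three small datasets transcribed from the published in-silico + in-vivo
survey this package reimplements, used as worked examples and test
oracles:

* a literature catalogue of mature miRNAs reported up-regulated in
  colorectal cancer, one entry per (miRNA group, citation set) as printed;
* CCAAT matrix calls on the minimal promoters (-500..+500 bp around the
  TSS) of four in-vivo validated miRNA clusters, with signed distances of
  each call from the TSS;
* CCAAT matrix calls in the 5 kb downstream of the 3' end of six
  pre-miRNAs, with distances from the pre-miRNA 3' end.

Strings are kept exactly as printed, including the capitalised initials of
two downstream calls; note that two of the promoter strings
(``ataattggttt`` and ``atcccaatcat``) score only 4/6 flank identity
against D/V/V/C/C/A/A/T/S/N/V and therefore fail the default >82 % policy
even though they appear in the published call set (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MatrixCall",
    "MatrixCallRow",
    "PackagedTables",
    "UPREGULATED_MIRNAS",
    "PROMOTER_MATRICES",
    "DOWNSTREAM_MATRICES",
    "load_packaged_tables",
    "distinct_upregulated_names",
]


@dataclass(frozen=True)
class MatrixCall:
    string: str
    distance: int  # signed bp from the row's anchor (TSS or pre-miRNA 3')


@dataclass(frozen=True)
class MatrixCallRow:
    locus: str
    reported_count: int  # the printed per-row "n of CCAAT matrices"
    calls: tuple[MatrixCall, ...]


#: (miRNA names, citation keys), one tuple per printed catalogue row.
UPREGULATED_MIRNAS: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = (
    (("miRNA-29b", "miRNA-30a-5p", "miRNA-140-5p", "miRNA-516-3p"), ("ref036",)),
    (("miRNA-99a",), ("ref036",)),
    (("miRNA-15a", "miRNA-27a", "miRNA-98", "miRNA-103", "miRNA-105"), ("ref037",)),
    (("miRNA-107", "miRNA-122a", "miRNA-128a", "miRNA-134", "miRNA-142-5p"), ("ref037",)),
    (("miRNA-142-3p", "miRNA-1", "miRNA-147", "miRNA-148a", "miRNA-151"), ("ref037",)),
    (("miRNA-181c", "miRNA-186", "miRNA-194", "miRNA-197", "miRNA-213"), ("ref037",)),
    (("miRNA-215", "miRNA-330", "miRNA-338", "miRNA-339", "miRNA-370"), ("ref037",)),
    (("miRNA-373", "miRNA-Let-7g"), ("ref037",)),
    (("miRNA-30e-3p", "miRNA-181d", "miRNA-220", "miRNA-302a", "miRNA-302b"), ("ref038",)),
    (("miRNA-493-3p", "miRNA-550", "miRNA-570"), ("ref038",)),
    (("miRNA-494", "miRNA-500", "miRNA-513a-5p", "miRNA-513b", "miRNA-513c"), ("ref039",)),
    (("miRNA-892b",), ("ref039",)),
    (("miRNA-337", "miRNA-483-3p", "miRNA-520b", "miRNA-520g"), ("ref040",)),
    (("miRNA-550a-3p", "miRNA-629-3p", "miRNA-663", "miRNA-135a-3p"), ("ref040",)),
    (("miRNA-32", "miRNA-33", "miRNA-188", "miRNA-503", "miRNA-542-5p"), ("ref041",)),
    (("miRNA-552", "miRNA-584", "miRNA-625"), ("ref041",)),
    (("miRNA-451", "miRNA-675"), ("ref042",)),
    (("miRNA-424", "miRNA-301b"), ("ref043",)),
    (("miRNA-335",), ("ref044",)),
    (("miRNA-10a", "miRNA-25", "miRNA-181a", "miRNA-200a", "miRNA-200b"), ("ref036", "ref037")),
    (("miRNA-34a", "miRNA-141", "miRNA-320"), ("ref036", "ref037")),
    (("miRNA-93", "miRNA-298"), ("ref036", "ref040")),
    (("miRNA-30a-3p",), ("ref036", "ref044")),
    (("miRNA-106b",), ("ref036", "ref043")),
    (("miRNA-20",), ("ref046", "ref037")),
    (("miRNA-15b", "miRNA-181b"), ("ref036", "ref037", "ref044")),
    (("miRNA-210", "miRNA-221", "miRNA-154-3p"), ("ref037", "ref040")),
    (("miRNA-182-3p",), ("ref037", "ref041")),
    (("miRNA-374",), ("ref037", "ref043")),
    (("miRNA-191", "miRNA-200c"), ("ref037", "ref044")),
    (("miRNA-92a-5p",), ("ref038", "ref040")),
    (("miRNA-196b",), ("ref038", "ref043")),
    (("miRNA-19b",), ("ref040", "ref042")),
    (("miRNA-203", "miRNA-130b", "miRNA-106"), ("ref036", "ref037", "ref040")),
    (("miRNA-135a",), ("ref037", "ref042", "ref045")),
    (("miRNA-17-3p",), ("ref037", "ref040", "ref041")),
    (("miRNA-301", "miRNA-92a-3p"), ("ref037", "ref040", "ref042")),
    (("miRNA-7",), ("ref038", "ref039", "ref040")),
    (("miRNA-18b",), ("ref038", "ref040", "ref043")),
    (("miRNA-31",), ("ref036", "ref037", "ref038", "ref041")),
    (("miRNA-29a",), ("ref036", "ref037", "ref041", "ref042")),
    (("miRNA-95",), ("ref036", "ref037", "ref038", "ref040")),
    (("miRNA-17-5p",), ("ref036", "ref037", "ref038", "ref042")),
    (("miRNA-96",), ("ref036", "ref037", "ref040", "ref041")),
    (("miRNA-19a",), ("ref036", "ref007", "ref040", "ref043", "ref046")),
    (("miRNA-224",), ("ref036", "ref037", "ref038", "ref041", "ref043")),
    (("miRNA-183", "miRNA-182-5p"), ("ref036", "ref037", "ref038", "ref040", "ref041")),
    (("miRNA-21",), ("ref036", "ref037", "ref039", "ref040", "ref042")),
    (("miRNA-20a",), ("ref036", "ref037", "ref040", "ref042", "ref043")),
    (("miRNA-18a",), ("ref036", "ref038", "ref040", "ref042", "ref043")),
    (("miRNA-135b",), ("ref037", "ref040", "ref041", "ref043", "ref045")),
)

#: Minimal-promoter (-500..+500 bp around the TSS) CCAAT matrix calls.
PROMOTER_MATRICES: tuple[MatrixCallRow, ...] = (
    MatrixCallRow(
        "mir-181a2/181b2",
        2,
        (MatrixCall("ataattggttt", -401), MatrixCall("agcccaatcag", -131)),
    ),
    MatrixCallRow(
        "mir-21",
        3,
        (
            MatrixCall("tatccaatccc", 218),
            MatrixCall("atcccaatcat", -416),
            MatrixCall("ttaattggttc", -102),
        ),
    ),
    MatrixCallRow(
        "mir-301b/130b",
        3,
        (
            MatrixCall("cggccaatgag", -55),
            MatrixCall("gagattggagc", -254),
            MatrixCall("gggccaatcgg", -140),
        ),
    ),
    MatrixCallRow(
        "mir-17/18a/20a/19b1/92a1",
        1,
        (MatrixCall("gtgattggcgg", -104),),
    ),
)

#: CCAAT matrix calls in the 5 kb downstream of six pre-miRNA 3' ends.
DOWNSTREAM_MATRICES: tuple[MatrixCallRow, ...] = (
    MatrixCallRow(
        "pre-miRNA-27a",
        6,
        (
            MatrixCall("aagccaatccc", 2698),
            MatrixCall("ctcccaatgcg", 1657),
            MatrixCall("aacattggtgt", 3190),
            MatrixCall("ttgattggcct", 1981),
            MatrixCall("ccgattggccc", 2663),
            MatrixCall("gagccaatggt", 4899),
        ),
    ),
    MatrixCallRow(
        "pre-miRNA-34a",
        6,
        (
            MatrixCall("tcaccaattgc", 793),
            MatrixCall("gtgccaatatc", 3219),
            MatrixCall("cccattggtgt", 963),
            MatrixCall("cagccaatgcc", 3694),
            MatrixCall("gggccaatga", 1709),
            MatrixCall("ggaattggacc", 1321),
        ),
    ),
    MatrixCallRow(
        "pre-miRNA-183",
        4,
        (
            MatrixCall("tgtccaatggt", 2470),
            MatrixCall("aggccaatgtt", 769),
            MatrixCall("gtgccaatatg", 197),
            MatrixCall("cccccaataaa", 1565),
        ),
    ),
    MatrixCallRow(
        "pre-miRNA-31",
        9,
        (
            MatrixCall("tgtccaataac", 2105),
            MatrixCall("gtcattggatc", 669),
            MatrixCall("tccattggctc", 2888),
            MatrixCall("cacattggcct", 163),
            MatrixCall("tttattgggaa", 705),
            MatrixCall("aacattggtgc", 352),
            MatrixCall("gttattggctt", 3706),
            MatrixCall("tcaattggcca", 1714),
            MatrixCall("taaattggggg", 3307),
        ),
    ),
    MatrixCallRow(
        "pre-miRNA-191",
        3,
        (
            MatrixCall("Aggattggcga", 157),
            MatrixCall("Tttattgggca", 1223),
            MatrixCall("ggcattggccc", 3152),
        ),
    ),
    MatrixCallRow(
        "pre-mir-148a",
        5,
        (
            MatrixCall("tgaccaattcc", 131),
            MatrixCall("aaaattggcgc", 4593),
            MatrixCall("tgcccaattgg", 3615),
            MatrixCall("gagattggcag", 4217),
            MatrixCall("ccaattggtta", 3618),
        ),
    ),
)


@dataclass(frozen=True)
class PackagedTables:
    upregulated: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    promoter: tuple[MatrixCallRow, ...]
    downstream: tuple[MatrixCallRow, ...]


def load_packaged_tables() -> PackagedTables:
    return PackagedTables(
        upregulated=UPREGULATED_MIRNAS,
        promoter=PROMOTER_MATRICES,
        downstream=DOWNSTREAM_MATRICES,
    )


def distinct_upregulated_names() -> list[str]:
    """Deduplicated, sorted view of the up-regulated miRNA catalogue."""
    names: set[str] = set()
    for group, _refs in UPREGULATED_MIRNAS:
        names.update(group)
    return sorted(names)


def promoter_row(locus: str) -> MatrixCallRow:
    for row in PROMOTER_MATRICES:
        if row.locus == locus:
            return row
    raise KeyError(locus)


def downstream_row(locus: str) -> MatrixCallRow:
    for row in DOWNSTREAM_MATRICES:
        if row.locus == locus:
            return row
    raise KeyError(locus)
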