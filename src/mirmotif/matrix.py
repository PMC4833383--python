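"""Degenerate IUPAC consensus matrices and mismatch policies.

The central object is :class:`ConsensusMatrix`: an ordered list of
allowed-nucleotide sets over {A, C, G, T}, one per motif position, plus a
boolean *core* mask marking invariant positions at which no mismatch is
ever tolerated.  The motivating example is the NF-Y binding consensus
``D/V/V/C/C/A/A/T/S/N/V`` (D = A/G/T, V = A/C/G, S = C/G, N = any): its
CCAAT pentanucleotide core must match exactly, while the six degenerate
flanking positions are scored by identity — a candidate site is kept when
strictly more than 82 % of the flanks match.

Matching is set-membership only; there is no log-odds (PWM) scoring.  An
``N`` in the scanned text matches nothing by default, so assembly gaps
cannot produce phantom hits (see :class:`MatchPolicy.n_matches_n`).
Matching is case-insensitive throughout (soft-masked genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "IUPAC_SETS",
    "MIN_LENGTH",
    "MAX_LENGTH",
    "ConsensusMatrix",
    "MatchPolicy",
    "MatrixError",
    "ExpansionCapError",
    "parse_consensus",
    "ccaat_matrix",
    "default_policy",
    "identity_fraction",
    "classify",
    "expand_exact",
    "reverse_complement_str",
]

#: Inclusive bounds on matrix length accepted by :func:`parse_consensus`.
MIN_LENGTH = 4
MAX_LENGTH = 30

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_ACGT = frozenset("ACGT")


class MatrixError(ValueError):
    """Invalid consensus specification or mismatching input length."""


class ExpansionCapError(MatrixError):
    """Raised when :func:`expand_exact` would exceed the requested cap."""

    def __init__(self, count: int, cap: int):
        self.count = count
        self.cap = cap
        super().__init__(
            f"exact expansion exceeds cap: more than {count - 1} k-mers "
            f"(cap {cap})"
        )


def reverse_complement_str(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T/N string (case preserved as upper)."""
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


@dataclass(frozen=True)
class ConsensusMatrix:
    """Ordered per-position allowed-nucleotide sets with an invariant core.

    Parameters
    ----------
    positions
        One ``frozenset`` of allowed bases (subset of {A,C,G,T}) per motif
        position, 5'→3'.
    core_mask
        ``True`` at positions where no mismatch is ever tolerated.  By
        default (see :func:`parse_consensus`) the core is the set of
        singleton positions, e.g. the CCAAT run of ``DVVCCAATSNV``.
    label
        Free-text name used in logs and reports.
    """

    positions: tuple[frozenset[str], ...]
    core_mask: tuple[bool, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.core_mask):
            raise MatrixError("positions and core_mask differ in length")
        if not self.positions:
            raise MatrixError("matrix must have at least one position")
        for i, s in enumerate(self.positions):
            if not s or not s <= _ACGT:
                raise MatrixError(
                    f"position {i + 1}: allowed set must be a non-empty "
                    "subset of {A,C,G,T}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> int:
        return len(self.positions)

    def to_iupac(self) -> str:
        """Render back to a one-letter-per-position IUPAC string."""
        return "".join(_SET_TO_IUPAC[s] for s in self.positions)

    def reverse_complement(self) -> "ConsensusMatrix":
        """Positions reversed, each set complemented base-wise, core mask reversed."""
        comp = tuple(
            frozenset(_COMPLEMENT[b] for b in s) for s in reversed(self.positions)
        )
        return ConsensusMatrix(comp, tuple(reversed(self.core_mask)), self.label)

    def flank_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.core_mask) if not c)

    def core_runs(self) -> list[tuple[int, str]]:
        """Maximal runs of invariant singleton positions as (start, literal)."""
        runs: list[tuple[int, str]] = []
        i = 0
        n = self.length
        while i < n:
            if self.core_mask[i] and len(self.positions[i]) == 1:
                j = i
                while (
                    j < n and self.core_mask[j] and len(self.positions[j]) == 1
                ):
                    j += 1
                runs.append((i, "".join(next(iter(self.positions[k])) for k in range(i, j))))
                i = j
            else:
                i += 1
        return runs

    def longest_core_run(self) -> tuple[int, str] | None:
        """Longest maximal invariant literal run (leftmost on ties), or None."""
        runs = self.core_runs()
        if not runs:
            return None
        return max(runs, key=lambda r: (len(r[1]), -r[0]))


@dataclass(frozen=True)
class MatchPolicy:
    """How degenerate positions may mismatch, and on which strands to search.

    Two modes are supported.  ``identity_threshold`` (the default) accepts a
    window when every core position matches exactly and the fraction of
    matching non-core (flank) positions is *strictly* greater than
    ``min_identity``.  ``max_mismatch`` accepts when the core matches, at
    most ``max_mismatches`` flank positions mismatch, and every mismatch
    falls inside ``allowed_positions`` (0-based indices; ``None`` = any
    non-core position).
    """

    mode: str = "identity_threshold"
    min_identity: float = 0.82
    max_mismatches: int = 0
    allowed_positions: frozenset[int] | None = None
    strands: str = "both"
    #: when True, an ``N`` in the text matches a position whose allowed set
    #: is the full {A,C,G,T}; the default (False) is conservative.
    n_matches_n: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("identity_threshold", "max_mismatch"):
            raise MatrixError(f"unknown policy mode {self.mode!r}")
        if not 0.0 <= self.min_identity <= 1.0:
            raise MatrixError("min_identity must lie in [0, 1]")
        if self.max_mismatches < 0:
            raise MatrixError("max_mismatches must be >= 0")
        if self.strands not in ("forward", "reverse", "both"):
            raise MatrixError(f"unknown strands selection {self.strands!r}")


def default_policy(strands: str = "both") -> MatchPolicy:
    """The CCAAT survey policy: exact core, flank identity strictly > 0.82."""
    return MatchPolicy(mode="identity_threshold", min_identity=0.82, strands=strands)


def parse_consensus(
    iupac: str,
    core: tuple[int, int] | None = None,
    label: str | None = None,
) -> ConsensusMatrix:
    """Parse an IUPAC string into a :class:`ConsensusMatrix`.

    Parameters
    ----------
    iupac
        Case-insensitive string over the 15-letter IUPAC alphabet, between
        4 and 30 positions long.
    core
        Optional 1-based inclusive ``(start, end)`` range forcing the core
        mask.  When absent, every singleton position is core — for
        ``DVVCCAATSNV`` that is exactly the CCAAT pentanucleotide.
    """
    s = iupac.strip().upper()
    if not MIN_LENGTH <= len(s) <= MAX_LENGTH:
        raise MatrixError(
            f"matrix length must be between {MIN_LENGTH} and {MAX_LENGTH} "
            f"nucleotides (got {len(s)})"
        )
    positions = []
    for i, ch in enumerate(s):
        try:
            positions.append(IUPAC_SETS[ch])
        except KeyError:
            raise MatrixError(
                f"invalid IUPAC symbol {ch!r} at position {i + 1}"
            ) from None
    if core is None:
        mask = tuple(len(p) == 1 for p in positions)
    else:
        lo, hi = core
        if not (1 <= lo <= hi <= len(s)):
            raise MatrixError(f"core range {core} outside matrix of length {len(s)}")
        mask = tuple(lo - 1 <= i <= hi - 1 for i in range(len(s)))
    return ConsensusMatrix(tuple(positions), mask, label if label is not None else s)


def ccaat_matrix() -> ConsensusMatrix:
    """The NF-Y CCAAT-box consensus D/V/V/C/C/A/A/T/S/N/V."""
    return parse_consensus("DVVCCAATSNV", label="NF-Y CCAAT")


def _char_matches(ch: str, allowed: frozenset[str], n_matches_n: bool) -> bool:
    if ch in _ACGT:
        return ch in allowed
    if ch == "N":
        return n_matches_n and allowed == _ACGT
    return False


def _score(
    window_str: str, matrix: ConsensusMatrix, n_matches_n: bool = False
) -> tuple[bool, int, int, list[int]]:
    """Return (core_ok, flank_matches, flank_total, flank_mismatch_indices)."""
    if len(window_str) != matrix.length:
        raise MatrixError(
            f"window length {len(window_str)} != matrix length {matrix.length}"
        )
    s = window_str.upper()
    core_ok = True
    flank_matches = 0
    flank_total = 0
    mismatches: list[int] = []
    for i, (ch, allowed, is_core) in enumerate(
        zip(s, matrix.positions, matrix.core_mask)
    ):
        hit = _char_matches(ch, allowed, n_matches_n)
        if is_core:
            if not hit:
                core_ok = False
        else:
            flank_total += 1
            if hit:
                flank_matches += 1
            else:
                mismatches.append(i)
    return core_ok, flank_matches, flank_total, mismatches


def identity_fraction(
    window_str: str, matrix: ConsensusMatrix, *, n_matches_n: bool = False
) -> tuple[bool, float]:
    """Evaluate one window: (core intact?, fraction of matching flanks).

    The fraction is over non-core positions only and is 1.0 when the matrix
    has no non-core positions (e.g. a plain literal like ``CCAAT``).
    """
    core_ok, fm, ft, _ = _score(window_str, matrix, n_matches_n)
    return core_ok, (fm / ft if ft else 1.0)


def _accept_forward(
    window_str: str, matrix: ConsensusMatrix, policy: MatchPolicy
) -> tuple[bool, float]:
    """Policy decision against the matrix as given (no strand logic)."""
    core_ok, fm, ft, mism = _score(window_str, matrix, policy.n_matches_n)
    fi = fm / ft if ft else 1.0
    if not core_ok:
        return False, fi
    if policy.mode == "identity_threshold":
        return fi > policy.min_identity, fi
    if len(mism) > policy.max_mismatches:
        return False, fi
    if policy.allowed_positions is not None and not set(mism) <= set(
        policy.allowed_positions
    ):
        return False, fi
    return True, fi


def classify(
    window_str: str, matrix: ConsensusMatrix, policy: MatchPolicy | None = None
) -> bool:
    """True iff the window satisfies the policy on any selected strand.

    ``strands="forward"`` tests the matrix as given; ``"reverse"`` tests its
    reverse complement against the same text; ``"both"`` accepts either.
    """
    policy = policy or default_policy()
    if policy.strands in ("forward", "both"):
        ok, _ = _accept_forward(window_str, matrix, policy)
        if ok:
            return True
    if policy.strands in ("reverse", "both"):
        ok, _ = _accept_forward(window_str, matrix.reverse_complement(), policy)
        if ok:
            return True
    return False


def _expand_forward(
    matrix: ConsensusMatrix, policy: MatchPolicy, cap: int, out: set[str]
) -> None:
    n = matrix.length
    if policy.mode == "identity_threshold":
        ft = len(matrix.flank_indices())
        budget = 0
        while budget + 1 <= ft and (ft - budget - 1) / ft > policy.min_identity:
            budget += 1
        allowed_at = None
    else:
        budget = policy.max_mismatches
        allowed_at = policy.allowed_positions

    buf: list[str] = [""] * n

    def rec(i: int, left: int) -> None:
        if i == n:
            out.add("".join(buf))
            if len(out) > cap:
                raise ExpansionCapError(len(out), cap)
            return
        allowed = matrix.positions[i]
        if matrix.core_mask[i]:
            choices: Iterable[tuple[str, int]] = ((b, 0) for b in sorted(allowed))
        else:
            mism_ok = left > 0 and (allowed_at is None or i in allowed_at)
            choices = [(b, 0) for b in sorted(allowed)]
            if mism_ok:
                choices += [(b, 1) for b in sorted(_ACGT - allowed)]
        for b, cost in choices:
            buf[i] = b
            rec(i + 1, left - cost)

    rec(0, budget)


def expand_exact(
    matrix: ConsensusMatrix, policy: MatchPolicy | None = None, cap: int = 1_000_000
) -> set[str]:
    """Enumerate the exact set of A/C/G/T strings accepted by :func:`classify`.

    Intended as a test oracle and for regex/set-scan cross-checks; raises
    :class:`ExpansionCapError` as soon as the expansion exceeds ``cap``.
    """
    policy = policy or default_policy()
    out: set[str] = set()
    if policy.strands in ("forward", "both"):
        _expand_forward(matrix, policy, cap, out)
    if policy.strands in ("reverse", "both"):
        _expand_forward(matrix.reverse_complement(), policy, cap, out)
    return out
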