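"""Degenerate consensus-motif parsing and double-stranded scanning.

Consensus motifs from ChIP-derived discovery tools are degenerate: a
position may be one base (``C``), a bracketed set (``[AT]``), or the
wildcard ``x`` matching any base. This module parses that bracket notation,
computes reverse complements on the pattern algebra, scans DNA sequences on
both strands, and classifies sequences as exact, partial, or non-matching
against a motif panel.

``N`` in a target never satisfies a non-wildcard position; matching is
case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

WILDCARD = "ACGT"  # a wildcard position admits every base
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class DegeneratePattern:
    """An ordered list of per-position allowed-base sets.

    Each position is a string of allowed bases in notation order (order is
    preserved so that ``parse(render(p)) == p``); a wildcard position is the
    full base set rendered as ``x``.
    """

    positions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("pattern must have at least one position")
        canonical = []
        for i, pos in enumerate(self.positions):
            if not pos or not set(pos) <= _VALID_BASES or len(set(pos)) != len(pos):
                raise ValueError(f"invalid base set {pos!r} at position {i}")
            # any full base set IS the wildcard; store it canonically
            canonical.append(WILDCARD if len(pos) == 4 else pos)
        object.__setattr__(self, "positions", tuple(canonical))

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, pos_index: int, base: str) -> bool:
        allowed = self.positions[pos_index]
        if len(allowed) == 4:
            return base in "ACGTN"  # wildcard admits the ambiguity code too
        return base in allowed  # N never satisfies a non-wildcard position


def parse_pattern(text: str) -> DegeneratePattern:
    """Parse bracket notation, e.g. ``"CCTC[AT][GC]CC[TA]CC[CT]"``.

    Raises ValueError with the offending offset on unbalanced brackets,
    empty groups, or characters outside ``{A,C,G,T,x,[,]}``.
    """
    if not text:
        raise ValueError("empty pattern text")
    positions: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        up = ch.upper()
        if up in _VALID_BASES:
            positions.append(up)
            i += 1
        elif ch in ("x", "X"):
            positions.append(WILDCARD)
            i += 1
        elif ch == "[":
            j = text.find("]", i + 1)
            if j == -1:
                raise ValueError(f"unbalanced bracket at offset {i}")
            group = text[i + 1 : j].upper()
            if not group:
                raise ValueError(f"empty bracket group at offset {i}")
            if not set(group) <= _VALID_BASES or len(set(group)) != len(group):
                raise ValueError(f"illegal bracket group {group!r} at offset {i}")
            positions.append(group)
            i = j + 1
        else:
            raise ValueError(f"illegal character {ch!r} at offset {i}")
    return DegeneratePattern(tuple(positions))


def render_pattern(pattern: DegeneratePattern) -> str:
    """Inverse of parse_pattern (wildcards render as ``x``)."""
    parts = []
    for pos in pattern.positions:
        if len(pos) == 4:
            parts.append("x")
        elif len(pos) == 1:
            parts.append(pos)
        else:
            parts.append(f"[{pos}]")
    return "".join(parts)


def reverse_complement(pattern: DegeneratePattern) -> DegeneratePattern:
    """Reverse the position order and complement each base set.

    The wildcard maps to itself; ``rc`` is an involution.
    """
    rc_positions = tuple(
        pos.translate(_COMPLEMENT) if len(pos) < 4 else WILDCARD
        for pos in reversed(pattern.positions)
    )
    return DegeneratePattern(rc_positions)


def reverse_complement_seq(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class MotifMatch:
    target_id: str
    offset: int  # 0-based position in the target (forward coordinates)
    strand: Literal["+", "-"]
    length: int
    match_type: Literal["EXACT", "PARTIAL"]
    matched_span: str


def _window_matches(window: str, pattern: DegeneratePattern) -> bool:
    return all(pattern.matches_at(i, b) for i, b in enumerate(window))


def scan(
    target: str,
    pattern: DegeneratePattern,
    both_strands: bool = True,
    target_id: str = "",
) -> list[MotifMatch]:
    """Report every full-length pattern match in the target.

    Every window of pattern length is tested on the forward strand; with
    ``both_strands`` the reverse-complement pattern is also scanned and its
    hits reported with strand ``-`` at forward coordinates. Output is sorted
    by (offset, strand). A pattern longer than the target yields no matches.
    """
    target = target.upper()
    L = len(pattern)
    hits: list[MotifMatch] = []
    strands: list[tuple[str, DegeneratePattern]] = [("+", pattern)]
    if both_strands:
        strands.append(("-", reverse_complement(pattern)))
    for strand, pat in strands:
        for off in range(len(target) - L + 1):
            window = target[off : off + L]
            if _window_matches(window, pat):
                hits.append(
                    MotifMatch(
                        target_id=target_id,
                        offset=off,
                        strand=strand,  # type: ignore[arg-type]
                        length=L,
                        match_type="EXACT",
                        matched_span=window,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _best_partial_run(
    target: str, pattern: DegeneratePattern
) -> tuple[int, int] | None:
    """Longest contiguous run of satisfied pattern positions over all
    alignments, including alignments where the pattern overhangs the target.

    Returns (run_length, target_offset_of_run_start), preferring longer
    runs then smaller target offsets; None when no position matches.
    """
    L, n = len(pattern), len(target)
    best: tuple[int, int] | None = None
    for align in range(-(L - 1), n):
        run = 0
        run_start = None
        for j in range(L):
            t = align + j
            ok = 0 <= t < n and pattern.matches_at(j, target[t])
            if ok:
                if run == 0:
                    run_start = align + j
                run += 1
                cand = (run, run_start)
                if best is None or (-cand[0], cand[1]) < (-best[0], best[1]):
                    best = cand
            else:
                run = 0
    return best


def classify_sequence(
    target: str,
    patterns: Iterable[DegeneratePattern],
    partial_min: int = 7,
    target_id: str = "",
) -> tuple[Literal["EXACT", "PARTIAL", "NONE"], MotifMatch | None]:
    """Classify a sequence against a motif panel.

    EXACT when any pattern matches full-length on either strand; otherwise
    PARTIAL when some contiguous run of at least ``partial_min`` consecutive
    pattern positions matches; otherwise NONE. The best match is reported
    with a deterministic tie-break: longest run, then smallest offset,
    then the forward strand.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("pattern list must not be empty")
    if partial_min < 1:
        raise ValueError("partial_min must be >= 1")
    target = target.upper()

    exact_best: MotifMatch | None = None
    for pat in patterns:
        for hit in scan(target, pat, both_strands=True, target_id=target_id):
            key = (hit.offset, hit.strand)
            if exact_best is None or key < (exact_best.offset, exact_best.strand):
                exact_best = hit
    if exact_best is not None:
        return "EXACT", exact_best

    best: tuple[int, int, str, DegeneratePattern] | None = None  # run, off, strand, pat
    for pat in patterns:
        for strand, oriented in (("+", pat), ("-", reverse_complement(pat))):
            res = _best_partial_run(target, oriented)
            if res is None:
                continue
            run, off = res
            cand = (-run, off, strand)
            if best is None or cand < (-best[0], best[1], best[2]):
                best = (run, off, strand, pat)
    if best is not None and best[0] >= partial_min:
        run, off, strand, pat = best
        return "PARTIAL", MotifMatch(
            target_id=target_id,
            offset=off,
            strand=strand,  # type: ignore[arg-type]
            length=run,
            match_type="PARTIAL",
            matched_span=target[off : off + run],
        )
    return "NONE", None
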