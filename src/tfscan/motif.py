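"""Degenerate protein-motif patterns and ribosome-binding-site (RBS) calling.

Trigger factor docks onto the 50S ribosomal subunit through a conserved
N-terminal signature, canonically GFRxGxxP (``x`` = any residue).  Natural
variants (GYRxGxxP, GFRKGKxx) share the relaxed core GxRxG, which is used as
the decision motif: a homolog is called RBS-positive when GxRxG matches
entirely within its first 100 residues.

Patterns are positional: each position is either a fixed set of allowed
amino-acid letters or a wildcard.  Ambiguity codes (B, Z, J, X, U, O) satisfy
wildcards but never fixed positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes: match wildcards only, never fixed positions.
AMBIGUOUS_AA = frozenset("BZJXUO")

#: Default N-terminal window (residues 1..100 inclusive) for RBS screening.
DEFAULT_RBS_WINDOW = 100


class PatternSyntaxError(ValueError):
    """Raised for a malformed motif specification; carries the offending index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (at spec index {index})")
        self.index = index


@dataclass(frozen=True)
class MotifPattern:
    """A positional degenerate motif.

    ``positions`` holds, per position, either a frozenset of allowed residues
    or ``None`` for a wildcard.
    """

    name: str
    positions: tuple[Optional[frozenset[str]], ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError("pattern must have at least one position")
        for i, pos in enumerate(self.positions):
            if pos is not None:
                if not pos or not pos <= STANDARD_AA:
                    raise ValueError(
                        f"position {i + 1}: fixed set must be a non-empty subset "
                        f"of the 20 standard residues, got {sorted(pos)}"
                    )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> int:
        return len(self.positions)

    def matches_at(self, sequence: str, start0: int) -> bool:
        """True if the pattern matches ``sequence`` at 0-based offset ``start0``."""
        if start0 < 0 or start0 + len(self) > len(sequence):
            return False
        for pos, letter in zip(self.positions, sequence[start0 : start0 + len(self)]):
            if pos is None:
                continue  # wildcard: any residue letter, incl. ambiguity codes
            if letter not in pos:
                return False
        return True

    def to_regex(self) -> str:
        parts = []
        for pos in self.positions:
            if pos is None:
                parts.append("[A-Z]")
            elif len(pos) == 1:
                parts.append(next(iter(pos)))
            else:
                parts.append("[" + "".join(sorted(pos)) + "]")
        return "".join(parts)


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a pattern; ``start`` is the 1-based residue position."""

    pattern_name: str
    start: int
    matched_text: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("match start must be >= 1")


def compile_pattern(spec: str, name: Optional[str] = None) -> MotifPattern:
    """Compile a motif string into a :class:`MotifPattern`.

    Grammar: one-letter residue codes fix a single residue; ``[..]`` groups fix
    a residue class; ``x`` or ``×`` is a wildcard.  Examples: ``"GxRxG"``,
    ``"GFRxGxxP"``, ``"[ST]P"``.
    """
    if not spec:
        raise PatternSyntaxError("empty pattern spec", 0)
    positions: list[Optional[frozenset[str]]] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch in ("x", "×"):
            positions.append(None)
            i += 1
        elif ch == "[":
            end = spec.find("]", i + 1)
            if end == -1:
                raise PatternSyntaxError("unterminated '[' group", i)
            group = spec[i + 1 : end].upper()
            if not group:
                raise PatternSyntaxError("empty '[]' group", i)
            bad = set(group) - STANDARD_AA
            if bad:
                raise PatternSyntaxError(
                    f"illegal residue(s) {sorted(bad)} in group", i
                )
            positions.append(frozenset(group))
            i = end + 1
        else:
            up = ch.upper()
            if up not in STANDARD_AA:
                raise PatternSyntaxError(f"illegal character {ch!r}", i)
            positions.append(frozenset(up))
            i += 1
    return MotifPattern(name=name if name is not None else spec, positions=tuple(positions))


def sanitize_sequence(sequence: str, label: str = "") -> str:
    """Uppercase a sequence; strip ``*`` (stop) and ``-`` (gap) with a warning."""
    seq = sequence.upper()
    if "*" in seq or "-" in seq:
        logger.warning(
            "stripping %d '*'/'-' character(s) from sequence %s",
            seq.count("*") + seq.count("-"),
            label or "<unnamed>",
        )
        seq = seq.replace("*", "").replace("-", "")
    return seq


def find_matches(
    pattern: MotifPattern,
    sequence: str,
    window_end: Optional[int] = None,
) -> list[MotifMatch]:
    """All occurrences of ``pattern`` whose last residue lies at <= ``window_end``.

    ``window_end=None`` means unlimited.  Overlapping matches are all
    reported, in ascending start order.
    """
    region = sequence if window_end is None else sequence[: max(window_end, 0)]
    if len(region) < len(pattern):
        return []
    rx = re.compile("(?=(" + pattern.to_regex() + "))")
    out = []
    for m in rx.finditer(region):
        text = m.group(1)
        # the regex is coarse at fixed positions only when groups collapse to
        # single letters, so it is exact; keep a guard for safety
        if pattern.matches_at(region, m.start()):
            out.append(MotifMatch(pattern.name, m.start() + 1, text))
    return out


# Packaged patterns ----------------------------------------------------------

#: Relaxed decision motif used to call RBS presence/absence.
DECISION_MOTIF = compile_pattern("GxRxG", name="GxRxG")

#: Named RBS variants, in reporting precedence order.
NAMED_VARIANTS: tuple[tuple[str, MotifPattern], ...] = (
    ("canonical", compile_pattern("GFRxGxxP", name="GFRxGxxP")),
    ("GYR-variant", compile_pattern("GYRxGxxP", name="GYRxGxxP")),
    ("GFRKGK-variant", compile_pattern("GFRKGKxx", name="GFRKGKxx")),
)


@dataclass(frozen=True)
class RBSStatus:
    """RBS call for one protein.

    ``variant_label`` is one of ``canonical`` / ``GYR-variant`` /
    ``GFRKGK-variant`` / ``degenerate-only`` / ``none``; the label is
    reporting-only and never changes presence.
    """

    present: bool
    decisive_match: Optional[MotifMatch]
    variant_label: str


def rbs_status(
    sequence: str,
    window: int = DEFAULT_RBS_WINDOW,
    decision: MotifPattern = DECISION_MOTIF,
    variants: Sequence[tuple[str, MotifPattern]] = NAMED_VARIANTS,
) -> RBSStatus:
    """Decide RBS presence inside the N-terminal window.

    Presence requires a decision-motif (GxRxG) match ending at residue
    <= ``window``; the decisive match is the earliest such match.  The variant
    label reports the first named pattern (by precedence) that also matches
    in-window, else ``degenerate-only``.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    hits = find_matches(decision, sequence, window_end=window)
    if not hits:
        return RBSStatus(present=False, decisive_match=None, variant_label="none")
    for label, pat in variants:
        if find_matches(pat, sequence, window_end=window):
            return RBSStatus(True, hits[0], label)
    return RBSStatus(True, hits[0], "degenerate-only")
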