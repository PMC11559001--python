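"""Domain-partitioned percent identity of TF homologs against a reference.

Trigger factor has three domains: an N-terminal ribosome-binding domain
(carrying the RBS motif), a middle FKBP-type PPIase domain, and a C-terminal
substrate-binding domain.  A query homolog is globally aligned to an
annotated reference TF (affine-gap Gotoh, BLOSUM62, gap open 11 / extend 1)
and alignment columns are partitioned by the reference residue's domain.
Per domain, identity is 100 x identical columns / columns where both
sequences carry a residue; a domain with no aligned query residues reports
no identity ('--' in the serialized table).  A query occupying < 20% of the
reference N-domain columns is called N-terminally deficient — the retained
duplicate class in multi-TF genomes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

#: Occupancy threshold below which the query is called N-terminally deficient.
DEFAULT_N_DEFICIENCY_OCCUPANCY = 0.20


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap global alignment scoring: a gap of length k costs
    ``gap_open + (k - 1) * gap_extend``."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class ReferenceTF:
    """An annotated reference trigger factor.

    ``n_end`` and ``ppiase_end`` are the 1-based inclusive last residues of
    the N-terminal and PPIase domains; the C-terminal domain runs from
    ``ppiase_end + 1`` to the end.  ``rbs_interval`` is the 1-based span of
    the reference RBS motif, inside the N-domain.
    """

    ref_id: str
    sequence: str
    n_end: int
    ppiase_end: int
    rbs_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if not 1 < self.n_end < self.ppiase_end < len(self.sequence):
            raise ValueError(
                "boundaries must satisfy 1 < n_end < ppiase_end < sequence length"
            )
        lo, hi = self.rbs_interval
        if not (1 <= lo <= hi <= self.n_end):
            raise ValueError("rbs_interval must lie within the N-domain (1..n_end)")

    def domain_of(self, position: int) -> str:
        """Domain label of a 1-based reference residue position."""
        if position <= self.n_end:
            return "N"
        if position <= self.ppiase_end:
            return "PPIase"
        return "C"


@dataclass(frozen=True)
class DomainIdentityProfile:
    """Per-domain identity of one query against the reference.

    An identity is ``None`` when no query residue aligns inside that
    reference domain; ``aligned_columns`` counts both-residue columns per
    domain.
    """

    query_id: str
    identity_N: Optional[float]
    identity_PPIase: Optional[float]
    identity_C: Optional[float]
    n_deficient: bool
    aligned_columns: dict[str, int]


_NONSTANDARD = str.maketrans({"J": "X", "U": "X", "O": "X"})


def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def global_align(
    a: str, b: str, scoring: AlignScoring = AlignScoring()
) -> tuple[str, str, float]:
    """Optimal affine-gap global alignment of two protein sequences.

    Returns the two gapped strings (equal length) and the alignment score.
    Residues outside the substitution matrix alphabet (J/U/O) are scored as X.
    Ties between co-optimal alignments are broken deterministically by taking
    the aligner's first traceback.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    sa = a.upper().translate(_NONSTANDARD)
    sb = b.upper().translate(_NONSTANDARD)
    alignments = _aligner(scoring).align(sa, sb)
    best = alignments[0]
    return str(best[0]), str(best[1]), float(best.score)


def align_score(a: str, b: str, scoring: AlignScoring = AlignScoring()) -> float:
    """Alignment score only (cheaper than a full traceback)."""
    sa = a.upper().translate(_NONSTANDARD)
    sb = b.upper().translate(_NONSTANDARD)
    return float(_aligner(scoring).score(sa, sb))


def domain_identities(
    query_id: str,
    query_sequence: str,
    ref: ReferenceTF,
    scoring: AlignScoring = AlignScoring(),
    n_deficiency_occupancy: float = DEFAULT_N_DEFICIENCY_OCCUPANCY,
) -> DomainIdentityProfile:
    """Align a query to the reference and profile per-domain identity."""
    ref_gapped, qry_gapped, _ = global_align(ref.sequence, query_sequence, scoring)

    ref_cols = {"N": 0, "PPIase": 0, "C": 0}     # columns with a ref residue
    both = {"N": 0, "PPIase": 0, "C": 0}         # ... where query also has one
    ident = {"N": 0, "PPIase": 0, "C": 0}
    ref_pos = 0
    for rc, qc in zip(ref_gapped, qry_gapped):
        if rc == "-":
            continue
        ref_pos += 1
        dom = ref.domain_of(ref_pos)
        ref_cols[dom] += 1
        if qc != "-":
            both[dom] += 1
            if qc == rc:
                ident[dom] += 1

    def pct(dom: str) -> Optional[float]:
        if both[dom] == 0:
            return None
        return 100.0 * ident[dom] / both[dom]

    n_occupancy = both["N"] / ref_cols["N"] if ref_cols["N"] else 0.0
    return DomainIdentityProfile(
        query_id=query_id,
        identity_N=pct("N"),
        identity_PPIase=pct("PPIase"),
        identity_C=pct("C"),
        n_deficient=n_occupancy < n_deficiency_occupancy,
        aligned_columns=both,
    )


# ---------------------------------------------------------------------------
# Reference / profile I/O
# ---------------------------------------------------------------------------

def load_reference(
    fasta_path: Union[str, Path], boundaries_path: Union[str, Path]
) -> ReferenceTF:
    """Load a reference TF from FASTA plus a boundaries TSV.

    The TSV has header ``ref_id, n_end, ppiase_end, rbs_start, rbs_end`` and
    one row matching the FASTA entry id.
    """
    entries = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(entries) != 1:
        raise ValueError(f"reference FASTA must hold exactly 1 entry, got {len(entries)}")
    entry = entries[0]
    with open(boundaries_path) as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    required = {"ref_id", "n_end", "ppiase_end", "rbs_start", "rbs_end"}
    if not rows or not required <= set(rows[0]):
        raise ValueError(f"boundaries TSV needs columns {sorted(required)}")
    row = next((r for r in rows if r["ref_id"] == entry.id), None)
    if row is None:
        raise ValueError(f"no boundaries row for reference id {entry.id!r}")
    return ReferenceTF(
        ref_id=entry.id,
        sequence=str(entry.seq).upper(),
        n_end=int(row["n_end"]),
        ppiase_end=int(row["ppiase_end"]),
        rbs_interval=(int(row["rbs_start"]), int(row["rbs_end"])),
    )


def write_profiles(
    profiles: list[DomainIdentityProfile], path: Union[str, Path]
) -> None:
    """Serialize profiles as TSV; absent identities become ``--``."""

    def fmt(v: Optional[float]) -> str:
        return "--" if v is None else f"{v:.2f}"

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["query_id", "identity_N", "identity_PPIase", "identity_C", "n_deficient"])
        for p in profiles:
            w.writerow([p.query_id, fmt(p.identity_N), fmt(p.identity_PPIase),
                        fmt(p.identity_C), str(p.n_deficient).lower()])
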