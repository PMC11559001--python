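"""Trigger-factor homolog identification and per-genome copy-number census.

A protein is a TF homolog if it hits one of the TF domain families
(TIGR00115 / COG0544 / PRK01490 by default) and is at least 120 residues
long — the conserved PPIase domain alone is ~120 aa, so anything shorter
cannot be a complete TF-family protein.  Genomes are then classified by TF
copy number (none / single / multiple) and, for multi-copy genomes, by how
many copies retain the ribosome-binding-site motif (zero-RBS / one-RBS /
multi-RBS).  Cohort-level percentages use two denominators: the fraction of
genomes with any TF is over all genomes; the single / one-RBS / multi-RBS
fractions are over TF-containing genomes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .motif import (
    DEFAULT_RBS_WINDOW,
    DECISION_MOTIF,
    NAMED_VARIANTS,
    MotifPattern,
    RBSStatus,
    rbs_status,
    sanitize_sequence,
)

logger = logging.getLogger(__name__)

#: Conserved-domain families annotating trigger factor.
DEFAULT_FAMILIES = frozenset({"TIGR00115", "COG0544", "PRK01490"})

#: Minimum homolog length (residues); the PPIase domain alone is ~120 aa.
DEFAULT_MIN_LENGTH = 120


class InsufficientDataError(ValueError):
    """A statistical comparison was requested with too few observations."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    genome_id: str
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(
                f"empty sequence for protein {self.protein_id!r} "
                f"in genome {self.genome_id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FamilyHit:
    protein_id: str
    family_id: str
    score: float
    evalue: float


@dataclass(frozen=True)
class TFHomolog:
    """A family-hit protein surviving the length filter, with its RBS call."""

    genome_id: str
    protein_id: str
    length: int
    rbs: RBSStatus
    families_hit: frozenset[str]
    sequence: str = ""


@dataclass(frozen=True)
class GenomeCensus:
    genome_id: str
    n_tf: int
    n_rbs: int
    category: str            # none | single | multiple
    rbs_class: Optional[str]  # multi-TF genomes only: zero-RBS | one-RBS | multi-RBS

    def __post_init__(self) -> None:
        if not 0 <= self.n_rbs <= self.n_tf:
            raise ValueError("n_rbs must lie in [0, n_tf]")


@dataclass(frozen=True)
class CensusSummary:
    n_genomes: int
    n_with_tf: int
    n_none: int
    n_single: int
    n_multiple: int
    n_multi_oneRBS: int
    n_multi_multiRBS: int
    n_multi_zeroRBS: int
    pct_with_tf: float
    pct_single: float
    pct_multi_oneRBS: float
    pct_multi_multiRBS: float

    @classmethod
    def from_counts(
        cls,
        n_genomes: int,
        n_none: int,
        n_single: int,
        n_multi_oneRBS: int,
        n_multi_multiRBS: int,
        n_multi_zeroRBS: int = 0,
    ) -> "CensusSummary":
        """Build a summary from class counts, computing all derived fields.

        ``pct_with_tf`` is over all genomes; the other percentages are over
        TF-containing genomes.  Percentages are rounded half-up to two
        decimals.
        """
        n_multiple = n_multi_oneRBS + n_multi_multiRBS + n_multi_zeroRBS
        n_with_tf = n_single + n_multiple
        if n_none + n_with_tf != n_genomes:
            raise ValueError("class counts do not sum to n_genomes")
        if n_genomes == 0:
            raise ValueError("summary of zero genomes")
        return cls(
            n_genomes=n_genomes,
            n_with_tf=n_with_tf,
            n_none=n_none,
            n_single=n_single,
            n_multiple=n_multiple,
            n_multi_oneRBS=n_multi_oneRBS,
            n_multi_multiRBS=n_multi_multiRBS,
            n_multi_zeroRBS=n_multi_zeroRBS,
            pct_with_tf=round_pct(n_with_tf, n_genomes),
            pct_single=round_pct(n_single, n_with_tf),
            pct_multi_oneRBS=round_pct(n_multi_oneRBS, n_with_tf),
            pct_multi_multiRBS=round_pct(n_multi_multiRBS, n_with_tf),
        )


@dataclass(frozen=True)
class LengthComparison:
    """Welch two-sided t-test of RBS+ vs RBS- homolog lengths."""

    n_rbs_pos: int
    n_rbs_neg: int
    mean_pos: float
    mean_neg: float
    median_pos: float
    median_neg: float
    t_statistic: float
    p_value: float
    test_label: str = "Welch two-sided"


def round_pct(numerator: int, denominator: int) -> float:
    """100 * numerator/denominator, rounded half-up to two decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(numerator * 100) / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

PathLike = Union[str, os.PathLike]


def load_proteomes(
    paths: Union[PathLike, Sequence[PathLike]],
    manifest: Optional[Mapping[str, str]] = None,
) -> list[ProteinRecord]:
    """Read per-genome protein FASTA files.

    ``paths`` is a directory (all ``*.fasta`` / ``*.fa`` / ``*.faa`` files) or
    an explicit list of FASTA files.  The genome id is the file stem, unless
    ``manifest`` maps file name (or stem) to a genome id.  Sequences are
    uppercased and stripped of ``*`` / ``-``; a duplicate protein id within
    one genome is an error.
    """
    if isinstance(paths, (str, os.PathLike)):
        root = Path(paths)
        if root.is_dir():
            files = sorted(
                p for p in root.iterdir()
                if p.suffix.lower() in {".fasta", ".fa", ".faa"}
            )
            if not files:
                raise FileNotFoundError(f"no FASTA files in directory {root}")
        else:
            files = [root]
    else:
        files = [Path(p) for p in paths]

    records: list[ProteinRecord] = []
    for path in files:
        if not path.exists():
            raise FileNotFoundError(str(path))
        genome_id = path.stem
        if manifest:
            genome_id = manifest.get(path.name, manifest.get(path.stem, genome_id))
        seen: set[str] = set()
        for entry in SeqIO.parse(str(path), "fasta"):
            if entry.id in seen:
                raise ValueError(
                    f"duplicate protein id {entry.id!r} in {path.name}"
                )
            seen.add(entry.id)
            seq = sanitize_sequence(str(entry.seq), label=entry.id)
            records.append(ProteinRecord(genome_id, entry.id, seq))
    return records


_HIT_DIALECTS = ("native", "outfmt6", "hmmer-tbl")


def load_hits(
    path: PathLike,
    families: Iterable[str] = DEFAULT_FAMILIES,
    dialect: str = "native",
) -> list[FamilyHit]:
    """Read a domain-family hit table.

    Dialects:

    ``native``
        TSV with header ``protein_id, family_id, score, evalue``.
    ``outfmt6``
        NCBI tabular (BLAST/rpsblast ``-outfmt 6``), headerless; qseqid is
        the protein, sseqid the family, bitscore the score.
    ``hmmer-tbl``
        hmmscan ``--tblout`` (space-separated, ``#`` comments); the target is
        the family profile and the query the protein.

    Rows whose family is outside ``families`` are dropped with a logged count.
    """
    families = set(families)
    if dialect not in _HIT_DIALECTS:
        raise ValueError(f"unknown hits dialect {dialect!r}; choose from {_HIT_DIALECTS}")

    rows: list[tuple[str, str, float, float]] = []
    if dialect == "native":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"protein_id", "family_id", "score", "evalue"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"hit table missing required column(s): {sorted(missing)}")
        for r in df.itertuples(index=False):
            rows.append((r.protein_id, r.family_id, float(r.score), float(r.evalue)))
    elif dialect == "outfmt6":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] < 12:
            raise ValueError("outfmt6 table needs >= 12 columns")
        for r in df.itertuples(index=False):
            rows.append((r[0], r[1], float(r[11]), float(r[10])))
    else:  # hmmer-tbl
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.split()
                if len(f) < 6:
                    raise ValueError("malformed hmmer tblout line: " + line.rstrip())
                # target(0)=profile, query(2)=protein, full-seq evalue(4), score(5)
                rows.append((f[2], f[0], float(f[5]), float(f[4])))

    hits, dropped = [], 0
    for protein_id, family_id, score, evalue in rows:
        if family_id in families:
            hits.append(FamilyHit(protein_id, family_id, score, evalue))
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d hit row(s) with family outside the configured set", dropped)
    return hits


# ---------------------------------------------------------------------------
# Homolog identification and classification
# ---------------------------------------------------------------------------

def identify_tf_homologs(
    proteins: Sequence[ProteinRecord],
    hits: Sequence[FamilyHit],
    min_length: int = DEFAULT_MIN_LENGTH,
    rbs_window: int = DEFAULT_RBS_WINDOW,
    decision: MotifPattern = DECISION_MOTIF,
    variants: Sequence[tuple[str, MotifPattern]] = NAMED_VARIANTS,
    max_evalue: Optional[float] = None,
    min_score: Optional[float] = None,
) -> list[TFHomolog]:
    """TF homologs: distinct proteins with >=1 family hit and length >= ``min_length``.

    Hits to several families for one protein collapse into one homolog (the
    three families are alternative annotations of the same domain content).
    No e-value/score threshold is applied unless given.  Hit protein ids that
    do not resolve against ``proteins`` are skipped with a warning.
    """
    index: dict[str, ProteinRecord] = {}
    ambiguous: set[str] = set()
    for rec in proteins:
        if rec.protein_id in index and index[rec.protein_id].genome_id != rec.genome_id:
            ambiguous.add(rec.protein_id)
        index[rec.protein_id] = rec

    by_protein: dict[str, set[str]] = {}
    unresolved = 0
    for hit in hits:
        if max_evalue is not None and hit.evalue > max_evalue:
            continue
        if min_score is not None and hit.score < min_score:
            continue
        if hit.protein_id in ambiguous:
            logger.warning(
                "hit protein id %r is ambiguous across genomes; skipped", hit.protein_id
            )
            continue
        if hit.protein_id not in index:
            unresolved += 1
            continue
        by_protein.setdefault(hit.protein_id, set()).add(hit.family_id)
    if unresolved:
        logger.warning("%d hit(s) did not resolve against the proteome set", unresolved)

    homologs = []
    for protein_id in sorted(by_protein):
        rec = index[protein_id]
        if rec.length < min_length:
            continue
        homologs.append(
            TFHomolog(
                genome_id=rec.genome_id,
                protein_id=protein_id,
                length=rec.length,
                rbs=rbs_status(rec.sequence, window=rbs_window,
                               decision=decision, variants=variants),
                families_hit=frozenset(by_protein[protein_id]),
                sequence=rec.sequence,
            )
        )
    return homologs


def classify_genome(genome_id: str, homologs: Sequence[TFHomolog]) -> GenomeCensus:
    """Classify one genome by TF copy number and RBS retention."""
    for h in homologs:
        if h.genome_id != genome_id:
            raise ValueError(
                f"homolog {h.protein_id!r} belongs to genome {h.genome_id!r}, "
                f"not {genome_id!r}"
            )
    n_tf = len(homologs)
    n_rbs = sum(1 for h in homologs if h.rbs.present)
    if n_tf == 0:
        category, rbs_class = "none", None
    elif n_tf == 1:
        category, rbs_class = "single", None
    else:
        category = "multiple"
        rbs_class = "zero-RBS" if n_rbs == 0 else ("one-RBS" if n_rbs == 1 else "multi-RBS")
    return GenomeCensus(genome_id, n_tf, n_rbs, category, rbs_class)


def classify_cohort(
    genome_ids: Iterable[str], homologs: Sequence[TFHomolog]
) -> list[GenomeCensus]:
    """Classify every genome in ``genome_ids``.

    Genomes with no homologs are counted as category ``none`` — the cohort
    denominator is the genome set, not the hit table.
    """
    by_genome: dict[str, list[TFHomolog]] = {}
    for h in homologs:
        by_genome.setdefault(h.genome_id, []).append(h)
    return [
        classify_genome(g, by_genome.get(g, []))
        for g in sorted(set(genome_ids))
    ]


def summarize(censuses: Sequence[GenomeCensus]) -> CensusSummary:
    """Cohort summary counts and percentages (one census per genome)."""
    if not censuses:
        raise ValueError("summary of zero genomes")
    ids = [c.genome_id for c in censuses]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome in census list")
    n_none = sum(1 for c in censuses if c.category == "none")
    n_single = sum(1 for c in censuses if c.category == "single")
    n_one = sum(1 for c in censuses if c.rbs_class == "one-RBS")
    n_multi = sum(1 for c in censuses if c.rbs_class == "multi-RBS")
    n_zero = sum(1 for c in censuses if c.rbs_class == "zero-RBS")
    return CensusSummary.from_counts(
        n_genomes=len(censuses),
        n_none=n_none,
        n_single=n_single,
        n_multi_oneRBS=n_one,
        n_multi_multiRBS=n_multi,
        n_multi_zeroRBS=n_zero,
    )


def compare_lengths(homologs: Sequence[TFHomolog]) -> LengthComparison:
    """Welch two-sided t-test on lengths of RBS+ vs RBS- homologs.

    The caller restricts ``homologs`` to multi-TF genomes; homologs are
    pooled across genomes.  Each group needs >= 2 members.
    """
    pos = [float(h.length) for h in homologs if h.rbs.present]
    neg = [float(h.length) for h in homologs if not h.rbs.present]
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientDataError(
            f"need >= 2 homologs per group, got {len(pos)} RBS+ / {len(neg)} RBS-"
        )
    t, p = stats.ttest_ind(pos, neg, equal_var=False)
    return LengthComparison(
        n_rbs_pos=len(pos),
        n_rbs_neg=len(neg),
        mean_pos=float(np.mean(pos)),
        mean_neg=float(np.mean(neg)),
        median_pos=float(np.median(pos)),
        median_neg=float(np.median(neg)),
        t_statistic=float(t),
        p_value=float(p),
    )


def multi_tf_homologs(
    homologs: Sequence[TFHomolog], censuses: Sequence[GenomeCensus]
) -> list[TFHomolog]:
    """Homologs restricted to genomes classified as multiple-TF."""
    multi = {c.genome_id for c in censuses if c.category == "multiple"}
    return [h for h in homologs if h.genome_id in multi]
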