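"""Synthetic proteome cohorts with ground-truth TF architectures.

Real cohorts of thousands of bacterial proteomes are too large to ship, so
the generator emulates the statistical structure the census assumes: genomes
carry 0-7 TF copies; when copies exist, exactly one "primary" copy is
full-length with a canonical GFRxGxxP ribosome-binding-site motif embedded
inside the first 100 residues; each extra copy either retains an RBS (small
probability) or loses its N-terminus — a truncation that removes ~130
residues and, by rejection sampling, is guaranteed to leave no in-window
GxRxG match.  Sub-threshold (<120 aa) family-hit decoys probe the length
filter, and non-TF background proteins provide bulk.  Every emitted protein
carries an exact ground-truth RBS label, so end-to-end recovery can be
asserted at 100%.

Residue composition is uniform over the 20 standard amino acids by default;
under that composition the chance of a spurious GxRxG at a given offset is
(1/20)^3, about 1.2% per 100-residue window, which the rejection sampler
removes from RBS-negative copies.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .census import DEFAULT_FAMILIES, FamilyHit, ProteinRecord
from .motif import DECISION_MOTIF, DEFAULT_RBS_WINDOW, find_matches, rbs_status

logger = logging.getLogger(__name__)

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_FAMILIES = tuple(sorted(DEFAULT_FAMILIES))

#: The canonical RBS motif as (fixed residue or None=random) per position.
_CANONICAL_RBS = ("G", "F", "R", None, "G", None, None, "P")

#: Cohort class counts of the reference survey this generator is shaped to:
#: no-TF / single-TF / multiple-one-RBS / multiple-multi-RBS genomes.
SURVEY_CLASS_COUNTS = (334, 14851, 367, 23)
SURVEY_N_GENOMES = sum(SURVEY_CLASS_COUNTS)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``copy_number_weights`` are probability weights over TF copy numbers
    0..7.  ``p_rbs_retained_extra`` is the probability that a non-primary
    copy keeps its RBS.  Lengths are in residues; RBS-negative copies lose a
    Normal(truncation_mean, truncation_sd) stretch from their N-terminus.
    A fixed seed gives byte-identical output.
    """

    n_genomes: int = 200
    copy_number_weights: tuple[float, ...] = (0.04, 0.60, 0.16, 0.08, 0.05, 0.03, 0.02, 0.02)
    p_rbs_retained_extra: float = 0.05
    full_length_mean: float = 440.0
    full_length_sd: float = 25.0
    truncation_mean: float = 130.0
    truncation_sd: float = 15.0
    n_background: int = 20
    p_decoy_short: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        w = self.copy_number_weights
        if len(w) != 8 or any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("copy_number_weights: 8 non-negative weights with positive sum")
        for p in (self.p_rbs_retained_extra, self.p_decoy_short):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.truncation_mean >= self.full_length_mean:
            raise ValueError("truncation_mean must be < full_length_mean")


@dataclass
class Cohort:
    """An in-memory cohort: proteomes, family-hit table, and ground truth."""

    proteins: list[ProteinRecord]
    hits: list[FamilyHit]
    protein_truth: pd.DataFrame  # genome_id, protein_id, is_tf, rbs, length
    genome_truth: pd.DataFrame   # genome_id, n_tf, n_rbs, category, rbs_class
    spec_json: dict

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genome_truth["genome_id"])

    def write(self, outdir: Union[str, Path]) -> Path:
        """Write genomes/*.fasta, hits.tsv, truth.tsv, truth_proteins.tsv, spec.json."""
        out = Path(outdir)
        (out / "genomes").mkdir(parents=True, exist_ok=True)
        by_genome: dict[str, list[ProteinRecord]] = {}
        for rec in self.proteins:
            by_genome.setdefault(rec.genome_id, []).append(rec)
        for genome_id in self.genome_ids:
            with open(out / "genomes" / f"{genome_id}.fasta", "w") as fh:
                for rec in by_genome.get(genome_id, []):
                    fh.write(f">{rec.protein_id}\n")
                    for i in range(0, len(rec.sequence), 60):
                        fh.write(rec.sequence[i : i + 60] + "\n")
        with open(out / "hits.tsv", "w") as fh:
            fh.write("protein_id\tfamily_id\tscore\tevalue\n")
            for h in self.hits:
                fh.write(f"{h.protein_id}\t{h.family_id}\t{h.score:.1f}\t{h.evalue:.3e}\n")
        self.genome_truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.protein_truth.to_csv(out / "truth_proteins.tsv", sep="\t", index=False)
        with open(out / "spec.json", "w") as fh:
            json.dump(self.spec_json, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return out


def largest_remainder(weights: Sequence[float], n: int) -> list[int]:
    """Apportion ``n`` items to classes proportionally to ``weights``.

    Deterministic largest-remainder (Hamilton) method; ties broken by class
    order.  Counts always sum to ``n``.
    """
    total = float(sum(weights))
    if total <= 0 or n < 0:
        raise ValueError("weights must have positive sum and n must be >= 0")
    quotas = [w * n / total for w in weights]
    base = [math.floor(q) for q in quotas]
    short = n - sum(base)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


# ---------------------------------------------------------------------------
# Sequence builders
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _AA[rng.integers(0, 20, size=length)].tobytes().decode("ascii")


def _embed_canonical_rbs(rng: np.random.Generator, seq: str, window: int) -> str:
    """Splice an instantiated GFRxGxxP so it ends at residue <= ``window``."""
    m = len(_CANONICAL_RBS)
    last_start0 = min(window - m, len(seq) - m)
    start0 = int(rng.integers(0, last_start0 + 1))
    motif = "".join(
        c if c is not None else _random_seq(rng, 1) for c in _CANONICAL_RBS
    )
    return seq[:start0] + motif + seq[start0 + m :]


def _tf_sequence(
    rng: np.random.Generator, length: int, with_rbs: bool, window: int
) -> str:
    """A TF copy sequence with an exact ground-truth RBS label.

    RBS-positive copies get an embedded canonical motif; RBS-negative copies
    are rejection-sampled until no GxRxG match survives in the window.
    """
    if with_rbs:
        return _embed_canonical_rbs(rng, _random_seq(rng, length), window)
    while True:
        seq = _random_seq(rng, length)
        if not find_matches(DECISION_MOTIF, seq, window_end=window):
            return seq


def _draw_full_length(rng: np.random.Generator, spec: CohortSpec) -> int:
    return max(240, int(round(rng.normal(spec.full_length_mean, spec.full_length_sd))))


def _draw_truncated_length(rng: np.random.Generator, spec: CohortSpec, full: int) -> int:
    trunc = int(round(rng.normal(spec.truncation_mean, spec.truncation_sd)))
    trunc = max(30, min(trunc, full - 160))
    return full - trunc


class _Emitter:
    """Accumulates proteins / hits / truth rows for one cohort build."""

    def __init__(self, rng: np.random.Generator, spec: CohortSpec, window: int):
        self.rng = rng
        self.spec = spec
        self.window = window
        self.proteins: list[ProteinRecord] = []
        self.hits: list[FamilyHit] = []
        self.protein_rows: list[dict] = []
        self.genome_rows: list[dict] = []

    def _add_protein(
        self, genome_id: str, protein_id: str, seq: str, is_tf: bool, true_rbs: bool
    ) -> None:
        self.proteins.append(ProteinRecord(genome_id, protein_id, seq))
        self.protein_rows.append(
            {"genome_id": genome_id, "protein_id": protein_id,
             "is_tf": is_tf, "rbs": true_rbs, "length": len(seq)}
        )

    def _add_hits(self, protein_id: str) -> None:
        rng = self.rng
        fams = [_FAMILIES[int(rng.integers(0, len(_FAMILIES)))]]
        if rng.random() < 0.3:
            extra = _FAMILIES[int(rng.integers(0, len(_FAMILIES)))]
            if extra not in fams:
                fams.append(extra)
        for fam in fams:
            score = float(rng.uniform(150.0, 400.0))
            evalue = float(10.0 ** rng.uniform(-120.0, -20.0))
            self.hits.append(FamilyHit(protein_id, fam, round(score, 1), evalue))

    def emit_genome(self, genome_id: str, n_rbs_pos: int, n_rbs_neg: int) -> None:
        """One genome with the given number of RBS+ / RBS- TF copies."""
        rng, spec = self.rng, self.spec
        n_tf = n_rbs_pos + n_rbs_neg
        serial = 0
        flags = [True] * n_rbs_pos + [False] * n_rbs_neg
        for with_rbs in flags:
            serial += 1
            pid = f"{genome_id}_P{serial:03d}"
            full = _draw_full_length(rng, spec)
            length = full if with_rbs else _draw_truncated_length(rng, spec, full)
            seq = _tf_sequence(rng, length, with_rbs, self.window)
            self._add_protein(genome_id, pid, seq, is_tf=True, true_rbs=with_rbs)
            self._add_hits(pid)
        if rng.random() < spec.p_decoy_short:
            serial += 1
            pid = f"{genome_id}_P{serial:03d}"
            seq = _random_seq(rng, int(rng.integers(40, 120)))
            self._add_protein(genome_id, pid, seq, is_tf=False,
                              true_rbs=rbs_status(seq, self.window).present)
            self._add_hits(pid)
        for _ in range(spec.n_background):
            serial += 1
            pid = f"{genome_id}_P{serial:03d}"
            length = int(np.clip(round(rng.normal(300.0, 120.0)), 50, 1200))
            seq = _random_seq(rng, length)
            self._add_protein(genome_id, pid, seq, is_tf=False,
                              true_rbs=rbs_status(seq, self.window).present)
        if n_tf == 0:
            category, rbs_class = "none", ""
        elif n_tf == 1:
            category, rbs_class = "single", ""
        else:
            category = "multiple"
            rbs_class = ("zero-RBS" if n_rbs_pos == 0
                         else "one-RBS" if n_rbs_pos == 1 else "multi-RBS")
        self.genome_rows.append(
            {"genome_id": genome_id, "n_tf": n_tf, "n_rbs": n_rbs_pos,
             "category": category, "rbs_class": rbs_class}
        )

    def cohort(self, spec_json: dict) -> Cohort:
        return Cohort(
            proteins=self.proteins,
            hits=self.hits,
            protein_truth=pd.DataFrame(
                self.protein_rows,
                columns=["genome_id", "protein_id", "is_tf", "rbs", "length"],
            ),
            genome_truth=pd.DataFrame(
                self.genome_rows,
                columns=["genome_id", "n_tf", "n_rbs", "category", "rbs_class"],
            ),
            spec_json=spec_json,
        )


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, window: int = DEFAULT_RBS_WINDOW) -> Cohort:
    """Generate a cohort by sampling TF copy numbers from ``spec``.

    Each genome draws its copy number from ``copy_number_weights``; the first
    copy (if any) is the full-length RBS-positive primary; extras keep an RBS
    with probability ``p_rbs_retained_extra``, else they are N-terminally
    truncated and RBS-negative.
    """
    rng = np.random.default_rng(spec.seed)
    em = _Emitter(rng, spec, window)
    w = np.asarray(spec.copy_number_weights, dtype=float)
    p = w / w.sum()
    width = len(str(max(spec.n_genomes, 1)))
    for i in range(spec.n_genomes):
        genome_id = f"G{i:0{width}d}"
        n_tf = int(rng.choice(len(p), p=p))
        if n_tf == 0:
            em.emit_genome(genome_id, 0, 0)
        else:
            extras = n_tf - 1
            kept = int(rng.binomial(extras, spec.p_rbs_retained_extra)) if extras else 0
            em.emit_genome(genome_id, 1 + kept, extras - kept)
    return em.cohort({"generator": "generate_cohort", **asdict(spec)})


#: Copy-number weights (2..7 copies) for multi-TF genomes in the shaped cohort.
_MULTI_COPY_WEIGHTS = (0.60, 0.20, 0.10, 0.05, 0.03, 0.02)


def survey_shaped_cohort(
    n_genomes: int,
    seed: int = 0,
    n_background: int = 3,
    p_decoy_short: float = 0.02,
    window: int = DEFAULT_RBS_WINDOW,
) -> Cohort:
    """A cohort whose class proportions follow the reference survey.

    Class counts (no-TF / single / multiple-one-RBS / multiple-multi-RBS) are
    apportioned from the survey fractions 334 : 14,851 : 367 : 23 over 15,575
    genomes by the deterministic largest-remainder method, then shuffled by
    ``seed``.  At ``n_genomes = 15,575`` the survey counts are reproduced
    exactly.
    """
    if n_genomes < 100:
        raise ValueError("survey-shaped cohorts need n_genomes >= 100")
    counts = largest_remainder(SURVEY_CLASS_COUNTS, n_genomes)
    for label, c in zip(("no-TF", "single", "multi-one-RBS", "multi-multi-RBS"), counts):
        if c == 0:
            logger.info("class %s apportioned 0 genomes at n=%d", label, n_genomes)
    labels = np.repeat(np.arange(4), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    spec = CohortSpec(
        n_genomes=n_genomes, n_background=n_background,
        p_decoy_short=p_decoy_short, seed=seed,
    )
    em = _Emitter(rng, spec, window)
    mw = np.asarray(_MULTI_COPY_WEIGHTS, dtype=float)
    mp = mw / mw.sum()
    width = len(str(n_genomes))
    for i, label in enumerate(labels):
        genome_id = f"G{i:0{width}d}"
        if label == 0:
            em.emit_genome(genome_id, 0, 0)
        elif label == 1:
            em.emit_genome(genome_id, 1, 0)
        else:
            k = 2 + int(rng.choice(len(mp), p=mp))
            if label == 2:
                em.emit_genome(genome_id, 1, k - 1)
            else:
                r = int(rng.integers(2, k + 1))
                em.emit_genome(genome_id, r, k - r)
    meta = {"generator": "survey_shaped_cohort", "n_genomes": n_genomes,
            "seed": seed, "n_background": n_background,
            "p_decoy_short": p_decoy_short,
            "class_counts": dict(zip(("none", "single", "multi_oneRBS", "multi_multiRBS"),
                                     counts))}
    return em.cohort(meta)


def synthetic_reference(seed: int = 2013) -> tuple[str, int, int, tuple[int, int]]:
    """A synthetic annotated reference TF for identity profiling.

    Returns (sequence, n_end, ppiase_end, rbs_interval).  Domain sizes follow
    the canonical TF architecture: ~110-aa N-domain carrying the RBS motif,
    ~120-aa PPIase domain, ~140-aa C-domain.  This is a synthetic stand-in,
    not a natural TF sequence.
    """
    rng = np.random.default_rng(seed)
    n_end, ppiase_end, total = 110, 230, 370
    seq = _random_seq(rng, total)
    rbs_start0 = 43  # 1-based 44..51, inside both the N-domain and the window
    motif = "".join(c if c is not None else _random_seq(rng, 1) for c in _CANONICAL_RBS)
    seq = seq[:rbs_start0] + motif + seq[rbs_start0 + len(motif):]
    return seq, n_end, ppiase_end, (rbs_start0 + 1, rbs_start0 + len(motif))
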