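"""Run configuration, scan orchestration, and report generation.

`run_scan` ties the stages together: load proteomes and family hits, identify
TF homologs (length filter + RBS call), classify every genome, summarize the
cohort, compare RBS+/RBS- homolog lengths in multi-TF genomes, and optionally
profile per-domain identities against a reference TF.  All artifacts are
written atomically (temp file + rename) together with a run manifest carrying
the resolved configuration, its hash, and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import time
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .census import (
    DEFAULT_FAMILIES,
    DEFAULT_MIN_LENGTH,
    CensusSummary,
    GenomeCensus,
    InsufficientDataError,
    LengthComparison,
    TFHomolog,
    classify_cohort,
    compare_lengths,
    identify_tf_homologs,
    load_hits,
    load_proteomes,
    multi_tf_homologs,
    round_pct,
    summarize,
)
from .identity import (
    DEFAULT_N_DEFICIENCY_OCCUPANCY,
    AlignScoring,
    domain_identities,
    load_reference,
    write_profiles,
)
from .motif import DEFAULT_RBS_WINDOW, compile_pattern

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Categorized pipeline failure: category is config / input / insufficient-data."""

    def __init__(self, category: str, message: str):
        super().__init__(message)
        self.category = category


@dataclass
class RunConfig:
    """Resolved configuration of one scan run.

    Defaults follow the census procedure: minimum homolog length 120
    residues, RBS window 100 residues, decision motif GxRxG with the three
    named variants.
    """

    proteomes: Optional[str] = None
    hits: Optional[str] = None
    out: Optional[str] = None
    families: tuple[str, ...] = tuple(sorted(DEFAULT_FAMILIES))
    min_length: int = DEFAULT_MIN_LENGTH
    rbs_window: int = DEFAULT_RBS_WINDOW
    rbs_decision_motif: str = "GxRxG"
    rbs_named_variants: tuple[tuple[str, str], ...] = (
        ("canonical", "GFRxGxxP"),
        ("GYR-variant", "GYRxGxxP"),
        ("GFRKGK-variant", "GFRKGKxx"),
    )
    hits_dialect: str = "native"
    hits_max_evalue: Optional[float] = None
    hits_min_score: Optional[float] = None
    reference_fasta: Optional[str] = None
    reference_boundaries: Optional[str] = None
    n_deficiency_occupancy: float = DEFAULT_N_DEFICIENCY_OCCUPANCY
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        flat: dict[str, Any] = {}
        # accept both flat keys and [rbs]/[hits] tables (rbs.window etc.)
        for key, value in data.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    flat[f"{key}_{sub}".replace(".", "_")] = v
            else:
                flat[key] = value
        alias = {"rbs_window": "rbs_window", "rbs_decision_motif": "rbs_decision_motif",
                 "rbs_named_variants": "rbs_named_variants", "hits_dialect": "hits_dialect",
                 "hits_max_evalue": "hits_max_evalue", "hits_min_score": "hits_min_score"}
        kwargs = {}
        for key, value in flat.items():
            key = alias.get(key, key)
            if key not in known:
                raise PipelineError("config", f"unknown config key {key!r}")
            if key in ("families",):
                value = tuple(value)
            if key == "rbs_named_variants":
                value = tuple((str(a), str(b)) for a, b in value)
            kwargs[key] = value
        return cls(**kwargs)

    def replace(self, **overrides: Any) -> "RunConfig":
        """CLI-flag overrides; None values are ignored."""
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        d["rbs_named_variants"] = [list(v) for v in self.rbs_named_variants]
        return d


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def atomic_write_text(path: Path, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _homolog_table(homologs: Sequence[TFHomolog]) -> pd.DataFrame:
    rows = []
    for h in homologs:
        rows.append({
            "genome_id": h.genome_id,
            "protein_id": h.protein_id,
            "length": h.length,
            "rbs_present": h.rbs.present,
            "variant_label": h.rbs.variant_label,
            "match_start": h.rbs.decisive_match.start if h.rbs.decisive_match else "",
            "sequence": h.sequence,
        })
    return pd.DataFrame(rows, columns=["genome_id", "protein_id", "length",
                                       "rbs_present", "variant_label",
                                       "match_start", "sequence"])


def _census_table(censuses: Sequence[GenomeCensus]) -> pd.DataFrame:
    rows = [{
        "genome_id": c.genome_id, "n_tf": c.n_tf, "n_rbs": c.n_rbs,
        "category": c.category, "rbs_class": c.rbs_class or "",
    } for c in censuses]
    return pd.DataFrame(rows, columns=["genome_id", "n_tf", "n_rbs",
                                       "category", "rbs_class"])


@dataclass
class ScanResult:
    """In-memory result of a scan; ``run_dir`` set when artifacts were written."""

    homologs: list[TFHomolog]
    censuses: list[GenomeCensus]
    summary: CensusSummary
    length_comparison: Optional[LengthComparison]
    length_comparison_note: str = ""
    run_dir: Optional[Path] = None


def scan_cohort(
    proteins,
    hits,
    genome_ids: Optional[Sequence[str]] = None,
    config: Optional[RunConfig] = None,
) -> ScanResult:
    """Run the census on in-memory records (the core of `run_scan`)."""
    config = config or RunConfig()
    decision = compile_pattern(config.rbs_decision_motif, name=config.rbs_decision_motif)
    variants = tuple(
        (label, compile_pattern(spec, name=spec))
        for label, spec in config.rbs_named_variants
    )
    homologs = identify_tf_homologs(
        proteins, hits,
        min_length=config.min_length,
        rbs_window=config.rbs_window,
        decision=decision,
        variants=variants,
        max_evalue=config.hits_max_evalue,
        min_score=config.hits_min_score,
    )
    if genome_ids is None:
        genome_ids = sorted({p.genome_id for p in proteins})
    censuses = classify_cohort(genome_ids, homologs)
    summary = summarize(censuses)
    comparison, note = None, ""
    try:
        comparison = compare_lengths(multi_tf_homologs(homologs, censuses))
    except InsufficientDataError as exc:
        note = str(exc)
        logger.info("length comparison unavailable: %s", exc)
    return ScanResult(homologs, censuses, summary, comparison, note)


def run_scan(config: RunConfig) -> ScanResult:
    """Execute a full scan from files and write all artifacts atomically."""
    if not config.proteomes or not config.out:
        raise PipelineError("config", "proteomes and out directories are required")
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setLevel(config.log_level.upper())
    logging.getLogger("tfscan").addHandler(handler)
    t0 = time.time()
    try:
        try:
            proteins = load_proteomes(config.proteomes)
        except (FileNotFoundError, ValueError) as exc:
            raise PipelineError("input", f"loading proteomes: {exc}") from exc
        if config.hits:
            try:
                hits = load_hits(config.hits, families=config.families,
                                 dialect=config.hits_dialect)
            except (FileNotFoundError, ValueError) as exc:
                raise PipelineError("input", f"loading hits: {exc}") from exc
        else:
            hits = []
        result = scan_cohort(proteins, hits, config=config)

        atomic_write_text(
            out / "homologs.tsv",
            _homolog_table(result.homologs).to_csv(sep="\t", index=False),
        )
        atomic_write_text(
            out / "genomes.tsv",
            _census_table(result.censuses).to_csv(sep="\t", index=False),
        )
        atomic_write_text(
            out / "summary.json",
            json.dumps(dataclasses.asdict(result.summary), indent=2, sort_keys=True) + "\n",
        )
        if result.length_comparison is not None:
            payload: dict[str, Any] = {"available": True,
                                       **dataclasses.asdict(result.length_comparison)}
        else:
            payload = {"available": False, "reason": result.length_comparison_note}
        atomic_write_text(out / "length_comparison.json",
                          json.dumps(payload, indent=2, sort_keys=True) + "\n")

        if config.reference_fasta and config.reference_boundaries:
            try:
                ref = load_reference(config.reference_fasta, config.reference_boundaries)
            except (FileNotFoundError, ValueError) as exc:
                raise PipelineError("input", f"loading reference: {exc}") from exc
            profiles = [
                domain_identities(h.protein_id, h.sequence, ref,
                                  n_deficiency_occupancy=config.n_deficiency_occupancy)
                for h in result.homologs if h.sequence
            ]
            tmp = out / "identities.tsv"
            write_profiles(profiles, tmp)

        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "tfscan_version": __version__,
            "started_unix": t0,
            "elapsed_seconds": round(time.time() - t0, 3),
            "inputs": _input_checksums(config),
        }
        atomic_write_text(out / "manifest.json",
                          json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        result.run_dir = out
        return result
    finally:
        logging.getLogger("tfscan").removeHandler(handler)
        handler.close()


def _input_checksums(config: RunConfig) -> dict[str, str]:
    sums: dict[str, str] = {}
    root = Path(config.proteomes) if config.proteomes else None
    if root and root.is_dir():
        for p in sorted(root.iterdir()):
            if p.suffix.lower() in {".fasta", ".fa", ".faa"}:
                sums[p.name] = _sha256_file(p)
    elif root and root.is_file():
        sums[root.name] = _sha256_file(root)
    if config.hits and Path(config.hits).is_file():
        sums[Path(config.hits).name] = _sha256_file(Path(config.hits))
    return sums


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

class ValidationError(ValueError):
    """A run artifact fails its internal consistency checks."""


def validate_summary(summary: dict) -> None:
    """Check partition identities and that percentages reconstruct from counts."""
    required = {"n_genomes", "n_with_tf", "n_none", "n_single", "n_multiple",
                "n_multi_oneRBS", "n_multi_multiRBS", "n_multi_zeroRBS",
                "pct_with_tf", "pct_single", "pct_multi_oneRBS", "pct_multi_multiRBS"}
    missing = required - set(summary)
    if missing:
        raise ValidationError(f"summary missing field(s): {sorted(missing)}")
    if summary["n_none"] + summary["n_with_tf"] != summary["n_genomes"]:
        raise ValidationError("n_none + n_with_tf != n_genomes")
    if summary["n_single"] + summary["n_multiple"] != summary["n_with_tf"]:
        raise ValidationError("n_single + n_multiple != n_with_tf")
    if (summary["n_multi_oneRBS"] + summary["n_multi_multiRBS"]
            + summary["n_multi_zeroRBS"] != summary["n_multiple"]):
        raise ValidationError("multi-TF RBS classes do not partition n_multiple")
    checks = [
        ("pct_with_tf", summary["n_with_tf"], summary["n_genomes"]),
        ("pct_single", summary["n_single"], summary["n_with_tf"]),
        ("pct_multi_oneRBS", summary["n_multi_oneRBS"], summary["n_with_tf"]),
        ("pct_multi_multiRBS", summary["n_multi_multiRBS"], summary["n_with_tf"]),
    ]
    for name, num, den in checks:
        if den == 0:
            continue
        if abs(summary[name] - round_pct(num, den)) > 1e-9:
            raise ValidationError(f"{name} does not reconstruct from its counts")


def run_report(run_dir: Union[str, Path]) -> str:
    """Render a human-readable markdown summary of a scan run.

    Validates the summary artifact first; every percentage printed is
    recomputed from the printed counts.
    """
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise PipelineError("input", f"missing artifact {summary_path}")
    try:
        summary = json.loads(summary_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"summary.json is not valid JSON: {exc}") from exc
    validate_summary(summary)

    lc_path = run_dir / "length_comparison.json"
    lc = json.loads(lc_path.read_text()) if lc_path.exists() else None

    nwt = summary["n_with_tf"]
    lines = [
        "# TF homolog census",
        "",
        "## Genome breakdown",
        "",
        f"- genomes scanned: {summary['n_genomes']}",
        f"- with >=1 TF homolog: {summary['n_with_tf']} ({summary['pct_with_tf']:.2f}%)",
        f"- lacking TF: {summary['n_none']}",
        f"- single TF: {summary['n_single']}",
        f"- multiple TF homologs: {summary['n_multiple']} "
        f"(one-RBS {summary['n_multi_oneRBS']}, multi-RBS {summary['n_multi_multiRBS']}, "
        f"zero-RBS {summary['n_multi_zeroRBS']})",
        "",
        "## Duplicate-fate fractions (of TF-containing genomes)",
        "",
        f"- single complete TF copy: {summary['pct_single']:.2f}% ({summary['n_single']}/{nwt})",
        f"- one complete copy + N-deficient extras: {summary['pct_multi_oneRBS']:.2f}% "
        f"({summary['n_multi_oneRBS']}/{nwt})",
        f"- more than one complete copy: {summary['pct_multi_multiRBS']:.2f}% "
        f"({summary['n_multi_multiRBS']}/{nwt})",
    ]
    if lc and lc.get("available"):
        lines += [
            "",
            "## Length comparison (multi-TF genomes)",
            "",
            f"- RBS+ homologs: n={lc['n_rbs_pos']}, mean {lc['mean_pos']:.1f} aa, "
            f"median {lc['median_pos']:.1f} aa",
            f"- RBS- homologs: n={lc['n_rbs_neg']}, mean {lc['mean_neg']:.1f} aa, "
            f"median {lc['median_neg']:.1f} aa",
            f"- {lc['test_label']} t-test: t = {lc['t_statistic']:.3f}, "
            f"p = {lc['p_value']:.3g}",
        ]
    report = "\n".join(lines) + "\n"
    atomic_write_text(run_dir / "report.md", report)
    return report
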