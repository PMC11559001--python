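# Methods

## Scientific model

Trigger factor (TF) is the universal bacterial ribosome-associated
chaperone. Its three-domain architecture — an N-terminal ribosome-binding
domain carrying the GFRxGxxP ribosome-binding-site (RBS) motif, a middle
FKBP-type PPIase domain of ~120 residues, and a C-terminal
substrate-binding domain — underlies both operations this package
implements: the minimum-length filter for homolog calling and the
domain-partitioned identity profile. The biological question the census
answers is how *tig* duplicates fare under TF's dosage constraint: most
genomes keep a single copy, and in genomes with several copies the extras
typically lose the N-terminal domain (and hence the RBS), leaving exactly
one complete, ribosome-binding copy.

## Homolog identification and RBS calling

A protein is a TF homolog when it has at least one hit to a TF
conserved-domain family (default set TIGR00115, COG0544, PRK01490 —
alternative annotations of the same domain content, so hits to several
families collapse into one homolog) and is **≥ 120 residues** long. The
boundary is inclusive: "shorter than the PPIase domain" excludes, 120 itself
passes. No e-value or bit-score cutoff is applied by default, because the
upstream family annotation is already a best-match assignment;
`hits.max_evalue` / `hits.min_score` are available in config when the hit
table is noisier (e.g., raw hmmscan output).

RBS presence is decided by the degenerate motif **GxRxG** inside the
N-terminal window of **100 residues**. Coordinates are 1-based counting the
initiator methionine; a match must fit *entirely* inside the window (last
residue ≤ 100) — a partial motif is not a motif, and the same rule is
applied uniformly to all patterns. The named variants GFRxGxxP, GYRxGxxP,
and GFRKGKxx are refinements of GxRxG (positions 1/3/5 of each are G/R/G),
so they can only ever add a label, never flip presence; the reported
variant label follows the fixed precedence canonical > GYR-variant >
GFRKGK-variant > degenerate-only. Ambiguity codes (B, Z, J, X, U, O)
satisfy wildcard positions but never fixed positions — conservative
calling, so an X never fakes a conserved glycine. Sequences are uppercased
on input and `*`/`-` characters stripped with a logged warning; sequences
are otherwise taken as given in the FASTA (no signal-peptide processing).

## Census statistics

Per genome: category none / single / multiple by TF copy count; multi-TF
genomes carry an RBS class (zero-RBS / one-RBS / multi-RBS) from the count
of RBS⁺ copies. Genomes present in the proteome set but absent from the hit
table count as category *none* — the cohort denominator is the genome set.
Cohort percentages use two denominators: the with-TF fraction is over all
genomes; single / one-RBS / multi-RBS fractions are over TF-containing
genomes. Percentages are rounded half-up to two decimals, matching the
convention of printed census tables; the reporting stage re-derives every
percentage from the printed counts and refuses to render artifacts that
fail the partition identities.

Length comparison pools RBS⁺ and RBS⁻ homologs across all multi-TF genomes
(no within-genome pairing) and applies a two-sided **Welch** *t*-test
(scipy, `equal_var=False`). Welch rather than Student because the two
groups have no reason to share a variance — RBS⁻ copies carry an extra
truncation-length variance component. Groups with fewer than two members
raise an explicit insufficient-data error rather than returning a
degenerate statistic.

## Domain identity profiling

Queries are globally aligned to an annotated reference TF with affine-gap
(Gotoh) scoring: BLOSUM62, gap open 11, gap extend 1 (a k-long gap costs
11 + (k−1)); ties between co-optimal alignments are broken by the aligner's
deterministic first traceback. Alignment columns are partitioned by the
*reference* residue's domain (1..n_end = N; ..ppiase_end = PPIase; rest =
C). Per-domain identity = 100 × identical columns / columns where both
sequences carry a residue; a domain in which no query residue aligns
reports no identity (serialized `--`). A query occupying fewer than **20%**
of the reference N-domain columns is called N-terminally deficient; the
threshold (`domains.n_deficiency_occupancy`) operationalizes "lacks the
N-terminal domain" and is deliberately permissive, since truly deficient
duplicates occupy essentially none of the domain. Domain boundaries are
user-supplied configuration, not constants — boundary conventions differ
between references — and the packaged reference
(`tfscan.simulate.synthetic_reference`) is an explicitly synthetic
370-residue stand-in (N 1–110 with the RBS at 44–51, PPIase 111–230,
C 231–370) for tests and demonstrations, not a natural TF sequence.

## Synthetic cohort generator

The generator emulates the statistical structure the census assumes, with
exact ground-truth labels:

- **Copy number** per genome is drawn from weights over 0..7 copies
  (default 0.04 / 0.60 / 0.16 / 0.08 / 0.05 / 0.03 / 0.02 / 0.02 — deliberately
  duplicate-rich so a 500-genome cohort exercises every class; the
  `survey_shaped_cohort` variant instead apportions the four survey classes
  334 : 14,851 : 367 : 23 deterministically by largest remainder and
  reproduces those counts exactly at n = 15,575).
- When copies exist, exactly one **primary** copy is full-length
  (Normal(440, 25) residues, floored at 240) with a canonical GFRxGxxP
  instantiated at a uniform in-window position. Each **extra** copy keeps an
  RBS with probability 0.05; otherwise a Normal(130, 15) stretch (clamped to
  [30, length−160]) is removed from its N-terminus and the sequence is
  rejection-sampled until no in-window GxRxG remains. Under uniform residue
  composition a spurious GxRxG arises at ~(1/20)³ per offset, ≈ 1.2% per
  window, so rejection is cheap; it converts probabilistic labels into hard
  ones, which is what lets the end-to-end tests assert 100% recovery.
- Each genome receives background proteins (default 20; lengths
  Normal(300, 120) clamped to [50, 1200]) with no family hits, and with
  probability 0.10 a sub-threshold **decoy** (40–119 aa) that *does* carry a
  family hit, probing the length filter. Residue composition is uniform over
  the 20 standard amino acids.
- A fixed seed yields byte-identical output files.

Full-length mean 440 / truncation mean 130 are generator choices shaped to
give RBS⁻ copies a clearly shorter length distribution; they are not
measured values. What passing tests therefore show is that the *procedure*
(filtering, motif logic, classification, arithmetic, test statistics) is
correct, not that real proteomes match these distributions: real data add
non-uniform residue composition, family-annotation noise, fragmented gene
models, and genuine biological variation in TF length that the generator
does not emulate.

## Numerical and design choices

- Percent rounding: decimal half-up, two places (`Decimal`), not banker's
  rounding.
- Motif scanning slices the window prefix and scans with an overlapping
  regex; semantics are fixed by the position-by-position definition and
  verified against an independent brute-force scan in tests.
- Welch degrees of freedom via Welch–Satterthwaite (scipy); identical
  groups give t = 0, p = 1 within floating-point tolerance.
- Alignments involving J/U/O are scored by mapping those letters to X.
- All artifacts are written atomically (temp file + rename); the manifest
  records the resolved config, its SHA-256, package version, and input
  checksums, and re-running from the manifest reproduces identical outputs.
- Problem sizes in the test suite — 500-genome default cohorts, 1,000
  random sequences per pattern for the scan oracle, 200 short pairs for
  the alignment-enumeration oracle, one 15,575-genome shaped cohort — were
  chosen to keep the whole suite around ten seconds while leaving failure
  probabilities of the stochastic checks negligible.

## Known limitations

- The census trusts the hit table; it does not run the domain search
  itself (pyhmmer/rpsblast output can be ingested via the `hmmer-tbl` and
  `outfmt6` dialects).
- Identity percentages depend on aligner and scoring choices; values from
  other alignment tools on the same pairs will differ by a few points, so
  cross-tool comparisons should use the same scoring throughout.
- The generator does not simulate phylogeny, codon-level evolution, or
  taxonomic structure; cohort-level fractions are exchangeable across
  genomes by construction.
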