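# Methods

## Scope and model

`rrnaprobe` selects small pools of short antisense DNA oligos that deplete
ribosomal RNA by hybridization capture. The design model rests on three
empirical observations about capture probes: (i) depletion efficiency
correlates with the predicted melting temperature of the probe/target
hybrid, so probes should sit on local Tm maxima and above the hybridization
denaturation temperature; (ii) probes with stable self-structure (hairpins,
homodimers) or mutual structure (heterodimers within the pool) underperform;
(iii) probes sharing ≥16 contiguous bases with a non-target transcript risk
co-depleting it. Everything else — consensus building, masking, spacing — is
plumbing to make those criteria applicable to real, multi-variant,
repeat-containing targets.

## Hybrid melting temperature

The probe/target duplex is RNA/DNA, so the nearest-neighbor sum uses
stacking parameters measured for RNA/DNA hybrids (Sugimoto et al. 1995),
indexed on the RNA (target-site) strand 5'→3' and shipped as a plain-text
asset (`data/rna_dna_nn.tsv`; ΔH in kcal/mol, ΔS in cal/(mol·K),
initiation ΔH=1.9, ΔS=−3.9). The 1 M Na⁺ melting temperature is

    Tm[K] = ΔH·1000 / (ΔS + R·ln C_eff),  R = 1.987 cal/(mol·K).

**Concentration term.** The probe concentration default is 250 nM. The
effective concentration entering the logarithm is C_eff = C/`conc_divisor`
with divisor 4, the standard non-self-complementary two-strand convention
for excess probe; the divisor is exposed in `ThermoConfig` because the
total-strand convention (divisor 1) is also in circulation and either can
be reproduced exactly.

**Salt correction.** Sub-molar monovalent salt (default 300 mM Na⁺) is
corrected in reciprocal-temperature space with the GC-dependent formula of
Owczarzy et al. (2004):

    1/Tm([Na+]) = 1/Tm(1M) + (4.29·f_GC − 3.95)·10⁻⁵·ln[Na+]
                  + 9.40·10⁻⁶·ln²[Na+].

This form is exact at 1 M (both correction terms vanish) and lowers Tm for
all f_GC ≤ 0.9 at 0.3 M. The implementation is cross-checked in tests
against an independently written summation of the same published table and
against Biopython's implementation of the identical model (agreement to
10⁻⁶ °C).

## Hairpin and dimer screening

The pipeline needs pass/fail verdicts at fixed thresholds (hairpin ΔG₃₇ >
−3 kcal/mol; homo-/heterodimer ΔG₃₇ > −10 kcal/mol), not publication-grade
folding energies, so two documented approximations are used instead of a
partition function:

* **Hairpin:** scan all stem–loop configurations with stem ≥ 3 bp and loop
  ≥ 3 nt; a stem is scored as the sum of DNA/DNA nearest-neighbor ΔG₃₇
  stacking terms (Allawi & SantaLucia 1997 unified parameters,
  `data/dna_dna_nn.tsv`) plus a loop-length initiation penalty
  (`data/hairpin_loops.tsv`, linearly interpolated, Jacobson–Stockmayer
  ln-extrapolated beyond 30 nt). The minimum over configurations is
  reported.
* **Dimer:** scan all ungapped antiparallel offsets of the two strands;
  maximal runs of ≥2 complementary pairs contribute their stacking sum, one
  duplex-initiation penalty (+1.97 kcal/mol) is added per offset, and the
  minimum over offsets is reported. The construction is exactly symmetric
  in its arguments because the DNA/DNA ΔG₃₇ table is complement-symmetric.

When no qualifying structure exists the functions return a large positive
sentinel (+999 kcal/mol) rather than NaN, keeping threshold comparisons
total. Verdict-level agreement at the −3/−10 thresholds is tested against
an external thermodynamic folding implementation (ViennaRNA with its DNA
parameter set) on a seeded panel of strong-stem, perfect-duplex, and
structure-free sequences; on that panel the two implementations' ΔG values
track within ~1.5 kcal/mol and never disagree on a verdict. Internal
loops, bulges, coaxial stacking and Mg²⁺ effects are out of scope — the
thresholds sit far from the regime where those corrections flip a verdict
for ~30-mers.

## Consensus and masking

Variants of one target (annotated transcript variants, or homologs from
several organisms) are multiply aligned — by mafft `--auto` when available
(the standard tool at rRNA scale), else by a built-in progressive method
(UPGMA ordering of pairwise Needleman–Wunsch identities, then sequential
sequence-to-profile alignment with match +1 / mismatch −1 / gap −2 and free
end gaps) that is adequate for the near-identical inputs this tool
receives. Consensus rule, per column: rows in a terminal-gap state
(sequence not yet started/already ended) are ignored; any internal gap or
any disagreement among covering rows produces `N`; otherwise the agreed
base is emitted. Terminal gaps do **not** force `N` — a shorter variant
should not veto probes on the region it simply does not cover; only
internal gaps (true indels) do. Probes may never overlap an `N`, so the
design is automatically restricted to regions identical across all
variants; mismatch-tolerant cross-variant placement is deliberately
unsupported.

Low-complexity masking is a symmetric DUST-style scan: within every window
of ≤64 nt the triplet score 10·Σc_t(c_t−1)/2/(k−1) is computed
incrementally; when a window exceeds the threshold (default 20) the
smallest left-anchored suffix still exceeding it is masked, which keeps
unique sequence adjacent to a repeat out of the mask. Verdicts
(masked/unmasked) agree with NCBI dustmasker on repeat, poly-A and clean
fixtures; exact interval edges may differ by a few nt from the reference
perfect-interval algorithm, which is immaterial here because masks only
veto probe footprints. Lowercase input can optionally be honored as a
pre-computed mask.

Coordinates are 0-based half-open everywhere internally; output TSV/FASTA
headers state their own conventions (probe tables are 1-based inclusive,
BED is 0-based half-open).

## Candidate filters

All probe-sequence rules are applied to the antisense (probe) strand:
GC fraction within [0.40, 0.60]; no run of ≥5 identical nucleotides; no run
of ≥4 A anywhere; no run of ≥4 C within the first ⌈L/2⌉ positions (the
empirical single-molecule-FISH composition rules; the C-rule's restriction
to the 5' half follows that rule set's grammar). Threshold semantics are
strict-violation: values exactly at a bound pass, matching the "greater
than" phrasing of the ΔG thresholds. Candidates are annotated rather than
discarded — every enumerated placement carries its failure flags, so the
selection plot can show all possible placement sites. An optional
probe/target duplex ΔG₃₇ window (off by default) reproduces the legacy
hybridization-energy band filter (−36 to −28 kcal/mol) used by older FISH
probe designers.

## Off-target screen

The database contains one record per non-target spliced transcript and one
per intron with 40 nt of flanking sequence (so unprocessed transcripts are
also covered), built from a genome FASTA plus GFF3/GTF via gffutils/pyfaidx;
records of the targeted genes are excluded. Screening orientation: the
candidate's sense target-site sequence is aligned against records in their
annotated orientation only — probes capture RNA molecules, and antisense
transcription is represented by its own annotated transcripts.

Alignment is affine-gap Smith–Waterman with blastn-short scoring (match +1,
mismatch −3; a gap of length k costs 5 + 2k; N never matches). The
implementation vectorizes each query row along the subject and resolves the
within-row gap recurrence with a max-plus prefix scan, so it computes the
exact full-DP optimum — no seeding heuristic exists that could miss a hit.
(An exact-seed fast path was considered and rejected: an alignment of raw
score 16 can consist of 10+9 matches split by one mismatch and therefore
contain no 11-mer seed.) Tests verify equality with an independently
written quadratic DP on hundreds of random pairs.

Raw scores map to bitscores via the ungapped Karlin–Altschul statistics for
+1/−3 equal-frequency scoring, λ = 1.374 nats and K = 0.711, shipped as
constants and re-derived at load time by solving Σpᵢpⱼe^{λsᵢⱼ} = 1
(gapped statistics are approximated by the ungapped values, as standard for
short-query search). The removal cutoff is 32 bits: a 16-nt contiguous
perfect match scores 32.21 bits and is removed, a 15-nt match scores 30.23
bits and survives. An optional wrapper (`blastn_best_bits`) shells out to an
installed blastn with the matching short-query flags for cross-validation;
the internal screen never depends on it, but their flag decisions agree on
the planted-match fixtures. E-values are not used as a filter — the screen is
exhaustive, so a search-sensitivity cutoff would have nothing to prune, and
the decisive criterion is the bitscore.

## Peaks and selection

Among candidates surviving all filters and the screen, a candidate is a
**Tm peak** if its Tm is at least the k-th largest within the window of
surviving candidates whose starts lie within ±100 nt of its own
(k = ⌈0.05·window size⌉, ties included, so every window yields at least one
peak; window 200 nt and fraction 5% are configurable). This windowed-top-
fraction rule is the only peak criterion the design model states; flags are
verified against a brute-force per-candidate recount in tests.

**Even spacing.** "As evenly spaced as possible" is made concrete as
anchor-greedy assignment: ideal anchors pᵢ = (i − 0.5)·L/n for a target of
length L and requested set size n; anchors are filled left to right with
the nearest eligible peak (ties: higher Tm, then smaller start), where
eligible means flag-free, non-overlapping with already-selected probes, and
heterodimer ΔG₃₇ above the dimer threshold against each of them. If no
peak lies within L/(2n) of an anchor the nearest eligible non-peak
candidate is used and logged; an anchor with no eligible candidate is
skipped with a warning, returning a short (but valid) set rather than
failing. The greedy pass is deterministic, and on dense uniform fixtures it
attains the exhaustive-search optimum of total |start − anchor| deviation;
a global ILP over subsets was rejected as needless for n ≤ ~20 probes.
Heterodimer compatibility is enforced within the selected set during
selection (order-dependent), not across all candidate pairs — the
thresholds concern the pool that will actually be mixed.

Every returned set is re-audited independently (composition, structure
thresholds, Tm floor, pairwise overlap and heterodimer) and the pipeline
aborts if the audit ever disagrees with the selection — this audit also
runs on every test fixture.

## Synthetic fixtures

The generator produces the three input classes the pipeline consumes, all
deterministic from one integer seed via independent spawned child streams
(adding a fixture never perturbs another):

* **Targets** draw i.i.d. bases per region from a GC profile; the default
  profile alternates GC-rich (~0.55–0.62) and AT-rich (~0.40–0.45) blocks,
  emulating the core/expansion-segment GC contrast of real rRNA that
  produces Tm peaks. Real rRNA's phylogenetic covariation, modified
  nucleotides and secondary structure are *not* modeled — passing tests
  demonstrate the selection machinery, not biological performance.
* **Variants** apply substitutions/indels at per-site rates (defaults
  2×10⁻³ and 5×10⁻⁴, the magnitude of divergence between annotated rRNA
  repeat-unit variants), or scripted edits with an exact truth table.
* **Decoys** plant exact probe-site substrings of chosen lengths into
  random transcripts, resampling context until the best local-alignment
  score equals the planted length — the truth table then *is* the expected
  screen outcome. A toy genome writer wraps decoys into a single
  chromosome with GFF3 annotation (every third transcript intron-split) to
  exercise the database extractor.

Problem sizes used in the shipped tests and acceptance checks — 1.5–4-kb
targets, ≤20 decoys of ≤1.5 kb, 10–20-nt planted matches — were chosen as
the smallest sizes at which every behavior under test (regional Tm
structure, masking, screen boundary, even spacing at n = 5–10) is
expressed; rRNA-scale runs behave identically, only slower.

## Numerical and degenerate-input choices

* Sentinel for "no structure possible": +999 kcal/mol, never NaN.
* Quantile/threshold ties: peaks include ties at the k-th largest value;
  composition/thermo thresholds fail only on strict violation.
* Selection tie-breaks: anchor distance, then higher Tm, then smaller
  start — fully deterministic; reruns produce byte-identical bundles.
* Consensus of a single sequence is that sequence; empty alignments,
  out-of-bounds intervals, non-ACGT input and sub-2-nt duplexes raise
  typed errors rather than propagating garbage.
* A consensus shorter than `len_min` yields an empty candidate list with a
  warning, and an unfillable anchor yields a short probe set with a
  warning (CLI exit code 4 unless `--allow-short`).

## Known limitations

* ΔG estimates are screening heuristics; they rank and threshold, but do
  not reproduce, a full secondary-structure model.
* Cross-species design requires exact identity at probe sites (the N-mask
  consensus); mismatch-tolerant multi-species placement is out of scope.
* The off-target screen covers annotated transcripts and flanked introns,
  not unannotated genomic background.
* Karlin–Altschul statistics use the ungapped λ/K for the gapped search, a
  standard approximation that is exact for the contiguous-match boundary
  the cutoff is calibrated to.
* The built-in aligner is for small, near-identical inputs; diverged or
  many-sequence alignments should use the external aligner path.
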