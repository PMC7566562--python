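# rrnaprobe

Design of short, high-affinity antisense DNA probe pools for ribosomal RNA
depletion.

Ribosomal RNA dominates total-RNA samples (often >95% of reads), so RNA-seq
outside the poly(A) fraction needs an rRNA removal step. One cost-effective
strategy hybridizes a small pool of ~30-mer biotinylated antisense DNA oligos
to the rRNA and pulls the hybrids out on streptavidin beads. The oligos do
all the work, and picking them well matters: depletion efficiency tracks the
predicted melting temperature of the probe/target hybrid, while badly chosen
probes fold on themselves, dimerize, or drag down non-target transcripts.

`rrnaprobe` automates that probe selection for any organism with a sequenced
genome. Given one or more target transcripts (multiple annotated variants
and/or homologs from several species), it:

1. **builds a consensus** per target from a multiple alignment, replacing
   every mismatch or internal-gap column with `N` so probes bind all
   variants identically;
2. **masks low-complexity regions** with a windowed triplet-frequency
   (DUST-style) score;
3. **enumerates candidate probes** of 26–32 nt (configurable) and filters on
   sequence composition — GC in [40%, 60%], no run of ≥5 identical bases, no
   run of ≥4 A anywhere or ≥4 C in the first half of the probe;
4. **filters on thermodynamics** — hybrid Tm from the nearest-neighbor model
   with RNA/DNA stacking parameters,

   Tm = ΔH·1000 / (ΔS + R·ln(C/4)) at 1 M Na⁺, corrected to 300 mM Na⁺ in
   reciprocal-Tm space via 1/Tm([Na⁺]) = 1/Tm(1M) + (4.29·f_GC −
   3.95)·10⁻⁵·ln[Na⁺] + 9.40·10⁻⁶·ln²[Na⁺],

   requiring Tm ≥ 72 °C, hairpin ΔG₃₇ > −3 kcal/mol and homodimer ΔG₃₇ >
   −10 kcal/mol;
5. **screens for off-target binding**: every candidate's target site is
   Smith–Waterman-aligned (match +1, mismatch −3, gap 5 + 2k) against a
   database of all non-target spliced transcripts *and* introns with 40 nt
   of flanking sequence; candidates whose best Karlin–Altschul bitscore
   (λ = 1.374, K = 0.711) exceeds 32 bits — equivalently, any contiguous
   perfect match of ≥16 nt — are removed;
6. **selects the final set**: candidates in the top 5% of Tm within a 200-nt
   moving window are "peaks", and a greedy pass over n evenly spaced anchor
   positions picks the nearest eligible peak for each, enforcing non-overlap
   and a pairwise heterodimer ΔG₃₇ > −10 kcal/mol within the set.

Every stage is importable on its own, and a seeded synthetic-fixture module
generates rRNA-like targets, mutated variants and decoy transcriptomes so
the full workflow runs and tests itself without any downloads.

## Worked example

```bash
# generate a synthetic 2-kb rRNA-like target with variants and a decoy
# transcriptome, then design 5 probes against it
rrnaprobe fixtures --seed 11 --length 2000 --decoys 10 -o demo_fixtures

cat > demo.yaml <<'EOF'
design:
  probes_per_target: 5
targets:
  - id: ssu
    fasta: demo_fixtures/synthetic_rRNA_variants.fa
offtarget:
  enabled: true
  genome: demo_fixtures/genome.fa
  annotation: demo_fixtures/genes.gff3
EOF

rrnaprobe design -c demo.yaml -o demo_out
```

which prints

```
ssu: 5 probes (400 nt/probe)
```

and writes `demo_out/probes.tsv`:

```
# coordinates: 1-based, inclusive, on the consensus target
target_id  start  end   length  probe_seq                         tm_C   gc_fraction  dg_hairpin  dg_homodimer
ssu        155    183   29      AAGCTGCACGCGGCTCTTGGCTATGCCTT     80.06  0.586        -0.56       -9.54
ssu        586    617   32      GTTATGAGGTCGGGCGACAGGTGAGCAGAGGT  80.38  0.594        0.73        -7.89
ssu        1040   1066  27      GCTTTCAGCTCACAGCATGGGCTTGCT       81.05  0.556        -0.98       -9.88
ssu        1306   1337  32      GTTAGCTCCCAGGGTGTTAATTGGCATGCTGT  80.53  0.500        1.11        -9.35
ssu        1843   1874  32      CCTCGTGAACGCTACAGTAGCCAAGGCAACCC  76.46  0.594        -0.61       -9.16
```

Five probes, all with predicted hybrid Tm well above the 72 °C selection
floor, hairpin ΔG above −3 and homodimer ΔG above −10 kcal/mol, landing
within a probe length of the ideal anchors at 200/600/1000/1400/1800 —
one probe per 400 nt of target. The bundle also contains the full candidate
table (`candidates.tsv`, the data behind a position-vs-Tm selection plot
with "possible" and "selected" flags in `plot_data.tsv`), the off-target
report, consensus/mask/exclusion files, and `manifest.json` with per-stage
candidate counts (enumerated → composition → thermo → specificity → peaks →
selected, always non-increasing).

Other subcommands: `rrnaprobe db` (build the off-target transcript database
from genome + GFF3/GTF), `rrnaprobe screen` (screen an existing probe FASTA),
`rrnaprobe audit` (re-verify a probes.tsv against all filters),
`rrnaprobe fixtures` (synthetic data).

## Layout

- `src/rrnaprobe/thermo.py` — NN-model Tm, salt correction, hairpin/dimer ΔG
- `src/rrnaprobe/targets.py` — alignment, consensus N-masking, DUST masking
- `src/rrnaprobe/candidates.py` — enumeration, composition/thermo filters
- `src/rrnaprobe/offtarget.py` — transcript DB, Smith–Waterman, bitscores
- `src/rrnaprobe/selection.py` — Tm peaks, even-spacing selection, audits
- `src/rrnaprobe/synthetic.py` — seeded fixture generators
- `src/rrnaprobe/pipeline.py`, `cli.py` — run orchestration and CLI
- `docs/methods.md` — model details, parameter choices, limitations
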