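"""Seeded synthetic fixtures: rRNA-like targets, variants, decoy transcriptomes.

Everything the pipeline consumes can be generated here, deterministically
from one integer seed, so the whole design workflow is exercisable without
any downloads.  Three generators mirror the three kinds of real input:

* ``make_target`` - a target transcript with regional GC structure.  Real
  rRNA has GC-rich core segments and AT-rich expansion segments, which is
  what produces local Tm peaks; the generator draws each region's bases
  i.i.d. at a specified GC fraction.
* ``make_variants`` - transcript variants mutated from the target at given
  substitution/indel rates (or at scripted positions), with a ground-truth
  record for consensus assertions.
* ``make_decoys`` - a decoy transcriptome in which chosen probe target
  sites are planted as exact contiguous matches of specified lengths, with
  a truth table for screen-soundness assertions.  Planted-site context is
  resampled until the best local-alignment score against the source site
  equals the planted length, so a truth-table row fully determines the
  expected screen verdict.

Each generator consumes its own child stream of the master seed, so adding
one fixture never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .offtarget import ScoringScheme, sw_max_score

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureRecipe:
    """Parameters of one synthetic fixture family."""

    seed: int = 0
    target_length: int = 2000
    gc_profile: List[Tuple[Tuple[int, int], float]] = field(default_factory=list)
    n_variants: int = 3
    substitution_rate: float = 0.002
    indel_rate: float = 0.0005
    decoy_count: int = 20
    decoy_length: int = 1500
    planted_match_lengths: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if not self.gc_profile:
            # default: rRNA-like alternation of GC-rich core blocks and
            # AT-rich expansion-segment-like blocks
            L = self.target_length
            bounds = np.linspace(0, L, 9).astype(int)
            gcs = [0.55, 0.42, 0.62, 0.45, 0.58, 0.40, 0.60, 0.50]
            self.gc_profile = [
                ((int(bounds[i]), int(bounds[i + 1])), gcs[i % len(gcs)])
                for i in range(len(bounds) - 1)
            ]
        pos = 0
        for (s, e), gc in self.gc_profile:
            if s != pos or not (0.0 <= gc <= 1.0):
                raise ValueError("gc_profile regions must tile [0, L) in order")
            pos = e
        if pos != self.target_length:
            raise ValueError("gc_profile must cover the full target length")

    def streams(self) -> Dict[str, np.random.Generator]:
        """One independent child generator per fixture component."""
        root = np.random.SeedSequence(self.seed)
        names = ("target", "variants", "decoys", "extra")
        children = root.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def make_target(recipe: FixtureRecipe, target_id: str = "synthetic_rRNA") -> str:
    """One rRNA-like target sequence with the recipe's regional GC profile."""
    rng = recipe.streams()["target"]
    parts = [
        _random_seq(rng, e - s, gc) for (s, e), gc in recipe.gc_profile
    ]
    return "".join(parts)


@dataclass
class VariantTruth:
    substituted_positions: List[int]
    insertion_positions: List[Tuple[int, int]]  # (position, length)
    deletion_positions: List[Tuple[int, int]]


def make_variants(
    target_seq: str,
    recipe: FixtureRecipe,
    scripted_substitutions: Optional[Sequence[int]] = None,
    scripted_insertions: Optional[Sequence[Tuple[int, int]]] = None,
) -> Tuple[List[Tuple[str, str]], VariantTruth]:
    """Mutated copies of the target plus the ground truth of what changed.

    The first variant is always the unmutated target.  With scripted
    positions, exactly those edits are applied to the second variant
    (deterministic truth for consensus tests); otherwise each additional
    variant draws substitutions/indels at the recipe's per-site rates.
    """
    rng = recipe.streams()["variants"]
    variants: List[Tuple[str, str]] = [("variant_1", target_seq)]
    subs: set = set()
    ins: List[Tuple[int, int]] = []
    dels: List[Tuple[int, int]] = []

    if scripted_substitutions is not None or scripted_insertions is not None:
        seq = list(target_seq)
        for p in scripted_substitutions or []:
            seq[p] = _other_base(rng, seq[p])
            subs.add(p)
        for p, ln in sorted(scripted_insertions or [], reverse=True):
            seq[p:p] = list(_random_seq(rng, ln))
            ins.append((p, ln))
        variants.append(("variant_2", "".join(seq)))
    else:
        L = len(target_seq)
        for v in range(2, recipe.n_variants + 1):
            seq = list(target_seq)
            sub_pos = np.nonzero(rng.random(L) < recipe.substitution_rate)[0]
            for p in sub_pos:
                seq[p] = _other_base(rng, seq[p])
                subs.add(int(p))
            indel_pos = np.nonzero(rng.random(L) < recipe.indel_rate)[0]
            for p in sorted(indel_pos.tolist(), reverse=True):
                ln = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    seq[p:p] = list(_random_seq(rng, ln))
                    ins.append((p, ln))
                else:
                    del seq[p : p + ln]
                    dels.append((p, ln))
            variants.append((f"variant_{v}", "".join(seq)))
    truth = VariantTruth(sorted(subs), sorted(ins), sorted(dels))
    return variants, truth


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def make_decoys(
    probe_sites: Sequence[str],
    recipe: FixtureRecipe,
    scheme: ScoringScheme = ScoringScheme(),
    max_resample: int = 50,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Decoy transcriptome with planted exact matches and its truth table.

    ``probe_sites`` are sense target-site sequences.  For each entry of
    ``recipe.planted_match_lengths`` a decoy receives an exact contiguous
    substring of that length copied from the corresponding probe site
    (cycled); remaining decoys are pure random.  Context around a plant is
    resampled until the decoy's best Smith-Waterman score against the
    source site equals the planted length, so the truth table's
    ``match_len`` column is exactly the attainable raw score.

    Returns ([(decoy_id, sequence)], truth table with columns decoy_id,
    source_site_index, match_len, plant_start).
    """
    rng = recipe.streams()["decoys"]
    decoys: List[Tuple[str, str]] = []
    rows = []
    n_planted = len(recipe.planted_match_lengths)
    for d in range(recipe.decoy_count):
        decoy_id = f"decoy_{d + 1}"
        if d < n_planted and probe_sites:
            match_len = recipe.planted_match_lengths[d]
            site_idx = d % len(probe_sites)
            site = probe_sites[site_idx]
            if match_len > len(site):
                raise ValueError("planted_match_lengths exceed probe length")
            off = int(rng.integers(0, len(site) - match_len + 1))
            plant = site[off : off + match_len]
            for _ in range(max_resample):
                pos = int(rng.integers(0, recipe.decoy_length - match_len + 1))
                ctx = _random_seq(rng, recipe.decoy_length - match_len)
                seq = ctx[:pos] + plant + ctx[pos:]
                if sw_max_score(site, seq, scheme) == match_len * scheme.match:
                    break
            else:
                raise RuntimeError(
                    f"could not isolate a clean {match_len}-nt plant; "
                    "decoy context too short?"
                )
            decoys.append((decoy_id, seq))
            rows.append({"decoy_id": decoy_id, "source_site_index": site_idx,
                         "match_len": match_len, "plant_start": pos})
        else:
            decoys.append((decoy_id, _random_seq(rng, recipe.decoy_length)))
            rows.append({"decoy_id": decoy_id, "source_site_index": -1,
                         "match_len": 0, "plant_start": -1})
    truth = pd.DataFrame(rows)
    return decoys, truth


# ---------------------------------------------------------------------------
# Toy genome + annotation (for the transcript-database builder)
# ---------------------------------------------------------------------------

def make_genome_with_annotation(
    transcripts: Sequence[Tuple[str, str]],
    recipe: FixtureRecipe,
    intron_every: int = 3,
    intron_length: int = 120,
    spacer_length: int = 200,
) -> Tuple[str, str]:
    """Wrap transcripts into a single-chromosome genome and GFF3 annotation.

    Every ``intron_every``-th transcript is split in the middle by a random
    intron, so the extractor produces both spliced and intron_flanked
    records; spliced records always reproduce the input transcripts.
    Returns (genome FASTA text, GFF3 text).
    """
    rng = recipe.streams()["extra"]
    chrom = "chr_syn"
    pieces: List[str] = []
    gff: List[str] = ["##gff-version 3"]
    pos = 0

    def emit(seq: str) -> Tuple[int, int]:
        nonlocal pos
        start = pos
        pieces.append(seq)
        pos += len(seq)
        return start, pos

    for i, (tx_id, tseq) in enumerate(transcripts):
        emit(_random_seq(rng, spacer_length))
        gene_id = f"gene_{tx_id}"
        if intron_every and (i + 1) % intron_every == 0 and len(tseq) > 40:
            mid = len(tseq) // 2
            ex1_s, ex1_e = emit(tseq[:mid])
            _in_s, _in_e = emit(_random_seq(rng, intron_length))
            ex2_s, ex2_e = emit(tseq[mid:])
            gene_s, gene_e = ex1_s, ex2_e
            exons = [(ex1_s, ex1_e), (ex2_s, ex2_e)]
        else:
            ex_s, ex_e = emit(tseq)
            gene_s, gene_e = ex_s, ex_e
            exons = [(ex_s, ex_e)]
        gff.append(f"{chrom}\t.\tgene\t{gene_s + 1}\t{gene_e}\t.\t+\t.\t"
                   f"ID={gene_id}")
        gff.append(f"{chrom}\t.\tmRNA\t{gene_s + 1}\t{gene_e}\t.\t+\t.\t"
                   f"ID={tx_id};Parent={gene_id}")
        for k, (s, e) in enumerate(exons):
            gff.append(f"{chrom}\t.\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                       f"ID={tx_id}.exon{k + 1};Parent={tx_id}")
    emit(_random_seq(rng, spacer_length))
    genome = f">{chrom}\n"
    body = "".join(pieces)
    genome += "\n".join(body[i : i + 70] for i in range(0, len(body), 70))
    genome += "\n"
    return genome, "\n".join(gff) + "\n"


def write_fasta(records: Sequence[Tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fixture_bundle(recipe: FixtureRecipe, outdir: str | Path,
                         target_id: str = "synthetic_rRNA") -> Dict[str, Path]:
    """Generate and write a complete fixture set into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    target = make_target(recipe, target_id)
    variants, truth_v = make_variants(target, recipe)
    # plant decoys from probe-sized windows of the target itself
    sites = [target[i : i + 30] for i in
             range(100, len(target) - 130, max(1, len(target) // 8))]
    decoys, truth_d = make_decoys(sites, recipe)
    genome, gff = make_genome_with_annotation(decoys, recipe)
    paths = {
        "target": outdir / f"{target_id}.fa",
        "variants": outdir / f"{target_id}_variants.fa",
        "decoys": outdir / "decoys.fa",
        "decoy_truth": outdir / "decoy_truth.tsv",
        "genome": outdir / "genome.fa",
        "annotation": outdir / "genes.gff3",
    }
    write_fasta([(target_id, target)], paths["target"])
    write_fasta(variants, paths["variants"])
    write_fasta(decoys, paths["decoys"])
    truth_d.to_csv(paths["decoy_truth"], sep="\t", index=False)
    paths["genome"].write_text(genome)
    paths["annotation"].write_text(gff)
    log.info("fixture bundle written to %s", outdir)
    return paths
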