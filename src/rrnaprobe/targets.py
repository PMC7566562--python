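"""Consensus construction and masking of probe-design targets.

A target (for example one rRNA transcript) may be supplied as several
sequence variants — annotated transcript variants of one organism and/or
homologs from several organisms.  Variants are multiply aligned, and a
consensus over {A, C, G, T, N} is built in which every column showing a
mismatch or an internal gap becomes N.  Probes are later restricted to
N-free stretches, so the consensus confines the design to regions identical
across all variants.  Low-complexity regions of the consensus are then
masked with a windowed triplet-frequency (DUST-style) score so repetitive
sequence cannot attract probes.

Coordinates are 0-based, half-open everywhere in this package.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np

log = logging.getLogger(__name__)

GAP = "-"
_CONS_ALPHABET = set("ACGTN")


class AlignerNotFoundError(RuntimeError):
    """An external aligner was requested but its executable is missing."""


@dataclass
class TargetSpec:
    """One design target and its input variants."""

    target_id: str
    variant_seqs: List[Tuple[str, str]]
    exclusion_intervals: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variant_seqs:
            raise ValueError("a target needs at least one variant sequence")
        labels = [lab for lab, _ in self.variant_seqs]
        if len(set(labels)) != len(labels):
            raise ValueError("variant labels must be unique")
        if any(not seq for _, seq in self.variant_seqs):
            raise ValueError("empty variant sequence")


@dataclass
class MultipleAlignment:
    rows: List[Tuple[str, str]]

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def __post_init__(self) -> None:
        if any(len(r) != self.ncol for _, r in self.rows):
            raise ValueError("alignment rows differ in length")

    def degapped(self, i: int) -> str:
        return self.rows[i][1].replace(GAP, "")


@dataclass
class ConsensusTarget:
    """Per-target consensus with mask and exclusion intervals."""

    target_id: str
    sequence: str
    mask_intervals: List[Tuple[int, int]] = field(default_factory=list)
    exclusion_intervals: List[Tuple[int, int]] = field(default_factory=list)
    n_variants: int = 1

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _CONS_ALPHABET
        if bad:
            raise ValueError(f"consensus contains invalid characters: {sorted(bad)}")
        n = len(self.sequence)
        for kind, ivs in (("mask", self.mask_intervals),
                          ("exclusion", self.exclusion_intervals)):
            for s, e in ivs:
                if not (0 <= s < e <= n):
                    raise ValueError(f"{kind} interval ({s}, {e}) outside [0, {n})")

    def blocked_positions(self) -> np.ndarray:
        """Boolean array: positions unusable for probe footprints
        (N, masked, or excluded)."""
        blocked = np.frombuffer(self.sequence.encode(), dtype=np.uint8) == ord("N")
        blocked = blocked.copy()
        for s, e in self.mask_intervals + self.exclusion_intervals:
            blocked[s:e] = True
        return blocked


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _pairwise_nw(a: str, b: str, match: int = 1, mismatch: int = -1,
                 gap: int = -2) -> Tuple[str, str]:
    """Pairwise Needleman-Wunsch with linear gap penalty and free end gaps
    (terminal gaps cost nothing, matching how variant sequences of different
    extents should overlay); returns gapped rows."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    sub = np.where(
        np.frombuffer(a.encode(), np.uint8)[:, None]
        == np.frombuffer(b.encode(), np.uint8)[None, :],
        match, mismatch,
    )
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + gap
        row = score[i]
        prev = row[0]
        for j in range(1, m + 1):
            prev = max(diag[j - 1], up[j - 1], prev + gap)
            row[j] = prev
    # best cell on the bottom/right border starts the traceback
    border = [(int(score[n, j]), n, j) for j in range(m + 1)]
    border += [(int(score[i, m]), i, m) for i in range(n + 1)]
    _, bi, bj = max(border, key=lambda t: (t[0], t[1] + t[2]))
    out_a = [a[bi:] , GAP * (m - bj)]
    out_b = [GAP * (n - bi), b[bj:]]
    rev_a: List[str] = []
    rev_b: List[str] = []
    i, j = bi, bj
    while i > 0 and j > 0:
        if score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            rev_a.append(a[i - 1]); rev_b.append(b[j - 1]); i -= 1; j -= 1
        elif score[i, j] == score[i - 1, j] + gap:
            rev_a.append(a[i - 1]); rev_b.append(GAP); i -= 1
        else:
            rev_a.append(GAP); rev_b.append(b[j - 1]); j -= 1
    head_a = a[:i] + GAP * j
    head_b = GAP * i + b[:j]
    ra = head_a + "".join(reversed(rev_a)) + "".join(out_a)
    rb = head_b + "".join(reversed(rev_b)) + "".join(out_b)
    return ra, rb


def _seq_to_profile_nw(seq: str, profile_rows: List[str], match: int = 1,
                       mismatch: int = -1, gap: int = -2) -> Tuple[str, List[str]]:
    """Align one sequence against a gapped profile (mean-score columns)."""
    ncol = len(profile_rows[0])
    col_chars = [[r[c] for r in profile_rows if r[c] != GAP] for c in range(ncol)]
    n, m = len(seq), ncol

    def col_score(x: str, c: int) -> float:
        chars = col_chars[c]
        if not chars:
            return 0.0
        return sum(match if ch == x else mismatch for ch in chars) / len(chars)

    score = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + col_score(seq[i - 1], j - 1),
                score[i - 1, j] + gap,
                score[i, j - 1] + gap,
            )
    border = [(score[n, j], n, j) for j in range(m + 1)]
    border += [(score[i, m], i, m) for i in range(n + 1)]
    _, bi, bj = max(border, key=lambda t: (t[0], t[1] + t[2]))
    new_row: List[str] = []
    insertions: List[int] = []  # profile column slots where seq inserts occur
    for k in range(n, bi, -1):  # unaligned seq tail: insert after last column
        new_row.append(seq[k - 1]); insertions.append(m)
    new_row.append(GAP * (m - bj))
    i, j = bi, bj
    while i > 0 and j > 0:
        if np.isclose(
            score[i, j], score[i - 1, j - 1] + col_score(seq[i - 1], j - 1)
        ):
            new_row.append(seq[i - 1]); i -= 1; j -= 1
        elif np.isclose(score[i, j], score[i - 1, j] + gap):
            new_row.append(seq[i - 1]); insertions.append(j); i -= 1
        else:
            new_row.append(GAP); j -= 1
    new_row.append(GAP * j)
    for k in range(i, 0, -1):  # unaligned seq head: insert before first column
        new_row.append(seq[k - 1]); insertions.append(0)
    new_row.reverse()
    new_row = [c for chunk in new_row for c in chunk]
    # expand the profile where the new sequence inserted columns
    if insertions:
        ins_at = sorted(insertions)
        expanded = []
        for r in profile_rows:
            out = []
            k = 0
            for c in range(ncol + 1):
                while k < len(ins_at) and ins_at[k] == c:
                    out.append(GAP); k += 1
                if c < ncol:
                    out.append(r[c])
            expanded.append("".join(out))
        profile_rows = expanded
    # new_row is already in expanded-column order: every insertion created
    # exactly one new column, in traceback order
    return "".join(new_row), profile_rows


def _identity(a: str, b: str) -> float:
    ra, rb = _pairwise_nw(a, b)
    same = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
    return same / max(len(a), len(b))


def _upgma_order(seqs: Sequence[str]) -> List[int]:
    """Leaf order of a UPGMA tree over pairwise NW identity distances."""
    k = len(seqs)
    if k <= 2:
        return list(range(k))
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = 1.0 - _identity(seqs[i], seqs[j])
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    return list(hierarchy.leaves_list(link))


def _align_external(spec: TargetSpec, executable: str) -> MultipleAlignment:
    exe = shutil.which(executable)
    if exe is None:
        raise AlignerNotFoundError(
            f"external aligner '{executable}' not found on PATH; install it or "
            "set aligner_mode='builtin'"
        )
    with tempfile.TemporaryDirectory() as td:
        fasta = Path(td) / "variants.fa"
        with open(fasta, "w") as fh:
            for lab, seq in spec.variant_seqs:
                fh.write(f">{lab}\n{seq}\n")
        res = subprocess.run(
            [exe, "--auto", "--quiet", str(fasta)],
            capture_output=True, text=True, check=True,
        )
    rows: List[Tuple[str, str]] = []
    label = None
    chunks: List[str] = []
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            if label is not None:
                rows.append((label, "".join(chunks).upper()))
            label = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if label is not None:
        rows.append((label, "".join(chunks).upper()))
    order = {lab: i for i, (lab, _) in enumerate(spec.variant_seqs)}
    rows.sort(key=lambda r: order[r[0]])
    return MultipleAlignment(rows)


def align_variants(spec: TargetSpec, aligner_mode: str = "auto",
                   external_exe: str = "mafft") -> MultipleAlignment:
    """Multiply align the variants of one target.

    ``aligner_mode``: 'external' shells out to an installed aligner (mafft by
    default, the standard choice for rRNA-scale inputs); 'builtin' uses the
    package's progressive pairwise method (adequate for small inputs);
    'auto' prefers external when the executable is present.
    """
    if len(spec.variant_seqs) == 1:
        lab, seq = spec.variant_seqs[0]
        return MultipleAlignment([(lab, seq.upper())])
    if aligner_mode not in {"auto", "external", "builtin"}:
        raise ValueError(f"unknown aligner_mode {aligner_mode!r}")
    if aligner_mode == "external" or (
        aligner_mode == "auto" and shutil.which(external_exe)
    ):
        return _align_external(spec, external_exe)

    labels = [lab for lab, _ in spec.variant_seqs]
    seqs = [seq.upper() for _, seq in spec.variant_seqs]
    order = _upgma_order(seqs)
    first = order[0]
    profile = [seqs[first]]
    row_ids = [first]
    for idx in order[1:]:
        new_row, profile = _seq_to_profile_nw(seqs[idx], profile)
        profile.append(new_row)
        row_ids.append(idx)
    aligned = {row_ids[i]: profile[i] for i in range(len(row_ids))}
    aln = MultipleAlignment([(labels[i], aligned[i]) for i in range(len(seqs))])
    for i in range(len(seqs)):
        if aln.degapped(i) != seqs[i]:
            raise AssertionError("builtin alignment corrupted a variant sequence")
    return aln


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def build_consensus(aln: MultipleAlignment, target_id: str = "target",
                    exclusion_intervals: Iterable[Tuple[int, int]] = ()) -> ConsensusTarget:
    """Collapse a multiple alignment into an N-masked consensus.

    Per column: rows whose sequence has not yet started or has already ended
    (terminal gaps) are ignored; if any covering row has an (internal) gap or
    the covering rows disagree, the column becomes N; otherwise the agreed
    base is emitted.  Columns gapped in every row are dropped.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    mat = [row for _, row in aln.rows]
    ncol = aln.ncol
    starts = [len(r) - len(r.lstrip(GAP)) for r in mat]
    ends = [len(r.rstrip(GAP)) for r in mat]
    out: List[str] = []
    for c in range(ncol):
        bases = set()
        internal_gap = False
        for r, row in enumerate(mat):
            if c < starts[r] or c >= ends[r]:
                continue  # terminal gap: row does not cover this column
            ch = row[c]
            if ch == GAP:
                internal_gap = True
            else:
                bases.add(ch)
        if not bases and not internal_gap:
            continue  # gap in all rows
        if internal_gap or len(bases) != 1 or not bases <= set("ACGT"):
            out.append("N")
        else:
            out.append(next(iter(bases)))
    seq = "".join(out)
    # exclusion intervals are given on consensus coordinates
    excl = sorted((int(s), int(e)) for s, e in exclusion_intervals)
    return ConsensusTarget(
        target_id=target_id,
        sequence=seq,
        exclusion_intervals=excl,
        n_variants=len(aln.rows),
    )


# ---------------------------------------------------------------------------
# Low-complexity masking (symmetric DUST-style triplet score)
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def dust_intervals(seq: str, window: int = 64, score_threshold: float = 20.0
                   ) -> List[Tuple[int, int]]:
    """Low-complexity intervals by a symmetric DUST-style triplet scan.

    For every subwindow [i, j) of up to ``window`` nt the score is
    10 * sum_t c_t(c_t-1)/2 / (k-1) over triplet counts c_t (k triplets in
    the subwindow); subwindows whose score exceeds ``score_threshold`` are
    masked.  Triplets containing N are skipped.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    n = len(seq)
    enc = np.full(n, -1, dtype=np.int64)
    for b, v in zip("ACGT", range(4)):
        enc[np.frombuffer(seq.encode(), np.uint8) == ord(b)] = v
    trip = np.full(max(n - 2, 0), -1, dtype=np.int64)
    for k in range(len(trip)):
        if enc[k] >= 0 and enc[k + 1] >= 0 and enc[k + 2] >= 0:
            trip[k] = 16 * enc[k] + 4 * enc[k + 1] + enc[k + 2]
    found: List[Tuple[int, int]] = []
    counts = np.zeros(64, dtype=np.int64)
    for i in range(n):
        counts[:] = 0
        ssum = 0
        ntrip = 0
        k_first = -1
        jmax = min(i + window - 2, len(trip))
        for k in range(i, jmax):
            t = trip[k]
            if t < 0:
                continue
            ssum += counts[t]
            counts[t] += 1
            ntrip += 1
            if ntrip >= 2 and 10.0 * ssum / (ntrip - 1) > score_threshold:
                k_first = k
                break
        if k_first < 0:
            continue
        # tighten the left edge: of all left anchors l in [i, k_first] whose
        # window [l, k_first+3) still exceeds the threshold, keep the largest,
        # so unique sequence next to a repeat is not swept into the mask
        left = i
        for k in range(i, k_first):
            t = trip[k]
            if t >= 0:
                counts[t] -= 1
                ssum -= counts[t]
                ntrip -= 1
            if ntrip >= 2 and 10.0 * ssum / (ntrip - 1) > score_threshold:
                left = k + 1
        found.append((left, k_first + 3))
    return _merge_intervals(found)


def mask_low_complexity(cons: ConsensusTarget, window: int = 64,
                        score_threshold: float = 20.0) -> ConsensusTarget:
    """Return a copy of the consensus with DUST-style mask intervals set.

    Masked positions behave like Ns for candidate placement.  Idempotent:
    re-masking an already-masked consensus reproduces the same intervals.
    """
    ivs = dust_intervals(cons.sequence, window=window,
                         score_threshold=score_threshold)
    merged = _merge_intervals(list(cons.mask_intervals) + ivs)
    if merged:
        log.info("%s: masked %d low-complexity interval(s), %d nt total",
                 cons.target_id, len(merged), sum(e - s for s, e in merged))
    return replace(cons, mask_intervals=merged)


# ---------------------------------------------------------------------------
# FASTA / BED I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, honor_lowercase_mask: bool = False
               ) -> List[Tuple[str, str, List[Tuple[int, int]]]]:
    """Read a FASTA file; returns (label, uppercase sequence, premask
    intervals).  Lowercase stretches become premask intervals when
    ``honor_lowercase_mask`` is set."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        premask: List[Tuple[int, int]] = []
        if honor_lowercase_mask:
            start = None
            for i, ch in enumerate(raw + "X"):
                if ch.islower() and start is None:
                    start = i
                elif not ch.islower() and start is not None:
                    premask.append((start, i))
                    start = None
        out.append((rec.id, raw.upper(), premask))
    return out


def write_consensus_fasta(cons: ConsensusTarget, path: str | Path) -> None:
    """Write the consensus; masked regions are lowercased."""
    seq = list(cons.sequence)
    for s, e in cons.mask_intervals:
        for i in range(s, e):
            seq[i] = seq[i].lower()
    with open(path, "w") as fh:
        fh.write(f">{cons.target_id}\n")
        body = "".join(seq)
        for i in range(0, len(body), 70):
            fh.write(body[i : i + 70] + "\n")


def write_bed(intervals: Iterable[Tuple[int, int]], chrom: str,
              path: str | Path, name: str = "region") -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(sorted(intervals)):
            fh.write(f"{chrom}\t{s}\t{e}\t{name}_{i}\n")
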