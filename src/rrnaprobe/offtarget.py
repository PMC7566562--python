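"""Off-target specificity screen against a non-target transcript database.

The database holds the sequences a probe could cross-hybridize with: every
spliced transcript, plus every intron with a stretch of flanking sequence
(so partially processed transcripts are covered too).  Records of the
targeted genes (the rRNA genes themselves) are excluded.

Each candidate's sense target-site sequence (the reverse complement of the
probe) is locally aligned against every record with short-query nucleotide
scoring (match +1, mismatch -3, gap open 5, gap extend 2; a gap of length k
costs open + k*extend).  Raw Smith-Waterman scores are converted to
bitscores with the ungapped Karlin-Altschul statistics for this scoring
scheme,

    bits = (lambda * S - ln K) / ln 2,    lambda = 1.374, K = 0.711,

and any candidate whose best bitscore exceeds the cutoff (32 bits, the
score of a 16-nt contiguous perfect match; a 15-nt match scores ~30.2) is
flagged.  The screen is exhaustive - every candidate against every record -
with the inner alignment vectorized along the subject, so no heuristic
seeding step can miss a hit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .candidates import FLAG_OFFTARGET, ProbeCandidate

log = logging.getLogger(__name__)

_LN2 = math.log(2.0)


def _solve_lambda(match: float, mismatch: float) -> float:
    """Ungapped Karlin-Altschul lambda for equal base frequencies: the
    positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1."""
    from scipy.optimize import brentq

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring and bitscore statistics (blastn-short style)."""

    match: int = 1
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lambda_: float = 1.374  # nats per raw-score unit
    K: float = 0.711
    bitscore_cutoff: float = 32.0

    def __post_init__(self) -> None:
        if not self.lambda_ > 0:
            raise ValueError("lambda_ must be positive")
        if not (0 < self.K < 1):
            raise ValueError("K must be in (0, 1)")
        # cross-check the shipped lambda against the Karlin-Altschul identity
        exact = _solve_lambda(self.match, self.mismatch)
        if abs(exact - self.lambda_) > 5e-3:
            raise ValueError(
                f"lambda_={self.lambda_} inconsistent with scoring "
                f"(+{self.match}/{self.mismatch}): expected ~{exact:.4f}"
            )


def bitscore(raw: float, s: ScoringScheme = ScoringScheme()) -> float:
    """Normalized bitscore of a raw local-alignment score."""
    return (s.lambda_ * raw - math.log(s.K)) / _LN2


def min_flagged_match_length(s: ScoringScheme = ScoringScheme()) -> int:
    """Smallest contiguous perfect-match length whose bitscore exceeds the
    cutoff (16 nt under the default scheme)."""
    n = 1
    while bitscore(n * s.match, s) <= s.bitscore_cutoff:
        n += 1
    return n


# ---------------------------------------------------------------------------
# Transcript database
# ---------------------------------------------------------------------------

@dataclass
class TranscriptRecord:
    record_id: str
    gene_id: str
    kind: str  # 'spliced' or 'intron_flanked'
    sequence: str
    flank_nt: int = 0


@dataclass
class TranscriptDB:
    records: List[TranscriptRecord] = field(default_factory=list)
    excluded_gene_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.gene_id in self.excluded_gene_ids:
                raise ValueError(
                    f"record {r.record_id} belongs to excluded gene {r.gene_id}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, path: str | Path,
                   excluded_gene_ids: Iterable[str] = ()) -> "TranscriptDB":
        """Build a database of spliced records directly from a transcript
        FASTA (record id doubles as gene id unless given as gene|transcript)."""
        from Bio import SeqIO

        excluded = set(excluded_gene_ids)
        recs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            gene = rec.id.split("|")[0]
            if gene in excluded:
                continue
            recs.append(TranscriptRecord(rec.id, gene, "spliced",
                                         str(rec.seq).upper()))
        return cls(records=recs, excluded_gene_ids=excluded)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.record_id} gene={r.gene_id} kind={r.kind}\n")
                for i in range(0, len(r.sequence), 70):
                    fh.write(r.sequence[i : i + 70] + "\n")


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def extract_transcript_db(
    genome_fasta: str | Path,
    annotation: str | Path,
    flank_nt: int = 40,
    excluded_gene_ids: Iterable[str] = (),
) -> TranscriptDB:
    """Extract spliced transcripts and flanked introns from genome + GFF3/GTF.

    One record per transcript (exons concatenated in transcript order;
    minus-strand transcripts reverse-complemented) and one record per intron
    (the intron plus ``flank_nt`` nt of flanking sequence on each side,
    clipped at chromosome ends, reverse-complemented for minus-strand
    transcripts).  Transcripts of excluded (target) genes are omitted.
    """
    import gffutils
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(
        str(annotation), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    excluded = set(excluded_gene_ids)
    records: List[TranscriptRecord] = []

    # group exons by parent transcript; accept both GFF3 (Parent) and GTF
    exons_by_tx: Dict[str, List] = {}
    tx_meta: Dict[str, Tuple[str, str, str]] = {}  # tx -> (chrom, strand, gene)
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get(
            "transcript_id") or []
        for tx_id in parents:
            exons_by_tx.setdefault(tx_id, []).append(exon)
            if tx_id not in tx_meta:
                gene = _gene_of(db, exon, tx_id)
                tx_meta[tx_id] = (exon.seqid, exon.strand, gene)

    for tx_id in sorted(exons_by_tx):
        chrom, strand, gene = tx_meta[tx_id]
        if gene in excluded:
            continue
        exons = sorted(exons_by_tx[tx_id], key=lambda e: e.start)
        chrom_len = len(genome[chrom])
        for e in exons:
            if e.end > chrom_len:
                raise ValueError(
                    f"exon {e.start}-{e.end} of {tx_id} beyond end of "
                    f"{chrom} ({chrom_len} nt)"
                )
        # gffutils coordinates are 1-based inclusive
        spliced = "".join(genome[chrom][e.start - 1 : e.end] for e in exons)
        if strand == "-":
            spliced = _revcomp(spliced)
        records.append(TranscriptRecord(tx_id, gene, "spliced", spliced))
        for left, right in zip(exons, exons[1:]):
            i_start = left.end  # 0-based start of intron
            i_end = right.start - 1  # 0-based end (exclusive)
            if i_end <= i_start:
                continue
            s = max(0, i_start - flank_nt)
            e = min(chrom_len, i_end + flank_nt)
            iv = genome[chrom][s:e]
            if strand == "-":
                iv = _revcomp(iv)
            records.append(TranscriptRecord(
                f"{tx_id}:intron:{i_start}-{i_end}", gene, "intron_flanked",
                iv, flank_nt=flank_nt,
            ))
    log.info("transcript db: %d records (%d spliced, %d intron) from %s",
             len(records),
             sum(r.kind == "spliced" for r in records),
             sum(r.kind == "intron_flanked" for r in records), annotation)
    return TranscriptDB(records=records, excluded_gene_ids=excluded)


def _gene_of(db, exon, tx_id: str) -> str:
    for key in ("gene_id", "gene"):
        if key in exon.attributes:
            return exon.attributes[key][0]
    try:
        parent = db[tx_id]
        for key in ("Parent", "gene_id", "gene"):
            if key in parent.attributes:
                return parent.attributes[key][0]
    except Exception:
        pass
    return tx_id


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    enc = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    return enc


def sw_max_score(query: str, subject: str, s: ScoringScheme = ScoringScheme()
                 ) -> int:
    """Best affine-gap Smith-Waterman raw score (score only, vectorized).

    Rows iterate over the (short) query; the within-row gap recurrence is
    resolved with a max-plus prefix scan, so each row is O(len(subject))
    numpy work.  N (or any non-ACGT character) never matches.
    """
    if not query or not subject:
        return 0
    q = _encode(query)
    t = _encode(subject)
    acgt = np.isin(t, np.frombuffer(b"ACGT", np.uint8))
    m = len(t)
    open_ = s.gap_open
    ext = s.gap_extend
    jidx = np.arange(1, m + 1)
    h_prev = np.zeros(m + 1)
    f = np.full(m + 1, -np.inf)
    best = 0.0
    for qc in q:
        match_vec = np.where((t == qc) & acgt & (qc in _ACGT_SET),
                             s.match, s.mismatch)
        f = np.maximum(f - ext, h_prev - open_ - ext)
        h_nogap = np.maximum(0.0, f)
        h_nogap[1:] = np.maximum(h_nogap[1:], h_prev[:-1] + match_vec)
        g = h_nogap + np.concatenate([[0.0], ext * jidx])
        e = np.full(m + 1, -np.inf)
        e[1:] = np.maximum.accumulate(g[:-1]) - open_ - ext * jidx
        h = np.maximum(h_nogap, e)
        best = max(best, float(h.max()))
        h_prev = h
    return int(round(best))


_ACGT_SET = set(np.frombuffer(b"ACGT", np.uint8).tolist())


def local_align(query: str, subject: str, s: ScoringScheme = ScoringScheme()
                ) -> Tuple[int, Tuple[int, int], Tuple[int, int]]:
    """Affine-gap Smith-Waterman with traceback.

    Returns (raw score, query span [qs, qe), subject span [ss, se)) of one
    optimal local alignment.  Plain quadratic DP; used for hit reporting on
    the few (candidate, record) pairs that matter.
    """
    if not query or not subject:
        return 0, (0, 0), (0, 0)
    n, m = len(query), len(subject)
    q = _encode(query)
    t = _encode(subject)
    NEG = -1 << 30
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        qi_ok = qi in _ACGT_SET
        for j in range(1, m + 1):
            sub = s.match if (qi_ok and qi == t[j - 1] and t[j - 1] in _ACGT_SET) \
                else s.mismatch
            E[i, j] = max(E[i, j - 1] - s.gap_extend,
                          H[i, j - 1] - s.gap_open - s.gap_extend)
            F[i, j] = max(F[i - 1, j] - s.gap_extend,
                          H[i - 1, j] - s.gap_open - s.gap_extend)
            H[i, j] = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            if H[i, j] > best:
                best, bi, bj = int(H[i, j]), i, j
    # traceback
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = s.match if (q[i - 1] == t[j - 1] and q[i - 1] in _ACGT_SET) \
            else s.mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            i, j = i - 1, j - 1
        elif H[i, j] == E[i, j]:
            k = j - 1
            while k > 0 and E[i, j] != H[i, k] - s.gap_open - s.gap_extend * (j - k):
                k -= 1
            j = k
        else:
            k = i - 1
            while k > 0 and F[i, j] != H[k, j] - s.gap_open - s.gap_extend * (i - k):
                k -= 1
            i = k
    return best, (i, bi), (j, bj)


@dataclass
class OffTargetHit:
    candidate: ProbeCandidate
    record_id: str
    raw_score: int
    bitscore: float
    query_span: Tuple[int, int]
    subject_span: Tuple[int, int]


def screen_candidates(
    cands: Sequence[ProbeCandidate],
    db: TranscriptDB,
    s: ScoringScheme = ScoringScheme(),
    report_all_hits: bool = False,
) -> List[OffTargetHit]:
    """Annotate candidates with their best off-target bitscore and flag
    those exceeding the cutoff.

    The query is each candidate's sense target-site sequence (the reverse
    complement of the probe), matching how the probe's complement would read
    along a transcribed off-target RNA; records are searched in their
    annotated orientation only.  Returns the hits (flagged candidates; all
    best hits when ``report_all_hits``).
    """
    hits: List[OffTargetHit] = []
    for cand in cands:
        best_raw = 0
        best_rec: Optional[TranscriptRecord] = None
        for rec in db.records:
            raw = sw_max_score(cand.target_site_seq, rec.sequence, s)
            if raw > best_raw:
                best_raw, best_rec = raw, rec
        if best_rec is None:
            cand.offtarget_max_bits = None
            continue
        bits = bitscore(best_raw, s)
        cand.offtarget_max_bits = bits
        cand.offtarget_best_record = best_rec.record_id
        flagged = bits > s.bitscore_cutoff
        if flagged:
            cand.filter_flags.add(FLAG_OFFTARGET)
        if flagged or report_all_hits:
            raw2, qspan, sspan = local_align(cand.target_site_seq,
                                             best_rec.sequence, s)
            hits.append(OffTargetHit(cand, best_rec.record_id, best_raw,
                                     bits, qspan, sspan))
    n_flag = sum(1 for c in cands if FLAG_OFFTARGET in c.filter_flags)
    log.info("off-target screen: %d/%d candidates flagged (cutoff %.1f bits)",
             n_flag, len(cands), s.bitscore_cutoff)
    return hits


def blastn_best_bits(queries: Dict[str, str], db_records: Dict[str, str],
                     evalue: float = 50.0) -> Dict[str, float]:
    """Cross-validation wrapper around an installed blastn.

    Runs ``blastn -task blastn-short -dust no -soft_masking false`` on the
    given query/database sequences and returns the best reported bitscore
    per query id (queries with no hit are absent).  Purely optional: the
    internal screen never depends on it.
    """
    import shutil
    import subprocess
    import tempfile

    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("blastn/makeblastdb not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        qf = Path(td) / "q.fa"
        dbf = Path(td) / "db.fa"
        qf.write_text("".join(f">{k}\n{v}\n" for k, v in queries.items()))
        dbf.write_text("".join(f">{k}\n{v}\n" for k, v in db_records.items()))
        subprocess.run(["makeblastdb", "-in", str(dbf), "-dbtype", "nucl",
                        "-out", str(Path(td) / "db")],
                       check=True, capture_output=True)
        res = subprocess.run(
            ["blastn", "-task", "blastn-short", "-dust", "no",
             "-soft_masking", "false", "-evalue", str(evalue),
             "-query", str(qf), "-db", str(Path(td) / "db"),
             "-outfmt", "6 qseqid bitscore"],
            check=True, capture_output=True, text=True)
    best: Dict[str, float] = {}
    for line in res.stdout.splitlines():
        qid, bits = line.split("\t")
        best[qid] = max(best.get(qid, 0.0), float(bits))
    return best
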