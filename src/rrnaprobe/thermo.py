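"""Nearest-neighbor thermodynamics for antisense probe design.

Melting temperature of the probe/target hybrid is computed with the
nearest-neighbor (NN) model using stacking parameters measured for RNA/DNA
hybrid duplexes, with the duplex summed on the RNA (target) strand 5'->3'.
Tm at 1 M Na+ is

    Tm = dH * 1000 / (dS + R * ln(C_eff))        [kelvin]

with dH in kcal/mol, dS in cal/(mol*K), R the gas constant in cal/(mol*K)
and C_eff the effective strand concentration in mol/L.  Sub-molar monovalent
salt is corrected in reciprocal-Tm space with the GC-dependent formula of
Owczarzy et al. (2004):

    1/Tm([Na+]) = 1/Tm(1M) + (4.29*fGC - 3.95)*1e-5*ln[Na+]
                            + 9.40e-6*ln^2[Na+]

Hairpin and dimer free energies at 37 C are screening heuristics, not a
partition function: a stem-loop scan (hairpins) and an ungapped antiparallel
offset scan (dimers) scored with DNA/DNA NN dG37 stacking plus loop/initiation
penalties.  They exist to apply pass/fail thresholds (-3 kcal/mol for
hairpins, -10 kcal/mol for dimers), not to reproduce a folding program's
exact numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Tuple

import numpy as np

GAS_CONSTANT = 1.987  # cal/(mol*K)
ZERO_C_IN_K = 273.15
DG_TEMP_K = 310.15  # 37 C

#: Sentinel returned when no base-paired structure is geometrically possible.
#: Large and positive so that every "dG > threshold" comparison passes.
NO_STRUCTURE_DG = 999.0

DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside the required alphabet."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (ACGTN; N maps to N)."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C over the full sequence length."""
    if not seq:
        raise InvalidSequenceError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _check_acgt(seq: str, min_len: int = 1) -> str:
    seq = seq.upper()
    if len(seq) < min_len:
        raise InvalidSequenceError(
            f"sequence length {len(seq)} below minimum {min_len}"
        )
    bad = set(seq) - set(_BASES)
    if bad:
        raise InvalidSequenceError(f"non-ACGT characters: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NNTable:
    """Nearest-neighbor dH/dS parameter set.

    ``pair_params`` maps a dinucleotide step (on the sense/target strand,
    5'->3') to (dH kcal/mol, dS cal/(mol*K)).  ``init_dH``/``init_dS`` are the
    duplex initiation terms.
    """

    pair_params: Dict[str, Tuple[float, float]]
    init_dH: float
    init_dS: float
    source_label: str

    def __post_init__(self) -> None:
        if set(self.pair_params) != {a + b for a in _BASES for b in _BASES}:
            raise ValueError("NN table must have exactly the 16 ACGT steps")
        for step, (dh, _ds) in self.pair_params.items():
            if not dh < 0:
                raise ValueError(f"stacking dH for {step} must be negative")

    def dg37(self, step: str) -> float:
        dh, ds = self.pair_params[step]
        return dh - DG_TEMP_K * ds / 1000.0

    def as_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """(dH, dS) as length-16 arrays indexed by 4*first + second base."""
        dh = np.empty(16)
        ds = np.empty(16)
        for step, (h, s) in self.pair_params.items():
            idx = 4 * _BASE_INDEX[step[0]] + _BASE_INDEX[step[1]]
            dh[idx] = h
            ds[idx] = s
        return dh, ds


def _read_table_asset(name: str) -> Dict[str, Tuple[float, float]]:
    text = resources.files("rrnaprobe.data").joinpath(name).read_text()
    out: Dict[str, Tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("step") \
                or line.startswith("loop_len"):
            continue
        key, *vals = line.split("\t")
        out[key] = tuple(float(v) for v in vals)  # type: ignore[assignment]
    return out


def load_nn_table(asset: str = "rna_dna_nn.tsv", label: str | None = None) -> NNTable:
    """Load an NN table from a packaged plain-text asset."""
    raw = _read_table_asset(asset)
    init = raw.pop("init")
    return NNTable(
        pair_params={k: (v[0], v[1]) for k, v in raw.items()},
        init_dH=init[0],
        init_dS=init[1],
        source_label=label or asset,
    )


def load_loop_penalties(asset: str = "hairpin_loops.tsv") -> Dict[int, float]:
    raw = _read_table_asset(asset)
    return {int(float(k)): v[0] for k, v in raw.items()}


RNA_DNA_TABLE = load_nn_table("rna_dna_nn.tsv", "RNA/DNA hybrid (Sugimoto 1995)")
DNA_DNA_TABLE = load_nn_table("dna_dna_nn.tsv", "DNA/DNA (Allawi & SantaLucia 1997)")
_LOOP_TABLE = load_loop_penalties()
_LOOP_SIZES = sorted(_LOOP_TABLE)


def loop_penalty(loop_len: int) -> float:
    """Hairpin loop initiation dG37 (kcal/mol) for a loop of ``loop_len`` nt."""
    if loop_len < 3:
        raise ValueError("hairpin loops shorter than 3 nt are sterically forbidden")
    if loop_len in _LOOP_TABLE:
        return _LOOP_TABLE[loop_len]
    nmax = _LOOP_SIZES[-1]
    if loop_len > nmax:
        return _LOOP_TABLE[nmax] + 1.75 * GAS_CONSTANT / 1000.0 * DG_TEMP_K * math.log(
            loop_len / nmax
        )
    hi = min(s for s in _LOOP_SIZES if s > loop_len)
    lo = max(s for s in _LOOP_SIZES if s < loop_len)
    frac = (loop_len - lo) / (hi - lo)
    return _LOOP_TABLE[lo] + frac * (_LOOP_TABLE[hi] - _LOOP_TABLE[lo])


# ---------------------------------------------------------------------------
# Configuration and annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermoConfig:
    """Solution conditions entering the Tm and dG calculations.

    probe_conc_nM is the DNA probe concentration; the concentration term in
    the Tm denominator is C_eff = probe_conc_nM*1e-9 / conc_divisor, with
    divisor 4 for the standard non-self-complementary excess-free convention
    (divisor 1 reproduces the total-strand convention).
    """

    na_molar: float = 0.3
    probe_conc_nM: float = 250.0
    dg_temp_C: float = 37.0
    gas_constant: float = GAS_CONSTANT
    conc_divisor: float = 4.0

    def __post_init__(self) -> None:
        if self.na_molar <= 0:
            raise ValueError("na_molar must be > 0")
        if self.probe_conc_nM <= 0:
            raise ValueError("probe_conc_nM must be > 0")

    @property
    def c_eff(self) -> float:
        return self.probe_conc_nM * 1e-9 / self.conc_divisor


@dataclass
class ThermoAnnotation:
    """Per-candidate thermodynamic summary."""

    tm_C: float
    gc_fraction: float
    dg_hairpin: float | None = None
    dg_homodimer: float | None = None
    dg_duplex37: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction outside [0, 1]")
        if not math.isfinite(self.tm_C):
            raise ValueError("tm_C must be finite")


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------

def salt_correct(tm_1M_C, gc_frac, na_molar: float):
    """Correct a 1 M Na+ Tm (deg C) to ``na_molar`` in reciprocal-Tm space.

    Accepts scalars or numpy arrays for ``tm_1M_C``/``gc_frac``.
    """
    if na_molar <= 0:
        raise ValueError("na_molar must be > 0")
    ln_na = math.log(na_molar)
    inv_tm = 1.0 / (np.asarray(tm_1M_C, dtype=float) + ZERO_C_IN_K)
    inv_tm = inv_tm + (4.29 * np.asarray(gc_frac, dtype=float) - 3.95) * 1e-5 * ln_na
    inv_tm = inv_tm + 9.40e-6 * ln_na**2
    out = 1.0 / inv_tm - ZERO_C_IN_K
    if np.ndim(tm_1M_C) == 0 and np.ndim(gc_frac) == 0:
        return float(out)
    return out


def nn_sums(target_site_seq: str, table: NNTable) -> Tuple[float, float]:
    """Total (dH, dS) of a duplex: initiation plus all dinucleotide steps."""
    dh = table.init_dH
    ds = table.init_dS
    for i in range(len(target_site_seq) - 1):
        h, s = table.pair_params[target_site_seq[i : i + 2]]
        dh += h
        ds += s
    return dh, ds


def tm_1m(target_site_seq: str, cfg: ThermoConfig, table: NNTable) -> float:
    """NN-model Tm (deg C) at 1 M Na+."""
    seq = _check_acgt(target_site_seq, min_len=2)
    dh, ds = nn_sums(seq, table)
    tm_k = dh * 1000.0 / (ds + cfg.gas_constant * math.log(cfg.c_eff))
    return tm_k - ZERO_C_IN_K


def duplex_tm(
    target_site_seq: str,
    cfg: ThermoConfig = ThermoConfig(),
    table: NNTable = RNA_DNA_TABLE,
) -> float:
    """Salt-corrected Tm (deg C) of the probe/target hybrid.

    ``target_site_seq`` is the sense (target) strand of the duplex, 5'->3'.
    """
    seq = _check_acgt(target_site_seq, min_len=2)
    return salt_correct(tm_1m(seq, cfg, table), gc_fraction(seq), cfg.na_molar)


def duplex_dg37(target_site_seq: str, table: NNTable = RNA_DNA_TABLE) -> float:
    """dG37 (kcal/mol) of the full probe/target duplex (used by the optional
    hybridization-energy window filter)."""
    seq = _check_acgt(target_site_seq, min_len=2)
    dh, ds = nn_sums(seq, table)
    return dh - DG_TEMP_K * ds / 1000.0


# ---------------------------------------------------------------------------
# Hairpin and dimer screening
# ---------------------------------------------------------------------------

def _complement_matrix(seq: str) -> np.ndarray:
    """Boolean matrix: C[i, j] iff seq[i] Watson-Crick pairs with seq[j]."""
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.frombuffer(seq.translate(DNA_COMPLEMENT).encode(), dtype=np.uint8)
    return enc[:, None] == comp[None, :]


def hairpin_dg(
    probe_seq: str,
    min_stem: int = 3,
    min_loop: int = 3,
    table: NNTable = DNA_DNA_TABLE,
) -> float:
    """Most stable stem-loop dG37 (kcal/mol) of a single strand.

    Scans all stems of >= ``min_stem`` base pairs enclosing a loop of
    >= ``min_loop`` nt; each stem is scored as the sum of its DNA/DNA NN
    stacking dG37 terms plus the loop-length penalty.  Returns
    ``NO_STRUCTURE_DG`` when no qualifying stem exists.
    """
    seq = _check_acgt(probe_seq, min_len=8)
    n = len(seq)
    pairs = _complement_matrix(seq)
    # run[i, j]: number of consecutive pairs (i, j), (i+1, j-1), ... inward
    run = np.zeros((n, n), dtype=np.int32)
    dg_step = np.array([table.dg37(a + b) for a in _BASES for b in _BASES])
    enc = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int32)
    step_idx = 4 * enc[:-1] + enc[1:]

    for span in range(1, n):  # span = j - i; fill inward-run lengths
        for i in range(0, n - span):
            j = i + span
            if pairs[i, j]:
                inner = run[i + 1, j - 1] if j - 1 > i + 1 else 0
                run[i, j] = inner + 1

    best = NO_STRUCTURE_DG
    for span in range(2 * min_stem + min_loop - 1, n):
        for i in range(0, n - span):
            j = i + span
            r = run[i, j]
            if r == 0:
                continue
            # try stems of every allowed depth starting at outer pair (i, j)
            max_stem = min(r, (span + 1 - min_loop) // 2)
            if max_stem < min_stem:
                continue
            stack = 0.0
            for s in range(2, max_stem + 1):
                stack += dg_step[step_idx[i + s - 2]]
                if s < min_stem:
                    continue
                loop = span + 1 - 2 * s
                dg = stack + loop_penalty(loop)
                if dg < best:
                    best = dg
    return best


def dimer_dg(
    seq_a: str,
    seq_b: str,
    table: NNTable = DNA_DNA_TABLE,
    init_dg: float | None = None,
) -> float:
    """Most stable ungapped antiparallel duplex dG37 between two strands.

    For every antiparallel offset of ``seq_a`` against ``seq_b``, maximal runs
    of complementary base pairs are scored by NN dG37 stacking (a run of r
    pairs contributes r-1 stacking terms; runs of one pair contribute
    nothing); one duplex initiation penalty is added per offset.  Returns the
    minimum over offsets, or ``NO_STRUCTURE_DG`` when no offset produces a
    run of >= 2 pairs.  Symmetric in its arguments.
    """
    a = _check_acgt(seq_a, min_len=2)
    b = _check_acgt(seq_b, min_len=2)
    if init_dg is None:
        init_dg = table.init_dH - DG_TEMP_K * table.init_dS / 1000.0
    br = b[::-1]
    la, lb = len(a), len(br)
    best = NO_STRUCTURE_DG
    for off in range(-(la - 1), lb):
        # a[i] faces br[i + off]
        i0 = max(0, -off)
        i1 = min(la, lb - off)
        total = 0.0
        run_start = None
        any_run = False
        for i in range(i0, i1 + 1):
            paired = i < i1 and a[i] == br[i + off].translate(DNA_COMPLEMENT)
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                if i - run_start >= 2:
                    any_run = True
                    for t in range(run_start, i - 1):
                        total += table.dg37(a[t : t + 2])
                run_start = None
        if any_run:
            best = min(best, init_dg + total)
    return best


def homodimer_dg(probe_seq: str, table: NNTable = DNA_DNA_TABLE) -> float:
    """Self-dimer dG37 of a probe."""
    return dimer_dg(probe_seq, probe_seq, table=table)


def annotate(
    target_site_seq: str,
    cfg: ThermoConfig = ThermoConfig(),
    table: NNTable = RNA_DNA_TABLE,
    with_structure: bool = True,
) -> ThermoAnnotation:
    """Full thermodynamic annotation of one candidate placement."""
    seq = _check_acgt(target_site_seq, min_len=2)
    probe = reverse_complement(seq)
    ann = ThermoAnnotation(
        tm_C=duplex_tm(seq, cfg, table),
        gc_fraction=gc_fraction(seq),
        dg_duplex37=duplex_dg37(seq, table),
    )
    if with_structure:
        ann.dg_hairpin = hairpin_dg(probe)
        ann.dg_homodimer = homodimer_dg(probe)
    return ann
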