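"""Candidate probe enumeration and local filtering.

Every possible probe placement in the allowed length range is enumerated on
the consensus target, skipping footprints that touch an N or a masked
position.  Candidates are annotated, never silently discarded: each carries
a (possibly empty) set of failure flags so that downstream reports can show
all "possible placement sites" alongside the surviving ones.

Filters:

* composition (applied to the antisense probe sequence): GC fraction must be
  inside [gc_min, gc_max]; no run of five or more identical nucleotides; no
  run of four or more A; no run of four or more C within the first half of
  the probe.  These are the empirical single-molecule-FISH oligo rules.
* thermodynamics: hybrid Tm at or above tm_min (and at or below tm_max when
  set); hairpin dG37 above dg_hairpin_min; homodimer dG37 above
  dg_dimer_min; optionally a probe/target duplex dG37 window.

Threshold semantics are strict-violation: a candidate fails only when it is
strictly beyond a bound, so values exactly at a threshold pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import thermo
from .targets import ConsensusTarget
from .thermo import (
    NNTable,
    RNA_DNA_TABLE,
    ThermoAnnotation,
    ThermoConfig,
    reverse_complement,
)

log = logging.getLogger(__name__)

# filter flag vocabulary
FLAG_GC_LOW = "gc_low"
FLAG_GC_HIGH = "gc_high"
FLAG_RUN5 = "run5"
FLAG_RUN_A4 = "runA4"
FLAG_RUN_C4 = "runC4_first_half"
FLAG_TM_LOW = "tm_low"
FLAG_TM_HIGH = "tm_high"
FLAG_HAIRPIN = "hairpin"
FLAG_HOMODIMER = "homodimer"
FLAG_DG_WINDOW = "dg_window"
FLAG_EXCLUDED = "excluded"
FLAG_OFFTARGET = "offtarget"


@dataclass
class DesignConfig:
    """All tunable probe-design parameters (units in field names/docs)."""

    len_min: int = 26
    len_max: int = 32
    tm_min: float = 72.0
    tm_max: Optional[float] = None
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_identical_run: int = 4   # reject runs of 5+
    max_a_run: int = 3           # reject runs of 4+ A
    max_c_run_first_half: int = 3  # reject runs of 4+ C in the first half
    dg_hairpin_min: float = -3.0   # kcal/mol
    dg_dimer_min: float = -10.0    # kcal/mol
    window_nt: int = 200
    top_fraction: float = 0.05
    probes_per_target: int = 10
    flank_nt: int = 40
    bitscore_cutoff: float = 32.0
    probe_target_dg_window: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.probes_per_target < 1:
            raise ValueError("probes_per_target must be >= 1")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass
class ProbeCandidate:
    """One candidate placement on a consensus target."""

    target_id: str
    start: int
    length: int
    target_site_seq: str
    probe_seq: str
    thermo: Optional[ThermoAnnotation] = None
    filter_flags: Set[str] = field(default_factory=set)
    offtarget_max_bits: Optional[float] = None
    offtarget_best_record: Optional[str] = None
    is_peak: bool = False
    selected: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def passes(self) -> bool:
        """True when the candidate survives every local filter and the
        off-target screen."""
        return not self.filter_flags

    def __post_init__(self) -> None:
        if self.probe_seq != reverse_complement(self.target_site_seq):
            raise ValueError("probe_seq must be the reverse complement of "
                             "target_site_seq")


def _max_run(seq: str, base: Optional[str] = None) -> int:
    """Longest run of one nucleotide (of ``base`` if given, else any)."""
    best = run = 0
    prev = None
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if base is None or ch == base:
            best = max(best, run)
    return best


def composition_filter(probe_seq: str, cfg: DesignConfig) -> Set[str]:
    """Sequence-composition failure flags for one probe (antisense) sequence."""
    flags: Set[str] = set()
    gc = thermo.gc_fraction(probe_seq)
    if gc < cfg.gc_min:
        flags.add(FLAG_GC_LOW)
    if gc > cfg.gc_max:
        flags.add(FLAG_GC_HIGH)
    if _max_run(probe_seq) > cfg.max_identical_run:
        flags.add(FLAG_RUN5)
    if _max_run(probe_seq, "A") > cfg.max_a_run:
        flags.add(FLAG_RUN_A4)
    half = probe_seq[: math.ceil(len(probe_seq) / 2)]
    if _max_run(half, "C") > cfg.max_c_run_first_half:
        flags.add(FLAG_RUN_C4)
    return flags


def thermo_filter(cand: ProbeCandidate, cfg: DesignConfig) -> Set[str]:
    """Thermodynamic failure flags; requires thermo annotations."""
    if cand.thermo is None:
        raise RuntimeError("candidate lacks thermodynamic annotation")
    t = cand.thermo
    flags: Set[str] = set()
    if t.tm_C < cfg.tm_min:
        flags.add(FLAG_TM_LOW)
    if cfg.tm_max is not None and t.tm_C > cfg.tm_max:
        flags.add(FLAG_TM_HIGH)
    if t.dg_hairpin is not None and t.dg_hairpin < cfg.dg_hairpin_min:
        flags.add(FLAG_HAIRPIN)
    if t.dg_homodimer is not None and t.dg_homodimer < cfg.dg_dimer_min:
        flags.add(FLAG_HOMODIMER)
    if cfg.probe_target_dg_window is not None and t.dg_duplex37 is not None:
        lo, hi = cfg.probe_target_dg_window
        if not (lo <= t.dg_duplex37 <= hi):
            flags.add(FLAG_DG_WINDOW)
    return flags


def enumerate_candidates(
    cons: ConsensusTarget,
    cfg: DesignConfig,
    thermo_cfg: ThermoConfig = ThermoConfig(),
    table: NNTable = RNA_DNA_TABLE,
    compute_structure: bool = True,
) -> List[ProbeCandidate]:
    """Enumerate and annotate every allowed probe placement.

    Footprints containing an N or a masked position are not placements at
    all and are skipped; footprints intersecting an exclusion interval are
    enumerated but flagged ``excluded``.  Composition and thermodynamic
    filters set flags on every candidate.  Hairpin/homodimer dG (the costly
    annotations) are computed only for candidates that are otherwise clean
    when ``compute_structure`` is true.
    """
    seq = cons.sequence
    n = len(seq)
    if n < cfg.len_min:
        log.warning("%s: consensus (%d nt) shorter than len_min (%d); "
                    "no candidates", cons.target_id, n, cfg.len_min)
        return []

    # positions on which no footprint may rest (N or low-complexity mask)
    hard_blocked = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
    hard_blocked = hard_blocked.copy()
    for s, e in cons.mask_intervals:
        hard_blocked[s:e] = True
    excluded = np.zeros(n, dtype=bool)
    for s, e in cons.exclusion_intervals:
        excluded[s:e] = True
    blocked_cum = np.concatenate([[0], np.cumsum(hard_blocked)])
    excl_cum = np.concatenate([[0], np.cumsum(excluded)])

    # vectorized NN sums: per-position step dH/dS (nan across N positions)
    dh_arr, ds_arr = table.as_arrays()
    enc = np.full(n, -1, dtype=np.int64)
    for b, v in zip("ACGT", range(4)):
        enc[np.frombuffer(seq.encode(), np.uint8) == ord(b)] = v
    valid_step = (enc[:-1] >= 0) & (enc[1:] >= 0)
    step_idx = np.where(valid_step, 4 * np.clip(enc[:-1], 0, 3) + np.clip(enc[1:], 0, 3), 0)
    # steps across N contribute 0; footprints containing them are excluded
    # by the hard-block mask, so the 0 never enters a reported sum
    dh_steps = np.where(valid_step, dh_arr[step_idx], 0.0)
    ds_steps = np.where(valid_step, ds_arr[step_idx], 0.0)
    dh_cum = np.concatenate([[0.0], np.cumsum(dh_steps)])
    ds_cum = np.concatenate([[0.0], np.cumsum(ds_steps)])
    gc_cum = np.concatenate(
        [[0], np.cumsum((enc == 1) | (enc == 2))]
    )

    r_ln_c = thermo_cfg.gas_constant * math.log(thermo_cfg.c_eff)
    out: List[ProbeCandidate] = []
    for length in range(cfg.len_min, cfg.len_max + 1):
        if length > n:
            continue
        starts = np.arange(0, n - length + 1)
        ok = (blocked_cum[starts + length] - blocked_cum[starts]) == 0
        dh = table.init_dH + dh_cum[starts + length - 1] - dh_cum[starts]
        ds = table.init_dS + ds_cum[starts + length - 1] - ds_cum[starts]
        gc = (gc_cum[starts + length] - gc_cum[starts]) / length
        with np.errstate(invalid="ignore"):
            tm1 = dh * 1000.0 / (ds + r_ln_c) - thermo.ZERO_C_IN_K
            tm = thermo.salt_correct(tm1, gc, thermo_cfg.na_molar)
            dg37 = dh - thermo.DG_TEMP_K * ds / 1000.0
        for s in starts[ok]:
            site = seq[s : s + length]
            probe = reverse_complement(site)
            ann = ThermoAnnotation(
                tm_C=float(tm[s]), gc_fraction=float(gc[s]),
                dg_duplex37=float(dg37[s]),
            )
            cand = ProbeCandidate(
                target_id=cons.target_id, start=int(s), length=length,
                target_site_seq=site, probe_seq=probe, thermo=ann,
            )
            if excl_cum[s + length] - excl_cum[s] > 0:
                cand.filter_flags.add(FLAG_EXCLUDED)
            cand.filter_flags |= composition_filter(probe, cfg)
            cand.filter_flags |= thermo_filter(cand, cfg)
            out.append(cand)

    if compute_structure:
        for cand in out:
            if not cand.filter_flags:
                hp, hd = _structure_dg(cand.probe_seq)
                cand.thermo.dg_hairpin = hp
                cand.thermo.dg_homodimer = hd
                cand.filter_flags |= thermo_filter(cand, cfg)

    out.sort(key=lambda c: (c.start, c.length))
    log.info("%s: %d candidates enumerated, %d pass local filters",
             cons.target_id, len(out), sum(1 for c in out if c.passes))
    return out


from functools import lru_cache


@lru_cache(maxsize=200_000)
def _structure_dg(probe_seq: str) -> Tuple[float, float]:
    """(hairpin, homodimer) dG37 under the default DNA/DNA table; memoized
    because overlapping candidates and repeated runs share probe sequences."""
    return thermo.hairpin_dg(probe_seq), thermo.homodimer_dg(probe_seq)


def candidate_table(cands: Sequence[ProbeCandidate]):
    """Candidate annotations as a pandas DataFrame (one row per placement)."""
    import pandas as pd

    rows = []
    for c in cands:
        t = c.thermo
        rows.append({
            "target_id": c.target_id,
            "start": c.start,
            "end": c.end,
            "length": c.length,
            "target_site_seq": c.target_site_seq,
            "probe_seq": c.probe_seq,
            "tm_C": round(t.tm_C, 4) if t else np.nan,
            "gc_fraction": round(t.gc_fraction, 4) if t else np.nan,
            "dg_hairpin": round(t.dg_hairpin, 4)
                if t and t.dg_hairpin is not None else np.nan,
            "dg_homodimer": round(t.dg_homodimer, 4)
                if t and t.dg_homodimer is not None else np.nan,
            "offtarget_max_bits": round(c.offtarget_max_bits, 4)
                if c.offtarget_max_bits is not None else np.nan,
            "filter_flags": ";".join(sorted(c.filter_flags)) or ".",
            "is_peak": c.is_peak,
            "selected": c.selected,
        })
    return pd.DataFrame(rows)
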