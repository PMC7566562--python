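"""Tm-peak detection and evenly spaced probe-set selection.

Depletion efficiency correlates with the predicted probe/target Tm, so the
final set should sit on local Tm maxima while tiling the target as evenly
as possible.  A candidate is a "peak" when its Tm is in the top fraction
(default 5%) of surviving candidates within a moving window (default
200 nt) around its start.  Selection then walks n ideal, evenly spaced
anchor positions left to right and assigns each the nearest eligible peak
candidate, where eligible means: survives every filter, does not overlap an
already-selected probe, and forms no strong heterodimer (dG37 above the
dimer threshold) with any already-selected probe.  When no peak lies within
half an anchor spacing, the nearest eligible candidate of any kind is used
as a logged fallback, so sparse targets still yield a usable set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import thermo
from .candidates import (
    FLAG_EXCLUDED,
    DesignConfig,
    ProbeCandidate,
    candidate_table,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class ProbeSet:
    """The selected probes of one target, in target order."""

    target_id: str
    probes: List[ProbeCandidate]
    target_length: int

    @property
    def density_nt_per_probe(self) -> float:
        return self.target_length / len(self.probes) if self.probes else math.inf

    def summary(self):
        return candidate_table(self.probes)


def apply_exclusions(cands: Sequence[ProbeCandidate],
                     exclusion_intervals: Iterable[Tuple[int, int]],
                     target_length: Optional[int] = None) -> None:
    """Flag candidates whose footprint intersects an exclusion interval
    (half-open coordinates; abutting footprints are untouched)."""
    ivs = sorted((int(s), int(e)) for s, e in exclusion_intervals)
    for s, e in ivs:
        if s >= e or s < 0 or (target_length is not None and e > target_length):
            raise ConfigError(f"bad exclusion interval ({s}, {e})")
    for c in cands:
        for s, e in ivs:
            if c.start < e and s < c.end:
                c.filter_flags.add(FLAG_EXCLUDED)
                break


def find_tm_peaks(cands: Sequence[ProbeCandidate], window_nt: int = 200,
                  top_fraction: float = 0.05) -> None:
    """Set ``is_peak`` on surviving candidates in the top Tm fraction of
    their local window.

    The window of a candidate holds the Tm values of all surviving
    candidates whose start is within +-window_nt/2 of its own start
    (clipped at the target ends).  With k = ceil(top_fraction * window
    size), the candidate is a peak iff its Tm is at least the k-th largest
    value, ties included, so every window contributes at least one peak.
    """
    if window_nt <= 0:
        raise ValueError("window_nt must be positive")
    surv = [c for c in cands if c.passes]
    for c in cands:
        c.is_peak = False
    if not surv:
        return
    starts = np.array([c.start for c in surv])
    tms = np.array([c.thermo.tm_C for c in surv])
    order = np.argsort(starts, kind="stable")
    starts_sorted = starts[order]
    half = window_nt / 2.0
    for idx, c in enumerate(surv):
        lo = np.searchsorted(starts_sorted, c.start - half, side="left")
        hi = np.searchsorted(starts_sorted, c.start + half, side="right")
        window_tms = tms[order[lo:hi]]
        k = max(1, math.ceil(top_fraction * window_tms.size))
        kth_largest = np.partition(window_tms, -k)[-k]
        c.is_peak = bool(c.thermo.tm_C >= kth_largest)
    log.info("peaks: %d of %d surviving candidates",
             sum(c.is_peak for c in surv), len(surv))


def _heterodimer_ok(cand: ProbeCandidate, chosen: Sequence[ProbeCandidate],
                    dg_min: float) -> bool:
    return all(
        thermo.dimer_dg(cand.probe_seq, p.probe_seq) > dg_min for p in chosen
    )


def select_probes(cands: Sequence[ProbeCandidate], cfg: DesignConfig,
                  target_length: int) -> ProbeSet:
    """Select up to ``cfg.probes_per_target`` evenly spaced probes.

    Ideal anchors are p_i = (i - 0.5) * L / n for i = 1..n.  Anchors are
    filled left to right with the nearest eligible peak candidate (distance
    |start - anchor|; ties broken by higher Tm, then smaller start).  When
    no eligible peak lies within L/(2n) of an anchor, the nearest eligible
    candidate of any kind is taken instead (logged); an anchor with no
    eligible candidate at all is skipped with a warning.
    """
    if not cands:
        log.warning("no candidates at all; empty probe set")
        return ProbeSet(target_id="", probes=[], target_length=target_length)
    target_id = cands[0].target_id
    n = cfg.probes_per_target
    L = target_length
    eligible = [c for c in cands if c.passes]
    if not eligible:
        log.warning("%s: zero surviving candidates; empty probe set", target_id)
        return ProbeSet(target_id=target_id, probes=[], target_length=L)

    chosen: List[ProbeCandidate] = []
    radius = L / (2.0 * n)
    for i in range(1, n + 1):
        anchor = (i - 0.5) * L / n

        def usable(c: ProbeCandidate) -> bool:
            if c.selected:
                return False
            if any(c.start < p.end and p.start < c.end for p in chosen):
                return False
            return _heterodimer_ok(c, chosen, cfg.dg_dimer_min)

        def pick(pool: List[ProbeCandidate]) -> Optional[ProbeCandidate]:
            ranked = sorted(
                pool,
                key=lambda c: (abs(c.start - anchor), -c.thermo.tm_C, c.start),
            )
            for c in ranked:
                if usable(c):
                    return c
            return None

        peaks_near = [c for c in eligible
                      if c.is_peak and abs(c.start - anchor) <= radius]
        best = pick(peaks_near)
        if best is None:
            best = pick(list(eligible))
            if best is not None and not (best.is_peak and
                                         abs(best.start - anchor) <= radius):
                log.info("%s: anchor %.0f filled by fallback candidate at %d "
                         "(peak=%s)", target_id, anchor, best.start,
                         best.is_peak)
        if best is None:
            log.warning("%s: anchor %.0f unfillable; probe set will be short",
                        target_id, anchor)
            continue
        best.selected = True
        chosen.append(best)

    chosen.sort(key=lambda c: c.start)
    ps = ProbeSet(target_id=target_id, probes=chosen, target_length=L)
    if chosen:
        log.info("%s: selected %d probes, %.0f nt of target per probe",
                 target_id, len(chosen), ps.density_nt_per_probe)
    return ps


def audit_probe_set(ps: ProbeSet, cands: Sequence[ProbeCandidate],
                    cfg: DesignConfig,
                    thermo_cfg: thermo.ThermoConfig = thermo.ThermoConfig()
                    ) -> List[str]:
    """Independent re-verification of a selected probe set.

    Re-checks, from the probe sequences alone: composition rules, hairpin
    and homodimer thresholds, pairwise heterodimer threshold, pairwise
    non-overlap, set size, and that every probe is flag-free.  Returns a
    list of violation strings (empty = clean).
    """
    from . import candidates as cd

    problems: List[str] = []
    if len(ps.probes) > cfg.probes_per_target:
        problems.append("probe set larger than probes_per_target")
    for c in ps.probes:
        if c.filter_flags:
            problems.append(f"{c.target_id}:{c.start} carries flags "
                            f"{sorted(c.filter_flags)}")
        comp = cd.composition_filter(c.probe_seq, cfg)
        if comp:
            problems.append(f"{c.target_id}:{c.start} composition {comp}")
        if thermo.hairpin_dg(c.probe_seq) < cfg.dg_hairpin_min:
            problems.append(f"{c.target_id}:{c.start} hairpin below threshold")
        if thermo.homodimer_dg(c.probe_seq) < cfg.dg_dimer_min:
            problems.append(f"{c.target_id}:{c.start} homodimer below threshold")
        tm = thermo.duplex_tm(c.target_site_seq, thermo_cfg)
        if tm < cfg.tm_min and not math.isclose(tm, cfg.tm_min):
            problems.append(f"{c.target_id}:{c.start} Tm {tm:.2f} below "
                            f"{cfg.tm_min}")
    for a, b in ((x, y) for i, x in enumerate(ps.probes)
                 for y in ps.probes[i + 1 :]):
        if a.start < b.end and b.start < a.end:
            problems.append(f"overlap {a.start} vs {b.start}")
        if thermo.dimer_dg(a.probe_seq, b.probe_seq) <= cfg.dg_dimer_min:
            problems.append(f"heterodimer {a.start} vs {b.start}")
    return problems


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_probe_tsv(probe_sets: Sequence[ProbeSet], path) -> None:
    """Selected probes, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive, on the consensus target\n")
        fh.write("target_id\tstart\tend\tlength\tprobe_seq\ttm_C\tgc_fraction\t"
                 "dg_hairpin\tdg_homodimer\n")
        for ps in probe_sets:
            for c in ps.probes:
                t = c.thermo
                fh.write(
                    f"{c.target_id}\t{c.start + 1}\t{c.end}\t{c.length}\t"
                    f"{c.probe_seq}\t{t.tm_C:.2f}\t{t.gc_fraction:.3f}\t"
                    f"{_fmt(t.dg_hairpin)}\t{_fmt(t.dg_homodimer)}\n"
                )


def _fmt(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.2f}"


def write_probe_fasta(probe_sets: Sequence[ProbeSet], path) -> None:
    """Probe (antisense) sequences 5'->3', named target:start-end (1-based)."""
    with open(path, "w") as fh:
        for ps in probe_sets:
            for c in ps.probes:
                fh.write(f">{c.target_id}:{c.start + 1}-{c.end}\n"
                         f"{c.probe_seq}\n")


def write_probe_bed(probe_sets: Sequence[ProbeSet], path) -> None:
    """Target-site footprints as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for ps in probe_sets:
            for c in ps.probes:
                fh.write(f"{c.target_id}\t{c.start}\t{c.end}\t"
                         f"{c.target_id}:{c.start + 1}-{c.end}\t"
                         f"{int(round(c.thermo.tm_C))}\t+\n")
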