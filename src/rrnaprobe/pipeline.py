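"""End-to-end probe-design runs: config file -> output bundle.

A run executes the stages in method order for every target: variant
alignment -> consensus with N-masking -> low-complexity masking ->
candidate enumeration with composition/thermodynamic filters -> optional
off-target screen -> Tm-peak detection -> evenly spaced selection.  All
artifacts are written as plain text (TSV/FASTA/BED/JSON) and a run
manifest records the config snapshot, input digests and the per-stage
candidate counts, which must shrink monotonically along the filter
cascade.  Identical inputs and config produce a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .candidates import (
    FLAG_DG_WINDOW,
    FLAG_EXCLUDED,
    FLAG_GC_HIGH,
    FLAG_GC_LOW,
    FLAG_HAIRPIN,
    FLAG_HOMODIMER,
    FLAG_OFFTARGET,
    FLAG_RUN5,
    FLAG_RUN_A4,
    FLAG_RUN_C4,
    FLAG_TM_HIGH,
    FLAG_TM_LOW,
    DesignConfig,
    ProbeCandidate,
    candidate_table,
    enumerate_candidates,
)
from .offtarget import ScoringScheme, TranscriptDB, extract_transcript_db, screen_candidates
from .selection import (
    ConfigError,
    ProbeSet,
    apply_exclusions,
    audit_probe_set,
    find_tm_peaks,
    select_probes,
    write_probe_bed,
    write_probe_fasta,
    write_probe_tsv,
)
from .targets import (
    ConsensusTarget,
    TargetSpec,
    align_variants,
    build_consensus,
    mask_low_complexity,
    read_fasta,
    write_bed,
    write_consensus_fasta,
)
from .thermo import ThermoConfig

log = logging.getLogger(__name__)

_COMPOSITION_FLAGS = {FLAG_GC_LOW, FLAG_GC_HIGH, FLAG_RUN5, FLAG_RUN_A4,
                      FLAG_RUN_C4, FLAG_EXCLUDED}
_THERMO_FLAGS = {FLAG_TM_LOW, FLAG_TM_HIGH, FLAG_HAIRPIN, FLAG_HOMODIMER,
                 FLAG_DG_WINDOW}


@dataclass
class StageCounts:
    enumerated: int = 0
    composition_pass: int = 0
    thermo_pass: int = 0
    specificity_pass: int = 0
    peaks: int = 0
    selected: int = 0

    def check_monotone(self) -> None:
        seq = [self.enumerated, self.composition_pass, self.thermo_pass,
               self.specificity_pass, self.peaks]
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise AssertionError(f"filter cascade counts not monotone: {seq}")
        if self.selected > self.specificity_pass:
            raise AssertionError("selected more probes than surviving candidates")


@dataclass
class RunManifest:
    tool_version: str
    config_snapshot: dict
    input_digests: Dict[str, str]
    per_target_counts: Dict[str, StageCounts]

    def to_json(self) -> str:
        payload = {
            "tool_version": self.tool_version,
            "config": self.config_snapshot,
            "input_digests": self.input_digests,
            "counts": {t: asdict(c) for t, c in
                       sorted(self.per_target_counts.items())},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def stage_counts(cands: Sequence[ProbeCandidate]) -> StageCounts:
    """Recompute cascade counts from candidate annotations."""
    c = StageCounts(enumerated=len(cands))
    for cand in cands:
        f = cand.filter_flags
        if f & _COMPOSITION_FLAGS:
            continue
        c.composition_pass += 1
        if f & _THERMO_FLAGS:
            continue
        c.thermo_pass += 1
        if FLAG_OFFTARGET in f:
            continue
        c.specificity_pass += 1
        if cand.is_peak:
            c.peaks += 1
        if cand.selected:
            c.selected += 1
    return c


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunConfig:
    """Parsed run configuration (see ``load_config``)."""

    design: DesignConfig
    thermo: ThermoConfig
    targets: List[dict]
    aligner_mode: str = "auto"
    mask_window: int = 64
    mask_threshold: float = 20.0
    honor_lowercase_mask: bool = False
    screen_enabled: bool = True
    transcripts_fasta: Optional[str] = None
    genome: Optional[str] = None
    annotation: Optional[str] = None
    excluded_gene_ids: List[str] = field(default_factory=list)
    output_dir: str = "probe_design_out"


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "targets" not in raw:
        raise ConfigError("config must be a mapping with a 'targets' section")
    design = DesignConfig(**(raw.get("design") or {}))
    thermo_cfg = ThermoConfig(**(raw.get("thermo") or {}))
    off = raw.get("offtarget") or {}
    return RunConfig(
        design=design,
        thermo=thermo_cfg,
        targets=raw["targets"],
        aligner_mode=raw.get("aligner", "auto"),
        mask_window=int((raw.get("masking") or {}).get("window", 64)),
        mask_threshold=float((raw.get("masking") or {}).get("threshold", 20.0)),
        honor_lowercase_mask=bool(
            (raw.get("masking") or {}).get("honor_lowercase", False)),
        screen_enabled=bool(off.get("enabled", bool(off))),
        transcripts_fasta=off.get("transcripts_fasta"),
        genome=off.get("genome"),
        annotation=off.get("annotation"),
        excluded_gene_ids=list(off.get("excluded_gene_ids", [])),
        output_dir=raw.get("output_dir", "probe_design_out"),
    )


def build_target_consensus(tspec: dict, rc: RunConfig, base_dir: Path
                           ) -> ConsensusTarget:
    """targets-section entry -> masked consensus."""
    target_id = tspec["id"]
    fastas = tspec["fasta"]
    if isinstance(fastas, str):
        fastas = [fastas]
    variant_seqs: List[Tuple[str, str]] = []
    premask: List[Tuple[int, int]] = []
    for f in fastas:
        p = (base_dir / f) if not Path(f).is_absolute() else Path(f)
        if not p.exists():
            raise FileNotFoundError(f"target FASTA not found: {p}")
        for label, seq, pm in read_fasta(p, rc.honor_lowercase_mask):
            variant_seqs.append((label, seq))
            if len(fastas) == 1 and len(variant_seqs) == 1:
                premask = pm
    spec = TargetSpec(target_id, variant_seqs,
                      [tuple(iv) for iv in tspec.get("exclusions", [])])
    aln = align_variants(spec, rc.aligner_mode)
    cons = build_consensus(aln, target_id, spec.exclusion_intervals)
    if premask:
        cons.mask_intervals = sorted(premask)
    cons = mask_low_complexity(cons, rc.mask_window, rc.mask_threshold)
    return cons


def build_db(rc: RunConfig, base_dir: Path) -> Optional[TranscriptDB]:
    if not rc.screen_enabled:
        return None
    excluded = rc.excluded_gene_ids
    if rc.transcripts_fasta:
        return TranscriptDB.from_fasta(base_dir / rc.transcripts_fasta, excluded)
    if rc.genome and rc.annotation:
        return extract_transcript_db(base_dir / rc.genome,
                                     base_dir / rc.annotation,
                                     flank_nt=rc.design.flank_nt,
                                     excluded_gene_ids=excluded)
    raise ConfigError("off-target screen enabled but neither transcripts_fasta "
                      "nor genome+annotation provided")


def run_design(config_path: str | Path, output_dir: Optional[str | Path] = None
               ) -> Tuple[RunManifest, List[ProbeSet]]:
    """Execute the full design pipeline as described by a config file.

    Writes the output bundle (probe TSV/FASTA/BED, candidate table,
    off-target report, consensus FASTA + BED masks, plot data, manifest)
    into the output directory and returns (manifest, probe sets).
    """
    config_path = Path(config_path)
    rc = load_config(config_path)
    base_dir = config_path.parent
    outdir = Path(output_dir) if output_dir else base_dir / rc.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    db = build_db(rc, base_dir)
    scheme = ScoringScheme(bitscore_cutoff=rc.design.bitscore_cutoff)

    digests: Dict[str, str] = {}
    for t in rc.targets:
        fastas = t["fasta"] if isinstance(t["fasta"], list) else [t["fasta"]]
        for f in fastas:
            p = (base_dir / f) if not Path(f).is_absolute() else Path(f)
            digests[str(f)] = _sha256(p)
    for name in ("transcripts_fasta", "genome", "annotation"):
        val = getattr(rc, name)
        if val:
            digests[str(val)] = _sha256(base_dir / val)

    probe_sets: List[ProbeSet] = []
    counts: Dict[str, StageCounts] = {}
    all_cands: List[ProbeCandidate] = []
    hits = []
    for tspec in sorted(rc.targets, key=lambda t: t["id"]):
        cons = build_target_consensus(tspec, rc, base_dir)
        write_consensus_fasta(cons, outdir / f"{cons.target_id}_consensus.fa")
        write_bed(cons.mask_intervals, cons.target_id,
                  outdir / f"{cons.target_id}_mask.bed", "mask")
        write_bed(cons.exclusion_intervals, cons.target_id,
                  outdir / f"{cons.target_id}_exclusion.bed", "exclusion")
        cands = enumerate_candidates(cons, rc.design, rc.thermo)
        if db is not None:
            surviving = [c for c in cands if c.passes]
            hits.extend(screen_candidates(surviving, db, scheme))
        find_tm_peaks(cands, rc.design.window_nt, rc.design.top_fraction)
        ps = select_probes(cands, rc.design, len(cons.sequence))
        problems = audit_probe_set(ps, cands, rc.design, rc.thermo)
        if problems:
            raise AssertionError(
                f"post-selection audit failed for {cons.target_id}: {problems}"
            )
        sc = stage_counts(cands)
        sc.check_monotone()
        counts[cons.target_id] = sc
        probe_sets.append(ps)
        all_cands.extend(cands)

    write_probe_tsv(probe_sets, outdir / "probes.tsv")
    write_probe_fasta(probe_sets, outdir / "probes.fa")
    write_probe_bed(probe_sets, outdir / "probes.bed")
    table = candidate_table(all_cands)
    table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    plot = table[["target_id", "start", "length", "tm_C", "filter_flags",
                  "is_peak", "selected"]].copy()
    plot["possible"] = plot.pop("filter_flags") == "."
    plot.to_csv(outdir / "plot_data.tsv", sep="\t", index=False)
    with open(outdir / "offtarget.tsv", "w") as fh:
        fh.write("target_id\tstart\trecord_id\traw_score\tbitscore\t"
                 "query_span\tsubject_span\n")
        for h in hits:
            fh.write(f"{h.candidate.target_id}\t{h.candidate.start}\t"
                     f"{h.record_id}\t{h.raw_score}\t{h.bitscore:.2f}\t"
                     f"{h.query_span[0]}-{h.query_span[1]}\t"
                     f"{h.subject_span[0]}-{h.subject_span[1]}\n")

    manifest = RunManifest(
        tool_version=__version__,
        config_snapshot=_config_snapshot(rc),
        input_digests=digests,
        per_target_counts=counts,
    )
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    log.info("run complete: %d probe set(s) in %s", len(probe_sets), outdir)
    return manifest, probe_sets


def _config_snapshot(rc: RunConfig) -> dict:
    snap = {
        "design": asdict(rc.design),
        "thermo": asdict(rc.thermo),
        "aligner_mode": rc.aligner_mode,
        "masking": {"window": rc.mask_window, "threshold": rc.mask_threshold,
                    "honor_lowercase": rc.honor_lowercase_mask},
        "offtarget": {
            "enabled": rc.screen_enabled,
            "transcripts_fasta": rc.transcripts_fasta,
            "genome": rc.genome,
            "annotation": rc.annotation,
            "excluded_gene_ids": sorted(rc.excluded_gene_ids),
        },
        "targets": rc.targets,
    }
    return snap
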