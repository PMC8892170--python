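"""End-to-end orchestration of the co-segregation pipeline.

Stages: ``simulate`` (optional) → ``ingest`` (VCF → binarized matrix
restricted to the analysis universe) → ``coseg`` (XOR scan, co-segregation
calls) → ``map`` (signature filter + window intersection) → ``report``.
Each stage persists a plain-text artifact under the output directory with a
fixed name, so stages can be re-run individually from the CLI; ``run_all``
chains them and writes a machine-readable run manifest (config snapshot,
input checksums, per-stage record counts, version, seed, timestamps).

All randomness (simulation, permutation nulls) funnels through the single
top-level seed.  Given the same configuration and seed, every data artifact
is byte-identical across reruns; the manifest additionally carries wall-clock
timestamps and is therefore the one file excluded from byte-level
reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coseg_engine import CosegConfig, cosegregating_markers, scan_pairs
from .errors import InputValidationError
from .gwas_mapper import (CARDIO_SIGNATURE, CandidateAssociation,
                          filter_by_signature, load_gwas_table,
                          summarize_candidates, window_intersect)
from .panel_io import (BinaryGenotypeMatrix, binarize, load_panel,
                       read_annotation, read_rsnp_list, restrict_to_transcribed)
from .synthetic_panel import PlantedPair, SimConfig, generate_panel

ARTIFACTS = {
    "variants": "variants.tsv",
    "matrix": "matrix.tsv",
    "absent": "absent_rsnps.txt",
    "distances": "distances.tsv",
    "candidates": "candidates.tsv",
    "candidates_bed": "candidates.bed",
    "summary": "summary.json",
    "manifest": "manifest.json",
}

CANDIDATE_COLUMNS = ["rsnp_id", "gwas_snp_id", "link_type", "marker_id",
                     "bp_distance", "trait", "target_genes", "chrom",
                     "pos_gwas"]


@dataclass
class PipelineConfig:
    """One structured configuration for the whole run."""

    out_dir: str = "cosegscan_out"
    vcf: str | None = None
    annotation: str | None = None
    rsnp_list: str | None = None
    gwas_table: str | None = None
    simulate: bool = False
    sim: SimConfig | None = None
    coding_mode: str = "carrier"
    alpha: float = 0.01
    normalization: str = "union"
    null_model: str = "hypergeometric_exact"
    n_permutations: int = 1000
    multiple_testing: str = "none"
    half_window: int = 5000
    signature_terms: list[str] = field(
        default_factory=lambda: list(CARDIO_SIGNATURE))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputValidationError(f"config {path} is not a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim_raw = raw.pop("sim", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim_raw is not None:
            pairs = [PlantedPair(**p) for p in sim_raw.pop("planted_pairs", [])]
            cfg.sim = SimConfig(planted_pairs=pairs, **sim_raw)
        return cfg

    def coseg_config(self) -> CosegConfig:
        return CosegConfig(alpha=self.alpha, normalization=self.normalization,
                           null_model=self.null_model,
                           n_permutations=self.n_permutations, seed=self.seed,
                           multiple_testing=self.multiple_testing)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str | None, what: str, stage: str, hint: str) -> Path:
    if path is None:
        raise InputValidationError(f"[{stage}] missing input: {what}; {hint}")
    p = Path(path)
    if not p.exists():
        raise InputValidationError(
            f"[{stage}] {what} not found at {p}; {hint}")
    return p


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig) -> PipelineConfig:
    """Generate a synthetic bundle and point the input paths at it."""
    from .synthetic_panel import default_config

    sim = config.sim or default_config(seed=config.seed)
    sim_dir = Path(config.out_dir) / "sim"
    bundle = generate_panel(sim, sim_dir)
    return dataclasses.replace(config,
                               vcf=str(bundle.vcf), annotation=str(bundle.bed),
                               rsnp_list=str(bundle.rsnp_tsv),
                               gwas_table=str(bundle.gwas_tsv))


def stage_ingest(config: PipelineConfig, counts: dict) -> tuple[
        BinaryGenotypeMatrix, list, list[str]]:
    """VCF + annotation + rSNP list → restricted binarized matrix."""
    hint = "run `simulate` first or point the config at real inputs"
    vcf = _require(config.vcf, "VCF panel", "ingest", hint)
    ann = _require(config.annotation, "gene annotation", "ingest", hint)
    rsnps = _require(config.rsnp_list, "rSNP list", "ingest", hint)

    panel = load_panel(vcf)
    matrix = binarize(panel, coding_mode=config.coding_mode)
    annotation = read_annotation(ann)
    queries = read_rsnp_list(rsnps)
    matrix, absent = restrict_to_transcribed(
        matrix, annotation, [q.rsnp_id for q in queries])

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.save(out / ARTIFACTS["variants"], out / ARTIFACTS["matrix"])
    with open(out / ARTIFACTS["absent"], "w") as fh:
        for rid in absent:
            fh.write(rid + "\n")

    counts.update(variants_loaded=len(panel.variants),
                  non_snv_skipped=panel.n_skipped_non_snv,
                  genotypes_imputed=matrix.n_imputed,
                  variants_retained=len(matrix.variant_index),
                  rsnps_queried=len(queries),
                  rsnps_found=len(queries) - len(absent),
                  rsnps_absent=len(absent))
    return matrix, queries, absent


def stage_coseg(config: PipelineConfig, matrix: BinaryGenotypeMatrix,
                rsnp_ids: list[str], counts: dict) -> pd.DataFrame:
    """Scan rSNPs against the transcribed-region markers and persist calls."""
    present = [r for r in rsnp_ids if r in matrix]
    rsnp_set = set(present)
    markers = [v.variant_id for v in matrix.variants
               if v.in_transcribed_region and v.variant_id not in rsnp_set]
    if not present:
        raise InputValidationError("[coseg] no query rSNP present in the panel")
    if not markers:
        raise InputValidationError(
            "[coseg] no transcribed-region markers to scan")
    frame = scan_pairs(matrix, present, markers, config.coseg_config())
    out = Path(config.out_dir)
    frame.to_csv(out / ARTIFACTS["distances"], sep="\t", index=False,
                 float_format="%.6g")
    counts.update(markers_scanned=len(markers),
                  pairs_tested=len(frame),
                  pairs_excluded=len(frame.attrs.get("excluded", [])),
                  pairs_called=int(frame["cosegregating"].sum()))
    return frame


def stage_map(config: PipelineConfig, matrix: BinaryGenotypeMatrix,
              queries, coseg_frame: pd.DataFrame,
              counts: dict) -> list[CandidateAssociation]:
    """Signature-filter the GWAS table and link rSNPs within the window."""
    gwas = _require(config.gwas_table, "GWAS table", "map",
                    "run `simulate` first or supply --gwas-table")
    entries, n_skipped = load_gwas_table(gwas)
    retained = filter_by_signature(entries, config.signature_terms)

    pos = {v.variant_id: (v.chrom, v.pos) for v in matrix.variants}
    rsnp_pos = {q.rsnp_id: pos[q.rsnp_id] for q in queries if q.rsnp_id in pos}
    target_genes = {q.rsnp_id: q.known_target_genes for q in queries}
    coseg = cosegregating_markers(coseg_frame)

    # warn on id-coincident entries with discordant coordinates
    for e in retained:
        hit = rsnp_pos.get(e.gwas_snp_id)
        if hit is not None and (hit[0].removeprefix("chr")
                                != e.chrom.removeprefix("chr")
                                or hit[1] != e.pos):
            import sys
            print(f"[map] warning: GWAS row {e.gwas_snp_id} has coordinates "
                  f"{e.chrom}:{e.pos} discordant with the panel "
                  f"{hit[0]}:{hit[1]}; coordinates win", file=sys.stderr)

    assoc = window_intersect(retained, rsnp_pos, coseg, pos,
                             half_window=config.half_window,
                             target_genes=target_genes)

    out = Path(config.out_dir)
    write_candidates(assoc, out / ARTIFACTS["candidates"])
    with open(out / ARTIFACTS["candidates_bed"], "w") as fh:
        for rid in sorted({a.rsnp_id for a in assoc}):
            chrom, p = rsnp_pos[rid]
            fh.write(f"{chrom}\t{p - 1}\t{p}\t{rid}\n")

    counts.update(gwas_rows=len(entries) + n_skipped,
                  gwas_skipped=n_skipped,
                  gwas_entries=len(entries),
                  gwas_retained=len(retained),
                  candidates=len(assoc))
    return assoc


def stage_report(config: PipelineConfig, assoc, queries, counts: dict) -> dict:
    summary = summarize_candidates(
        assoc, {q.rsnp_id: q.known_target_genes for q in queries})
    summary["half_window_bp"] = config.half_window
    out = Path(config.out_dir)
    with open(out / ARTIFACTS["summary"], "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    counts.update(candidate_rsnps=summary["n_candidate_rsnps"],
                  direct_links=summary["n_direct"],
                  via_marker_links=summary["n_via_marker"])
    return summary


def write_candidates(assoc, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for a in assoc:
            fh.write("\t".join([
                a.rsnp_id, a.gwas_snp_id, a.link_type, a.marker_id or ".",
                str(a.bp_distance), a.trait, ",".join(a.target_genes),
                a.chrom, str(a.pos_gwas)]) + "\n")


def read_candidates(path: str | Path) -> list[CandidateAssociation]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(CandidateAssociation(
                rsnp_id=f[0], gwas_snp_id=f[1], link_type=f[2],
                marker_id=None if f[3] == "." else f[3], bp_distance=int(f[4]),
                trait=f[5], target_genes=[g for g in f[6].split(",") if g],
                chrom=f[7], pos_gwas=int(f[8])))
    return out


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    if config.simulate or config.vcf is None and config.sim is not None:
        config = stage_simulate(config)

    matrix, queries, absent = stage_ingest(config, counts)
    frame = stage_coseg(config, matrix, [q.rsnp_id for q in queries], counts)
    assoc = stage_map(config, matrix, queries, frame, counts)
    stage_report(config, assoc, queries, counts)

    manifest = {
        "tool": "cosegscan",
        "version": __version__,
        "seed": config.seed,
        "config": {**dataclasses.asdict(config)},
        "inputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                   for name, p in (("vcf", config.vcf),
                                   ("annotation", config.annotation),
                                   ("rsnp_list", config.rsnp_list),
                                   ("gwas_table", config.gwas_table))
                   if p is not None},
        "counts": counts,
        "started": t0,
        "finished": time.time(),
    }
    with open(out / ARTIFACTS["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
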