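"""GWAS-catalog filtering and rSNP-to-signal window linking.

A catalog-style association table is filtered by a trait keyword signature
(default: the 12-term cardiovascular signature — heart, coronary artery
disease, CAD, platelet, blood, blood cells, pressure, count, vessel, caliber,
pulse, artery).  An rSNP is then linked to a retained GWAS signal when the
rSNP itself (direct link) or one of its co-segregating coding markers
(via_marker link) lies within a genomic window of the GWAS SNP position.

The window is total-width 10 Kbp centered at the GWAS SNP by default
(half_window = 5,000 bp, closed bounds); the half-window is a parameter so a
one-sided 10 Kbp reading is available.  Direct links dominate: when both a
direct and a marker link exist for an (rSNP, GWAS SNP) pair, only the direct
association is emitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import InputValidationError

#: Trait keyword signature for the cardiovascular disease domain.
CARDIO_SIGNATURE = ("heart", "coronary artery disease", "CAD", "platelet",
                    "blood", "blood cells", "pressure", "count", "vessel",
                    "caliber", "pulse", "artery")

DEFAULT_HALF_WINDOW = 5_000  # bp; 10 Kbp total window centered at the GWAS SNP

# GWAS Catalog download dialect → canonical names; a minimal generic header
# is also accepted.
_COLUMN_ALIASES = {
    "snp": ("SNPS", "snp", "snp_id", "rsid"),
    "chrom": ("CHR_ID", "chrom", "chr", "chromosome"),
    "pos": ("CHR_POS", "pos", "position", "bp"),
    "trait": ("DISEASE/TRAIT", "trait", "disease_trait", "phenotype"),
    "genes": ("MAPPED_GENE", "genes", "mapped_genes", "gene"),
}

_SNP_SPLIT = re.compile(r"\s*(?:;|\sx\s)\s*")
_GENE_SPLIT = re.compile(r"\s*[;,]\s*|\s+-\s+")


@dataclass
class GwasEntry:
    """One GWAS association row after parsing (one SNP per entry)."""

    gwas_snp_id: str
    chrom: str
    pos: int  # 1-based
    trait: str
    mapped_genes: list[str] = field(default_factory=list)
    matched_terms: list[str] = field(default_factory=list)


@dataclass
class CandidateAssociation:
    """One rSNP linked to one GWAS signal, directly or through a marker."""

    rsnp_id: str
    gwas_snp_id: str
    link_type: str  # "direct" | "via_marker"
    marker_id: str | None
    bp_distance: int
    trait: str
    target_genes: list[str] = field(default_factory=list)
    chrom: str = ""
    pos_gwas: int = 0


def load_gwas_table(path) -> tuple[list[GwasEntry], int]:
    """Parse a GWAS-catalog-style TSV.

    Returns (entries, n_skipped) where rows without parseable coordinates are
    skipped and counted.  Multi-SNP rows ("rs1; rs2", "rs1 x rs2") are split
    into independent entries sharing the trait.  Raises
    :class:`InputValidationError` if a mandatory column is missing.
    """
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise InputValidationError(f"empty GWAS table {path}")
        header = header_line.split("\t")
        idx: dict[str, int] = {}
        for canon, aliases in _COLUMN_ALIASES.items():
            for alias in aliases:
                hits = [i for i, h in enumerate(header)
                        if h.strip().lower() == alias.lower()]
                if hits:
                    idx[canon] = hits[0]
                    break
            else:
                if canon != "genes":  # genes column optional
                    raise InputValidationError(
                        f"GWAS table {path} lacks a recognizable "
                        f"{canon!r} column (tried {aliases})")

        entries: list[GwasEntry] = []
        n_skipped = 0
        for line in fh:
            row = line.rstrip("\n").split("\t")
            if len(row) < 2 or not any(x.strip() for x in row):
                continue

            def get(canon: str) -> str:
                i = idx.get(canon)
                return row[i].strip() if i is not None and i < len(row) else ""

            snps = [s for s in _SNP_SPLIT.split(get("snp")) if s]
            chroms = [c for c in _SNP_SPLIT.split(get("chrom")) if c]
            poss = [p for p in _SNP_SPLIT.split(get("pos")) if p]
            trait = get("trait")
            genes = [g for g in _GENE_SPLIT.split(get("genes")) if g] \
                if "genes" in idx else []
            if not snps:
                n_skipped += 1
                continue
            for k, snp in enumerate(snps):
                chrom = chroms[k] if len(chroms) == len(snps) else \
                    (chroms[0] if chroms else "")
                pos_s = poss[k] if len(poss) == len(snps) else \
                    (poss[0] if poss else "")
                try:
                    pos = int(pos_s)
                except ValueError:
                    n_skipped += 1
                    continue
                if not chrom:
                    n_skipped += 1
                    continue
                entries.append(GwasEntry(snp, chrom.removeprefix("chr"),
                                         pos, trait, genes))
    return entries, n_skipped


def _term_pattern(term: str) -> re.Pattern:
    # word-boundary substring: "CAD" must not match "decade"; internal
    # whitespace in multi-word terms is flexible
    body = r"\s+".join(re.escape(w) for w in term.split())
    return re.compile(rf"(?<![A-Za-z0-9]){body}(?![A-Za-z0-9])", re.IGNORECASE)


def filter_by_signature(entries: Sequence[GwasEntry],
                        terms: Sequence[str] = CARDIO_SIGNATURE,
                        ) -> list[GwasEntry]:
    """Retain entries whose trait matches ≥1 signature term (case-insensitive
    substring on word boundaries); populates ``matched_terms``."""
    if not terms:
        raise InputValidationError("signature term list is empty")
    patterns = [(t, _term_pattern(t)) for t in terms]
    out: list[GwasEntry] = []
    for e in entries:
        matched = [t for t, p in patterns if p.search(e.trait)]
        if matched:
            out.append(GwasEntry(e.gwas_snp_id, e.chrom, e.pos, e.trait,
                                 list(e.mapped_genes), matched))
    return out


def window_intersect(
    gwas_entries: Sequence[GwasEntry],
    rsnp_positions: Mapping[str, tuple[str, int]],
    coseg_markers: Mapping[str, Sequence[str]],
    marker_positions: Mapping[str, tuple[str, int]],
    half_window: int = DEFAULT_HALF_WINDOW,
    target_genes: Mapping[str, Sequence[str]] | None = None,
) -> list[CandidateAssociation]:
    """Link rSNPs to GWAS signals within ±half_window bp (closed bounds).

    For each (GWAS entry, rSNP): a direct link is emitted iff they share a
    chromosome and |pos_rsnp − pos_gwas| ≤ half_window; otherwise a via_marker
    link is emitted for the closest co-segregating marker of that rSNP that
    satisfies the window test (ties broken by marker_id).  At most one
    association per (rSNP, GWAS SNP) pair; output sorted by
    (chrom, pos_gwas, rsnp_id).
    """
    import numpy as np

    if half_window < 0:
        raise InputValidationError("half_window must be non-negative")
    target_genes = target_genes or {}

    # index GWAS entries per chromosome, positions sorted for binary search
    grouped: dict[str, list[tuple[int, int]]] = {}
    for i, e in enumerate(gwas_entries):
        grouped.setdefault(e.chrom.removeprefix("chr"), []).append((e.pos, i))
    by_chrom: dict[str, tuple[np.ndarray, list[int]]] = {}
    for c, pairs in grouped.items():
        pairs.sort()
        by_chrom[c] = (np.asarray([p for p, _ in pairs]),
                       [i for _, i in pairs])

    def entries_in_window(chrom: str, pos: int) -> list[int]:
        hit = by_chrom.get(chrom.removeprefix("chr"))
        if hit is None:
            return []
        positions, order = hit
        lo = int(np.searchsorted(positions, pos - half_window, side="left"))
        hi = int(np.searchsorted(positions, pos + half_window, side="right"))
        return order[lo:hi]

    # (rsnp, entry_idx) -> ("direct", None, bp) or ("via_marker", mid, bp)
    links: dict[tuple[str, int], tuple[str, str | None, int]] = {}
    for rid, (rchrom, rpos) in rsnp_positions.items():
        for i in entries_in_window(rchrom, rpos):
            links[(rid, i)] = ("direct", None, abs(rpos - gwas_entries[i].pos))
    for rid in rsnp_positions:
        for mid in coseg_markers.get(rid, ()):
            mp = marker_positions.get(mid)
            if mp is None:
                continue
            mchrom, mpos = mp
            for i in entries_in_window(mchrom, mpos):
                key = (rid, i)
                prev = links.get(key)
                if prev is not None and prev[0] == "direct":
                    continue  # direct dominates
                d = abs(mpos - gwas_entries[i].pos)
                if prev is None or (d, mid) < (prev[2], prev[1]):
                    links[key] = ("via_marker", mid, d)

    out = [CandidateAssociation(
        rsnp_id=rid, gwas_snp_id=gwas_entries[i].gwas_snp_id,
        link_type=link_type, marker_id=marker_id, bp_distance=bp,
        trait=gwas_entries[i].trait,
        target_genes=list(target_genes.get(rid, [])),
        chrom=gwas_entries[i].chrom.removeprefix("chr"),
        pos_gwas=gwas_entries[i].pos)
        for (rid, i), (link_type, marker_id, bp) in links.items()]
    out.sort(key=lambda c: (c.chrom, c.pos_gwas, c.rsnp_id, c.gwas_snp_id))
    return out


def summarize_candidates(associations: Sequence[CandidateAssociation],
                         rsnp_queries: Mapping[str, Sequence[str]] | None = None,
                         ) -> dict:
    """Per-rSNP roll-up and global tallies of the candidate associations.

    Tallies: distinct candidate rSNPs, direct-coincidence links, via-marker
    links, and rSNPs attached to more than one target gene.
    """
    rsnp_queries = rsnp_queries or {}
    per_rsnp: dict[str, dict] = {}
    for a in associations:
        d = per_rsnp.setdefault(a.rsnp_id, {
            "traits": [], "gwas_snp_ids": [], "link_types": [],
            "target_genes": list(rsnp_queries.get(a.rsnp_id, a.target_genes))})
        if a.trait not in d["traits"]:
            d["traits"].append(a.trait)
        d["gwas_snp_ids"].append(a.gwas_snp_id)
        d["link_types"].append(a.link_type)
    n_direct = sum(1 for a in associations if a.link_type == "direct")
    n_via = sum(1 for a in associations if a.link_type == "via_marker")
    n_multi = sum(1 for d in per_rsnp.values() if len(d["target_genes"]) > 1)
    return {
        "n_associations": len(associations),
        "n_candidate_rsnps": len(per_rsnp),
        "n_direct": n_direct,
        "n_via_marker": n_via,
        "n_multi_target_gene_rsnps": n_multi,
        "per_rsnp": per_rsnp,
    }
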