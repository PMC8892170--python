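"""Variant panel ingestion and genotype binarization.

Reads a diploid VCF panel, keeps biallelic SNVs, and turns genotypes into the
0/1 minor-allele codes that the co-segregation scan operates on: per variant
the panel-wide most frequent allele is coded 0 and the minor allele 1.  Two
coding modes are supported —

``carrier``
    one row per individual; an individual is coded 1 iff it carries at least
    one copy of the panel-wide minor allele (heterozygotes collapse to 1);
``haplotype``
    one row per phased haplotype (2N rows), each coded by the allele it
    carries.  Requires phased heterozygous genotypes.

Missing genotypes are imputed to the major allele (code 0) and counted; this
is conservative with respect to co-segregation.  Coordinates follow the VCF
1-based convention; BED annotation intervals (0-based half-open) are converted
to 1-based closed internally.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .errors import InputValidationError

_SNV_ALLELES = frozenset("ACGT")


@dataclass
class VariantInfo:
    """Identity and allele bookkeeping for one panel variant.

    ``mac`` is the number of matrix rows coded 1 under the active coding mode
    (carrier individuals, or minor-allele haplotypes); ``maf`` is the minor
    allele frequency over 2N chromosomes, in [0, 0.5] after orientation.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    minor_allele: str = ""
    mac: int = 0
    maf: float = 0.0
    in_transcribed_region: bool = False


@dataclass
class RsnpQuery:
    """One query regulatory SNP with its known target genes."""

    rsnp_id: str
    known_target_genes: list[str] = field(default_factory=list)


@dataclass
class RawPanel:
    """Diploid genotypes as read from a VCF, before binarization.

    ``alleles`` has shape (n_variants, n_individuals, 2) with entries in
    {0, 1, -1} (-1 = missing); ``phased`` flags each genotype call.
    """

    individual_ids: list[str]
    variants: list[VariantInfo]
    alleles: np.ndarray
    phased: np.ndarray
    n_skipped_non_snv: int = 0

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)


@dataclass
class BinaryGenotypeMatrix:
    """Rows × variants matrix of 0/1 minor-allele codes.

    In carrier mode rows are individuals; in haplotype mode rows are phased
    haplotypes (ids ``<sample>.1`` / ``<sample>.2``).  Column sums equal the
    per-variant ``mac`` exactly.
    """

    individual_ids: list[str]
    variant_index: list[str]
    codes: np.ndarray  # bool, shape (n_rows, n_variants)
    coding_mode: str
    variants: list[VariantInfo]
    n_imputed: int = 0

    def __post_init__(self) -> None:
        self._col = {vid: j for j, vid in enumerate(self.variant_index)}

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.codes[:, self._col[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def column_index(self, variant_id: str) -> int:
        return self._col[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._col

    def mac_array(self) -> np.ndarray:
        return self.codes.sum(axis=0)

    # -- persistence (two-part plain-text artifact) --

    def save(self, variants_path: str | Path, matrix_path: str | Path) -> None:
        with open(variants_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["variant_id", "chrom", "pos", "ref", "alt", "minor",
                        "mac", "maf", "in_transcribed_region"])
            for v in self.variants:
                w.writerow([v.variant_id, v.chrom, v.pos, v.ref_allele,
                            v.alt_allele, v.minor_allele, v.mac,
                            repr(v.maf), int(v.in_transcribed_region)])
        with open(matrix_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["row_id", "coding_mode:" + self.coding_mode]
                       + self.variant_index)
            for i, rid in enumerate(self.individual_ids):
                w.writerow([rid, ""] + self.codes[i].astype(int).tolist())

    @classmethod
    def load(cls, variants_path: str | Path,
             matrix_path: str | Path) -> "BinaryGenotypeMatrix":
        variants: list[VariantInfo] = []
        with open(variants_path) as fh:
            r = csv.reader(fh, delimiter="\t")
            next(r)
            for row in r:
                variants.append(VariantInfo(
                    variant_id=row[0], chrom=row[1], pos=int(row[2]),
                    ref_allele=row[3], alt_allele=row[4], minor_allele=row[5],
                    mac=int(row[6]), maf=float(row[7]),
                    in_transcribed_region=bool(int(row[8]))))
        with open(matrix_path) as fh:
            r = csv.reader(fh, delimiter="\t")
            header = next(r)
            coding_mode = header[1].split(":", 1)[1]
            variant_index = header[2:]
            row_ids, rows = [], []
            for row in r:
                row_ids.append(row[0])
                rows.append([int(x) for x in row[2:]])
        codes = np.asarray(rows, dtype=bool)
        return cls(row_ids, variant_index, codes, coding_mode, variants)


# ---------------------------------------------------------------------------
# VCF ingestion


def _in_regions(chrom: str, pos: int,
                regions: Sequence[tuple[str, int, int]]) -> bool:
    c = chrom.removeprefix("chr")
    return any(c == rc.removeprefix("chr") and start <= pos <= end
               for rc, start, end in regions)


def load_panel(vcf_path: str | Path,
               regions: Sequence[tuple[str, int, int]] | None = None) -> RawPanel:
    """Read biallelic SNVs from a VCF into a :class:`RawPanel`.

    Parameters
    ----------
    vcf_path
        Path to a VCF 4.x file (plain or bgzipped) with GT fields.
    regions
        Optional 1-based closed intervals ``(chrom, start, end)``; variants
        outside every interval are skipped.

    Raises
    ------
    InputValidationError
        If the file is unreadable/malformed or zero variants are retained.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(vcf_path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise InputValidationError(f"cannot read VCF {vcf_path}: {exc}") from exc

    individual_ids = list(reader.samples)
    variants: list[VariantInfo] = []
    allele_rows: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []
    n_skipped = 0
    seen_ids: set[str] = set()

    try:
        for rec in reader:
            alts = rec.ALT
            if (len(alts) != 1 or rec.REF not in _SNV_ALLELES
                    or alts[0] not in _SNV_ALLELES):
                n_skipped += 1
                continue
            if regions is not None and not _in_regions(rec.CHROM, rec.POS, regions):
                continue
            vid = rec.ID if rec.ID not in (None, ".") else \
                f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alts[0]}"
            if vid in seen_ids:
                raise InputValidationError(
                    f"duplicate variant id {vid!r} at {rec.CHROM}:{rec.POS}")
            seen_ids.add(vid)
            gts = np.asarray(rec.genotypes, dtype=np.int8)  # (n, 3)
            allele_rows.append(gts[:, :2].copy())
            phased_rows.append(gts[:, 2].astype(bool))
            variants.append(VariantInfo(vid, rec.CHROM.removeprefix("chr"),
                                        rec.POS, rec.REF, alts[0]))
    except InputValidationError:
        raise
    except Exception as exc:
        raise InputValidationError(
            f"malformed VCF record in {vcf_path} after "
            f"{len(variants) + n_skipped} records: {exc}") from exc

    if not variants:
        raise InputValidationError(
            f"zero variants retained from {vcf_path}"
            + (" (region restriction)" if regions is not None else ""))

    return RawPanel(individual_ids, variants,
                    np.stack(allele_rows), np.stack(phased_rows),
                    n_skipped_non_snv=n_skipped)


# ---------------------------------------------------------------------------
# Binarization


def binarize(panel: RawPanel, coding_mode: str = "carrier") -> BinaryGenotypeMatrix:
    """Orient alleles panel-wide (most frequent → 0) and emit the 0/1 matrix.

    Missing alleles are imputed to the major allele and counted in
    ``n_imputed``.  Frequency ties (maf = 0.5) designate ALT as minor.
    """
    if coding_mode not in ("carrier", "haplotype"):
        raise InputValidationError(f"unknown coding_mode {coding_mode!r}")

    alleles = panel.alleles  # (m, n, 2)
    m, n, _ = alleles.shape
    missing = alleles < 0
    n_imputed = int(missing.sum())

    # Orientation from observed allele counts; missing alleles side with the
    # major allele, so they never decide orientation against the data.
    alt_counts = (alleles == 1).sum(axis=(1, 2))
    obs_counts = (~missing).sum(axis=(1, 2))
    alt_is_minor = alt_counts * 2 <= obs_counts  # ties → ALT minor

    if coding_mode == "haplotype":
        het = (alleles[:, :, 0] >= 0) & (alleles[:, :, 1] >= 0) \
            & (alleles[:, :, 0] != alleles[:, :, 1])
        unphased_het = het & ~panel.phased
        if unphased_het.any():
            i, j = np.argwhere(unphased_het)[0]
            raise InputValidationError(
                "haplotype coding requires phased genotypes: unphased "
                f"heterozygote for sample {panel.individual_ids[j]!r} at "
                f"variant {panel.variants[i].variant_id!r}; use carrier mode")
        hap = alleles.reshape(m, 2 * n).T  # (2n, m); rows s1.1, s1.2, s2.1, ...
        imputed = np.where(hap < 0, 0, hap)
        codes = np.where(alt_is_minor[None, :], imputed == 1, imputed == 0)
        row_ids = [f"{sid}.{k}" for sid in panel.individual_ids for k in (1, 2)]
    else:
        a0 = np.where(missing[:, :, 0], 0, alleles[:, :, 0])
        a1 = np.where(missing[:, :, 1], 0, alleles[:, :, 1])
        has_alt = (a0 == 1) | (a1 == 1)
        has_ref = (a0 == 0) | (a1 == 0)
        codes = np.where(alt_is_minor[:, None], has_alt, has_ref).T  # (n, m)
        row_ids = list(panel.individual_ids)

    codes = np.ascontiguousarray(codes, dtype=bool)
    mac = codes.sum(axis=0)
    # imputed alleles are major by construction: denominator stays 2N
    minor_counts = np.where(alt_is_minor, alt_counts, obs_counts - alt_counts)
    maf = minor_counts / (2 * n)

    variants = [replace(v,
                        minor_allele=(v.alt_allele if alt_is_minor[j] else v.ref_allele),
                        mac=int(mac[j]), maf=float(maf[j]))
                for j, v in enumerate(panel.variants)]

    return BinaryGenotypeMatrix(row_ids, [v.variant_id for v in variants],
                                codes, coding_mode, variants,
                                n_imputed=n_imputed)


# ---------------------------------------------------------------------------
# Annotation and analysis-universe restriction


def read_annotation(path: str | Path) -> dict[str, IntervalTree]:
    """Read gene/transcript intervals from BED (0-based half-open) or GFF3
    (1-based closed) into per-chromosome interval trees keyed 1-based closed.
    """
    path = Path(path)
    trees: dict[str, IntervalTree] = {}
    is_gff = path.suffix.lower() in (".gff", ".gff3", ".gtf")
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if is_gff:
                    chrom, start, end = f[0], int(f[3]), int(f[4])
                else:
                    chrom, start, end = f[0], int(f[1]) + 1, int(f[2])
            except (IndexError, ValueError) as exc:
                raise InputValidationError(
                    f"malformed annotation line {ln} in {path}: {line!r}") from exc
            if end < start:
                continue
            # IntervalTree is half-open: [start, end + 1) covers 1-based closed
            trees.setdefault(chrom.removeprefix("chr"), IntervalTree()) \
                 .addi(start, end + 1)
    if not trees:
        raise InputValidationError(f"no intervals read from {path}")
    return trees


def read_rsnp_list(path: str | Path) -> list[RsnpQuery]:
    """Read the 2-column rSNP query TSV (rsnp_id, comma-separated genes)."""
    queries: list[RsnpQuery] = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rid = parts[0].strip()
            if ln == 1 and rid.lower() in ("rsnp_id", "rsnp", "id"):
                continue
            if not rid:
                raise InputValidationError(f"empty rsnp_id at line {ln} of {path}")
            if rid in seen:
                continue
            seen.add(rid)
            genes = []
            if len(parts) > 1 and parts[1].strip():
                genes = [g.strip() for g in parts[1].split(",") if g.strip()]
            queries.append(RsnpQuery(rid, genes))
    if not queries:
        raise InputValidationError(f"no rSNP queries read from {path}")
    return queries


def restrict_to_transcribed(
    matrix: BinaryGenotypeMatrix,
    annotation: Mapping[str, IntervalTree],
    rsnp_ids: Iterable[str],
) -> tuple[BinaryGenotypeMatrix, list[str]]:
    """Restrict columns to the analysis universe.

    Retained columns are the query rSNPs present in the panel plus every SNP
    whose position falls inside at least one annotation interval; rSNPs are
    retained regardless of annotation overlap.  Returns the restricted matrix
    and the list of query rSNPs absent from the panel.
    """
    rsnp_set = set(rsnp_ids)
    absent = sorted(rsnp_set - set(matrix.variant_index))

    keep: list[int] = []
    new_variants: list[VariantInfo] = []
    for j, v in enumerate(matrix.variants):
        tree = annotation.get(v.chrom.removeprefix("chr"))
        in_tx = bool(tree is not None and tree[v.pos])
        if in_tx or v.variant_id in rsnp_set:
            keep.append(j)
            new_variants.append(replace(v, in_transcribed_region=in_tx))

    if not keep:
        raise InputValidationError(
            "restriction to transcribed regions retained zero variants")

    sub = np.ascontiguousarray(matrix.codes[:, keep])
    return (BinaryGenotypeMatrix(matrix.individual_ids,
                                 [v.variant_id for v in new_variants],
                                 sub, matrix.coding_mode, new_variants,
                                 n_imputed=matrix.n_imputed),
            absent)
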