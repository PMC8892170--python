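"""Seeded synthetic input bundles for the co-segregation pipeline.

Emulates, at desk scale, the study design the pipeline targets: a
multi-population diploid panel (population structure as Balding–Nichols
frequency-shifted strata), background SNPs in linkage equilibrium, planted
rSNP–marker pairs whose minor-allele carrier vectors co-segregate (the marker
is a copy of the rSNP carrier vector with independent per-row flips at
probability ε), a gene annotation delimiting transcribed regions, a
GWAS-catalog-style trait table partially matching the cardiovascular keyword
signature, and a machine-readable truth file.

Genome layout guarantees an exact truth set for the planted candidate
associations: each query rSNP gets its own locus on chromosome 1, loci are
separated by many window widths, background SNPs live on chromosome 2 far
from every GWAS position, and by default the query carrier sets are drawn
disjointly across queries so that, with ε = 0, a planted marker can never be
falsely called co-segregating with another locus' rSNP (their carrier overlap
is exactly zero, hence p = 1).  Generation is a pure function of the
configuration: the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputValidationError

POPULATION_NAMES = ("AFR", "AMR", "ASN", "EUR")

#: trait strings that match the cardiovascular signature
CARDIO_TRAITS = (
    "Systolic blood pressure",
    "Coronary artery disease",
    "Platelet count",
    "Heart rate response to exercise",
    "Pulse pressure",
    "Retinal vessel caliber",
    "Red blood cell count",
    "Diastolic blood pressure",
)

#: trait strings that match no signature term (word-boundary matching)
NEUTRAL_TRAITS = (
    "Height",
    "Educational attainment",
    "Male-pattern baldness",
    "Freckling",
    "Bone mineral density",
)

_GT_STR = ("0|0", "0|1", "1|0", "1|1")
_DIRECT_OFFSET_CYCLE = (0, 0, 2500, -1, 0, 1234)  # -1 → exactly half_window


@dataclass
class PlantedPair:
    """One planted co-segregating rSNP–marker pair.

    ``marker_offset_bp`` is the rSNP-to-marker distance; offsets larger than
    the half-window create loci whose GWAS link can only be via the marker.
    ``target_maf`` is the target carrier fraction of the rSNP column.
    """

    rsnp_index: int
    marker_offset_bp: int = 500
    flip_prob: float = 0.0
    target_maf: float = 0.06


@dataclass
class SimConfig:
    """Full description of one synthetic bundle."""

    n_individuals: int = 500
    n_populations: int = 4
    n_background_snps: int = 2000
    n_rsnps: int = 12
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    maf_beta_a: float = 0.8
    maf_beta_b: float = 1.8
    fst: float = 0.05
    n_genes: int = 20
    gene_length_bp: int = 4000
    n_gwas_entries: int = 40
    fraction_signature_matching: float = 0.6
    fraction_within_window: float = 0.5
    half_window_bp: int = 5000
    n_absent_rsnps: int = 2
    unplanted_carrier_fraction: float = 0.05
    rsnp_carrier_mode: str = "disjoint"  # or "independent"
    fraction_background_in_genes: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_individuals, self.n_rsnps, self.n_genes,
               self.gene_length_bp) <= 0 or self.n_background_snps < 0:
            raise InputValidationError("all counts must be positive")
        for f in (self.fraction_signature_matching, self.fraction_within_window,
                  self.fraction_background_in_genes):
            if not 0.0 <= f <= 1.0:
                raise InputValidationError("fractions must lie in [0, 1]")
        if self.rsnp_carrier_mode not in ("disjoint", "independent"):
            raise InputValidationError(
                f"unknown rsnp_carrier_mode {self.rsnp_carrier_mode!r}")
        seen = set()
        for p in self.planted_pairs:
            if not 0 <= p.rsnp_index < self.n_rsnps:
                raise InputValidationError(
                    f"planted rsnp_index {p.rsnp_index} out of range")
            if p.rsnp_index in seen:
                raise InputValidationError(
                    f"duplicate planted rsnp_index {p.rsnp_index}")
            seen.add(p.rsnp_index)
            if not 0.0 <= p.flip_prob <= 1.0:
                raise InputValidationError("flip_prob must lie in [0, 1]")
            if not 0.0 < p.target_maf <= 0.5:
                raise InputValidationError("target_maf must lie in (0, 0.5]")
            if p.marker_offset_bp >= self._locus_spacing() // 4:
                raise InputValidationError(
                    f"marker_offset_bp {p.marker_offset_bp} too large for the "
                    f"locus spacing {self._locus_spacing()}")
        n_planted = len(self.planted_pairs)
        if self.n_genes <= n_planted and self.n_background_snps > 0:
            raise InputValidationError(
                "n_genes must exceed the number of planted pairs so that "
                "background SNPs have transcribed regions to live in")
        if self.rsnp_carrier_mode == "disjoint":
            total = sum(round(p.target_maf * self.n_individuals)
                        for p in self.planted_pairs)
            total += (self.n_rsnps - n_planted) * round(
                self.unplanted_carrier_fraction * self.n_individuals)
            if total > self.n_individuals:
                raise InputValidationError(
                    f"disjoint carrier sets infeasible: {total} carriers "
                    f"needed for {self.n_individuals} individuals; use "
                    "rsnp_carrier_mode='independent'")

    def _locus_spacing(self) -> int:
        return max(20 * self.half_window_bp, 100_000)


def default_config(seed: int = 0) -> SimConfig:
    """The canonical end-to-end bundle: 12 query rSNPs (8 planted pairs,
    three of them linkable only via their marker), 2,000 background SNPs,
    40 GWAS rows, all planted flips at ε = 0."""
    planted = [
        PlantedPair(0, 500, 0.0, 0.05),
        PlantedPair(1, 800, 0.0, 0.06),
        PlantedPair(2, 1200, 0.0, 0.07),
        PlantedPair(3, 2000, 0.0, 0.08),
        PlantedPair(4, 500, 0.0, 0.05),
        PlantedPair(5, 12000, 0.0, 0.06),
        PlantedPair(6, 12000, 0.0, 0.07),
        PlantedPair(7, 15000, 0.0, 0.05),
    ]
    return SimConfig(planted_pairs=planted, seed=seed)


@dataclass
class GeneratedBundle:
    """Paths of one generated input bundle plus its truth record."""

    vcf: Path
    bed: Path
    rsnp_tsv: Path
    gwas_tsv: Path
    truth_json: Path
    truth: dict


# ---------------------------------------------------------------------------
# low-level generators (also used directly by the statistical studies)


def generate_null_pairs(n_pairs: int, n_rows: int,
                        maf_range: tuple[float, float] = (0.05, 0.5),
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Independent carrier-vector pairs for type-I-error estimation.

    Carrier frequencies are uniform in ``maf_range``; each vector's rows are
    i.i.d. Bernoulli draws.  Returns two boolean arrays (n_pairs, n_rows).
    """
    lo, hi = maf_range
    if not (0 <= lo <= hi <= 1):
        raise InputValidationError("maf_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    fa = rng.uniform(lo, hi, n_pairs)
    fb = rng.uniform(lo, hi, n_pairs)
    a = rng.random((n_pairs, n_rows)) < fa[:, None]
    b = rng.random((n_pairs, n_rows)) < fb[:, None]
    return a, b


def generate_planted_pairs(n_pairs: int, n_rows: int, flip_prob: float,
                           carrier_range: tuple[float, float] = (0.05, 0.2),
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Planted co-segregating carrier-vector pairs for recovery studies.

    The rSNP vector gets an exact carrier count drawn from
    round(f · n_rows), f uniform in ``carrier_range``; the marker is a copy
    with independent per-row flips at probability ``flip_prob``.
    """
    rng = np.random.default_rng(seed)
    a = np.zeros((n_pairs, n_rows), dtype=bool)
    for i in range(n_pairs):
        k = round(rng.uniform(*carrier_range) * n_rows)
        a[i, rng.choice(n_rows, size=k, replace=False)] = True
    flips = rng.random((n_pairs, n_rows)) < flip_prob
    return a, a ^ flips


def _carrier_to_genotypes(carrier: np.ndarray, rng: np.random.Generator,
                          ) -> np.ndarray:
    """Realize phased diploid genotypes consistent with a carrier vector.

    The haploid minor-allele frequency q solves the Hardy–Weinberg carrier
    relation 1 − (1 − q)² = f; carriers are heterozygous (random phase) or
    homozygous with the conditional HW probabilities, non-carriers are 0|0.
    """
    n = carrier.shape[0]
    f = max(carrier.mean(), 1.0 / n)
    q = 1.0 - np.sqrt(max(0.0, 1.0 - f))
    p_hom_given_carrier = q * q / f if f > 0 else 0.0
    gt = np.zeros((n, 2), dtype=np.int8)
    idx = np.flatnonzero(carrier)
    hom = rng.random(idx.size) < p_hom_given_carrier
    phase = rng.integers(0, 2, idx.size)
    gt[idx[hom]] = (1, 1)
    het = idx[~hom]
    gt[het, phase[~hom]] = 1
    return gt


# ---------------------------------------------------------------------------
# bundle generation


def generate_panel(config: SimConfig, out_dir: str | Path) -> GeneratedBundle:
    """Write a complete synthetic input bundle into ``out_dir``.

    Files: ``panel.vcf`` (VCF 4.2, phased diploid), ``genes.bed`` (BED3 with
    gene names), ``rsnps.tsv`` (query list incl. deliberately absent ids),
    ``gwas.tsv`` (GWAS Catalog column dialect) and ``truth.json``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    hw = config.half_window_bp
    spacing = config._locus_spacing()

    # -- populations and samples
    pop_names = list(POPULATION_NAMES[:config.n_populations])
    pop_names += [f"POP{k}" for k in range(len(pop_names) + 1,
                                           config.n_populations + 1)]
    pop_of = np.repeat(np.arange(config.n_populations),
                       -(-n // config.n_populations))[:n]
    sample_ids = [f"{pop_names[pop_of[i]]}_{i:04d}" for i in range(n)]

    # -- genome layout
    planted = sorted(config.planted_pairs, key=lambda p: p.rsnp_index)
    planted_by_idx = {p.rsnp_index: p for p in planted}
    locus_center = {j: 50_000 + j * spacing for j in range(config.n_rsnps)}
    gene_rows: list[tuple[str, int, int, str]] = []  # chrom, start0, end0, name
    rsnp_pos: dict[int, tuple[str, int]] = {}
    marker_pos: dict[int, tuple[str, int]] = {}
    half_gene = config.gene_length_bp // 2
    for j in range(config.n_rsnps):
        c = locus_center[j]
        if j in planted_by_idx:
            p = planted_by_idx[j]
            gene_rows.append(("1", c - half_gene - 1,
                              c - half_gene - 1 + config.gene_length_bp,
                              f"GENE_L{j:02d}"))
            marker_pos[j] = ("1", c)
            rsnp_pos[j] = ("1", c - p.marker_offset_bp)
        else:
            rsnp_pos[j] = ("1", c)

    n_bg_genes = config.n_genes - len(planted)
    bg_gene_pitch = config.gene_length_bp + 46_000
    bg_region_start = 100_000
    for k in range(n_bg_genes):
        s = bg_region_start + k * bg_gene_pitch
        gene_rows.append(("2", s - 1, s - 1 + config.gene_length_bp,
                          f"GENE_B{k:02d}"))
    bg_region_end = bg_region_start + max(n_bg_genes, 1) * bg_gene_pitch
    desert_start = bg_region_end + 500_000

    # -- background SNP positions (chrom 2): in-gene vs intergenic
    n_bg = config.n_background_snps
    n_in_gene = round(config.fraction_background_in_genes * n_bg)
    bg_positions: list[tuple[int, bool]] = []  # (pos, in_gene)
    if n_bg:
        bg_genes = [g for g in gene_rows if g[0] == "2"]
        per_gene = np.bincount(np.arange(n_in_gene) % max(n_bg_genes, 1),
                               minlength=max(n_bg_genes, 1))
        for k, g in enumerate(bg_genes):
            size = int(per_gene[k])
            if size > config.gene_length_bp:
                raise InputValidationError(
                    "gene_length_bp too small for the requested number of "
                    "in-gene background SNPs")
            lo, hi = g[1] + 1, g[2]  # 1-based closed
            pos = rng.choice(np.arange(lo, hi + 1), size=size, replace=False)
            bg_positions += [(int(x), True) for x in pos]
        n_inter = n_bg - len(bg_positions)
        margin = hw + 2_000
        gaps = []
        for k in range(len(bg_genes)):
            gap_lo = bg_genes[k][2] + margin
            gap_hi = (bg_genes[k + 1][1] - margin if k + 1 < len(bg_genes)
                      else bg_region_end)
            if gap_hi > gap_lo:
                gaps.append((gap_lo, gap_hi))
        if not gaps and n_inter:
            raise InputValidationError("no intergenic room for background SNPs")
        pool = np.concatenate([np.arange(lo, hi) for lo, hi in gaps])
        pos = rng.choice(pool, size=n_inter, replace=False)
        bg_positions += [(int(x), False) for x in pos]

    # -- carrier vectors for query rSNPs (and planted markers)
    rsnp_carrier: dict[int, np.ndarray] = {}
    if config.rsnp_carrier_mode == "disjoint":
        pool = rng.permutation(n)
        cursor = 0
    for j in range(config.n_rsnps):
        f = (planted_by_idx[j].target_maf if j in planted_by_idx
             else config.unplanted_carrier_fraction)
        k = round(f * n)
        vec = np.zeros(n, dtype=bool)
        if config.rsnp_carrier_mode == "disjoint":
            vec[pool[cursor:cursor + k]] = True
            cursor += k
        else:
            vec[rng.choice(n, size=k, replace=False)] = True
        rsnp_carrier[j] = vec
    marker_carrier = {j: rsnp_carrier[j]
                      ^ (rng.random(n) < planted_by_idx[j].flip_prob)
                      for j in planted_by_idx}

    # -- assemble variants
    rsnp_ids = {j: f"rs1{j:06d}" for j in range(config.n_rsnps)}
    marker_ids = {j: f"rs2{j:06d}" for j in planted_by_idx}
    alleles = np.array(list("ACGT"))

    variants: list[dict] = []  # vid, chrom, pos, ref, alt, gt (n,2)
    truth_freqs: dict[str, dict] = {}

    for j in range(config.n_rsnps):
        ref, alt = rng.choice(alleles, size=2, replace=False)
        gt = _carrier_to_genotypes(rsnp_carrier[j], rng)
        variants.append(dict(vid=rsnp_ids[j], chrom=rsnp_pos[j][0],
                             pos=rsnp_pos[j][1], ref=str(ref), alt=str(alt),
                             gt=gt))
        truth_freqs[rsnp_ids[j]] = {
            "carrier_freq": float(rsnp_carrier[j].mean())}
        if j in planted_by_idx:
            ref2, alt2 = rng.choice(alleles, size=2, replace=False)
            c, m = rsnp_carrier[j], marker_carrier[j]
            gt2 = gt.copy()
            flipped_in = m & ~c
            gt2[~m] = 0
            if flipped_in.any():
                gt2[flipped_in] = _carrier_to_genotypes(m, rng)[flipped_in]
            variants.append(dict(vid=marker_ids[j], chrom=marker_pos[j][0],
                                 pos=marker_pos[j][1], ref=str(ref2),
                                 alt=str(alt2), gt=gt2))
            truth_freqs[marker_ids[j]] = {"carrier_freq": float(m.mean())}

    # background SNPs: Balding–Nichols frequency-shifted strata
    if n_bg:
        p0 = 0.01 + 0.49 * rng.beta(config.maf_beta_a, config.maf_beta_b, n_bg)
        F = config.fst
        shape_a = p0 * (1 - F) / F
        shape_b = (1 - p0) * (1 - F) / F
        pop_freq = rng.beta(shape_a[None, :], shape_b[None, :],
                            (config.n_populations, n_bg))
        hap = rng.random((n_bg, n, 2)) < pop_freq[pop_of, :].T[:, :, None]
        for i, (pos, in_gene) in enumerate(bg_positions):
            ref, alt = rng.choice(alleles, size=2, replace=False)
            vid = f"rs3{i:06d}"
            variants.append(dict(vid=vid, chrom="2", pos=pos, ref=str(ref),
                                 alt=str(alt), gt=hap[i].astype(np.int8)))
            truth_freqs[vid] = {
                "base_freq": float(p0[i]),
                "pop_freqs": [float(x) for x in pop_freq[:, i]],
                "in_gene": in_gene}

    chrom_order = {"1": 0, "2": 1}
    variants.sort(key=lambda v: (chrom_order[v["chrom"]], v["pos"], v["vid"]))

    # -- GWAS table
    n_sig = round(config.fraction_signature_matching * config.n_gwas_entries)
    n_linked = round(config.fraction_within_window * n_sig)
    target_genes: dict[int, list[str]] = {}
    for j in range(config.n_rsnps):
        if j in planted_by_idx:
            target_genes[j] = [f"GENE_L{j:02d}"]
        else:
            target_genes[j] = [f"GENE_U{j:02d}"]
    if config.n_rsnps > 0:
        target_genes[0] = target_genes[0] + ["GENE_X00"]  # multi-target case

    gwas_rows: list[dict] = []  # snp, chrom, pos, trait, gene
    expected_candidates: list[dict] = []
    gwas_serial = 0
    direct_cycle = 0
    for i in range(n_linked):
        j = i % config.n_rsnps
        trait = CARDIO_TRAITS[i % len(CARDIO_TRAITS)]
        p = planted_by_idx.get(j)
        if p is not None and p.marker_offset_bp > hw:
            # via-marker locus: within window of the marker, out of the
            # rSNP's window
            d = min(1000, hw)
            pos = marker_pos[j][1] + d
            gid = f"rs9{gwas_serial:05d}"
            gwas_serial += 1
            gwas_rows.append(dict(snp=gid, chrom="1", pos=pos, trait=trait,
                                  gene=target_genes[j][0]))
            if p.flip_prob == 0.0:
                expected_candidates.append(dict(
                    rsnp_id=rsnp_ids[j], gwas_snp_id=gid,
                    link_type="via_marker", marker_id=marker_ids[j],
                    bp_distance=d, trait=trait,
                    target_genes=target_genes[j], chrom="1", pos_gwas=pos))
        else:
            off = _DIRECT_OFFSET_CYCLE[direct_cycle % len(_DIRECT_OFFSET_CYCLE)]
            direct_cycle += 1
            d = hw if off == -1 else min(off, hw)
            pos = rsnp_pos[j][1] + d
            # a zero-distance GWAS SNP *is* the rSNP (coinciding positions
            # share the id, as in real catalogs) — but only once per rSNP
            gid = rsnp_ids[j] if d == 0 and i < config.n_rsnps \
                else f"rs9{gwas_serial:05d}"
            gwas_serial += 1
            gwas_rows.append(dict(snp=gid, chrom="1", pos=pos, trait=trait,
                                  gene=target_genes[j][0]))
            expected_candidates.append(dict(
                rsnp_id=rsnp_ids[j], gwas_snp_id=gid, link_type="direct",
                marker_id=None, bp_distance=d, trait=trait,
                target_genes=target_genes[j], chrom="1", pos_gwas=pos))
    for i in range(n_sig - n_linked):
        gwas_rows.append(dict(
            snp=f"rs9{gwas_serial:05d}", chrom="2",
            pos=desert_start + i * 25_000,
            trait=CARDIO_TRAITS[(n_linked + i) % len(CARDIO_TRAITS)],
            gene=f"GENE_D{i:02d}"))
        gwas_serial += 1
    for i in range(config.n_gwas_entries - n_sig):
        gwas_rows.append(dict(
            snp=f"rs9{gwas_serial:05d}", chrom="2",
            pos=desert_start + (n_sig - n_linked + i) * 25_000 + 12_500,
            trait=NEUTRAL_TRAITS[i % len(NEUTRAL_TRAITS)],
            gene=f"GENE_D{i + 50:02d}"))
        gwas_serial += 1

    expected_candidates.sort(
        key=lambda c: (c["chrom"], c["pos_gwas"], c["rsnp_id"],
                       c["gwas_snp_id"]))

    # -- write files
    vcf_path = out_dir / "panel.vcf"
    _write_vcf(vcf_path, sample_ids, variants)

    bed_path = out_dir / "genes.bed"
    with open(bed_path, "w") as fh:
        for chrom, s0, e0, name in sorted(
                gene_rows, key=lambda g: (chrom_order[g[0]], g[1])):
            fh.write(f"{chrom}\t{s0}\t{e0}\t{name}\n")

    rsnp_path = out_dir / "rsnps.tsv"
    absent_ids = [f"rs8{k:06d}" for k in range(config.n_absent_rsnps)]
    with open(rsnp_path, "w") as fh:
        fh.write("rsnp_id\ttarget_genes\n")
        for j in range(config.n_rsnps):
            fh.write(f"{rsnp_ids[j]}\t{','.join(target_genes[j])}\n")
        for k, rid in enumerate(absent_ids):
            fh.write(f"{rid}\tGENE_A{k:02d}\n")

    gwas_path = out_dir / "gwas.tsv"
    with open(gwas_path, "w") as fh:
        fh.write("SNPS\tCHR_ID\tCHR_POS\tDISEASE/TRAIT\tMAPPED_GENE\n")
        for r in gwas_rows:
            fh.write(f"{r['snp']}\t{r['chrom']}\t{r['pos']}\t{r['trait']}\t"
                     f"{r['gene']}\n")

    truth = {
        "config": {**asdict(config),
                   "planted_pairs": [asdict(p) for p in planted]},
        "planted_coseg_pairs": [
            dict(rsnp_id=rsnp_ids[p.rsnp_index],
                 marker_id=marker_ids[p.rsnp_index],
                 flip_prob=p.flip_prob,
                 rsnp_mac=int(rsnp_carrier[p.rsnp_index].sum()),
                 marker_mac=int(marker_carrier[p.rsnp_index].sum()))
            for p in planted],
        "planted_candidates": expected_candidates,
        "rsnp_ids": [rsnp_ids[j] for j in range(config.n_rsnps)],
        "absent_rsnp_ids": absent_ids,
        "variant_frequencies": truth_freqs,
        "n_variants": len(variants),
        "n_gwas_signature_matching": n_sig,
        "n_gwas_within_window": n_linked,
    }
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return GeneratedBundle(vcf_path, bed_path, rsnp_path, gwas_path,
                           truth_path, truth)


def _write_vcf(path: Path, sample_ids: list[str], variants: list[dict]) -> None:
    max_pos: dict[str, int] = {}
    for v in variants:
        max_pos[v["chrom"]] = max(max_pos.get(v["chrom"], 0), v["pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cosegscan-synthetic\n")
        for chrom in sorted(max_pos):
            fh.write(f"##contig=<ID={chrom},length={max_pos[chrom] + 10_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for v in variants:
            codes = v["gt"][:, 0] * 2 + v["gt"][:, 1]
            gts = "\t".join(_GT_STR[c] for c in codes)
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['vid']}\t{v['ref']}\t"
                     f"{v['alt']}\t.\tPASS\t.\tGT\t{gts}\n")
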