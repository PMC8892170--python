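"""XOR co-segregation scan between query rSNPs and coding markers.

The statistic is the Hamming (XOR) distance between two binarized genotype
columns: the number of rows at which the minor-allele codes differ.  Two
variants that travel together through genotypes have a small XOR distance.

Writing A and B for the carrier sets of the two columns (mac_a = |A|,
mac_b = |B|, overlap = |A ∩ B|), the identity

    xor = mac_a + mac_b − 2·overlap

links the distance to the carrier-set overlap.  Under random assortment of
carriers with both margins fixed, overlap follows the hypergeometric law
Hypergeometric(N, mac_a, mac_b); the exact one-sided p-value of an observed
distance is P(XOR ≤ observed) = P(overlap ≥ k_obs).  A seeded permutation
estimate of the same tail is provided as a cross-validating null.

The default normalization divides by the union of carrier sets, giving the
Jaccard distance: 0 iff the carrier sets coincide (and are non-empty), 1 iff
they are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .errors import ComputationError, InputValidationError
from .panel_io import BinaryGenotypeMatrix

NORMALIZATION_MODES = ("union", "min_mac", "max_mac", "sum_mac")
RECORD_COLUMNS = ["rsnp_id", "marker_id", "xor_distance", "union_count",
                  "normalized_distance", "p_value", "cosegregating"]


@dataclass
class DistanceRecord:
    """One scanned rSNP–marker pair."""

    rsnp_id: str
    marker_id: str
    xor_distance: int
    union_count: int
    normalized_distance: float
    p_value: float
    cosegregating: bool


@dataclass
class CosegConfig:
    """Scan configuration.

    alpha
        Calling threshold on the (possibly adjusted) p-value; the default
        0.01 mirrors the p < 0.01 calling rule of the original analysis.
    normalization
        Denominator for the normalized distance; ``union`` (Jaccard) is the
        only mode bounded in [0, 1].
    null_model
        ``hypergeometric_exact`` (deterministic) or ``permutation``.
    multiple_testing
        ``none`` reproduces raw p < alpha calling; ``benjamini_hochberg``
        controls FDR across all tested pairs of a scan.
    """

    alpha: float = 0.01
    normalization: str = "union"
    null_model: str = "hypergeometric_exact"
    n_permutations: int = 1000
    seed: int = 0
    multiple_testing: str = "none"
    chunk_size: int = 8192

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.normalization not in NORMALIZATION_MODES:
            raise InputValidationError(
                f"normalization must be one of {NORMALIZATION_MODES}")
        if self.null_model not in ("hypergeometric_exact", "permutation"):
            raise InputValidationError(f"unknown null_model {self.null_model!r}")
        if self.null_model == "permutation" and self.n_permutations < 100:
            raise InputValidationError("n_permutations must be >= 100")
        if self.multiple_testing not in ("none", "benjamini_hochberg"):
            raise InputValidationError(
                f"unknown multiple_testing {self.multiple_testing!r}")


def _as_binary(vec) -> np.ndarray:
    a = np.asarray(vec)
    if a.dtype != bool:
        if not np.isin(a, (0, 1)).all():
            raise InputValidationError("vector entries must be 0/1")
        a = a.astype(bool)
    return a


def xor_distance(a, b) -> int:
    """Hamming distance between two equal-length 0/1 vectors."""
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise InputValidationError(
            f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return int(np.count_nonzero(a != b))


def normalized_distance(xor: int, mac_a: int, mac_b: int, overlap: int,
                        mode: str = "union") -> float:
    """Normalize an XOR distance by the minor-allele occurrence of the pair."""
    if mode not in NORMALIZATION_MODES:
        raise InputValidationError(f"unknown normalization mode {mode!r}")
    if xor != mac_a + mac_b - 2 * overlap:
        raise InputValidationError(
            f"inconsistent inputs: xor={xor} != {mac_a}+{mac_b}-2*{overlap}")
    denom = {"union": mac_a + mac_b - overlap,
             "min_mac": min(mac_a, mac_b),
             "max_mac": max(mac_a, mac_b),
             "sum_mac": mac_a + mac_b}[mode]
    if denom <= 0:
        raise ComputationError("degenerate pair: zero normalization denominator")
    return xor / denom


def _check_xor_feasible(n_rows: int, mac_a: int, mac_b: int, xor: int) -> int:
    """Validate feasibility and return the implied overlap k_obs."""
    if not (0 < mac_a <= n_rows and 0 < mac_b <= n_rows):
        raise InputValidationError(
            f"macs must be in (0, n_rows]: {mac_a}, {mac_b}, n={n_rows}")
    if (mac_a + mac_b - xor) % 2:
        raise InputValidationError(
            f"xor={xor} infeasible for macs {mac_a},{mac_b} (parity)")
    k = (mac_a + mac_b - xor) // 2
    if not (max(0, mac_a + mac_b - n_rows) <= k <= min(mac_a, mac_b)):
        raise InputValidationError(
            f"xor={xor} out of feasible range for n={n_rows}, "
            f"macs {mac_a},{mac_b}")
    return k


def exact_pvalue(n_rows: int, mac_a: int, mac_b: int, observed_xor: int) -> float:
    """Exact one-sided tail P(XOR ≤ observed) under random carrier assortment.

    overlap ~ Hypergeometric(n_rows, mac_a, mac_b); small XOR means large
    overlap, so the tail is P(overlap ≥ (mac_a + mac_b − observed_xor)/2).
    """
    k = _check_xor_feasible(n_rows, mac_a, mac_b, observed_xor)
    return float(hypergeom.sf(k - 1, n_rows, mac_a, mac_b))


def exact_pvalue_array(n_rows: int, mac_a, mac_b, observed_xor) -> np.ndarray:
    """Vectorized :func:`exact_pvalue` (inputs broadcast elementwise)."""
    mac_a = np.asarray(mac_a, dtype=np.int64)
    mac_b = np.asarray(mac_b, dtype=np.int64)
    k = (mac_a + mac_b - np.asarray(observed_xor, dtype=np.int64)) // 2
    return hypergeom.sf(k - 1, n_rows, mac_a, mac_b)


def permutation_pvalue(a, b, n_permutations: int = 1000,
                       seed: int = 0) -> float:
    """Monte-Carlo tail estimate by permuting the row order of one vector.

    Uses the add-one estimator (1 + #{xor_perm ≤ xor_obs}) / (1 + B), which
    never returns 0 and is reproducible for a fixed seed.
    """
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise InputValidationError("length mismatch")
    if n_permutations < 1:
        raise InputValidationError("n_permutations must be >= 1")
    observed = int(np.count_nonzero(a != b))
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 0
    # chunk to bound memory at ~8M cells
    step = max(1, 8_000_000 // max(n, 1))
    done = 0
    while done < n_permutations:
        block = min(step, n_permutations - done)
        perms = rng.permuted(np.tile(a, (block, 1)), axis=1)
        hits += int(np.count_nonzero((perms != b).sum(axis=1) <= observed))
        done += block
    return (1 + hits) / (1 + n_permutations)


def scan_pairs(matrix: BinaryGenotypeMatrix,
               rsnp_ids: Sequence[str],
               marker_ids: Sequence[str],
               config: CosegConfig | None = None) -> pd.DataFrame:
    """Scan every (rSNP, marker) pair and call co-segregating markers.

    Markers are processed in column chunks so memory stays bounded by a
    constant number of columns regardless of panel width.  Monomorphic
    columns (all-0 or all-1 codes) are excluded as degenerate; exclusions are
    recorded in ``result.attrs['excluded']`` as (rsnp_id, marker_id, reason).

    Returns a DataFrame with one row per tested pair (the
    :class:`DistanceRecord` fields), sorted by (rsnp_id, p_value,
    normalized_distance, marker_id).
    """
    config = config or CosegConfig()
    rsnp_ids = list(rsnp_ids)
    marker_ids = list(marker_ids)
    if not rsnp_ids or not marker_ids:
        raise InputValidationError("empty rSNP or marker set")
    for vid in rsnp_ids + marker_ids:
        if vid not in matrix:
            raise InputValidationError(f"id {vid!r} not a matrix column")

    n = matrix.n_rows
    excluded: list[tuple[str, str, str]] = []

    mac_all = matrix.mac_array()
    poly = {vid: 0 < mac_all[matrix.column_index(vid)] < n
            for vid in set(rsnp_ids) | set(marker_ids)}

    good_markers = [m for m in marker_ids if poly[m]]
    for m in marker_ids:
        if not poly[m]:
            excluded.append(("*", m, "degenerate pair: monomorphic marker"))

    frames: list[pd.DataFrame] = []
    mcols = np.array([matrix.column_index(m) for m in good_markers], dtype=np.intp)
    marker_arr = np.asarray(good_markers, dtype=object)

    for rid in rsnp_ids:
        if not poly[rid]:
            excluded.append((rid, "*", "degenerate pair: monomorphic rSNP"))
            continue
        a = matrix.codes[:, matrix.column_index(rid)]
        mac_a = int(a.sum())
        for lo in range(0, len(mcols), config.chunk_size):
            cols = mcols[lo:lo + config.chunk_size]
            block = matrix.codes[:, cols]
            mac_b = block.sum(axis=0).astype(np.int64)
            overlap = (a.astype(np.int64) @ block)
            xor = mac_a + mac_b - 2 * overlap
            union = mac_a + mac_b - overlap
            if config.normalization == "union":
                denom = union
            elif config.normalization == "min_mac":
                denom = np.minimum(mac_a, mac_b)
            elif config.normalization == "max_mac":
                denom = np.maximum(mac_a, mac_b)
            else:
                denom = mac_a + mac_b
            norm = xor / denom
            if config.null_model == "hypergeometric_exact":
                pvals = exact_pvalue_array(n, mac_a, mac_b, xor)
            else:
                rng = np.random.default_rng(config.seed)
                pvals = np.array([
                    permutation_pvalue(a, block[:, j], config.n_permutations,
                                       seed=int(rng.integers(2**31)))
                    for j in range(block.shape[1])])
            frames.append(pd.DataFrame({
                "rsnp_id": rid,
                "marker_id": marker_arr[lo:lo + config.chunk_size],
                "xor_distance": xor,
                "union_count": union,
                "normalized_distance": norm,
                "p_value": pvals,
            }))

    if not frames:  # every pair degenerate: an empty, correctly-typed result
        frames = [pd.DataFrame({
            "rsnp_id": pd.Series(dtype=object),
            "marker_id": pd.Series(dtype=object),
            "xor_distance": pd.Series(dtype=np.int64),
            "union_count": pd.Series(dtype=np.int64),
            "normalized_distance": pd.Series(dtype=float),
            "p_value": pd.Series(dtype=float)})]

    result = pd.concat(frames, ignore_index=True)
    if config.multiple_testing == "benjamini_hochberg":
        adjusted = false_discovery_control(result["p_value"].to_numpy(), method="bh")
        result["cosegregating"] = adjusted < config.alpha
    else:
        result["cosegregating"] = result["p_value"] < config.alpha
    result = result.sort_values(
        ["rsnp_id", "p_value", "normalized_distance", "marker_id"],
        kind="mergesort").reset_index(drop=True)
    result.attrs["excluded"] = excluded
    result.attrs["n_rows"] = n
    return result


def records_from_frame(frame: pd.DataFrame) -> list[DistanceRecord]:
    """Materialize scan rows as :class:`DistanceRecord` objects."""
    return [DistanceRecord(r.rsnp_id, r.marker_id, int(r.xor_distance),
                           int(r.union_count), float(r.normalized_distance),
                           float(r.p_value), bool(r.cosegregating))
            for r in frame.itertuples(index=False)]


def cosegregating_markers(frame: pd.DataFrame) -> dict[str, list[str]]:
    """rSNP → list of called marker ids, from a scan result frame."""
    called = frame[frame["cosegregating"]]
    return {rid: sorted(g["marker_id"]) for rid, g in called.groupby("rsnp_id")}
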