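"""Detection logic and array-level normalization of Ct matrices.

Ct values are log2-scale abundance measurements (one cycle = one doubling of
template), so sample-level technical variation — differing RNA input, serial
dilution, extraction yield — appears as an additive per-sample shift.
Array-level normalization estimates and removes that shift.

The restricted (fully detected) gene set is central: with low RNA inputs a
large fraction of assays is non-determined (right-censored at ``ct_max``),
and a per-sample mean taken over *all* assays is biased by the censoring
pattern, which differs between samples. Mean-centering restricted (MCR)
instead centers each sample on the mean of the genes detected in *every*
sample, which is shift-equivariant and therefore removes per-sample offsets
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CtNormError, DegenerateScaleError, NoFullyDetectedGenesError
from .io import CtMatrix

_ND_ADVICE = (
    "no gene is fully detected at this threshold; raise the detection "
    "threshold (appropriate when some samples are RNA-depleted) or remove "
    "outlier samples with very low overall detection"
)


@dataclass
class DetectionConfig:
    """Strict upper Ct bound for calling a reaction 'detected'.

    The default of 40 cycles matches the censoring bound of the run; the
    normalizer-selection workflow typically uses a stricter bound of 35
    because Ct determinations between 35 and 40 cycles are noisy.
    """

    detect_threshold: float = 40.0

    def __post_init__(self) -> None:
        if self.detect_threshold <= 0:
            raise ValueError("detect_threshold must be positive")


@dataclass
class NormalizationResult:
    """Normalized expression values plus the bookkeeping of how they were made.

    ``normalized`` has the same shape, labels and ND mask as the input:
    normalization never invents or removes detections. ``per_sample_offset``
    is the net constant subtracted from each sample where the method defines
    one (None for quantile and MAD-scale, which are not pure shifts).
    """

    normalized: pd.DataFrame
    method: str
    ct_max: float
    restricted_set: list[str] = field(default_factory=list)
    normalizers: list[str] = field(default_factory=list)
    per_sample_offset: pd.Series | None = None


def detected_mask(matrix: CtMatrix, cfg: DetectionConfig | None = None) -> pd.DataFrame:
    """True where a reaction is numeric and strictly below the threshold."""
    cfg = cfg or DetectionConfig()
    if cfg.detect_threshold > matrix.ct_max:
        raise ValueError("detect_threshold cannot exceed ct_max")
    return matrix.data.notna() & (matrix.data < cfg.detect_threshold)


def fully_detected_set(matrix: CtMatrix, cfg: DetectionConfig | None = None) -> list[str]:
    """Genes detected in every sample, in input row order (may be empty)."""
    mask = detected_mask(matrix, cfg)
    keep = mask.all(axis=1)
    return list(matrix.data.index[keep])


def restricted_sample_means(
    matrix: CtMatrix, cfg: DetectionConfig | None = None
) -> pd.Series:
    """Per-sample mean Ct over the fully detected (restricted) gene set."""
    genes = fully_detected_set(matrix, cfg)
    if not genes:
        raise NoFullyDetectedGenesError(_ND_ADVICE)
    return matrix.data.loc[genes].mean(axis=0)


def mcr_normalize(
    matrix: CtMatrix,
    cfg: DetectionConfig | None = None,
    recentre: bool = True,
) -> NormalizationResult:
    """Mean-centering restricted: subtract the restricted-set mean per sample.

    Because every restricted gene is observed in every sample, the per-sample
    centering value shifts one-for-one with any constant added to a sample,
    so the normalized values are invariant to per-sample offsets (with
    ``recentre=True`` the output additionally carries the grand mean of the
    centering values, a single global constant that keeps values on a
    Ct-like scale).
    """
    cfg = cfg or DetectionConfig()
    genes = fully_detected_set(matrix, cfg)
    if not genes:
        raise NoFullyDetectedGenesError(_ND_ADVICE)
    m = matrix.data.loc[genes].mean(axis=0)
    offset = m.copy()
    if recentre:
        offset = m - m.mean()
    normalized = matrix.data.sub(offset, axis=1)
    return NormalizationResult(
        normalized=normalized,
        method="MCR",
        ct_max=matrix.ct_max,
        restricted_set=genes,
        per_sample_offset=offset,
    )


def mean_center(
    matrix: CtMatrix, recentre: bool = True, nd_as_ct_max: bool = True
) -> NormalizationResult:
    """Plain mean-centering over all genes (the Mestdagh-style MC comparator).

    The per-sample mean is taken over every assay. Non-determined cells enter
    the mean at the censoring bound ``ct_max`` (they are known to exceed it),
    which is exactly the weakness MCR avoids: the centering value no longer
    shifts one-for-one with sample offsets once censored cells pin part of
    the mean at 40. ``nd_as_ct_max=False`` uses the available-case mean
    instead.
    """
    filled = matrix.data.fillna(matrix.ct_max) if nd_as_ct_max else matrix.data
    m = filled.mean(axis=0)
    offset = m - m.mean() if recentre else m.copy()
    normalized = matrix.data.sub(offset, axis=1)
    return NormalizationResult(
        normalized=normalized,
        method="MC",
        ct_max=matrix.ct_max,
        per_sample_offset=offset,
    )


def mad_scale(matrix: CtMatrix) -> NormalizationResult:
    """Median/MAD scale normalization ("Scale").

    Each sample is centered on its median and rescaled so all samples share
    a common spread, the geometric mean of the per-sample raw median absolute
    deviations (no normal-consistency constant); the median of the
    per-sample medians is added back so values stay on a Ct-like scale.
    ND cells are excluded from the location/scale estimates and preserved.
    """
    data = matrix.data
    medians = data.median(axis=0, skipna=True)
    mads = (data - medians).abs().median(axis=0, skipna=True)
    zero = mads[mads == 0]
    if len(zero) > 0:
        raise DegenerateScaleError(
            f"zero median absolute deviation in sample(s) {list(zero.index)}"
        )
    if mads.isna().any():
        bad = list(mads.index[mads.isna()])
        raise DegenerateScaleError(f"too few numeric values in sample(s) {bad}")
    common = float(np.exp(np.log(mads).mean()))
    grand = float(np.median(medians))
    normalized = (data - medians).div(mads, axis=1) * common + grand
    return NormalizationResult(normalized=normalized, method="Scale", ct_max=matrix.ct_max)


def quantile_normalize(matrix: CtMatrix) -> NormalizationResult:
    """Quantile normalization over the numeric (detected or sub-cap) cells.

    Samples with equal numeric counts get the classic treatment: the k-th
    smallest value in every sample is replaced by the mean of the k-th
    smallest values across samples, ties sharing the mean reference value of
    their tied ranks. With unequal counts (differing censoring), each
    sample's empirical quantile function is linearly interpolated onto a
    common grid of the maximum count to build the reference distribution,
    and mapped back through the same interpolation. ND cells are untouched.
    """
    data = matrix.data.to_numpy(dtype=float)
    n_genes, n_samples = data.shape
    counts = np.sum(np.isfinite(data), axis=0)
    if np.any(counts == 0):
        bad = [matrix.sample_ids[j] for j in np.flatnonzero(counts == 0)]
        raise CtNormError(f"sample(s) with no numeric values: {bad}")
    m = int(counts.max())
    grid = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
    reference = np.zeros(m)
    for j in range(n_samples):
        vals = np.sort(data[np.isfinite(data[:, j]), j])
        if len(vals) == 1:
            reference += vals[0]
        else:
            p = np.linspace(0.0, 1.0, len(vals))
            reference += np.interp(grid, p, vals)
    reference /= n_samples

    out = np.full_like(data, np.nan)
    for j in range(n_samples):
        idx = np.flatnonzero(np.isfinite(data[:, j]))
        vals = data[idx, j]
        order = np.argsort(vals, kind="stable")
        n_j = len(vals)
        p = np.linspace(0.0, 1.0, n_j) if n_j > 1 else np.array([0.5])
        ref_grid = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
        mapped_sorted = np.interp(p, ref_grid, reference)
        mapped = np.empty(n_j)
        mapped[order] = mapped_sorted
        # ties share the mean of their ranks' reference values
        uniq, inverse = np.unique(vals, return_inverse=True)
        if len(uniq) < n_j:
            sums = np.bincount(inverse, weights=mapped)
            cnts = np.bincount(inverse)
            mapped = (sums / cnts)[inverse]
        out[idx, j] = mapped
    normalized = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return NormalizationResult(normalized=normalized, method="Quantile", ct_max=matrix.ct_max)


def normalize_by_genes(
    matrix: CtMatrix,
    normalizers: list[str],
    recentre: bool = True,
) -> NormalizationResult:
    """Delta-Ct normalization against a set of reference (normalizer) genes.

    Subtracts the per-sample mean Ct of the normalizer genes from every
    assay. Normalizers must be numeric in every sample — a reference gene
    that drops out in any sample cannot anchor that sample.
    """
    if not normalizers:
        raise CtNormError("normalizer list is empty")
    unknown = [g for g in normalizers if g not in matrix.data.index]
    if unknown:
        raise CtNormError(f"unknown normalizer gene id(s): {unknown}")
    rows = matrix.data.loc[normalizers]
    if rows.isna().any().any():
        bad = list(rows.index[rows.isna().any(axis=1)])
        raise CtNormError(
            f"normalizer gene(s) {bad} are non-determined in at least one "
            "sample; normalizers must be fully detected"
        )
    m = rows.mean(axis=0)
    offset = m - m.mean() if recentre else m.copy()
    normalized = matrix.data.sub(offset, axis=1)
    return NormalizationResult(
        normalized=normalized,
        method="Normalizer",
        ct_max=matrix.ct_max,
        normalizers=list(normalizers),
        per_sample_offset=offset,
    )


def no_normalization(matrix: CtMatrix) -> NormalizationResult:
    """Identity pass-through, for benchmarking against the unnormalized data."""
    return NormalizationResult(
        normalized=matrix.data.copy(),
        method="None",
        ct_max=matrix.ct_max,
        per_sample_offset=pd.Series(0.0, index=matrix.data.columns),
    )
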