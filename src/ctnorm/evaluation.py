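"""Benchmarking metrics for normalization quality.

Two complementary views:

* :func:`per_mirna_sd` — technical variance. Within an origin group, samples
  differ only in input amount and handling, so after a good normalization
  each gene's values should be nearly constant within the group. The metric
  is the per-gene standard deviation within each group, summarized as the
  mean over genes (over all genes, or over the restricted fully detected
  set).
* :func:`variance_pca` — biological signal. Principal components are
  extracted from the normalized matrix (samples as observations) and, for
  each of the leading components, a one-way random-effects model with origin
  as the random factor splits the score variance into between-origin and
  residual parts. The eigenvalue-weighted average of the between-origin
  fractions is the percent variance explained by sample origin: a
  normalization that removes technical shifts without erasing biology
  pushes this number up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CtNormError
from .io import SampleAnnotation, origin_series
from .normalize import NormalizationResult

__all__ = ["EvaluationReport", "VariancePCAResult", "per_mirna_sd", "variance_pca"]


@dataclass
class EvaluationReport:
    """Per-gene within-group SDs of normalized values plus group summaries.

    ``per_gene_sd`` is genes x groups; cells with fewer than two numeric
    observations in a group are NaN (undefined, not zero) and are excluded
    from the group mean summaries.
    """

    per_gene_sd: pd.DataFrame
    mean_sd_all: pd.Series
    mean_sd_restricted: pd.Series | None
    gene_universe: str  # "all" | "restricted"


@dataclass
class VariancePCAResult:
    """Eigenvalue-weighted percent variance explained by sample origin."""

    eigenvalues: list[float]
    pc_scores: pd.DataFrame  # samples x components
    per_pc_fraction: list[float]
    weighted_percent: float


def per_mirna_sd(
    result: NormalizationResult,
    groups: list[SampleAnnotation] | SampleAnnotation | None,
    universe: str = "all",
    restricted: list[str] | None = None,
) -> EvaluationReport:
    """Within-group per-gene standard deviation of normalized expression.

    SDs use the n-1 divisor over the numeric (non-ND) values of each gene
    within each origin group. ``universe`` selects which summary the caller
    is after; the restricted summary additionally needs the restricted gene
    list (typically ``NormalizationResult.restricted_set`` from MCR, or
    ``fully_detected_set`` computed separately).
    """
    if universe not in ("all", "restricted"):
        raise ValueError("universe must be 'all' or 'restricted'")
    if universe == "restricted" and not restricted:
        raise CtNormError("universe='restricted' requires a non-empty restricted gene list")
    if groups is None:
        raise CtNormError("per_mirna_sd requires sample annotations")
    origins = origin_series(groups, list(result.normalized.columns))
    labels = list(dict.fromkeys(origins))
    sizes = origins.value_counts()
    small = [g for g in labels if sizes[g] < 2]
    if small:
        raise CtNormError(f"group(s) with fewer than 2 samples: {small}")

    per_group = {}
    for g in labels:
        cols = origins.index[origins == g]
        sub = result.normalized[cols]
        per_group[g] = sub.std(axis=1, ddof=1, skipna=True).where(sub.notna().sum(axis=1) >= 2)
    per_gene_sd = pd.DataFrame(per_group)

    mean_all = per_gene_sd.mean(axis=0, skipna=True)
    mean_restricted = None
    if restricted:
        unknown = [g for g in restricted if g not in per_gene_sd.index]
        if unknown:
            raise CtNormError(f"restricted gene(s) not in matrix: {unknown}")
        mean_restricted = per_gene_sd.loc[restricted].mean(axis=0, skipna=True)
    return EvaluationReport(
        per_gene_sd=per_gene_sd,
        mean_sd_all=mean_all,
        mean_sd_restricted=mean_restricted,
        gene_universe=universe,
    )


def _anova_origin_fraction(y: np.ndarray, group_of: np.ndarray, n_groups: int) -> float:
    """One-way random-effects variance fraction by ANOVA method of moments.

    Uses the unbalanced-design coefficient n0 = (N - sum n_g^2 / N)/(G - 1)
    for the between-group mean square; a negative between-origin component
    is truncated to zero.
    """
    N = len(y)
    sizes = np.array([np.sum(group_of == g) for g in range(n_groups)])
    grand = y.mean()
    group_means = np.array([y[group_of == g].mean() for g in range(n_groups)])
    ssb = float(np.sum(sizes * (group_means - grand) ** 2))
    ssw = float(sum(np.sum((y[group_of == g] - group_means[g]) ** 2) for g in range(n_groups)))
    msb = ssb / (n_groups - 1)
    msw = ssw / (N - n_groups)
    n0 = (N - np.sum(sizes**2) / N) / (n_groups - 1)
    sigma2_origin = max((msb - msw) / n0, 0.0)
    total = sigma2_origin + msw
    return sigma2_origin / total if total > 0 else 0.0


def _reml_origin_fraction(y: np.ndarray, group_of: np.ndarray, n_groups: int) -> float:
    """REML variant of the variance fraction, via a profile grid + refinement."""
    from scipy.optimize import minimize_scalar

    sizes = np.array([np.sum(group_of == g) for g in range(n_groups)])
    group_means = np.array([y[group_of == g].mean() for g in range(n_groups)])
    ssw = float(sum(np.sum((y[group_of == g] - group_means[g]) ** 2) for g in range(n_groups)))

    def neg_reml(log_ratio: float) -> float:
        ratio = np.exp(log_ratio)  # sigma2_origin / sigma2_resid
        w = sizes / (1 + ratio * sizes)
        mu = np.sum(w * group_means) / np.sum(w)
        quad = ssw + np.sum(w * (group_means - mu) ** 2)
        N = len(y)
        logdet = np.sum(np.log(1 + ratio * sizes))
        s2 = quad / (N - 1)
        return 0.5 * ((N - 1) * np.log(s2) + logdet + np.log(np.sum(w)))

    res = minimize_scalar(neg_reml, bounds=(-12, 12), method="bounded")
    ratio = float(np.exp(res.x))
    if ratio < 1e-8:
        return 0.0
    return ratio / (1 + ratio)


def variance_pca(
    result: NormalizationResult,
    groups: list[SampleAnnotation],
    n_pcs: int = 3,
    use_reml: bool = False,
) -> VariancePCAResult:
    """Percent variance explained by sample origin, eigenvalue-weighted over PCs.

    The normalized matrix (ND imputed at ``ct_max`` so weak/non-detection
    remains informative) is column-centered per gene and decomposed by PCA
    with samples as observations. For each of the first ``n_pcs`` score
    vectors a one-way random-effects model with origin as the random factor
    yields the fraction f_k of score variance attributable to origin;
    the summary is 100 * sum(lambda_k f_k) / sum(lambda_k).
    """
    origins = origin_series(groups, list(result.normalized.columns))
    labels = list(dict.fromkeys(origins))
    if len(labels) < 2:
        raise CtNormError("variance_pca requires at least 2 origin groups")
    sizes = origins.value_counts()
    small = [g for g in labels if sizes[g] < 2]
    if small:
        raise CtNormError(f"group(s) with fewer than 2 samples: {small}")
    n_samples = result.normalized.shape[1]
    if not 1 <= n_pcs <= n_samples - 1:
        raise CtNormError(
            f"n_pcs must be between 1 and n_samples-1 = {n_samples - 1}, got {n_pcs}"
        )

    X = result.normalized.fillna(result.ct_max).to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = (s**2) / (n_samples - 1)
    scores = U * s  # samples x components
    k = min(n_pcs, len(eigenvalues))

    group_of = np.array([labels.index(o) for o in origins])
    fractions = []
    estimator = _reml_origin_fraction if use_reml else _anova_origin_fraction
    tol = eigenvalues[0] * 1e-12 if len(eigenvalues) else 0.0
    for comp in range(k):
        if eigenvalues[comp] <= tol:
            fractions.append(0.0)  # numerically null component carries no variance
            continue
        fractions.append(estimator(scores[:, comp], group_of, len(labels)))
    lam = eigenvalues[:k]
    weighted = 100.0 * float(np.sum(lam * np.array(fractions)) / np.sum(lam))
    return VariancePCAResult(
        eigenvalues=[float(v) for v in lam],
        pc_scores=pd.DataFrame(
            scores[:, :k],
            index=result.normalized.columns,
            columns=[f"PC{i+1}" for i in range(k)],
        ),
        per_pc_fraction=[float(f) for f in fractions],
        weighted_percent=weighted,
    )
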