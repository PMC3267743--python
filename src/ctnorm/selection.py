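"""Normalizer (reference gene) selection for migrating multiplex signatures
to singleplex RT-qPCR.

Three selectors are provided:

* :func:`ccr_select` — concordance correlation restricted (CCR): greedy
  forward selection of genes whose averaged Ct profile agrees, in Lin's
  concordance sense, with the restricted sample means. Concordance (unlike
  Pearson correlation) penalizes location and scale shifts, so a selected
  normalizer does not merely co-vary with the mean expression level — it
  *tracks* it, which is what a singleplex reference assay must do.
* :func:`genorm_select` — the classical pairwise-stability measure: a gene's
  M value is the mean standard deviation of its Ct difference against every
  other gene, with iterative exclusion of the least stable gene.
* :func:`normfinder_select` — the model-based decomposition of each gene's
  variation into intragroup variance and intergroup (gene-by-group)
  deviation, combined into a single stability value (lower = more stable).

All selectors operate on raw Ct restricted to genes fully detected at the
configured threshold; they do not pre-normalize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CtNormError, DegenerateInputError, NoFullyDetectedGenesError
from .io import CtMatrix, SampleAnnotation, origin_series
from .normalize import DetectionConfig, fully_detected_set, restricted_sample_means

__all__ = [
    "CCCResult",
    "SelectionResult",
    "StabilityTable",
    "ccc",
    "ccr_select",
    "genorm_select",
    "normfinder_select",
]


@dataclass
class CCCResult:
    """Lin's concordance correlation coefficient with a Fisher-z confidence interval."""

    rho_c: float
    ci_low: float
    ci_high: float
    confidence: float
    pearson_r: float
    n: int


@dataclass
class SelectionResult:
    """Outcome of CCR greedy forward selection."""

    normalizers: list[str]
    score_trajectory: list[float]
    stop_reason: str  # "converged" | "max_count" | "exhausted"
    candidate_set: list[str]


@dataclass
class StabilityTable:
    """Per-gene stability scores from geNorm or NormFinder (lower = more stable)."""

    method: str
    gene_ids: list[str]
    stability: list[float]
    ranking: list[str]

    def as_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"gene_id": self.gene_ids, "stability": self.stability})
        rank = {g: i + 1 for i, g in enumerate(self.ranking)}
        frame["rank"] = [rank[g] for g in self.gene_ids]
        return frame.sort_values("rank", kind="stable").reset_index(drop=True)


def ccc(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> CCCResult:
    """Lin's concordance correlation coefficient between two paired vectors.

    rho_c = 2*s_xy / (s_x^2 + s_y^2 + (mean(x) - mean(y))^2), with n-divisor
    (biased) moments. The confidence interval applies the Fisher
    z-transformation with Lin's (1989) asymptotic standard error. The
    Pearson correlation is reported alongside: |rho_c| <= |r| always, with
    equality only when the two vectors share location and scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CtNormError("ccc requires two 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise CtNormError("ccc requires at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise CtNormError("ccc requires finite values")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")

    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise DegenerateInputError("both vectors constant and equal; concordance undefined")
    rho_c = 2 * sxy / denom

    if sx2 > 0 and sy2 > 0:
        r = sxy / np.sqrt(sx2 * sy2)
    else:
        r = np.nan  # one vector constant: Pearson undefined, rho_c = 0

    if np.isnan(r) or abs(rho_c) >= 1 - 1e-15 or r == 0:
        # perfect or degenerate agreement: the z-SE is undefined
        lo = hi = float(np.clip(rho_c, -1.0, 1.0))
    else:
        u = (mx - my) / (sx2 * sy2) ** 0.25  # location shift relative to scale
        z = np.arctanh(rho_c)
        se2 = (
            (1 - r**2) * rho_c**2 / ((1 - rho_c**2) * r**2)
            + 2 * rho_c**3 * (1 - rho_c) * u**2 / (r * (1 - rho_c**2) ** 2)
            - rho_c**4 * u**4 / (2 * r**2 * (1 - rho_c**2) ** 2)
        ) / (n - 2)
        se = np.sqrt(max(se2, 0.0))
        zcrit = stats.norm.ppf(0.5 + confidence / 2)
        lo = float(np.tanh(z - zcrit * se))
        hi = float(np.tanh(z + zcrit * se))
    return CCCResult(
        rho_c=float(rho_c),
        ci_low=min(lo, float(rho_c)),
        ci_high=max(hi, float(rho_c)),
        confidence=confidence,
        pearson_r=float(r),
        n=n,
    )


def ccr_select(
    matrix: CtMatrix,
    cfg: DetectionConfig | None = None,
    max_normalizers: int | None = None,
    epsilon: float = 0.01,
    target_threshold: float | None = None,
) -> SelectionResult:
    """Concordance correlation restricted (CCR) normalizer selection.

    Candidates are the genes fully detected at ``cfg.detect_threshold``
    (default 35 cycles — Ct determinations between 35 and 40 are too noisy
    to anchor a reference assay). The target is the restricted sample mean
    vector at the same threshold (``target_threshold`` overrides). Selection
    is greedy: the first normalizer maximizes CCC(gene Ct, target); each
    subsequent step adds the candidate maximizing CCC(mean of selected +
    candidate, target). In convergence mode a step is accepted only if it
    improves CCC by at least ``epsilon``; with ``max_normalizers`` given,
    epsilon is ignored and exactly that many genes are taken (or all
    candidates, if fewer).
    """
    cfg = cfg or DetectionConfig(detect_threshold=35.0)
    if max_normalizers is not None and max_normalizers < 1:
        raise ValueError("max_normalizers must be >= 1")
    candidates = fully_detected_set(matrix, cfg)
    if not candidates:
        raise NoFullyDetectedGenesError(
            f"no gene fully detected at Ct < {cfg.detect_threshold}; adjust the "
            "threshold upward (RNA-depleted samples present) or downward "
            "(to drop weakly detected genes), or remove outlier samples"
        )
    tgt_cfg = cfg if target_threshold is None else DetectionConfig(target_threshold)
    target = restricted_sample_means(matrix, tgt_cfg).to_numpy()

    rows = matrix.data.loc[candidates].to_numpy(dtype=float)
    selected: list[int] = []
    trajectory: list[float] = []
    remaining = list(range(len(candidates)))
    stop_reason = "exhausted"
    while remaining:
        running = rows[selected].sum(axis=0) if selected else 0.0
        k = len(selected) + 1
        best_i, best_score = None, -np.inf
        for i in remaining:
            score = ccc((running + rows[i]) / k, target).rho_c
            if score > best_score:
                best_i, best_score = i, score
        if max_normalizers is None:
            if trajectory and best_score - trajectory[-1] < epsilon:
                stop_reason = "converged"
                break
        selected.append(best_i)
        trajectory.append(float(best_score))
        remaining.remove(best_i)
        if max_normalizers is not None and len(selected) == max_normalizers:
            stop_reason = "max_count"
            break
    return SelectionResult(
        normalizers=[candidates[i] for i in selected],
        score_trajectory=trajectory,
        stop_reason=stop_reason,
        candidate_set=candidates,
    )


def genorm_select(
    matrix: CtMatrix, cfg: DetectionConfig | None = None
) -> StabilityTable:
    """geNorm expression-stability ranking on the fully detected genes.

    Works directly on Ct differences: since relative quantities are
    Q = 2^(-Ct), the log2 ratio of two genes' quantities across samples is
    (Ct_k - Ct_j), so M_j = mean over partners k of SD(Ct_k - Ct_j)
    (n-1 divisor). The gene with the highest M is excluded and M recomputed
    until two genes remain; each gene's reported stability is its M at the
    stage of its exclusion, the final pair keeping their values from the
    last three-gene stage. Ranking is most-stable first (reverse exclusion
    order); ties follow input gene order.
    """
    cfg = cfg or DetectionConfig()
    genes = fully_detected_set(matrix, cfg)
    if len(genes) < 3:
        raise CtNormError(
            f"geNorm requires at least 3 fully detected genes, found {len(genes)}"
        )
    X = matrix.data.loc[genes].to_numpy(dtype=float)
    # pairwise SD(Ct_k - Ct_j) is independent of which genes remain active,
    # so compute it once: Var(X_k - X_j) = C_kk + C_jj - 2 C_kj
    C = np.cov(X, ddof=1)
    var_diff = np.maximum(np.diag(C)[:, None] + np.diag(C)[None, :] - 2 * C, 0.0)
    D = np.sqrt(var_diff)
    np.fill_diagonal(D, 0.0)

    active = list(range(len(genes)))
    stability = {}
    removal_order: list[int] = []
    while len(active) > 2:
        idx = np.array(active)
        M = {j: float(D[j, idx].sum()) / (len(active) - 1) for j in active}
        worst = max(M.values())
        # among ties, drop the latest in input order so earlier genes rank first
        drop = max(j for j in active if M[j] == worst)
        stability[drop] = M[drop]
        if len(active) == 3:
            for j in active:  # final pair keeps its last computed M
                if j != drop:
                    stability[j] = M[j]
        active.remove(drop)
        removal_order.append(drop)
    pair = sorted(active, key=lambda j: (stability[j], j))
    ranking_idx = pair + removal_order[::-1]
    return StabilityTable(
        method="geNorm",
        gene_ids=list(genes),
        stability=[stability[j] for j in range(len(genes))],
        ranking=[genes[j] for j in ranking_idx],
    )


def _normfinder_components(
    Z: np.ndarray, group_of: np.ndarray, group_sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Method-of-moments variance components for the NormFinder model.

    Z is the genes x samples matrix after subtracting each sample's
    across-gene mean. Returns (sigma2[genes, groups], d_hat[genes, groups],
    gamma2), where sigma2 is the intragroup variance (unbiased for the
    gene-level error variance when k >= 3), d_hat the raw gene-by-group
    deviation, and gamma2 the across-genes variance of the true deviations
    used for shrinkage.
    """
    k = Z.shape[0]
    G = len(group_sizes)
    zbar = np.stack([Z[:, group_of == g].mean(axis=1) for g in range(G)], axis=1)
    s2 = np.stack([Z[:, group_of == g].var(axis=1, ddof=1) for g in range(G)], axis=1)
    if k >= 3:
        total = s2.sum(axis=0) * k / (k - 1)  # estimates sum_i sigma2_ig
        sigma2 = (s2 - total[None, :] / k**2) / (1 - 2 / k)
        sigma2 = np.maximum(sigma2, 0.0)
    else:
        sigma2 = s2
    d_hat = zbar - zbar.mean(axis=1, keepdims=True)
    if G > 1:
        gamma2 = float(
            np.sum(d_hat**2) / ((k - 1) * (G - 1))
            - np.sum(sigma2 / group_sizes[None, :]) / (k * G)
        )
        gamma2 = max(gamma2, 0.0)
    else:
        gamma2 = 0.0
    return sigma2, d_hat, gamma2


def normfinder_select(
    matrix: CtMatrix,
    groups: Sequence[SampleAnnotation] | None = None,
    cfg: DetectionConfig | None = None,
) -> StabilityTable:
    """NormFinder model-based stability ranking on the fully detected genes.

    Ct values are already on a log2 scale, so they enter the model directly.
    Each sample's across-gene mean is removed; per gene and origin group the
    intragroup variance sigma2_ig and the gene-by-group deviation d_ig are
    estimated by the method of moments, d shrunk toward zero by the factor
    gamma2 / (gamma2 + sigma2_ig/n_g), and the stability value is the
    group-average of |d~_ig| + sqrt(Var(d~_ig)). With a single group (or no
    annotation) the stability reduces to the gene's cross-sample variance of
    the sample-mean-centered values. Lower is more stable.
    """
    cfg = cfg or DetectionConfig()
    genes = fully_detected_set(matrix, cfg)
    if len(genes) < 2:
        raise CtNormError(
            f"NormFinder requires at least 2 fully detected genes, found {len(genes)}"
        )
    X = matrix.data.loc[genes].to_numpy(dtype=float)
    Z = X - X.mean(axis=0, keepdims=True)

    if groups is not None:
        origins = origin_series(groups, matrix.sample_ids)
        labels = list(dict.fromkeys(origins))
    else:
        labels = ["all"]

    if groups is None or len(labels) == 1:
        stab = Z.var(axis=1, ddof=1)
    else:
        group_of = np.array([labels.index(o) for o in origins])
        group_sizes = np.array([np.sum(group_of == g) for g in range(len(labels))])
        small = [labels[g] for g in range(len(labels)) if group_sizes[g] < 2]
        if small:
            raise CtNormError(f"group(s) with fewer than 2 samples: {small}")
        sigma2, d_hat, gamma2 = _normfinder_components(Z, group_of, group_sizes)
        var_d = sigma2 / group_sizes[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(gamma2 + var_d > 0, gamma2 / (gamma2 + var_d), 0.0)
        d_tilde = shrink * d_hat
        stab = np.mean(np.abs(d_tilde) + np.sqrt(shrink * var_d), axis=1)

    order = sorted(range(len(genes)), key=lambda i: (stab[i], i))
    return StabilityTable(
        method="NormFinder",
        gene_ids=list(genes),
        stability=[float(s) for s in stab],
        ranking=[genes[i] for i in order],
    )
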