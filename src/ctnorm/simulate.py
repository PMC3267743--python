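"""Synthetic titration-series generator.

Emulates the structure of serial-dilution RT-qPCR array experiments: each
origin (e.g. brain, placenta, serum) is profiled at a ladder of input
amounts; every dilution step raises all Ct values in that sample by
log2(dilution factor) cycles (perfect PCR efficiency), gene baselines span a
realistic detection range, each gene may express differently between
origins, Ct determination noise inflates near the top of the dynamic range,
and reactions landing above ``ct_max`` are right-censored to non-determined.
The key emergent property — the fraction of non-determined calls grows with
the overall Ct level of a sample — is exactly the regime that separates
restricted-set normalization from whole-array methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .io import CtMatrix, SampleAnnotation

__all__ = ["SimulationConfig", "simulate_titration", "simulate_flat"]

#: planted normalizer genes get this tiny measurement noise (cycles)
_PLANTED_NOISE_SD = 0.01

DEFAULT_ORIGINS: tuple[tuple[str, int, int], ...] = (
    ("brain", 6, 1),
    ("placenta", 6, 1),
    ("serum", 5, 1),
)


@dataclass
class SimulationConfig:
    """Parameters of the titration-series model.

    ``origins`` lists (label, n_titration_levels, n_replicates). Level 1 is
    the highest input; each further level adds log2(dilution_factor) cycles.
    ``planted_normalizers`` genes receive no origin effect and near-zero
    noise, making them ideal reference assays with a known identity.
    """

    n_genes: int = 377
    origins: Sequence[tuple[str, int, int]] = DEFAULT_ORIGINS
    dilution_factor: float = 10.0
    base_ct_range: tuple[float, float] = (18.0, 34.0)
    group_effect_sd: float = 1.5
    noise_base_sd: float = 0.25
    noise_highct_sd: float = 1.0
    noise_knee: float = 35.0
    ct_max: float = 40.0
    planted_normalizers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if not self.origins:
            raise ValueError("at least one origin is required")
        for label, levels, reps in self.origins:
            if not label or levels < 1 or reps < 1:
                raise ValueError(f"invalid origin entry {(label, levels, reps)!r}")
        if min(self.group_effect_sd, self.noise_base_sd, self.noise_highct_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.planted_normalizers <= self.n_genes:
            raise ValueError("planted_normalizers must be between 0 and n_genes")
        lo, hi = self.base_ct_range
        if not 0 < lo < hi:
            raise ValueError("base_ct_range must satisfy 0 < low < high")
        if self.ct_max <= 0:
            raise ValueError("ct_max must be positive")


def simulate_titration(
    cfg: SimulationConfig,
) -> tuple[CtMatrix, list[SampleAnnotation], dict[str, Any]]:
    """Draw one titration-series Ct matrix from the model.

    Ct[i, j] = b_i + g_{i, origin(j)} + t_j + noise, censored to ND above
    ``ct_max``. Baselines b_i ~ Uniform(base_ct_range); origin effects
    g_{i,o} ~ Normal(0, group_effect_sd) per gene x origin (zero for planted
    normalizers); the titration shift t_j = log2(dilution_factor) * (level-1);
    noise SD is ``noise_base_sd`` below ``noise_knee`` (pre-noise Ct) and
    ``noise_highct_sd`` above. Deterministic given ``cfg.seed``. The truth
    record carries b, g, t and the planted normalizer ids.
    """
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_genes))
    gene_ids = [f"miR-sim-{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    planted_ids = gene_ids[: cfg.planted_normalizers]

    origin_labels = [o[0] for o in cfg.origins]
    baseline = rng.uniform(*cfg.base_ct_range, size=cfg.n_genes)
    group_effect = rng.normal(0.0, cfg.group_effect_sd, size=(cfg.n_genes, len(origin_labels)))
    group_effect[: cfg.planted_normalizers, :] = 0.0

    sample_ids: list[str] = []
    annotations: list[SampleAnnotation] = []
    shifts: list[float] = []
    origin_of: list[int] = []
    step = np.log2(cfg.dilution_factor)
    for oi, (label, n_levels, n_reps) in enumerate(cfg.origins):
        for level in range(1, n_levels + 1):
            for rep in range(1, n_reps + 1):
                sid = f"{label}-L{level}" + (f"-r{rep}" if n_reps > 1 else "")
                sample_ids.append(sid)
                annotations.append(
                    SampleAnnotation(
                        sample_id=sid,
                        origin=label,
                        input_level=100.0 * cfg.dilution_factor ** (1 - level),
                    )
                )
                shifts.append(step * (level - 1))
                origin_of.append(oi)
    shifts_arr = np.array(shifts)
    origin_arr = np.array(origin_of)

    mu = baseline[:, None] + group_effect[:, origin_arr] + shifts_arr[None, :]
    sd = np.where(mu < cfg.noise_knee, cfg.noise_base_sd, cfg.noise_highct_sd)
    sd[: cfg.planted_normalizers, :] = _PLANTED_NOISE_SD
    ct = mu + rng.normal(0.0, 1.0, size=mu.shape) * sd
    ct = np.where(ct > cfg.ct_max, np.nan, np.maximum(ct, 1e-3))

    matrix = CtMatrix(
        pd.DataFrame(ct, index=gene_ids, columns=sample_ids), ct_max=cfg.ct_max
    )
    truth = {
        "baseline": pd.Series(baseline, index=gene_ids),
        "group_effect": pd.DataFrame(group_effect, index=gene_ids, columns=origin_labels),
        "sample_shift": pd.Series(shifts_arr, index=sample_ids),
        "planted_normalizers": planted_ids,
    }
    return matrix, annotations, truth


def simulate_flat(n_genes: int, n_samples: int, seed: int = 0) -> CtMatrix:
    """An i.i.d. Ct matrix with no censoring (uniform on a detected range).

    The shape benchmark used for scaling/smoke tests of the selection
    algorithms (e.g. 500 pseudogenes x 20 pseudosamples, no missing values).
    """
    if n_genes < 1 or n_samples < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = [f"pseudo-{i + 1}" for i in range(n_genes)]
    sample_ids = [f"sample-{j + 1}" for j in range(n_samples)]
    values = rng.uniform(20.0, 34.0, size=(n_genes, n_samples))
    return CtMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
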