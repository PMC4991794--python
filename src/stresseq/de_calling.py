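"""MA-statistic differential-transcription calling with a self-calibrated cutoff.

For each gene the two conditions are summarised by the arithmetic mean of
replicate RPKM values, then

    M = log2(mean_trt) - log2(mean_ref)      (signal intensity ratio)
    A = (log2(mean_trt) + log2(mean_ref))/2  (signal intensity)

Genes failing the expression filter (both condition means below
``rpkm_min``, or ``A <= a_min``) are set aside.  Under the assumption that
most genes are not differentially transcribed, the M-values of the genes
passing the filter are approximately a null distribution; a two-sided 1%
significance cutoff is therefore self-calibrated as

    m_min = z_coeff * STDEV(M),  z_coeff = 2.58

(the 99% quantile pair of a normal), and the effective cutoff is
``max(m_floor, m_min)`` with a floor of |M| = 1.5 (fold change 2.8 up /
0.4 down).  Genes with M at or beyond the effective cutoff are called up-
or down-regulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CATEGORY_UP = "up"
CATEGORY_DOWN = "down"
CATEGORY_NON = "non"
CATEGORY_FILTERED = "filtered"

#: MA-plot colour tags, matching the conventional rendering
_CATEGORY_COLOR = {CATEGORY_UP: "green", CATEGORY_DOWN: "red", CATEGORY_NON: "grey"}


@dataclass(frozen=True)
class DEConfig:
    rpkm_min: float = 30.0
    a_min: float = 2.0
    m_floor: float = 1.5
    z_coeff: float = 2.58

    def __post_init__(self) -> None:
        if min(self.rpkm_min, self.a_min, self.m_floor, self.z_coeff) < 0:
            raise ValueError("DEConfig values must be non-negative")


@dataclass(frozen=True)
class CutoffCalibration:
    stdev_m: float
    m_min: float
    m_effective: float


def ma_statistics(
    rpkm_ref_reps: Sequence[float], rpkm_trt_reps: Sequence[float]
) -> tuple[float, float]:
    """(M, A) for one gene from replicate RPKM values of the two conditions."""
    ref = np.asarray(rpkm_ref_reps, dtype=float)
    trt = np.asarray(rpkm_trt_reps, dtype=float)
    if ref.size == 0 or trt.size == 0:
        raise ValueError("need at least one replicate per condition")
    if (ref <= 0).any() or (trt <= 0).any():
        raise ValueError("RPKM values must be positive (pseudocount guarantees this)")
    lr, lt = math.log2(ref.mean()), math.log2(trt.mean())
    return lt - lr, (lt + lr) / 2.0


def fold_change(M: float) -> float:
    """Linear fold change ``2**M`` corresponding to a log2 ratio."""
    return float(2.0**M)


def compute_ma_table(
    rpkm_df: pd.DataFrame,
    ref_samples: Sequence[str],
    trt_samples: Sequence[str],
) -> pd.DataFrame:
    """Per-gene means, M, A and fold change for a two-condition contrast.

    M is oriented treatment minus reference, so genes induced by the
    treatment get positive M.
    """
    mean_ref = rpkm_df[list(ref_samples)].mean(axis=1)
    mean_trt = rpkm_df[list(trt_samples)].mean(axis=1)
    if (mean_ref <= 0).any() or (mean_trt <= 0).any():
        raise ValueError("RPKM means must be positive")
    lr, lt = np.log2(mean_ref), np.log2(mean_trt)
    out = pd.DataFrame(
        {
            "gene_id": rpkm_df.index,
            "mean_rpkm_ref": mean_ref.to_numpy(),
            "mean_rpkm_trt": mean_trt.to_numpy(),
            "A": ((lt + lr) / 2.0).to_numpy(),
            "M": (lt - lr).to_numpy(),
        }
    ).set_index("gene_id", drop=False)
    out["fold_change"] = 2.0 ** out["M"]
    return out


def expression_filter(table: pd.DataFrame, config: DEConfig) -> pd.Series:
    """True for genes passing the expression filter.

    The RPKM >= ``rpkm_min`` requirement applies to the larger of the two
    condition means — a gene silent in one condition but strong in the other
    is exactly the interesting case — and A must exceed ``a_min``.
    """
    rpkm_ok = table[["mean_rpkm_ref", "mean_rpkm_trt"]].max(axis=1) >= config.rpkm_min
    return rpkm_ok & (table["A"] > config.a_min)


def calibrate_cutoff(all_M: Sequence[float], config: DEConfig = DEConfig()) -> CutoffCalibration:
    """Self-calibrate the minimal M cutoff from the observed M distribution.

    ``all_M`` should be the M-values of the genes passing the expression
    filter.  Uses the sample (n-1) standard deviation.
    """
    m = np.asarray(all_M, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 M-values to calibrate")
    stdev = float(np.std(m, ddof=1))
    m_min = config.z_coeff * stdev
    return CutoffCalibration(stdev_m=stdev, m_min=m_min, m_effective=max(config.m_floor, m_min))


def classify(
    table: pd.DataFrame, calibration: CutoffCalibration, config: DEConfig = DEConfig()
) -> pd.DataFrame:
    """Attach a regulation category to every gene of the contrast table.

    Categories partition the gene set: ``filtered`` (failed expression
    filter), ``up`` (M >= +m_effective), ``down`` (M <= -m_effective),
    else ``non``.
    """
    table = table.copy()
    passing = expression_filter(table, config)
    m = table["M"]
    category = np.where(
        ~passing,
        CATEGORY_FILTERED,
        np.where(
            m >= calibration.m_effective,
            CATEGORY_UP,
            np.where(m <= -calibration.m_effective, CATEGORY_DOWN, CATEGORY_NON),
        ),
    )
    table["category"] = category
    return table


def call_differential(
    rpkm_df: pd.DataFrame,
    ref_samples: Sequence[str],
    trt_samples: Sequence[str],
    config: DEConfig = DEConfig(),
) -> tuple[pd.DataFrame, CutoffCalibration]:
    """Full contrast: MA statistics, filter, cutoff calibration, classification."""
    table = compute_ma_table(rpkm_df, ref_samples, trt_samples)
    passing = expression_filter(table, config)
    calibration = calibrate_cutoff(table.loc[passing, "M"].to_numpy(), config)
    return classify(table, calibration, config), calibration


def ma_plot_table(results: pd.DataFrame) -> pd.DataFrame:
    """One row per non-filtered gene with the MA-plot colour tag."""
    kept = results[results["category"] != CATEGORY_FILTERED]
    out = kept[["gene_id", "A", "M", "category"]].copy()
    out["color"] = out["category"].map(_CATEGORY_COLOR)
    return out


def render_ma_plot(results: pd.DataFrame, path) -> None:
    """Render the MA plot (thin view over :func:`ma_plot_table`)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = ma_plot_table(results)
    fig, ax = plt.subplots(figsize=(6, 5))
    for cat, color in _CATEGORY_COLOR.items():
        sub = table[table["category"] == cat]
        ax.scatter(sub["A"], sub["M"], s=6, c=color, label=cat, alpha=0.6)
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("A (mean log2 RPKM)")
    ax.set_ylabel("M (log2 ratio)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
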