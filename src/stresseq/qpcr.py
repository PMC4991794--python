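"""qRT-PCR crossing-point (CP) reduction with propagated uncertainty.

CP values (cycles at the second-derivative maximum of the amplification
curve) are averaged in two stages: technical replicates are averaged within
each biological replicate, then the biological-replicate means are averaged.
The standard deviation is taken across the biological-replicate means.  For
a contrast, ΔCP = mean_b − mean_a, with the combined standard deviation by
quadrature (uncorrelated errors): sd_Δ = sqrt(sd_a² + sd_b²).  The relative
transcript amount assumes a doubling per cycle: rel = efficiency^(−ΔCP),
efficiency 2 by default.  No reference-gene normalisation is applied — the
comparison is on fixed RNA input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CpRecord:
    gene_id: str
    strain: str
    condition: str
    bio_rep: int
    tech_rep: int
    cp: float

    def __post_init__(self) -> None:
        if self.cp <= 0:
            raise ValueError("CP must be positive")


@dataclass(frozen=True)
class CpSummary:
    gene_id: str
    strain: str
    condition: str
    mean_cp: float
    sd: float
    n_bio: int


@dataclass(frozen=True)
class DeltaCp:
    gene_id: str
    contrast: tuple[str, str]  # (condition_a, condition_b)
    mean_cp_a: float
    mean_cp_b: float
    sd_a: float
    sd_b: float
    delta_cp: float
    sd_delta: float
    rel_amount: float


def summarize_cp(records: Sequence[CpRecord], min_bio: int = 2) -> CpSummary:
    """Two-stage average of one gene/strain/condition cell.

    Technical replicates are averaged per biological replicate first; the
    summary mean and sd are then taken over the biological-replicate means.
    Proceeds with a warning if a biological replicate is missing, as long as
    at least ``min_bio`` remain.
    """
    if not records:
        raise ValueError("no CP records")
    keys = {(r.gene_id, r.strain, r.condition) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple gene/strain/condition cells: {keys}")
    gene_id, strain, condition = next(iter(keys))

    by_bio: dict[int, list[float]] = {}
    for r in records:
        by_bio.setdefault(r.bio_rep, []).append(r.cp)
    declared = max(by_bio)
    if len(by_bio) < declared:
        logger.warning(
            "%s/%s/%s: %d of %d biological replicates present",
            gene_id, strain, condition, len(by_bio), declared,
        )
    if len(by_bio) < min_bio:
        raise ValueError(f"need >= {min_bio} biological replicates, got {len(by_bio)}")

    bio_means = np.array([float(np.mean(v)) for _, v in sorted(by_bio.items())])
    return CpSummary(
        gene_id=gene_id,
        strain=strain,
        condition=condition,
        mean_cp=float(bio_means.mean()),
        sd=float(bio_means.std(ddof=1)),
        n_bio=len(bio_means),
    )


def relative_amount(
    summary_a: CpSummary, summary_b: CpSummary, efficiency: float = 2.0
) -> DeltaCp:
    """ΔCP and relative transcript amount for the contrast a → b.

    ``rel_amount = efficiency**(-ΔCP)``: a condition with *lower* CP has
    *more* template, so rel_amount > 1 means condition b has more transcript.
    """
    if summary_a.gene_id != summary_b.gene_id or summary_a.strain != summary_b.strain:
        raise ValueError("contrast must compare the same gene and strain")
    delta = summary_b.mean_cp - summary_a.mean_cp
    sd_delta = math.hypot(summary_a.sd, summary_b.sd)
    return DeltaCp(
        gene_id=summary_a.gene_id,
        contrast=(summary_a.condition, summary_b.condition),
        mean_cp_a=summary_a.mean_cp,
        mean_cp_b=summary_b.mean_cp,
        sd_a=summary_a.sd,
        sd_b=summary_b.sd,
        delta_cp=delta,
        sd_delta=sd_delta,
        rel_amount=float(efficiency ** (-delta)),
    )


def read_cp_table(path) -> list[CpRecord]:
    """Read a CP table TSV: gene_id, strain, condition, bio_rep, tech_rep, cp."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "strain", "condition", "bio_rep", "tech_rep", "cp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        CpRecord(
            gene_id=row.gene_id,
            strain=row.strain,
            condition=row.condition,
            bio_rep=int(row.bio_rep),
            tech_rep=int(row.tech_rep),
            cp=float(row.cp),
        )
        for row in df.itertuples()
    ]


def analyze_cp_table(
    records: Sequence[CpRecord],
    condition_a: str = "unstressed",
    condition_b: str = "stressed",
    efficiency: float = 2.0,
) -> list[DeltaCp]:
    """Per-(gene, strain) ΔCP analysis of a full CP table."""
    cells: dict[tuple[str, str, str], list[CpRecord]] = {}
    for r in records:
        cells.setdefault((r.gene_id, r.strain, r.condition), []).append(r)
    out: list[DeltaCp] = []
    pairs = sorted({(g, s) for g, s, _ in cells})
    for gene, strain in pairs:
        a = cells.get((gene, strain, condition_a))
        b = cells.get((gene, strain, condition_b))
        if a is None or b is None:
            logger.warning("gene %s strain %s lacks one condition; skipped", gene, strain)
            continue
        out.append(
            relative_amount(summarize_cp(a), summarize_cp(b), efficiency=efficiency)
        )
    return out
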