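"""Fragment counting per CDS and pseudocount RPKM normalisation.

A fragment is assigned to the CDS that contains its midpoint (and, when
counting stranded, lies on the same strand); fragments whose midpoint falls
in intergenic space, or over an ambiguous overlap, contribute only to the
library size.  RPKM is computed from the raw count *plus one pseudo read*,
so every gene has a strictly positive expression value:

    RPKM = (count + 1) * 1e9 / (length_bp * total_fragments)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragment_assembly import Fragment
from .io_formats import CdsFeature

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Raw fragment counts (genes x samples) plus per-sample library sizes.

    ``total_fragments`` counts every assembled fragment of the sample,
    assigned to a CDS or not — the "per million mapped" denominator refers
    to mapping, not to feature assignment.
    """

    counts: pd.DataFrame  # genes x samples, int
    total_fragments: pd.Series  # per sample, int
    gene_lengths: pd.Series  # per gene, bp

    def __post_init__(self) -> None:
        if (self.total_fragments < self.counts.sum(axis=0)).any():
            raise ValueError("per-sample counts exceed total_fragments")


def _midpoints(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    return (starts + ends - 1) // 2


class _StrandIndex:
    """Midpoint -> CDS lookup for one (ref_id, strand) group.

    Uses a vectorised sorted-interval lookup when the group is
    non-overlapping (the common case for a bacterial CDS annotation);
    falls back to an interval tree otherwise.
    """

    def __init__(self, feats: Sequence[CdsFeature]):
        feats = sorted(feats, key=lambda f: f.start)
        self.starts = np.array([f.start for f in feats], dtype=np.int64)
        self.ends = np.array([f.end for f in feats], dtype=np.int64)
        self.gene_idx: list[str] = [f.gene_id for f in feats]
        self.overlapping = bool((self.ends[:-1] > self.starts[1:]).any())
        if self.overlapping:
            from intervaltree import IntervalTree

            self.tree = IntervalTree()
            for f in feats:
                self.tree[f.start:f.end] = f.gene_id

    def assign(self, mids: np.ndarray) -> list[str | None]:
        if not self.overlapping:
            idx = np.searchsorted(self.starts, mids, side="right") - 1
            ok = (idx >= 0) & (mids < self.ends[np.clip(idx, 0, None)])
            return [self.gene_idx[i] if hit else None for i, hit in zip(idx, ok)]
        out: list[str | None] = []
        for m in mids:
            hits = self.tree[int(m)]
            # ambiguous midpoints (overlapping CDSs) are left unassigned
            out.append(next(iter(hits)).data if len(hits) == 1 else None)
        return out


def count_fragments(
    fragments: Iterable[Fragment],
    annotation: Sequence[CdsFeature],
    stranded: bool = True,
) -> tuple[pd.Series, int]:
    """Count fragments per CDS by midpoint assignment for one sample.

    Returns the per-gene counts (indexed by gene_id, annotation order) and
    the total number of fragments seen (the library size).
    """
    if not annotation:
        raise ValueError("empty annotation")
    index: dict[tuple[str, str], list[CdsFeature]] = {}
    known_refs = set()
    for f in annotation:
        known_refs.add(f.ref_id)
        key = (f.ref_id, f.strand) if stranded else (f.ref_id, ".")
        index.setdefault(key, []).append(f)
    lookups = {key: _StrandIndex(feats) for key, feats in index.items()}

    fragments = list(fragments)
    total = len(fragments)
    counts = pd.Series(0, index=[f.gene_id for f in annotation], dtype=np.int64)

    # bucket fragments per lookup group, then assign vectorised
    buckets: dict[tuple[str, str], list[int]] = {}
    warned_refs: set[str] = set()
    frag_ref = [f.ref_id for f in fragments]
    for i, f in enumerate(fragments):
        if f.ref_id not in known_refs:
            if f.ref_id not in warned_refs:
                logger.warning("fragment reference %r absent from annotation", f.ref_id)
                warned_refs.add(f.ref_id)
            continue
        key = (f.ref_id, f.strand) if stranded else (f.ref_id, ".")
        buckets.setdefault(key, []).append(i)

    starts = np.array([f.start for f in fragments], dtype=np.int64)
    ends = np.array([f.end for f in fragments], dtype=np.int64)
    for key, idxs in buckets.items():
        lookup = lookups.get(key)
        if lookup is None:  # no CDS on this strand of this reference
            continue
        mids = _midpoints(starts[idxs], ends[idxs])
        assigned = lookup.assign(mids)
        hit_genes = [g for g in assigned if g is not None]
        if hit_genes:
            vc = pd.Series(hit_genes).value_counts()
            counts.loc[vc.index] += vc.astype(np.int64)
    return counts, total


def build_count_matrix(
    per_sample_fragments: Mapping[str, Iterable[Fragment]],
    annotation: Sequence[CdsFeature],
    stranded: bool = True,
) -> CountMatrix:
    """Count every sample against one annotation into a CountMatrix."""
    cols = {}
    totals = {}
    for sample_id, frags in per_sample_fragments.items():
        counts, total = count_fragments(frags, annotation, stranded=stranded)
        cols[sample_id] = counts
        totals[sample_id] = total
    lengths = pd.Series(
        {f.gene_id: f.length_bp for f in annotation}, name="length_bp"
    )
    return CountMatrix(
        counts=pd.DataFrame(cols),
        total_fragments=pd.Series(totals, dtype=np.int64),
        gene_lengths=lengths,
    )


def rpkm(count: int, length_bp: int, total_fragments: int) -> float:
    """Pseudocount RPKM: ``(count + 1) * 1e9 / (length_bp * total_fragments)``."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if total_fragments < 1:
        raise ValueError("total_fragments must be >= 1")
    return (count + 1) * 1e9 / (length_bp * total_fragments)


def rpkm_matrix(matrix: CountMatrix) -> pd.DataFrame:
    """Per-(gene, sample) pseudocount RPKM; strictly positive by construction."""
    lengths = matrix.gene_lengths.reindex(matrix.counts.index)
    vals = (
        (matrix.counts + 1).to_numpy(dtype=float)
        * 1e9
        / np.outer(lengths.to_numpy(dtype=float), matrix.total_fragments.to_numpy(dtype=float))
    )
    return pd.DataFrame(vals, index=matrix.counts.index, columns=matrix.counts.columns)
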