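"""End-to-end convenience wrappers: SAM files -> fragments -> RPKM -> DE calls."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .de_calling import CutoffCalibration, DEConfig, call_differential
from .expression import CountMatrix, build_count_matrix, rpkm_matrix
from .fragment_assembly import AssemblyStats, assemble_fragments
from .io_formats import CdsFeature, read_mapped_reads


def quantify_samples(
    sam_paths: Mapping[str, str | Path],
    annotation: Sequence[CdsFeature],
    max_distance: int = 1000,
    stranded: bool = True,
    multimap: str = "drop",
) -> tuple[CountMatrix, dict[str, AssemblyStats]]:
    """Assemble and count every sample's mapped reads against one annotation."""
    per_sample = {}
    stats: dict[str, AssemblyStats] = {}
    for sample_id, path in sam_paths.items():
        frags, st = assemble_fragments(
            read_mapped_reads(path), max_distance=max_distance, multimap=multimap
        )
        per_sample[sample_id] = frags
        stats[sample_id] = st
    return build_count_matrix(per_sample, annotation, stranded=stranded), stats


def run_contrast(
    sam_paths: Mapping[str, str | Path],
    annotation: Sequence[CdsFeature],
    ref_samples: Sequence[str],
    trt_samples: Sequence[str],
    config: DEConfig = DEConfig(),
    **kwargs,
) -> tuple[pd.DataFrame, CutoffCalibration]:
    """Full two-condition contrast from SAM files to classified DE results."""
    matrix, _stats = quantify_samples(sam_paths, annotation, **kwargs)
    return call_differential(rpkm_matrix(matrix), ref_samples, trt_samples, config)
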