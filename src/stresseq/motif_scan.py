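"""Response-regulator binding-site scanning by ungapped percent identity.

Candidate operator sites are compared to a 16-bp reference binding site
(the *S. reticuli* SenR operator site III, ``CCGGGCCGCGTCCCGT``) by sliding
the shorter sequence along the longer one over every full-overlap offset and
taking the best positionwise match count:

    pct_identity = 100 * max_offset(matches) / len(shorter)

reported as a round-half-up integer, matching how operator-site
conservation is conventionally tabulated.  Upstream promoter regions are
scanned exhaustively over a window-length range, and aligned site sets are
summarised by per-position logo information content (bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: the S. reticuli SenR binding site III, the default reference operator
SENR_SITE_III = "CCGGGCCGCGTCCCGT"


@dataclass(frozen=True)
class ReferenceSite:
    sequence: str = SENR_SITE_III
    name: str = "SenR_site_III"

    def __post_init__(self) -> None:
        if len(self.sequence) < 4:
            raise ValueError("reference site must be at least 4 bp")


@dataclass(frozen=True)
class MotifHit:
    candidate: str
    pct_identity: float
    reported_identity: int
    best_offset: int
    upstream_position: int | None = None  # 0-based start within upstream region
    distance_to_start: int | None = None  # bp strictly between 3' end and start codon

    @property
    def length(self) -> int:
        return len(self.candidate)


@dataclass(frozen=True)
class LogoColumn:
    position: int  # 1-based
    freqs: dict[str, float]
    bits: float


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def ungapped_identity(candidate: str, reference: str) -> MotifHit:
    """Best ungapped percent identity of ``candidate`` against ``reference``.

    The shorter sequence slides along the longer over every offset with full
    overlap; identity is the best positionwise match count over the shorter
    length.  Ties are broken by the smallest offset.  Characters outside
    A/C/G/T never match (but still count toward length).
    """
    if not candidate or not reference:
        raise ValueError("sequences must be non-empty")
    shorter, longer = (candidate, reference) if len(candidate) <= len(reference) else (reference, candidate)
    best_matches, best_offset = -1, 0
    valid = set("ACGT")
    for offset in range(len(longer) - len(shorter) + 1):
        matches = sum(
            a == b and a in valid
            for a, b in zip(shorter, longer[offset : offset + len(shorter)])
        )
        if matches > best_matches:
            best_matches, best_offset = matches, offset
    pct = 100.0 * best_matches / len(shorter)
    return MotifHit(
        candidate=candidate,
        pct_identity=pct,
        reported_identity=_round_half_up(pct),
        best_offset=best_offset,
    )


def scan_upstream(
    upstream_seq: str,
    reference: str | ReferenceSite = SENR_SITE_III,
    len_range: tuple[int, int] = (10, 20),
    min_identity: float = 53.0,
) -> list[MotifHit]:
    """Scan an upstream region for candidate operator sites.

    ``upstream_seq`` is oriented 5'→3' on the coding strand and ends at the
    base immediately before the start codon.  Every substring with length in
    ``len_range`` is scored against the reference; hits at or above
    ``min_identity`` are resolved greedily (identity desc, length desc,
    leftmost) so reported hits do not overlap.  ``distance_to_start`` counts
    the bases strictly between the site's 3' end and the start codon.
    """
    if isinstance(reference, ReferenceSite):
        reference = reference.sequence
    lo, hi = len_range
    if lo > hi:
        raise ValueError(f"inverted length range {len_range}")
    n = len(upstream_seq)
    if n < lo:
        raise ValueError("upstream region shorter than the minimum window")

    candidates: list[MotifHit] = []
    for length in range(lo, min(hi, n) + 1):
        for start in range(n - length + 1):
            window = upstream_seq[start : start + length]
            hit = ungapped_identity(window, reference)
            if hit.pct_identity >= min_identity:
                candidates.append(
                    replace(
                        hit,
                        upstream_position=start,
                        distance_to_start=n - (start + length),
                    )
                )

    candidates.sort(
        key=lambda h: (-h.pct_identity, -h.length, h.upstream_position)
    )
    chosen: list[MotifHit] = []
    occupied: list[tuple[int, int]] = []
    for h in candidates:
        s, e = h.upstream_position, h.upstream_position + h.length
        if all(e <= s0 or s >= e0 for s0, e0 in occupied):
            chosen.append(h)
            occupied.append((s, e))
    chosen.sort(key=lambda h: h.upstream_position)
    return chosen


def information_content(
    sites: Sequence[str], correction: bool = False
) -> list[LogoColumn]:
    """Per-position logo information content of equal-length aligned sites.

    For each column the base frequencies are taken over non-gap characters
    and ``bits = 2 + sum(f * log2 f)`` (Shannon information of a 4-letter
    alphabet).  The optional small-sample correction subtracts
    ``3 / (2 ln2 n)`` with n the number of non-gap characters, clamped at 0.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    lengths = {len(s) for s in sites}
    if len(lengths) != 1:
        raise ValueError("sites must be of equal length (align them first)")
    (L,) = lengths
    columns: list[LogoColumn] = []
    for pos in range(L):
        chars = [s[pos] for s in sites if s[pos] != "-"]
        n = len(chars)
        if n == 0:
            columns.append(LogoColumn(pos + 1, {}, 0.0))
            continue
        freqs = {b: chars.count(b) / n for b in sorted(set(chars))}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        bits = 2.0 - entropy
        if correction:
            bits -= 3.0 / (2.0 * math.log(2) * n)
        columns.append(LogoColumn(pos + 1, freqs, max(0.0, min(2.0, bits))))
    return columns


def logo_matrix(columns: Sequence[LogoColumn]) -> "np.ndarray":
    """Position x base (A,C,G,T) matrix of frequency*bits, for logo plotting."""
    bases = "ACGT"
    mat = np.zeros((len(columns), 4))
    for i, col in enumerate(columns):
        for j, b in enumerate(bases):
            mat[i, j] = col.freqs.get(b, 0.0) * col.bits
    return mat
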