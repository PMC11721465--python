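"""Complementary-hydropathy screening.

Converts protein sequences to signed hydropathy maps on the Kyte–Doolittle
scale, slides short motifs over a target in both reading orientations, and
scores every window by two criteria:

* **percent match** — the percentage of aligned residue pairs whose
  hydropathy signs are opposite;
* **complementarity degree** ``C = Σ|H(i) − H'(i)| / (L·9)`` — the mean
  absolute hydropathy difference normalised by the scale span (9), bounded
  in [0, 1].

A window is a hit when percent match exceeds 75 and the degree exceeds 0.5
(strict comparisons).  Passing hits can be accumulated into per-residue
counts and merged into candidate binding regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlphabetError, BlimapError

#: Kyte & Doolittle hydropathy indices for the 20 standard amino acids.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5,
    "V": 4.2,
    "L": 3.8,
    "F": 2.8,
    "C": 2.5,
    "M": 1.9,
    "A": 1.8,
    "G": -0.4,
    "T": -0.7,
    "S": -0.8,
    "W": -0.9,
    "Y": -1.3,
    "P": -1.6,
    "H": -3.2,
    "E": -3.5,
    "Q": -3.5,
    "D": -3.5,
    "N": -3.5,
    "K": -3.9,
    "R": -4.5,
}

#: Scale span (max − min = 4.5 − (−4.5)); the Eq.-1 normaliser.
SCALE_SPAN = 9.0

#: Default hit thresholds (strict: a hit needs match > 75 AND degree > 0.5).
MATCH_THRESHOLD = 75.0
DEGREE_THRESHOLD = 0.5

AMINO_ACIDS = tuple(KYTE_DOOLITTLE)

_INDEX = np.full(128, np.nan)
for _aa, _h in KYTE_DOOLITTLE.items():
    _INDEX[ord(_aa)] = _h


def hydropathy_map(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (signs, values): per-residue hydropathy sign (±1) and raw index.

    No standard residue has index 0, so the sign is always ±1.  Non-standard
    letters (B, J, O, U, X, Z, ...) raise :class:`AlphabetError` naming the
    first offending position (1-based).
    """
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    values = _INDEX[np.clip(codes, 0, 127)]
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        pos = int(bad[0])
        raise AlphabetError(
            f"non-standard residue {seq[pos]!r} at position {pos + 1}"
        )
    signs = np.where(values > 0, 1, -1).astype(np.int8)
    if values.size == 0:
        signs = np.zeros(0, dtype=np.int8)
    return signs, values


def percent_match(motif_signs: np.ndarray, window_signs: np.ndarray) -> float:
    """Percentage of aligned pairs with opposite hydropathy signs."""
    a = np.asarray(motif_signs)
    b = np.asarray(window_signs)
    if a.shape != b.shape:
        raise BlimapError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise BlimapError("empty sign vectors")
    return 100.0 * float(np.count_nonzero(a != b)) / a.size


def complementarity_degree(motif_indices: np.ndarray, window_indices: np.ndarray) -> float:
    """Degree of complementary hydropathy: mean |H − H'| over the scale span."""
    a = np.asarray(motif_indices, dtype=float)
    b = np.asarray(window_indices, dtype=float)
    if a.shape != b.shape:
        raise BlimapError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise BlimapError("empty hydropathy vectors")
    return float(np.sum(np.abs(a - b)) / (a.size * SCALE_SPAN))


@dataclass(frozen=True)
class Motif:
    """A short query sequence, typically one secondary-structure element."""

    name: str
    sequence: str
    source: tuple[str, int, int] | None = None  # (protein, start, end), 1-based inclusive

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise BlimapError(f"motif {self.name!r}: sequence shorter than 3 residues")
        if self.source is not None:
            protein, start, end = self.source
            if end - start + 1 != len(self.sequence):
                raise BlimapError(
                    f"motif {self.name!r}: region {protein}:{start}-{end} length "
                    f"does not match sequence length {len(self.sequence)}"
                )
        hydropathy_map(self.sequence)  # validate alphabet eagerly


@dataclass(frozen=True)
class HydropathyHit:
    """Score of one motif orientation against one target window."""

    motif: str
    orientation: str  # "forward" | "reverse"
    window_start: int  # 1-based, inclusive
    window_end: int  # 1-based, inclusive
    percent_match: float
    degree: float
    passes: bool


def screen(
    motif: Motif,
    target: str,
    match_threshold: float = MATCH_THRESHOLD,
    degree_threshold: float = DEGREE_THRESHOLD,
) -> list[HydropathyHit]:
    """Slide a motif over every target window in both orientations.

    Exhaustive at step 1: ``len(target) − L + 1`` windows per orientation.
    Reverse orientation means reversed residue order of the motif.
    """
    L = len(motif.sequence)
    _, target_vals = hydropathy_map(target)
    if len(target) < L:
        raise BlimapError(
            f"motif {motif.name!r} (L={L}) longer than target ({len(target)})"
        )
    # scale indices to exact deci-units so threshold comparisons are exact
    target_deci = np.round(target_vals * 10.0).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(target_deci, L)
    win_signs = windows > 0

    hits: list[HydropathyHit] = []
    _, fwd_vals = hydropathy_map(motif.sequence)
    fwd_deci = np.round(fwd_vals * 10.0).astype(np.int64)
    for orientation, vals in (("forward", fwd_deci), ("reverse", fwd_deci[::-1])):
        signs = vals > 0
        match = 100.0 * np.count_nonzero(signs[None, :] != win_signs, axis=1) / L
        degree = np.sum(np.abs(vals[None, :] - windows), axis=1) / (L * SCALE_SPAN * 10.0)
        passing = (match > match_threshold) & (degree > degree_threshold)
        for i in range(windows.shape[0]):
            hits.append(
                HydropathyHit(
                    motif=motif.name,
                    orientation=orientation,
                    window_start=i + 1,
                    window_end=i + L,
                    percent_match=float(match[i]),
                    degree=float(degree[i]),
                    passes=bool(passing[i]),
                )
            )
    return hits


@dataclass
class RegionSummary:
    """Per-residue passing-hit coverage on a target plus merged hit regions."""

    target_length: int
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    regions: list[tuple[int, int]] = field(default_factory=list)


def merge_spans(spans: list[tuple[int, int]], max_gap: int = 1) -> list[tuple[int, int]]:
    """Merge 1-based inclusive spans that overlap or abut (gap ≤ ``max_gap``)."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for start, end in spans[1:]:
        if start - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def screen_region_set(
    motifs: list[Motif],
    target: str,
    match_threshold: float = MATCH_THRESHOLD,
    degree_threshold: float = DEGREE_THRESHOLD,
    max_gap: int = 1,
) -> RegionSummary:
    """Screen every motif in both orientations and cluster the passing hits.

    Counts, per target residue, how many passing windows cover it; merges
    passing windows into non-overlapping candidate regions.
    """
    counts = np.zeros(len(target), dtype=int)
    spans: list[tuple[int, int]] = []
    for motif in motifs:
        for hit in screen(motif, target, match_threshold, degree_threshold):
            if hit.passes:
                counts[hit.window_start - 1 : hit.window_end] += 1
                spans.append((hit.window_start, hit.window_end))
    return RegionSummary(
        target_length=len(target),
        counts=counts,
        regions=merge_spans(spans, max_gap=max_gap),
    )


def hits_to_frame(hits: list[HydropathyHit], target_name: str = "") -> pd.DataFrame:
    """Tabulate hits with the canonical TSV column layout."""
    return pd.DataFrame(
        {
            "motif": [h.motif for h in hits],
            "orientation": [h.orientation for h in hits],
            "target": target_name,
            "window_start": [h.window_start for h in hits],
            "window_end": [h.window_end for h in hits],
            "percent_match": [h.percent_match for h in hits],
            "degree": [h.degree for h in hits],
            "passes": [h.passes for h in hits],
        }
    )
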