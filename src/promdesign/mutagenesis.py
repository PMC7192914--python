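"""In silico saturation mutagenesis of designed promoters.

For a sequence and a trained model, every single-base substitution is
scored.  Sign conventions, fixed throughout the package:

* score differential = mutant score - original score (negative means the
  mutation is predicted to lose activity);
* position score = max over the three mutants of (original - mutant), the
  greatest predicted loss at that position (always >= 0 when any mutation
  hurts).

Importance profiles average position scores over a design set and normalize
to the largest value.  Candidate motif blocks are contiguous runs of
positions in the most-negative tail of the signed differentials.  Two
motif-level summaries quantify effects the models discover in designed
sequences: mutations inside TA dinucleotide repeats, and mutations in the
GCTA tetramer extending the ZEV binding site GCGTGGGCG.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scaffold import BASES, _BASE_INDEX


@dataclass
class MutagenesisProfile:
    """Per-position, per-alternative-base differentials for one sequence.

    ``diffs`` has shape (L, 4): mutant - original score for each
    alternative base, NaN at the original base.  ``position_scores`` is the
    greatest predicted loss per position.  ``mask`` marks randomized
    (mutable) positions.
    """

    sequence: str
    original_score: float
    diffs: np.ndarray
    mask: np.ndarray

    @property
    def position_scores(self) -> np.ndarray:
        return -np.nanmin(self.diffs, axis=1)

    @property
    def min_differential(self) -> np.ndarray:
        """Most negative signed differential per position."""
        return np.nanmin(self.diffs, axis=1)


@dataclass
class ImportanceProfile:
    scores: np.ndarray  # in [0, 1], max exactly 1 when any nonzero
    mask: np.ndarray


def single_mutant_scan(
    seq: str, scorer, objective, mask: np.ndarray | None = None
) -> MutagenesisProfile:
    """Score all 3L single-base substitutions of ``seq`` in one batch."""
    L = len(seq)
    if mask is None:
        mask = np.ones(L, dtype=bool)
    mutants, where = [], []
    for p in range(L):
        for b in BASES:
            if b != seq[p]:
                mutants.append(seq[:p] + b + seq[p + 1 :])
                where.append((p, _BASE_INDEX[b]))
    scores = np.asarray(scorer.score_seqs([seq] + mutants, objective))
    original = float(scores[0])
    diffs = np.full((L, 4), np.nan)
    for (p, bi), s in zip(where, scores[1:]):
        diffs[p, bi] = float(s) - original
    return MutagenesisProfile(seq, original, diffs, np.asarray(mask, dtype=bool))


def position_importance(profiles: list[MutagenesisProfile]) -> ImportanceProfile:
    """Mean position score across sequences, normalized to the maximum."""
    if not profiles:
        raise ValueError("need at least one profile")
    L = len(profiles[0].sequence)
    if any(len(p.sequence) != L for p in profiles):
        raise ValueError("profiles must share one length")
    mean = np.mean([p.position_scores for p in profiles], axis=0)
    top = mean.max()
    scores = mean / top if top > 0 else mean
    return ImportanceProfile(scores, profiles[0].mask.copy())


def low_score_blocks(
    profiles: list[MutagenesisProfile],
    min_len: int = 6,
    select_fraction: float = 0.05,
) -> tuple[list[list[tuple[int, int]]], float]:
    """Candidate motif blocks: runs of >= ``min_len`` consecutive
    randomizable positions whose most-negative differential falls strictly below the
    quantile threshold selecting ``select_fraction`` of randomizable bases.

    Returns per-sequence lists of half-open (start, end) intervals, plus
    the threshold used.
    """
    if not (0.0 < select_fraction < 1.0):
        raise ValueError("select_fraction must lie in (0, 1)")
    pooled = np.concatenate([p.min_differential[p.mask] for p in profiles])
    threshold = float(np.quantile(pooled, select_fraction))
    out = []
    for p in profiles:
        below = (p.min_differential < threshold) & p.mask
        out.append([iv for iv in _runs(below) if iv[1] - iv[0] >= min_len])
    return out, threshold


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open intervals."""
    out = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(flags)))
    return out


def find_longest_repeat(seq: str, unit: str = "TA", min_len: int = 6) -> tuple[int, int] | None:
    """Longest run of whole ``unit`` repeats of at least ``min_len`` bases;
    half-open coordinates, or None."""
    best = None
    for m in re.finditer(f"(?:{unit})+", seq):
        ln = (m.end() - m.start()) // len(unit) * len(unit)
        if ln >= min_len and (best is None or ln > best[1] - best[0]):
            best = (m.start(), m.start() + ln)
    return best


def repeat_differential(
    seqs: list[str],
    profiles: list[MutagenesisProfile],
    unit: str = "TA",
    min_len: int = 6,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Median score differentials inside each sequence's longest TA repeat,
    grouped by repeat length, against a non-repeat baseline.

    ``region`` restricts the analysis to a scaffold window (e.g. the 5'
    spacer); positions there that fall outside any qualifying repeat feed
    the baseline row (repeat_length = 0).  Each row carries the per-sequence
    median of all single-mutation differentials at the relevant positions.
    """
    rows = []
    for si, (seq, prof) in enumerate(zip(seqs, profiles)):
        lo, hi = (0, len(seq)) if region is None else region
        sub = seq[lo:hi]
        hit = find_longest_repeat(sub, unit, min_len)
        in_repeat = np.zeros(len(seq), dtype=bool)
        if hit is not None:
            start, end = hit[0] + lo, hit[1] + lo
            in_repeat[start:end] = True
            vals = prof.diffs[start:end][~np.isnan(prof.diffs[start:end])]
            rows.append(
                {
                    "sequence_index": si,
                    "repeat_length": end - start,
                    "median_differential": float(np.median(vals)),
                }
            )
        base_sel = np.zeros(len(seq), dtype=bool)
        base_sel[lo:hi] = True
        base_sel &= ~in_repeat & prof.mask
        if base_sel.any():
            vals = prof.diffs[base_sel][~np.isnan(prof.diffs[base_sel])]
            rows.append(
                {
                    "sequence_index": si,
                    "repeat_length": 0,
                    "median_differential": float(np.median(vals)),
                }
            )
    return pd.DataFrame(rows)


def site_extension_differential(
    seqs: list[str],
    profiles: list[MutagenesisProfile],
    site_motif: str = "GCGTGGGCG",
    extension: str = "GCTA",
    site_positions: list[int] | None = None,
) -> pd.DataFrame:
    """Median differentials of the tetramer following each binding-site
    occurrence, classified by whether that tetramer is the extension.

    ``site_positions`` are scaffold-coordinate starts of the site; when
    None, occurrences are found in the first sequence.  Rows: one per
    (sequence, site index) with is_extension and median differential over
    the four following positions.
    """
    if site_positions is None:
        site_positions = [m.start() for m in re.finditer(site_motif, seqs[0])]
    if not site_positions:
        import warnings

        warnings.warn("site motif not found; empty result")
        return pd.DataFrame(columns=["sequence_index", "site_index", "is_extension", "median_differential"])
    rows = []
    ext_len = len(extension)
    for si, seq in enumerate(seqs):
        prof = profiles[si]
        for k, pos in enumerate(site_positions):
            start = pos + len(site_motif)
            end = start + ext_len
            if end > len(seq) or seq[pos : pos + len(site_motif)] != site_motif:
                continue
            tet = seq[start:end]
            vals = prof.diffs[start:end][~np.isnan(prof.diffs[start:end])]
            rows.append(
                {
                    "sequence_index": si,
                    "site_index": k,
                    "is_extension": tet == extension,
                    "median_differential": float(np.median(vals)),
                }
            )
    return pd.DataFrame(rows)


def frequency_matrix(seqs: list[str], region: tuple[int, int] | None = None) -> np.ndarray:
    """Per-column base counts (4 x region length); column sums equal the
    number of sequences.  Input to sequence-logo rendering."""
    if not seqs:
        raise ValueError("need at least one sequence")
    lo, hi = (0, len(seqs[0])) if region is None else region
    width = hi - lo
    counts = np.zeros((4, width), dtype=int)
    for s in seqs:
        if len(s) < hi:
            raise ValueError("sequence shorter than region")
        for j, c in enumerate(s[lo:hi]):
            counts[_BASE_INDEX[c], j] += 1
    return counts
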