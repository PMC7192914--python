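"""Promoter library scaffolds.

A scaffold is an ordered arrangement of constant motifs (transcription factor
binding sites, TATA box, TSS) and randomized spacer segments with specified
base composition.  It defines both the sequence space of a promoter library
and the mutable mask used by the design and mutagenesis stages.

Coordinates are 0-based, half-open throughout.  One-hot rows are ordered
A, C, G, T everywhere in this package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: BsaI recognition site and its reverse complement.
BSAI_SITE = "GGTCTC"
BSAI_SITE_RC = "GAGACC"


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside A, C, G, T."""


def _check_dna(seq: str) -> str:
    if any(c not in _BASE_INDEX for c in seq):
        bad = sorted({c for c in seq if c not in _BASE_INDEX})
        raise InvalidSequenceError(f"non-ACGT characters: {bad}")
    return seq


@dataclass(frozen=True)
class Segment:
    """One scaffold segment: a constant motif or a randomized spacer.

    Constant segments carry a literal sequence; randomized segments carry a
    length and a base-frequency 4-vector over (A, C, G, T).  A frequency of
    zero excludes a base from the spacer (e.g. no G after the TSS, to avoid
    premature ATG start codons).
    """

    kind: str  # "constant" | "randomized"
    sequence: str | None = None
    length: int | None = None
    base_freqs: tuple[float, float, float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if not self.sequence:
                raise ValueError("constant segment needs a sequence")
            _check_dna(self.sequence)
            object.__setattr__(self, "length", len(self.sequence))
        elif self.kind == "randomized":
            if self.length is None or self.length < 1:
                raise ValueError("randomized segment needs length >= 1")
            if self.base_freqs is None or len(self.base_freqs) != 4:
                raise ValueError("randomized segment needs a base_freqs 4-vector")
            f = np.asarray(self.base_freqs, dtype=float)
            if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("base_freqs must be nonnegative and sum to 1")
        else:
            raise ValueError(f"unknown segment kind {self.kind!r}")

    @property
    def is_randomized(self) -> bool:
        return self.kind == "randomized"


@dataclass(frozen=True)
class LibraryScaffold:
    """An ordered list of segments plus flanking vector context."""

    name: str
    segments: tuple[Segment, ...]
    flank_5: str = ""
    flank_3: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        _check_dna(self.flank_5)
        _check_dna(self.flank_3)
        if not self.segments:
            raise ValueError("scaffold needs at least one segment")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def fraction_randomized(self) -> float:
        return sum(s.length for s in self.segments if s.is_randomized) / self.total_length

    def randomized_mask(self) -> np.ndarray:
        """Boolean vector, True where a position lies in a randomized segment."""
        mask = np.zeros(self.total_length, dtype=bool)
        pos = 0
        for seg in self.segments:
            if seg.is_randomized:
                mask[pos : pos + seg.length] = True
            pos += seg.length
        return mask

    def segment_bounds(self) -> list[tuple[int, int, Segment]]:
        """(start, end, segment) triples in scaffold coordinates."""
        out, pos = [], 0
        for seg in self.segments:
            out.append((pos, pos + seg.length, seg))
            pos += seg.length
        return out

    def base_freq_matrix(self) -> np.ndarray:
        """Per-position sampling frequencies, shape (4, L).

        Constant positions get probability 1 on their base.  Used by the
        design stage to restrict moves to the library's sequence space.
        """
        freqs = np.zeros((4, self.total_length))
        for start, end, seg in self.segment_bounds():
            if seg.is_randomized:
                freqs[:, start:end] = np.asarray(seg.base_freqs)[:, None]
            else:
                for j, c in enumerate(seg.sequence):
                    freqs[_BASE_INDEX[c], start + j] = 1.0
        return freqs

    def constant_backbone(self) -> str:
        """Constant segments verbatim, randomized positions as ``N``."""
        parts = []
        for seg in self.segments:
            parts.append(seg.sequence if not seg.is_randomized else "N" * seg.length)
        return "".join(parts)

    def matches_constant_regions(self, seq: str) -> bool:
        if len(seq) != self.total_length:
            return False
        for start, end, seg in self.segment_bounds():
            if not seg.is_randomized and seq[start:end] != seg.sequence:
                return False
        return True


def sample_sequence(scaffold: LibraryScaffold, rng: np.random.Generator) -> str:
    """Draw one library member: constant segments verbatim, randomized
    positions i.i.d. from their segment's base frequencies."""
    parts = []
    for seg in scaffold.segments:
        if seg.is_randomized:
            idx = rng.choice(4, size=seg.length, p=np.asarray(seg.base_freqs))
            parts.append("".join(BASES[i] for i in idx))
        else:
            parts.append(seg.sequence)
    return "".join(parts)


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode, shape (4, L), rows A, C, G, T; columns sum to 1."""
    _check_dna(seq)
    mat = np.zeros((4, len(seq)))
    for p, c in enumerate(seq):
        mat[_BASE_INDEX[c], p] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot` (argmax per column)."""
    return "".join(BASES[i] for i in np.asarray(mat).argmax(axis=0))


def gc_window_ok(seq: str, window: int = 20, lo: float = 0.25, hi: float = 0.80) -> bool:
    """Synthesizability filter: every ``window``-length substring must have a
    GC fraction within [lo, hi] inclusive.  Sequences shorter than ``window``
    pass vacuously."""
    _check_dna(seq)
    n = len(seq)
    if n < window:
        return True
    gc = np.frompyfunc(lambda c: c in "GC", 1, 1)(list(seq)).astype(float)
    cs = np.concatenate([[0.0], np.cumsum(gc)])
    sums = cs[window:] - cs[:-window]
    frac = sums / window
    return bool((frac >= lo - 1e-12).all() and (frac <= hi + 1e-12).all())


def contains_bsai(seq: str) -> bool:
    """True iff the sequence contains a BsaI site on either strand."""
    return BSAI_SITE in seq or BSAI_SITE_RC in seq


# ---------------------------------------------------------------------------
# Scaffold file format: tab-separated, one row per segment, with '#'-prefixed
# header lines for name and flanks.  Columns:
#   kind  label  sequence  length  freq_A  freq_C  freq_G  freq_T
# ('.' marks inapplicable fields.)
# ---------------------------------------------------------------------------

def save_scaffold(scaffold: LibraryScaffold, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {scaffold.name}\n")
        fh.write(f"# flank_5: {scaffold.flank_5}\n")
        fh.write(f"# flank_3: {scaffold.flank_3}\n")
        fh.write("kind\tlabel\tsequence\tlength\tfreq_A\tfreq_C\tfreq_G\tfreq_T\n")
        for seg in scaffold.segments:
            if seg.is_randomized:
                fa, fc, fg, ft = seg.base_freqs
                fh.write(
                    f"randomized\t{seg.label or '.'}\t.\t{seg.length}"
                    f"\t{fa:g}\t{fc:g}\t{fg:g}\t{ft:g}\n"
                )
            else:
                fh.write(f"constant\t{seg.label or '.'}\t{seg.sequence}\t.\t.\t.\t.\t.\n")


def load_scaffold(path_or_buf) -> LibraryScaffold:
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    meta = {"name": "scaffold", "flank_5": "", "flank_3": ""}
    segments = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
            continue
        fields = line.split("\t")
        if fields[0] == "kind":
            continue
        kind, label, sequence, length = fields[0], fields[1], fields[2], fields[3]
        label = "" if label == "." else label
        if kind == "constant":
            segments.append(Segment("constant", sequence=sequence, label=label))
        else:
            freqs = tuple(float(x) for x in fields[4:8])
            segments.append(
                Segment("randomized", length=int(length), base_freqs=freqs, label=label)
            )
    return LibraryScaffold(
        meta["name"], tuple(segments), meta["flank_5"], meta["flank_3"]
    )


def export_backbone_fasta(scaffold: LibraryScaffold, path) -> None:
    """Write the constant backbone (randomized positions as N) as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(scaffold.constant_backbone()), id=scaffold.name, description="")
    seqio_write([rec], str(path), "fasta")


def load_bundled_scaffold(name: str) -> LibraryScaffold:
    """Load one of the scaffold files shipped with the package.

    ``"pGPD-final"`` — the final constitutive library design (312 bp, 83%
    randomized); ``"pZEV-design4"`` — the inducible design with three ZEV
    binding sites (246 bp, 79% randomized).  Constant motifs in these files
    are editable consensus placeholders at the published segment lengths.
    """
    ref = importlib.resources.files("promdesign.data").joinpath(f"{name}.tsv")
    with ref.open() as fh:
        return load_scaffold(fh)
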