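"""Synthetic FACS-seq fixtures with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: each library member has a sequence-determined mean activity
(log10 GFP:mCherry); single cells scatter normally around that mean with a
shared standard deviation sigma; a fraction epsilon of sorted cells land in a
uniformly random bin (contaminants); cells are sorted into 12 equal-width
bins; and sequencing reads carry independent per-base substitution errors.

Ground truth is additive on the log10 activity scale: a baseline, optional
per-position per-base weights, and optional motif bonuses.  The default
ZEV-like truth plants a TA-repeat bonus and a GCTA extension of the ZEV
binding site so that mutagenesis analyses have recoverable signal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scaffold import BASES, LibraryScaffold, _BASE_INDEX, sample_sequence


@dataclass(frozen=True)
class GroundTruthModel:
    """Deterministic additive sequence -> activity map.

    ``position_weights`` has shape (L, 4) (may be None); ``motif_weights``
    is a list of (motif, weight) pairs scored once per (possibly
    overlapping) occurrence; ``pair_weights`` optionally adds pairwise
    (epistatic) terms ((p1, b1, p2, b2), weight) to stress-test models that
    assume additivity.
    """

    baseline: float = 0.0
    position_weights: np.ndarray | None = None
    motif_weights: tuple[tuple[str, float], ...] = ()
    induced_offset: float = 0.0
    pair_weights: tuple[tuple[tuple[int, str, int, str], float], ...] = ()

    def __post_init__(self) -> None:
        if self.position_weights is not None:
            pw = np.asarray(self.position_weights, dtype=float)
            if pw.ndim != 2 or pw.shape[1] != 4:
                raise ValueError("position_weights must have shape (L, 4)")
            object.__setattr__(self, "position_weights", pw)


def true_activity(model: GroundTruthModel, seq: str) -> tuple[float, float]:
    """Return (uninduced, induced) log10 activity for one sequence."""
    score = model.baseline
    if model.position_weights is not None:
        if len(seq) != model.position_weights.shape[0]:
            raise ValueError("sequence length does not match position_weights")
        idx = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=int, count=len(seq))
        score += float(model.position_weights[np.arange(len(seq)), idx].sum())
    for motif, w in model.motif_weights:
        start = 0
        while True:
            hit = seq.find(motif, start)
            if hit < 0:
                break
            score += w
            start = hit + 1
    for (p1, b1, p2, b2), w in model.pair_weights:
        if seq[p1] == b1 and seq[p2] == b2:
            score += w
    return score, score + model.induced_offset


@dataclass(frozen=True)
class SortConfig:
    """FACS sort model: bin layout, cell-level noise and contamination.

    Defaults follow the study structure: 12 equal-width bins spanning
    [-0.6, 0.6] log10 units (resembling the measured constitutive activity
    range), sigma = 0.15, epsilon = 0.01.
    """

    n_bins: int = 12
    bin_edges: np.ndarray | None = None
    sigma_cell: float = 0.15
    epsilon: float = 0.01
    cells_per_sequence: float = 200.0
    out_of_range: str = "clip"  # "clip" -> nearest end bin; "discard"

    def __post_init__(self) -> None:
        edges = self.bin_edges
        if edges is None:
            edges = np.linspace(-0.6, 0.6, self.n_bins + 1)
        edges = np.asarray(edges, dtype=float)
        if edges.ndim != 1 or len(edges) != self.n_bins + 1:
            raise ValueError("bin_edges must have n_bins + 1 entries")
        if not (np.diff(edges) > 0).all():
            raise ValueError("bin_edges must be strictly increasing")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")
        if self.sigma_cell <= 0:
            raise ValueError("sigma_cell must be positive")
        if self.out_of_range not in ("clip", "discard"):
            raise ValueError("out_of_range must be 'clip' or 'discard'")
        object.__setattr__(self, "bin_edges", edges)


@dataclass(frozen=True)
class ReadSimConfig:
    """Sequencing-read model: depth and substitution error."""

    substitution_rate: float = 0.005
    mean_depth: float = 10.0
    id_depth: float = 10.0
    key_length: int = 35

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate < 0.5):
            raise ValueError("substitution_rate must lie in [0, 0.5)")


def simulate_sort(
    activities: np.ndarray, cfg: SortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Simulate sorting cells into bins; returns an (S, n_bins) count matrix.

    Per sequence, the number of cells is Poisson(cells_per_sequence).  Each
    cell is a contaminant (uniform random bin) with probability epsilon and
    otherwise draws activity ~ Normal(mu, sigma); out-of-range cells go to
    the nearest end bin (or are discarded, per config).
    """
    activities = np.asarray(activities, dtype=float)
    counts = np.zeros((len(activities), cfg.n_bins), dtype=int)
    edges = cfg.bin_edges
    for s, mu in enumerate(activities):
        n = rng.poisson(cfg.cells_per_sequence)
        if n == 0:
            continue
        contam = rng.random(n) < cfg.epsilon
        n_c = int(contam.sum())
        if n_c:
            bins_c = rng.integers(0, cfg.n_bins, n_c)
            np.add.at(counts[s], bins_c, 1)
        n_r = n - n_c
        if n_r:
            x = rng.normal(mu, cfg.sigma_cell, n_r)
            b = np.searchsorted(edges, x, side="right") - 1
            if cfg.out_of_range == "clip":
                b = np.clip(b, 0, cfg.n_bins - 1)
            else:
                keep = (b >= 0) & (b < cfg.n_bins)
                b = b[keep]
            np.add.at(counts[s], b, 1)
    return counts


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    chars = list(seq)
    for p in hits:
        alts = [b for b in BASES if b != chars[p]]
        chars[p] = alts[rng.integers(0, 3)]
    return "".join(chars)


def simulate_reads(
    seq: str,
    counts: np.ndarray,
    cfg: ReadSimConfig,
    rng: np.random.Generator,
    cells_per_sequence: float = 200.0,
) -> dict:
    """Simulate bin-tagged counting reads plus full-length identification
    reads for one sequence.

    Counting reads per bin are Poisson(mean_depth * count / cells_per_sequence);
    identification reads are Poisson(id_depth).  Every read is the sequence
    with independent per-base substitutions.
    """
    counting: list[tuple[int, str]] = []
    for b, c in enumerate(np.asarray(counts)):
        n = rng.poisson(cfg.mean_depth * c / cells_per_sequence) if c > 0 else 0
        for _ in range(n):
            counting.append((b, _mutate(seq, cfg.substitution_rate, rng)))
    n_id = rng.poisson(cfg.id_depth)
    identification = [_mutate(seq, cfg.substitution_rate, rng) for _ in range(n_id)]
    return {"counting": counting, "identification": identification}


def make_ground_truth(
    scaffold: LibraryScaffold,
    rng: np.random.Generator,
    target_activity_sd: float = 0.2,
    baseline: float = 0.0,
    induced_offset: float = 0.0,
    ta_repeat_bonus: float = 0.0,
    gcta_extension_bonus: float = 0.0,
) -> GroundTruthModel:
    """Build an additive ground truth for a scaffold.

    Per-base weights are drawn at randomized positions, centred per
    position over the bases the segment can emit (weighted by emission
    frequency), zeroed at constant positions, and rescaled exactly so the
    activity of a random library member has standard deviation
    ``target_activity_sd`` around the baseline — the defaults give an
    activity distribution resembling a measured constitutive library
    (roughly -0.5 to 0.6 log10 units across a large sample).  Optional
    motif bonuses plant a TA-repeat effect (per TATATA occurrence) and a
    GCTA extension effect after the ZEV binding site.
    """
    L = scaffold.total_length
    pw = rng.normal(0.0, 1.0, (L, 4))
    freqs = scaffold.base_freq_matrix().T  # (L, 4)
    pw[freqs == 0.0] = 0.0
    mask = scaffold.randomized_mask()
    pw[~mask] = 0.0
    # centre weights over emittable bases (frequency-weighted) so the
    # expected activity equals the baseline
    for p in np.nonzero(mask)[0]:
        sel = freqs[p] > 0
        pw[p, sel] -= (freqs[p, sel] * pw[p, sel]).sum() / freqs[p, sel].sum()
    # exact variance of the additive part under the sampling distribution
    mean_p = (freqs * pw).sum(axis=1)
    var_p = (freqs * pw**2).sum(axis=1) - mean_p**2
    total_sd = np.sqrt(var_p.sum())
    if total_sd > 0:
        pw *= target_activity_sd / total_sd
    motifs = []
    if ta_repeat_bonus:
        motifs.append(("TATATA", ta_repeat_bonus))
    if gcta_extension_bonus:
        motifs.append(("GCGTGGGCGGCTA", gcta_extension_bonus))
    return GroundTruthModel(
        baseline=baseline,
        position_weights=pw,
        motif_weights=tuple(motifs),
        induced_offset=induced_offset,
    )


def make_fixture(
    scaffold: LibraryScaffold,
    n_sequences: int,
    model: GroundTruthModel,
    sort_cfg: SortConfig,
    read_cfg: ReadSimConfig,
    seed: int,
    out_dir,
) -> dict:
    """Write a complete fixture bundle to ``out_dir``.

    Files: ground_truth.fasta, activities.tsv, cell_counts.tsv, per-bin
    counting-read FASTQ files, identification.fastq, manifest.json.  Given
    the same seed and configs the bundle is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    seqs = [sample_sequence(scaffold, rng) for _ in range(n_sequences)]
    acts = np.array([true_activity(model, s) for s in seqs]).reshape(n_sequences, 2)
    counts = simulate_sort(acts[:, 0], sort_cfg, rng) if n_sequences else np.zeros(
        (0, sort_cfg.n_bins), dtype=int
    )

    fasta = out / "ground_truth.fasta"
    with open(fasta, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">seq{i:05d}\n{s}\n")

    with open(out / "activities.tsv", "w") as fh:
        fh.write("sequence_id\tuninduced\tinduced\n")
        for i in range(n_sequences):
            fh.write(f"seq{i:05d}\t{acts[i, 0]:.6f}\t{acts[i, 1]:.6f}\n")

    cells_per_bin = counts.sum(axis=0)
    with open(out / "cell_counts.tsv", "w") as fh:
        fh.write("bin\ta\tb\tcells_sorted\n")
        for b in range(sort_cfg.n_bins):
            fh.write(
                f"{b}\t{sort_cfg.bin_edges[b]:.6f}\t{sort_cfg.bin_edges[b + 1]:.6f}"
                f"\t{cells_per_bin[b]}\n"
            )

    bin_files = [open(out / f"counting_bin{b:02d}.fastq", "w") for b in range(sort_cfg.n_bins)]
    id_path = out / "identification.fastq"
    try:
        with open(id_path, "w") as idfh:
            for i, s in enumerate(seqs):
                reads = simulate_reads(
                    s, counts[i], read_cfg, rng, sort_cfg.cells_per_sequence
                )
                for j, (b, r) in enumerate(reads["counting"]):
                    bin_files[b].write(
                        f"@seq{i:05d}_bin{b}_r{j}\n{r}\n+\n{'I' * len(r)}\n"
                    )
                for j, r in enumerate(reads["identification"]):
                    idfh.write(f"@seq{i:05d}_id_r{j}\n{r}\n+\n{'I' * len(r)}\n")
    finally:
        for fh in bin_files:
            fh.close()

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    checksums = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest() for name in files
    }
    manifest = {
        "seed": seed,
        "n_sequences": n_sequences,
        "scaffold": scaffold.name,
        "sort": {
            "n_bins": sort_cfg.n_bins,
            "bin_edges": list(map(float, sort_cfg.bin_edges)),
            "sigma_cell": sort_cfg.sigma_cell,
            "epsilon": sort_cfg.epsilon,
            "cells_per_sequence": sort_cfg.cells_per_sequence,
        },
        "reads": {
            "substitution_rate": read_cfg.substitution_rate,
            "mean_depth": read_cfg.mean_depth,
            "id_depth": read_cfg.id_depth,
            "key_length": read_cfg.key_length,
        },
        "checksums": checksums,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


class OracleScorer:
    """Ground-truth model exposed through the scorer protocol.

    Lets the design and mutagenesis stages run against the known
    sequence -> activity map: ``score_seqs`` evaluates the additive truth;
    ``objective_grad`` returns the exact gradient of the position-weight
    (linear) part with respect to a relaxed one-hot input.  Motif bonuses
    are step functions of the sequence and contribute no gradient; use a
    motif-free truth when a fully linear oracle is required.
    """

    def __init__(self, model: GroundTruthModel):
        self.model = model

    def _value(self, seq: str, target: str) -> float:
        unind, ind = true_activity(self.model, seq)
        if target == "induced_activity":
            return ind
        if target == "activation_ratio":
            return ind - unind
        return unind

    def score_seqs(self, seqs, objective) -> np.ndarray:
        return np.array([self._value(s, objective.target) for s in seqs])

    def objective_grad(self, x_seq: np.ndarray, objective) -> tuple[float, np.ndarray]:
        if objective.target == "activation_ratio":
            # additive truth: induced - uninduced is the constant offset
            return self.model.induced_offset, np.zeros_like(x_seq)
        pw = self.model.position_weights
        grad = pw.T.copy() if pw is not None else np.zeros_like(x_seq)
        value = self.model.baseline + float((grad * x_seq).sum())
        if objective.target == "induced_activity":
            value += self.model.induced_offset
        return value, grad


def demo_scaffold(inducible: bool = False) -> LibraryScaffold:
    """Compact scaffolds for demonstrations and desk-scale experiments.

    Structurally faithful miniatures of the bundled library designs —
    constant motifs separating randomized spacers with the same composition
    rules (T-rich core, G excluded after the TSS) — at roughly a third of
    the full length so that model training runs quickly.  The inducible
    variant carries two ZEV binding sites and a 5' spacer long enough for
    TA-repeat analyses.
    """
    from .scaffold import Segment

    U = (0.25, 0.25, 0.25, 0.25)
    CORE = (0.30, 0.12, 0.12, 0.46)
    NOG = (0.35, 0.25, 0.0, 0.40)
    if inducible:
        segments = (
            Segment("randomized", length=24, base_freqs=U, label="spacer5p"),
            Segment("constant", sequence="GCGTGGGCG", label="ZEV_1"),
            Segment("randomized", length=14, base_freqs=U, label="internal1"),
            Segment("constant", sequence="GCGTGGGCG", label="ZEV_2"),
            Segment("randomized", length=10, base_freqs=U, label="spacer_tata"),
            Segment("constant", sequence="TATATAAA", label="TATA"),
            Segment("randomized", length=12, base_freqs=CORE, label="core"),
            Segment("constant", sequence="ACAT", label="TSS"),
            Segment("randomized", length=10, base_freqs=NOG, label="utr"),
        )
        name = "demo-inducible"
    else:
        segments = (
            Segment("randomized", length=30, base_freqs=U, label="spacer_up"),
            Segment("constant", sequence="CACCCATACA", label="RAP1"),
            Segment("randomized", length=16, base_freqs=U, label="spacer_tata"),
            Segment("constant", sequence="TATATAAA", label="TATA"),
            Segment("randomized", length=12, base_freqs=CORE, label="core"),
            Segment("constant", sequence="ACAT", label="TSS"),
            Segment("randomized", length=10, base_freqs=NOG, label="utr"),
        )
        name = "demo-constitutive"
    flank_5 = "TAATATCGAATCGGGGTATACTCTATACGAACAAGCCTCAAATACGGCAC"
    flank_3 = "GACAACATCTCTTAACAGTTAACGCGCTGAAGCAAGCTAAGTCAAGCCAT"
    return LibraryScaffold(name, segments, flank_5, flank_3)
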