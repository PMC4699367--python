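"""Transcript and intron sequence features associated with kinetics.

Folding energies per nucleotide (whole intron, 5'ss-to-branch-point,
fixed windows), position-weight-matrix splice-site scores, lengths and
k-mer composition.

The default folding backend is a documented dynamic-programming proxy: a
Nussinov-style minimum-"energy" fold over nested base pairs with
nearest-neighbor stacking bonuses.  It is deliberately *not* claimed to be
thermodynamically equivalent to a full nearest-neighbor model; external
backends (e.g. ViennaRNA, available as ``backend="vienna"`` when its
bindings are importable, or any callable) can be plugged in wherever a
folding energy is consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel

__all__ = [
    "FeatureVector",
    "per_base_energy",
    "fold_energy",
    "nussinov_energy",
    "build_pwm",
    "site_score",
    "kmer_frequencies",
    "extract_intron_features",
    "feature_table",
    "PAIR_ENERGY",
    "STACK_BONUS",
    "MIN_LOOP",
]

# proxy scoring: energy per closing pair (kcal/mol-like scale) plus a bonus
# when a pair stacks directly on another pair; hairpin loops keep >= 3
# unpaired bases.
PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
STACK_BONUS = -1.0
MIN_LOOP = 3

WINDOW_HALF = 15  # +/-15 nt windows around transcript start/stop and the 3'ss

_RNA = set("ACGU")


@dataclass
class FeatureVector:
    """Per-transcript/intron features used in kinetic association analyses.

    Energies are in the proxy's kcal/mol-like units, always <= 0;
    ``score_*`` are PWM log-odds scores in bits; ``kmer_freq`` maps k-mer ->
    fraction for k = 1..3 (fractions sum to 1 within each k).
    """

    transcript_id: str
    dg_per_nt_intron: float
    dg_per_nt_5ss_to_bp: float
    dg_window_start: float
    dg_window_stop: float
    dg_window_3ss: float
    intron_length: int
    exon2_length: int
    transcript_length: int
    score_5ss: float
    score_3ss: float
    score_bp: float
    kmer_freq: dict[str, float] = field(default_factory=dict)
    flags: str = ""

    def to_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items() if k != "kmer_freq"}
        row.update(self.kmer_freq)
        return row


# --------------------------------------------------------------------------
# folding
# --------------------------------------------------------------------------

def _check_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = [i for i, b in enumerate(seq) if b not in _RNA]
    if bad:
        raise ValueError(f"non-ACGU characters at positions {bad[:10]}")
    return seq


def nussinov_energy(seq: str) -> float:
    """Minimum proxy folding energy over nested secondary structures.

    Interval DP: ``V[i][j]`` is the best energy with (i, j) paired
    (pair energy + best inner arrangement, with a stacking bonus when the
    inner pair (i+1, j-1) is also formed); ``W[i][j]`` is the best energy
    of the subsequence.  Hairpin loops keep at least MIN_LOOP unpaired
    bases.  Returns 0 for unpairable sequences.
    """
    seq = _check_rna(seq)
    n = len(seq)
    if n < MIN_LOOP + 2:
        return 0.0
    INF = float("inf")
    V = [[INF] * n for _ in range(n)]
    W = [[0.0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pe = PAIR_ENERGY.get((seq[i], seq[j]))
            if pe is not None:
                best_inner = W[i + 1][j - 1]
                if V[i + 1][j - 1] < INF:
                    best_inner = min(best_inner, V[i + 1][j - 1] + STACK_BONUS)
                V[i][j] = pe + best_inner
            w = W[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if V[i][k] < INF:
                    rest = W[k + 1][j] if k + 1 <= j else 0.0
                    w = min(w, V[i][k] + rest)
            W[i][j] = w
    return min(0.0, W[0][n - 1])


def _vienna_energy(seq: str) -> float:
    import RNA  # ViennaRNA python bindings; optional backend

    _, mfe = RNA.fold(_check_rna(seq))
    return float(min(0.0, mfe))


def fold_energy(seq: str, backend="proxy") -> float:
    """Minimum folding free energy of ``seq`` under the chosen backend.

    ``backend`` is ``"proxy"`` (default, the built-in DP), ``"vienna"``
    (requires the ViennaRNA python bindings) or any callable
    ``seq -> energy``.
    """
    if callable(backend):
        return float(backend(_check_rna(seq)))
    if backend == "proxy":
        return nussinov_energy(seq)
    if backend == "vienna":
        return _vienna_energy(seq)
    raise ValueError(f"unknown folding backend {backend!r}")


def per_base_energy(dg_total: float, n_bases: int) -> float:
    """Folding energy divided by the number of bases (dG per nt, <= 0)."""
    if n_bases <= 0:
        raise ValueError("n_bases must be positive")
    if dg_total > 0:
        raise ValueError("dg_total must be <= 0")
    return dg_total / n_bases


# --------------------------------------------------------------------------
# PWM scoring
# --------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def build_pwm(windows: list[str], pseudocount: float = 0.5) -> np.ndarray:
    """Position frequency matrix (width x 4, A/C/G/U) from aligned windows."""
    if not windows:
        raise ValueError("at least one window required")
    width = len(windows[0])
    counts = np.full((width, 4), pseudocount, dtype=float)
    for w in windows:
        w = _check_rna(w)
        if len(w) != width:
            raise ValueError("all windows must share one width")
        for pos, b in enumerate(w):
            counts[pos, _BASE_INDEX[b]] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


def site_score(seq_window: str, pwm: np.ndarray) -> float:
    """Log-odds score in bits: sum of log2(f_base / 0.25) over positions."""
    seq_window = _check_rna(seq_window)
    if len(seq_window) != pwm.shape[0]:
        raise ValueError(
            f"window length {len(seq_window)} != PWM width {pwm.shape[0]}"
        )
    return float(
        sum(
            math.log2(pwm[pos, _BASE_INDEX[b]] / 0.25)
            for pos, b in enumerate(seq_window)
        )
    )


# --------------------------------------------------------------------------
# k-mers
# --------------------------------------------------------------------------

def kmer_frequencies(seq: str, k: int) -> dict[str, float]:
    """Overlapping k-mer fractions, normalized by (len - k + 1)."""
    seq = _check_rna(seq)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    n = len(seq) - k + 1
    counts: dict[str, int] = {}
    for i in range(n):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return {kmer: c / n for kmer, c in sorted(counts.items())}


# --------------------------------------------------------------------------
# feature extraction
# --------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return _check_rna(seq).translate(_COMPLEMENT)[::-1]


def transcript_sequences(model: TranscriptModel, genome: dict[str, str]):
    """(precursor, intron, exon2) sequences in transcription orientation.

    Genome sequences are given 5'->3' on the plus strand; minus-strand
    genes are reverse-complemented before any windowing, so feature
    extraction is strand-symmetric.
    """
    chrom_seq = _check_rna(genome[model.chrom])
    pre = chrom_seq[model.start : model.end]
    if model.strand == "-":
        pre = reverse_complement(pre)
    e1 = model.exon1_length
    il = model.intron_length
    intron = pre[e1 : e1 + il] if il else ""
    exon2 = pre[e1 + il :] if il else ""
    return pre, intron, exon2


def _window(seq: str, center: int, half: int = WINDOW_HALF):
    """Sequence window of +/-``half`` nt around ``center``; flags truncation."""
    lo = max(0, center - half)
    hi = min(len(seq), center + half + 1)
    truncated = (lo != center - half) or (hi != center + half + 1)
    return seq[lo:hi], truncated


def extract_intron_features(
    model: TranscriptModel,
    genome: dict[str, str],
    bp_position: int,
    pwms: dict[str, np.ndarray] | None = None,
    backend="proxy",
    kmax: int = 3,
) -> FeatureVector:
    """Populate the full feature vector for a single-intron gene.

    ``bp_position`` is the 1-based intron position of the branch-point
    adenosine; the 5'ss-to-BP region is intron positions 1..bp inclusive.
    ``pwms`` maps "5ss"/"3ss"/"bp" to frequency matrices built from the
    annotation set (scores are NaN when absent).  Windows at the transcript
    start/stop shorter than 2*15+1 nt are truncated and flagged.
    """
    if not model.has_intron:
        raise ValueError(f"{model.gene_id}: no intron")
    pre, intron, _exon2 = transcript_sequences(model, genome)
    if not (1 <= bp_position <= len(intron)):
        raise ValueError(
            f"{model.gene_id}: BP position {bp_position} outside intron "
            f"of length {len(intron)}"
        )
    flags = []
    dg_intron = fold_energy(intron, backend)
    region_5ss_bp = intron[:bp_position]
    dg_5bp = fold_energy(region_5ss_bp, backend)
    w_start, trunc1 = _window(pre, 0)
    w_stop, trunc2 = _window(pre, len(pre) - 1)
    if trunc1 or trunc2:
        flags.append("window-truncated")
    intron_start_in_pre = model.exon1_length
    w_3ss, _ = _window(pre, intron_start_in_pre + len(intron) - 1)
    scores = {"5ss": math.nan, "3ss": math.nan, "bp": math.nan}
    if pwms:
        sites = {
            "5ss": intron[: pwms["5ss"].shape[0]] if "5ss" in pwms else None,
            "3ss": intron[-pwms["3ss"].shape[0] :] if "3ss" in pwms else None,
            "bp": (
                _bp_window(intron, bp_position, pwms["bp"].shape[0])
                if "bp" in pwms
                else None
            ),
        }
        for name, site in sites.items():
            if site is not None and len(site) == pwms[name].shape[0]:
                scores[name] = site_score(site, pwms[name])
    kmers: dict[str, float] = {}
    for k in range(1, kmax + 1):
        if len(intron) >= k:
            kmers.update(
                {f"k{k}_{m}": f for m, f in kmer_frequencies(intron, k).items()}
            )
    return FeatureVector(
        transcript_id=model.gene_id,
        dg_per_nt_intron=per_base_energy(dg_intron, len(intron)),
        dg_per_nt_5ss_to_bp=per_base_energy(dg_5bp, len(region_5ss_bp)),
        dg_window_start=fold_energy(w_start, backend),
        dg_window_stop=fold_energy(w_stop, backend),
        dg_window_3ss=fold_energy(w_3ss, backend),
        intron_length=len(intron),
        exon2_length=model.exon2_length,
        transcript_length=model.mature_length,
        score_5ss=scores["5ss"],
        score_3ss=scores["3ss"],
        score_bp=scores["bp"],
        kmer_freq=kmers,
        flags=";".join(flags),
    )


def _bp_window(intron: str, bp_position: int, width: int) -> str | None:
    """Branch-point window ending on the BP adenosine (1-based position)."""
    start = bp_position - width
    if start < 0:
        return None
    return intron[start:bp_position]


def feature_table(
    models: list[TranscriptModel],
    genome: dict[str, str],
    bp_positions: dict[str, int],
    pwms: dict[str, np.ndarray] | None = None,
    backend="proxy",
) -> pd.DataFrame:
    """Feature vectors for every intron-containing model, as a DataFrame."""
    rows = []
    for m in models:
        if not m.has_intron or m.gene_id not in bp_positions:
            continue
        fv = extract_intron_features(
            m, genome, bp_positions[m.gene_id], pwms=pwms, backend=backend
        )
        rows.append(fv.to_row())
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("transcript_id")
    return df
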