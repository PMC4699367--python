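"""Synthetic 4tU-style labeling time courses with known ground truth.

This module generates everything the downstream stages consume — gene
annotations, labeled precursor/mature abundances from explicit kinetic
models, aligned fragments, intron sequences and feature tables — so the
whole pipeline is testable without external sequencing data.

The kinetic model is a linear chain: synthesis at constant rate ``k_syn``
feeds a precursor pool that matures with rate ``k_splice`` (optionally
through an Erlang chain of ``n_maturation_steps`` sub-steps preserving the
mean maturation time), and the mature species decays at ``k_decay``.  The
label is added at t = 0 and incorporation begins after ``label_offset``
minutes (default 0.5 min, i.e. ~30 s), so labeled material starts from
zero.  For a single maturation step the solution is the classic
two-compartment closed form; for longer chains the exact matrix-exponential
solution of the affine linear system is used.

All randomness flows from one integer seed through ``numpy.random.default_rng``;
no global state is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .io_formats import ReadRecord, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "KineticParams",
    "SimTruth",
    "IntronSequence",
    "DEFAULT_TIMES",
    "generate_annotation",
    "sample_kinetic_params",
    "simulate_labeled_abundances",
    "labeled_abundance",
    "steady_state",
    "labeled_fpkm_trajectory",
    "simulate_reads",
    "reads_from_table",
    "simulate_intron_sequences",
    "generate_feature_table",
    "DEFAULT_CLASS_SEPARATION",
]

#: nascent labeling times (minutes) of the experimental design this
#: simulator emulates; steady state is handled as the t -> inf limit.
DEFAULT_TIMES = (1.5, 2.5, 5.0)


@dataclass(frozen=True)
class KineticParams:
    """Per-gene kinetic parameters.

    k_syn : synthesis rate, molecules/min
    k_splice : maturation (splicing or processing) rate, 1/min; for an
        Erlang chain this is 1/mean-maturation-time
    k_decay : mature-species decay rate, 1/min
    n_maturation_steps : Erlang chain length (1 = first-order maturation)
    label_offset : minutes before label incorporation begins
    """

    k_syn: float
    k_splice: float
    k_decay: float
    n_maturation_steps: int = 1
    label_offset: float = 0.5

    def __post_init__(self) -> None:
        if self.k_syn <= 0 or self.k_splice <= 0 or self.k_decay <= 0:
            raise ValueError("all rates must be positive")
        if self.n_maturation_steps < 1:
            raise ValueError("n_maturation_steps must be >= 1")
        if self.label_offset < 0:
            raise ValueError("label_offset must be >= 0")


@dataclass
class SimTruth:
    """Ground-truth labeled abundances for a set of genes.

    ``P``/``M``/``R`` are (n_genes, n_times) arrays of precursor abundance,
    mature abundance and splicing ratio M/(M+P); ``*_ss`` are the t -> inf
    limits.  ``R`` is 0 where P + M = 0 (before any label incorporation).
    """

    gene_ids: list[str]
    times: np.ndarray
    P: np.ndarray
    M: np.ndarray
    R: np.ndarray
    P_ss: np.ndarray
    M_ss: np.ndarray
    R_ss: np.ndarray
    params: list[KineticParams]
    background_fraction: float = 0.0


# --------------------------------------------------------------------------
# kinetic model
# --------------------------------------------------------------------------

def labeled_abundance(params: KineticParams, t: float) -> tuple[float, float]:
    """Labeled (precursor, mature) abundance at time ``t`` minutes.

    Exact solution of the linear chain starting from zero labeled material.
    """
    tp = max(0.0, t - params.label_offset)
    if tp == 0.0:
        return 0.0, 0.0
    ksyn, ks, kd = params.k_syn, params.k_splice, params.k_decay
    n = params.n_maturation_steps
    if n == 1:
        P = (ksyn / ks) * (1.0 - np.exp(-ks * tp))
        if abs(ks - kd) < 1e-10 * max(ks, kd):
            k = ks
            M = (ksyn / k) * (1.0 - np.exp(-k * tp)) - ksyn * tp * np.exp(-k * tp)
        else:
            M = (
                ksyn / kd
                - (ksyn / (kd - ks)) * np.exp(-ks * tp)
                + (ksyn * ks / (kd * (kd - ks))) * np.exp(-kd * tp)
            )
        return float(P), float(M)
    # Erlang chain: n precursor stages at rate n*k_splice each, then decay.
    # Affine system dx/dt = A x + b solved exactly via the augmented matrix
    # exponential; P is the sum over chain stages.
    r = n * ks
    dim = n + 1
    A = np.zeros((dim + 1, dim + 1))
    for i in range(n):
        A[i, i] = -r
        if i > 0:
            A[i, i - 1] = r
    A[n, n - 1] = r
    A[n, n] = -kd
    A[0, dim] = ksyn  # constant input into the first stage
    x = expm(A * tp)[:, dim]  # state from zero initial condition
    return float(np.sum(x[:n])), float(x[n])


def steady_state(params: KineticParams) -> tuple[float, float]:
    """t -> inf labeled (precursor, mature) abundances.

    Total chain occupancy is k_syn/k_splice regardless of chain length.
    """
    return params.k_syn / params.k_splice, params.k_syn / params.k_decay


def simulate_labeled_abundances(
    params: KineticParams | list[KineticParams],
    times,
    gene_ids: list[str] | None = None,
    background_fraction: float = 0.0,
) -> SimTruth:
    """Evaluate the kinetic model on a sorted grid of labeling times."""
    plist = [params] if isinstance(params, KineticParams) else list(params)
    t = np.asarray(list(times), dtype=float)
    if t.size == 0 or np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(1, len(plist) + 1)]
    P = np.zeros((len(plist), t.size))
    M = np.zeros_like(P)
    for gi, p in enumerate(plist):
        for ti, tv in enumerate(t):
            P[gi, ti], M[gi, ti] = labeled_abundance(p, tv)
    total = P + M
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(total > 0, M / np.where(total > 0, total, 1.0), 0.0)
    ss = np.array([steady_state(p) for p in plist])
    P_ss, M_ss = ss[:, 0], ss[:, 1]
    R_ss = M_ss / (M_ss + P_ss)
    return SimTruth(
        gene_ids=list(gene_ids),
        times=t,
        P=P,
        M=M,
        R=R,
        P_ss=P_ss,
        M_ss=M_ss,
        R_ss=R_ss,
        params=plist,
        background_fraction=background_fraction,
    )


def labeled_fpkm_trajectory(truth: SimTruth, lengths=None) -> pd.DataFrame:
    """Per-sample-normalized labeled abundance relative to steady state.

    Emulates FPKM-style normalization: within each time point (and at
    steady state) each gene's labeled abundance is divided by the sample
    total, and the normalized nascent value is expressed relative to the
    normalized steady-state value.  This is the scale on which unstable
    transcripts sit *above* their steady-state level at short labeling
    times and on which delayed-maturation species plateau.
    """
    total_t = truth.P + truth.M  # (genes, times)
    total_ss = truth.P_ss + truth.M_ss
    if lengths is not None:
        L = np.asarray(lengths, dtype=float)[:, None]
        total_t = total_t / L
        total_ss = total_ss / L[:, 0]
    norm_t = total_t / total_t.sum(axis=0, keepdims=True)
    norm_ss = total_ss / total_ss.sum()
    ratio = norm_t / norm_ss[:, None]
    return pd.DataFrame(ratio, index=truth.gene_ids, columns=list(truth.times))


# --------------------------------------------------------------------------
# annotation generation
# --------------------------------------------------------------------------

INTRONIC_CLASSES = ("RP-intronic", "non-RP-intronic")

# (median length, lognormal sigma) per region; single-exon classes carry one
# entry.  SUT median length exceeds CUT median length, mirroring yeast
# lncRNA length distributions.
DEFAULT_LENGTH_PARAMS: dict[str, dict] = {
    "RP-intronic": {"exon1": (150, 0.3), "intron": (400, 0.25), "exon2": (600, 0.3)},
    "non-RP-intronic": {"exon1": (120, 0.3), "intron": (150, 0.4), "exon2": (450, 0.3)},
    "CUT": {"length": (300, 0.4)},
    "SUT": {"length": (550, 0.4)},
    "XUT": {"length": (600, 0.4)},
    "snoRNA": {"length": (120, 0.2)},
    "other": {"length": (1000, 0.4)},
}

_MIN_REGION = 60  # floor on sampled region lengths, nt


def generate_annotation(
    n_genes: int,
    class_mix: dict[str, float],
    length_params: dict[str, dict] | None = None,
    seed: int = 0,
    chrom: str = "chrI",
    gap: int = 100,
) -> list[TranscriptModel]:
    """Sample a non-overlapping gene annotation with class labels.

    Intron-containing classes get exactly one intron; all other classes are
    single-exon.  Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    props = np.array(list(class_mix.values()), dtype=float)
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("class_mix proportions must be nonnegative and sum to 1")
    lp = dict(DEFAULT_LENGTH_PARAMS)
    if length_params:
        lp.update(length_params)
    rng = np.random.default_rng(seed)
    classes = list(class_mix)
    draws = rng.choice(len(classes), size=n_genes, p=props)
    models = []
    pos = gap
    for i, ci in enumerate(draws):
        cls = classes[ci]
        strand = "+" if rng.random() < 0.5 else "-"
        spec = lp.get(cls, {"length": (500, 0.4)})
        if cls in INTRONIC_CLASSES:
            e1 = _sample_len(rng, *spec["exon1"])
            iv = _sample_len(rng, *spec["intron"])
            e2 = _sample_len(rng, *spec["exon2"])
            exons = [(pos, pos + e1), (pos + e1 + iv, pos + e1 + iv + e2)]
            end = pos + e1 + iv + e2
        else:
            L = _sample_len(rng, *spec["length"])
            exons = [(pos, pos + L)]
            end = pos + L
        models.append(
            TranscriptModel(
                gene_id=f"g{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                tx_class=cls,
            )
        )
        pos = end + gap
    return models


def _sample_len(rng, median, sigma):
    return max(_MIN_REGION, int(round(median * np.exp(rng.normal(0.0, sigma)))))


# Per-class kinetic regimes.  Intron-containing mRNAs mature (splice) fast
# and decay slowly; CUT-like species show delayed multi-step maturation
# followed by rapid decay (hence low steady-state levels but a flat, high
# nascent plateau); SUTs sit in between; stable classes turn over slowly.
# Values are (k_syn, k_splice, k_decay, n_steps) medians with lognormal
# spread sigma on the rates.
DEFAULT_CLASS_KINETICS: dict[str, tuple[float, float, float, int]] = {
    "RP-intronic": (50.0, 1.5, 0.15, 1),
    "non-RP-intronic": (20.0, 0.8, 0.2, 1),
    "CUT": (5.0, 0.2, 2.0, 4),
    "SUT": (5.0, 0.25, 0.6, 3),
    "XUT": (5.0, 0.3, 0.8, 3),
    "snoRNA": (30.0, 1.0, 0.05, 1),
    "other": (15.0, 1.0, 0.1, 1),
}


def sample_kinetic_params(
    models: list[TranscriptModel],
    seed: int = 0,
    class_kinetics: dict | None = None,
    sigma: float = 0.4,
    label_offset: float = 0.5,
) -> list[KineticParams]:
    """Draw per-gene kinetic parameters from per-class lognormal regimes."""
    ck = dict(DEFAULT_CLASS_KINETICS)
    if class_kinetics:
        ck.update(class_kinetics)
    rng = np.random.default_rng(seed)
    out = []
    for m in models:
        ksyn, ks, kd, nst = ck.get(m.tx_class, ck["other"])
        out.append(
            KineticParams(
                k_syn=ksyn * np.exp(rng.normal(0.0, sigma)),
                k_splice=ks * np.exp(rng.normal(0.0, sigma)),
                k_decay=kd * np.exp(rng.normal(0.0, sigma)),
                n_maturation_steps=nst,
                label_offset=label_offset,
            )
        )
    return out


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

READ_TABLE_COLUMNS = [
    "read_id",
    "gene_id",
    "block_starts",
    "block_ends",
    "category",
    "isoform",
    "origin",
]


def simulate_reads(
    truth: SimTruth,
    models: list[TranscriptModel],
    read_len: int = 30,
    frag_len_mean: float = 50.0,
    frag_len_sd: float = 10.0,
    n_fragments: int = 10000,
    background_fraction: float = 0.0,
    seed: int = 0,
    time_index: int = 0,
    min_anchor: int = 5,
) -> pd.DataFrame:
    """Simulate aligned fragments for one labeled sample.

    Fragments are drawn from (gene, isoform) pairs with probability
    proportional to abundance x effective length, with a uniform start over
    valid positions and a truncated-normal fragment length (lower-truncated
    at ``read_len``).  ``time_index`` selects the time point from ``truth``;
    pass ``time_index="ss"`` for a steady-state sample.  A fraction
    ``background_fraction`` of fragments is drawn from the steady-state
    (mostly mature) composition instead, emulating unlabeled RNA carried
    through the purification.  The whole fragment is reported as covered;
    isoforms shorter than the drawn fragment are skipped with a warning at
    weighting time.

    Returns the internal read table (one row per fragment) with a category
    column (junction / b5 / b3 / intron / exon1 / exon2).
    """
    if not (0.0 <= background_fraction < 1.0):
        raise ValueError("background_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_id = {m.gene_id: m for m in models}
    order = [g for g in truth.gene_ids if g in by_id]

    def _abundances(ti):
        if ti == "ss":
            return truth.P_ss, truth.M_ss
        return truth.P[:, ti], truth.M[:, ti]

    mean_frag = max(float(read_len), float(frag_len_mean))
    sig_weights, sig_pairs = _isoform_weights(
        order, truth.gene_ids, by_id, *_abundances(time_index), mean_frag
    )
    sig_pairs = [(g, iso, "signal") for g, iso in sig_pairs]
    bg_weights, bg_pairs = _isoform_weights(
        order, truth.gene_ids, by_id, truth.P_ss, truth.M_ss, mean_frag
    )
    bg_pairs = [(g, iso, "background") for g, iso in bg_pairs]
    rows = []
    n_bg = rng.binomial(n_fragments, background_fraction)
    choices = np.concatenate(
        [
            rng.choice(len(sig_pairs), size=n_fragments - n_bg, p=sig_weights),
            (
                rng.choice(len(bg_pairs), size=n_bg, p=bg_weights) + len(sig_pairs)
                if n_bg
                else np.empty(0, dtype=int)
            ),
        ]
    )
    all_pairs = sig_pairs + bg_pairs
    for i, ci in enumerate(choices):
        gene_id, isoform, origin = all_pairs[ci]
        m = by_id[gene_id]
        iso_len = m.mature_length if isoform == "mature" else m.precursor_length
        frag = int(round(rng.normal(frag_len_mean, frag_len_sd)))
        frag = int(np.clip(frag, read_len, iso_len))
        start = int(rng.integers(0, iso_len - frag + 1))
        blocks = _fragment_blocks(m, isoform, start, frag)
        rows.append(
            {
                "read_id": f"r{i:06d}",
                "gene_id": gene_id,
                "block_starts": ",".join(str(s) for s, _ in blocks),
                "block_ends": ",".join(str(e) for _, e in blocks),
                "category": _categorize(blocks, m, min_anchor),
                "isoform": isoform,
                "origin": origin,
            }
        )
    return pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)


def _isoform_weights(order, gene_ids, by_id, P, M, mean_frag):
    idx = {g: i for i, g in enumerate(gene_ids)}
    weights, pairs = [], []
    skipped = []
    for g in order:
        m = by_id[g]
        if m.has_intron:
            species = (
                ("precursor", P[idx[g]], m.precursor_length),
                ("mature", M[idx[g]], m.mature_length),
            )
        else:
            # single-exon genes: one species carrying the total labeled pool
            species = (("mature", P[idx[g]] + M[idx[g]], m.mature_length),)
        for isoform, abundance, iso_len in species:
            eff = iso_len - mean_frag + 1
            if eff < 1:
                if abundance > 0:
                    skipped.append((g, isoform))
                continue
            if abundance > 0:
                weights.append(abundance * eff)
                pairs.append((g, isoform))
    if skipped:
        logger.warning(
            "skipped %d isoforms shorter than the mean fragment: %s",
            len(skipped),
            skipped[:5],
        )
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or w.sum() <= 0:
        raise ValueError("no isoform has positive abundance and sufficient length")
    return w / w.sum(), pairs


def _fragment_blocks(m: TranscriptModel, isoform: str, start: int, frag: int):
    if isoform == "precursor" or not m.has_intron:
        s = m.start + start
        return [(s, s + frag)]
    (e1s, e1e), (e2s, e2e) = m.exons
    len1 = e1e - e1s
    end = start + frag
    if end <= len1:  # wholly in genomic-first exon
        return [(e1s + start, e1s + end)]
    if start >= len1:  # wholly in genomic-second exon
        return [(e2s + start - len1, e2s + end - len1)]
    return [(e1s + start, e1e), (e2s, e2s + end - len1)]


def _categorize(blocks, m: TranscriptModel, min_anchor: int) -> str:
    iv = m.intron
    if iv is None:
        return "exon1"
    left, right = iv
    if len(blocks) == 2 and (blocks[0][1], blocks[1][0]) == iv:
        return "junction"
    b_left, b_right = ("b5", "b3") if m.strand == "+" else ("b3", "b5")
    for s, e in blocks:
        if s <= left - min_anchor and e >= left + min_anchor:
            return b_left
        if s <= right - min_anchor and e >= right + min_anchor:
            return b_right
    if any(max(0, min(e, right) - max(s, left)) for s, e in blocks):
        return "intron"
    first_exon = m.exons_tx_order[0]
    s, e = blocks[0]
    if max(0, min(e, first_exon[1]) - max(s, first_exon[0])):
        return "exon1"
    return "exon2"


def reads_from_table(table: pd.DataFrame) -> dict[str, list[ReadRecord]]:
    """Convert a simulated read table into per-gene ReadRecord lists."""
    by_gene: dict[str, list[ReadRecord]] = {}
    for row in table.itertuples(index=False):
        starts = [int(x) for x in str(row.block_starts).split(",")]
        ends = [int(x) for x in str(row.block_ends).split(",")]
        rec = ReadRecord(row.read_id, row.gene_id, list(zip(starts, ends)))
        by_gene.setdefault(row.gene_id, []).append(rec)
    return by_gene


# --------------------------------------------------------------------------
# intron sequences
# --------------------------------------------------------------------------

FIVE_SS_MOTIF = "GUAUGU"
BP_MOTIF = "UACUAAC"  # branch-point adenosine is the penultimate base
THREE_SS_MOTIF = "UAG"
_BP_TO_3SS_SPACER = 23  # preferred nt between BP motif end and the 3'ss YAG
_MIN_INTRON = 30  # enough for the three motifs plus a short BP-3'ss spacer


@dataclass
class IntronSequence:
    """A synthetic intron (RNA alphabet) with annotated signals.

    ``bp_pos`` is the 1-based intron position of the branch-point adenosine.
    """

    seq: str
    bp_pos: int
    five_ss: tuple[int, int] = (0, 6)

    @property
    def length(self) -> int:
        return len(self.seq)


def simulate_intron_sequences(
    n: int, au_bias: float, length: int, seed: int = 0, a_fraction: float = 0.5
) -> list[IntronSequence]:
    """Generate introns with consensus-like splicing signals.

    Non-motif positions are i.i.d. with the A+U probability adjusted so the
    *whole-sequence* A+U fraction matches ``au_bias`` in expectation
    (the fixed motifs are themselves A/U-rich).  ``a_fraction`` sets the
    share of the A+U mass given to adenosine; varying it at fixed
    ``au_bias`` reproduces the compositional regime in which A and U
    frequencies are strongly anticorrelated across introns.
    """
    if not (0.0 < au_bias < 1.0):
        raise ValueError("au_bias must be in (0, 1)")
    if not (0.0 <= a_fraction <= 1.0):
        raise ValueError("a_fraction must be in [0, 1]")
    if length < _MIN_INTRON:
        raise ValueError(f"length must be >= {_MIN_INTRON} to fit splicing motifs")
    rng = np.random.default_rng(seed)
    # shrink the BP-3'ss spacer on short introns so the motifs always fit
    spacer = min(
        _BP_TO_3SS_SPACER,
        length - len(FIVE_SS_MOTIF) - 1 - len(BP_MOTIF) - len(THREE_SS_MOTIF),
    )
    bp_motif_start = length - len(THREE_SS_MOTIF) - spacer - len(BP_MOTIF)
    motif_positions = (
        set(range(len(FIVE_SS_MOTIF)))
        | set(range(bp_motif_start, bp_motif_start + len(BP_MOTIF)))
        | set(range(length - len(THREE_SS_MOTIF), length))
    )
    motif_au = sum(
        1 for b in FIVE_SS_MOTIF + BP_MOTIF + THREE_SS_MOTIF if b in "AU"
    )
    n_free = length - len(motif_positions)
    p_au = np.clip((length * au_bias - motif_au) / max(n_free, 1), 0.02, 0.98)
    probs = np.array(
        [
            p_au * a_fraction,
            p_au * (1.0 - a_fraction),
            (1 - p_au) / 2,
            (1 - p_au) / 2,
        ]
    )
    alphabet = np.array(list("AUGC"))
    out = []
    for _ in range(n):
        seq = np.empty(length, dtype="<U1")
        seq[: len(FIVE_SS_MOTIF)] = list(FIVE_SS_MOTIF)
        seq[bp_motif_start : bp_motif_start + len(BP_MOTIF)] = list(BP_MOTIF)
        seq[length - len(THREE_SS_MOTIF) :] = list(THREE_SS_MOTIF)
        free = sorted(set(range(length)) - motif_positions)
        seq[free] = rng.choice(alphabet, size=len(free), p=probs)
        out.append(
            IntronSequence(seq="".join(seq), bp_pos=bp_motif_start + len(BP_MOTIF) - 1)
        )
    return out


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

#: class separation (in within-class SD units, applied to two informative
#: features) at which a Gaussian naive Bayes 10-fold AUC lands near 0.7,
#: the regime observed for CUT/SUT stability classification.
DEFAULT_CLASS_SEPARATION = 0.52


def generate_feature_table(
    n: int,
    class_separation: float = DEFAULT_CLASS_SEPARATION,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled feature vectors for fast- vs slow-degrading transcripts.

    Two informative features (folding energy per nucleotide and log10
    length) are shifted between classes by ``class_separation`` SD units;
    two window-energy features carry no signal.  ``label`` is 1 for the
    fast-degrading class.  Fast degraders are *less* structured (less
    negative dG/nt) and shorter, matching the direction of the association
    between stability, length and structure.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    n_fast = n // 2
    labels = np.array([1] * n_fast + [0] * (n - n_fast))
    d = float(class_separation)
    dg_per_nt = rng.normal(-0.25, 0.05, size=n) + labels * d * 0.05
    log10_len = rng.normal(2.6, 0.2, size=n) - labels * d * 0.2
    dg_start = rng.normal(-3.0, 1.0, size=n)
    dg_stop = rng.normal(-3.0, 1.0, size=n)
    df = pd.DataFrame(
        {
            "transcript_id": [f"t{i:05d}" for i in range(n)],
            "label": labels,
            "dg_per_nt": np.minimum(dg_per_nt, 0.0),
            "log10_length": log10_len,
            "dg_start_window": np.minimum(dg_start, 0.0),
            "dg_stop_window": np.minimum(dg_stop, 0.0),
        }
    )
    return df
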