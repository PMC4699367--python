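"""Kinetic statistics over per-time-point estimates.

* ``splicing_speed_auc`` — the trapezoidal area-under-the-curve splicing
  speed over the 1.5/2.5/5-minute splicing ratios, normalized by the
  steady-state ratio.  Equals 1 when every nascent ratio already equals the
  steady-state ratio; larger values mean faster splicing.
* ``decay_rate_proxy`` — log2 of the (weighted) mean nascent abundance over
  the steady-state abundance.  At very short labeling times nascent levels
  track synthesis, while steady state tracks synthesis/decay, so a higher
  ratio indicates faster degradation.
* ``background_bound`` — upper bound on the unlabeled-background fraction
  from intronic-FPKM fractions of the background and labeled samples.
* ``table1_decreases`` — per-class median log2 FPKM decreases between time
  points with a Welch t-test between classes.
* ``class_enrichment_summary`` — fraction of each transcript class called
  enriched by an external differential-expression run.
* ``first_order_check`` — least-squares fit of first-order labeled
  accumulation, to flag transcripts whose trajectories are incompatible
  with single-step kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SpeedScore",
    "DecayScore",
    "BackgroundEstimate",
    "DECAY_WEIGHTS",
    "splicing_speed_auc",
    "speed_score",
    "decay_rate_proxy",
    "decay_table",
    "background_bound",
    "table1_decreases",
    "class_enrichment_summary",
    "first_order_check",
]

#: trapezoid interval weights of the AUC statistic at 1.5/2.5/5.0 min:
#: numerator = 0.5*R_1.5 + 1.75*R_2.5 + 1.25*R_5.0, total weight 3.5.
DECAY_WEIGHTS = (0.5 / 3.5, 1.75 / 3.5, 1.25 / 3.5)

NASCENT_TIMES = (1.5, 2.5, 5.0)


@dataclass
class SpeedScore:
    """AUC splicing speed for one gene."""

    gene_id: str
    r_1_5: float
    r_2_5: float
    r_5_0: float
    r_ss: float
    auc: float


@dataclass
class DecayScore:
    """Decay-rate proxy for one transcript (higher = faster degradation)."""

    transcript_id: str
    fpkm_1_5: float
    fpkm_2_5: float
    fpkm_5_0: float
    fpkm_ss: float
    proxy: float


@dataclass
class BackgroundEstimate:
    """Worst-case bound on the unlabeled-background fraction.

    alpha0/alpha1 are the intronic FPKM fractions in the background and
    labeled samples; beta is the (unknown, bounded) intronic fraction of
    true signal.  ``fraction_bound`` = (m/n) / (1 + m/n) where
    m/n = (beta - alpha1) / (alpha1 - alpha0).
    """

    alpha0: float
    alpha1: float
    beta: float
    m_over_n: float
    fraction_bound: float


# --------------------------------------------------------------------------

def splicing_speed_auc(
    r_1_5: float, r_2_5: float, r_5_0: float, r_ss: float
) -> float:
    """Trapezoidal AUC splicing speed, normalized by the steady-state ratio.

    AUC = [(R_2.5 + R_1.5)/2 + 2.5 * (R_5.0 + R_2.5)/2] / (3.5 * R_SS).
    """
    for name, r in (("r_1_5", r_1_5), ("r_2_5", r_2_5), ("r_5_0", r_5_0)):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    if not (0.0 < r_ss <= 1.0):
        raise ValueError(f"r_ss must be in (0, 1], got {r_ss}")
    num = (r_2_5 + r_1_5) / 2.0 + 2.5 * (r_5_0 + r_2_5) / 2.0
    return num / (3.5 * r_ss)


def speed_score(gene_id: str, r_1_5, r_2_5, r_5_0, r_ss) -> SpeedScore:
    return SpeedScore(
        gene_id, r_1_5, r_2_5, r_5_0, r_ss,
        splicing_speed_auc(r_1_5, r_2_5, r_5_0, r_ss),
    )


def decay_rate_proxy(
    fpkm_nascent,
    fpkm_ss: float,
    weights=DECAY_WEIGHTS,
    transcript_id: str = "",
) -> DecayScore:
    """log2 of the weighted mean nascent FPKM over the steady-state FPKM.

    Defaults to the AUC trapezoid interval weights at 1.5/2.5/5.0 min for
    internal consistency with the splicing-speed statistic; pass uniform
    weights for a plain mean.  All FPKMs must be positive.
    """
    nasc = np.asarray(list(fpkm_nascent), dtype=float)
    if nasc.size != 3:
        raise ValueError("expected FPKM values at the three nascent times")
    if np.any(nasc <= 0) or fpkm_ss <= 0:
        raise ValueError("all FPKM values must be positive")
    w = np.asarray(list(weights), dtype=float)
    if w.size != 3 or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be three nonnegative values")
    w = w / w.sum()
    proxy = float(np.log2(float(np.dot(w, nasc)) / fpkm_ss))
    return DecayScore(transcript_id, *nasc.tolist(), fpkm_ss, proxy)


def decay_table(
    fpkm: pd.DataFrame, weights=DECAY_WEIGHTS
) -> pd.DataFrame:
    """Apply the decay proxy to a (transcripts x [1.5, 2.5, 5.0, ss]) table.

    Transcripts with any nonpositive FPKM are flagged and excluded from the
    proxy (``proxy`` is NaN, ``flag`` = "nonpositive-fpkm").
    """
    cols = [1.5, 2.5, 5.0, "ss"]
    missing = [c for c in cols if c not in fpkm.columns]
    if missing:
        raise ValueError(f"missing FPKM columns: {missing}")
    rows = []
    for tid, row in fpkm.iterrows():
        vals = [row[c] for c in cols]
        if any(v <= 0 or not np.isfinite(v) for v in vals):
            rows.append({"transcript_id": tid, "proxy": math.nan,
                         "flag": "nonpositive-fpkm"})
            continue
        score = decay_rate_proxy(vals[:3], vals[3], weights, transcript_id=str(tid))
        rows.append({"transcript_id": tid, "proxy": score.proxy, "flag": ""})
    return pd.DataFrame(rows).set_index("transcript_id")


def background_bound(
    alpha0: float, alpha1: float, beta: float = 0.5
) -> BackgroundEstimate:
    """Bound the unlabeled-background fraction of a labeled sample.

    With intronic fractions alpha0 (background sample), alpha1 (labeled
    sample) and beta (true signal, worst case 0.5), the background:signal
    ratio obeys m/n = (beta - alpha1) / (alpha1 - alpha0) and the
    background fraction of the sample is (m/n) / (1 + m/n).
    """
    for name, v in (("alpha0", alpha0), ("alpha1", alpha1), ("beta", beta)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if alpha1 <= alpha0:
        raise ValueError("alpha1 must exceed alpha0 (no labeling signal)")
    if beta < alpha1:
        raise ValueError("beta must be >= alpha1 for a nonnegative bound")
    m_over_n = (beta - alpha1) / (alpha1 - alpha0)
    fraction = m_over_n / (1.0 + m_over_n)
    return BackgroundEstimate(alpha0, alpha1, beta, m_over_n, fraction)


# --------------------------------------------------------------------------

def table1_decreases(
    fpkm_by_class: dict[str, pd.DataFrame],
    time_pairs=((1.5, 2.5), (1.5, 5.0), (1.5, "ss")),
) -> pd.DataFrame:
    """Median log2-FPKM decreases per class and time gap, with Welch t-tests.

    ``fpkm_by_class`` maps a class name to a (transcripts x time) FPKM
    table.  For each pair (t1, t2) the per-transcript decrease is
    log2(FPKM_t1) - log2(FPKM_t2); the median over transcripts is reported
    per class, and a Welch (unequal-variance) two-sample t-test compares
    the two classes' decreases.  Exactly two classes are compared.
    """
    if len(fpkm_by_class) != 2:
        raise ValueError("exactly two classes are compared")
    (name_a, fa), (name_b, fb) = fpkm_by_class.items()
    rows = []
    for t1, t2 in time_pairs:
        decs = {}
        for name, f in ((name_a, fa), (name_b, fb)):
            with np.errstate(divide="ignore", invalid="ignore"):
                d = np.log2(f[t1].to_numpy(dtype=float)) - np.log2(
                    f[t2].to_numpy(dtype=float)
                )
            decs[name] = d[np.isfinite(d)]
        t_stat, p = stats.ttest_ind(decs[name_a], decs[name_b], equal_var=False)
        rows.append(
            {
                "time_gap": f"{t1}-{t2}",
                f"{name_a}_median_decrease": float(np.median(decs[name_a])),
                f"{name_b}_median_decrease": float(np.median(decs[name_b])),
                "t_stat": float(t_stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def class_enrichment_summary(
    de_table: pd.DataFrame, p_thresh: float = 0.05
) -> pd.Series:
    """Fraction of each class enriched (adjusted p strictly below threshold).

    ``de_table`` needs columns ``tx_class`` and ``padj`` (adjusted p-values
    from an external differential-expression caller).  Classes present but
    empty after NaN removal are reported as missing (NaN), not zero.
    """
    if not {"tx_class", "padj"}.issubset(de_table.columns):
        raise ValueError("de_table needs 'tx_class' and 'padj' columns")
    out = {}
    for cls, grp in de_table.groupby("tx_class", sort=True):
        padj = grp["padj"].to_numpy(dtype=float)
        padj = padj[np.isfinite(padj)]
        out[cls] = math.nan if padj.size == 0 else float((padj < p_thresh).mean())
    return pd.Series(out, name="enriched_fraction")


def first_order_check(values, times) -> dict:
    """Fit first-order labeled accumulation A(t) = A_ss * (1 - e^(-k t)).

    Returns the fitted rate ``k``, plateau ``a_ss`` and a relative RMS
    residual; trajectories that plateau above their steady state (delayed
    multi-step maturation) leave a large residual and can be flagged.
    Requires at least three time points (two leave the fit underdetermined).
    """
    y = np.asarray(list(values), dtype=float)
    t = np.asarray(list(times), dtype=float)
    if y.size != t.size:
        raise ValueError("values and times must have equal length")
    if y.size < 3:
        raise ValueError("need at least three time points")

    def model(tt, a_ss, k):
        return a_ss * (1.0 - np.exp(-k * tt))

    a0 = max(float(np.max(y)), 1e-9)
    k0 = 1.0 / max(float(np.median(t)), 1e-9)
    popt, _ = optimize.curve_fit(
        model, t, y, p0=(a0, k0), bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=10000,
    )
    resid = y - model(t, *popt)
    scale = max(float(np.mean(np.abs(y))), 1e-12)
    rel_rms = float(np.sqrt(np.mean(resid**2)) / scale)
    return {"k": float(popt[1]), "a_ss": float(popt[0]), "rel_rms": rel_rms}
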