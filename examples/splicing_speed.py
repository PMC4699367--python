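"""Rank genes by splicing speed from a simulated time course.

Genes with different true splicing rates are simulated at 1.5/2.5/5 min;
per-time splicing ratios feed the trapezoidal AUC statistic, whose ranking
should recover the ranking of the true rates.
"""

import numpy as np
from scipy.stats import spearmanr

from tukinetics import kinetics as kin
from tukinetics import splicing_quant as sq
from tukinetics import synthetic_data as sd

rng = np.random.default_rng(0)
geom = sq.GeneGeometry()
k_splice = np.exp(rng.normal(0.0, 0.6, 12))
k_decay = 0.2

print("gene   k_splice   R_1.5   R_2.5   R_5.0   R_ss    AUC")
aucs = []
for g, ks in enumerate(k_splice):
    p = sd.KineticParams(10.0, ks, k_decay, label_offset=0.5)
    rs = []
    for t in (1.5, 2.5, 5.0):
        P, M = sd.labeled_abundance(p, t)
        counts = sq.simulate_read_counts(geom, M / (M + P), 500, rng)
        amb = counts["mature_exon"] + counts["precursor_exon"]
        est = sq.posterior_ratio_from_counts(
            *sq.unambiguous_counts(counts),
            [(amb, 1 / geom.eff_mature, 1 / geom.eff_precursor)],
            eff_len_mature=geom.eff_mature,
            eff_len_precursor=geom.eff_precursor,
            seed=int(rng.integers(2**31)),
        )
        rs.append(min(max(est.mean, 0.0), 1.0))
    r_ss = ks / (ks + k_decay)
    auc = kin.splicing_speed_auc(*rs, r_ss)
    aucs.append(auc)
    print(
        f"g{g:02d}    {ks:6.2f}    {rs[0]:.3f}   {rs[1]:.3f}   {rs[2]:.3f}"
        f"   {r_ss:.3f}   {auc:.3f}"
    )

rho = spearmanr(k_splice, aucs).statistic
print(
    f"\nSpearman rho between true splicing rate and AUC speed: {rho:.3f}\n"
    "AUC = 1 means the gene is already at its steady-state splicing ratio\n"
    "during the labeling window (instantaneous splicing); smaller = slower."
)
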