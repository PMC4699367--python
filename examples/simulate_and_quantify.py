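"""Simulate one labeled sample and estimate a gene's splicing ratio.

Builds a small single-intron annotation, simulates 1.5-minute labeled
fragments from known kinetics, then runs the probabilistic estimator and
prints the true ratio next to the posterior mean and 95% credible interval.
"""

from tukinetics import io_formats as io
from tukinetics import splicing_quant as sq
from tukinetics import synthetic_data as sd

models = sd.generate_annotation(5, {"RP-intronic": 1.0}, seed=1)
params = [sd.KineticParams(k_syn=50, k_splice=1.5, k_decay=0.15)] * len(models)
truth = sd.simulate_labeled_abundances(
    params, (1.5,), gene_ids=[m.gene_id for m in models]
)
table = sd.simulate_reads(truth, models, n_fragments=8000, seed=2)
reads = sd.reads_from_table(table)

print("gene      true_R   posterior_mean   95% CI            n_reads")
for m in models:
    est = sq.posterior_ratio(reads[m.gene_id], m, seed=3, time=1.5)
    true_r = truth.R[truth.gene_ids.index(m.gene_id), 0]
    print(
        f"{m.gene_id}   {true_r:.3f}    {est.mean:.3f}            "
        f"[{est.ci_lo:.3f}, {est.ci_hi:.3f}]    {est.n_reads}"
    )
print(
    "\nEach row compares the simulated gene's true labeled mRNA fraction at\n"
    "1.5 min with the posterior estimate; intervals should cover the truth\n"
    "about 95% of the time at this coverage."
)
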