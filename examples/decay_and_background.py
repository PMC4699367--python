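"""Decay-rate proxies for unstable ncRNA classes, and the background bound.

Simulates CUT-like (delayed maturation, fast decay) and SUT-like species,
computes the nascent/steady-state decay proxy, and evaluates the
worst-case unlabeled-background bound from intronic FPKM fractions.
"""

import pandas as pd

from tukinetics import kinetics as kin
from tukinetics import synthetic_data as sd

cut = sd.KineticParams(5, 0.2, 2.0, n_maturation_steps=4)
sut = sd.KineticParams(5, 0.25, 0.6, n_maturation_steps=3)
stable = sd.KineticParams(20, 1.0, 0.1)

truth = sd.simulate_labeled_abundances(
    [cut, sut, stable], (1.5, 2.5, 5.0), gene_ids=["cut1", "sut1", "mrna1"]
)
traj = sd.labeled_fpkm_trajectory(truth)
fpkm = pd.DataFrame(
    {1.5: traj[1.5], 2.5: traj[2.5], 5.0: traj[5.0], "ss": 1.0}
)
decays = kin.decay_table(fpkm)
print("normalized nascent/SS trajectories and decay proxies:")
print(pd.concat([traj.round(3), decays["proxy"].round(3)], axis=1))
print(
    "\nHigher proxy = faster degradation: the CUT-like species sits far\n"
    "above its steady-state level while nascent, the stable mRNA does not.\n"
)

est = kin.background_bound(alpha0=0.075, alpha1=0.461, beta=0.5)
print(
    f"background bound: m/n = {est.m_over_n:.4f}, "
    f"fraction <= {100 * est.fraction_bound:.2f}%"
)
print(
    "With 7.5% intronic signal in the unlabeled control and 46.1% in the\n"
    "1.5-min labeled sample, unlabeled carry-over RNA can account for at\n"
    "most ~9.2% of the labeled sample even in the worst case."
)
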