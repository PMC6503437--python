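"""Type-I-error calibration on all-noise data.

Generates studies where every gene is independent noise and the labels
carry no information, then measures how often each per-radius p-value
falls below 0.05.  Rates near 0.05 mean the tests are calibrated: they do
not invent drivers when none exist.
"""

import numpy as np

from genesurrounder import make_network, make_null_study, score_study

net = make_network("small-world", 100, seed=2)
p_sphere, p_decay, p_comb = [], [], []
for s in range(2):
    study, marked = make_null_study(net, n_per_class=20, seed=s)
    res = score_study(study, marked, b_sphere=200, b_decay=200, seed=s)
    at2 = res.curves[res.curves.radius == 2]
    p_sphere += list(at2.p_sphere)
    p_decay += list(at2.p_decay)
    p_comb += list(at2.p_comb)

n = len(p_comb)
print(f"{n} null genes, radius 2, nominal level 0.05")
for name, values in [
    ("sphere of influence", p_sphere),
    ("decay of DE", p_decay),
    ("combined", p_comb),
]:
    rate = float(np.mean(np.asarray(values) <= 0.05))
    print(f"  {name:20s} rejection rate: {rate:.3f}")

n_sig = int(res.results["significant"].sum())
print(f"genes passing the diameter-scaled threshold in the last study: {n_sig}")
print(
    "Rejection rates near 0.05 indicate calibrated per-radius tests. The\n"
    "diameter-scaled threshold corrects the radius scan per gene, not the\n"
    "gene multiplicity, so a few of 100 null genes can still pass by chance\n"
    "(use genewise_fwer for a family-wise adjustment across genes)."
)
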