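"""Mutualistic-like vs antagonistic-like niche-center dispersion.

Generates two small ensembles — consumer niche centers drawn uniformly
("mutualistic-like") vs clumped around one peak ("antagonistic-like") —
runs the full study pipeline (fit all models, compute all metrics), and
compares the fitted center-dispersion distributions with a two-sample
Kolmogorov-Smirnov test.  Clumped generation should yield smaller fitted
dispersion.
"""

import numpy as np

from nicheweb import AnnealConfig, SyntheticSpec, class_comparison, generate_synthetic_network, run_study

networks = []
for seed in range(6):
    for law, label in [(("uniform",), "mutualistic-like"),
                       (("clumped", 1, 0.05), "antagonistic-like")]:
        spec = SyntheticSpec(s_c=10, s_r=10, center_law=law,
                             width_law=("fixed", 0.25), class_label=label, seed=seed)
        net, _ = generate_synthetic_network(spec)
        networks.append((net, label))

records = run_study(networks, AnnealConfig(n_sweeps=150, n_restarts=2, seed=0),
                    n_sim=20, seed=0)
by_class = {}
for rec in records:
    by_class.setdefault(rec.class_label, []).append(rec.c_sd)
for label, vals in by_class.items():
    print(f"{label:20s} median c-dispersion = {np.median(vals):.3f}")

d, p, qq = class_comparison(records)
print(f"\nKS D = {d:.3f}, asymptotic p = {p:.3f}")
print("smaller dispersion in the antagonistic-like class reflects its clumped centers;")
print("the Q-Q pairs returned alongside are plot-ready quantile matches.")
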