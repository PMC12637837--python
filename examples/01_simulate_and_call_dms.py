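"""Simulate a two-cohort methylation study and call differential sites.

Generates the default synthetic conditions (two cohorts of PT/LN/LU samples
with a hypomethylation-dominant planted lung effect), then calls DMS for the
lung-vs-rest contrast: a CpG is a DMS when |Δβ| > 0.15 and the two-sided
rank-sum p < 0.05.
"""

from epimet import SimulationConfig, call_dms, simulate_cohorts, truth_confusion

sim = simulate_cohorts(SimulationConfig(seed=1))
dms = call_dms(sim.betas["XEN"], sim.sheets["XEN"])

n_hypo, n_hyper = dms.attrs["n_hypo"], dms.attrs["n_hyper"]
print(f"probes tested: {dms.attrs['n_tested']}")
print(f"DMS called:    {n_hypo + n_hyper} ({n_hypo} hypo, {n_hyper} hyper)")
print(f"hypo/hyper ratio: {n_hypo / n_hyper:.1f}  (the planted mix is 90% hypo)")

conf = truth_confusion(dms, sim.truth, "XEN")
print(f"against planted truth: TP={conf['TP']} FP={conf['FP']} FN={conf['FN']}")
# A ratio far above 1 reproduces the dominant methylation loss expected in
# distant metastases; TP/FN show how many planted sites the caller recovered.
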