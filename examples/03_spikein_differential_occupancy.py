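"""Spike-in quantitative ChIP comparison with planted global and local changes.

Simulates three conditions sharing one baseline occupancy: a wild type, a
mutant with a 1.3x genome-wide gain plus 2x gains in 5% of bins, and a
revertant drawn from the wild-type model. Spike-in scale factors expose the
global gain, the empirical-Bayes NB Wald test finds the local gains, and the
rescue classifier checks the revertant.
"""

from scarline import qchip_do as q
from scarline import synthetic_data as sd

sim = sd.simulate_qchip_counts(
    n_bins=2_000,
    global_scale={"WT": 1.0, "MUT": 1.3, "RES": 1.0},
    local_changes={"MUT": (0.05, 2.0)},
    seed=11,
)
factors = q.spikein_scale_factors(sim.spike_totals)
norm = q.normalize_signal(sim.counts, factors).normalized
wt = [c for c in norm if c.startswith("WT")]
mut = [c for c in norm if c.startswith("MUT")]
ratio = norm[mut].to_numpy().mean() / norm[wt].to_numpy().mean()
print(f"spike-normalized global mutant/WT ratio: {ratio:.3f} (planted 1.3x + local gains)")

do_mut, audit = q.test_differential_occupancy(sim.counts, sim.sample_info, factors, ("WT", "MUT"))
planted = set(sim.truth["local"]["MUT"]["bins"])
gains = set(do_mut.index[do_mut["class"] == "gain"])
print(
    f"DO bins called gain at FDR<0.1: {len(gains)} "
    f"({len(gains & planted)}/{len(planted)} of planted 2x bins recovered;"
    " the rest reflect the genuine 1.3x genome-wide gain)"
)

do_res, _ = q.test_differential_occupancy(sim.counts, sim.sample_info, factors, ("WT", "RES"))
_, fraction = q.classify_rescue(do_mut, do_res)
print(f"fraction of mutant DO bins rescued in the revertant: {fraction:.2%}")
print("A rescued bin loses significance, or >50% of its fold change, versus WT.")
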