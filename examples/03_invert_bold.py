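"""Full inversion: recover capacity parameters from synthetic BOLD.

Generates an isolated-trial subject with known ground truth, runs
trial averaging -> deconvolution -> spline upsampling -> two-state fit,
and compares the recovered relative capacities to the truth.
"""

import logging

import neuroipc as n
from neuroipc.estimation import fit_shared_k, predict_and_score

logging.basicConfig(level=logging.ERROR)

hrf = n.peak_normalized(n.HRFParams())
truth = n.GroundTruth(
    alpha={"C": 1.0, "IC": 1.3},
    ipc=n.IPCParams(p=1.0, m=2.0),  # k = p/m = 0.5 1/s, T_c = 2 s
    hrf=hrf,
)
paradigm = n.generate_paradigm(
    n_runs=1, trials_per_condition_per_run=4, conditions=("C", "IC"),
    min_isi_s=50.0, seed=3,
)
bold, _ = n.generate_subject(paradigm, truth)
irfs = {c: n.trial_average(bold, paradigm, c) for c in ("C", "IC")}

# joint fit: C and IC share the decay rate k = p/m (same region capacities)
params = fit_shared_k(irfs, hrf)
a_ref = params["C"].a  # congruent condition normalizes the capacities
for cond in ("C", "IC"):
    res = predict_and_score(params[cond], hrf, irfs[cond], reference_amp=a_ref)
    d = res.derived
    print(f"[{cond}] k = {params[cond].k:.4f} 1/s  "
          f"p/alpha = {d.rel_processing:.4f}  m/alpha = {d.rel_storage:.4f}  "
          f"T_c = {d.t_const:.4f} s  MSE = {res.mse:.2e}")

ratio = params["IC"].a / params["C"].a
print(f"\nfitted alpha_IC/alpha_C = {ratio:.4f}  (generated: 1.3)")
print(f"true k = {truth.ipc.k} 1/s, true T_c = {truth.ipc.t_const} s")
print()
print("Noise-free isolated trials are recovered essentially exactly; the")
print("relative capacities p/alpha and m/alpha are normalized by the fitted")
print("congruent amplitude (absolute p, m, alpha are not identifiable).")
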