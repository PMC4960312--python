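"""Simulate one NMJ's recordings and compute its direct quantal content.

Quantal content (QC) — the number of vesicles released per stimulus — is the
mean evoked amplitude divided by the mean miniature (single-vesicle)
amplitude. Here the simulator's ground truth is known, so the estimate can
be checked against N * Pvr * q / q = N * Pvr.
"""

import nmjquant as nq

truth = nq.GroundTruth(n_rrp=300, q_mean=0.8)
protocols = [
    nq.Protocol.low_freq_evoked(ca_mm=0.5, n_stim=100),  # evoked EJCs at 0.2 Hz
    nq.Protocol.spontaneous(duration_s=120.0),           # minis for quantal size
]
dataset = nq.simulate_cohort(truth, protocols, n_nmjs=1, seed=42)

ejc = dataset.events.query("kind == 'ejc'")["amplitude_na"]
mejc = dataset.events.query("kind == 'mejc'")["amplitude_na"]
summary = nq.qc_ratio(ejc, mejc, nmj_id="demo", ca_mm=0.5)

p = nq.p_release(0.5, truth)
print(f"mean EJC  : {summary.mean_ejc_na:.3f} nA  (n={summary.n_ejc} stimuli)")
print(f"mean mEJC : {summary.mean_mejc_na:.3f} nA  (n={summary.n_mejc} minis)")
print(f"QC        : {summary.qc:.2f} vesicles/stimulus")
print(f"expected  : N * Pvr = {truth.n_rrp} * {p:.4f} = {truth.n_rrp * p:.2f}")
# QC should sit within sampling error of the expected value: at 0.5 mM
# calcium the release probability is low, so each stimulus releases only a
# few of the 300 release-ready vesicles.
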