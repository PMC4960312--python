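"""Variance-mean (multiple-probability fluctuation) analysis.

Recording >= 20 EJCs at each of several calcium concentrations traces out a
downward parabola Var(I) = A*I - B*I^2: at low release probability variance
grows with the mean, near saturation it falls again. The curvature gives
the readily releasable pool N = 1/B, and each calcium level yields
q = A/(1+CV^2) and Pvr = I*(B/A)*(1+CV^2).
"""

import nmjquant as nq

truth = nq.GroundTruth(n_rrp=300, q_mean=0.8, q_cv=0.3, nmj_cv=0.0)
levels = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
protocols = [nq.Protocol.low_freq_evoked(ca_mm=c, n_stim=100) for c in levels]
dataset = nq.simulate_cohort(truth, protocols, n_nmjs=1, seed=11)

by_ca = {ca: g["amplitude_na"].to_numpy() for ca, g in dataset.events.groupby("ca_mm")}
series = nq.vm_points(by_ca)
fit = nq.fit_parabola(series)
params = nq.vm_params(fit, series)

print("ca (mM)  mean I (nA)  Var (nA^2)   Pvr     q (nA)")
for row in params.itertuples():
    var = series.var_I_na2[series.ca_mm == row.ca_mm][0]
    print(f"{row.ca_mm:6.1f} {row.mean_I_na:12.2f} {var:11.2f} {row.p_vr:7.3f} {row.q_na:8.3f}")
print(f"\nfitted A = {fit.A:.3f} nA, B = {fit.B:.5f}")
print(f"RRP size N = 1/B = {fit.n_vm:.0f} vesicles  (ground truth {truth.n_rrp})")
print(f"true Pvr at 3 mM = {nq.p_release(3.0, truth):.3f}")
# Pvr should climb with calcium toward its Hill-curve maximum while the
# per-level quantal size stays near q_mean = 0.8 nA.
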