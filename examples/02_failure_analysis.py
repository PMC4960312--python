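"""Failure analysis: quantal content from the fraction of failed stimuli.

At very low calcium, release is Poisson and the probability that a stimulus
releases nothing is exp(-QC), so QC = ln(total stimuli / failures). A
stimulus counts as a failure when its amplitude lies inside the baseline
noise distribution and below the mini amplitude distribution.
"""

import numpy as np

import nmjquant as nq
from nmjquant.detect import NoiseModel

# pin the per-vesicle release probability so the true quantal content is 1.8
truth = nq.calibrate_ca_half(nq.GroundTruth(nmj_cv=0.0), ca_mm=0.25, p_target=1.8 / 300)
protocols = [nq.Protocol.failure(), nq.Protocol.spontaneous(60.0)]  # 300 stimuli, 1 Hz
dataset = nq.simulate_cohort(truth, protocols, n_nmjs=1, seed=7)

amps = dataset.events.query("kind == 'ejc'").sort_values("stim_index")["amplitude_na"]
minis = dataset.events.query("kind == 'mejc'")["amplitude_na"]
noise = NoiseModel(mean_na=0.0, sd_na=truth.noise_sd, sample_sd_na=truth.noise_sd, n_windows=8)

cls = nq.classify_failures(amps.to_numpy(), noise, minis.to_numpy())
result = nq.failure_qc(cls.m_total, cls.n_fail)

true_failures = (dataset.oracle_counts["n_released"] == 0).sum()
print(f"stimuli          : {cls.m_total}")
print(f"failures detected: {cls.n_fail}  (true zero-release stimuli: {true_failures})")
print(f"QC = ln(m/n0)    : {result.qc_fail:.3f}   (ground truth 1.8)")
print(f"Poisson check    : exp(-QC) = {np.exp(-result.qc_fail):.3f} "
      f"vs failure fraction {cls.n_fail / cls.m_total:.3f}")
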