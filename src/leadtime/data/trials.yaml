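# Sensitivity (beta) and mean sojourn time (lam, years) for four historical
# breast-cancer screening trials, as estimated by maximum likelihood from the
# cohorts receiving both mammography and physical examination.  Standard
# errors are carried as metadata only; the point estimates are the inputs to
# every table in this package.
HIP:
  beta: 0.70
  se_beta: 0.20
  lam: 2.50
  se_lam: 1.20
Edinburgh:
  beta: 0.78
  se_beta: 0.04
  lam: 4.30
  se_lam: 0.37
CNBS1:
  beta: 0.91
  se_beta: 0.18
  lam: 1.90
  se_lam: 1.20
CNBS2:
  beta: 0.82
  se_beta: 0.12
  lam: 3.10
  se_lam: 0.94
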