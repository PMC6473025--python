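"""Sample a cohort from a known Gompertz law and recover the parameters.

Draws 10,000 lifespans at the reference regime (mu0=-11.4 per month log
baseline hazard, mu1=0.7 per month slope), builds the empirical survival
step curve, and refits by least squares.  The recovered slope should land
within a few thousandths of the generating value at this sample size.
"""

from maxlifespan import GompertzParams
from maxlifespan.simulate import parameter_recovery_experiment

true = GompertzParams(mu0=-11.4, mu1=0.7)
res = parameter_recovery_experiment(true, n=10_000, seed=1)

print(f"true:      mu0 = {true.mu0:.3f}, mu1 = {true.mu1:.3f}")
print(f"recovered: mu0 = {res.recovered.mu0:.3f}, mu1 = {res.recovered.mu1:.3f}")
print(f"absolute errors: {res.err_mu0:.4f} (mu0), {res.err_mu1:.4f} (mu1)")
print()
print("mu1 controls how fast mortality accelerates with age; recovering it")
print("within ~0.01 at n=10^4 shows the fit pipeline is unbiased at scale.")
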