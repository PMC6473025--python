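"""Recorded study constants: printed summary numbers used as worked-example inputs.

The study deposited no per-animal raw data; the published summaries below are
therefore first-class inputs to the reproduction pipeline.  Printed
uncertainties are recorded verbatim — they are NOT reproducible from the
standard Student-t computation (see docs/methods.md) and are kept strictly
separate from half-widths this package computes itself.
"""

from __future__ import annotations

from .gompertz import GompertzParams

# cohort bookkeeping
CONTROL_N = 20
EXPERIMENTAL_N_ENROLLED = 56          # 5 of these reserved for chimerism control
EXPERIMENTAL_N_ANALYZED = 51          # after excluding the 5 sacrificed animals
N_EMBOLIC_DEATHS = 9                  # counted as natural deaths
N_INJECTIONS_APPROX = 150             # ~150 injections overall -> ~0.06 risk each
T_INTERVENTION_MONTHS = 15.0          # age at first injection; ~50% already dead

# observed tails (months): the only individual ages published
CONTROL_TAIL_AGES = (17.6, 19.3)                      # top 10% of n=20
EXPERIMENTAL_TAIL_AGES = (21.0, 22.5, 22.7, 23.8, 24.2)  # top 10% of n=51

# Gompertz fit to pre-intervention experimental mortality (published values)
FITTED_PARAMS = GompertzParams(mu0=-11.4, mu1=0.7)

# published point estimates and half-widths (P = 0.05), verbatim
PRINTED = {
    "mls1c": (18.45, 2.6),
    "mls2c": (17.2, 0.6),
    "mls_exp": (22.8, 0.8),
    "mlsc": (17.4, 0.5),
    "extension_percent": (31.0, 5.0),
    "survival_fold": (3.25, 0.3),
}

# chimerism: observed GFP+ fraction, heterozygous-donor reference, published result
OBSERVED_GFP_FRACTION = 0.07
DONOR_POSITIVE_FRACTION = 0.25
PRINTED_CHIMERISM_PERCENT = 28.0

# decimals at which each published value is printed (for comparison display)
PRINTED_DECIMALS = {
    "mls1c": 2,
    "mls2c": 1,
    "mls_exp": 1,
    "mlsc": 1,
    "extension_percent": 0,
    "survival_fold": 2,
    "chimerism_percent": 0,
}
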