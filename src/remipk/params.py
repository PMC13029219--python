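"""Final adult population-model estimates for remimazolam.

Typical values are quoted at a 63-kg reference adult; clearances in L/min,
volumes in L.  Inter-individual variability is log-normal on all six
structural parameters, with covariance between (CL, V1) and between
(V2, Q2).  Residual error is additive on log-concentration.
"""

from .compartments import PKParameters
from .population import OmegaMatrix, ResidualSpec

#: typical values at the 63-kg reference weight
ADULT_TYPICAL = PKParameters(CL=1.03, V1=2.08, V2=10.9, Q2=1.49, V3=19.7, Q3=0.266)

#: log-scale variances of the inter-individual random effects
ADULT_OMEGA = OmegaMatrix(
    variances={
        "CL": 0.0203,
        "V1": 0.00546,
        "V2": 0.0509,
        "Q2": 0.107,
        "V3": 0.072,
        "Q3": 0.0777,
    },
    covariances={("CL", "V1"): 0.00948, ("V2", "Q2"): 0.0555},
)

#: additive variance on log-concentration (~12.7% CV on the natural scale)
ADULT_RESIDUAL = ResidualSpec(variance=0.0162, scale="log-concentration")

#: adult study population weight distribution, kg (mean, SD)
ADULT_WEIGHT_MEAN = 63.4
ADULT_WEIGHT_SD = 7.3
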