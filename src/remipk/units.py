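"""Unit conventions used throughout the package.

Internal computation uses minutes, milligrams and litres, so amounts are in
mg and central-compartment concentrations in mg/L.  The public interface
reports concentrations in ng/mL and areas under the curve in ng*h/mL, the
units customary for remimazolam exposure tables.  1 mg/L == 1000 ng/mL.
"""

MGL_TO_NGML = 1000.0
MIN_PER_HOUR = 60.0


def mg_per_l_to_ng_per_ml(x):
    return x * MGL_TO_NGML


def auc_mgmin_per_l_to_nghr_per_ml(x):
    """Convert an AUC in mg*min/L to ng*h/mL."""
    return x * MGL_TO_NGML / MIN_PER_HOUR
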