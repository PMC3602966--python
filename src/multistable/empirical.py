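"""Published group-level reversal statistics for the three displays.

Only group summaries exist for the human data: kinetic depth (KD), binocular
rivalry (BR) and Necker cube (NC).  Values are mean +/- sd across observers;
they serve as matching targets and plausibility fixtures.
"""

from __future__ import annotations

from .observables import ObservableSet

__all__ = ["EMPIRICAL", "EMPIRICAL_SD", "KS_PVALUES", "GAMMA_SHAPE_RANGE"]

#: group-mean observables per display
EMPIRICAL = {
    "KD": ObservableSet(t_dom=11.4, c_v=0.67, c_h=0.24, tau_h=5.2, balance=0.50),
    "BR": ObservableSet(t_dom=2.4, c_v=0.48, c_h=0.30, tau_h=1.2, balance=0.49),
    "NC": ObservableSet(t_dom=6.6, c_v=0.63, c_h=0.23, tau_h=3.2, balance=0.50),
}

#: across-observer standard deviations of the same quantities
EMPIRICAL_SD = {
    "KD": ObservableSet(t_dom=7.6, c_v=0.18, c_h=0.10, tau_h=0.85, balance=0.007),
    "BR": ObservableSet(t_dom=1.05, c_v=0.12, c_h=0.08, tau_h=0.1, balance=0.005),
    "NC": ObservableSet(t_dom=5.0, c_v=0.17, c_h=0.08, tau_h=0.9, balance=0.021),
}

#: group-mean KS p-values of the duration distribution against fitted
#: Gamma / exponential / Gaussian distributions ("<0.001" entered as 0.001)
KS_PVALUES = {
    "KD": {"gamma": 0.74, "exponential": 0.09, "gaussian": 0.09},
    "BR": {"gamma": 0.69, "exponential": 0.001, "gaussian": 0.05},
    "NC": {"gamma": 0.66, "exponential": 0.001, "gaussian": 0.17},
}

#: range of fitted Gamma shape parameters counted as human-like
GAMMA_SHAPE_RANGE = (3.1, 4.3)
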