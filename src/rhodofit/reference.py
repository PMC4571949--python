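"""Published spectral parameters of Drosophila Rh1 and five charge mutants.

λmax values (nm) of the rhodopsin (R) and metarhodopsin (M) states
measured in vivo for wild-type Rh1 and the five charge-neutralizing
substitutions at conserved acidic sites, with the reported fit
correlations and fly counts.  These are the standard simulation ground
truths for the package's synthetic pigments; `None` marks quantities that
could not be measured for a genotype (the D96N and E194Q M states).
"""

from __future__ import annotations

RH1_PIGMENTS: dict[str, dict] = {
    "Rh1": {"R": 480, "M": 560, "corr_SS": 0.983, "corr_MSP": 0.997, "n_SS": 3, "n_MSP": 7},
    "Rh1 D96N": {"R": 485, "M": None, "corr_SS": 0.991, "corr_MSP": None, "n_SS": 12, "n_MSP": 0},
    "Rh1 D124N": {"R": 486, "M": 554, "corr_SS": 0.987, "corr_MSP": 0.995, "n_SS": 8, "n_MSP": 12},
    "Rh1 D147N": {"R": 486, "M": 551, "corr_SS": 0.988, "corr_MSP": 0.994, "n_SS": 13, "n_MSP": 13},
    "Rh1 E194Q": {"R": 484, "M": None, "corr_SS": 0.990, "corr_MSP": None, "n_SS": 8, "n_MSP": 0},
    "Rh1 D203N": {"R": 481, "M": 555, "corr_SS": 0.977, "corr_MSP": 0.993, "n_SS": 11, "n_MSP": 10},
}

WILD_TYPE = "Rh1"
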