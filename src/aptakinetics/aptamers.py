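"""Reference kinetic constants for thrombin exosite-I aptamers.

Single-molecule FRET measurements (5 nM labeled aptamer, 0.1-s frames) give
these rate constants for the three structurally related DNA aptamers that
bind thrombin's exosite I.  HD1 is the minimal G-quadruplex; RE31 and NU172
are duplex-stabilized variants.  Values are mean +/- SD over three
independent replicates and are used throughout the examples and acceptance
runs as ground-truth inputs for parameter-recovery simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AptamerKinetics", "APTAMERS", "ASSAY_CONCENTRATION"]

ASSAY_CONCENTRATION = 5e-9  # M donor-labeled aptamer in the smFRET assay


@dataclass(frozen=True)
class AptamerKinetics:
    name: str
    k_on: float  # M^-1 s^-1
    k_on_sd: float
    k_off: float  # s^-1
    k_off_sd: float
    K_d: float  # M (replicate-mean affinity; not forced to k_off/k_on of
    # the rounded rate means)
    K_d_sd: float


APTAMERS: dict[str, AptamerKinetics] = {
    "HD1": AptamerKinetics("HD1", 0.7e8, 0.1e8, 0.7, 0.1, 9.2e-9, 0.8e-9),
    "RE31": AptamerKinetics("RE31", 1.1e8, 0.1e8, 0.3, 0.1, 2.9e-9, 0.1e-9),
    "NU172": AptamerKinetics("NU172", 0.2e8, 0.1e8, 0.1, 0.1, 3.3e-9, 0.7e-9),
}
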