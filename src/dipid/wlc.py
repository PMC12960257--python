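"""Worm-like-chain statistics for short single-stranded DNA linkers.

The binding strands that hold Dipid monomers together are mostly
single-stranded oligo-dT, which at the 1--30 nt scale is well described
by the worm-like chain (WLC) interpolation formula for the
root-mean-square end-to-end distance,

    <R^2> = 2 Lp^2 (Lc/Lp - 1 + exp(-Lc/Lp)),

with contour length ``Lc`` and persistence length ``Lp``.  The physical
length assigned to a binding strand is this RMS extent of its
single-stranded part plus half the duplex length of the hybridized
sticky segment (the duplex is shared between the two bound strands).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["WLCParams", "wlc_end_to_end"]

#: nm of contour length per nucleotide of single-stranded DNA
RISE_SS_NM = 0.63
#: nm of helix rise per base pair of double-stranded DNA
RISE_DS_NM = 0.34
#: persistence length of single-stranded DNA, nm
PERSISTENCE_SS_NM = 1.5


@dataclass(frozen=True)
class WLCParams:
    """Polymer constants used by the strand-length model.

    Attributes
    ----------
    rise_ss : float
        Contour length per ssDNA nucleotide, nm (default 0.63).
    rise_ds : float
        Rise per dsDNA base pair, nm (default 0.34).
    Lp : float
        ssDNA persistence length, nm (default 1.5).
    """

    rise_ss: float = RISE_SS_NM
    rise_ds: float = RISE_DS_NM
    Lp: float = PERSISTENCE_SS_NM

    def __post_init__(self) -> None:
        if self.rise_ss <= 0 or self.rise_ds <= 0 or self.Lp <= 0:
            raise ValueError("all WLC parameters must be strictly positive")


def wlc_end_to_end(Lc_ss: float, params: WLCParams = WLCParams()) -> float:
    """RMS end-to-end distance of a worm-like chain of contour length ``Lc_ss``.

    Parameters
    ----------
    Lc_ss : float
        Contour length of the single-stranded segment, nm.  Must be >= 0.
    params : WLCParams
        Polymer constants; only ``Lp`` enters here.

    Returns
    -------
    float
        sqrt(2 Lp^2 (Lc/Lp - 1 + exp(-Lc/Lp))), in nm.  Bounded above by
        ``Lc_ss`` (rigid-rod limit) and asymptotically sqrt(2 Lp Lc)
        (ideal-coil limit).
    """
    if Lc_ss < 0:
        raise ValueError(f"contour length must be non-negative, got {Lc_ss}")
    if Lc_ss == 0.0:
        return 0.0
    x = Lc_ss / params.Lp
    # expm1 keeps the small-x branch accurate: the bracket is x^2/2 - x^3/6 + ...
    bracket = x + math.expm1(-x)
    return math.sqrt(2.0 * params.Lp**2 * bracket)
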