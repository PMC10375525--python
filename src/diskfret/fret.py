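"""FRET transfer timescale, rate and efficiency from donor lifetimes.

When a donor's excited state gains an energy-transfer channel to an
acceptor, its fluorescence lifetime shortens from tau_D to tau_DA.
The transfer timescale, rate and efficiency follow from the two
lifetimes alone:

    1/tau_DA = 1/tau_D + 1/tau_T      =>  tau_T = 1/(1/tau_DA - 1/tau_D)
    k_T = 1/tau_T
    E = 1 - tau_DA/tau_D  ( = tau_DA/tau_T )

If tau_DA >= tau_D there is no lifetime evidence of transfer; the
expressions are undefined and a no-transfer sentinel (infinite
timescale, zero rate and efficiency) is returned instead of a negative
timescale.

The total rate can further be apportioned across geometric pathways
with the distance-only weights of :func:`diskfret.geometry.pathway_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from diskfret.geometry import PathwayTable

__all__ = [
    "FretError",
    "NO_TRANSFER",
    "FretEstimate",
    "transfer_timescale",
    "transfer_rate",
    "efficiency",
    "estimate_from_lifetimes",
    "apportion_pathways",
    "forster_pair_rate",
]

#: Sentinel transfer timescale when tau_DA >= tau_D (no detectable transfer).
NO_TRANSFER = math.inf


class FretError(ValueError):
    """Invalid lifetime or pathway inputs."""


@dataclass(frozen=True)
class FretEstimate:
    """Transfer quantities for one donor-only vs donor+acceptor pair.

    ``tau_T`` is infinite (``NO_TRANSFER``) and ``k_T`` and ``E`` are
    zero when the coupled lifetime is not shorter than the reference.
    Provenance labels record which samples supplied each lifetime and
    the component-averaging scheme used.
    """

    tau_D: float
    tau_DA: float
    tau_T: float
    k_T: float
    E: float
    tau_D_source: str = ""
    tau_DA_source: str = ""
    averaging_scheme: str = ""

    @property
    def has_transfer(self) -> bool:
        return math.isfinite(self.tau_T)


def _check_lifetime(tau: float, name: str) -> None:
    if not tau > 0:
        raise FretError(f"{name} must be positive, got {tau}")


def transfer_timescale(tau_DA: float, tau_D: float) -> float:
    """Energy-transfer timescale tau_T = 1/(1/tau_DA - 1/tau_D) in ns.

    Returns ``NO_TRANSFER`` (infinity) when tau_DA >= tau_D.
    """
    _check_lifetime(tau_DA, "tau_DA")
    _check_lifetime(tau_D, "tau_D")
    if tau_DA >= tau_D:
        return NO_TRANSFER
    return 1.0 / (1.0 / tau_DA - 1.0 / tau_D)


def transfer_rate(tau_T: float) -> float:
    """Energy-transfer rate k_T = 1/tau_T in ns^-1 (0 for no transfer)."""
    if math.isinf(tau_T):
        return 0.0
    if not tau_T > 0:
        raise FretError(f"tau_T must be positive, got {tau_T}")
    return 1.0 / tau_T


def efficiency(tau_DA: float, tau_D: float) -> float:
    """Transfer efficiency E = 1 - tau_DA/tau_D, reported as 0 when
    the coupled lifetime is not shorter than the reference."""
    _check_lifetime(tau_DA, "tau_DA")
    _check_lifetime(tau_D, "tau_D")
    e = 1.0 - tau_DA / tau_D
    return max(e, 0.0)


def estimate_from_lifetimes(
    tau_DA: float,
    tau_D: float,
    tau_DA_source: str = "",
    tau_D_source: str = "",
    averaging_scheme: str = "",
) -> FretEstimate:
    """Build a full :class:`FretEstimate` from the two donor lifetimes."""
    tau_T = transfer_timescale(tau_DA, tau_D)
    return FretEstimate(
        tau_D=tau_D,
        tau_DA=tau_DA,
        tau_T=tau_T,
        k_T=transfer_rate(tau_T),
        E=efficiency(tau_DA, tau_D),
        tau_D_source=tau_D_source,
        tau_DA_source=tau_DA_source,
        averaging_scheme=averaging_scheme,
    )


def apportion_pathways(k_T: float, table: PathwayTable) -> np.ndarray:
    """Per-pathway rates k_i = p_i * k_T for a normalized pathway table.

    The rates sum to ``k_T`` to within 1e-12 relative.
    """
    if k_T < 0:
        raise FretError("k_T must be non-negative")
    if not table.is_normalized(tol=1e-9):
        raise FretError("pathway table weights must sum to 1")
    return table.weights * k_T


def forster_pair_rate(R: float, R0: float, tau_D: float) -> float:
    """Pairwise Forster rate (1/tau_D) * (R0/R)^6 in ns^-1."""
    for name, v in (("R", R), ("R0", R0), ("tau_D", tau_D)):
        if not v > 0:
            raise FretError(f"{name} must be positive, got {v}")
    return (1.0 / tau_D) * (R0 / R) ** 6
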