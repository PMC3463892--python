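"""Four-buffer Ca2+ reaction network: Fluo-3, ATP, calmodulin (mobile)
and troponin C (stationary, excluded from the sub-sarcolemmal shell).

Each buffer binds Ca by single-site mass action,
    d[CaB]/dt = k_on [Ca] (B_tot - [CaB]) - k_off [CaB],
and the free-Ca equation receives minus the sum, so binding conserves
total Ca pointwise.  Free buffer is represented implicitly as
(total - bound).  Mobile buffers diffuse with their own coefficient
(free and Ca-bound forms alike, so the total stays uniform); TnC has
D = 0 and its total reduced by each voxel's sub-sarcolemmal shell
fraction, mirroring its absence from the sarcolemma and the 40-50 nm
sub-membrane space at any grid resolution.

Default kinetic constants follow the whole-cell rabbit model lineage
(Fluo-3 total of 50 uM matches the dye loading of the underlying
voltage-clamp experiments); all are config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


class BufferError(ValueError):
    pass


@dataclass(frozen=True)
class BufferSpec:
    name: str
    total: float      # uM
    k_on: float       # uM^-1 ms^-1
    k_off: float      # ms^-1
    D: float          # um^2/ms; 0 = stationary
    excluded_from_shell: bool = False  # zero total in the sub-sarc shell

    def __post_init__(self):
        if min(self.total, self.k_on, self.k_off, self.D) < 0:
            raise BufferError(f"{self.name}: negative parameter")
        if self.k_on == 0:
            raise BufferError(f"{self.name}: k_on must be > 0")

    @property
    def Kd(self) -> float:
        """uM."""
        return self.k_off / self.k_on

    @property
    def mobile(self) -> bool:
        return self.D > 0


#: free-Ca diffusion coefficient, um^2/ms
D_CA = 0.35


def default_buffers() -> list[BufferSpec]:
    """Lineage defaults: dye per the loading condition (50 uM Fluo-3,
    Kd 1.1 uM, fast measured on-rate, myoplasmic diffusivity of the
    protein-bound dye); endogenous ATP, calmodulin and low-affinity TnC
    sites from the rabbit ventricular model family.  The fast dye
    on-rate keeps the global trigger flux temporally aligned with the
    L-type waveform, matching the observed coincidence of their maxima.
    """
    return [
        BufferSpec("fluo3", total=50.0, k_on=0.23, k_off=0.253, D=0.025),
        BufferSpec("atp", total=455.0, k_on=0.225, k_off=45.0, D=0.14),
        BufferSpec("calmodulin", total=24.0, k_on=0.034, k_off=0.238, D=0.025),
        BufferSpec("tnc", total=70.0, k_on=0.0327, k_off=0.0196, D=0.0,
                   excluded_from_shell=True),
    ]


def local_totals(spec: BufferSpec, n_voxels: int,
                 shell_fraction: np.ndarray | None = None
                 ) -> np.ndarray | float:
    """Per-voxel total for a buffer, honoring the shell exclusion.

    ``shell_fraction`` gives the fraction of each voxel's volume inside
    the sub-sarcolemmal shell; an excluded buffer keeps total x
    (1 - fraction), so the excluded pool matches the physical shell
    volume at any resolution."""
    if spec.excluded_from_shell and shell_fraction is not None:
        return spec.total * (1.0 - np.asarray(shell_fraction, dtype=float))
    return spec.total


def reaction_term(Ca, bound: dict, specs: list[BufferSpec],
                  totals: dict | None = None):
    """Mass-action rates (dCa/dt, {name: dbound/dt}) in uM/ms.

    ``totals`` optionally carries per-voxel total arrays (shell-excluded
    TnC); defaults to each spec's uniform total.  Raises if any bound
    concentration exceeds its local total.
    """
    Ca = np.asarray(Ca, dtype=float)
    dca = np.zeros_like(Ca)
    dbound = {}
    for s in specs:
        cab = np.asarray(bound[s.name], dtype=float)
        tot = totals[s.name] if totals else s.total
        if np.any(cab > np.asarray(tot) + 1e-9) or np.any(cab < -1e-12):
            raise BufferError(f"{s.name}: bound outside [0, total]")
        rate = s.k_on * Ca * (tot - cab) - s.k_off * cab
        dbound[s.name] = rate
        dca = dca - rate
    return dca, dbound


def equilibrate(Ca0: float, specs: list[BufferSpec],
                totals: dict | None = None) -> dict:
    """Equilibrium bound concentrations at uniform free Ca0:
    [CaB] = B_tot Ca0 / (Kd + Ca0), honoring exclusion masks."""
    if Ca0 < 0:
        raise BufferError("Ca0 must be >= 0")
    out = {}
    for s in specs:
        tot = totals[s.name] if totals else s.total
        out[s.name] = np.asarray(tot) * Ca0 / (s.Kd + Ca0) \
            if np.ndim(tot) else tot * Ca0 / (s.Kd + Ca0)
    return out


def buffering_ratio(Ca, specs: list[BufferSpec]) -> float:
    """Instantaneous buffer capacity beta = 1 + sum B_tot Kd/(Kd+Ca)^2,
    the factor relating total to free Ca increments at equilibrium."""
    Ca = np.asarray(Ca, dtype=float)
    beta = np.ones_like(Ca)
    for s in specs:
        beta = beta + s.total * s.Kd / (s.Kd + Ca) ** 2
    return float(beta) if beta.ndim == 0 else beta
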