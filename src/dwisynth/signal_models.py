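"""Closed-form Bloch-equation signal models and a stepwise verification oracle.

Two sequences are modelled, each by the steady-state analytical solution
of the Bloch equations for longitudinal magnetisation:

Spin echo (T2-weighted)
    S_se = rho * (1 - exp(-TR/T1)) * exp(-TE/T2)

    The 90-degree excitation saturates Mz, which then recovers for TR;
    the echo refocuses static-field inhomogeneity, so the TE decay is
    governed by T2 (not T2*). T1 recovery during TE itself is neglected
    (the standard idealisation; below 1% error for TE << TR).

MPRAGE (T1-weighted, inversion-recovery gradient echo)
    S_mp = | rho * sin(alpha) * (1 - 2 exp(-TI/T1) + exp(-TR/T1))
              * exp(-TE/T2star) |

    Single-excitation simplification of the inversion-prepared gradient
    echo: a perfect 180-degree inversion, recovery for TI, a low-flip
    readout whose echo decays with T2* (gradient echo: no refocusing),
    and the assumption that the readout train fully saturates Mz before
    the remaining TR - TI of recovery. The magnitude is taken because MR
    images are magnitude images: with the default 3T tissue values, CSF
    at TI = 900 ms is past its null but not yet recovered, so its
    pre-magnitude signal is negative and small — which is exactly the
    dark-CSF appearance of a real MPRAGE.

The stepwise oracle (:func:`bloch_oracle`) propagates Mz through an
explicit block sequence until steady state and serves as an independent
check that each closed form is the fixed point of its recursion.

All times are milliseconds; flip angles are degrees at the interface.
Proton density ``rho`` is relative to CSF, so signals are in arbitrary
units on a common scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import ConvergenceError

__all__ = [
    "TissueProperties",
    "MPRAGEParams",
    "SpinEchoParams",
    "PropertyRegistry",
    "default_registry",
    "default_mprage",
    "default_spin_echo",
    "spin_echo_signal",
    "mprage_signal",
    "Inversion",
    "Excitation",
    "Relax",
    "Spoil",
    "bloch_oracle",
    "mprage_blocks",
    "spin_echo_blocks",
]


@dataclass(frozen=True)
class TissueProperties:
    """Relaxometry constants of one tissue at 3T.

    t1, t2, t2star in ms with t2star <= t2 <= t1; rho is proton density
    relative to CSF, in (0, 1].
    """

    t1: float
    t2: float
    t2star: float
    rho: float

    def __post_init__(self) -> None:
        if not (0 < self.t2star <= self.t2 <= self.t1):
            raise ValueError(
                f"require 0 < T2* <= T2 <= T1, got "
                f"T1={self.t1}, T2={self.t2}, T2*={self.t2star}"
            )
        if not 0 < self.rho <= 1:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")


@dataclass(frozen=True)
class MPRAGEParams:
    """MPRAGE acquisition parameters: flip angle (deg), TE, TI, TR (ms)."""

    alpha_deg: float
    te_ms: float
    ti_ms: float
    tr_ms: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha_deg < 90:
            raise ValueError(f"flip angle must be in (0, 90) deg, got {self.alpha_deg}")
        if not 0 < self.te_ms < self.ti_ms < self.tr_ms:
            raise ValueError(
                f"require 0 < TE < TI < TR, got TE={self.te_ms}, "
                f"TI={self.ti_ms}, TR={self.tr_ms}"
            )


@dataclass(frozen=True)
class SpinEchoParams:
    """Spin-echo acquisition parameters: TE, TR (ms)."""

    te_ms: float
    tr_ms: float

    def __post_init__(self) -> None:
        if not 0 < self.te_ms < self.tr_ms:
            raise ValueError(f"require 0 < TE < TR, got TE={self.te_ms}, TR={self.tr_ms}")


@dataclass(frozen=True)
class PropertyRegistry:
    """Relaxometry for the three tissue classes WM, GM, CSF."""

    wm: TissueProperties
    gm: TissueProperties
    csf: TissueProperties

    def __getitem__(self, label: str) -> TissueProperties:
        try:
            return getattr(self, label.lower())
        except AttributeError:
            raise KeyError(label) from None

    def items(self):
        return [("wm", self.wm), ("gm", self.gm), ("csf", self.csf)]


def default_registry() -> PropertyRegistry:
    """3T literature relaxometry for healthy adult WM, GM and CSF.

    These are population averages; subject age and pathology shift them,
    and the registry is overridable through the config file for such
    cases.
    """
    return PropertyRegistry(
        wm=TissueProperties(t1=830.0, t2=80.0, t2star=53.0, rho=0.7),
        gm=TissueProperties(t1=1330.0, t2=110.0, t2star=66.0, rho=0.8),
        csf=TissueProperties(t1=4000.0, t2=1000.0, t2star=250.0, rho=1.0),
    )


def default_mprage() -> MPRAGEParams:
    """ADNI MPRAGE protocol: alpha 9 deg, TE 2.9 ms, TI 900 ms, TR 2300 ms."""
    return MPRAGEParams(alpha_deg=9.0, te_ms=2.9, ti_ms=900.0, tr_ms=2300.0)


def default_spin_echo() -> SpinEchoParams:
    """Clinical T2w spin echo: TE 80 ms, TR 4500 ms."""
    return SpinEchoParams(te_ms=80.0, tr_ms=4500.0)


def spin_echo_signal(params: SpinEchoParams, tissue: TissueProperties) -> float:
    """Steady-state spin-echo signal rho*(1-exp(-TR/T1))*exp(-TE/T2)."""
    return (
        tissue.rho
        * (1.0 - math.exp(-params.tr_ms / tissue.t1))
        * math.exp(-params.te_ms / tissue.t2)
    )


def mprage_signal(
    params: MPRAGEParams, tissue: TissueProperties, signed: bool = False
) -> float:
    """Steady-state MPRAGE signal (simplified IR gradient-echo solution).

    Returns |rho*sin(alpha)*(1 - 2 exp(-TI/T1) + exp(-TR/T1))*exp(-TE/T2*)|,
    or the signed (pre-magnitude) value if ``signed`` is true — useful for
    inspecting which side of the inversion null a tissue sits on.
    """
    value = (
        tissue.rho
        * math.sin(math.radians(params.alpha_deg))
        * (
            1.0
            - 2.0 * math.exp(-params.ti_ms / tissue.t1)
            + math.exp(-params.tr_ms / tissue.t1)
        )
        * math.exp(-params.te_ms / tissue.t2star)
    )
    return value if signed else abs(value)


# --- stepwise magnetisation-propagation oracle ---------------------------


@dataclass(frozen=True)
class Inversion:
    """Perfect 180-degree inversion pulse: Mz -> -Mz."""


@dataclass(frozen=True)
class Excitation:
    """RF excitation that records a signal sample.

    Records Mz * sin(alpha) * exp(-TE/decay) where ``decay`` names the
    transverse constant governing the echo ("t2" for spin echo, "t2star"
    for gradient echo). If the oracle's saturation flag is set, Mz is
    reduced to Mz*cos(alpha) by the pulse; otherwise Mz is untouched.
    """

    alpha_deg: float
    te_ms: float
    decay: str = "t2"  # "t2" or "t2star"


@dataclass(frozen=True)
class Relax:
    """Free T1 recovery for t ms: Mz -> rho + (Mz - rho) * exp(-t/T1)."""

    t_ms: float


@dataclass(frozen=True)
class Spoil:
    """Complete saturation of longitudinal magnetisation: Mz -> 0.

    Models a readout train that consumes all longitudinal magnetisation
    (spin-echo 90-degree excitation, or the idealised MPRAGE readout the
    simplified closed form assumes).
    """


def bloch_oracle(
    sequence: list,
    tissue: TissueProperties,
    n_cycles: int = 200,
    saturation: bool = True,
    tol: float = 1e-9,
) -> float:
    """Propagate Mz through repeated sequence cycles to steady state.

    Starts from thermal equilibrium Mz = rho and repeats the block list
    ``n_cycles`` times at most, returning the signal recorded in the last
    cycle once consecutive-cycle signals differ by less than ``tol``.

    This is deliberately a brute-force recursion with no closed-form
    shortcuts, so it can independently confirm that each analytical
    signal expression is the fixed point of its sequence.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    mz = tissue.rho
    prev_signal = None
    signal = None
    for _ in range(n_cycles):
        signal = None
        for block in sequence:
            if isinstance(block, Inversion):
                mz = -mz
            elif isinstance(block, Relax):
                mz = tissue.rho + (mz - tissue.rho) * math.exp(-block.t_ms / tissue.t1)
            elif isinstance(block, Spoil):
                mz = 0.0
            elif isinstance(block, Excitation):
                decay_ms = tissue.t2 if block.decay == "t2" else tissue.t2star
                alpha = math.radians(block.alpha_deg)
                signal = mz * math.sin(alpha) * math.exp(-block.te_ms / decay_ms)
                if saturation:
                    mz = mz * math.cos(alpha)
            else:
                raise TypeError(f"unknown block {block!r}")
        if signal is None:
            raise ValueError("sequence records no signal (no Excitation block)")
        if prev_signal is not None and abs(signal - prev_signal) < tol:
            return signal
        prev_signal = signal
    delta = "n/a" if prev_signal is None else f"{abs(signal - prev_signal):.3g}"
    raise ConvergenceError(f"no steady state after {n_cycles} cycles; last signal change {delta}")


def spin_echo_blocks(params: SpinEchoParams) -> list:
    """Spin-echo cycle: saturating 90-degree excitation, then TR of recovery."""
    return [Excitation(alpha_deg=90.0, te_ms=params.te_ms, decay="t2"), Relax(params.tr_ms)]


def mprage_blocks(params: MPRAGEParams) -> list:
    """MPRAGE cycle matching the simplified closed form.

    Inversion, TI of recovery, the low-flip readout (T2* echo decay)
    followed by a spoiler representing complete readout saturation, then
    TR - TI of recovery. The spoiler is what makes the simplified closed
    form the exact fixed point; without it the steady state carries an
    extra factor 1/(1 + exp(-TR/T1)) from incomplete saturation.
    """
    return [
        Inversion(),
        Relax(params.ti_ms),
        Excitation(alpha_deg=params.alpha_deg, te_ms=params.te_ms, decay="t2star"),
        Spoil(),
        Relax(params.tr_ms - params.ti_ms),
    ]
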