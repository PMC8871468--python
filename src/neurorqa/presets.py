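"""Named configurations for the experiments studied with this package.

The single-neuron regimes (n-spike bursting, chaos, single-spike firing)
arise from one membrane parameter set under different field frequencies;
the coupled experiments use a slightly mismatched pair (different ``u2``
and ``u3``) so that the two chaotic bursters have a genuine frequency
mismatch for coupling and field to overcome.
"""

from __future__ import annotations

import numpy as np

from .model import CoupledConfig, EFStimulus, MLParams
from .recurrence import EMBEDDING_PRESETS

__all__ = [
    "REGIME_OMEGAS",
    "mismatched_pair",
    "coupled_config",
    "single_stimulus",
    "EMBEDDING_PRESETS",
]

#: Field frequencies (rad/ms) producing the four reference firing regimes.
REGIME_OMEGAS: dict[str, float] = {
    "4_spike": 0.05,
    "2_spike": 0.10,
    "chaos": 0.286,
    "1_spike": 0.5,
}


def single_stimulus(omega: float | np.ndarray = 0.286, A: float = 0.1) -> EFStimulus:
    """Stimulus with the standard direct-voltage offset VE = −17.63 mV."""
    return EFStimulus(A=A, omega=omega, VE=-17.63)


def mismatched_pair(
    u2: tuple[float, float] = (18.0, 18.1),
    u3: tuple[float, float] = (-12.8, -10.0),
    u2_sign: int = +1,
) -> tuple[MLParams, MLParams]:
    """The slightly mismatched neuron pair used in the coupling experiments.

    ``u2_sign=-1`` flips the sign of both u2 values (an alternative
    parameterization that leaves the pair quiescent; kept available for
    comparison — the positive-sign pair is the one that bursts chaotically).
    """
    return (
        MLParams(u2=u2_sign * abs(u2[0]), u3=u3[0]),
        MLParams(u2=u2_sign * abs(u2[1]), u3=u3[1]),
    )


def coupled_config(
    g: float | np.ndarray = 0.0,
    A: float = 0.0,
    omega: float = 0.286,
    u2_sign: int = +1,
) -> CoupledConfig:
    """Standard coupled-pair configuration: mismatched chaotic bursters,
    initial conditions v1(0)=−65.6 mV, v2(0)=−60 mV, w(0)=0."""
    p1, p2 = mismatched_pair(u2_sign=u2_sign)
    return CoupledConfig(
        params1=p1, params2=p2, g=g, stimulus=single_stimulus(omega=omega, A=A)
    )
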