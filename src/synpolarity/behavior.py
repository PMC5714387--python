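"""Markov model linking motor-pool activities to locomotory states.

The worm occupies one of three locomotory states — forward, backward, stop —
with no direct forward<->backward transitions.  Arrhenius-type rates driven by
the motor-pool voltage difference E_f - E_b yield closed-form stationary
probabilities and a sigmoidal forward-time ratio

    R = T_f / (T_f + T_b) = 1 / (1 + exp[(E_b - E_f)/eta]),

which is independent of the stop threshold Delta and the basal rate W_o.
Those two constants only set the stop-state occupancy and the transition time
scale; defaults Delta = 5 mV, W_o = 1 Hz are used when P_s or trajectories
are requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import expit, logsumexp

__all__ = [
    "TransitionRates",
    "BehaviorOutcome",
    "transition_rates",
    "stationary_probabilities",
    "forward_ratio",
    "integrate_master_equation",
    "DEFAULT_DELTA",
    "DEFAULT_W_O",
]

DEFAULT_DELTA = 5.0  # mV, threshold separating motion from stop
DEFAULT_W_O = 1.0    # Hz, basal transition rate


@dataclass(frozen=True)
class TransitionRates:
    """Rates between the three behavioral states (Hz)."""

    W_fs: float  # stop -> forward
    W_bs: float  # stop -> backward
    W_sf: float  # forward -> stop
    W_sb: float  # backward -> stop
    W_o: float
    Delta: float

    @property
    def matrix(self) -> np.ndarray:
        """Generator matrix Q for p = (P_f, P_s, P_b); columns sum to zero.

        The forward<->backward entries are structurally zero: those
        transitions pass through the stop state.
        """
        return np.array(
            [
                [-self.W_sf, self.W_fs, 0.0],
                [self.W_sf, -(self.W_fs + self.W_bs), self.W_sb],
                [0.0, self.W_bs, -self.W_sb],
            ]
        )


@dataclass(frozen=True)
class BehaviorOutcome:
    P_f: float
    P_b: float
    P_s: float
    Z: float
    R: float


def transition_rates(
    E_f: float,
    E_b: float,
    eta: float,
    W_o: float = DEFAULT_W_O,
    Delta: float = DEFAULT_DELTA,
) -> TransitionRates:
    """Arrhenius-type rates; note the 4 eta in the denominator of the exponents."""
    if eta <= 0:
        raise ValueError("eta must be > 0")
    if W_o <= 0:
        raise ValueError("W_o must be > 0")
    x = (E_f - E_b - Delta) / (4.0 * eta)
    y = (E_b - E_f - Delta) / (4.0 * eta)
    return TransitionRates(
        W_fs=W_o * np.exp(x),
        W_bs=W_o * np.exp(y),
        W_sf=W_o * np.exp(-x),
        W_sb=W_o * np.exp(-y),
        W_o=W_o,
        Delta=Delta,
    )


def stationary_probabilities(
    E_f: float, E_b: float, eta: float, Delta: float = DEFAULT_DELTA
) -> BehaviorOutcome:
    """Closed-form stationary distribution of the three-state chain.

    P_f : exp[(E_f-E_b)/(2 eta)] / Z,  P_b : the mirror term,
    P_s : exp[Delta/(2 eta)] / Z,  with
    Z = 2 cosh[(E_f-E_b)/(2 eta)] + exp[Delta/(2 eta)].
    Evaluated through log-sum-exp so large |E_f-E_b|/eta cannot overflow.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    x = (E_f - E_b) / (2.0 * eta)
    logits = np.array([x, -x, Delta / (2.0 * eta)])
    logz = logsumexp(logits)
    pf, pb, ps = np.exp(logits - logz)
    with np.errstate(over="ignore"):
        z = float(np.exp(logz))  # may be inf at extreme drive; probabilities are safe
    return BehaviorOutcome(
        P_f=float(pf),
        P_b=float(pb),
        P_s=float(ps),
        Z=z,
        R=float(forward_ratio(E_f, E_b, eta)),
    )


def forward_ratio(E_f, E_b, eta: float):
    """Forward-time ratio R = 1 / (1 + exp[(E_b - E_f)/eta]).

    A sigmoid of the motor-pool voltage difference; independent of Delta and
    W_o, which cancel in the ratio of dwelling times.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    return expit((np.asarray(E_f, dtype=float) - E_b) / eta)


def integrate_master_equation(
    rates: TransitionRates,
    p0,
    t_end: float,
    n_steps: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability trajectory of the master equation for p = (P_f, P_s, P_b).

    The chain is linear, so the trajectory is computed exactly as
    p(t) = expm(Q t) p0 on a uniform time grid; probability is conserved to
    machine precision.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (3,) or np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must be a probability 3-vector")
    times = np.linspace(0.0, t_end, n_steps + 1)
    step = expm(rates.matrix * (times[1] - times[0]))
    traj = np.empty((times.size, 3))
    traj[0] = p0
    for k in range(1, times.size):
        traj[k] = step @ traj[k - 1]
    return times, traj
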