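"""Goal function: standardized Euclidean distance over the ablation panel.

A candidate configuration (polarities, input pattern, physiological
parameters) is scored by computing the stationary motor-pool activities for
every circuit variant in the panel, mapping them to forward-time ratios R,
and taking the standardized Euclidean distance

    SED = sqrt( sum_i [(R_th_i - R_exp_i) / SD_exp_i]^2 )

to the behavioral table.  The per-variant steady states are independent of
each other, so evaluation is order-independent and embarrassingly parallel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import forward_ratio
from .connectome import AblationSpec, Connectome, ConnectionSet
from .neurodynamics import (
    CircuitEnsemble,
    InputPattern,
    PhysioParams,
    PolarityMatrix,
    SolverConfig,
    SteadyStateResult,
)

__all__ = ["BehavioralData", "SEDResult", "sed", "PanelEvaluator", "evaluate"]


@dataclass(frozen=True)
class BehavioralData:
    """Per-variant forward-motion ratios and their standard deviations."""

    labels: tuple[str, ...]
    r_exp: np.ndarray
    sd_exp: np.ndarray
    panel: tuple[AblationSpec, ...]

    def __post_init__(self):
        n = len(self.labels)
        if not (len(self.r_exp) == len(self.sd_exp) == len(self.panel) == n):
            raise ValueError("labels, r_exp, sd_exp and panel must have equal length")
        if np.any(self.sd_exp <= 0):
            raise ValueError("every SD_exp must be > 0")
        if np.any((self.r_exp < 0) | (self.r_exp > 1)):
            raise ValueError("R_exp values must lie in [0, 1]")
        for label, ab in zip(self.labels, self.panel):
            if label != ab.label:
                raise ValueError(f"row label {label!r} does not match panel {ab.label!r}")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, panel: Sequence[AblationSpec]) -> "BehavioralData":
        by_label = {ab.label: ab for ab in panel}
        specs = tuple(by_label[lab] for lab in df["variant"])
        return cls(
            labels=tuple(df["variant"]),
            r_exp=df["R_exp"].to_numpy(dtype=float),
            sd_exp=df["SD_exp"].to_numpy(dtype=float),
            panel=specs,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, panel: Sequence[AblationSpec]) -> "BehavioralData":
        return cls.from_frame(pd.read_csv(path, sep="\t"), panel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant": self.labels, "R_exp": self.r_exp, "SD_exp": self.sd_exp}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SEDResult:
    sed: float
    per_variant: pd.DataFrame  # variant, R_exp, SD_exp, R_th, residual, converged

    def to_tsv(self, path: str | Path) -> None:
        self.per_variant.to_csv(path, sep="\t", index=False)


def sed(r_th, r_exp, sd_exp) -> float:
    """Standardized Euclidean distance between predictions and data.

    With 18 variants each off by exactly one standard deviation this equals
    sqrt(18) ~ 4.24.
    """
    r_th = np.asarray(r_th, dtype=float)
    r_exp = np.asarray(r_exp, dtype=float)
    sd_exp = np.asarray(sd_exp, dtype=float)
    if not (r_th.shape == r_exp.shape == sd_exp.shape):
        raise ValueError("r_th, r_exp and sd_exp must have equal length")
    if np.any(sd_exp == 0):
        raise ValueError("sd_exp entries must be nonzero")
    z = (r_th - r_exp) / sd_exp
    return float(np.sqrt(np.sum(z * z)))


class PanelEvaluator:
    """Reusable evaluator of configurations against a behavioral panel.

    Builds the batched circuit ensemble once per (connectome, panel, solver)
    and caches SED values by configuration, which matters inside the genetic
    algorithm where converged populations re-propose identical genomes.
    """

    def __init__(
        self,
        connectome: Connectome,
        connset: ConnectionSet,
        data: BehavioralData,
        solver: SolverConfig | None = None,
    ):
        if len(data) == 0:
            raise ValueError("behavioral panel is empty")
        self.connectome = connectome
        self.connset = connset
        self.data = data
        self.ensemble = CircuitEnsemble(
            connectome, connset, list(data.panel), solver=solver
        )
        self._cache: dict = {}

    def ratios(
        self, eps: PolarityMatrix, sigma: InputPattern, params: PhysioParams
    ) -> tuple[np.ndarray, list[SteadyStateResult]]:
        """Theoretical R per variant plus the underlying steady states."""
        self.ensemble.configure(eps, sigma, params)
        states = self.ensemble.steady_states()
        r = np.array(
            [forward_ratio(s.state.E_f, s.state.E_b, params.eta) for s in states]
        )
        return r, states

    def __call__(
        self, eps: PolarityMatrix, sigma: InputPattern, params: PhysioParams
    ) -> SEDResult:
        r_th, states = self.ratios(eps, sigma, params)
        conv = np.array([s.converged for s in states])
        resid = (r_th - self.data.r_exp) / self.data.sd_exp
        if not conv.all():
            # documented penalty keeps the search well-defined without
            # silently treating a failed solve as a real prediction
            base = np.max(np.abs(resid[conv])) if conv.any() else 1.0
            resid = resid.copy()
            resid[~conv] = 10.0 * max(base, 1.0)
        table = pd.DataFrame(
            {
                "variant": self.data.labels,
                "R_exp": self.data.r_exp,
                "SD_exp": self.data.sd_exp,
                "R_th": r_th,
                "residual": resid,
                "converged": conv,
            }
        )
        return SEDResult(sed=float(np.sqrt(np.sum(resid * resid))), per_variant=table)

    def sed_cached(
        self,
        key: bytes,
        eps: PolarityMatrix,
        sigma: InputPattern,
        params: PhysioParams,
    ) -> float:
        """SED keyed by an externally supplied configuration fingerprint."""
        hit = self._cache.get(key)
        if hit is None:
            hit = self(eps, sigma, params).sed
            self._cache[key] = hit
        return hit


def evaluate(
    c: Connectome,
    cs: ConnectionSet,
    eps: PolarityMatrix,
    sigma: InputPattern,
    p: PhysioParams,
    data: BehavioralData,
    solver: SolverConfig | None = None,
) -> SEDResult:
    """Score one configuration across the ablation panel."""
    return PanelEvaluator(c, cs, data, solver=solver)(eps, sigma, p)
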