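"""Model/Results facade for fitting synaptic polarities to behavioral data.

``CircuitPolarityModel`` bundles a connectome, an ablation panel with its
behavioral table, and the search configuration; ``fit()`` runs the island
genetic algorithm and returns a ``CircuitPolarityResults`` carrying the
decoded optimum, its SED, the optimization history, and the post-fit
sensitivity analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import (
    AblationSpec,
    Connectome,
    ConnectionSet,
    default_connectome,
    reduce_by_cutoff,
)
from .neurodynamics import (
    InputPattern,
    PhysioParams,
    PolarityMatrix,
    SolverConfig,
)
from .objective import BehavioralData, PanelEvaluator, SEDResult
from .optimizer import (
    CONTINUOUS_ORDER,
    GAConfig,
    GenomeLayout,
    OptimizationResult,
    run_islands,
)
from . import sensitivity as _sens

__all__ = ["CircuitPolarityModel", "CircuitPolarityResults"]


class CircuitPolarityModel:
    """Inverse model of the pre-motor circuit fitted to ablation behavior.

    Parameters
    ----------
    data
        Behavioral table (one forward-ratio row per ablation variant).
    connectome
        Circuit graph; defaults to the packaged 9-node fixture.
    cutoff
        Mean-contact-count threshold below which connections are removed
        from the dynamics (default 0.75).
    n_free
        If given, only the n strongest connections are optimized; weaker
        above-cutoff connections stay in the dynamics pinned inhibitory.
    optimize_fields
        Continuous parameters included in the genome (subset of
        q_s, q_e, X_o, c_ash, f_ash, eta); empty tuple fixes them all at
        ``base_params``.
    optimize_sigma
        Whether the input pattern is part of the genome.
    """

    def __init__(
        self,
        data: BehavioralData,
        connectome: Connectome | None = None,
        cutoff: float = 0.75,
        n_free: int | None = None,
        base_params: PhysioParams | None = None,
        optimize_fields: Sequence[str] = CONTINUOUS_ORDER,
        optimize_sigma: bool = True,
        solver: SolverConfig | None = None,
    ):
        self.data = data
        self.connectome = connectome or default_connectome()
        self.connset: ConnectionSet = reduce_by_cutoff(self.connectome, cutoff)
        if n_free is not None:
            self.connset = self.connset.restrict(n_free)
        self.base_params = base_params or PhysioParams()
        self.solver = solver or SolverConfig()
        self.evaluator = PanelEvaluator(
            self.connectome, self.connset, data, solver=self.solver
        )
        receivers = tuple(self.evaluator.ensemble.dyn)
        self.layout = GenomeLayout(
            base_params=self.base_params,
            continuous_fields=tuple(optimize_fields),
            sigma_neurons=receivers if optimize_sigma else (),
            eps_connections=tuple(self.connset.free),
        )
        self._default_sigma = InputPattern.uniform(receivers, 1)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        panel: Sequence[AblationSpec],
        **kwargs,
    ) -> "CircuitPolarityModel":
        """Build from a DataFrame with columns variant, R_exp, SD_exp."""
        return cls(BehavioralData.from_frame(df, panel), **kwargs)

    # -- evaluation --------------------------------------------------------

    def _materialize(self, genome: np.ndarray):
        params, sigma_bits, eps_bits = self.layout.decode(genome)
        sigma = InputPattern(sigma_bits) if sigma_bits else self._default_sigma
        eps = PolarityMatrix.for_connection_set(self.connset, eps_bits)
        return params, sigma, eps

    def _objective(self, genome: np.ndarray) -> float:
        params, sigma, eps = self._materialize(genome)
        return self.evaluator.sed_cached(genome.tobytes(), eps, sigma, params)

    def evaluate(
        self,
        polarity: PolarityMatrix | Mapping | None = None,
        sigma: InputPattern | None = None,
        params: PhysioParams | None = None,
    ) -> SEDResult:
        """Score one explicit configuration across the panel."""
        if polarity is None:
            polarity = PolarityMatrix.all_inhibitory(self.connset)
        elif not isinstance(polarity, PolarityMatrix):
            polarity = PolarityMatrix.for_connection_set(self.connset, polarity)
        sigma = sigma or self._default_sigma
        params = params or self.base_params
        return self.evaluator(polarity, sigma, params)

    # -- fitting -----------------------------------------------------------

    def fit(self, config: GAConfig | None = None, seed: int | None = None
            ) -> "CircuitPolarityResults":
        """Minimize SED with the island genetic algorithm."""
        config = config or GAConfig()
        if seed is not None:
            config = GAConfig(**{**config.__dict__, "seed": seed})
        opt = run_islands(self._objective, self.layout, config)
        params, sigma, eps = self._materialize(opt.best_genome)
        return CircuitPolarityResults(
            model=self, optimization=opt, params=params, sigma=sigma, polarity=eps,
        )


@dataclass
class CircuitPolarityResults:
    """Fitted configuration with its diagnostics and sensitivity analyses."""

    model: CircuitPolarityModel
    optimization: OptimizationResult
    params: PhysioParams
    sigma: InputPattern
    polarity: PolarityMatrix
    _fit: SEDResult | None = field(default=None, repr=False)

    @property
    def sed(self) -> float:
        return self.optimization.best_sed

    @property
    def fitted(self) -> SEDResult:
        if self._fit is None:
            self._fit = self.model.evaluator(self.polarity, self.sigma, self.params)
        return self._fit

    @property
    def per_variant(self) -> pd.DataFrame:
        return self.fitted.per_variant

    # -- sensitivity -------------------------------------------------------

    def flip_scan(self) -> pd.DataFrame:
        return _sens.flip_scan(self.model.evaluator, self.polarity, self.sigma, self.params)

    def input_pattern_scan(self) -> pd.DataFrame:
        return _sens.input_pattern_scan(self.model.evaluator, self.polarity, self.params)

    def parameter_sweep(self, which: str, grid=None) -> pd.DataFrame:
        if grid is None:
            grid = _sens.default_sweep_grid(getattr(self.params, which))
        return _sens.parameter_sweep(
            which, grid, self.model.evaluator, self.polarity, self.sigma, self.params
        )

    def ablation_report(self):
        return _sens.ablation_report(
            self.model.evaluator, self.polarity, self.sigma, self.params
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        opt = self.optimization
        lines = [
            "Circuit polarity fit (island genetic algorithm)",
            "=" * 55,
            f"SED at optimum            {self.sed:10.4f}",
            f"variants                  {len(self.model.data):10d}",
            f"free connections          {len(self.model.connset.free):10d}",
            f"migrations / evaluations  {opt.n_migrations:6d} / {opt.n_evaluations}",
            "",
            "Optimized parameters",
            "-" * 55,
        ]
        for name in self.model.layout.continuous_fields or ("(all fixed)",):
            if name.startswith("("):
                lines.append(name)
            else:
                lines.append(f"  {name:8s} {getattr(self.params, name):10.4f}")
        lines += ["", "Input pattern sigma", "-" * 55]
        for n, s in self.sigma.sigma.items():
            lines.append(f"  {n:8s} {s:+d}")
        lines += ["", "Synaptic polarities (free connections)", "-" * 55]
        for conn in self.model.connset.free:
            kind = "excitatory" if self.polarity[conn] else "inhibitory"
            w = self.model.connectome.weight(*conn)
            lines.append(f"  {conn[0]:>4s} -> {conn[1]:<4s} (w={w:5.2f})  {kind}")
        lines += ["", "Per-variant fit", "-" * 55]
        for _, row in self.per_variant.iterrows():
            lines.append(
                f"  {row['variant']:<14s} R_exp={row['R_exp']:.3f} "
                f"R_th={row['R_th']:.3f} resid={row['residual']:+.2f}"
            )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write the fit as JSON + TSV traces under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        obj = {
            "sed": self.sed,
            "params": {f: getattr(self.params, f) for f in CONTINUOUS_ORDER},
            "sigma": dict(self.sigma.sigma),
            "polarity": {f"{a}->{b}": v for (a, b), v in self.polarity.eps.items()},
            "history": list(self.optimization.history),
            "n_migrations": self.optimization.n_migrations,
            "n_evaluations": self.optimization.n_evaluations,
        }
        (out / "fit.json").write_text(json.dumps(obj, indent=1))
        self.per_variant.to_csv(out / "per_variant.tsv", sep="\t", index=False)
        hist = pd.DataFrame(
            {
                "migration": np.arange(1, len(self.optimization.history) + 1),
                "best_sed": self.optimization.history,
            }
        )
        hist.to_csv(out / "history.tsv", sep="\t", index=False)

    def plot_fit(self, ax=None):
        """Experimental vs fitted forward ratios per variant."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        df = self.per_variant
        x = np.arange(len(df))
        ax.errorbar(x, df["R_exp"], yerr=df["SD_exp"], fmt="o", label="data",
                    color="tab:blue", capsize=3)
        ax.plot(x, df["R_th"], "s", color="tab:red", label="model")
        ax.set_xticks(x)
        ax.set_xticklabels(df["variant"], rotation=60, ha="right", fontsize=7)
        ax.set_ylabel("forward ratio R")
        ax.legend()
        return ax
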