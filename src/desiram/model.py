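"""Model/Results interface over the decipherment pipeline.

Two fitted-model objects cover the package's two estimation stages:

* :class:`SixLineTemplateModel` -- fit the six-line template to one CW-bias
  trace; its :class:`TemplateFitResults` carries the template geometry, the
  15-index characteristic vector and the residual diagnostics.
* :class:`ChemicalDeciphermentModel` -- learn the per-chemical dose-response
  model functions from a labelled training set; its
  :class:`DeciphermentResults` exposes classification, concentration
  estimation, leave-one-out benchmarking and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation
from .classifier import ClassifierConfig, PosteriorResult, posterior
from .concentration import ModelSet, TrainingSet, fit_model_functions
from .template import (
    INDEX_DESCRIPTIONS,
    N_INDICES,
    CharacteristicVector,
    SixLineTemplate,
    TemplateFitConfig,
    fit_template,
    render_template,
    template_to_vector,
)
from .traces import CWBiasTrace


class SixLineTemplateModel:
    """Six-line template model for a single ensemble CW-bias trace."""

    def __init__(self, trace: CWBiasTrace, config: TemplateFitConfig | None = None):
        self.trace = trace
        self.config = config or TemplateFitConfig()

    def fit(self) -> "TemplateFitResults":
        tpl, rms = fit_template(self.trace, self.config)
        return TemplateFitResults(model=self, template=tpl, rms=rms)


@dataclass
class TemplateFitResults:
    """Fitted template for one trace."""

    model: SixLineTemplateModel
    template: SixLineTemplate
    rms: float

    def vector(self, label="UNKNOWN", concentration=float("nan")) -> CharacteristicVector:
        return template_to_vector(
            self.template, self.rms, label=label, concentration=concentration
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return render_template(self.template, self.model.trace.times)

    @property
    def resid(self) -> np.ndarray:
        return self.model.trace.values - self.fittedvalues

    def summary(self) -> str:
        tpl = self.template
        v = self.vector()
        lines = [
            "Six-line template fit",
            "=" * 44,
            f"bins (non-missing)    {len(self.model.trace) - self.model.trace.n_missing:>10d}",
            f"RMS residual          {self.rms:>10.4f}",
            f"baseline b (L1)       {tpl.b:>10.4f}",
            f"response r (L2)       {tpl.r:>10.4f}",
            f"final g (L6)          {tpl.g:>10.4f}",
            f"breakpoints t1..t5    " + "  ".join(f"{t:7.1f}" for t in tpl.breakpoints),
            "-" * 44,
        ]
        for i in range(N_INDICES):
            lines.append(f"y{i + 1:<3d} {v.y[i]:>12.4f}   {INDEX_DESCRIPTIONS[i]}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the fitted template on the trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.trace.times
        ax.plot(t, self.model.trace.values, ".", ms=3, alpha=0.6, label="CW bias")
        ax.plot(t, self.fittedvalues, "-", lw=2, label="template")
        ax.axvline(self.template.t1, color="k", ls=":", lw=1, label="stimulus")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("CW bias")
        ax.set_ylim(-0.02, 1.0)
        ax.legend(frameon=False)
        return ax


class ChemicalDeciphermentModel:
    """Decipherment model: dose-response regressions feeding a Bayesian
    posterior over chemical identity with the concentration marginalised."""

    def __init__(
        self,
        training: TrainingSet,
        basis: str = "linear",
        classifier_config: ClassifierConfig | None = None,
    ):
        self.training = training
        self.basis = basis
        self.classifier_config = classifier_config or ClassifierConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ChemicalDeciphermentModel":
        """Build from a frame with columns y1..y15, label, concentration_mM."""
        return cls(TrainingSet.from_dataframe(df), **kwargs)

    def fit(self) -> "DeciphermentResults":
        models = fit_model_functions(self.training, basis=self.basis)
        return DeciphermentResults(model=self, model_set=models)


@dataclass
class DeciphermentResults:
    """Learned model functions plus the classification interface."""

    model: ChemicalDeciphermentModel
    model_set: ModelSet

    @property
    def chemicals(self) -> list:
        return list(self.model_set.chemicals)

    def posterior(self, vector: CharacteristicVector) -> PosteriorResult:
        return posterior(vector, self.model_set, self.model.classifier_config)

    def classify(self, vectors) -> list:
        """Maximum-posterior label for each vector."""
        if isinstance(vectors, CharacteristicVector):
            vectors = [vectors]
        return [self.posterior(v).decision for v in vectors]

    def predict_proba(self, vectors) -> pd.DataFrame:
        if isinstance(vectors, CharacteristicVector):
            vectors = [vectors]
        rows = [self.posterior(v).probabilities for v in vectors]
        return pd.DataFrame(rows, columns=self.chemicals)

    def estimate_concentration(self, vector: CharacteristicVector, chemical: str) -> float:
        if chemical not in self.chemicals:
            from .exceptions import BadConfigError

            raise BadConfigError(f"unknown chemical {chemical!r}")
        return self.posterior(vector).profiles[chemical].map_concentration

    def loo_accuracy(self, group=None, rs_seed: int = 0, rs_reps: int = 100_000):
        return evaluation.loo_accuracy(
            self.model.training,
            group=group,
            basis=self.model.basis,
            classifier_config=self.model.classifier_config,
            rs_seed=rs_seed,
            rs_reps=rs_reps,
        )

    def accuracy_spectrum(self, k: int, rs_seed: int = 0, rs_reps: int = 10_000):
        return evaluation.accuracy_spectrum(
            self.model.training,
            k,
            basis=self.model.basis,
            classifier_config=self.model.classifier_config,
            rs_seed=rs_seed,
            rs_reps=rs_reps,
        )

    def summary(self, indices=(1, 2, 4)) -> str:
        """Per-chemical table of the fitted dose-response models.

        Shows intercept/slope (and curvature for the quadratic basis) plus
        the residual scale for the selected indices.
        """
        lines = [
            "Chemical decipherment model",
            "=" * 64,
            f"chemicals: {len(self.chemicals)}   basis: {self.model_set.basis}   "
            f"records: {len(self.model.training)}",
            "-" * 64,
            f"{'chemical':<10}{'index':>6}{'intercept':>12}{'slope':>10}{'sigma':>10}"
            f"{'x range (mM)':>16}",
        ]
        for s in self.chemicals:
            for i in indices:
                f = self.model_set.function(s, i)
                slope = f.coef[1] if f.coef.size > 1 else 0.0
                lines.append(
                    f"{s:<10}{'y' + str(i):>6}{f.coef[0]:>12.3f}{slope:>10.3f}"
                    f"{f.sigma:>10.3f}{f.x_lo:>8.3g} -{f.x_hi:>6.3g}"
                )
        return "\n".join(lines)

    def plot_model_functions(self, index: int = 1, ax=None, n_points: int = 100):
        """Index value versus log concentration, one curve per chemical."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.chemicals:
            f = self.model_set.function(s, index)
            x = np.logspace(np.log10(f.x_lo), np.log10(f.x_hi), n_points)
            (line,) = ax.plot(x, f.predict(x), label=s)
            recs = [r for r in self.model.training.records if r.label == s]
            ax.plot(
                [r.concentration for r in recs],
                [r.y[index - 1] for r in recs],
                "o", ms=4, color=line.get_color(), alpha=0.6,
            )
        ax.set_xscale("log")
        ax.set_xlabel("concentration (mM)")
        ax.set_ylabel(f"y{index}")
        ax.legend(frameon=False, fontsize=8)
        return ax
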