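"""Model/Results interface over the fitting and time-course machinery.

`SaccadeDDM` is the package's front door for the diffusion analysis: build
it from a trial table, call :meth:`SaccadeDDM.fit` for one variant or
:meth:`SaccadeDDM.fit_family` for the eight-variant comparison, and read
estimates, diagnostics and summary tables off the returned results
objects. `SmartTimecourse` plays the same role for the smoothed
time-course analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fitting, smart
from .inference import ParameterEffectsReport, parameter_effects
from .params import CONDITIONS, VariantSpec, all_variants
from .session import Session, read_trials


def _as_session(data) -> Session:
    if isinstance(data, Session):
        return data
    if isinstance(data, pd.DataFrame):
        return Session(data)
    return read_trials(data)


class SaccadeDDM:
    """Two-boundary diffusion model of dual-saccade target selection.

    Each trial's second-saccade choice (face vs noise) and fixation
    duration on the inspection target are modelled jointly as the outcome
    of a Wiener evidence-accumulation process; the model family frees
    drift rate, boundary separation and/or non-decision time across the
    four inspection x preview conditions. Fitting is per participant, by
    the Kolmogorov–Smirnov criterion on the signed response-time
    distribution.

    Parameters
    ----------
    data : Session, DataFrame or path
        Trial table with the documented columns.
    options : FitOptions, optional
        Fitting options applied to every participant.
    """

    def __init__(self, data, options: fitting.FitOptions | None = None):
        self.session = _as_session(data)
        self.options = options or fitting.FitOptions()

    @classmethod
    def from_csv(cls, path, options=None) -> "SaccadeDDM":
        return cls(read_trials(path), options=options)

    def fit(self, variant=("v", "t0"), options=None) -> "SaccadeDDMResults":
        """Fit one variant to every participant."""
        spec = variant if isinstance(variant, VariantSpec) else VariantSpec(frozenset(variant))
        opts = options or self.options
        fits = {
            pid: fitting.fit_variant(self.session.for_participant(pid), spec, opts)
            for pid in self.session.participants
        }
        return SaccadeDDMResults(model=self, variant=spec, fits=fits)

    def fit_family(self, options=None) -> "DDMFamilyResults":
        """Fit all eight variants to every participant."""
        opts = options or self.options
        family = {
            pid: fitting.fit_all_variants(self.session.for_participant(pid), opts)
            for pid in self.session.participants
        }
        return DDMFamilyResults(model=self, family=family)


@dataclass
class SaccadeDDMResults:
    """Per-participant fits of a single model variant."""

    model: SaccadeDDM
    variant: VariantSpec
    fits: dict  # participant -> VariantFit

    @property
    def params(self) -> pd.DataFrame:
        """Tidy table: one row per participant x condition."""
        rows = []
        for pid, fit in self.fits.items():
            for c in CONDITIONS:
                p = fit.params_by_condition[c]
                rows.append(
                    {"participant_id": pid, "condition": c, "a": p.a, "zr": p.zr,
                     "v": p.v, "t0": p.t0, "sv": p.sv, "sz": p.sz, "st0": p.st0,
                     "ks": fit.ks_by_condition[c], "objective": fit.objective,
                     "bic": fit.bic, "converged": fit.converged}
                )
        return pd.DataFrame(rows)

    def parameter_effects(self) -> ParameterEffectsReport:
        """Group-level ANOVAs and tests over the fitted parameters."""
        return parameter_effects(self.params)

    def condition_means(self) -> pd.DataFrame:
        tab = self.params.groupby("condition")[["v", "t0", "a"]].agg(["mean", "sem"])
        return tab.reindex(CONDITIONS)

    def summary(self) -> str:
        lines = [
            f"SaccadeDDM variant '{self.variant.name}' "
            f"(k = {self.variant.k}), {len(self.fits)} participants",
            "",
            self.condition_means().to_string(float_format="%.3f"),
            "",
            "mean KS distance: %.4f; %d/%d fits converged"
            % (
                np.mean([f.objective for f in self.fits.values()]),
                sum(f.converged for f in self.fits.values()),
                len(self.fits),
            ),
        ]
        return "\n".join(lines)


@dataclass
class DDMFamilyResults:
    """The eight-variant family fitted to every participant."""

    model: SaccadeDDM
    family: dict  # participant -> {variant name -> VariantFit}
    _weights: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def information_weights(self) -> pd.DataFrame:
        """Participants x variants BIC information weights."""
        if self._weights is None:
            names = [v.name for v in all_variants()]
            rows = {
                pid: fitting.information_weights([fits[n].bic for n in names])
                for pid, fits in self.family.items()
            }
            self._weights = pd.DataFrame.from_dict(rows, orient="index", columns=names)
        return self._weights

    def select(self):
        """Winning variant by mean information weight, plus the full table."""
        return fitting.select_model(self.information_weights)

    @property
    def selected(self) -> VariantSpec:
        return self.select()[0]

    def results_for(self, variant) -> SaccadeDDMResults:
        spec = variant if isinstance(variant, VariantSpec) else VariantSpec(frozenset(variant))
        fits = {pid: self.family[pid][spec.name] for pid in self.family}
        return SaccadeDDMResults(model=self.model, variant=spec, fits=fits)

    def summary(self) -> str:
        winner, mean_w = self.select()
        lines = [
            f"DDM family fit, {len(self.family)} participants",
            "mean information weights:",
            mean_w.sort_values(ascending=False).to_string(float_format="%.3f"),
            f"selected variant: {winner.name} (k = {winner.k})",
        ]
        return "\n".join(lines)


class SmartTimecourse:
    """Smoothed time course of selection outcome over fixation duration.

    Wraps the SMART analysis for one condition contrast: per-participant
    Gaussian-kernel smoothing, weighted group aggregation and the
    cluster-based permutation test.
    """

    def __init__(self, data, contrast="inspection_within_outline",
                 config: smart.SmartConfig | None = None):
        self.session = _as_session(data)
        self.contrast = contrast
        self.config = config or smart.SmartConfig()

    def fit(self) -> smart.SmartResult:
        return smart.timecourse_contrast(self.session.trials, self.contrast, self.config)
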