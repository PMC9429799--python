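"""Group-level descriptive and inferential statistics.

All factors in this design are two-level and within-participant, so every
repeated-measures ANOVA effect reduces exactly to a paired contrast
t-test: the effect's F statistic is the square of the t statistic of the
per-participant contrast scores, with df = (1, n - 1). That identity is
exact and is how the effects are computed here — transparent, testable,
and free of sphericity concerns (none arise with two levels).

Selection proportions are compared against chance with Wilcoxon
signed-rank tests (exact for small samples, normal approximation with
continuity correction otherwise), and fitted diffusion parameters get the
standard battery: per-parameter 2x2 ANOVA, condition means/SEs, and
one-sample t-tests of drift against zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import CONDITIONS
from .session import Session

logger = logging.getLogger(__name__)

#: factor levels: condition label -> (inspection coded +1 face, preview +1 preview)
_COND_CODES = {"FP": (1, 1), "FO": (1, -1), "NP": (-1, 1), "NO": (-1, -1)}


class MissingCellError(ValueError):
    """A participant lacks trials in a required design cell."""

    def __init__(self, participants):
        self.participants = list(participants)
        super().__init__(
            "missing design cells for participants "
            f"{self.participants}; exclude them (listwise) before the ANOVA"
        )


@dataclass
class CellTable:
    """Participant x design-cell matrix of means with missing-cell flags."""

    values: pd.DataFrame  # participants x cells (MultiIndex or plain columns)
    design: str  # "2x2" or "2x2x2"
    measure: str
    missing: list = field(default_factory=list)  # (participant, cell) pairs

    @property
    def complete(self) -> pd.DataFrame:
        """Rows without missing cells (listwise deletion, logged)."""
        bad = {p for p, _ in self.missing}
        if bad:
            logger.info("excluding participants with missing cells: %s", sorted(bad))
        return self.values.loc[[p for p in self.values.index if p not in bad]]


def cell_means(session: Session | pd.DataFrame, measure: str, design: str = "2x2") -> CellTable:
    """Per-participant cell means of a measure.

    ``measure``: "fixation_duration" (ms) or "face_choice" (proportion of
    face choices). ``design``: "2x2" (inspection x preview, i.e. the four
    conditions) or "2x2x2" (additionally split by selection outcome).
    """
    df = session.trials if isinstance(session, Session) else session
    if measure == "fixation_duration":
        values = df["fixation_duration_ms"].astype(float)
    elif measure == "face_choice":
        values = (df["choice"] == "face").astype(float)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    work = df.assign(_value=values)
    if design == "2x2":
        cells = [(c,) for c in CONDITIONS]
        grouped = work.groupby(["participant_id", "condition"], observed=True)["_value"].mean()
        table = grouped.unstack("condition").reindex(columns=CONDITIONS)
        table.columns = [(c,) for c in table.columns]
    elif design == "2x2x2":
        cells = list(itertools.product(CONDITIONS, ("face", "noise")))
        grouped = work.groupby(
            ["participant_id", "condition", "choice"], observed=True
        )["_value"].mean()
        table = grouped.unstack(["condition", "choice"])
        table = table.reindex(columns=pd.MultiIndex.from_tuples(cells))
        table.columns = [tuple(c) for c in table.columns]
    else:
        raise ValueError("design must be '2x2' or '2x2x2'")
    missing = [
        (pid, cell)
        for pid in table.index
        for cell in cells
        if pd.isna(table.loc[pid, [cell]]).any()
    ]
    return CellTable(values=table, design=design, measure=measure, missing=missing)


def _contrast_codes(design: str):
    """Effect name -> per-cell +-1 codes, cells ordered as in cell_means."""
    if design == "2x2":
        cells = [(c,) for c in CONDITIONS]
        factors = {"inspection": 0, "preview": 1}
        base = {name: [ _COND_CODES[c[0]][i] for c in cells] for name, i in factors.items()}
    else:
        cells = list(itertools.product(CONDITIONS, ("face", "noise")))
        base = {
            "inspection": [_COND_CODES[c][0] for c, _ in cells],
            "preview": [_COND_CODES[c][1] for c, _ in cells],
            "outcome": [1 if ch == "face" else -1 for _, ch in cells],
        }
    effects = {}
    names = list(base)
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            codes = np.prod([np.array(base[n]) for n in combo], axis=0)
            effects[" x ".join(combo)] = codes
    return effects


def rm_anova(table: CellTable) -> pd.DataFrame:
    """All main effects and interactions of an all-two-level within design.

    Each effect is the paired t-test of the per-participant contrast score
    (mean of +cells minus mean of -cells); F = t^2 with df = (1, n - 1).
    Raises :class:`MissingCellError` when any participant has an empty
    cell — exclusions are the caller's explicit, logged decision.
    """
    if table.missing:
        raise MissingCellError(sorted({p for p, _ in table.missing}))
    values = table.values.to_numpy(float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    rows = []
    for name, codes in _contrast_codes(table.design).items():
        half = len(codes) / 2
        scores = values @ (codes / half)  # mean(+) - mean(-) per participant
        t = _one_sample_t(scores)
        F = t**2
        p = stats.f.sf(F, 1, n - 1)
        rows.append(
            {"effect": name, "F": F, "df1": 1, "df2": n - 1, "p": p,
             "t": t, "mean_difference": scores.mean()}
        )
    return pd.DataFrame(rows).set_index("effect")


def _one_sample_t(x, popmean=0.0) -> float:
    x = np.asarray(x, float)
    se = x.std(ddof=1) / np.sqrt(len(x))
    if se == 0:
        return 0.0 if np.isclose(x.mean(), popmean) else np.inf
    return float((x.mean() - popmean) / se)


def paired_t_test(x, y=None, popmean: float = 0.0) -> dict:
    """Two-sided paired (or one-sample) t-test."""
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    if d.size < 2:
        raise ValueError("need at least two observations")
    t = _one_sample_t(d, popmean)
    df = d.size - 1
    p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return {"t": t, "df": df, "p": float(p), "mean": float(d.mean())}


def wilcoxon_test(values, reference: float = 0.5) -> dict:
    """Two-sided Wilcoxon signed-rank test against a reference value.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 nonzero differences, the normal approximation with continuity
    correction beyond that. All differences zero gives the degenerate
    p = 1 (logged).
    """
    d = np.asarray(values, float) - reference
    d = d[d != 0]
    if d.size == 0:
        logger.info("wilcoxon: all differences zero; degenerate p = 1")
        return {"W": 0.0, "n": 0, "p": 1.0}
    mode = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(mode == "approx"),
                         alternative="two-sided", method=mode)
    return {"W": float(res.statistic), "n": int(d.size), "p": float(res.pvalue)}


@dataclass
class ParameterEffectsReport:
    """Statistical battery over per-participant fitted parameters."""

    condition_stats: pd.DataFrame  # parameter x condition means and SEs
    anovas: dict  # parameter -> rm_anova table
    drift_vs_zero: pd.DataFrame  # per-condition one-sample t of drift

    def summary(self) -> str:
        lines = ["condition means (SE):"]
        lines.append(self.condition_stats.to_string(float_format="%.3f"))
        for par, tab in self.anovas.items():
            lines.append(f"\n2x2 repeated-measures ANOVA on {par}:")
            lines.append(
                tab[["F", "df1", "df2", "p"]].to_string(float_format="%.3g")
            )
        lines.append("\ndrift rate vs 0 per condition:")
        lines.append(self.drift_vs_zero.to_string(float_format="%.3g"))
        return "\n".join(lines)


def parameter_effects(params_table: pd.DataFrame) -> ParameterEffectsReport:
    """2x2 ANOVAs, condition means/SEs and drift-vs-zero tests.

    ``params_table``: one row per participant x condition with columns
    ``participant_id``, ``condition`` and the fitted parameters (``v``,
    ``t0``, optionally ``a``). Parameters constant across conditions are
    skipped in the ANOVA battery.
    """
    report_params = [
        p for p in ("v", "t0", "a")
        if p in params_table.columns
        and params_table.groupby("participant_id")[p].nunique().max() > 1
    ]
    stats_rows, anovas = [], {}
    for par in report_params:
        wide = params_table.pivot(index="participant_id", columns="condition", values=par)
        wide = wide.reindex(columns=CONDITIONS)
        for c in CONDITIONS:
            stats_rows.append(
                {"parameter": par, "condition": c,
                 "mean": wide[c].mean(), "se": wide[c].sem()}
            )
        table = CellTable(
            values=wide.set_axis([(c,) for c in CONDITIONS], axis=1),
            design="2x2", measure=par,
            missing=[(p, (c,)) for p in wide.index for c in CONDITIONS
                     if pd.isna(wide.loc[p, c])],
        )
        anovas[par] = rm_anova(table)
    drift_rows = []
    if "v" in params_table.columns:
        wide_v = params_table.pivot(index="participant_id", columns="condition", values="v")
        for c in CONDITIONS:
            res = paired_t_test(wide_v[c].dropna().to_numpy(), popmean=0.0)
            drift_rows.append({"condition": c, **res})
    return ParameterEffectsReport(
        condition_stats=pd.DataFrame(stats_rows).set_index(["parameter", "condition"]),
        anovas=anovas,
        drift_vs_zero=pd.DataFrame(drift_rows).set_index("condition"),
    )
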