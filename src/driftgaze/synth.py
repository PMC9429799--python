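"""Synthetic dual-saccade experiments with the study's design structure.

The generator reproduces the experimental design — 36 participants, a 2x2
within-participant design (inspection identity x preview) with 256 trials
per condition (1024 per participant), 128 face and 128 noise stimuli with
each stimulus serving four times as inspection target and eight times as
selection target, no stimulus repeated within a trial — and draws choices
and fixation durations from the two-boundary diffusion process.

The generating truth follows the winning model class of the analysis this
package implements: drift rate and non-decision time differ between
conditions, boundary separation, starting point and the variability
components are shared. Default condition means are the fitted group means
(drift 0.607 / 0.320 / -0.024 / 0.096 and non-decision time 208 / 211 /
183 / 192 ms for FP / FO / NP / NO); the remaining defaults are plausible
conventional values, documented in docs/methods.md. Between-participant
variability is a normal offset per participant on drift, non-decision time
and boundary separation, shared across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import CONDITIONS, DDMParams
from .session import Session
from .wiener import simulate_trials

#: fitted group-mean drift rates per condition (evidence / s)
DEFAULT_DRIFT = {"FP": 0.607, "FO": 0.320, "NP": -0.024, "NO": 0.096}
#: fitted group-mean non-decision times per condition (seconds)
DEFAULT_T0 = {"FP": 0.208, "FO": 0.211, "NP": 0.183, "NO": 0.192}
#: shared base parameters (a, zr and variabilities are not condition-specific)
DEFAULT_SHARED = dict(a=1.0, zr=0.5, sv=0.3, sz=0.1, st0=0.080)
#: Between-participant variability of the participant offsets, decomposed
#: into a shared component and random inspection-identity, preview and
#: interaction slopes (offset in condition (I, P) with effect codes
#: I, P in {+1, -1}: s + b*I + c*P + d*I*P). The slope SDs are the ones
#: implied by the reported group effect sizes and t statistics over 36
#: participants (contrast-score SD = |effect| / t * sqrt(36)), and the
#: shared SD completes the reported per-condition marginal SDs
#: (SE * sqrt(36), about 1.0 for drift and 112 ms for non-decision time).
#: Boundary separation has no reported dispersion; a moderate shared
#: offset is used.
DEFAULT_POPULATION_SD = {
    "v": {"shared": 0.74, "identity": 0.65, "preview": 0.19, "interaction": 0.17},
    "t0": {"shared": 0.111, "identity": 0.0122, "preview": 0.0067, "interaction": 0.0078},
    "a": 0.15,
}

#: effect codes per condition: (identity: face = +1, preview: preview = +1)
_EFFECT_CODES = {"FP": (1, 1), "FO": (1, -1), "NP": (-1, 1), "NO": (-1, -1)}


def default_population_means() -> dict[str, DDMParams]:
    return {
        c: DDMParams(v=DEFAULT_DRIFT[c], t0=DEFAULT_T0[c], **DEFAULT_SHARED)
        for c in CONDITIONS
    }


class CounterbalanceError(ValueError):
    """The requested trial/stimulus counts cannot be counterbalanced."""


@dataclass
class SyntheticConfig:
    """Population-level truth and design counts for one synthetic study."""

    n_participants: int = 36
    trials_per_condition: int = 256
    n_stimuli_per_category: int = 128
    population_means: dict = field(default_factory=default_population_means)
    population_sds: dict = field(default_factory=lambda: dict(DEFAULT_POPULATION_SD))
    seed: int = 0
    sim_dt: float = 5e-4  # Euler-Maruyama step, seconds

    def __post_init__(self):
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ValueError("participant and trial counts must be >= 1")
        for name, sd in self.population_sds.items():
            if isinstance(sd, dict):
                bad = set(sd) - {"shared", "identity", "preview", "interaction"}
                if bad:
                    raise ValueError(f"unknown SD components for {name}: {sorted(bad)}")
                vals = sd.values()
            else:
                vals = [sd]
            if any(s < 0 for s in vals):
                raise ValueError("population SDs must be >= 0")
        for c in CONDITIONS:
            self.population_means[c].validate()

    def describe(self) -> dict:
        """JSON-serialisable provenance record of the generating truth."""
        return {
            "n_participants": self.n_participants,
            "trials_per_condition": self.trials_per_condition,
            "n_stimuli_per_category": self.n_stimuli_per_category,
            "population_means": {
                c: vars(p).copy() for c, p in self.population_means.items()
            },
            "population_sds": dict(self.population_sds),
            "seed": self.seed,
            "sim_dt": self.sim_dt,
        }


def _spawn(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: one master seed, per-use child keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def build_design(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-participant trial design with stimulus counterbalancing.

    Returns one row per trial (all participants concatenated) with the
    condition sequence randomly interleaved, inspection location (above or
    below fixation) and face side (left or right) balanced within
    condition, and stimulus identifiers assigned so that every stimulus
    appears the same number of times in the inspection and selection roles
    and never twice within one trial.
    """
    seed = config.seed if seed is None else seed
    tpc, n_stim = config.trials_per_condition, config.n_stimuli_per_category
    n_trials = 4 * tpc
    # role counts per category: 2*tpc inspection uses, 4*tpc selection uses
    if (2 * tpc) % n_stim or (4 * tpc) % n_stim:
        raise CounterbalanceError(
            f"trials_per_condition={tpc} with {n_stim} stimuli per category: "
            f"inspection uses 2*{tpc} and selection uses 4*{tpc} per category "
            f"must both be multiples of {n_stim}"
        )
    if tpc % 2:
        raise CounterbalanceError(
            f"trials_per_condition={tpc} must be even to balance "
            "inspection location and face side within condition"
        )
    frames = []
    for p in range(config.n_participants):
        rng = _spawn(seed, 0, p)
        cond = np.repeat(CONDITIONS, tpc)
        order = rng.permutation(n_trials)
        cond = np.asarray(cond)[order]
        # balance location and side within each condition
        loc = np.empty(n_trials, object)
        side = np.empty(n_trials, object)
        for c in CONDITIONS:
            idx = np.flatnonzero(cond == c)
            half = len(idx) // 2
            loc[idx] = rng.permutation(np.repeat(["up", "down"], half))
            side[idx] = rng.permutation(np.repeat(["left", "right"], half))
        insp, sel_face, sel_noise = _assign_stimuli(cond, tpc, n_stim, rng)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": f"P{p + 1:02d}",
                    "trial_index": np.arange(1, n_trials + 1),
                    "inspection_identity": ["face" if c_[0] == "F" else "noise" for c_ in cond],
                    "preview": ["preview" if c_[1] == "P" else "outline" for c_ in cond],
                    "condition": cond,
                    "inspection_location": loc,
                    "face_side": side,
                    "inspection_stimulus": insp,
                    "selection_face_stimulus": sel_face,
                    "selection_noise_stimulus": sel_noise,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _assign_stimuli(cond, tpc, n_stim, rng, max_repair=10_000):
    """Assign stimulus ids to roles under the no-repeat-within-trial rule.

    Each category's selection-role pool holds every stimulus ``4*tpc /
    n_stim`` times and the inspection pool ``2*tpc / n_stim`` times; pools
    are shuffled and conflicts (inspection stimulus equal to the same-
    category selection stimulus of its own trial) repaired by swapping with
    a random other trial.
    """
    n_trials = len(cond)
    sel_face = rng.permutation(np.repeat(np.arange(n_stim), 4 * tpc // n_stim))
    sel_noise = rng.permutation(np.repeat(np.arange(n_stim), 4 * tpc // n_stim))
    insp = np.full(n_trials, -1)
    for cat, label in [("face", "F"), ("noise", "N")]:
        idx = np.flatnonzero(np.char.startswith(cond.astype(str), label))
        pool = rng.permutation(np.repeat(np.arange(n_stim), 2 * tpc // n_stim))
        insp[idx] = pool
        same = sel_face if cat == "face" else sel_noise
        for _ in range(max_repair):
            clash = idx[insp[idx] == same[idx]]
            if clash.size == 0:
                break
            for t in clash:
                t2 = rng.choice(idx)
                insp[t], insp[t2] = insp[t2], insp[t]
        else:  # pragma: no cover - pools are large enough in practice
            raise CounterbalanceError("could not resolve stimulus clashes")
    face_ids = np.char.add("face", np.char.zfill((sel_face + 1).astype(str), 3))
    noise_ids = np.char.add("noise", np.char.zfill((sel_noise + 1).astype(str), 3))
    insp_ids = np.where(
        np.char.startswith(cond.astype(str), "F"),
        np.char.add("face", np.char.zfill((insp + 1).astype(str), 3)),
        np.char.add("noise", np.char.zfill((insp + 1).astype(str), 3)),
    )
    return insp_ids, face_ids, noise_ids


def sample_population_params(
    config: SyntheticConfig, seed: int | None = None, max_tries: int = 200
) -> dict[str, dict[str, DDMParams]]:
    """Draw per-participant condition parameters around the population means.

    Each participant's deviation from the population means follows a
    random-effects decomposition over the 2x2 design: a shared offset plus
    random inspection-identity, preview and interaction slopes, so
    individuals differ both in overall level and in the size of their
    condition effects (the structure the reported group statistics imply).
    A plain float SD means a shared offset only. Draws violating parameter
    legality are rejected and resampled; if more than half of the attempts
    for a participant fail, the configured SDs are too wide and an error
    advises narrowing them.
    """
    seed = config.seed if seed is None else seed
    out: dict[str, dict[str, DDMParams]] = {}
    sds = config.population_sds
    for p in range(config.n_participants):
        rng = _spawn(seed, 1, p)
        pid = f"P{p + 1:02d}"
        tries = 0
        while True:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    "population SDs reject too many parameter draws; "
                    "narrow population_sds"
                )
            offsets = {}
            for name, sd in sds.items():
                comp = sd if isinstance(sd, dict) else {"shared": sd}
                s = rng.normal(0.0, comp.get("shared", 0.0))
                b = rng.normal(0.0, comp.get("identity", 0.0))
                c_ = rng.normal(0.0, comp.get("preview", 0.0))
                d = rng.normal(0.0, comp.get("interaction", 0.0))
                offsets[name] = {
                    cond: s + b * ci + c_ * pc + d * ci * pc
                    for cond, (ci, pc) in _EFFECT_CODES.items()
                }
            try:
                cand = {}
                for c in CONDITIONS:
                    mean = config.population_means[c]
                    cand[c] = replace(
                        mean,
                        v=mean.v + offsets.get("v", {}).get(c, 0.0),
                        t0=mean.t0 + offsets.get("t0", {}).get(c, 0.0),
                        a=mean.a + offsets.get("a", {}).get(c, 0.0),
                        zr=mean.zr + offsets.get("zr", {}).get(c, 0.0),
                    ).validate()
            except ValueError:
                if tries > max_tries // 2 and tries > 20:
                    raise ValueError(
                        "population SDs reject more than half of the draws; "
                        "narrow population_sds"
                    ) from None
                continue
            out[pid] = cand
            break
    return out


def simulate_session(
    params: dict[str, dict[str, DDMParams]],
    design: pd.DataFrame,
    seed: int,
    dt: float = 5e-4,
) -> Session:
    """Simulate choices and fixation durations for a built design.

    Each trial's (choice, response time) pair is drawn from the diffusion
    simulator under that trial's condition parameters; absorption at the
    upper boundary codes a saccade to the face. Fixation duration is
    decision time plus the non-decision-time draw, in milliseconds.
    """
    design = design.copy()
    design["choice"] = ""
    design["fixation_duration_ms"] = np.nan
    for pi, (pid, block) in enumerate(design.groupby("participant_id", sort=False)):
        rng = _spawn(seed, 2, pi)
        for cond, sub in block.groupby("condition", sort=False):
            upper, rt = simulate_trials(params[pid][cond], len(sub), rng, dt=dt)
            design.loc[sub.index, "choice"] = np.where(upper, "face", "noise")
            design.loc[sub.index, "fixation_duration_ms"] = rt * 1000.0
    return Session(
        design,
        metadata={"generator_seed": int(seed), "generated": True},
    )


def generate_session(config: SyntheticConfig, seed: int | None = None) -> Session:
    """Design + population draw + simulation in one call."""
    seed = config.seed if seed is None else seed
    design = build_design(config, seed)
    params = sample_population_params(config, seed)
    session = simulate_session(params, design, seed, dt=config.sim_dt)
    session.metadata["config"] = config.describe()
    session.metadata["true_params"] = {
        pid: {c: vars(p).copy() for c, p in by_cond.items()}
        for pid, by_cond in params.items()
    }
    return session
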