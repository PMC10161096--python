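"""Synthetic behavioral agent: the trial-log generator.

The agent is a stand-in for the animals, not a mechanistic claim.  Its
generative model is a feature-value reinforcement learner in the
attention-augmentation family: values of the chosen object's features are
updated by a delta rule with learning rate ``eta``, while values of the
features of non-chosen displayed objects decay ("unlearning") at rate
``omega``.  Choice is softmax over summed feature values with an additive
perseveration bias toward features chosen on the previous trial and a lapse
mixture.  Response times follow decision conflict (normalized choice
entropy), which — with value carry-over across blocks — produces the
characteristic fast-slow-fast RT trajectory within a learning block.

A dose condition multiplies ``(eta, omega)`` through a :class:`DoseMap`
whose default is an inverted-U peaking at the middle dose; the map is a
configurable emulation device, not a pharmacological model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .task import (
    ConfigurationError,
    FRLBlockSpec,
    SessionSchedule,
    TaskConfig,
    TaskObject,
    TrialDisplay,
    VSBlockSpec,
    advance_block,
    build_session_schedule,
    sample_frl_trial,
    sample_vs_familiarization_trial,
    sample_vs_trial,
    vs_set_size_sequence,
)

__all__ = [
    "AgentParams",
    "DoseMap",
    "ValueState",
    "ChoiceTrace",
    "default_dose_map",
    "choice_probabilities",
    "choose",
    "update",
    "generate_rt",
    "simulate_session",
    "simulate_frl_trials",
    "fit_agent_parameters",
    "TRIAL_LOG_COLUMNS",
]

#: Shared trial-log schema (one CSV row per trial).
TRIAL_LOG_COLUMNS = [
    "subject",
    "session",
    "dose",
    "task",
    "block",
    "trial_in_block",
    "load",
    "target_feature",
    "target_dimension",
    "switch_type",
    "set_size",
    "mean_shared_features",
    "objects",
    "choice_index",
    "chosen_features",
    "correct",
    "rewarded",
    "rt_ms",
]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the synthetic learner.

    Learning: ``eta`` (delta-rule rate for chosen features), ``omega``
    (decay rate for non-chosen displayed features).  Choice: ``beta``
    (softmax inverse temperature), ``kappa_persev`` (additive bias per
    feature repeated from the previous choice), ``epsilon_lapse`` (uniform
    lapse probability).  Response times are in milliseconds.
    """

    eta: float = 0.08
    omega: float = 0.10
    beta: float = 3.0
    kappa_persev: float = 0.4
    persev_decay: float = 0.3
    epsilon_lapse: float = 0.05
    rt_base: float = 820.0
    rt_conflict: float = 350.0
    rt_outcome_rate: float = 0.2
    rt_noise_sd: float = 80.0
    value_init: float = 0.0
    carry_values: bool = True
    rt_floor: float = 100.0
    # Visual search: probability of being captured by a distractor grows
    # with its shared-feature count; search time is linear in set size.
    vs_confusion: float = 0.005
    vs_rt_base: float = 900.0
    vs_rt_per_distractor: float = 57.0
    vs_rt_per_shared: float = 120.0
    vs_rt_noise_sd: float = 150.0
    fam_rt_mean: float = 550.0
    fam_rt_noise_sd: float = 60.0

    def __post_init__(self) -> None:
        for name in ("eta", "omega", "epsilon_lapse", "persev_decay", "rt_outcome_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("beta", "rt_base", "rt_noise_sd", "rt_conflict",
                     "vs_rt_noise_sd", "vs_confusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_dose(self, multipliers: tuple[float, float]) -> "AgentParams":
        """Apply dose multipliers to (eta, omega), clipped into [0, 1]."""
        m_eta, m_omega = multipliers
        return dataclasses.replace(
            self,
            eta=min(1.0, self.eta * m_eta),
            omega=min(1.0, self.omega * m_omega),
        )


@dataclass(frozen=True)
class DoseMap:
    """Dose condition -> multipliers on (eta, omega); vehicle is identity."""

    multipliers: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        frozen = {str(k): (float(v[0]), float(v[1])) for k, v in self.multipliers.items()}
        object.__setattr__(self, "multipliers", frozen)
        if frozen.get("vehicle") != (1.0, 1.0):
            raise ValueError("vehicle multipliers must be the identity (1, 1)")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.multipliers)

    def for_condition(self, condition: str) -> tuple[float, float]:
        try:
            return self.multipliers[condition]
        except KeyError:
            raise ConfigurationError(
                f"dose condition {condition!r} is not defined in the dose map "
                f"(known: {list(self.multipliers)})"
            ) from None


def default_dose_map() -> DoseMap:
    """Inverted-U multipliers peaking at the middle (1 mg/kg) dose label."""
    return DoseMap(
        {
            "vehicle": (1.0, 1.0),
            "0.3": (1.10, 1.10),
            "1": (1.70, 1.70),
            "3": (1.05, 1.05),
        }
    )


class ValueState:
    """Learned value per feature value (feature values are globally unique).

    Also carries ``deliberation``, a running average of unrewarded outcomes
    in [0, 1] that gates the conflict term of the response-time model
    (post-error slowing); a fresh state deliberates fully (1.0).
    """

    def __init__(self, default: float = 0.0) -> None:
        self.default = float(default)
        self.v: dict[str, float] = {}
        self.deliberation: float = 1.0

    def __getitem__(self, feature: str) -> float:
        return self.v.get(feature, self.default)

    def __setitem__(self, feature: str, value: float) -> None:
        self.v[feature] = float(value)

    def object_utility(
        self,
        obj: TaskObject,
        params: AgentParams,
        prev_features: "Mapping[str, float] | frozenset[str]" = frozenset(),
    ) -> float:
        """Summed feature values plus the perseveration bias.

        ``prev_features`` is either the previous trial's chosen feature set
        (weight 1 each) or a decaying choice trace mapping feature -> weight.
        """
        values = obj.feature_values()
        u = sum(self[f] for f in values)
        if isinstance(prev_features, (set, frozenset)):
            u += params.kappa_persev * len(values & prev_features)
        else:
            u += params.kappa_persev * sum(prev_features.get(f, 0.0) for f in values)
        return u

    def copy(self) -> "ValueState":
        clone = ValueState(self.default)
        clone.v = dict(self.v)
        clone.deliberation = self.deliberation
        return clone


class ChoiceTrace:
    """Exponentially decaying memory of chosen features.

    After each trial every weight is multiplied by ``1 - persev_decay`` and
    the chosen features are reset to weight 1.  With ``persev_decay = 1``
    only the immediately preceding choice carries weight — the classic
    one-trial perseveration bias.
    """

    def __init__(self, decay: float) -> None:
        self.decay = float(decay)
        self.w: dict[str, float] = {}

    def get(self, feature: str, default: float = 0.0) -> float:
        return self.w.get(feature, default)

    def record(self, chosen: Iterable[str]) -> None:
        keep = 1.0 - self.decay
        self.w = {f: v * keep for f, v in self.w.items() if v * keep > 1e-6}
        for f in chosen:
            self.w[f] = 1.0


def _softmax(utilities: np.ndarray, beta: float) -> np.ndarray:
    z = beta * np.asarray(utilities, dtype=float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def choice_probabilities(
    state: ValueState,
    trial: TrialDisplay,
    params: AgentParams,
    prev_features: "Mapping[str, float] | frozenset[str] | ChoiceTrace" = frozenset(),
) -> np.ndarray:
    """Softmax-with-lapse probability of choosing each displayed object."""
    u = np.array(
        [state.object_utility(o, params, prev_features) for o in trial.objects]
    )
    p = _softmax(u, params.beta)
    n = len(trial.objects)
    return (1.0 - params.epsilon_lapse) * p + params.epsilon_lapse / n


def choose(
    state: ValueState,
    trial: TrialDisplay,
    params: AgentParams,
    rng: np.random.Generator,
    prev_features: "Mapping[str, float] | frozenset[str] | ChoiceTrace" = frozenset(),
) -> int:
    """Sample a choice index from the softmax-with-lapse policy."""
    p = choice_probabilities(state, trial, params, prev_features)
    return int(rng.choice(len(p), p=p))


def update(
    state: ValueState,
    trial: TrialDisplay,
    choice: int,
    reward: int,
    params: AgentParams,
) -> ValueState:
    """Delta-rule update of chosen features; decay of non-chosen displayed features.

    A feature appearing both on the chosen object and on a distractor (possible
    in visual search) is updated, not decayed.  The deliberation gate of the
    RT model tracks the outcome with rate ``rt_outcome_rate``.
    """
    chosen = trial.objects[choice].feature_values()
    lam = params.rt_outcome_rate
    state.deliberation = (1.0 - lam) * state.deliberation + lam * (1.0 - float(reward))
    for f in chosen:
        state[f] = state[f] + params.eta * (float(reward) - state[f])
    for i, obj in enumerate(trial.objects):
        if i == choice:
            continue
        for f in obj.feature_values():
            if f not in chosen:
                state[f] = (1.0 - params.omega) * state[f]
    return state


def _normalized_entropy(p: np.ndarray) -> float:
    n = len(p)
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(-terms.sum() / math.log(n))


def generate_rt(
    state: ValueState,
    trial: TrialDisplay,
    params: AgentParams,
    rng: np.random.Generator | None = None,
    prev_features: "Mapping[str, float] | frozenset[str] | ChoiceTrace" = frozenset(),
) -> float:
    """Conflict-driven response time in ms, gated by recent outcomes.

    Conflict is the entropy of the (lapse-free) softmax choice distribution
    scaled to [0, 1], multiplied by the state's deliberation gate (a running
    average of unrewarded outcomes: responding stays fast while the current
    policy keeps being rewarded, and slows after accumulating errors).  For a
    fresh state the gate is 1 and the RT is exactly
    ``rt_base + rt_conflict * H``.  Additive Gaussian noise is truncated at
    the RT floor.
    """
    u = np.array(
        [state.object_utility(o, params, prev_features) for o in trial.objects]
    )
    p = _softmax(u, params.beta)
    rt = params.rt_base + params.rt_conflict * state.deliberation * _normalized_entropy(p)
    if rng is not None and params.rt_noise_sd > 0:
        rt += rng.normal(0.0, params.rt_noise_sd)
    return float(max(params.rt_floor, rt))


def _blank_row(schedule: SessionSchedule) -> dict:
    return {
        "subject": schedule.subject_id,
        "session": schedule.session,
        "dose": schedule.dose_condition,
        "load": "",
        "target_feature": "",
        "target_dimension": "",
        "switch_type": "",
        "set_size": 0,
        "mean_shared_features": float("nan"),
    }


def _simulate_vs_block(
    schedule: SessionSchedule,
    block: VSBlockSpec,
    block_id: int,
    params: AgentParams,
    rng: np.random.Generator,
) -> list[dict]:
    """Minimal search model: lapse + similarity-graded distractor capture."""
    space = schedule.config.feature_space
    target_label = "|".join(v for _, v in block.target.features)
    rows: list[dict] = []
    for t in range(1, block.n_familiarization + 1):
        display = sample_vs_familiarization_trial(block)
        rt = params.fam_rt_mean + rng.normal(0.0, params.fam_rt_noise_sd)
        rows.append(
            {
                **_blank_row(schedule),
                "task": "VS_familiarization",
                "block": block_id,
                "trial_in_block": t,
                "target_feature": target_label,
                "objects": ";".join(o.serialize() for o in display.objects),
                "choice_index": 0,
                "chosen_features": display.objects[0].serialize(),
                "correct": 1,
                "rewarded": 1,
                "rt_ms": float(max(params.rt_floor, rt)),
            }
        )
    for t, set_size in enumerate(vs_set_size_sequence(block, rng), start=1):
        display = sample_vs_trial(
            block, set_size, space, rng,
            similarity_choices=schedule.config.vs_similarity_choices,
        )
        capture = np.array(
            [min(1.0, params.vs_confusion * (1 + s)) for s in display.shared_features]
        )
        distractor_idx = [i for i in range(set_size + 1) if i != display.correct_index]
        if rng.random() < params.epsilon_lapse:
            choice = int(rng.integers(set_size + 1))
        elif rng.random() < 1.0 - float(np.prod(1.0 - capture)):
            weights = capture / capture.sum()
            choice = int(distractor_idx[int(rng.choice(len(capture), p=weights))])
        else:
            choice = display.correct_index
        correct = int(choice == display.correct_index)
        rt = (
            params.vs_rt_base
            + params.vs_rt_per_distractor * set_size
            + params.vs_rt_per_shared * display.mean_shared()
            + rng.normal(0.0, params.vs_rt_noise_sd)
        )
        rows.append(
            {
                **_blank_row(schedule),
                "task": "VS",
                "block": block_id,
                "trial_in_block": t,
                "target_feature": target_label,
                "set_size": set_size,
                "mean_shared_features": display.mean_shared(),
                "objects": ";".join(o.serialize() for o in display.objects),
                "choice_index": choice,
                "chosen_features": display.objects[choice].serialize(),
                "correct": correct,
                "rewarded": correct,
                "rt_ms": float(max(params.rt_floor, rt)),
            }
        )
    return rows


def simulate_session(
    schedule: SessionSchedule,
    params: AgentParams | None = None,
    dose_map: DoseMap | None = None,
    seed: int | np.random.SeedSequence = 0,
    chooser: Callable[[TrialDisplay, np.random.Generator], int] | None = None,
) -> pd.DataFrame:
    """Simulate one full session and return its trial log.

    Dose multipliers from ``dose_map`` are applied to (eta, omega) before
    simulation.  Feature values carry over across FRL blocks by default so
    that perseveration on the previous block's target is possible.  An
    optional ``chooser`` overrides the learned policy (used for oracle and
    chance reference agents).
    """
    params = params or AgentParams()
    dose_map = dose_map or default_dose_map()
    eff = params.with_dose(dose_map.for_condition(schedule.dose_condition))
    rng = np.random.default_rng(seed)
    space = schedule.config.feature_space

    rows: list[dict] = _simulate_vs_block(schedule, schedule.vs_first, 0, eff, rng)

    state = ValueState(eff.value_init)
    trace = ChoiceTrace(eff.persev_decay)
    n_frl = len(schedule.frl_blocks)
    for block in schedule.frl_blocks:
        if not eff.carry_values:
            state = ValueState(eff.value_init)
            trace = ChoiceTrace(eff.persev_decay)
        outcomes: list[int] = []
        while True:
            display = sample_frl_trial(block, space, rng)
            if chooser is None:
                choice = choose(state, display, eff, rng, trace)
            else:
                choice = chooser(display, rng)
            rt = generate_rt(state, display, eff, rng, trace)
            correct = int(choice == display.correct_index)
            p_reward = block.reward_prob_target if correct else block.reward_prob_other
            reward = int(rng.random() < p_reward)
            update(state, display, choice, reward, eff)
            trace.record(display.objects[choice].feature_values())
            outcomes.append(correct)
            rows.append(
                {
                    **_blank_row(schedule),
                    "task": "FRL",
                    "block": block.block_index,
                    "trial_in_block": len(outcomes),
                    "load": block.load,
                    "target_feature": block.target_feature,
                    "target_dimension": block.target_dimension,
                    "switch_type": block.switch_type,
                    "objects": ";".join(o.serialize() for o in display.objects),
                    "choice_index": choice,
                    "chosen_features": display.objects[choice].serialize(),
                    "correct": correct,
                    "rewarded": reward,
                    "rt_ms": rt,
                }
            )
            if advance_block(block, outcomes) == "switch":
                break

    rows.extend(
        _simulate_vs_block(schedule, schedule.vs_second, n_frl + 1, eff, rng)
    )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def simulate_frl_trials(
    n_trials: int,
    policy: str | Callable[[TrialDisplay, np.random.Generator], int] = "oracle",
    config: TaskConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run a fixed choice policy through FRL blocks until ``n_trials`` trials.

    ``policy`` is ``"oracle"`` (always the target-feature object),
    ``"random"`` (uniform), or a callable ``(display, rng) -> index``.
    Returns a frame with block ids, correctness and realized rewards —
    the reference input for chance/oracle calibration checks.
    """
    config = config or TaskConfig()
    if policy == "oracle":
        chooser = lambda d, r: d.correct_index
    elif policy == "random":
        chooser = lambda d, r: int(r.integers(len(d.objects)))
    else:
        chooser = policy
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    session = 0
    while len(rows) < n_trials:
        schedule = build_session_schedule(
            config, seed=int(rng.integers(2**31)), session=session
        )
        for block in schedule.frl_blocks:
            outcomes: list[int] = []
            while True:
                display = sample_frl_trial(block, config.feature_space, rng)
                choice = chooser(display, rng)
                correct = int(choice == display.correct_index)
                p = block.reward_prob_target if correct else block.reward_prob_other
                rows.append(
                    {
                        "session": session,
                        "block": block.block_index,
                        "trial_in_block": len(outcomes) + 1,
                        "correct": correct,
                        "rewarded": int(rng.random() < p),
                    }
                )
                outcomes.append(correct)
                if advance_block(block, outcomes) == "switch":
                    break
            if len(rows) >= n_trials:
                break
        session += 1
    return pd.DataFrame(rows[:n_trials])


# ---------------------------------------------------------------------------
# Likelihood-based parameter recovery


def _parse_frl_log(log: pd.DataFrame) -> list[dict]:
    """Pre-parse FRL rows of a trial log into per-session replay arrays."""
    frl = log[log["task"] == "FRL"]
    sessions = []
    for (_, _), grp in frl.groupby(["subject", "session"], sort=True):
        grp = grp.sort_values(["block", "trial_in_block"])
        trials = []
        for objects, choice, reward in zip(
            grp["objects"], grp["choice_index"], grp["rewarded"]
        ):
            feats = [
                frozenset(item.split("=", 1)[1] for item in obj.split("|"))
                for obj in objects.split(";")
            ]
            trials.append((feats, int(choice), int(reward)))
        sessions.append({"trials": trials, "blocks": grp["block"].to_numpy()})
    return sessions


def _frl_nll(sessions: list[dict], params: AgentParams) -> float:
    nll = 0.0
    for sess in sessions:
        state = ValueState(params.value_init)
        trace = ChoiceTrace(params.persev_decay)
        last_block = None
        for (feats, choice, reward), block in zip(sess["trials"], sess["blocks"]):
            if not params.carry_values and block != last_block:
                state = ValueState(params.value_init)
                trace = ChoiceTrace(params.persev_decay)
            last_block = block
            u = np.array(
                [
                    sum(state[f] for f in fs)
                    + params.kappa_persev * sum(trace.get(f) for f in fs)
                    for fs in feats
                ]
            )
            p = _softmax(u, params.beta)
            n = len(feats)
            p_choice = (1 - params.epsilon_lapse) * p[choice] + params.epsilon_lapse / n
            nll -= math.log(max(p_choice, 1e-12))
            chosen = feats[choice]
            for f in chosen:
                state[f] = state[f] + params.eta * (reward - state[f])
            for i, fs in enumerate(feats):
                if i != choice:
                    for f in fs - chosen:
                        state[f] = (1 - params.omega) * state[f]
            trace.record(chosen)
    return nll


def fit_agent_parameters(
    log: pd.DataFrame,
    template: AgentParams | None = None,
    fit: Sequence[str] = ("eta", "beta"),
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[AgentParams, float]:
    """Maximum-likelihood fit of agent parameters to a trial log's FRL choices.

    Non-fitted parameters are taken from ``template``.  A coarse grid seeds a
    Nelder–Mead polish.  Returns the fitted parameter set and the negative
    log-likelihood at the optimum.
    """
    template = template or AgentParams()
    default_bounds = {
        "eta": (0.01, 0.99), "omega": (0.0, 0.99),
        "beta": (0.1, 30.0), "kappa_persev": (0.0, 2.0),
    }
    bounds = {**default_bounds, **(bounds or {})}
    sessions = _parse_frl_log(log)
    if not sessions:
        raise ValueError("trial log contains no FRL trials")

    def objective(x: np.ndarray) -> float:
        values = {}
        for name, v in zip(fit, x):
            lo, hi = bounds[name]
            if not lo <= v <= hi:
                return 1e9
            values[name] = float(v)
        return _frl_nll(sessions, dataclasses.replace(template, **values))

    grids = {name: np.linspace(*bounds[name], 4) for name in fit}
    best_x, best_val = None, np.inf
    for combo in np.array(np.meshgrid(*[grids[n] for n in fit])).reshape(len(fit), -1).T:
        val = objective(combo)
        if val < best_val:
            best_x, best_val = combo, val
    res = optimize.minimize(
        objective, best_x, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 200},
    )
    fitted = dataclasses.replace(
        template, **{name: float(v) for name, v in zip(fit, res.x)}
    )
    return fitted, float(res.fun)
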