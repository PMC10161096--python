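"""Trial-level generators for the two touchscreen tasks.

Two paradigms make up one daily session:

* **FRL** (feature-reward learning): blocks of three-object trials in which a
  single feature value (e.g. "red") is probabilistically rewarded.  Objects
  vary in one feature dimension (low distractor load) or two (high load), and
  within a trial no two objects share any varying feature.  Blocks switch once
  performance reaches >=80% over the previous 10 trials after a jittered
  minimum of 35/40/45 trials, or after 60 trials regardless.
* **VS** (visual search): a target object defined by three features is
  familiarized over 10 single-object trials and then searched for among 3, 6,
  9 or 12 distractors, each of which shares 0, 1 or 2 of the target's
  features.

The module generates symbolic stimuli only; rendering, touch timing and fluid
reward magnitudes are out of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "BlockOrderError",
    "FeatureSpace",
    "TaskObject",
    "FRLBlockSpec",
    "VSBlockSpec",
    "TrialDisplay",
    "SessionSchedule",
    "TaskConfig",
    "default_feature_space",
    "build_session_schedule",
    "classify_switch_type",
    "sample_frl_trial",
    "advance_block",
    "vs_set_size_sequence",
    "sample_vs_trial",
    "sample_vs_familiarization_trial",
    "similarity_condition",
    "similarity_bin",
    "SWITCH_TYPES",
    "SIMILARITY_EDGES",
]


class ConfigurationError(ValueError):
    """The task configuration cannot generate the requested structure."""


class BlockOrderError(ValueError):
    """Blocks passed to a transition classifier are not consecutive."""


SWITCH_TYPES = ("first_block", "intradimensional", "extradimensional", "novel_dimension")

#: Tercile edges on the trial-mean number of target-shared distractor
#: features (range 0..2), binning trials into low/medium/high similarity.
SIMILARITY_EDGES = (2.0 / 3.0, 4.0 / 3.0)


@dataclass(frozen=True)
class FeatureSpace:
    """The symbolic stimulus space: dimensions and their feature values.

    Every feature value belongs to exactly one dimension, and each dimension
    offers at least 3 values so that three mutually non-overlapping objects
    can be drawn per FRL trial.
    """

    values_per_dimension: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        frozen = {str(d): tuple(v) for d, v in self.values_per_dimension.items()}
        object.__setattr__(self, "values_per_dimension", frozen)
        seen: dict[str, str] = {}
        for dim, values in frozen.items():
            if len(values) < 3:
                raise ConfigurationError(
                    f"dimension {dim!r} offers {len(values)} values; at least 3 are "
                    "required for disjoint three-object trials"
                )
            if len(set(values)) != len(values):
                raise ConfigurationError(f"dimension {dim!r} repeats a feature value")
            for v in values:
                if v in seen:
                    raise ConfigurationError(
                        f"feature value {v!r} appears in dimensions {seen[v]!r} and {dim!r}"
                    )
                seen[v] = dim

    @property
    def dimensions(self) -> tuple[str, ...]:
        return tuple(self.values_per_dimension)

    def values(self, dimension: str) -> tuple[str, ...]:
        return self.values_per_dimension[dimension]

    def dimension_of(self, value: str) -> str:
        for dim, values in self.values_per_dimension.items():
            if value in values:
                return dim
        raise KeyError(value)


def default_feature_space() -> FeatureSpace:
    """Quaddle-like space: four dimensions with nine values each."""
    return FeatureSpace(
        {
            "color": ("red", "blue", "yellow", "green", "cyan", "magenta",
                      "orange", "purple", "teal"),
            "pattern": ("checkered", "striped", "dotted", "solid", "wavy",
                        "grid", "zigzag", "swirl", "crosshatch"),
            "shape": ("sphere", "cube", "pyramid", "cylinder", "cone",
                      "torus", "prism", "bulb", "disk"),
            "arms": ("straight", "curved", "forked", "stubby", "spiral",
                     "flat", "pointed", "knobbed", "split"),
        }
    )


@dataclass(frozen=True)
class TaskObject:
    """A symbolic multi-feature stimulus: one feature value per varying dimension."""

    features: tuple[tuple[str, str], ...]  # sorted (dimension, value) pairs

    def __post_init__(self) -> None:
        pairs = tuple(sorted((str(d), str(v)) for d, v in self.features))
        dims = [d for d, _ in pairs]
        if len(set(dims)) != len(dims):
            raise ValueError("an object may carry at most one value per dimension")
        object.__setattr__(self, "features", pairs)

    @classmethod
    def from_dict(cls, features: Mapping[str, str]) -> "TaskObject":
        return cls(tuple(features.items()))

    def feature_dict(self) -> dict[str, str]:
        return dict(self.features)

    def feature_values(self) -> frozenset[str]:
        return frozenset(v for _, v in self.features)

    def contains(self, value: str) -> bool:
        return any(v == value for _, v in self.features)

    def shared_with(self, other: "TaskObject") -> int:
        """Number of (dimension, value) features in common with ``other``."""
        return len(set(self.features) & set(other.features))

    def serialize(self) -> str:
        return "|".join(f"{d}={v}" for d, v in self.features)

    @classmethod
    def deserialize(cls, text: str) -> "TaskObject":
        if not text:
            return cls(())
        return cls(tuple(tuple(item.split("=", 1)) for item in text.split("|")))


@dataclass(frozen=True)
class FRLBlockSpec:
    """One feature-reward-learning block: its target, load and switch rule."""

    block_index: int
    load: str  # "low" | "high"
    target_dimension: str
    target_feature: str
    distractor_dimensions: tuple[str, ...]
    min_trials: int
    switch_type: str
    max_trials: int = 60
    reward_prob_target: float = 0.85
    reward_prob_other: float = 0.0

    def __post_init__(self) -> None:
        if self.load not in ("low", "high"):
            raise ValueError(f"unknown load {self.load!r}")
        expected = {"low": 0, "high": 1}[self.load]
        if len(self.distractor_dimensions) != expected:
            raise ValueError(
                f"{self.load} load requires {expected} distractor dimension(s), "
                f"got {self.distractor_dimensions!r}"
            )
        if self.min_trials not in (35, 40, 45):
            raise ValueError("min_trials must be one of 35, 40, 45")
        if self.switch_type not in SWITCH_TYPES:
            raise ValueError(f"unknown switch type {self.switch_type!r}")
        if self.target_dimension in self.distractor_dimensions:
            raise ValueError("target dimension cannot also be a distractor dimension")

    @property
    def varying_dimensions(self) -> tuple[str, ...]:
        return (self.target_dimension, *self.distractor_dimensions)


@dataclass(frozen=True)
class VSBlockSpec:
    """One visual-search block: familiarized target, counts and background."""

    block_position: str  # "first" | "second"
    target: TaskObject
    background_id: str
    n_familiarization: int = 10
    n_search: int = 100
    set_sizes: tuple[int, ...] = (3, 6, 9, 12)

    def __post_init__(self) -> None:
        if self.block_position not in ("first", "second"):
            raise ValueError(f"unknown block position {self.block_position!r}")
        if len(self.target.features) != 3:
            raise ValueError("the search target must carry exactly 3 features")


@dataclass(frozen=True)
class TrialDisplay:
    """One trial's object array: what is on screen and which choice is correct."""

    task: str  # "FRL" | "VS" | "VS_familiarization"
    objects: tuple[TaskObject, ...]
    correct_index: int
    set_size: int = 0  # number of distractors (VS search only)
    shared_features: tuple[int, ...] = ()  # per distractor, display order

    def mean_shared(self) -> float:
        if not self.shared_features:
            return float("nan")
        return float(np.mean(self.shared_features))


@dataclass
class TaskConfig:
    """Generative configuration of a daily session."""

    feature_space: FeatureSpace = field(default_factory=default_feature_space)
    n_frl_blocks: int = 21
    p_high_load: float = 0.5
    reward_prob_target: float = 0.85
    reward_prob_other: float = 0.0
    min_trials_choices: tuple[int, ...] = (35, 40, 45)
    # Relative weights for drawing the next block's target dimension; a
    # category that is unavailable (e.g. no distractor dimension after a
    # low-load block) is dropped and the rest renormalized.
    switch_weights: dict[str, float] = field(
        default_factory=lambda: {
            "intradimensional": 1.0,
            "extradimensional": 1.0,
            "novel_dimension": 1.0,
        }
    )
    n_backgrounds: int = 5
    vs_set_sizes: tuple[int, ...] = (3, 6, 9, 12)
    vs_n_familiarization: int = 10
    vs_n_search: int = 100
    vs_similarity_choices: tuple[int, ...] = (0, 1, 2)


@dataclass
class SessionSchedule:
    """The generative plan of one behavioral session.

    One leading VS block, 21 FRL blocks, one trailing VS block; the two VS
    backgrounds are drawn without replacement from the configured set.
    """

    subject_id: str
    dose_condition: str
    vs_first: VSBlockSpec
    frl_blocks: list[FRLBlockSpec]
    vs_second: VSBlockSpec
    seed: int
    session: int = 0
    config: TaskConfig = field(default_factory=TaskConfig)


def classify_switch_type(previous: FRLBlockSpec | None, current: FRLBlockSpec) -> str:
    """Classify a block transition as ID, ED, novel-dimension or first-block.

    Intradimensional (ID): the new target is in the same dimension as the
    previous target.  Extradimensional (ED): the new target dimension was a
    *distractor* (varying, non-target) dimension of the previous block.
    Novel-dimension: the new target dimension did not vary at all in the
    previous block.
    """
    if previous is None:
        return "first_block"
    if current.block_index != previous.block_index + 1:
        raise BlockOrderError(
            f"blocks {previous.block_index} and {current.block_index} are not consecutive"
        )
    if current.target_dimension == previous.target_dimension:
        return "intradimensional"
    if current.target_dimension in previous.varying_dimensions:
        return "extradimensional"
    return "novel_dimension"


def _draw_target_dimension(
    rng: np.random.Generator,
    config: TaskConfig,
    previous: FRLBlockSpec | None,
) -> str:
    dims = config.feature_space.dimensions
    if previous is None:
        return str(rng.choice(list(dims)))
    candidates: dict[str, list[str]] = {
        "intradimensional": [previous.target_dimension],
        "extradimensional": list(previous.distractor_dimensions),
        "novel_dimension": [d for d in dims if d not in previous.varying_dimensions],
    }
    kinds = [k for k in candidates if candidates[k] and config.switch_weights.get(k, 0) > 0]
    weights = np.array([config.switch_weights[k] for k in kinds], dtype=float)
    kind = kinds[int(rng.choice(len(kinds), p=weights / weights.sum()))]
    return str(rng.choice(candidates[kind]))


def build_session_schedule(
    config: TaskConfig,
    seed: int,
    subject_id: str = "sim",
    dose_condition: str = "vehicle",
    session: int = 0,
) -> SessionSchedule:
    """Draw one deterministic session plan: VS, 21 FRL blocks, VS.

    Raises :class:`ConfigurationError` when the feature space cannot
    guarantee disjoint three-object trials or three-feature search targets.
    """
    space = config.feature_space
    if len(space.dimensions) < 3:
        raise ConfigurationError(
            f"feature space has {len(space.dimensions)} dimensions; at least 3 are needed"
        )
    rng = np.random.default_rng(seed)

    backgrounds = rng.choice(config.n_backgrounds, size=2, replace=False)
    vs_blocks = []
    for position, bg in zip(("first", "second"), backgrounds):
        target_dims = rng.choice(list(space.dimensions), size=3, replace=False)
        target = TaskObject.from_dict(
            {d: str(rng.choice(space.values(d))) for d in target_dims}
        )
        vs_blocks.append(
            VSBlockSpec(
                block_position=position,
                target=target,
                background_id=f"background_{int(bg) + 1}",
                n_familiarization=config.vs_n_familiarization,
                n_search=config.vs_n_search,
                set_sizes=config.vs_set_sizes,
            )
        )

    frl_blocks: list[FRLBlockSpec] = []
    previous: FRLBlockSpec | None = None
    for index in range(1, config.n_frl_blocks + 1):
        load = "high" if rng.random() < config.p_high_load else "low"
        target_dim = _draw_target_dimension(rng, config, previous)
        values = [v for v in space.values(target_dim)]
        if previous is not None and previous.target_feature in values:
            values.remove(previous.target_feature)  # the rule always changes
        target_feature = str(rng.choice(values))
        if load == "high":
            others = [d for d in space.dimensions if d != target_dim]
            distractor_dims: tuple[str, ...] = (str(rng.choice(others)),)
        else:
            distractor_dims = ()
        block = FRLBlockSpec(
            block_index=index,
            load=load,
            target_dimension=target_dim,
            target_feature=target_feature,
            distractor_dimensions=distractor_dims,
            min_trials=int(rng.choice(config.min_trials_choices)),
            switch_type="first_block",
            reward_prob_target=config.reward_prob_target,
            reward_prob_other=config.reward_prob_other,
        )
        block = dataclasses.replace(block, switch_type=classify_switch_type(previous, block))
        frl_blocks.append(block)
        previous = block

    return SessionSchedule(
        subject_id=subject_id,
        dose_condition=dose_condition,
        vs_first=vs_blocks[0],
        frl_blocks=frl_blocks,
        vs_second=vs_blocks[1],
        seed=seed,
        session=session,
        config=config,
    )


def sample_frl_trial(
    block: FRLBlockSpec, space: FeatureSpace, rng: np.random.Generator
) -> TrialDisplay:
    """Draw a three-object FRL display, pairwise disjoint on varying dimensions.

    Exactly one object carries the block's target feature; non-varying
    dimensions are omitted (held at the block's neutral context).
    """
    n_objects = 3
    target_index = int(rng.integers(n_objects))
    assignment: list[dict[str, str]] = [{} for _ in range(n_objects)]
    for dim in block.varying_dimensions:
        pool = list(space.values(dim))
        if dim == block.target_dimension:
            pool.remove(block.target_feature)
            others = rng.choice(pool, size=n_objects - 1, replace=False)
            values = list(others)
            values.insert(target_index, block.target_feature)
        else:
            values = list(rng.choice(pool, size=n_objects, replace=False))
        for obj, value in zip(assignment, values):
            obj[dim] = str(value)
    objects = tuple(TaskObject.from_dict(f) for f in assignment)
    return TrialDisplay(task="FRL", objects=objects, correct_index=target_index)


def advance_block(block: FRLBlockSpec, trial_outcomes: Sequence[int]) -> str:
    """Decide whether an FRL block continues or switches after the last trial.

    Switch once at least ``min_trials`` are complete and the previous 10
    trials reach >=80% accuracy, or unconditionally after ``max_trials``.
    """
    n = len(trial_outcomes)
    if n == 0:
        return "continue"
    if n >= block.max_trials:
        return "switch"
    if n >= block.min_trials and float(np.mean(trial_outcomes[-10:])) >= 0.8:
        return "switch"
    return "continue"


def vs_set_size_sequence(block: VSBlockSpec, rng: np.random.Generator) -> list[int]:
    """Counterbalanced set-size order: shuffled groups covering each size once.

    With 100 search trials and sizes {3,6,9,12} every size occurs exactly 25
    times; a non-divisible trial count fills the remainder from one further
    shuffled group.
    """
    sizes = list(block.set_sizes)
    sequence: list[int] = []
    while len(sequence) < block.n_search:
        group = list(rng.permutation(sizes))
        sequence.extend(group)
    return [int(s) for s in sequence[: block.n_search]]


def sample_vs_trial(
    block: VSBlockSpec,
    set_size: int,
    space: FeatureSpace,
    rng: np.random.Generator,
    shared_counts: Sequence[int] | None = None,
    similarity_choices: Sequence[int] = (0, 1, 2),
) -> TrialDisplay:
    """Draw one search display: the target plus ``set_size`` distractors.

    Each distractor shares 0, 1 or 2 of the target's three features (drawn
    uniformly unless ``shared_counts`` pins them) and differs from the target
    on the remaining dimensions.
    """
    if set_size not in block.set_sizes:
        raise ConfigurationError(f"set size {set_size} not in {block.set_sizes}")
    target_features = block.target.features
    if shared_counts is None:
        shared_counts = [int(s) for s in rng.choice(similarity_choices, size=set_size)]
    elif len(shared_counts) != set_size:
        raise ConfigurationError("one shared-feature count is required per distractor")

    distractors: list[TaskObject] = []
    for s in shared_counts:
        if not 0 <= s <= 2:
            raise ConfigurationError(f"shared-feature count {s} outside 0..2")
        keep = set(rng.choice(3, size=s, replace=False))
        features: dict[str, str] = {}
        for i, (dim, value) in enumerate(target_features):
            if i in keep:
                features[dim] = value
            else:
                alternatives = [v for v in space.values(dim) if v != value]
                if not alternatives:
                    raise ConfigurationError(
                        f"dimension {dim!r} offers no alternative to {value!r}"
                    )
                features[dim] = str(rng.choice(alternatives))
        distractors.append(TaskObject.from_dict(features))

    target_index = int(rng.integers(set_size + 1))
    objects = list(distractors)
    objects.insert(target_index, block.target)
    ordered_shared = tuple(
        o.shared_with(block.target) for i, o in enumerate(objects) if i != target_index
    )
    return TrialDisplay(
        task="VS",
        objects=tuple(objects),
        correct_index=target_index,
        set_size=set_size,
        shared_features=ordered_shared,
    )


def sample_vs_familiarization_trial(block: VSBlockSpec) -> TrialDisplay:
    """A familiarization trial shows the target alone, no distractors."""
    return TrialDisplay(task="VS_familiarization", objects=(block.target,), correct_index=0)


def similarity_bin(mean_shared: float) -> str:
    """Bin a trial-mean shared-feature count into low/medium/high similarity."""
    if not np.isfinite(mean_shared):
        raise ValueError("mean shared-feature count is undefined")
    if mean_shared < SIMILARITY_EDGES[0]:
        return "low"
    if mean_shared < SIMILARITY_EDGES[1]:
        return "medium"
    return "high"


def similarity_condition(trial: TrialDisplay) -> str:
    """Target-distractor similarity condition of a VS search trial."""
    if trial.task != "VS":
        raise ValueError("similarity is defined for VS search trials only")
    return similarity_bin(trial.mean_shared())
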