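"""Hierarchical task-switching design: cues, rule mapping, transition labels.

The task presents one of 8 colored geometric cues per trial (0.5 s), followed
by a face/scene probe (2.5 s). Cue attributes are organized hierarchically:
the fill *texture* (solid/hollow) is the task context and selects which
mid-level feature dimension (shape or color) is relevant; the value on the
relevant dimension selects the response rule (face vs. scene); the rule plus
the probe category determines the yes/no response.

Consecutive trials are labeled by the level of task representation they
update:

* ``EDS`` (extra-dimensional switch) — the context (texture) changed,
* ``IDS`` (inter-dimensional switch) — same context, but the value on the
  context-relevant dimension changed, switching the response rule,
* ``Stay`` — same rule as the previous trial (the cue may still change on the
  irrelevant dimension).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ValidationError

TEXTURES = ("solid", "hollow")
SHAPES = ("circle", "square")
COLORS = ("blue", "red")
RULES = ("face", "scene")
PROBES = ("face", "scene")
CONDITIONS = ("Stay", "EDS", "IDS")
UNLABELED = "unlabeled"

#: Default transition mix reproducing the 204/102/102 per-subject design.
DEFAULT_PROPORTIONS: Mapping[str, float] = {"Stay": 0.5, "EDS": 0.25, "IDS": 0.25}

CUE_DURATION = 0.5  # s
PROBE_DURATION = 2.5  # s
ITI_MIN, ITI_MAX = 1.5, 10.5  # s


@dataclass(frozen=True, order=True)
class Cue:
    """One of the 8 factorial cues (texture x shape x color)."""

    texture: str
    shape: str
    color: str

    def __post_init__(self) -> None:
        if self.texture not in TEXTURES or self.shape not in SHAPES or self.color not in COLORS:
            raise ValidationError(f"invalid cue attributes: {self!r}")

    def value(self, dimension: str) -> str:
        """The cue's value on a feature dimension ('shape' or 'color')."""
        if dimension == "shape":
            return self.shape
        if dimension == "color":
            return self.color
        raise ValidationError(f"unknown dimension {dimension!r}")


#: All 8 cues in a fixed canonical order.
ALL_CUES: tuple[Cue, ...] = tuple(
    Cue(t, s, c) for t, s, c in itertools.product(TEXTURES, SHAPES, COLORS)
)


def _default_rule_response() -> dict:
    # face rule: respond "yes" iff the probe is a face; scene rule symmetric.
    return {
        ("face", "face"): "yes",
        ("face", "scene"): "no",
        ("scene", "face"): "no",
        ("scene", "scene"): "yes",
    }


@dataclass(frozen=True)
class TaskMapping:
    """The full (counterbalanceable) context -> feature -> rule -> response map.

    ``context_to_dimension`` maps each texture to its relevant dimension,
    ``feature_to_rule`` maps (dimension, value) pairs to response rules,
    ``rule_response`` maps (rule, probe category) to a yes/no response, and
    ``response_to_button`` maps responses to fingers.
    """

    context_to_dimension: Mapping[str, str] = field(
        default_factory=lambda: {"solid": "shape", "hollow": "color"}
    )
    feature_to_rule: Mapping[tuple[str, str], str] = field(
        default_factory=lambda: {
            ("shape", "circle"): "face",
            ("shape", "square"): "scene",
            ("color", "blue"): "face",
            ("color", "red"): "scene",
        }
    )
    rule_response: Mapping[tuple[str, str], str] = field(default_factory=_default_rule_response)
    response_to_button: Mapping[str, str] = field(
        default_factory=lambda: {"yes": "index", "no": "middle"}
    )

    def validate(self) -> None:
        dims = [self.context_to_dimension.get(t) for t in TEXTURES]
        if sorted(d or "" for d in dims) != ["color", "shape"]:
            raise ConfigurationError(
                "context_to_dimension must map the two textures to the two "
                f"different dimensions, got {dict(self.context_to_dimension)}"
            )
        for dim, values in (("shape", SHAPES), ("color", COLORS)):
            rules = {self.feature_to_rule.get((dim, v)) for v in values}
            if rules != set(RULES):
                raise ConfigurationError(
                    f"feature_to_rule must map the two {dim} values to the two rules"
                )
        for rule in RULES:
            for probe in PROBES:
                if self.rule_response.get((rule, probe)) not in ("yes", "no"):
                    raise ConfigurationError(f"rule_response missing ({rule}, {probe})")
        if set(self.response_to_button) != {"yes", "no"}:
            raise ConfigurationError("response_to_button must map 'yes' and 'no'")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "context_to_dimension": dict(self.context_to_dimension),
            "feature_to_rule": {f"{d}:{v}": r for (d, v), r in self.feature_to_rule.items()},
            "rule_response": {f"{r}:{p}": a for (r, p), a in self.rule_response.items()},
            "response_to_button": dict(self.response_to_button),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskMapping":
        split = lambda m: {tuple(k.split(":")): v for k, v in m.items()}
        return cls(
            context_to_dimension=dict(d["context_to_dimension"]),
            feature_to_rule=split(d["feature_to_rule"]),
            rule_response=split(d["rule_response"]),
            response_to_button=dict(d["response_to_button"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaskMapping":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def relevant_dimension(cue: Cue, mapping: TaskMapping) -> str:
    """The feature dimension the cue's context makes task-relevant."""
    try:
        return mapping.context_to_dimension[cue.texture]
    except KeyError as err:
        raise ConfigurationError(f"mapping lacks dimension for texture {cue.texture!r}") from err


def response_rule(cue: Cue, mapping: TaskMapping) -> str:
    """Read the cue through the hierarchy: texture -> dimension -> value -> rule."""
    dim = relevant_dimension(cue, mapping)
    try:
        return mapping.feature_to_rule[(dim, cue.value(dim))]
    except KeyError as err:
        raise ConfigurationError(f"mapping lacks rule for ({dim}, {cue.value(dim)})") from err


def correct_response(cue: Cue, probe: str, mapping: TaskMapping) -> str:
    """Yes/no response for a cue-probe pair under the mapping."""
    rule = response_rule(cue, mapping)
    try:
        return mapping.rule_response[(rule, probe)]
    except KeyError as err:
        raise ConfigurationError(f"mapping lacks response for ({rule}, {probe})") from err


def label_transition(prev: Cue, cur: Cue, mapping: TaskMapping) -> str:
    """EDS if the context changed; IDS if the relevant-dimension value changed
    within the same context; Stay otherwise (same rule as before)."""
    if prev.texture != cur.texture:
        return "EDS"
    dim = relevant_dimension(cur, mapping)
    if prev.value(dim) != cur.value(dim):
        return "IDS"
    return "Stay"


# ---------------------------------------------------------------------------
# Trial sequences
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "onset", "duration", "run", "trial", "texture", "shape", "color",
    "probe", "probe_onset", "iti", "correct_response", "condition",
    "cue_transition", "response_transition",
]


def _cue_of_row(row) -> Cue:
    return Cue(row["texture"], row["shape"], row["color"])


def cues_of(seq: pd.DataFrame) -> list[Cue]:
    """Cue objects for each row of an events table."""
    return [_cue_of_row(r) for _, r in seq.iterrows()]


def sublabel_transitions(seq: pd.DataFrame, mapping: TaskMapping) -> pd.DataFrame:
    """Annotate cue repeat/switch and response repeat/switch sub-labels.

    The first trial of each run stays unlabeled, mirroring the main
    condition labels (no cross-run transitions).
    """
    seq = seq.copy()
    cue_tr, resp_tr = [], []
    prev_key = None
    prev_run = None
    prev_resp = None
    for _, row in seq.iterrows():
        key = (row["texture"], row["shape"], row["color"])
        resp = row["correct_response"]
        if prev_run != row["run"] or prev_key is None:
            cue_tr.append(UNLABELED)
            resp_tr.append(UNLABELED)
        else:
            cue_tr.append("repeat" if key == prev_key else "switch")
            resp_tr.append("repeat" if resp == prev_resp else "switch")
        prev_key, prev_resp, prev_run = key, resp, row["run"]
    seq["cue_transition"] = cue_tr
    seq["response_transition"] = resp_tr
    return seq


def _condition_candidates(prev: Cue, condition: str, mapping: TaskMapping) -> list[Cue]:
    return [c for c in ALL_CUES if label_transition(prev, c, mapping) == condition]


def _quota_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n transitions to conditions."""
    raw = {k: n * v for k, v in proportions.items()}
    counts = {k: int(np.floor(x)) for k, x in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def generate_trial_sequence(
    n_runs: int = 8,
    trials_per_run: int = 51,
    proportions: Mapping[str, float] | None = None,
    seed: int = 0,
    mapping: TaskMapping | None = None,
) -> pd.DataFrame:
    """Sample a trial table with a target transition-condition mix.

    Conditions are consumed from an exact global quota (largest-remainder
    apportionment of the requested proportions over all within-run
    transitions), and cue/probe identities are chosen to keep the 8 cues and
    the 2 probe categories near-equally frequent. With the defaults
    (8 runs x 51 trials, Stay/EDS/IDS = 0.5/0.25/0.25) the labeled-transition
    counts are 200/100/100 and per-trial totals match the 204/102/102 design
    up to the unlabeled first trial of each run.
    """
    mapping = mapping or TaskMapping()
    mapping.validate()
    proportions = dict(proportions or DEFAULT_PROPORTIONS)
    if trials_per_run < 2:
        raise ValidationError("trials_per_run must be >= 2")
    if unknown := set(proportions) - set(CONDITIONS):
        raise ValidationError(f"unknown conditions in proportions: {sorted(unknown)}")
    if abs(sum(proportions.values()) - 1.0) > 1e-9 or min(proportions.values()) < 0:
        raise ValidationError("proportions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    n_labeled = n_runs * (trials_per_run - 1)
    remaining = {c: 0 for c in CONDITIONS}
    remaining.update(_quota_counts(n_labeled, proportions))
    cue_counts = {c: 0 for c in ALL_CUES}
    probe_counts = {"face": 0, "scene": 0}

    def pick_min(counts: dict, candidates: Iterable):
        candidates = list(candidates)
        lo = min(counts[c] for c in candidates)
        best = [c for c in candidates if counts[c] == lo]
        return best[rng.integers(len(best))]

    rows = []
    for run in range(1, n_runs + 1):
        t = 0.0
        prev: Cue | None = None
        for trial in range(1, trials_per_run + 1):
            if prev is None:
                condition = UNLABELED
                cue = pick_min(cue_counts, ALL_CUES)
            else:
                conds = [c for c in CONDITIONS if remaining[c] > 0]
                weights = np.array([remaining[c] for c in conds], dtype=float)
                condition = conds[rng.choice(len(conds), p=weights / weights.sum())]
                remaining[condition] -= 1
                cue = pick_min(cue_counts, _condition_candidates(prev, condition, mapping))
            cue_counts[cue] += 1
            probe = pick_min(probe_counts, PROBES)
            probe_counts[probe] += 1
            iti = min(ITI_MIN + rng.exponential(3.0), ITI_MAX)
            rows.append(
                {
                    "onset": round(t, 3),
                    "duration": CUE_DURATION,
                    "run": run,
                    "trial": trial,
                    "texture": cue.texture,
                    "shape": cue.shape,
                    "color": cue.color,
                    "probe": probe,
                    "probe_onset": round(t + CUE_DURATION, 3),
                    "iti": round(iti, 3),
                    "correct_response": correct_response(cue, probe, mapping),
                    "condition": condition,
                }
            )
            t += CUE_DURATION + PROBE_DURATION + iti
            prev = cue
    seq = pd.DataFrame(rows)
    return sublabel_transitions(seq, mapping)[EVENT_COLUMNS]


def write_events(seq: pd.DataFrame, path: str | Path) -> None:
    """Write an events table as a BIDS-dialect tab-separated file."""
    seq.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
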