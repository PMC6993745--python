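"""Generator configuration, validation, and ordinal-item calibration.

Ordinal questionnaire items are produced by thresholding a standard-normal
latent variable at per-item cutpoints.  The cutpoints are calibrated in closed
form so that the *expected* value of the binned item equals a target mean at a
target spread: for an item with levels ``lo..hi`` we place bin edges at
``(k + 0.5 - loc) / scale`` and solve for ``loc`` such that the discretised
normal has exactly the target mean.  This makes the default generator
reproduce the published marginal descriptive statistics in expectation, so
any deviation observed in a generated cohort is pure Monte-Carlo error.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from typing import Any, Mapping

import numpy as np
from scipy import optimize, stats

DAY_TYPES = ("weekday", "weekend")

TECH_PATHWAYS = (
    "participation",
    "bedtime_use",
    "time_spent_diary",
    "time_spent_retro",
)

#: columns belonging to each missingness block of the cohort table
MISSINGNESS_BLOCKS: dict[str, tuple[str, ...]] = {
    "demographics": ("sex", "age", "mother_white"),
    "family": ("income", "father_home", "n_siblings"),
    "mother": ("word_activity", "nvq", "time_with_child", "kessler"),
    "child": (
        "close_mother",
        "close_father",
        "argue_mother",
        "argue_father",
        "longterm_illness",
        "motiv_1",
        "motiv_2",
        "motiv_3",
        "motiv_4",
        "motiv_5",
        "motiv_6",
    ),
    "sleep_items": (
        "bedtime_weekday",
        "bedtime_weekend",
        "wake_weekday",
        "wake_weekend",
    ),
    "screen_items": ("screen_tv", "screen_games", "screen_internet", "screen_social"),
    "difficulties": ("fall_asleep_time", "night_waking"),
}


class ConfigurationError(ValueError):
    """Raised for invalid generator / bootstrap configuration."""


def discretized_mean(loc: float, scale: float, lo: int, hi: int) -> float:
    """Expected value of ``clip(round(loc + scale*z), lo, hi)`` for z ~ N(0,1).

    Equivalent to binning a N(loc, scale^2) latent at half-integer edges with
    the two extreme bins absorbing the tails.
    """
    levels = np.arange(lo, hi + 1)
    edges = (levels[:-1] + 0.5 - loc) / scale
    cdf = stats.norm.cdf(edges)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    return float(np.sum(probs * levels))


def calibrate_cutpoints(
    target_mean: float, target_sd: float, lo: int, hi: int
) -> np.ndarray:
    """Strictly increasing z-scale cutpoints reproducing ``target_mean`` exactly.

    Returns ``hi - lo`` thresholds; an item takes level ``lo + k`` when the
    latent z falls in the k-th bin (``searchsorted`` convention).
    """
    if not (lo < hi):
        raise ConfigurationError("item must have at least two levels")
    if target_sd <= 0:
        raise ConfigurationError("target_sd must be positive")
    if not (lo < target_mean < hi):
        raise ConfigurationError("target mean outside the item range")

    def gap(loc: float) -> float:
        return discretized_mean(loc, target_sd, lo, hi) - target_mean

    loc = optimize.brentq(gap, lo - 6 * target_sd, hi + 6 * target_sd, xtol=1e-12)
    return (np.arange(lo, hi) + 0.5 - loc) / target_sd


@dataclasses.dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort generator.

    ``true_effects`` maps ``(day_type, technology_pathway)`` to a standardized
    effect size injected additively on the latent sleep outcomes (diary sleep
    onset, retrospective bedtime, and — down-weighted by
    ``wake_effect_weight`` — the wake-time component of total sleep).
    """

    n_participants: int
    seed: int = 0
    diary_fraction: float = 1.0 / 3.0
    true_effects: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    difficulty_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    participation_prob: dict[str, float] = dataclasses.field(default_factory=dict)
    digital_time_params: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=dict
    )
    sleep_onset_params: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=dict
    )
    wake_slot_params: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=dict
    )
    abut_prob: dict[str, float] = dataclasses.field(default_factory=dict)
    missingness_rates: dict[str, float] = dataclasses.field(default_factory=dict)
    item_cutpoints: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    latent_loadings: dict[str, float] = dataclasses.field(default_factory=dict)
    code_probs: dict[str, float] = dataclasses.field(default_factory=dict)
    # share of variance of the sleep latents common to the three sleep measures
    sleep_cross_corr: float = 0.35
    # weight with which the injected effect also loads on the wake-time latent
    wake_effect_weight: float = 0.1
    # small covariate-dependent tilt of the diary subsample (0 = uniform)
    diary_tilt: float = 0.0
    # onset score assigned to diaries without any sleep onset
    onset_fallback_score: float = 1.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not (0.0 < self.diary_fraction <= 1.0):
            raise ConfigurationError("diary_fraction must lie in (0, 1]")
        for name, mapping in (
            ("participation_prob", self.participation_prob),
            ("abut_prob", self.abut_prob),
            ("missingness_rates", self.missingness_rates),
        ):
            for key, value in mapping.items():
                if not (0.0 <= float(value) <= 1.0):
                    raise ConfigurationError(
                        f"{name}[{key!r}] = {value} outside [0, 1]"
                    )
        for (day, pathway) in self.true_effects:
            if day not in DAY_TYPES:
                raise ConfigurationError(f"unknown day_type {day!r} in true_effects")
            if pathway not in TECH_PATHWAYS:
                raise ConfigurationError(
                    f"unknown technology pathway {pathway!r} in true_effects"
                )
        for item, cuts in self.item_cutpoints.items():
            arr = np.asarray(cuts, dtype=float)
            if arr.ndim != 1 or arr.size < 1:
                raise ConfigurationError(f"cutpoints for {item!r} must be a 1-d array")
            if not np.all(np.diff(arr) > 0):
                raise ConfigurationError(
                    f"cutpoints for {item!r} must be strictly increasing"
                )
        for day, params in self.digital_time_params.items():
            if params.get("mean", 1.0) <= 0:
                raise ConfigurationError(f"digital time mean for {day!r} must be > 0")
            if params.get("sd", 0.0) < 0:
                raise ConfigurationError(f"digital time sd for {day!r} must be >= 0")
        if not (0.0 <= self.sleep_cross_corr < 1.0):
            raise ConfigurationError("sleep_cross_corr must lie in [0, 1)")

    def effect(self, day_type: str, pathway: str) -> float:
        return float(self.true_effects.get((day_type, pathway), 0.0))

    def to_dict(self) -> dict[str, Any]:
        """JSON-serialisable snapshot (tuple keys flattened, arrays listed)."""
        out: dict[str, Any] = {}
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if field.name == "true_effects":
                value = {f"{d}.{p}": v for (d, p), v in value.items()}
            elif field.name == "item_cutpoints":
                value = {k: np.asarray(v).tolist() for k, v in value.items()}
            out[field.name] = value
        return out


# printed marginal targets used to calibrate the default ordinal items:
# (levels lo..hi, mean, sd)
_ITEM_TARGETS: dict[str, tuple[int, int, float, float]] = {
    # reversed bedtime score (higher = earlier); raw item stored as 6 - reversed
    "bedtime_rev_weekday": (1, 5, 3.06, 0.96),
    "bedtime_rev_weekend": (1, 5, 2.04, 0.93),
    # wake items chosen so total sleep means come out at 8.62 / 10.53 h
    "wake_weekday": (1, 5, 2.56, 0.90),
    "wake_weekend": (1, 6, 3.49, 1.00),
    "screen": (1, 8, 4.82, 1.26),
    "fall_asleep_time": (1, 5, 3.73, 1.27),
    "night_waking": (1, 6, 4.61, 1.37),
}


def _default_cutpoints() -> dict[str, np.ndarray]:
    return {
        name: calibrate_cutpoints(mean, sd, lo, hi)
        for name, (lo, hi, mean, sd) in _ITEM_TARGETS.items()
    }


#: published medians used as default injected effects, by (day, pathway)
DEFAULT_TRUE_EFFECTS: dict[tuple[str, str], float] = {
    ("weekday", "participation"): -0.02,
    ("weekday", "bedtime_use"): -0.02,
    ("weekday", "time_spent_diary"): -0.18,
    ("weekday", "time_spent_retro"): -0.23,
    ("weekend", "participation"): 0.01,
    ("weekend", "bedtime_use"): -0.02,
    ("weekend", "time_spent_diary"): -0.15,
    ("weekend", "time_spent_retro"): -0.13,
}

DEFAULT_DIFFICULTY_EFFECTS = {"fall_asleep_time": -0.067, "night_waking": -0.015}


def default_config(n_participants: int, seed: int = 0, **overrides: Any) -> GeneratorConfig:
    """Calibrated default configuration.

    The defaults target the printed descriptives: weekday/weekend diary
    participation 0.81/0.85, digital hours among participants 3.45/4.59,
    before-bed use 0.46/0.47, composite screen score 4.82, total retro sleep
    8.62/10.53 h, and diary onset scores 30.22/27.74.
    """
    participation = {"weekday": 0.81, "weekend": 0.85}
    cfg = GeneratorConfig(
        n_participants=n_participants,
        seed=seed,
        true_effects=dict(DEFAULT_TRUE_EFFECTS),
        difficulty_effects=dict(DEFAULT_DIFFICULTY_EFFECTS),
        participation_prob=participation,
        digital_time_params={
            "weekday": {"mean": 3.45, "sd": 2.49, "tech_loading": 0.30},
            "weekend": {"mean": 4.59, "sd": 2.98, "tech_loading": 0.30},
        },
        sleep_onset_params={
            "weekday": {"mean": 30.22, "sd": 14.41},
            "weekend": {"mean": 27.74, "sd": 13.81},
        },
        wake_slot_params={
            "weekday": {"mean": 19.5, "sd": 4.0},
            "weekend": {"mean": 28.0, "sd": 5.0},
        },
        # before-bed use target / participation target, so that
        # P(bedtime_use) = P(participation) * abut_prob hits 0.46 / 0.47
        abut_prob={
            "weekday": 0.46 / participation["weekday"],
            "weekend": 0.47 / participation["weekend"],
        },
        missingness_rates={
            "demographics": 0.005,
            "family": 0.04,
            "mother": 0.06,
            "child": 0.03,
            "sleep_items": 0.01,
            "screen_items": 0.01,
            "difficulties": 0.02,
        },
        item_cutpoints=_default_cutpoints(),
        latent_loadings={
            "screen_item": 0.75,
            "participation": 0.35,
            "sex": 0.25,
            "closeness": -0.15,
            "argue": 0.10,
            "motivation": 0.12,
        },
        code_probs={
            "DIG_MSG": 0.10,
            "DIG_SOCIAL": 0.20,
            "DIG_BROWSE": 0.20,
            "DIG_GAMES": 0.15,
            "DIG_TV": 0.35,
        },
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown configuration key: {key}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def null_config(n_participants: int, seed: int = 0, **overrides: Any) -> GeneratorConfig:
    """Default configuration with every injected effect set to zero."""
    cfg = default_config(n_participants, seed=seed, **overrides)
    cfg.true_effects = {k: 0.0 for k in cfg.true_effects}
    cfg.difficulty_effects = {k: 0.0 for k in cfg.difficulty_effects}
    return cfg


def _parse_effects(raw: Mapping[str, Any]) -> dict[tuple[str, str], float]:
    effects: dict[tuple[str, str], float] = {}
    for key, value in raw.items():
        if isinstance(value, Mapping):  # nested [true_effects.weekday] table
            for pathway, size in value.items():
                effects[(key, pathway)] = float(size)
        else:  # flat "weekday.time_spent_diary" key
            day, _, pathway = key.partition(".")
            effects[(day, pathway)] = float(value)
    return effects


def load_config(path: str, seed: int | None = None) -> GeneratorConfig:
    """Read a TOML configuration file (documented in the README).

    Only ``n_participants`` is required under ``[generator]``; every other key
    overrides the calibrated default.  ``--seed`` on the CLI wins over the
    file's seed.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    section = dict(raw.get("generator", raw))
    if "n_participants" not in section:
        raise ConfigurationError("missing config key: generator.n_participants")
    n = int(section.pop("n_participants"))
    if "true_effects" in section:
        section["true_effects"] = _parse_effects(section["true_effects"])
    if seed is not None:
        section["seed"] = seed
    section.setdefault("seed", 0)
    return default_config(n, **section)
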