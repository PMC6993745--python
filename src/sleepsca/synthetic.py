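"""Synthetic cohort and time-use diary generator.

One latent technology-propensity score per adolescent drives the four
technology pathways (diary participation, before-bed use, diary hours, and
the four retrospective screen items).  Configurable standardized effects are
injected additively on the latent sleep outcomes: for each day type the
realised technology quantities are empirically standardized, combined with
the configured effect sizes, and added to the latent diary sleep-onset score,
the latent retrospective bedtime, and (down-weighted) the latent wake time.
The residual scale is chosen from the realised effect variance so each latent
sleep outcome has unit variance, which makes the implied standardized
regression coefficient equal the configured effect for a single injected
pathway.

Diary days span 4 AM to 4 AM as 144 ten-minute primary-activity slots.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    DAY_TYPES,
    MISSINGNESS_BLOCKS,
    TECH_PATHWAYS,
    ConfigurationError,
    GeneratorConfig,
)

#: allowed diary activity codes; one code per 10-minute slot
CODES = ("SLEEP", "DIG_MSG", "DIG_SOCIAL", "DIG_BROWSE", "DIG_GAMES", "DIG_TV", "OTHER")
DIGITAL_CODES = ("DIG_MSG", "DIG_SOCIAL", "DIG_BROWSE", "DIG_GAMES", "DIG_TV")
N_SLOTS = 144

COHORT_COLUMNS = (
    "person_id",
    "sex",
    "age",
    "mother_white",
    "income",
    "father_home",
    "n_siblings",
    "word_activity",
    "nvq",
    "time_with_child",
    "kessler",
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
    "bedtime_weekday",
    "bedtime_weekend",
    "wake_weekday",
    "wake_weekend",
    "screen_tv",
    "screen_games",
    "screen_internet",
    "screen_social",
    "fall_asleep_time",
    "night_waking",
    "has_diary",
)


@dataclasses.dataclass
class LatentPerson:
    """Continuous latent state from which observed items are produced."""

    person_id: int
    tech_propensity: float
    sleep_baseline: float
    covariate_latents: dict[str, float] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class DiaryMatrix:
    """One person-day of 144 ten-minute activity codes (4 AM to 4 AM)."""

    person_id: int
    day_type: str
    slots: np.ndarray  # length 144, entries from CODES

    def __post_init__(self) -> None:
        self.slots = np.asarray(self.slots, dtype=object)
        if self.slots.shape != (N_SLOTS,):
            raise ValueError(f"diary must have exactly {N_SLOTS} slots")
        if self.day_type not in DAY_TYPES:
            raise ValueError(f"unknown day_type {self.day_type!r}")
        bad = set(self.slots) - set(CODES)
        if bad:
            raise ValueError(f"unknown activity codes: {sorted(bad)}")


def _bin_item(z: np.ndarray, cutpoints: np.ndarray, lo: int = 1) -> np.ndarray:
    """Threshold a latent z at the cutpoints; levels start at ``lo``."""
    return lo + np.searchsorted(np.asarray(cutpoints, float), z)


def _standardize(values: np.ndarray, defined: np.ndarray) -> np.ndarray:
    """Z-score over defined entries; zero elsewhere (no effect contribution)."""
    out = np.zeros_like(values, dtype=float)
    vals = values[defined]
    sd = vals.std()
    if vals.size and sd > 0:
        out[defined] = (vals - vals.mean()) / sd
    return out


def _clip_round(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(np.rint(values), lo, hi)


def generate_diary_day(
    person: LatentPerson,
    day_type: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    participation: bool | None = None,
    n_digital: int | None = None,
    onset_slot: int | None = None,
    wake_slot: int | None = None,
    abut: bool | None = None,
) -> DiaryMatrix:
    """Assemble one diary day.

    Explicit keyword overrides let :func:`generate_cohort` drive the assembly
    with effect-shifted onsets; when omitted, each quantity is drawn from the
    configuration with zero injected effect.

    Layout: sleep before ``wake_slot``, a single final transition into sleep
    at ``onset_slot`` (145 = no onset during the diary day), and digital
    episodes placed evening-weighted within the awake span.  With probability
    ``abut_prob`` one episode ends in the slot immediately before sleep onset;
    otherwise the three slots before onset carry no digital code, which keeps
    before-bed use independent of onset time under a null configuration.
    """
    if day_type not in DAY_TYPES:
        raise ConfigurationError(f"unknown day_type {day_type!r}")
    config.validate()

    p_part = config.participation_prob.get(day_type, 0.0)
    if participation is None:
        lam = config.latent_loadings.get("participation", 0.35)
        latent = lam * person.tech_propensity + np.sqrt(1 - lam**2) * rng.standard_normal()
        participation = bool(latent > stats.norm.ppf(1.0 - p_part)) if p_part > 0 else False
        if p_part >= 1.0:
            participation = True
    if onset_slot is None:
        params = config.sleep_onset_params[day_type]
        score = params["mean"] + params["sd"] * (
            0.5 * person.sleep_baseline + np.sqrt(0.75) * rng.standard_normal()
        )
        onset_slot = 145 if score < 0.5 else int(np.clip(np.rint(145 - score), 2, 144))
    if wake_slot is None:
        params = config.wake_slot_params[day_type]
        wake_slot = int(np.clip(np.rint(params["mean"] + params["sd"] * rng.standard_normal()), 1, 144))
    wake_slot = int(min(wake_slot, onset_slot - 1)) if onset_slot > 1 else 1
    wake_slot = max(wake_slot, 1)
    if n_digital is None:
        n_digital = _draw_digital_slots(person, day_type, config, rng)
    if abut is None:
        abut = bool(rng.random() < config.abut_prob.get(day_type, 0.0))

    slots = np.full(N_SLOTS, "OTHER", dtype=object)
    if wake_slot > 1:
        slots[: wake_slot - 1] = "SLEEP"
    if onset_slot <= N_SLOTS:
        slots[onset_slot - 1 :] = "SLEEP"

    if participation and n_digital > 0:
        _place_digital(slots, wake_slot, onset_slot, int(n_digital), abut, config, rng)

    return DiaryMatrix(person_id=person.person_id, day_type=day_type, slots=slots)


def _draw_digital_slots(
    person: LatentPerson,
    day_type: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> int:
    params = config.digital_time_params[day_type]
    enrichment = _participation_enrichment(
        params,
        config.participation_prob.get(day_type, 0.0),
        config.latent_loadings.get("participation", 0.35),
    )
    hours = _draw_hours(
        np.asarray([person.tech_propensity]), params, rng, enrichment
    )[0]
    return max(1, int(np.rint(hours * 6)))


def _participation_enrichment(
    params: dict[str, float], p_part: float, part_loading: float
) -> float:
    """Selection factor E[e^{k*tech} | participant] / E[e^{k*tech}].

    Participation and hours share the technology latent, so the published
    mean-among-participants exceeds the marginal mean by Phi(k*a - c) / p
    (bivariate-normal truncation identity with c the participation threshold).
    """
    mean, sd = float(params["mean"]), float(params["sd"])
    if sd == 0.0 or not (0.0 < p_part < 1.0):
        return 1.0
    sigma_tot_sq = np.log1p((sd / mean) ** 2)
    k = min(float(params.get("tech_loading", 0.0)), np.sqrt(sigma_tot_sq) * 0.99)
    c = stats.norm.ppf(1.0 - p_part)
    return float(stats.norm.cdf(k * part_loading - c) / p_part)


def _draw_hours(
    tech: np.ndarray,
    params: dict[str, float],
    rng: np.random.Generator,
    enrichment: float = 1.0,
) -> np.ndarray:
    """Right-skewed daily digital hours, calibrated among participants.

    Log-normal with a technology loading k on the log scale; the location is
    ``ln(mean / enrichment) - sigma_tot^2/2`` so the mean *conditional on
    participation* equals the target mean.  ``sd == 0`` degenerates to a
    constant.
    """
    mean, sd = float(params["mean"]), float(params["sd"])
    if sd == 0.0:
        return np.full(tech.shape, mean)
    sigma_tot_sq = np.log1p((sd / mean) ** 2)
    k = float(params.get("tech_loading", 0.0))
    if k**2 >= sigma_tot_sq:
        k = np.sqrt(sigma_tot_sq) * 0.99
    sigma_eps = np.sqrt(sigma_tot_sq - k**2)
    # ln H = mu + k*tech + sigma_eps*eps has total log-variance sigma_tot_sq
    mu = np.log(mean / enrichment) - sigma_tot_sq / 2.0
    return np.exp(mu + k * tech + sigma_eps * rng.standard_normal(tech.shape))


def _place_digital(
    slots: np.ndarray,
    wake_slot: int,
    onset_slot: int,
    budget: int,
    abut: bool,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    """Place exactly ``min(budget, capacity)`` digital slots as episodes."""
    end = min(onset_slot, N_SLOTS + 1)  # first sleeping slot (1-based), 145 if none
    awake_lo, awake_hi = wake_slot - 1, end - 1  # 0-based half-open awake span
    if awake_hi <= awake_lo:
        return
    # 3 slots before the *measured* onset (no-onset diaries score the 4 AM
    # fallback, slot 144, so their window is slots 141-143)
    measured_onset = min(onset_slot, N_SLOTS)
    window = set(range(max(awake_lo, measured_onset - 4), min(measured_onset - 1, awake_hi)))

    codes = list(config.code_probs) or list(DIGITAL_CODES)
    probs = np.asarray([config.code_probs.get(c, 1.0) for c in codes], float)
    probs = probs / probs.sum()

    free = np.zeros(N_SLOTS, dtype=bool)
    free[awake_lo:awake_hi] = True

    def assign(idx: Iterable[int]) -> None:
        code = codes[rng.choice(len(codes), p=probs)]
        for i in idx:
            slots[i] = code
            free[i] = False

    if abut and window:
        length = min(budget, 1 + int(rng.poisson(2.0)))
        placed = []
        i = max(window)  # episode ends in the slot just before measured onset
        while i >= awake_lo and len(placed) < length and free[i]:
            placed.append(i)
            i -= 1
        assign(placed)
        budget -= len(placed)

    for w in window:  # non-abutting episodes never enter the before-bed window
        free[w] = False

    while budget > 0:
        candidates = np.flatnonzero(free)
        if candidates.size == 0:
            break
        weights = np.exp(candidates / 36.0)  # evening-weighted starts
        start = int(rng.choice(candidates, p=weights / weights.sum()))
        length = min(budget, 1 + int(rng.poisson(5.0)))
        episode = []
        i = start
        while i < N_SLOTS and free[i] and len(episode) < length:
            episode.append(i)
            i += 1
        assign(episode)
        budget -= len(episode)


def _draw_covariates(
    n: int, tech: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    load = config.latent_loadings
    cols: dict[str, np.ndarray] = {}
    lam = load.get("sex", 0.0)
    cols["sex"] = (
        lam * tech + np.sqrt(1 - lam**2) * rng.standard_normal(n) > 0
    ).astype(float)
    cols["age"] = rng.choice([13.0, 14.0, 15.0], size=n, p=[0.2410, 0.7455, 0.0135])
    cols["mother_white"] = (rng.random(n) < 0.85).astype(float)
    cols["income"] = np.round(np.exp(np.log(550.0) + 0.6 * rng.standard_normal(n)), 2)
    cols["father_home"] = (rng.random(n) < 0.75).astype(float)
    cols["n_siblings"] = rng.poisson(1.3, size=n).astype(float)
    cols["word_activity"] = _clip_round(12.0 + 4.0 * rng.standard_normal(n), 0, 20)
    cols["nvq"] = rng.choice(
        [1.0, 2.0, 3.0, 4.0, 5.0], size=n, p=[0.12, 0.22, 0.30, 0.22, 0.14]
    )
    cols["time_with_child"] = _clip_round(3.0 + 1.0 * rng.standard_normal(n), 1, 5)
    cols["kessler"] = _clip_round(4.5 + 3.8 * rng.standard_normal(n), 0, 24)

    close_l = load.get("closeness", 0.0)
    argue_l = load.get("argue", 0.0)
    for col in ("close_mother", "close_father"):
        z = close_l * tech + np.sqrt(1 - close_l**2) * rng.standard_normal(n)
        cols[col] = _clip_round(3.4 + 0.75 * z, 1, 4)
    for col in ("argue_mother", "argue_father"):
        z = argue_l * tech + np.sqrt(1 - argue_l**2) * rng.standard_normal(n)
        cols[col] = _clip_round(2.0 + 0.8 * z, 1, 4)
    cols["longterm_illness"] = (rng.random(n) < 0.13).astype(float)

    mot_l = load.get("motivation", 0.0)
    for j in range(1, 7):
        z = mot_l * tech + np.sqrt(1 - mot_l**2) * rng.standard_normal(n)
        loc = 1.8 if j <= 2 else 2.8  # first two items positively keyed
        cols[f"motiv_{j}"] = _clip_round(loc + 0.8 * z, 1, 4)
    return cols


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, list[DiaryMatrix]]:
    """Generate a cohort table and time-use diaries for the diary subsample.

    Deterministic for a fixed ``config.seed``.  Latent technology behaviour
    (participation, daily hours, before-bed episodes) is drawn for every
    person on both day types so injected effects act identically on diary and
    retrospective outcomes; diaries are materialised only for the subsample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    tech = rng.standard_normal(n)
    sleep_base = rng.standard_normal(n)
    cols = _draw_covariates(n, tech, config, rng)

    # four retrospective screen items from a shared latent
    screen_cuts = config.item_cutpoints["screen"]
    a = config.latent_loadings.get("screen_item", 0.75)
    screen_items = {}
    for col in ("screen_tv", "screen_games", "screen_internet", "screen_social"):
        z = a * tech + np.sqrt(1 - a**2) * rng.standard_normal(n)
        screen_items[col] = _bin_item(z, screen_cuts).astype(float)
        cols[col] = screen_items[col]
    composite = np.mean(np.column_stack(list(screen_items.values())), axis=1)

    # latent technology behaviour per day type
    behaviour: dict[str, dict[str, np.ndarray]] = {}
    p_load = config.latent_loadings.get("participation", 0.35)
    for day in DAY_TYPES:
        p = config.participation_prob[day]
        latent = p_load * tech + np.sqrt(1 - p_load**2) * rng.standard_normal(n)
        if p >= 1.0:
            part = np.ones(n, dtype=bool)
        elif p <= 0.0:
            part = np.zeros(n, dtype=bool)
        else:
            part = latent > stats.norm.ppf(1.0 - p)
        enrichment = _participation_enrichment(
            config.digital_time_params[day], p, p_load
        )
        hours = _draw_hours(tech, config.digital_time_params[day], rng, enrichment)
        n_dig = np.maximum(1, np.rint(hours * 6)).astype(int)
        abut = rng.random(n) < config.abut_prob.get(day, 0.0)
        behaviour[day] = {
            "participation": part,
            "n_digital": n_dig,
            "hours_q": n_dig / 6.0,
            "abut": abut,
        }

    # injected standardized effects -> latent sleep outcomes
    rho = config.sleep_cross_corr
    onset_slots: dict[str, np.ndarray] = {}
    wake_slots: dict[str, np.ndarray] = {}
    for day in DAY_TYPES:
        beh = behaviour[day]
        part = beh["participation"]
        z_paths = {
            "participation": _standardize(part.astype(float), np.ones(n, bool)),
            "bedtime_use": _standardize(
                (part & beh["abut"]).astype(float), np.ones(n, bool)
            ),
            "time_spent_diary": _standardize(beh["hours_q"], part),
            "time_spent_retro": _standardize(composite, np.ones(n, bool)),
        }
        effect_term = np.zeros(n)
        for pathway in TECH_PATHWAYS:
            effect_term += config.effect(day, pathway) * z_paths[pathway]
        var_e = float(effect_term.var())

        shared = np.sqrt(rho) * (
            np.sqrt(0.6) * sleep_base + np.sqrt(0.4) * rng.standard_normal(n)
        )

        def sleep_latent(weight: float, shared_sign: float = 1.0) -> np.ndarray:
            resid_scale = np.sqrt(max(1.0 - weight**2 * var_e, 0.04))
            noise = shared_sign * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
            return weight * effect_term + resid_scale * noise

        z_onset = sleep_latent(1.0)
        z_bedrev = sleep_latent(1.0)
        # late-to-bed adolescents wake late: the wake *lateness* latent loads
        # negatively on the shared earliness factor, pulling the total-sleep
        # spread toward the printed 1.04 / 1.23 h
        z_wake = sleep_latent(config.wake_effect_weight, shared_sign=-1.0)

        onset = config.sleep_onset_params[day]
        score = onset["mean"] + onset["sd"] * z_onset
        slot = np.where(
            score < 0.5, 145, np.clip(np.rint(145 - score), 2, 144)
        ).astype(int)
        onset_slots[day] = slot

        wake_p = config.wake_slot_params[day]
        w = _clip_round(
            wake_p["mean"] + wake_p["sd"] * (0.5 * z_wake + np.sqrt(0.75) * rng.standard_normal(n)),
            1,
            144,
        ).astype(int)
        wake_slots[day] = np.maximum(1, np.minimum(w, slot - 1))

        rev = _bin_item(z_bedrev, config.item_cutpoints[f"bedtime_rev_{day}"])
        cols[f"bedtime_{day}"] = (6 - rev).astype(float)
        wake_cuts = config.item_cutpoints[f"wake_{day}"]
        cols[f"wake_{day}"] = _bin_item(z_wake, wake_cuts).astype(float)

    # sleep difficulties driven by the composite score
    z_comp = _standardize(composite, np.ones(n, bool))
    for item in ("fall_asleep_time", "night_waking"):
        beta = float(config.difficulty_effects.get(item, 0.0))
        resid = np.sqrt(max(1.0 - beta**2, 0.04))
        z = beta * z_comp + resid * rng.standard_normal(n)
        cols[item] = _bin_item(z, config.item_cutpoints[item]).astype(float)

    # diary subsample (uniform by default; optional covariate tilt)
    draw = rng.random(n)
    if config.diary_tilt != 0.0:
        tilt = config.diary_tilt * (cols["sex"] - 0.5 + 0.2 * tech)
        has_diary = draw < np.clip(config.diary_fraction + tilt, 0.0, 1.0)
    else:
        has_diary = draw < config.diary_fraction

    table = pd.DataFrame({"person_id": np.arange(1, n + 1)})
    for col in COHORT_COLUMNS:
        if col in ("person_id", "has_diary"):
            continue
        table[col] = cols[col]
    table["has_diary"] = has_diary.astype(bool)

    table = apply_missingness(table, config, rng)

    diaries: list[DiaryMatrix] = []
    diary_idx = np.flatnonzero(has_diary)
    for day in DAY_TYPES:
        beh = behaviour[day]
        for i in diary_idx:
            person = LatentPerson(
                person_id=int(i + 1),
                tech_propensity=float(tech[i]),
                sleep_baseline=float(sleep_base[i]),
            )
            diaries.append(
                generate_diary_day(
                    person,
                    day,
                    config,
                    rng,
                    participation=bool(beh["participation"][i]),
                    n_digital=int(beh["n_digital"][i]),
                    onset_slot=int(onset_slots[day][i]),
                    wake_slot=int(wake_slots[day][i]),
                    abut=bool(beh["abut"][i]),
                )
            )
    return table, diaries


def apply_missingness(
    table: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Independently blank targeted fields at the configured rates.

    Keys of ``missingness_rates`` may be block names (expanded via
    ``MISSINGNESS_BLOCKS``) or individual column names.  ``person_id`` and
    ``has_diary`` are never blanked.
    """
    for key, rate in config.missingness_rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ConfigurationError(f"missingness rate for {key!r} outside [0, 1]")
    out = table.copy()
    for key, rate in config.missingness_rates.items():
        if rate == 0.0:
            continue
        columns = MISSINGNESS_BLOCKS.get(key, (key,))
        for col in columns:
            if col in ("person_id", "has_diary") or col not in out.columns:
                continue
            mask = rng.random(len(out)) < rate
            out.loc[mask, col] = np.nan
    return out


def diaries_to_frame(diaries: Sequence[DiaryMatrix]) -> pd.DataFrame:
    """Long representation: person_id, day_type, slot (1-144), code."""
    records = {
        "person_id": np.repeat([d.person_id for d in diaries], N_SLOTS),
        "day_type": np.repeat([d.day_type for d in diaries], N_SLOTS),
        "slot": np.tile(np.arange(1, N_SLOTS + 1), len(diaries)),
        "code": np.concatenate([d.slots for d in diaries]) if diaries else np.array([]),
    }
    return pd.DataFrame(records)


def frame_to_diaries(frame: pd.DataFrame) -> list[DiaryMatrix]:
    diaries = []
    for (pid, day), group in frame.groupby(["person_id", "day_type"], sort=True):
        ordered = group.sort_values("slot")
        diaries.append(
            DiaryMatrix(person_id=int(pid), day_type=str(day), slots=ordered["code"].to_numpy())
        )
    return diaries
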