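"""Synthetic NEISS-FISS-like worlds with known ground truth.

The generator emulates the structure of the national firearm-injury
surveillance sample that motivates this package: a stratified probability
sample of hospitals (PSUs) with case weights, 23 years of emergency-
department visits, coder-shorthand narratives whose vocabulary depends on
the true injury location, covariates (intent, disposition, body part,
demographics) correlated with location, covariate-dependent missingness of
the coded location (~45% missing by default), and mid-series high-volume
hospital replacement events that inflate weighted counts.

Every world carries a :class:`TruthTable` — the true four-class location of
every record (including masked ones), the true population shares, the
masked ids, and the replacement event log — so that estimator-recovery and
coverage experiments can score themselves against known truth.

All randomness flows from the single seed in :class:`GeneratorConfig`;
there are no hidden entropy sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import (
    AGE_GROUPS, BODY_PARTS, DISPOSITIONS, INTENTS, LOCATION_CLASSES, MISSING,
    RACES, RecordSet, SEXES, STRATA,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


# --------------------------------------------------------------------------
# Default condition tables.  Conditional distributions are loosely
# calibrated to the published surveillance sample margins (see margins.py):
# victims predominantly male and young, intent mostly assault, street
# injuries overwhelmingly assaults, home injuries split between assault and
# unintentional, hospitalization slightly more than half.
# --------------------------------------------------------------------------

#: Location-indicative narrative terms, disjoint across classes.  Values are
#: relative emission weights within the class.
DEFAULT_LOCATION_TERMS: dict[str, dict[str, float]] = {
    "HOME": {"HUSBAND": 1, "BOYFRIEND": 1, "HOME": 2, "APARTMENT": 1,
             "BEDROOM": 1, "CLEANING": 1, "DOMESTIC": 1},
    "STREET": {"STREET": 2, "CAR": 2, "DRIVING": 1, "HIGHWAY": 1,
               "SIDEWALK": 1, "DRIVEBY": 1, "CORNER": 1},
    "PUBLIC": {"STORE": 2, "BAR": 1, "CLUB": 1, "RESTAURANT": 1,
               "PARKING": 1},
    "OTHER": {"SCHOOL": 1, "WOODS": 1, "HUNTING": 1, "RANGE": 1, "FARM": 1},
}

#: Shared background vocabulary (location-uninformative coder shorthand).
DEFAULT_BACKGROUND_TERMS: dict[str, float] = {
    "SHOT": 4, "GSW": 3, "WOUND": 2, "GUNSHOT": 2, "PT": 2, "MALE": 1,
    "LEFT": 1, "RIGHT": 1, "FRIEND": 1, "POLICE": 1, "UNKNOWN": 1,
    "GUN": 2, "BULLET": 1, "XRAY": 1, "ADMIT": 1,
}

#: Tokens appended when the incident intent leaves a trace in the text.
INTENT_TOKENS: dict[str, tuple[str, ...]] = {
    "assault": ("ASSAULT",),
    "unintentional": ("ACCIDENTLY", "ACCIDENTALLY"),
    "self_harm": ("SELFINFL",),
    "unknown": (),
}
INTENT_TOKEN_PROB = {"assault": 0.35, "unintentional": 0.35,
                     "self_harm": 0.5, "unknown": 0.0}

#: Body-part shorthand included in most narratives.
BODY_PART_TOKENS: dict[str, str] = {
    "head_neck": "HEAD", "upper_trunk": "CHEST", "lower_trunk": "ABD",
    "arm_hand": "HAND", "leg_foot": "LEG", "other": "BODY",
}

#: Conditional intent distribution given true location.
DEFAULT_INTENT_GIVEN_LOCATION: dict[str, dict[str, float]] = {
    "HOME": {"assault": 0.40, "unintentional": 0.37, "self_harm": 0.14, "unknown": 0.09},
    "STREET": {"assault": 0.88, "unintentional": 0.03, "self_harm": 0.01, "unknown": 0.08},
    "PUBLIC": {"assault": 0.79, "unintentional": 0.12, "self_harm": 0.02, "unknown": 0.07},
    "OTHER": {"assault": 0.45, "unintentional": 0.40, "self_harm": 0.08, "unknown": 0.07},
}

DEFAULT_RACE_GIVEN_LOCATION: dict[str, dict[str, float]] = {
    "HOME": {"black": 0.44, "white": 0.26, "not_stated": 0.18, "other": 0.12},
    "STREET": {"black": 0.57, "white": 0.14, "not_stated": 0.18, "other": 0.11},
    "PUBLIC": {"black": 0.42, "white": 0.24, "not_stated": 0.20, "other": 0.14},
    "OTHER": {"black": 0.35, "white": 0.35, "not_stated": 0.18, "other": 0.12},
}

DEFAULT_MALE_PROB_GIVEN_LOCATION = {"HOME": 0.84, "STREET": 0.92,
                                    "PUBLIC": 0.90, "OTHER": 0.88}

DEFAULT_AGE_DIST = {"0-14": 0.039, "15-24": 0.458, "25-34": 0.266,
                    "35-44": 0.126, "45-54": 0.062, "55-64": 0.026, "65+": 0.023}

DEFAULT_DISPOSITION_DIST = {"treated_released": 0.410, "transferred_released": 0.033,
                            "transferred_hospital": 0.001, "hospitalized": 0.537,
                            "observation": 0.019}

DEFAULT_BODY_PART_DIST = {"head_neck": 0.142, "upper_trunk": 0.181,
                          "lower_trunk": 0.165, "arm_hand": 0.153,
                          "leg_foot": 0.343, "other": 0.016}

#: Raw nine-code location given the true four-class location.
RAW_GIVEN_CLASS: dict[str, dict[str, float]] = {
    "HOME": {"home": 0.70, "apartment": 0.28, "mobile_home": 0.02},
    "STREET": {"street_highway": 1.0},
    "PUBLIC": {"other_public": 1.0},
    "OTHER": {"recreation": 0.35, "school": 0.30, "industry": 0.15, "farm": 0.20},
}

#: Stratum share of record volume (very large hospitals dominate).
DEFAULT_STRATUM_VOLUME = {"small": 0.040, "medium": 0.065, "large": 0.145,
                          "very_large": 0.717, "childrens": 0.033}

#: Hospitals per stratum (defaults sum to 100).
DEFAULT_STRATUM_ALLOCATION = {"small": 25, "medium": 20, "large": 20,
                              "very_large": 25, "childrens": 10}

#: Case-weight lognormal location parameter by stratum: low-volume strata
#: are sampled at lower rates, so their case weights are larger.
DEFAULT_WEIGHT_MODEL = {"small": (4.4, 0.30), "medium": (3.7, 0.30),
                        "large": (3.0, 0.30), "very_large": (2.3, 0.30),
                        "childrens": (3.4, 0.30)}

_AGE_BOUNDS = {"0-14": (1, 14), "15-24": (15, 24), "25-34": (25, 34),
               "35-44": (35, 44), "45-54": (45, 54), "55-64": (55, 64),
               "65+": (65, 90)}


@dataclass
class MissingnessModel:
    """Logistic model for P(location code missing | covariates).

    logit p = intercept + stratum effect + intent effect + body-part effect
    (+ optionally a true-location effect, which makes the mechanism
    non-ignorable).  When ``intercept`` is None it is solved by bisection so
    the realized mean missingness equals ``target_rate``.
    """

    target_rate: float = 0.45
    intercept: float | None = None
    stratum: dict[str, float] = field(default_factory=dict)
    intent: dict[str, float] = field(default_factory=dict)
    body_part: dict[str, float] = field(default_factory=dict)
    location: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, df: pd.DataFrame, true_locations: pd.Series) -> np.ndarray:
        eta = np.zeros(len(df))
        for col, effects in (("stratum", self.stratum), ("intent", self.intent),
                             ("body_part", self.body_part)):
            if effects:
                eta += df[col].map(effects).fillna(0.0).to_numpy()
        if self.location:
            eta += true_locations.map(self.location).fillna(0.0).to_numpy()
        return eta

    def probabilities(self, df: pd.DataFrame, true_locations: pd.Series) -> np.ndarray:
        eta = self.linear_predictor(df, true_locations)
        if self.intercept is not None:
            return 1.0 / (1.0 + np.exp(-(self.intercept + eta)))
        # calibrate the intercept so the mean probability hits target_rate
        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if (1.0 / (1.0 + np.exp(-(mid + eta)))).mean() < self.target_rate:
                lo = mid
            else:
                hi = mid
        return 1.0 / (1.0 + np.exp(-(0.5 * (lo + hi) + eta)))


def default_missingness_model() -> MissingnessModel:
    """Covariate-dependent but location-ignorable-given-text mechanism:
    missingness skews toward assaults, unknown intent, trunk wounds and
    very large hospitals, matching the published missing-column profile."""
    return MissingnessModel(
        target_rate=0.45,
        stratum={"very_large": 0.40, "small": -0.80, "medium": -0.30,
                 "childrens": -0.30},
        intent={"assault": 0.30, "unknown": 1.00, "unintentional": -0.40},
        body_part={"upper_trunk": 0.30},
    )


def nonignorable_missingness_model() -> MissingnessModel:
    """Mechanism with a direct effect of the true location: street injuries
    are far more likely to lose their code.  Demonstrates the bias of the
    known-records-only estimator."""
    m = default_missingness_model()
    return replace(m, location={"STREET": 1.20, "HOME": -0.80})


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic surveillance world."""

    n_records: int = 20_000
    years: tuple[int, int] = (1993, 2015)
    n_hospitals: int = 100
    stratum_allocation: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_ALLOCATION))
    location_shares: tuple[float, float, float, float] = (0.30, 0.50, 0.15, 0.05)
    location_terms: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LOCATION_TERMS.items()})
    background_terms: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_TERMS))
    p_location_token: float = 0.35
    narrative_length: dict[int, float] = field(
        default_factory=lambda: {5: 0.15, 6: 0.25, 7: 0.25, 8: 0.20, 9: 0.15})
    missingness_model: MissingnessModel = field(default_factory=default_missingness_model)
    weight_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_MODEL))
    replacement_events: list[tuple[str, int, float]] = field(default_factory=list)
    intent_given_location: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENT_GIVEN_LOCATION.items()})
    race_given_location: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RACE_GIVEN_LOCATION.items()})
    male_prob_given_location: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MALE_PROB_GIVEN_LOCATION))
    bb_nongsw_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        shares = np.asarray(self.location_shares, dtype=float)
        if shares.shape != (4,) or abs(shares.sum() - 1.0) > 1e-12 or (shares < 0).any():
            raise ConfigError(f"location_shares must be a 4-simplex, got {self.location_shares}")
        if self.years[0] > self.years[1]:
            raise ConfigError("years range reversed")
        if len(self.narrative_length) < 1 or min(self.narrative_length) < 3:
            raise ConfigError("narrative_length support must be >= 3 tokens")
        for cls, terms in self.location_terms.items():
            for t, w in terms.items():
                if not (0 < w):
                    raise ConfigError(f"non-positive emission weight for {t}")
        if sum(self.stratum_allocation.values()) != self.n_hospitals:
            raise ConfigError("stratum_allocation must sum to n_hospitals")


@dataclass
class TruthTable:
    """Ground truth of a generated world."""

    true_locations: pd.Series          # record_id -> LocationClass4
    true_shares: dict[str, float]      # configured population shares
    masked_ids: list[str] = field(default_factory=list)
    replacement_log: list[dict] = field(default_factory=list)
    n_flagged_bb: int = 0

    def masked_true_shares(self) -> dict[str, float]:
        """Empirical true-class shares among masked records."""
        sub = self.true_locations.loc[self.masked_ids]
        counts = sub.value_counts()
        return {c: counts.get(c, 0) / max(len(sub), 1) for c in LOCATION_CLASSES}


def _draw(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    keys = list(dist)
    p = np.asarray([dist[k] for k in keys], dtype=float)
    return np.asarray(keys, dtype=object)[rng.choice(len(keys), size=n, p=p / p.sum())]


def _conditional_draw(rng, mapping: dict[str, dict[str, float]],
                      condition: np.ndarray) -> np.ndarray:
    out = np.empty(len(condition), dtype=object)
    for level, dist in mapping.items():
        idx = np.flatnonzero(condition == level)
        if len(idx):
            out[idx] = _draw(rng, dist, len(idx))
    return out


def _narratives(rng, config: GeneratorConfig, locations, sexes, ages,
                intents, body_parts) -> list[str]:
    n = len(locations)
    lengths = _draw(rng, {str(k): v for k, v in config.narrative_length.items()}, n)
    lengths = lengths.astype(int)
    loc_term_tables = {
        cls: (list(terms), np.asarray(list(terms.values()), float) /
              sum(terms.values()))
        for cls, terms in config.location_terms.items()
    }
    bg_terms = list(config.background_terms)
    bg_p = np.asarray(list(config.background_terms.values()), float)
    bg_p /= bg_p.sum()

    texts: list[str] = []
    for i in range(n):
        L = lengths[i]
        cls = locations[i]
        toks = [f"{ages[i]}YO{'M' if sexes[i] == 'male' else 'F'}", "GSW"]
        terms, p = loc_term_tables[cls]
        is_loc = rng.random(L) < config.p_location_token
        loc_idx = rng.choice(len(terms), size=int(is_loc.sum()), p=p)
        bg_idx = rng.choice(len(bg_terms), size=int(L - is_loc.sum()), p=bg_p)
        li = bi = 0
        for flag in is_loc:
            if flag:
                toks.append(terms[loc_idx[li]]); li += 1
            else:
                toks.append(bg_terms[bg_idx[bi]]); bi += 1
        itoks = INTENT_TOKENS[intents[i]]
        if itoks and rng.random() < INTENT_TOKEN_PROB[intents[i]]:
            toks.append(itoks[rng.integers(len(itoks))])
        toks.append(BODY_PART_TOKENS[body_parts[i]])
        texts.append(" ".join(toks))
    return texts


def generate_records(config: GeneratorConfig) -> tuple[RecordSet, TruthTable]:
    """Generate a complete world (locations present; no masking applied).

    Use :func:`impose_missingness` and :func:`inject_hospital_replacement`
    afterwards, or :func:`generate_world` for the full chain.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_records

    # survey design: stratum by volume share, hospital uniform within stratum
    hospitals, hosp_stratum = [], {}
    h = 0
    for stratum in STRATA:
        for _ in range(config.stratum_allocation.get(stratum, 0)):
            hid = f"H{h:03d}"
            hospitals.append(hid)
            hosp_stratum[hid] = stratum
            h += 1
    stratum_of_record = _draw(rng, DEFAULT_STRATUM_VOLUME, n)
    hosp_by_stratum = {s: [x for x in hospitals if hosp_stratum[x] == s] for s in STRATA}
    hospital_ids = np.array([
        hosp_by_stratum[s][rng.integers(len(hosp_by_stratum[s]))]
        for s in stratum_of_record
    ], dtype=object)

    years = rng.integers(config.years[0], config.years[1] + 1, size=n)
    weights = np.array([
        rng.lognormal(*config.weight_model[s]) for s in stratum_of_record
    ])

    locations = np.asarray(LOCATION_CLASSES, dtype=object)[
        rng.choice(4, size=n, p=np.asarray(config.location_shares, float))
    ]
    raw_locations = _conditional_draw(rng, RAW_GIVEN_CLASS, locations)
    intents = _conditional_draw(rng, config.intent_given_location, locations)
    races = _conditional_draw(rng, config.race_given_location, locations)
    male_p = np.asarray([config.male_prob_given_location[c] for c in locations])
    sexes = np.where(rng.random(n) < male_p, "male", "female").astype(object)
    age_groups = _draw(rng, DEFAULT_AGE_DIST, n)
    ages = np.array([rng.integers(_AGE_BOUNDS[g][0], _AGE_BOUNDS[g][1] + 1)
                     for g in age_groups])
    dispositions = _draw(rng, DEFAULT_DISPOSITION_DIST, n)
    body_parts = _draw(rng, DEFAULT_BODY_PART_DIST, n)
    flagged = rng.random(n) < config.bb_nongsw_rate

    narratives = _narratives(rng, config, locations, sexes, ages, intents,
                             body_parts)
    record_ids = [f"R{i:06d}" for i in range(n)]

    df = pd.DataFrame({
        "record_id": record_ids,
        "year": years,
        "hospital_id": hospital_ids,
        "stratum": stratum_of_record,
        "weight": weights,
        "narrative": narratives,
        "sex": sexes,
        "race": races,
        "age_group": age_groups,
        "intent": intents,
        "disposition": dispositions,
        "body_part": body_parts,
        "raw_location": raw_locations,
        "is_bb_or_nongsw": flagged,
    })
    truth = TruthTable(
        true_locations=pd.Series(locations, index=record_ids, name="true_location"),
        true_shares=dict(zip(LOCATION_CLASSES, config.location_shares)),
        n_flagged_bb=int(flagged.sum()),
    )
    return RecordSet(df, provenance=f"synthetic seed={config.seed}"), truth


def impose_missingness(rs: RecordSet, truth: TruthTable,
                       missingness_model: MissingnessModel,
                       seed: int) -> tuple[RecordSet, TruthTable]:
    """Mask location codes by Bernoulli draws from the logistic model.

    Only ``raw_location`` changes; the narrative is never altered, so the
    text signal survives masking (the premise of text-based imputation).
    """
    rng = np.random.default_rng(seed)
    df = rs.records.copy()
    true_locs = truth.true_locations.loc[df["record_id"]].reset_index(drop=True)
    p = missingness_model.probabilities(df, true_locs)
    mask = rng.random(len(df)) < p
    df.loc[mask, "raw_location"] = MISSING
    masked_ids = df.loc[mask, "record_id"].tolist()
    new_truth = TruthTable(truth.true_locations, truth.true_shares,
                           masked_ids=sorted(set(truth.masked_ids) | set(masked_ids)),
                           replacement_log=list(truth.replacement_log),
                           n_flagged_bb=truth.n_flagged_bb)
    logger.info("masked %d/%d locations (%.1f%%)", mask.sum(), len(df),
                100 * mask.mean())
    return RecordSet(df, provenance=rs.provenance + " [masked]"), new_truth


def inject_hospital_replacement(rs: RecordSet, truth: TruthTable,
                                events: list[tuple[str, int, float]],
                                seed: int,
                                years: tuple[int, int] | None = None,
                                ) -> tuple[RecordSet, TruthTable]:
    """Multiply a hospital's annual record volume from an event year onward.

    Emulates mid-series replacement of a low-volume PSU by a high-volume
    one: for multiplier m > 1, Poisson((m-1)·n) extra records are resampled
    (with fresh ids) from the hospital-year's existing records; for m < 1
    records are thinned.  The event log lands in the truth table so the
    replacement correction can be scored.
    """
    if not events:
        return rs, truth
    rng = np.random.default_rng(seed)
    df = rs.records.copy()
    yr_lo = int(df["year"].min()) if years is None else years[0]
    yr_hi = int(df["year"].max()) if years is None else years[1]
    extra_frames = []
    drop_idx: list[int] = []
    log = list(truth.replacement_log)
    new_truth_rows = {}
    rep_counter = 0
    for hospital_id, event_year, mult in events:
        if not (yr_lo <= event_year <= yr_hi):
            raise ConfigError(f"replacement year {event_year} outside {yr_lo}-{yr_hi}")
        if hospital_id not in set(df["hospital_id"]):
            raise ConfigError(f"unknown hospital {hospital_id!r} in replacement event")
        for year in range(event_year, yr_hi + 1):
            block = df[(df["hospital_id"] == hospital_id) & (df["year"] == year)]
            if mult > 1:
                n_extra = rng.poisson((mult - 1.0) * len(block))
                if n_extra and len(block):
                    picks = block.sample(n=n_extra, replace=True,
                                         random_state=int(rng.integers(2**31)))
                    picks = picks.copy()
                    new_ids = [f"{rid}-rep{rep_counter + j}"
                               for j, rid in enumerate(picks["record_id"])]
                    rep_counter += n_extra
                    for new_id, old_id in zip(new_ids, picks["record_id"]):
                        new_truth_rows[new_id] = truth.true_locations.loc[old_id]
                    picks["record_id"] = new_ids
                    extra_frames.append(picks)
            elif mult < 1:
                keep = rng.random(len(block)) < mult
                drop_idx.extend(block.index[~keep].tolist())
        log.append({"hospital_id": hospital_id, "year": event_year,
                    "multiplier": float(mult)})
    if drop_idx:
        df = df.drop(index=drop_idx)
    if extra_frames:
        df = pd.concat([df, *extra_frames], ignore_index=True)
    df = df.reset_index(drop=True)
    true_locs = pd.concat([truth.true_locations,
                           pd.Series(new_truth_rows, name="true_location", dtype=object)])
    new_truth = TruthTable(true_locs, truth.true_shares,
                           masked_ids=list(truth.masked_ids),
                           replacement_log=log, n_flagged_bb=truth.n_flagged_bb)
    return RecordSet(df, provenance=rs.provenance + " [replacement]"), new_truth


def generate_world(config: GeneratorConfig) -> tuple[RecordSet, TruthTable]:
    """generate → inject replacement events → impose missingness."""
    rs, truth = generate_records(config)
    if config.replacement_events:
        rs, truth = inject_hospital_replacement(
            rs, truth, config.replacement_events, seed=config.seed + 1,
            years=config.years)
    rs, truth = impose_missingness(rs, truth, config.missingness_model,
                                   seed=config.seed + 2)
    return rs, truth
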