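"""Survey-weighted national estimates of gunshot-injury locations.

Observed and model-predicted locations are combined with case weights to
produce mean annual national estimates per location class, with and
without the text-based adjustment.  Variance comes from a stratified-PSU
bootstrap that resamples hospitals within stratum and refits the
prediction model inside every replication, composing survey sampling
variance with model variance.  Hospital-replacement artifacts (mid-series
swaps of low-volume for high-volume PSUs) are corrected by rescaling the
affected hospital's weighted annual contribution back to its pre-event
level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import LOCATION_CLASSES, MISSING, RecordSet, UNKNOWN

logger = logging.getLogger(__name__)


@dataclass
class EstimationConfig:
    n_bootstrap: int = 500
    alpha: float = 0.05
    seed: int = 0
    replacement_correction: bool = True
    years: tuple[int, int] = (1993, 2015)

    def __post_init__(self):
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1


def combine_locations(observed: RecordSet, predictions: pd.DataFrame
                      ) -> pd.DataFrame:
    """Merge observed location codes with model predictions for the
    missing ones.

    Returns the record table with two extra columns: ``location`` (a
    four-class label for every record) and ``location_source``
    (``observed`` / ``predicted``).  Predictions must cover exactly the
    missing records — a prediction for a record that already has a
    location, or a missing record without one, is an error.
    """
    df = observed.records.copy()
    if "location4" not in df.columns:
        raise ValueError("records must be recoded before combining")
    missing_ids = set(df.loc[df["location4"] == MISSING, "record_id"])
    pred_ids = set(predictions["record_id"]) if len(predictions) else set()
    if pred_ids - missing_ids:
        raise ValueError(f"predictions supplied for nonmissing record(s): "
                         f"{sorted(pred_ids - missing_ids)[:5]}")
    if missing_ids - pred_ids:
        raise ValueError(f"missing record(s) without prediction: "
                         f"{sorted(missing_ids - pred_ids)[:5]}")
    pred_map = (predictions.set_index("record_id")["predicted"]
                if len(predictions) else pd.Series(dtype=object))
    loc = df["location4"].copy()
    src = pd.Series("observed", index=df.index)
    mask = df["location4"] == MISSING
    loc[mask] = df.loc[mask, "record_id"].map(pred_map)
    src[mask] = "predicted"
    df["location"] = loc
    df["location_source"] = src
    return df


def impute_replacement_hospitals(df: pd.DataFrame, events: list
                                 ) -> tuple[pd.DataFrame, list[dict]]:
    """Rescale replaced hospitals' weighted contributions to prior-year
    levels.

    For each event (hospital, event year), every year from the event year
    onward has that hospital's case weights multiplied by
    (prior-year weighted total) / (that year's weighted total), so the
    hospital's expected annual weighted level returns to its pre-event
    level.  Other hospitals are untouched.  Returns the adjusted table and
    a log of the factors applied.
    """
    out = df.copy()
    factors: list[dict] = []
    for ev in events:
        hospital_id, event_year = (ev["hospital_id"], ev["year"]) \
            if isinstance(ev, dict) else (ev[0], ev[1])
        hosp = out["hospital_id"] == hospital_id
        prior = out.loc[hosp & (out["year"] == event_year - 1), "weight"].sum()
        if prior <= 0:
            logger.warning("hospital %s has no pre-event year %d volume; "
                           "event skipped", hospital_id, event_year - 1)
            continue
        for year in range(event_year, int(out["year"].max()) + 1):
            sel = hosp & (out["year"] == year)
            level = out.loc[sel, "weight"].sum()
            if level <= 0:
                continue
            factor = prior / level
            out.loc[sel, "weight"] *= factor
            factors.append({"hospital_id": hospital_id, "year": year,
                            "factor": factor})
    return out, factors


def weighted_annual_estimates(assignments: pd.DataFrame,
                              config: EstimationConfig,
                              adjusted: bool) -> pd.DataFrame:
    """Per-location mean annual weighted counts and shares.

    estimate(location) = Σ case weights / number of calendar years in the
    configured range (years with zero records still divide).  In
    unadjusted mode, records with missing locations form an UNKNOWN row;
    adjusted mode requires every record to carry a four-class location.
    Shares are over the reported rows, so total mass is conserved between
    modes.
    """
    df = assignments
    loc_col = "location" if "location" in df.columns else "location4"
    locs = df[loc_col].replace({MISSING: UNKNOWN})
    if adjusted and (locs == UNKNOWN).any():
        raise ValueError("adjusted estimates must not contain UNKNOWN locations")
    order = list(LOCATION_CLASSES) + ([] if adjusted else [UNKNOWN])
    totals = df.groupby(locs)["weight"].sum()
    rows = []
    grand = totals.sum()
    for c in order:
        wsum = float(totals.get(c, 0.0))
        rows.append({"location": c, "adjusted": adjusted,
                     "estimate": wsum / config.n_years,
                     "share": wsum / grand if grand else 0.0,
                     "ci_low": np.nan, "ci_high": np.nan})
    return pd.DataFrame(rows)


def resample_psus(rs: RecordSet, rng: np.random.Generator) -> RecordSet:
    """Resample hospitals (PSUs) with replacement within each stratum.

    A stratum containing a single PSU enters as fixed (with a warning), as
    its within-stratum variance cannot be estimated by resampling.
    Duplicate draws get suffixed hospital/record ids to keep ids unique.
    """
    df = rs.records
    hosp = df["hospital_id"].to_numpy()
    strat = df["stratum"].to_numpy()
    codes, uniques = pd.factorize(hosp, sort=True)
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(len(uniques)))
    ends = np.append(starts[1:], len(codes))
    rows_of = [order[s:e] for s, e in zip(starts, ends)]
    stratum_of = [strat[r[0]] for r in rows_of]
    by_stratum: dict[str, list[int]] = {}
    for i, s in enumerate(stratum_of):
        by_stratum.setdefault(s, []).append(i)

    pieces: list[np.ndarray] = []
    suffixes: list[np.ndarray] = []
    copy_counter = 0
    for stratum in sorted(by_stratum):
        hs = by_stratum[stratum]
        if len(hs) == 1:
            logger.warning("stratum %s has a single PSU; kept fixed", stratum)
            pieces.append(rows_of[hs[0]])
            suffixes.append(np.full(len(rows_of[hs[0]]), "", dtype=object))
            continue
        draws = rng.choice(len(hs), size=len(hs), replace=True)
        for d in draws:
            r = rows_of[hs[d]]
            copy_counter += 1
            pieces.append(r)
            suffixes.append(np.full(len(r), f"#b{copy_counter}", dtype=object))
    rows = np.concatenate(pieces)
    suf = np.concatenate(suffixes)
    out = df.iloc[rows].reset_index(drop=True)
    out["record_id"] = out["record_id"].to_numpy(dtype=object) + suf
    out["hospital_id"] = out["hospital_id"].to_numpy(dtype=object) + suf
    return RecordSet(out, provenance=f"{rs.provenance} [psu-resample]")


def bootstrap_ci(rs: RecordSet, estimate_closure, config: EstimationConfig
                 ) -> pd.DataFrame:
    """Percentile bootstrap CIs for the adjusted national estimates.

    Each replication resamples PSUs with replacement within stratum, then
    calls ``estimate_closure(resampled_recordset, seed)`` — which is
    expected to refit the preferred model on the resampled labeled
    records, re-predict the resampled missing records, and return the
    adjusted estimates DataFrame.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    reps_est: dict[str, list[float]] = {c: [] for c in LOCATION_CLASSES}
    reps_share: dict[str, list[float]] = {c: [] for c in LOCATION_CLASSES}
    for _ in range(config.n_bootstrap):
        resampled = resample_psus(rs, rng)
        est = estimate_closure(resampled, int(rng.integers(2 ** 31)))
        est = est.set_index("location")
        for c in LOCATION_CLASSES:
            reps_est[c].append(float(est.loc[c, "estimate"]))
            reps_share[c].append(float(est.loc[c, "share"]))
    lo_q, hi_q = 100 * config.alpha / 2, 100 * (1 - config.alpha / 2)
    rows = []
    for c in LOCATION_CLASSES:
        rows.append({
            "location": c,
            "ci_low": float(np.percentile(reps_est[c], lo_q)),
            "ci_high": float(np.percentile(reps_est[c], hi_q)),
            "share_ci_low": float(np.percentile(reps_share[c], lo_q)),
            "share_ci_high": float(np.percentile(reps_share[c], hi_q)),
        })
    return pd.DataFrame(rows)


def compare_distributions_chi2(shares_adjusted: dict[str, float],
                               shares_unadjusted: dict[str, float],
                               n_effective: int,
                               unknown: str = "drop") -> tuple[float, float]:
    """Pearson chi-square between the adjusted and unadjusted location
    distributions.

    Weighted shares are rescaled to the unweighted sample size
    ``n_effective`` before the test, so population-scale weights do not
    inflate the statistic.  The unadjusted distribution's UNKNOWN mass is
    dropped and renormalized by default (``unknown="pool"`` pools it into
    OTHER instead).  df = categories − 1; two-sided p.
    """
    unadj = dict(shares_unadjusted)
    if UNKNOWN in unadj:
        mass = unadj.pop(UNKNOWN)
        if unknown == "pool":
            unadj["OTHER"] = unadj.get("OTHER", 0.0) + mass
    total = sum(unadj.values())
    unadj = {c: v / total for c, v in unadj.items()}
    adj_total = sum(shares_adjusted[c] for c in LOCATION_CLASSES)
    obs = np.array([shares_adjusted[c] / adj_total * n_effective
                    for c in LOCATION_CLASSES])
    exp = np.array([unadj[c] * n_effective for c in LOCATION_CLASSES])
    statistic, p = stats.chisquare(f_obs=obs, f_exp=exp)
    return float(statistic), float(p)


def stratified_estimates(assignments: pd.DataFrame, by: str,
                         config: EstimationConfig,
                         adjusted: bool) -> pd.DataFrame:
    """Within-location weighted estimates by a covariate (intent, race or
    sex) — the adjusted and unadjusted national tables side by side are
    produced by calling this twice."""
    if by not in ("intent", "race", "sex"):
        raise ValueError(f"unsupported stratifier {by!r}")
    loc_col = "location" if "location" in assignments.columns else "location4"
    df = assignments[assignments[loc_col].isin(LOCATION_CLASSES)]
    rows = []
    for c in LOCATION_CLASSES:
        block = df[df[loc_col] == c]
        totals = block.groupby(by)["weight"].sum()
        grand = totals.sum()
        for level, wsum in totals.sort_index().items():
            rows.append({"location": c, by: level, "adjusted": adjusted,
                         "estimate": float(wsum) / config.n_years,
                         "share_within_location": float(wsum) / grand if grand else 0.0})
    return pd.DataFrame(rows)
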