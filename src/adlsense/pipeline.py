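"""End-to-end experiment recipes tying the stages together.

Two reference scenarios exercise the full stack on simulated deployments:

* the *macro* scenario trains the entropy-rate day detector on a clean
  history and injects visitor, away and agitation days into a test
  stretch, measuring day-level sensitivity and false-positive rate plus
  the week-level validated-anomaly fraction;
* the *micro* scenario injects agitation (AIA) episodes with partial
  physiological excursions, runs threshold scoring, label categorisation
  and the two group HMMs, learns reliability weights by cross-validation
  and measures per-group and fused day-level AUC.

`run_home` performs both tracks for one simulated home and returns all
artifacts; the CLI's ``run-all`` maps it over a cohort.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import fusion as fusion_mod
from . import scoring
from .hmm import DiscreteHMM
from .macro import (EntropyRateDetector, anomaly_notification_correlation,
                    weekly_sensitivity)
from .preprocess import ActivityScaler, aggregate_windows, hourly_aggregate
from .simulate import (START_DATE, AIAEpisode, AnomalySchedule,
                       DEFAULT_CLINICAL_THRESHOLDS, GroundTruth, HomeProfile,
                       default_group_map, default_profile, simulate_deployment,
                       simulate_home)

__all__ = [
    "make_macro_schedule",
    "run_macro_scenario",
    "make_micro_schedule",
    "run_micro_scenario",
    "run_home",
    "macro_cohort_correlation",
]


def _subseed(seed: int, *salt: int) -> int:
    """Deterministic derived seed, kept below 2**31."""
    return int(np.random.SeedSequence([int(seed), *salt]).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# macro scenario
# ---------------------------------------------------------------------------

def make_macro_schedule(
    seed: int,
    test_start: int,
    test_end: int,
    n_away: int = 4,
    n_visitor: int = 3,
    n_aia: int = 3,
) -> AnomalySchedule:
    """Inject disjoint away/visitor/AIA days into the test stretch.

    Macro-track AIA days model day-scale restlessness: recurring bursts of
    agitated, repetitive movement through the waking hours (five 1-2 h
    episodes between 8:00 and 22:00) with an intense ambient pacing echo —
    as opposed to the single short episodes the micro track targets.
    Agitation waxes and wanes over a bad day rather than holding a
    constant level.
    """
    rng = np.random.default_rng(_subseed(seed, 1))
    total = n_away + n_visitor + n_aia
    days = rng.choice(np.arange(test_start, test_end), size=total, replace=False)
    away = frozenset(int(d) for d in days[:n_away])
    visitor = frozenset(int(d) for d in days[n_away:n_away + n_visitor])
    aia_days = days[n_away + n_visitor:]
    episodes = []
    for d in aia_days:
        for anchor in (8, 11, 14, 17, 20):
            start_hour = anchor + int(rng.integers(0, 2))
            episodes.append(AIAEpisode(int(d), start_hour,
                                       start_hour + int(rng.integers(1, 3))))
    return AnomalySchedule(visitor_days=visitor, away_days=away,
                           aia_episodes=tuple(episodes), aia_g3_rate=60.0)


@dataclass
class MacroResult:
    sensitivity: float
    fpr: float
    rho: float | None
    n_flagged: int
    n_true_anomalous: int
    flags: pd.DataFrame
    truth: GroundTruth
    detector: EntropyRateDetector


def run_macro_scenario(
    seed: int,
    n_train: int = 60,
    n_verif: int = 14,
    n_test: int = 60,
    n_away: int = 4,
    n_visitor: int = 3,
    n_aia: int = 3,
    mu: float = 2.0,
    profile: HomeProfile | None = None,
) -> MacroResult:
    """Simulate one home, fit the day detector on its clean history, and
    measure detection of the injected anomalous days.

    The horizon is train + verification + test days; anomalies are injected
    into the test stretch only, so training and verification represent the
    participant's undisturbed routine.
    """
    profile = profile or default_profile()
    total = n_train + n_verif + n_test
    t0 = n_train + n_verif
    schedule = make_macro_schedule(seed, t0, total, n_away, n_visitor, n_aia)
    events, truth = simulate_home(profile, schedule, total, _subseed(seed, 2))

    sensor_index = [s.sensor_id for s in profile.sensors]
    raw, days, _ = aggregate_windows(events, n_days=total, start=START_DATE,
                                     sensor_index=sensor_index)
    scaler = ActivityScaler().fit(raw[:n_train])
    norm = scaler.transform(raw)

    detector = EntropyRateDetector(mu=mu, random_state=_subseed(seed, 3))
    detector.fit(norm[:n_train], norm[n_train:t0])
    flags = detector.score_days(norm[t0:], days=days[t0:])

    flagged = flags["flagged"].to_numpy()
    labels = np.asarray(truth.day_labels[t0:], dtype=object)
    anomalous = labels != "normal"
    sensitivity = float(flagged[anomalous].mean()) if anomalous.any() else float("nan")
    fpr = float(flagged[~anomalous].mean()) if (~anomalous).any() else float("nan")
    rho = weekly_sensitivity(flagged, labels)
    return MacroResult(sensitivity, fpr, rho, int(flagged.sum()),
                       int(anomalous.sum()), flags, truth, detector)


def macro_cohort_correlation(
    seed: int,
    n_homes: int = 8,
    base_anomalies: int = 3,
    **scenario_kwargs,
) -> tuple[float | None, np.ndarray, np.ndarray]:
    """Across a cohort with varying numbers of injected anomalous days,
    correlate each home's detected-anomaly count with its validated
    (ground-truth) count."""
    detected, validated = [], []
    for i in range(n_homes):
        extra = 2 * i  # cohort members range from quiet to very eventful
        res = run_macro_scenario(
            _subseed(seed, 10 + i), n_away=base_anomalies + extra,
            n_visitor=base_anomalies, n_aia=base_anomalies, **scenario_kwargs)
        detected.append(res.n_flagged)
        validated.append(res.n_true_anomalous)
    detected = np.asarray(detected, dtype=float)
    validated = np.asarray(validated, dtype=float)
    return anomaly_notification_correlation(detected, validated), detected, validated


# ---------------------------------------------------------------------------
# micro scenario
# ---------------------------------------------------------------------------

def make_micro_schedule(
    seed: int,
    n_days: int,
    n_aia: int = 30,
    n_visitor: int = 10,
    episode_hours: int = 4,
    physio_fraction: float = 0.5,
) -> AnomalySchedule:
    """AIA days scattered over the horizon, plus visitor days as ambient
    (G3) confounders; about `physio_fraction` of episodes carry a
    heart-rate excursion, making the physiological group only weakly
    informative."""
    rng = np.random.default_rng(_subseed(seed, 4))
    chosen = rng.choice(np.arange(n_days), size=n_aia + n_visitor, replace=False)
    aia_days, visitor_days = chosen[:n_aia], chosen[n_aia:]
    episodes = []
    for d in aia_days:
        start_hour = int(rng.integers(12, 24 - episode_hours))
        vitals = ("heart_rate",) if rng.random() < physio_fraction else ()
        episodes.append(AIAEpisode(int(d), start_hour, start_hour + episode_hours,
                                   physio_vitals=vitals))
    return AnomalySchedule(
        visitor_days=frozenset(int(d) for d in visitor_days),
        aia_episodes=tuple(episodes))


def _group_alphabet(labelsets: dict[str, scoring.LabelSet],
                    sensors: list[str]) -> list[str]:
    """All composite symbols a group's label sets can produce."""
    choices = [(labelsets[s].normal_label, labelsets[s].abnormal_label)
               for s in sorted(sensors)]
    return ["".join(combo) for combo in itertools.product(*choices)]


def _g1_day_scores(physio: pd.DataFrame, n_days: int,
                   thresholds=DEFAULT_CLINICAL_THRESHOLDS) -> np.ndarray:
    """Physiological day score: the day's worst reading's D_CS / |G1|."""
    n_vitals = physio["vital"].nunique()
    ts = pd.to_datetime(physio["timestamp"])
    day = ((ts - ts.min().normalize()) / pd.Timedelta(days=1)).astype(int)
    scores = np.zeros(n_days)
    frame = physio.assign(day=day.to_numpy())
    for (d, _t), reading in frame.groupby(["day", "timestamp"]):
        obs = dict(zip(reading["vital"], reading["value"]))
        d_cs = scoring.expert_decision_score(obs, thresholds)
        if 0 <= d < n_days:
            scores[d] = max(scores[d], d_cs / n_vitals)
    return scores


@dataclass
class MicroResult:
    auc: dict[str, float]  # per group and "fused"
    report: dict  # fused per-class + weighted precision/recall/F1
    reliability: pd.DataFrame
    day_scores: pd.DataFrame  # per-day scores, split, truth
    labelsets: dict[str, scoring.LabelSet]


def run_micro_scenario(
    seed: int,
    n_days: int = 120,
    n_aia: int = 30,
    n_visitor: int = 10,
    train_fraction: float = 0.5,
    k_folds: int = 10,
    mad_k: float = 3.0,
    profile: HomeProfile | None = None,
    deployment: tuple[pd.DataFrame, pd.DataFrame, GroundTruth] | None = None,
) -> MicroResult:
    """Full micro-track run on one simulated home.

    Splits days (stratified on the AIA label) into a training partition —
    used to fit the label bounds, the group HMMs (supervised on ground-truth
    hour labels, standing in for clinician-curated seed data), the MAD
    candidate-window thresholds, and the cross-validated reliability
    weights — and a held-out partition on which per-group and fused
    day-level AUC and the fused classification report are measured.
    """
    profile = profile or default_profile()
    if deployment is None:
        schedule = make_micro_schedule(seed, n_days, n_aia, n_visitor)
        events, physio, truth = simulate_deployment(
            profile, schedule, n_days, _subseed(seed, 5))
    else:
        events, physio, truth = deployment

    group_map = default_group_map(profile)
    # only the grouped sensors feed the micro track (e.g. the bathroom-door
    # sensor belongs to neither the participant-proximal nor ambient group)
    grouped_events = events[events["sensor_id"].isin(group_map)]
    hourly = hourly_aggregate(grouped_events, group_map, n_days=n_days,
                              start=START_DATE)
    day_truth = np.asarray(
        ["AIA" if l == "aia" else "normal" for l in truth.day_labels], dtype=object)

    day_ids = np.arange(n_days)
    train_days, test_days = train_test_split(
        day_ids, train_size=train_fraction, stratify=day_truth,
        random_state=_subseed(seed, 6) % (2 ** 31))
    train_mask = np.isin(day_ids, train_days)

    groups = {g: sorted(s for s, gg in group_map.items() if gg == g)
              for g in ("G2", "G3")}
    labelsets = scoring.fit_labelsets(
        hourly[hourly["day"].isin(train_days)], sensors=sorted(group_map))
    symbols = scoring.categorise(hourly, labelsets)

    # per-group hourly totals for MAD candidate-window seeding
    totals = (hourly.groupby(["group", "day", "hour"])["p_x"].sum()
              .rename("total").reset_index())

    day_scores = pd.DataFrame({
        "day": day_ids, "truth": day_truth,
        "split": np.where(train_mask, "train", "test"),
    })
    day_scores["G1"] = _g1_day_scores(physio, n_days)

    for g, sensors in groups.items():
        gsym = symbols[symbols["group"] == g].sort_values(["day", "hour"])
        seq_by_day = {d: grp["symbol"].tolist()
                      for d, grp in gsym.groupby("day")}
        model = DiscreteHMM(alphabet=_group_alphabet(labelsets, sensors))
        model.fit([seq_by_day[d] for d in train_days],
                  [list(truth.hour_labels[d]) for d in train_days])

        gtot = totals[totals["group"] == g]
        train_totals = gtot[gtot["day"].isin(train_days)]["total"].to_numpy()
        med = float(np.median(train_totals))
        mad = float(np.median(np.abs(train_totals - med)))

        scores = np.zeros(n_days)
        for d in day_ids:
            seq = seq_by_day[d]
            post = model.posterior(seq)[:, model.aia_index_]
            day_totals = gtot[gtot["day"] == d]["total"].to_numpy()
            candidates = scoring.mad_flag(day_totals, k=mad_k, center=med, mad=mad) \
                if mad > 0 else np.zeros(len(day_totals), dtype=bool)
            scores[d] = float(post[candidates].mean() if candidates.any()
                              else post.mean())
        day_scores[g] = scores

    train_scores = day_scores.loc[train_mask, ["G1", "G2", "G3"]]
    reliability = fusion_mod.crossval_reliability(
        train_scores, day_truth[train_mask], k=k_folds, seed=_subseed(seed, 7))

    fused_aia, fused_labels = [], []
    for _, row in day_scores.iterrows():
        result = fusion_mod.fuse(
            {g: (row[g], 1.0 - row[g]) for g in ("G1", "G2", "G3")}, reliability)
        total = sum(result.class_scores.values())
        fused_aia.append(result.class_scores["AIA"] / total if total > 0 else 0.5)
        fused_labels.append(result.label)
    day_scores["fused"] = fused_aia
    day_scores["fused_label"] = fused_labels

    test = day_scores.loc[~train_mask]
    auc = {}
    for col in ("G1", "G2", "G3", "fused"):
        auc[col], _, _ = fusion_mod.roc_auc(test[col], test["truth"])
    report = fusion_mod.classification_report_frame(
        test["fused_label"], test["truth"])
    return MicroResult(auc, report, reliability, day_scores, labelsets)


# ---------------------------------------------------------------------------
# whole-home run (used by the CLI's run-all)
# ---------------------------------------------------------------------------

@dataclass
class HomeRunResult:
    home_id: str
    events: pd.DataFrame
    physio: pd.DataFrame
    truth: GroundTruth
    macro_flags: pd.DataFrame
    macro_rho: float | None
    micro: MicroResult


def run_home(
    home_id: str,
    seed: int,
    days: int = 120,
    n_train: int = 60,
    n_verif: int = 14,
    mu: float = 2.0,
    n_away: int = 3,
    n_visitor: int = 3,
) -> HomeRunResult:
    """Both analysis tracks for one simulated home over a shared stream.

    Away and visitor days land in the macro test stretch (the day model is
    trained on a vetted clean history); short agitation episodes are
    scattered over the whole horizon — they are near-invisible at day
    scale but give the micro track training and test examples, as the
    clinician-curated seed data did in the original deployment.
    """
    profile = default_profile(home_id)
    rng = np.random.default_rng(_subseed(seed, 11))
    t0_macro = n_train + n_verif
    macro_days = rng.choice(np.arange(t0_macro, days),
                            size=n_away + n_visitor, replace=False)
    away = frozenset(int(d) for d in macro_days[:n_away])
    visitor = frozenset(int(d) for d in macro_days[n_away:])
    # episodes start after the (vetted-clean) macro training stretch but may
    # fall in verification days, which only widens the deviation band
    remaining = np.asarray([d for d in range(n_train, days)
                            if d not in away and d not in visitor])
    aia_days = rng.choice(remaining, size=10, replace=False)
    episodes = []
    for d in aia_days:
        start_hour = int(rng.integers(12, 20))
        vitals = ("heart_rate",) if rng.random() < 0.5 else ()
        episodes.append(AIAEpisode(int(d), start_hour, start_hour + 4,
                                   physio_vitals=vitals))
    schedule = AnomalySchedule(visitor_days=visitor, away_days=away,
                               aia_episodes=tuple(episodes))
    events, physio, truth = simulate_deployment(profile, schedule, days,
                                                _subseed(seed, 8))

    sensor_index = [s.sensor_id for s in profile.sensors]
    raw, day_index, _ = aggregate_windows(events, n_days=days, start=START_DATE,
                                          sensor_index=sensor_index)
    scaler = ActivityScaler().fit(raw[:n_train])
    norm = scaler.transform(raw)
    t0 = n_train + n_verif
    detector = EntropyRateDetector(mu=mu, random_state=_subseed(seed, 9))
    detector.fit(norm[:n_train], norm[n_train:t0])
    flags = detector.score_days(norm[t0:], days=day_index[t0:])
    flags.insert(0, "home_id", home_id)
    rho = weekly_sensitivity(flags["flagged"].to_numpy(),
                             np.asarray(truth.day_labels[t0:], dtype=object))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        micro = run_micro_scenario(seed, n_days=days, n_aia=10, n_visitor=5,
                                   profile=profile,
                                   deployment=(events, physio, truth))
    return HomeRunResult(home_id, events, physio, truth, flags, rho, micro)
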