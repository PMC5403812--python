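"""Seeded generator of complete synthetic labeling-study bundles.

Emulates the data shapes of published deuterated-glucose labeling
studies — per-subject anthropometrics, primed-infusion dosing schemes,
meal logs, sparse plasma enrichment samples, and T cell DNA enrichment
time series — with known ground-truth turnover parameters, so that the
whole estimation pipeline can be exercised and validated without any
external data.

Study templates:

``tigas_A``/``tigas_C``/``tigas_D``
    Fasted primed infusions (prime 5.95 mg/kg, rate 0.1 mg/kg/min) of
    2.5, 5 and 14.5 h; plasma sampled near end of infusion and for 4 h
    after.
``oneday``
    Primed ~1 g/kg infusion over 24 h with up to six meals at jittered
    times; plasma sampled intermittently at mixed fasting and
    postprandial times — the sampling scheme whose square-pulse summary
    the analysis interrogates.
``sevenday``
    30 g/day for 7 days, prime 6.6% of the daily dose, very low CHO
    intake (45 g/day over three meals); one overnight-fasted plasma
    sample per day.

After the labeling period all feeding templates deliver 237 g CHO/day
over three meals for 5 days (typical ad libitum intake), which feeds
the glycogen-recycling delabelling tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kh_turnover import KhParams, LabelCurve, simulate_kh
from .square_pulse import EnrichmentSamples
from .tracer_simulator import (EnrichmentProfile, InfusionSegment, MealEvent,
                               ModelParams, Protocol, Subject, build_params,
                               simulate)

__all__ = [
    "TEMPLATES",
    "NoiseModel",
    "StudyBundle",
    "make_cohort",
    "make_protocol",
    "sampling_times",
    "make_plasma_dataset",
    "make_dna_dataset",
    "write_study_bundle",
    "read_study_bundle",
    "generate_bundle",
]

TEMPLATES = ("tigas_A", "tigas_C", "tigas_D", "oneday", "sevenday")

#: infusion durations of the fasted-protocol templates, h
_TIGAS_DURATIONS = {"tigas_A": 2.5, "tigas_C": 5.0, "tigas_D": 14.5}

#: post-labeling ad libitum feeding: daily CHO and meal clock times
_POSTLABEL_CHO_PER_DAY = 237.0
_MEAL_CLOCK = (8.0, 13.0, 19.0)
_POSTLABEL_DAYS = 5


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal measurement noise, CV-parameterized."""

    plasma_cv: float = 0.05
    dna_cv: float = 0.10
    kind: str = "lognormal"

    def __post_init__(self) -> None:
        if self.plasma_cv < 0 or self.dna_cv < 0:
            raise ValueError("CVs must be >= 0")

    def _factors(self, cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
        if cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(cv ** 2))
        # unit-mean multiplicative noise
        return np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=n))

    def perturb_plasma(self, values: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
        return values * self._factors(self.plasma_cv, len(values), rng)

    def perturb_dna(self, values: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
        return values * self._factors(self.dna_cv, len(values), rng)


_DEFAULT_RANGES = {"weight": (60.0, 90.0), "height": (155.0, 190.0),
                   "age": (24.0, 32.0)}


def make_cohort(n: int, seed: int = 0,
                ranges: dict | None = None) -> list[Subject]:
    """Draw ``n`` subjects uniformly within anthropometric ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = {**_DEFAULT_RANGES, **(ranges or {})}
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {key}")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        subjects.append(Subject(
            weight=float(rng.uniform(*ranges["weight"])),
            height=float(rng.uniform(*ranges["height"])),
            sex="male" if rng.random() < 0.5 else "female",
            age=float(rng.uniform(*ranges["age"]))))
    return subjects


def _postlabel_meals(label_end_h: float) -> list[MealEvent]:
    meals = []
    per_meal = _POSTLABEL_CHO_PER_DAY / len(_MEAL_CLOCK)
    first_day = int(np.ceil(label_end_h / 24.0))
    for day in range(first_day, first_day + _POSTLABEL_DAYS):
        for clock in _MEAL_CLOCK:
            t = day * 24.0 + clock
            if t > label_end_h:
                meals.append(MealEvent(time=t, cho=per_meal))
    return meals


def make_protocol(template: str, subject: Subject, seed: int = 0,
                  horizon_days: float = 21.0) -> Protocol:
    """Instantiate a study-template dosing/feeding schedule for a subject.

    Doses stated per kg are expanded by the subject's weight; the one-day
    template's meal times and sizes are jittered deterministically per
    seed.  The horizon extends past labeling to cover DNA follow-up.
    """
    rng = np.random.default_rng(seed)
    w = subject.weight
    if template in _TIGAS_DURATIONS:
        dur = _TIGAS_DURATIONS[template]
        # horizon covers at least the delabelling follow-up window
        horizon = max(dur + 5.0, horizon_days * 24.0)
        return Protocol(
            subject=subject,
            infusions=(InfusionSegment(0.0, dur, rate=0.1e-3 * w * 60.0,
                                       prime=5.95e-3 * w),),
            meals=(), horizon=horizon)
    horizon = horizon_days * 24.0
    if template == "oneday":
        dose = 1.0 * w  # g, ~1 g/kg over ~24 h
        prime = 0.066 * dose
        rate = (dose - prime) / 24.0
        meal_times = np.array([8.0, 11.5, 14.0, 17.5, 20.5])
        meal_times = meal_times + rng.uniform(-0.5, 0.5, size=len(meal_times))
        chos = rng.uniform(30.0, 90.0, size=len(meal_times))
        meals = [MealEvent(time=float(t), cho=float(c))
                 for t, c in zip(meal_times, chos)]
        meals += _postlabel_meals(24.0)
        meals = [m for m in meals if m.time + m.duration <= horizon]
        return Protocol(subject=subject,
                        infusions=(InfusionSegment(0.0, 24.0, rate,
                                                   prime=prime),),
                        meals=tuple(meals), horizon=horizon)
    if template == "sevenday":
        daily = 30.0
        prime = 0.066 * daily
        meals = [MealEvent(time=day * 24.0 + clock, cho=45.0 / 3.0)
                 for day in range(7) for clock in _MEAL_CLOCK]
        meals += _postlabel_meals(168.0)
        meals = [m for m in meals if m.time + m.duration <= horizon]
        return Protocol(subject=subject,
                        infusions=(InfusionSegment(0.0, 168.0, daily / 24.0,
                                                   prime=prime),),
                        meals=tuple(meals), horizon=horizon)
    raise ValueError(f"unknown study template: {template!r}")


def sampling_times(template: str, protocol: Protocol) -> np.ndarray:
    """Plasma sampling schedule (hours) implied by a study template."""
    if template in _TIGAS_DURATIONS:
        stop = protocol.infusions[0].stop
        return np.concatenate([[stop - 0.5, stop - 0.25, stop],
                               stop + np.array([0.5, 1.0, 2.0, 3.0, 4.0])])
    if template == "oneday":
        # intermittent daytime sampling: mixed fasting/postprandial during
        # the infusion, two points after end of label
        return np.array([1.0, 4.0, 8.75, 10.0, 12.5, 16.0, 20.0, 23.5,
                         25.0, 27.0])
    if template == "sevenday":
        # one overnight-fasted sample per day (>= 10 h after last meal)
        return np.array([24.0 * k + 7.0 for k in range(1, 8)])
    raise ValueError(f"unknown study template: {template!r}")


def make_plasma_dataset(protocol: Protocol, params: ModelParams,
                        times: np.ndarray, noise: NoiseModel,
                        seed: int = 0, label_window: tuple | None = None,
                        grid_step: float = 0.05) -> EnrichmentSamples:
    """Simulate a protocol and sample noisy plasma enrichments at ``times``."""
    grid = np.arange(0.0, protocol.horizon + grid_step / 2, grid_step)
    traj = simulate(protocol, params, grid)
    values = traj.enrichment(np.asarray(times, float))
    rng = np.random.default_rng(seed)
    noisy = np.clip(noise.perturb_plasma(values, rng), 0.0, 1.0)
    if label_window is None:
        starts = [s.start for s in protocol.infusions]
        stops = [s.stop for s in protocol.infusions]
        label_window = (min(starts), max(stops))
    return EnrichmentSamples(t=np.asarray(times, float), e=noisy,
                             label_start=label_window[0],
                             label_end=label_window[1])


def make_dna_dataset(u: EnrichmentProfile, kh: KhParams,
                     times_days: np.ndarray, noise: NoiseModel,
                     seed: int = 0) -> LabelCurve:
    """Noisy DNA enrichment observations generated from the kh model."""
    times_days = np.asarray(times_days, float)
    clean = simulate_kh(u, kh, times_days)
    rng = np.random.default_rng(seed)
    noisy = noise.perturb_dna(clean.l_star, rng)
    return LabelCurve(t=times_days, l_star=noisy)


@dataclass
class StudyBundle:
    """In-memory study bundle: cohort, protocols, observations, truth."""

    template: str
    subjects: dict  # id -> Subject
    protocols: dict  # id -> Protocol
    plasma: dict  # id -> EnrichmentSamples
    dna: dict  # (id, population) -> LabelCurve
    truth: dict  # (id, population) -> KhParams
    seed: int | None = None


#: DNA sampling days for the synthetic cohorts (8 points over 3 weeks)
DNA_SAMPLING_DAYS = np.array([1.0, 3.0, 5.0, 7.0, 10.0, 14.0, 17.0, 21.0])

_TRUTH_RANGES = {"p": (0.003, 0.03), "d_star": (0.01, 0.2)}


def generate_bundle(template: str, n_subjects: int, seed: int = 0,
                    noise: NoiseModel | None = None,
                    param_overrides: dict | None = None,
                    horizon_days: float = 22.0,
                    dna_days: np.ndarray | None = None) -> StudyBundle:
    """Generate a full synthetic study bundle for a feeding template.

    Each subject gets anthropometrics, a dosing/feeding protocol, noisy
    plasma samples on the template's schedule, and CD4+/CD8+ DNA
    enrichment observations generated from the kh model driven by the
    subject's own simulated plasma profile, with ground-truth turnover
    parameters drawn uniformly from physiological ranges.
    """
    noise = noise or NoiseModel()
    dna_days = DNA_SAMPLING_DAYS if dna_days is None else np.asarray(dna_days)
    rng = np.random.default_rng(seed)
    cohort = make_cohort(n_subjects, seed=int(rng.integers(2 ** 31)))
    subjects, protocols, plasma, dna, truth = {}, {}, {}, {}, {}
    for i, subj in enumerate(cohort):
        sid = f"S{i + 1:02d}"
        subjects[sid] = subj
        proto = make_protocol(template, subj,
                              seed=int(rng.integers(2 ** 31)),
                              horizon_days=horizon_days)
        protocols[sid] = proto
        params = build_params(subj, param_overrides)
        times = sampling_times(template, proto)
        plasma[sid] = make_plasma_dataset(
            proto, params, times, noise, seed=int(rng.integers(2 ** 31)))
        grid = np.arange(0.0, proto.horizon + 0.025, 0.05)
        profile = simulate(proto, params, grid).enrichment
        for pop in ("cd4", "cd8"):
            kh = KhParams(p=float(rng.uniform(*_TRUTH_RANGES["p"])),
                          d_star=float(rng.uniform(*_TRUTH_RANGES["d_star"])))
            truth[(sid, pop)] = kh
            dna[(sid, pop)] = make_dna_dataset(
                profile, kh, dna_days, noise,
                seed=int(rng.integers(2 ** 31)))
    return StudyBundle(template=template, subjects=subjects,
                       protocols=protocols, plasma=plasma, dna=dna,
                       truth=truth, seed=seed)


def write_study_bundle(directory: str | Path, bundle: StudyBundle) -> None:
    """Write a bundle as the standard CSV file set (enrichments in percent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = list(bundle.subjects)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")

    pd.DataFrame(
        [(sid, s.weight, s.height, s.sex, s.age)
         for sid, s in bundle.subjects.items()],
        columns=["id", "weight_kg", "height_cm", "sex", "age_years"],
    ).to_csv(directory / "subjects.csv", index=False)

    pd.DataFrame(
        [(sid, seg.start, seg.stop, seg.rate, seg.prime)
         for sid, proto in bundle.protocols.items()
         for seg in proto.infusions],
        columns=["id", "start_h", "stop_h", "rate_g_per_h", "prime_g"],
    ).to_csv(directory / "dosing.csv", index=False)

    pd.DataFrame(
        [(sid, m.time, m.cho, m.kcal, m.duration, proto.horizon)
         for sid, proto in bundle.protocols.items() for m in proto.meals],
        columns=["id", "time_h", "cho_g", "energy_kcal", "duration_h",
                 "horizon_h"],
    ).to_csv(directory / "meals.csv", index=False)

    pd.DataFrame(
        [(sid, t, 100.0 * e, s.label_start, s.label_end)
         for sid, s in bundle.plasma.items() for t, e in zip(s.t, s.e)],
        columns=["id", "time_h", "enrichment_pct", "label_start_h",
                 "label_end_h"],
    ).to_csv(directory / "plasma_enrichment.csv", index=False)

    missing = set(bundle.dna) - {(sid, pop) for sid in ids
                                 for pop in ("cd4", "cd8")}
    if missing:
        raise ValueError(f"dna data for unknown subjects: {sorted(missing)}")
    pd.DataFrame(
        [(sid, pop, t, 100.0 * l)
         for (sid, pop), c in bundle.dna.items()
         for t, l in zip(c.t, c.l_star)],
        columns=["id", "population", "time_day", "dna_enrichment_pct"],
    ).to_csv(directory / "dna_enrichment.csv", index=False)

    pd.DataFrame(
        [(sid, pop, kh.p, kh.d_star, kh.b, kh.lag)
         for (sid, pop), kh in bundle.truth.items()],
        columns=["id", "population", "p_per_day", "d_star_per_day", "b",
                 "lag_day"],
    ).to_csv(directory / "truth.csv", index=False)

    (directory / "template.txt").write_text(bundle.template + "\n")


def read_study_bundle(directory: str | Path) -> StudyBundle:
    """Round-trip a bundle written by :func:`write_study_bundle`."""
    directory = Path(directory)
    template = (directory / "template.txt").read_text().strip() \
        if (directory / "template.txt").exists() else "unknown"
    subjects_df = pd.read_csv(directory / "subjects.csv")
    subjects = {
        r.id: Subject(weight=r.weight_kg, height=r.height_cm, sex=r.sex,
                      age=None if pd.isna(r.age_years) else r.age_years)
        for r in subjects_df.itertuples()}
    dosing = pd.read_csv(directory / "dosing.csv")
    meals_path = directory / "meals.csv"
    meals_df = pd.read_csv(meals_path) if meals_path.exists() else None
    protocols = {}
    for sid, subj in subjects.items():
        segs = tuple(InfusionSegment(r.start_h, r.stop_h, r.rate_g_per_h,
                                     r.prime_g)
                     for r in dosing[dosing.id == sid].itertuples())
        meals: tuple = ()
        horizon = max((s.stop for s in segs), default=24.0) + 5.0
        if meals_df is not None and (meals_df.id == sid).any():
            sub = meals_df[meals_df.id == sid]
            meals = tuple(MealEvent(time=r.time_h, cho=r.cho_g,
                                    energy=r.energy_kcal,
                                    duration=r.duration_h)
                          for r in sub.itertuples())
            horizon = float(sub.horizon_h.iloc[0])
        protocols[sid] = Protocol(subject=subj, infusions=segs,
                                  meals=meals, horizon=horizon)
    plasma_df = pd.read_csv(directory / "plasma_enrichment.csv")
    plasma = {}
    for sid, sub in plasma_df.groupby("id"):
        sub = sub.sort_values("time_h")
        plasma[sid] = EnrichmentSamples(
            t=sub.time_h.to_numpy(), e=sub.enrichment_pct.to_numpy() / 100.0,
            label_start=float(sub.label_start_h.iloc[0]),
            label_end=float(sub.label_end_h.iloc[0]))
    dna, truth = {}, {}
    dna_path = directory / "dna_enrichment.csv"
    if dna_path.exists():
        for (sid, pop), sub in pd.read_csv(dna_path).groupby(
                ["id", "population"]):
            sub = sub.sort_values("time_day")
            dna[(sid, pop)] = LabelCurve(
                t=sub.time_day.to_numpy(),
                l_star=sub.dna_enrichment_pct.to_numpy() / 100.0)
    truth_path = directory / "truth.csv"
    if truth_path.exists():
        for r in pd.read_csv(truth_path).itertuples():
            truth[(r.id, r.population)] = KhParams(
                p=r.p_per_day, d_star=r.d_star_per_day, b=r.b, lag=r.lag_day)
    return StudyBundle(template=template, subjects=subjects,
                       protocols=protocols, plasma=plasma, dna=dna,
                       truth=truth)
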