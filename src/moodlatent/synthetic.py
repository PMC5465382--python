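"""Synthetic longitudinal questionnaire data with planted sparse latent
structure.

The generator emulates a three-cohort observational mood-monitoring study:
bipolar disorder (BD, 48 participants), borderline personality disorder
(BPD, 32) and healthy controls (HC, 51), followed for ~363 days, answering
a 6-item daily mood questionnaire (MZ, 1-7 Likert) and three weekly
instruments (ASRM 0-4, QIDS 0-3, GAD-7 0-3), with ~20% of records missing.

Generative model (per cohort, per instrument)
---------------------------------------------
Each participant p carries a reporting-bias vector ``b_p ~ N(0, bias_sd^2)``
per item (different people anchor the same mood at different scale points).
At each scheduled timestamp t a latent factor vector
``z_t ~ N(0, diag(factor_sd^2))`` is drawn i.i.d. and mapped through a
sparse loading template W (columns with disjoint item supports), so

    raw_i = baseline_i + b_{p,i} + (W z_t)_i + N(0, noise_sd^2)

and the recorded response is ``clip(round(raw_i), scale_min, scale_max)``.
Rounding-and-clipping is the simplest discretization whose centered output
has approximately the planted covariance.  Records (all items at once, by
default, matching listwise-deletion semantics) are dropped with probability
``missing_rate`` (MCAR).  Factors are i.i.d. across timestamps because the
downstream analysis treats records as exchangeable; an AR(1) factor mode
(``ar_coefficient``) is available for robustness experiments.

Cohorts differ in which factor carries the most variance (``factor_sd``
ordering): in the default study the patient-like cohorts lead with the
anxious+sad factor and the control-like cohort with the elated+energetic
factor, while the factor supports themselves are shared — cohort
differences live in the component *order*, not the item membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import CSV_COLUMNS, LongitudinalDataset
from .exceptions import ValidationError
from .questionnaires import DEFAULT_SPECS, QuestionnaireSpec, get_spec

__all__ = [
    "InstrumentTemplate",
    "CohortTemplate",
    "StudyConfig",
    "generate_study",
    "default_study",
    "study_truth",
    "mz_template",
]

START_DATE = np.datetime64("2014-01-01")


@dataclass(frozen=True)
class InstrumentTemplate:
    """Planted generative structure of one instrument within one cohort.

    ``W`` is an M x K loading template whose columns have disjoint supports
    by default; ``factor_sd`` fixes which factor dominates (strictly
    decreasing = first factor explains most variance).  ``schedule`` is
    ``"daily"`` or ``"weekly"``.  ``missing_mode`` is ``"record"``
    (drop all items of a record together; default, matching listwise
    deletion) or ``"item"`` (mask items independently).
    """

    instrument: str
    W: tuple[tuple[float, ...], ...]
    factor_sd: tuple[float, ...]
    noise_sd: float
    bias_sd: float
    baseline: tuple[float, ...]
    missing_rate: float = 0.2
    schedule: str = "daily"
    missing_mode: str = "record"
    ar_coefficient: float = 0.0

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        spec = get_spec_or_custom(self.instrument)
        if W.shape[0] != spec.n_items:
            raise ValidationError(
                f"{self.instrument}: W has {W.shape[0]} rows for "
                f"{spec.n_items} items"
            )
        if W.shape[1] != len(self.factor_sd):
            raise ValidationError(
                f"{self.instrument}: {W.shape[1]} factors vs "
                f"{len(self.factor_sd)} factor_sd entries"
            )
        if len(self.baseline) != spec.n_items:
            raise ValidationError(
                f"{self.instrument}: baseline length {len(self.baseline)} "
                f"!= {spec.n_items} items"
            )
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.schedule not in ("daily", "weekly"):
            raise ValidationError("schedule must be 'daily' or 'weekly'")
        if self.missing_mode not in ("record", "item"):
            raise ValidationError("missing_mode must be 'record' or 'item'")
        if any(sd <= 0 for sd in self.factor_sd):
            raise ValidationError("factor_sd entries must be positive")

    @property
    def W_array(self) -> np.ndarray:
        return np.asarray(self.W, dtype=float)

    @property
    def supports(self) -> tuple[tuple[int, ...], ...]:
        """Planted per-factor item supports (nonzero rows of each column)."""
        W = self.W_array
        return tuple(
            tuple(int(i) for i in np.flatnonzero(np.abs(W[:, k]) > 0))
            for k in range(W.shape[1])
        )


def get_spec_or_custom(name: str) -> QuestionnaireSpec:
    return DEFAULT_SPECS.get(name) or get_spec(name)


@dataclass(frozen=True)
class CohortTemplate:
    """A named cohort: one :class:`InstrumentTemplate` per instrument."""

    name: str
    templates: tuple[InstrumentTemplate, ...]

    def template_for(self, instrument: str) -> InstrumentTemplate:
        for t in self.templates:
            if t.instrument == instrument:
                return t
        raise ValidationError(
            f"cohort {self.name!r} has no template for {instrument!r}"
        )


@dataclass(frozen=True)
class StudyConfig:
    """Full study design: cohorts with sizes, duration and seed."""

    cohorts: tuple[tuple[CohortTemplate, int], ...]
    duration_days: int = 363
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValidationError("duration_days must be >= 1")
        for template, n in self.cohorts:
            if n < 1:
                raise ValidationError(
                    f"cohort {template.name!r} needs n_participants >= 1"
                )

    @property
    def instruments(self) -> list[str]:
        names: list[str] = []
        for template, _ in self.cohorts:
            for t in template.templates:
                if t.instrument not in names:
                    names.append(t.instrument)
        return names


# ---------------------------------------------------------------------------
# Default templates
# ---------------------------------------------------------------------------

def _support_matrix(n_items: int, supports: Sequence[Sequence[int]]
                    ) -> tuple[tuple[float, ...], ...]:
    """Unit-norm loading columns with equal weights on given supports."""
    W = np.zeros((n_items, len(supports)))
    for k, idx in enumerate(supports):
        W[list(idx), k] = 1.0 / np.sqrt(len(idx))
    return tuple(tuple(row) for row in W)


# MZ item order: anxious, elated, sad, angry, irritable, energetic.
_MZ_SUPPORTS = {
    "anxious_sad": (0, 2),
    "elated_energetic": (1, 5),
    "angry_irritable": (3, 4),
}


def mz_template(
    factor_order: Sequence[str] = ("anxious_sad", "elated_energetic",
                                   "angry_irritable"),
    factor_sd: Sequence[float] = (1.5, 1.2, 0.9),
    noise_sd: float = 0.8,
    bias_sd: float = 0.7,
    missing_rate: float = 0.2,
    **kwargs,
) -> InstrumentTemplate:
    """Daily 6-item mood template with three disjoint 2-item factors.

    ``factor_order`` names which planted factor receives each (descending)
    ``factor_sd`` entry, so cohorts can share supports while differing in
    which factor dominates.
    """
    supports = [_MZ_SUPPORTS[name] for name in factor_order]
    return InstrumentTemplate(
        instrument="MZ",
        W=_support_matrix(6, supports),
        factor_sd=tuple(factor_sd),
        noise_sd=noise_sd,
        bias_sd=bias_sd,
        baseline=(4.0,) * 6,
        missing_rate=missing_rate,
        schedule="daily",
        **kwargs,
    )


# ASRM item order: happy, confident, sleepy, talkative, active.
def _asrm_template(patient: bool, scale: float = 1.0) -> InstrumentTemplate:
    if patient:
        supports = [(0, 4), (2, 3), (1,)]   # happy+active, sleepy+talkative, confident
    else:
        supports = [(0, 1), (3, 4), (2,)]   # happy+confident, talkative+active, sleepy
    return InstrumentTemplate(
        instrument="ASRM",
        W=_support_matrix(5, supports),
        factor_sd=tuple(scale * s for s in (0.9, 0.7, 0.5)),
        noise_sd=0.5,
        bias_sd=0.4,
        baseline=(1.0,) * 5,
        missing_rate=0.2,
        schedule="weekly",
    )


# QIDS: factors planted on raw items; supports chosen so that after the
# 9-domain max-mapping each factor still concentrates on few domains.
# Item indices: 0-3 sleep, 4 sad, 5-8 appetite/weight, 9 concentration,
# 10 self_view, 11 suicide, 12 interest, 13 energy, 14-15 psychomotor.
def _qids_template(cohort: str) -> InstrumentTemplate:
    supports = {
        "BD": [(4, 10), (0, 1), (5, 13)],     # sad+self_view, sleep, appetite+energy
        "BPD": [(12, 13), (5, 15), (10, 11)], # interest+energy, appetite+restless, self_view+suicide
        "HC": [(0, 1), (5, 13), (4, 10)],     # sleep, appetite+energy, sad+self_view
    }.get(cohort, [(4, 10), (0, 1), (5, 13)])
    return InstrumentTemplate(
        instrument="QIDS",
        W=_support_matrix(16, supports),
        factor_sd=(0.9, 0.7, 0.5),
        noise_sd=0.5,
        bias_sd=0.4,
        baseline=(1.2,) * 16,
        missing_rate=0.2,
        schedule="weekly",
    )


# GAD-7 item order: nervous, control_worries, worried, relaxed, restless,
# irritable, afraid.
def _gad7_template(cohort: str) -> InstrumentTemplate:
    supports = {
        "BD": [(0, 1), (5, 3), (4,)],
        "BPD": [(3, 4), (5, 6), (1, 2)],
        "HC": [(0, 1), (5, 2), (2, 6)],
    }.get(cohort, [(0, 1), (5, 3), (4,)])
    return InstrumentTemplate(
        instrument="GAD7",
        W=_support_matrix(7, supports),
        factor_sd=(0.9, 0.7, 0.5),
        noise_sd=0.5,
        bias_sd=0.4,
        baseline=(1.2,) * 7,
        missing_rate=0.2,
        schedule="weekly",
    )


def default_study(seed: int = 0) -> StudyConfig:
    """The default three-cohort study design.

    48 BD + 32 BPD + 51 HC participants, 363 days, daily MZ and weekly
    ASRM/QIDS/GAD-7, 20% record-wise missingness.  The MZ factor supports
    are shared across cohorts; the patient-like cohorts lead with the
    anxious+sad factor (BD second factor elated+energetic, BPD second
    factor angry+irritable) and the control cohort leads with
    elated+energetic.
    """
    bd = CohortTemplate(
        name="BD",
        templates=(
            mz_template(("anxious_sad", "elated_energetic", "angry_irritable")),
            _asrm_template(patient=True),
            _qids_template("BD"),
            _gad7_template("BD"),
        ),
    )
    bpd = CohortTemplate(
        name="BPD",
        templates=(
            mz_template(("anxious_sad", "angry_irritable", "elated_energetic")),
            _asrm_template(patient=True),
            _qids_template("BPD"),
            _gad7_template("BPD"),
        ),
    )
    hc = CohortTemplate(
        name="HC",
        templates=(
            mz_template(("elated_energetic", "anxious_sad", "angry_irritable")),
            _asrm_template(patient=False, scale=0.5),
            _qids_template("HC"),
            _gad7_template("HC"),
        ),
    )
    return StudyConfig(
        cohorts=((bd, 48), (bpd, 32), (hc, 51)),
        duration_days=363,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _schedule_days(schedule: str, duration_days: int) -> np.ndarray:
    if schedule == "daily":
        return np.arange(duration_days)
    return np.arange(0, duration_days, 7)


def _generate_instrument(
    template: InstrumentTemplate,
    cohort_name: str,
    participant_ids: Sequence[str],
    duration_days: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    spec = get_spec_or_custom(template.instrument)
    W = template.W_array
    M, K = W.shape
    days = _schedule_days(template.schedule, duration_days)
    T = len(days)
    P = len(participant_ids)

    bias = rng.normal(0.0, template.bias_sd, size=(P, M))
    z = rng.normal(0.0, 1.0, size=(P, T, K)) * np.asarray(template.factor_sd)
    if template.ar_coefficient:
        phi = template.ar_coefficient
        # Stationary AR(1): scale innovations, then filter along time.
        z *= np.sqrt(1.0 - phi**2)
        for t in range(1, T):
            z[:, t] += phi * z[:, t - 1]
        z[:, 0] /= np.sqrt(1.0 - phi**2)
    noise = rng.normal(0.0, template.noise_sd, size=(P, T, M))

    raw = (
        np.asarray(template.baseline)
        + bias[:, None, :]
        + z @ W.T
        + noise
    )
    values = np.clip(np.rint(raw), spec.scale_min, spec.scale_max).astype(int)

    if template.missing_mode == "record":
        keep = rng.random(size=(P, T)) >= template.missing_rate
        item_keep = np.broadcast_to(keep[:, :, None], values.shape)
    else:
        item_keep = rng.random(size=values.shape) >= template.missing_rate

    pid_idx, day_idx, item_idx = np.nonzero(item_keep)
    frame = pd.DataFrame(
        {
            "participant_id": np.asarray(participant_ids)[pid_idx],
            "cohort": cohort_name,
            "date": START_DATE + days[day_idx].astype("timedelta64[D]"),
            "questionnaire": template.instrument,
            "item": np.asarray(spec.items)[item_idx],
            "value": values[pid_idx, day_idx, item_idx],
        }
    )
    return frame


def generate_study(cfg: StudyConfig) -> LongitudinalDataset:
    """Generate a full longitudinal dataset from a study design.

    Fully reproducible from ``cfg.seed``: cohorts, participants,
    instruments and timestamps are generated in a fixed order with
    dedicated random substreams.
    """
    root = np.random.SeedSequence(cfg.seed)
    cohort_seeds = root.spawn(len(cfg.cohorts))
    frames: list[pd.DataFrame] = []
    specs: dict[str, QuestionnaireSpec] = dict(DEFAULT_SPECS)
    for (cohort, n), cseed in zip(cfg.cohorts, cohort_seeds):
        pids = [f"{cohort.name}-{i + 1:03d}" for i in range(n)]
        inst_seeds = cseed.spawn(len(cohort.templates))
        for template, iseed in zip(cohort.templates, inst_seeds):
            rng = np.random.default_rng(iseed)
            frames.append(
                _generate_instrument(
                    template, cohort.name, pids, cfg.duration_days, rng
                )
            )
            specs[template.instrument] = get_spec_or_custom(template.instrument)
    frame = pd.concat(frames, ignore_index=True)[CSV_COLUMNS]
    frame["date"] = pd.to_datetime(frame["date"])
    return LongitudinalDataset(frame=frame, specs=specs)


def study_truth(cfg: StudyConfig) -> dict:
    """Ground-truth record of the planted structure, for recovery tests
    and the CLI's truth JSON."""
    cohorts = []
    for cohort, n in cfg.cohorts:
        cohorts.append(
            {
                "name": cohort.name,
                "n_participants": n,
                "instruments": [
                    {
                        "instrument": t.instrument,
                        "W": [list(row) for row in t.W],
                        "supports": [list(s) for s in t.supports],
                        "factor_sd": list(t.factor_sd),
                        "noise_sd": t.noise_sd,
                        "bias_sd": t.bias_sd,
                        "baseline": list(t.baseline),
                        "missing_rate": t.missing_rate,
                        "schedule": t.schedule,
                    }
                    for t in cohort.templates
                ],
            }
        )
    return {
        "seed": cfg.seed,
        "duration_days": cfg.duration_days,
        "cohorts": cohorts,
    }
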