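"""Synthetic RCT cohorts with known ground truth.

Emulates the data streams of a six-visit, 8-week placebo RCT in chronic
back pain: twice-daily app VAS ratings across baseline, two treatment and
two washout periods; a table of questionnaire subscales with planted
correlations to the realised %analgesia; per-visit ROI connectivity
matrices with planted group-dependent edges; and per-visit subcortical
volume tables with a planted rightward asymmetry in responders.  Every
downstream stage of the pipeline can therefore be tested against known
truth without any patient data.

Study-design constants are fixed by the trial schedule: BL = 14 d,
T1 = 14 d, W1 = 7 d, T2 = 14 d, W2 = 7 d; ratings nominally at 09:00 and
21:00 (jittered ±2 h); scans at visits V2–V5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .brain import ConnectivityMatrix, fisher_z_inverse
from .ema import PERIODS, RatingSeries, subject_seed

logger = logging.getLogger(__name__)

#: days from V1 to each visit V1..V6 (BL 14 d, T1 14 d, W1 7 d, T2 14 d, W2 7 d)
VISIT_OFFSETS_DAYS = (0, 14, 28, 35, 49, 56)
SCAN_VISITS = ("V2", "V3", "V4", "V5")
PRETREATMENT_VISIT = "V2"

_VOLUME_REGIONS = ("NAc", "AMY", "HIP")
# typical adult unilateral volumes, mm^3
_VOLUME_MEANS = {"NAc": 550.0, "AMY": 1550.0, "HIP": 3900.0}
_VOLUME_CV = 0.08  # between-subject coefficient of variation


@dataclass
class CohortParams:
    """Generation parameters for a synthetic cohort.

    Defaults encode the study conditions of the trial design: 43 placebo
    (PTx) and 20 no-treatment (NoTx) subjects, baseline phone rating
    6.10 ± 1.2 VAS units between subjects, 33% plateau analgesia in
    responders with onset on day 1 of treatment, full carryover of
    analgesia into washout, 38 questionnaire subscales and 122 network
    nodes.
    """

    n_ptx: int = 43
    n_notx: int = 20
    responder_fraction_ptx: float = 24 / 43
    responder_fraction_notx: float = 4 / 20
    baseline_mean: float = 6.10
    baseline_sd: float = 1.2
    analgesia_pct: float = 33.0
    analgesia_subject_sd: float = 8.0  # between-responder spread of %analgesia
    onset_day: float = 1.0
    washout_carryover: float = 1.0
    rating_noise_sd: float = 1.0
    rating_autocorr: float = 0.0  # AR(1) coefficient of within-subject noise
    miss_prob: float = 0.10
    n_subscales: int = 38
    planted_subscale_effects: list[tuple[int, float]] = field(default_factory=list)
    n_nodes: int = 122
    n_factors: int = 5  # latent factors behind the base correlation structure
    n_timepoints: int = 150  # pseudo time-series samples per connectivity matrix
    planted_edges: list[tuple[int, int, float, bool]] = field(default_factory=list)
    asymmetry_effect: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("responder_fraction_ptx", "responder_fraction_notx",
                     "miss_prob", "washout_carryover"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.analgesia_pct < 0:
            raise ValueError("analgesia_pct must be >= 0")
        for name in ("baseline_sd", "rating_noise_sd", "analgesia_subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        seen = set()
        for i, j, _, _ in self.planted_edges:
            if i == j or not (0 <= i < self.n_nodes) or not (0 <= j < self.n_nodes):
                raise ValueError(f"planted edge ({i},{j}) out of range")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"planted edge ({i},{j}) duplicated")
            seen.add(key)
        for idx, _ in self.planted_subscale_effects:
            if not 0 <= idx < self.n_subscales:
                raise ValueError(f"planted subscale index {idx} out of range")


@dataclass
class SyntheticCohort:
    params: CohortParams
    start_date: datetime
    visit_dates: list[datetime]
    subjects: pd.DataFrame  # subject_id, arm, true_responder, true_analgesia_pct
    ratings: dict[str, RatingSeries]
    questionnaires: pd.DataFrame  # subject_id + subscale_00..NN
    connectivity: dict[tuple[str, str], ConnectivityMatrix]  # (subject, visit)
    volumes: pd.DataFrame  # subject_id, visit, region_L/R volumes, covariates

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])


def _subject_table(params: CohortParams) -> pd.DataFrame:
    """Arm assignment and planted responder status (deterministic counts)."""
    rows = []
    for arm, n, frac in (
        ("PTx", params.n_ptx, params.responder_fraction_ptx),
        ("NoTx", params.n_notx, params.responder_fraction_notx),
    ):
        n_resp = int(round(frac * n))
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"{arm}{k + 1:03d}",
                    "arm": arm,
                    "true_responder": k < n_resp,
                }
            )
    return pd.DataFrame(rows)


def _rating_schedule(start: datetime, rng: np.random.Generator) -> list[datetime]:
    """Twice-daily timestamps at 9:00/21:00 jittered ±2 h over the 56 days."""
    out = []
    start = start.replace(hour=0, minute=0, second=0, microsecond=0)
    for day in range(VISIT_OFFSETS_DAYS[-1]):
        for hour in (9, 21):
            jitter = rng.uniform(-120, 120)  # minutes
            out.append(start + timedelta(days=day, hours=hour, minutes=jitter))
    return sorted(out)


def _expected_level(
    t_days: float,
    baseline: float,
    analgesia_pct: float,
    onset_day: float,
    carryover: float,
) -> float:
    """Noise-free expected rating at t days after V1 for a treated responder."""
    full = baseline * (1.0 - analgesia_pct / 100.0)
    drop = baseline - full
    v = dict(zip(("V1", "V2", "V3", "V4", "V5", "V6"), VISIT_OFFSETS_DAYS))
    if t_days < v["V2"]:  # baseline
        return baseline
    if t_days < v["V3"]:  # T1: effect from onset_day after treatment start
        return baseline if t_days < v["V2"] + onset_day else full
    if t_days < v["V4"]:  # W1
        return baseline - carryover * drop
    if t_days < v["V5"]:  # T2 (re-introduction: onset applies again)
        return baseline if t_days < v["V4"] + onset_day else full
    return baseline - carryover * drop  # W2


def _ar1_noise(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    if rho == 0.0 or n == 0:
        return rng.normal(0.0, sd, size=n)
    e = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + e[i]
    return x


def _subject_ratings(
    subject_id: str,
    treated_responder: bool,
    baseline: float,
    analgesia_pct: float,
    params: CohortParams,
    start: datetime,
    rng: np.random.Generator,
) -> RatingSeries:
    times = _rating_schedule(start, rng)
    keep = rng.random(len(times)) >= params.miss_prob
    times = [t for t, k in zip(times, keep) if k]
    noise = _ar1_noise(len(times), params.rating_noise_sd, params.rating_autocorr, rng)
    rows = []
    for ts, eps in zip(times, noise):
        t_days = (ts - start).total_seconds() / 86_400.0
        mu = (
            _expected_level(
                t_days, baseline, analgesia_pct, params.onset_day, params.washout_carryover
            )
            if treated_responder
            else baseline
        )
        rows.append((ts, float(np.clip(mu + eps, 0.0, 10.0))))
    return RatingSeries(
        subject_id=subject_id, entries=pd.DataFrame(rows, columns=["timestamp", "vas"])
    )


def _base_correlation(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """Latent-factor population correlation: normalise ΛΛᵀ + Ψ."""
    n, k = params.n_nodes, params.n_factors
    lam = rng.normal(0.0, 1.0, size=(n, k)) * rng.uniform(0.3, 0.7, size=(n, 1))
    cov = lam @ lam.T + np.diag(rng.uniform(0.5, 1.5, size=n))
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _plant_edges(
    corr: np.ndarray,
    planted: list[tuple[int, int, float, bool]],
    responder: bool,
    pretreatment: bool,
) -> np.ndarray:
    """Offset planted edges in Fisher-z space for responders.

    Non-persistent edges carry the offset only at the pre-treatment visit.
    The result is projected back to a valid correlation matrix by
    eigenvalue clipping.
    """
    if not responder or not planted:
        return corr
    z = np.arctanh(np.clip(corr, -0.999999, 0.999999))
    touched = False
    for i, j, dz, persistent in planted:
        if persistent or pretreatment:
            z[i, j] += dz
            z[j, i] += dz
            touched = True
    if not touched:
        return corr
    out = fisher_z_inverse(z)
    np.fill_diagonal(out, 1.0)
    # nearest-PSD projection, then renormalise the diagonal
    w, v = np.linalg.eigh(out)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    return out


def generate_connectivity(
    params: CohortParams,
    subject_group: str,
    visit: str,
    rng: np.random.Generator | None = None,
    base_corr: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """One subject-visit correlation matrix in r-space.

    The subject's matrix is the empirical correlation of ``n_timepoints``
    pseudo time-series samples drawn from the group-level population
    correlation (latent-factor base, planted z-offsets for responders),
    so it is symmetric, unit-diagonal and positive semi-definite by
    construction, with realistic sampling variability across subjects.

    ``subject_group`` is "responder" or "nonresponder".
    """
    if params.planted_edges and params.n_nodes <= max(
        max(i, j) for i, j, _, _ in params.planted_edges
    ):
        raise ValueError("n_nodes too small for the planted edges")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if base_corr is None:
        base_corr = _base_correlation(params, np.random.default_rng(params.seed + 7))
    pop = _plant_edges(
        base_corr,
        params.planted_edges,
        responder=(subject_group == "responder"),
        pretreatment=(visit == PRETREATMENT_VISIT),
    )
    if np.abs(pop[~np.eye(len(pop), dtype=bool)]).max() > 1.0 - 1e-9:
        logger.warning("generate_connectivity: planted offset clipped at |r|=1")
        pop = np.clip(pop, -1.0 + 1e-7, 1.0 - 1e-7)
        np.fill_diagonal(pop, 1.0)
    chol = np.linalg.cholesky(pop + 1e-10 * np.eye(len(pop)))
    samples = rng.normal(size=(params.n_timepoints, params.n_nodes)) @ chol.T
    r = np.corrcoef(samples, rowvar=False)
    node_ids = [f"node{i:03d}" for i in range(params.n_nodes)]
    return ConnectivityMatrix(node_ids=node_ids, weights=r, space="r")


def _questionnaires(
    params: CohortParams,
    analgesia: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian-copula subscales with planted correlations to %analgesia.

    Each subscale s with planted correlation rho is rho·Z + sqrt(1−rho²)·ε
    on the standardised analgesia Z; unplanted subscales are independent
    noise.  Marginals are left Gaussian (scaled to plausible score ranges).
    """
    n = len(analgesia)
    z = (analgesia - analgesia.mean()) / (analgesia.std() or 1.0)
    planted = dict(params.planted_subscale_effects)
    out = np.empty((n, params.n_subscales))
    for s in range(params.n_subscales):
        rho = planted.get(s, 0.0)
        latent = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(size=n)
        out[:, s] = 20.0 + 5.0 * latent  # arbitrary instrument scale
    return out


def _volumes(
    params: CohortParams,
    subjects: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-visit subcortical volumes; responders get a rightward offset."""
    rows = []
    for _, sub in subjects.iterrows():
        srng = np.random.default_rng(subject_seed(params.seed + 11, sub.subject_id))
        base = {
            reg: _VOLUME_MEANS[reg] * (1.0 + _VOLUME_CV * srng.normal())
            for reg in _VOLUME_REGIONS
        }
        shift = params.asymmetry_effect if sub.true_responder else 0.0
        age = float(np.clip(45 + 12 * srng.normal(), 21, 70))
        sex = int(srng.random() < 0.5)
        pgm = float(620_000 * (1 + 0.06 * srng.normal()))
        for visit in SCAN_VISITS:
            row = {"subject_id": sub.subject_id, "visit": visit,
                   "age": age, "sex": sex, "peripheral_gm": pgm}
            for reg in _VOLUME_REGIONS:
                meas = 0.015 * _VOLUME_MEANS[reg]  # scan-to-scan noise
                left = base[reg] * (1.0 - shift / 2.0) + meas * srng.normal()
                right = base[reg] * (1.0 + shift / 2.0) + meas * srng.normal()
                row[f"{reg}_L"] = max(left, 1.0)
                row[f"{reg}_R"] = max(right, 1.0)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    params: CohortParams, start_date: datetime | None = None
) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducibly from ``params.seed``.

    Per-subject random streams are derived by stable hashing of the
    subject id, so regenerating a cohort with more subjects leaves the
    shared subjects' data unchanged.
    """
    if start_date is None:
        start_date = datetime(2024, 1, 8, 8, 0)
    visit_dates = [start_date + timedelta(days=d) for d in VISIT_OFFSETS_DAYS]
    subjects = _subject_table(params)

    master = np.random.default_rng(params.seed)
    true_analgesia = np.zeros(len(subjects))
    ratings: dict[str, RatingSeries] = {}
    for i, sub in subjects.iterrows():
        srng = np.random.default_rng(subject_seed(params.seed, sub.subject_id))
        baseline = float(
            np.clip(params.baseline_mean + params.baseline_sd * srng.normal(), 3.0, 9.5)
        )
        if sub.true_responder:
            a = params.analgesia_pct + params.analgesia_subject_sd * srng.normal()
            a = float(np.clip(a, 0.0, 90.0))
        else:
            a = 0.0
        true_analgesia[i] = a
        ratings[sub.subject_id] = _subject_ratings(
            sub.subject_id,
            # NoTx responders model natural-history improvement: the design's
            # 20% no-treatment response rate is real signal, not type-I error
            treated_responder=bool(sub.true_responder),
            baseline=baseline,
            analgesia_pct=a,
            params=params,
            start=start_date,
            rng=srng,
        )
    subjects = subjects.assign(true_analgesia_pct=true_analgesia)

    q = _questionnaires(params, true_analgesia, np.random.default_rng(params.seed + 3))
    questionnaires = pd.DataFrame(
        q, columns=[f"subscale_{s:02d}" for s in range(params.n_subscales)]
    )
    questionnaires.insert(0, "subject_id", subjects["subject_id"])

    base_corr = _base_correlation(params, np.random.default_rng(params.seed + 7))
    connectivity: dict[tuple[str, str], ConnectivityMatrix] = {}
    for _, sub in subjects.iterrows():
        group = "responder" if sub.true_responder else "nonresponder"
        for visit in SCAN_VISITS:
            crng = np.random.default_rng(
                subject_seed(params.seed + 5, f"{sub.subject_id}:{visit}")
            )
            connectivity[(sub.subject_id, visit)] = generate_connectivity(
                params, group, visit, rng=crng, base_corr=base_corr
            )

    volumes = _volumes(params, subjects, master)
    return SyntheticCohort(
        params=params,
        start_date=start_date,
        visit_dates=visit_dates,
        subjects=subjects,
        ratings=ratings,
        questionnaires=questionnaires,
        connectivity=connectivity,
        volumes=volumes,
    )


def study_conditions(seed: int = 0) -> CohortParams:
    """Cohort parameters matching the trial's reported design and effects.

    43 placebo / 20 no-treatment subjects with 24/43 and 4/20 responder
    rates, 6.10 mean baseline rating, 33% plateau analgesia with day-1
    onset and full washout carryover, 38 subscales of which six carry
    moderate-to-strong correlations (0.45–0.60) with the magnitude of
    response, and three group-dependent edges among the 122 network nodes:
    one stronger-in-responders connection and two weaker ones, one of the
    weaker pair transient (pre-treatment visit only).
    """
    return CohortParams(
        planted_subscale_effects=[
            (0, 0.60), (5, 0.55), (11, 0.50), (17, 0.50), (23, 0.45), (30, 0.45),
        ],
        planted_edges=[
            (5, 17, 0.30, True),     # stronger connectivity in responders
            (20, 44, -0.30, True),   # weaker, persistent across visits
            (33, 101, -0.30, False),  # weaker, pre-treatment only
        ],
        seed=seed,
    )


def generate_null_ratings(
    n_subjects: int, params: CohortParams | None = None
) -> list[RatingSeries]:
    """Stationary null subjects: every period drawn from one distribution.

    Used for type-I calibration of the responder classifier — no period
    effect whatsoever is simulated.
    """
    if params is None:
        params = CohortParams()
    out: list[RatingSeries] = []
    start = datetime(2024, 1, 8, 8, 0)
    for k in range(n_subjects):
        sid = f"NULL{k + 1:04d}"
        srng = np.random.default_rng(subject_seed(params.seed, sid))
        baseline = float(
            np.clip(params.baseline_mean + params.baseline_sd * srng.normal(), 3.0, 9.5)
        )
        out.append(
            _subject_ratings(
                sid, treated_responder=False, baseline=baseline, analgesia_pct=0.0,
                params=params, start=start, rng=srng,
            )
        )
    return out
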