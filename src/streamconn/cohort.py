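"""Synthetic cohort generator for the visual-stream connectivity pipeline.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any imaging data:

* 47 subjects (28 gamers, 19 nongamers), 4 runs of 860 samples at TR = 535 ms
  (3440 volumes in total);
* per-subject bivariate VAR(6) dynamics on the designated dorsal pair
  (L SOG -> L SPL), with a directed cross-coupling whose mean differs by
  group and whose subject-level spread drives individual differences;
* the remaining 12 atlas ROIs as independent AR(1) channels (they carry no
  designed effect and exist to keep the 14-ROI table shape);
* response times linked negatively and monotonically to the latent coupling,
  with a ~190 ms group gap mediated entirely through the coupling
  separation;
* per-connection structural anisotropy (FA, QA) tables with a group shift on
  designated dorsal connections only;
* completeness flags reproducing the cohort bookkeeping (one gamer missing
  tractography, one nongamer missing fMRI, one of each missing response
  time), giving effective n of 46 (functional), 44 (functional
  brain-behavior), 46 (structural), 44 (structural brain-behavior).

Seeding is counter-based: every subject and stage derives its own
``numpy.random.Generator`` from ``(seed, stage, subject_index)``, so adding
subjects or stages never perturbs existing draws.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from .connectivity import DEFAULT_FS_HZ, VARModel, simulate_var
from .errors import SizingError, ValidationError

#: Designated directed functional connection (source, target).
DESIGNATED_PAIR = ("L SOG", "L SPL")

#: Designated structural connections receiving the FA/QA group shift.
DESIGNATED_STRUCTURAL = ("L SOG-L IPL",)

# stage tags for counter-based substreams
_STAGE_COUPLING = 1
_STAGE_BOLD = 2
_STAGE_RT = 3
_STAGE_STRUCT = 4
_STAGE_BACKGROUND = 5


@dataclass
class CohortConfig:
    """Generator configuration; the defaults are the packaged study conditions."""

    n_gamers: int = 28
    n_nongamers: int = 19
    n_runs: int = 4
    samples_per_run: int = 860
    tr_seconds: float = 0.535
    #: mean VAR cross-coefficient (source lag-1) per group
    coupling_gamer: float = 0.345
    coupling_nongamer: float = 0.255
    #: between-subject SD of the coupling within group
    coupling_sd: float = 0.011
    #: SD of the per-subject innovation-correlation nuisance (FC jitter)
    innovation_corr_sd: float = 0.0
    #: SD of the per-subject zero-DC cross-coupling nuisance (TGC jitter):
    #: equal-and-opposite cross-coefficients at lags 2 and 3 add directed
    #: predictability without low-frequency covariance
    cross_pair_sd: float = 0.17
    #: SD of per-subject jitter on the diagonal lag-1 coefficients
    diag_sd: float = 0.005
    rt_mean_nongamer: float = 610.0
    rt_gap: float = 190.0
    rt_noise_sd: float = 15.0
    #: unitless; 1.0 mediates the full rt_gap through the coupling
    behavior_link_strength: float = 1.0
    fa_shift: float = 0.055
    qa_shift: float = 0.07
    seed: int = 0

    # pair-dynamics shape (true order 6: lag-1 and lag-6 diagonal memory)
    diag_lag1: float = 0.30
    diag_lag6: float = 0.25
    background_ar1: float = 0.30

    # structural baselines
    fa_base: float = 0.45
    fa_sd: float = 0.06
    qa_base: float = 0.35
    qa_sd: float = 0.08

    def __post_init__(self) -> None:
        for name in ("n_gamers", "n_nongamers", "n_runs", "samples_per_run"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be > 0")
        if self.rt_noise_sd < 0:
            raise ValidationError("rt_noise_sd must be >= 0")
        if self.coupling_sd < 0:
            raise ValidationError("coupling_sd must be >= 0")
        if self.behavior_link_strength < 0:
            warnings.warn(
                "behavior_link_strength < 0 produces a positive coupling-RT "
                "correlation; the packaged link is negative"
            )

    @property
    def n_subjects(self) -> int:
        return self.n_gamers + self.n_nongamers

    @property
    def fs(self) -> float:
        return 1.0 / self.tr_seconds

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "gamer" | "nongamer"
    response_time: float  # ms; NaN when rt_complete is False
    fmri_complete: bool = True
    rt_complete: bool = True
    tract_complete: bool = True

    def __post_init__(self) -> None:
        if self.group not in ("gamer", "nongamer"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.rt_complete and not self.response_time > 0:
            raise ValidationError("response_time must be > 0 when rt_complete")


@dataclass
class ROITimeSeries:
    """Per-subject sampled BOLD-like signals, one column per ROI."""

    data: pd.DataFrame
    run_lengths: list[int]
    fs: float = DEFAULT_FS_HZ


@dataclass
class Cohort:
    config: CohortConfig
    records: list[SubjectRecord]
    pair_models: dict[str, VARModel]
    couplings: dict[str, float]

    @property
    def roster(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "response_time_ms": r.response_time,
                    "fmri_complete": r.fmri_complete,
                    "rt_complete": r.rt_complete,
                    "tract_complete": r.tract_complete,
                }
                for r in self.records
            ]
        )


def _rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stage, index)))


def build_pair_model(
    coupling: float,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> VARModel:
    """Bivariate VAR(6) for (source, target) = the designated dorsal pair.

    Channel 0 is the source (L SOG), channel 1 the target (L SPL).  Both
    channels carry lag-1 and lag-6 diagonal memory (true order 6); the
    directed influence is the lag-1 cross-coefficient target <- source.
    Per-subject nuisance variability comes from small diagonal jitter and a
    zero-DC cross-coupling pair (equal-and-opposite coefficients at lags 2
    and 3) that perturbs directed predictability while leaving the
    low-frequency covariance, hence FC, nearly untouched.
    """
    p = 6
    coeffs = np.zeros((p, 2, 2))
    d1 = np.full(2, config.diag_lag1)
    s12 = 0.0
    bpair = 0.0
    if rng is not None:
        d1 = d1 + rng.normal(0.0, config.diag_sd, size=2)
        if config.innovation_corr_sd > 0:
            s12 = float(np.clip(rng.normal(0.0, config.innovation_corr_sd), -0.8, 0.8))
        # truncate at 2.5 SD to keep a stationarity margin in the tails
        sd = config.cross_pair_sd
        bpair = float(np.clip(rng.normal(0.0, sd), -2.5 * sd, 2.5 * sd))
    coeffs[0, 0, 0] = d1[0]
    coeffs[0, 1, 1] = d1[1]
    coeffs[5, 0, 0] = config.diag_lag6
    coeffs[5, 1, 1] = config.diag_lag6
    coeffs[0, 1, 0] = coupling  # target <- source, lag 1
    # zero-DC temporal-profile nuisance: cancels at f = 0, so it perturbs
    # directed predictability while leaving the low-frequency covariance
    # (hence FC) nearly untouched
    coeffs[1, 1, 0] = bpair
    coeffs[2, 1, 0] = -bpair
    sigma = np.array([[1.0, s12], [s12, 1.0]])
    model = VARModel(coeffs=coeffs, sigma=sigma, fs=config.fs)
    return model.require_stationary()


def _subject_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    gamers = [f"G{i + 1:02d}" for i in range(config.n_gamers)]
    nongamers = [f"N{i + 1:02d}" for i in range(config.n_nongamers)]
    return gamers, nongamers


def _completeness_flags(config: CohortConfig) -> dict[str, dict[str, bool]]:
    """Default exclusion pattern (first subjects of each group carry them)."""
    gamers, nongamers = _subject_ids(config)
    flags: dict[str, dict[str, bool]] = {}
    if config.n_gamers >= 1:
        flags.setdefault(gamers[0], {})["tract_complete"] = False
    if config.n_nongamers >= 1:
        flags.setdefault(nongamers[0], {})["fmri_complete"] = False
    if config.n_gamers >= 2:
        flags.setdefault(gamers[1], {})["rt_complete"] = False
    if config.n_nongamers >= 2:
        flags.setdefault(nongamers[1], {})["rt_complete"] = False
    return flags


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate subject records, latent couplings and per-subject VAR models."""
    config = config or CohortConfig()
    gamers, nongamers = _subject_ids(config)
    flags = _completeness_flags(config)

    couplings: dict[str, float] = {}
    pair_models: dict[str, VARModel] = {}
    groups: dict[str, str] = {}
    all_ids = gamers + nongamers
    for idx, sid in enumerate(all_ids):
        group = "gamer" if sid.startswith("G") else "nongamer"
        groups[sid] = group
        mean_c = config.coupling_gamer if group == "gamer" else config.coupling_nongamer
        rng = _rng(config.seed, _STAGE_COUPLING, idx)
        c = float(rng.normal(mean_c, config.coupling_sd))
        couplings[sid] = c
        pair_models[sid] = build_pair_model(c, config, rng=rng)

    rts = generate_response_times(groups, couplings, config)
    records = []
    for sid in all_ids:
        f = flags.get(sid, {})
        rt_complete = f.get("rt_complete", True)
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=groups[sid],
                response_time=rts[sid] if rt_complete else float("nan"),
                fmri_complete=f.get("fmri_complete", True),
                rt_complete=rt_complete,
                tract_complete=f.get("tract_complete", True),
            )
        )
    return Cohort(config=config, records=records, pair_models=pair_models, couplings=couplings)


def generate_response_times(
    groups: Mapping[str, str],
    couplings: Mapping[str, float],
    config: CohortConfig,
) -> dict[str, float]:
    """Response times negatively and monotonically linked to coupling.

    RT_i = rt_mean_nongamer + s * (zbar_nongamer - z_i) + noise, where z is
    the coupling standardized by its theoretical pooled moments and the
    slope s = behavior_link_strength * rt_gap / (zbar_gamer - zbar_nongamer).
    The expected group gap is therefore behavior_link_strength * rt_gap, the
    noise-free map is strictly decreasing in coupling (Spearman exactly -1),
    and behavior_link_strength = 0 removes both gap and association.
    """
    missing = set(groups) - set(couplings)
    if missing:
        raise ValidationError(f"no coupling summary for subjects {sorted(missing)}")
    p = config.n_gamers / max(config.n_subjects, 1)
    mu_g, mu_n = config.coupling_gamer, config.coupling_nongamer
    mu_pool = p * mu_g + (1 - p) * mu_n
    var_pool = config.coupling_sd**2 + p * (1 - p) * (mu_g - mu_n) ** 2
    sd_pool = float(np.sqrt(var_pool))
    dz = (mu_g - mu_n) / sd_pool if sd_pool > 0 else 0.0
    if dz == 0.0 or config.behavior_link_strength == 0.0:
        slope = 0.0
    else:
        slope = config.behavior_link_strength * config.rt_gap / dz
    zbar_non = (mu_n - mu_pool) / sd_pool if sd_pool > 0 else 0.0

    rts: dict[str, float] = {}
    ordered = sorted(groups)
    for idx, sid in enumerate(ordered):
        z = (couplings[sid] - mu_pool) / sd_pool if sd_pool > 0 else 0.0
        noise = 0.0
        if config.rt_noise_sd > 0:
            noise = float(
                _rng(config.seed, _STAGE_RT, idx).normal(0.0, config.rt_noise_sd)
            )
        rts[sid] = config.rt_mean_nongamer + slope * (zbar_non - z) + noise
    return rts


def simulate_bold(
    var_model: VARModel,
    n_runs: int,
    samples_per_run: int,
    seed: int | np.random.SeedSequence,
    channel_names: Sequence[str] = DESIGNATED_PAIR,
) -> ROITimeSeries:
    """Independent VAR realizations per run, stacked into one table."""
    if samples_per_run <= var_model.order:
        raise SizingError("samples_per_run must exceed the model order")
    var_model.require_stationary()
    rng = np.random.default_rng(seed)
    runs = [
        simulate_var(var_model, samples_per_run, rng) for _ in range(int(n_runs))
    ]
    data = pd.DataFrame(np.vstack(runs), columns=list(channel_names))
    return ROITimeSeries(data=data, run_lengths=[samples_per_run] * int(n_runs), fs=var_model.fs)


def simulate_subject_pair(cohort: Cohort, subject_id: str) -> ROITimeSeries:
    """BOLD-like series for the designated pair of one subject."""
    config = cohort.config
    idx = [r.subject_id for r in cohort.records].index(subject_id)
    seed = np.random.SeedSequence((int(config.seed), _STAGE_BOLD, idx))
    return simulate_bold(
        cohort.pair_models[subject_id],
        config.n_runs,
        config.samples_per_run,
        seed,
        channel_names=DESIGNATED_PAIR,
    )


def simulate_subject_timeseries(cohort: Cohort, subject_id: str) -> ROITimeSeries:
    """Full 14-ROI series: designated pair dynamics + independent AR(1) rest."""
    config = cohort.config
    pair_ts = simulate_subject_pair(cohort, subject_id)
    roi_names = [r.name for r in atlas_mod.load_atlas()]
    idx = [r.subject_id for r in cohort.records].index(subject_id)
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), _STAGE_BACKGROUND, idx)))
    T = config.n_runs * config.samples_per_run
    a = config.background_ar1
    data = pd.DataFrame(index=range(T), columns=roi_names, dtype=float)
    for name in roi_names:
        if name in DESIGNATED_PAIR:
            data[name] = pair_ts.data[name].to_numpy()
        else:
            from scipy.signal import lfilter

            innov = rng.standard_normal(T + 200)
            series = lfilter([1.0], [1.0, -a], innov)[200:]
            data[name] = series
    return ROITimeSeries(data=data, run_lengths=pair_ts.run_lengths, fs=config.fs)


def generate_structural_table(cohort: Cohort, config: CohortConfig | None = None) -> pd.DataFrame:
    """Per-subject, per-connection FA and QA values.

    Gamer distributions are shifted upward by ``fa_shift`` / ``qa_shift`` on
    the designated dorsal connections only.  Subjects with incomplete
    tractography are absent from the table (their data is 'missing').
    FA values falling outside (0, 1) are clipped with a warning.
    """
    config = config or cohort.config
    connections = atlas_mod.enumerate_connections(atlas_mod.load_atlas())
    rows = []
    clipped = 0
    for idx, rec in enumerate(cohort.records):
        if not rec.tract_complete:
            continue
        rng = _rng(config.seed, _STAGE_STRUCT, idx)
        for con in connections:
            fa = rng.normal(config.fa_base, config.fa_sd)
            qa = rng.normal(config.qa_base, config.qa_sd)
            if rec.group == "gamer" and con.label in DESIGNATED_STRUCTURAL:
                fa += config.fa_shift
                qa += config.qa_shift
            eps = 1e-6
            if not (0 < fa < 1):
                clipped += 1
                fa = float(np.clip(fa, eps, 1 - eps))
            qa = max(qa, eps)
            rows.append((rec.subject_id, con.label, float(fa), float(qa)))
    if clipped:
        warnings.warn(f"{clipped} FA values clipped into (0, 1)")
    return pd.DataFrame(rows, columns=["subject_id", "connection", "fa", "qa"])
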