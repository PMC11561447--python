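"""Synthetic cohorts and raw keystroke event streams.

Generates participant records (two groups with configurable normal
marginals coupled through a Gaussian copula) and, per participant, raw
press/release event streams whose extracted features recover the latent
participant means. Defaults reproduce the statistical structure the
analysis modules assume: group marginals, pooled cross-measure Spearman
correlations, session/press count distributions tuned so roughly 78% of
sessions pass the >40-press filter, and optional outlier contamination
beyond the preprocessing thresholds.

Pooling two groups with shifted means inflates the magnitude of pooled
rank correlations relative to the within-group dependence, so the copula
is calibrated on the pooled scale by default: for each variable pair the
within-group latent correlation is found by bisection so that the pooled
Spearman correlation of the simulated mixture matches the target.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Variable order used by the copula.
COPULA_VARIABLES = ("moca_k", "cbt_accuracy", "mean_ht_ms", "mean_ft_ms")


@dataclass
class GroupParams:
    """Marginal parameters of one participant group (normal mean/sd each)."""

    n: int
    label: str
    ht_mean: float
    ht_sd: float
    ft_mean: float
    ft_sd: float
    moca_mean: float
    moca_sd: float
    mmse_mean: float
    mmse_sd: float
    cbt_mean: float
    cbt_sd: float
    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    sex_fraction_male: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("ht_sd", "ft_sd", "moca_sd", "mmse_sd", "cbt_sd", "age_sd", "education_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.sex_fraction_male <= 1:
            raise ValueError("sex_fraction_male must be in [0, 1]")


def default_hc_params(n: int = 64) -> GroupParams:
    """Healthy-control group defaults (study cohort characteristics)."""
    return GroupParams(
        n=n, label="HC",
        ht_mean=108.77, ht_sd=25.25,
        ft_mean=622.925, ft_sd=135.14,
        moca_mean=25.83, moca_sd=2.11,
        mmse_mean=26.86, mmse_sd=1.39,
        cbt_mean=0.773, cbt_sd=0.06,
        age_mean=75.52, age_sd=7.00,
        education_mean=6.48, education_sd=4.41,
        sex_fraction_male=30 / 64,
    )


def default_mci_params(n: int = 47) -> GroupParams:
    """Impaired group defaults (study cohort characteristics)."""
    return GroupParams(
        n=n, label="MCI",
        ht_mean=184.85, ht_sd=25.24,
        ft_mean=1351.51, ft_sd=242.75,
        moca_mean=22.77, moca_sd=2.26,
        mmse_mean=26.55, mmse_sd=1.15,
        cbt_mean=0.687, cbt_sd=0.07,
        age_mean=74.45, age_sd=6.98,
        education_mean=6.34, education_sd=4.81,
        sex_fraction_male=21 / 47,
    )


def default_target_spearman() -> np.ndarray:
    """Pooled Spearman targets over (MoCA-K, CBT, HT, FT)."""
    return np.array(
        [
            [1.000, 0.302, -0.468, -0.491],
            [0.302, 1.000, -0.487, -0.492],
            [-0.468, -0.487, 1.000, 0.733],
            [-0.491, -0.492, 0.733, 1.000],
        ]
    )


@dataclass
class CopulaSpec:
    """Dependence specification over the copula variables.

    ``mode="pooled"`` calibrates the within-group latent correlation so the
    pooled-sample Spearman matches ``target_spearman``; ``mode="within"``
    applies the standard Gaussian-copula identity directly per group.
    """

    target_spearman: np.ndarray = field(default_factory=default_target_spearman)
    mode: str = "pooled"
    calibration_n: int = 40000
    calibration_tol: float = 0.005

    def __post_init__(self) -> None:
        t = np.asarray(self.target_spearman, dtype=float)
        if t.shape != (4, 4) or not np.allclose(t, t.T) or not np.allclose(np.diag(t), 1):
            raise ValueError("target_spearman must be a symmetric 4x4 matrix with unit diagonal")
        if np.abs(t).max() > 1:
            raise ValueError("Spearman targets must be in [-1, 1]")
        if self.mode not in ("pooled", "within"):
            raise ValueError(f"unknown copula mode {self.mode!r}")
        self.target_spearman = t


@dataclass
class StreamConfig:
    """Generative model of the raw event streams.

    Session and press counts are gamma-Poisson (negative binomial) with
    ``var = mean + dispersion * mean^2``; dispersion 0 means a fixed count.
    Per-keystroke HT/FT are gamma-distributed around the participant's
    latent mean with the given coefficient of variation; outliers beyond
    the preprocessing thresholds are injected at the configured rates.
    """

    sessions_mean: float = 32.0
    sessions_dispersion: float = 0.3
    presses_mean: float = 120.0
    presses_dispersion: float = 0.73
    within_participant_cv: float = 0.35
    ht_outlier_rate: float = 0.02
    ft_outlier_rate: float = 0.02
    ft_rollover_shift_ms: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ht_outlier_rate", "ft_outlier_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.sessions_mean < 0 or self.presses_mean < 0:
            raise ValueError("count means must be >= 0")
        if self.within_participant_cv < 0:
            raise ValueError("within_participant_cv must be >= 0")


@dataclass
class CohortConfig:
    """Full generative specification of a synthetic cohort."""

    hc: GroupParams = field(default_factory=default_hc_params)
    mci: GroupParams = field(default_factory=default_mci_params)
    copula: CopulaSpec = field(default_factory=CopulaSpec)
    stream: StreamConfig = field(default_factory=StreamConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["copula"]["target_spearman"] = self.copula.target_spearman.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        hc = GroupParams(**d["hc"]) if "hc" in d else default_hc_params()
        mci = GroupParams(**d["mci"]) if "mci" in d else default_mci_params()
        cop = d.get("copula", {})
        copula = CopulaSpec(
            target_spearman=np.asarray(cop.get("target_spearman", default_target_spearman())),
            mode=cop.get("mode", "pooled"),
            calibration_n=cop.get("calibration_n", 40000),
            calibration_tol=cop.get("calibration_tol", 0.005),
        )
        stream = StreamConfig(**d.get("stream", {}))
        return cls(hc=hc, mci=mci, copula=copula, stream=stream, seed=d.get("seed", 0))


def calibrate_copula(target_spearman):
    """Latent Pearson correlation for a Spearman target: rho = 2 sin(pi r/6).

    Accepts a scalar or a matrix; the matrix version applies the identity
    elementwise and repairs the result to the nearest positive
    semi-definite correlation matrix if needed.
    """
    r = np.asarray(target_spearman, dtype=float)
    if np.abs(r).max() > 1:
        raise ValueError("|spearman| must be <= 1")
    rho = 2.0 * np.sin(np.pi * r / 6.0)
    if rho.ndim == 0:
        return float(rho)
    return nearest_psd_correlation(rho)


def nearest_psd_correlation(matrix: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    m = np.asarray(matrix, dtype=float)
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    if vals.min() >= 0:
        return m
    logger.info("repairing non-PSD correlation matrix (min eigenvalue %.3g)", vals.min())
    vals = np.clip(vals, eps, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


# ---------------------------------------------------------------------------
# marginal transforms

def _transform_marginal(z: np.ndarray, var: str, params: GroupParams) -> np.ndarray:
    """Map standard-normal draws to the marginal of one copula variable."""
    if var == "moca_k":
        x = params.moca_mean + params.moca_sd * z
        return np.clip(np.round(x), 0, 30)
    if var == "cbt_accuracy":
        return np.clip(params.cbt_mean + params.cbt_sd * z, 0.0, 1.0)
    if var == "mean_ht_ms":
        return np.maximum(params.ht_mean + params.ht_sd * z, 1.0)
    if var == "mean_ft_ms":
        return np.maximum(params.ft_mean + params.ft_sd * z, 1.0)
    raise ValueError(f"unknown copula variable {var!r}")


def _pooled_spearman_for_rho(
    rho: float,
    var_i: str,
    var_j: str,
    hc: GroupParams,
    mci: GroupParams,
    z1: np.ndarray,
    z2: np.ndarray,
    n_hc: int,
) -> float:
    """Pooled Spearman of pair (i, j) when the within-group latent
    correlation is ``rho``; uses common random numbers for smoothness."""
    zi = z1
    zj = rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2
    xi = np.empty_like(zi)
    xj = np.empty_like(zj)
    xi[:n_hc] = _transform_marginal(zi[:n_hc], var_i, hc)
    xj[:n_hc] = _transform_marginal(zj[:n_hc], var_j, hc)
    xi[n_hc:] = _transform_marginal(zi[n_hc:], var_i, mci)
    xj[n_hc:] = _transform_marginal(zj[n_hc:], var_j, mci)
    return float(sps.spearmanr(xi, xj).statistic)


def calibrate_pooled_copula(
    hc: GroupParams,
    mci: GroupParams,
    target_spearman: np.ndarray,
    *,
    n_calib: int = 40000,
    tol: float = 0.005,
    seed: int = 12345,
    max_iter: int = 40,
) -> np.ndarray:
    """Within-group latent Pearson matrix matching pooled Spearman targets.

    The pooled Spearman of one variable pair depends only on that pair's
    within-group latent correlation and the two groups' marginals, so each
    off-diagonal entry is calibrated independently by bisection on a fixed
    Monte-Carlo sample (common random numbers), then the assembled matrix
    is repaired to the nearest PSD correlation matrix.
    """
    rng = np.random.default_rng(seed)
    n_hc = int(round(n_calib * hc.n / (hc.n + mci.n)))
    z1 = rng.standard_normal(n_calib)
    z2 = rng.standard_normal(n_calib)
    k = len(COPULA_VARIABLES)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            target = float(target_spearman[i, j])
            vi, vj = COPULA_VARIABLES[i], COPULA_VARIABLES[j]

            def f(rho: float) -> float:
                return (
                    _pooled_spearman_for_rho(rho, vi, vj, hc, mci, z1, z2, n_hc) - target
                )

            lo, hi = -0.999, 0.999
            flo, fhi = f(lo), f(hi)
            if flo > 0:  # even maximal negative dependence overshoots
                rho = lo
                logger.warning("pair (%s, %s): target %.3f unreachable, clamping", vi, vj, target)
            elif fhi < 0:
                rho = hi
                logger.warning("pair (%s, %s): target %.3f unreachable, clamping", vi, vj, target)
            else:
                rho = 0.0
                for _ in range(max_iter):
                    rho = 0.5 * (lo + hi)
                    fm = f(rho)
                    if abs(fm) <= tol:
                        break
                    if fm < 0:
                        lo = rho
                    else:
                        hi = rho
            latent[i, j] = latent[j, i] = rho
    return nearest_psd_correlation(latent)


def latent_correlation(config: CohortConfig) -> np.ndarray:
    """Within-group latent Pearson matrix for a cohort configuration."""
    cop = config.copula
    if cop.mode == "within":
        return calibrate_copula(cop.target_spearman)
    return calibrate_pooled_copula(
        config.hc,
        config.mci,
        cop.target_spearman,
        n_calib=cop.calibration_n,
        tol=cop.calibration_tol,
        seed=config.seed + 987654321,
    )


METADATA_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "sex",
    "education_years",
    "mmse_k",
    "moca_k",
    "cbt_accuracy",
    "mean_ht_ms",
    "mean_ft_ms",
]


def generate_cohort(
    config: CohortConfig, latent: np.ndarray | None = None
) -> pd.DataFrame:
    """Draw one synthetic cohort as a participant-record table.

    The returned ``mean_ht_ms``/``mean_ft_ms`` columns are the latent
    participant-level truth that the event-stream generator reproduces.
    Identical config and seed give identical output.
    """
    if latent is None:
        latent = latent_correlation(config)
    latent = np.asarray(latent, dtype=float)
    if np.linalg.eigvalsh(latent).min() < -1e-8:
        raise ValueError("latent correlation matrix is not positive semi-definite")
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(latent + 1e-12 * np.eye(len(latent)))
    frames = []
    offset = 0
    for params in (config.hc, config.mci):
        z = rng.standard_normal((params.n, len(COPULA_VARIABLES))) @ chol.T
        cols = {
            var: _transform_marginal(z[:, k], var, params)
            for k, var in enumerate(COPULA_VARIABLES)
        }
        mmse = np.clip(np.round(rng.normal(params.mmse_mean, params.mmse_sd, params.n)), 0, 30)
        age = np.round(rng.normal(params.age_mean, params.age_sd, params.n), 1)
        edu = np.round(np.maximum(rng.normal(params.education_mean, params.education_sd, params.n), 0.0), 1)
        sex = np.where(rng.random(params.n) < params.sex_fraction_male, "M", "F")
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": [f"P{offset + i:04d}" for i in range(params.n)],
                    "group": params.label,
                    "age": age,
                    "sex": sex,
                    "education_years": edu,
                    "mmse_k": mmse,
                    "moca_k": cols["moca_k"],
                    "cbt_accuracy": cols["cbt_accuracy"],
                    "mean_ht_ms": cols["mean_ht_ms"],
                    "mean_ft_ms": cols["mean_ft_ms"],
                }
            )
        )
        offset += params.n
    return pd.concat(frames, ignore_index=True)[METADATA_COLUMNS]


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Gamma-Poisson count with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(round(mean))
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return int(rng.negative_binomial(shape, p))


def _draw_gamma(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean)
    shape = 1.0 / (cv * cv)
    return rng.gamma(shape, mean / shape, size=size)


def generate_event_stream(
    record: pd.Series | dict,
    stream: StreamConfig,
    rng: np.random.Generator,
    *,
    n_keys: int = 30,
) -> list[dict]:
    """Raw press/release event sessions for one participant record.

    Per session a press count is drawn; per keystroke HT and FT come from
    gamma distributions around the participant's latent means
    (``mean_ht_ms`` / ``mean_ft_ms``); outliers beyond the preprocessing
    thresholds are substituted at the configured rates. Timestamps are
    built cumulatively (press = previous release + FT, release = press +
    HT) and the interleaved events are emitted in the event-log schema.
    """
    mean_ht = float(record["mean_ht_ms"])
    mean_ft = float(record["mean_ft_ms"])
    if mean_ht <= 0 or mean_ft <= 0:
        raise ValueError("latent mean HT/FT must be positive")
    pid = str(record["participant_id"])
    n_sessions = _draw_count(rng, stream.sessions_mean, stream.sessions_dispersion)
    sessions = []
    shift = stream.ft_rollover_shift_ms
    for s in range(n_sessions):
        n_press = max(1, _draw_count(rng, stream.presses_mean, stream.presses_dispersion))
        ht = _draw_gamma(rng, mean_ht, stream.within_participant_cv, n_press)
        ft = _draw_gamma(rng, mean_ft + shift, stream.within_participant_cv, n_press) - shift
        if stream.ht_outlier_rate > 0:
            mask = rng.random(n_press) < stream.ht_outlier_rate
            ht[mask] = rng.uniform(700.0, 1400.0, mask.sum()) + 1e-9
        if stream.ft_outlier_rate > 0:
            mask = rng.random(n_press) < stream.ft_outlier_rate
            ft[mask] = rng.uniform(3000.0, 10000.0, mask.sum()) + 1e-9
        # keep press times strictly increasing even under rollover
        ft = np.maximum(ft, -0.9 * ht)
        events = []
        t = 1000.0
        release_prev = None
        for k in range(n_press):
            press = t if release_prev is None else release_prev + ft[k]
            release = press + ht[k]
            key = f"k{rng.integers(n_keys):02d}"
            events.append({"t": round(press, 3), "action": "down", "key": key})
            events.append({"t": round(release, 3), "action": "up", "key": key})
            release_prev = release
        events.sort(key=lambda e: (e["t"], 0 if e["action"] == "down" else 1))
        sessions.append(
            {"participant_id": pid, "session_id": f"{pid}-s{s:04d}", "events": events}
        )
    return sessions


def generate_cohort_streams(
    cohort: pd.DataFrame, stream: StreamConfig, seed: int
) -> Iterator[dict]:
    """Event-stream sessions for every participant of a cohort.

    Each participant gets an independent child generator derived from the
    seed, so streams are reproducible regardless of iteration order.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(cohort))
    for (_, row), child in zip(cohort.iterrows(), children):
        rng = np.random.default_rng(child)
        yield from generate_event_stream(row, stream, rng)


def write_event_log(sessions: Sequence[dict], path: str | Path, ndjson: bool = False) -> None:
    """Serialize sessions to the event-log JSON schema (array or NDJSON)."""
    path = Path(path)
    if ndjson:
        with path.open("w") as fh:
            for s in sessions:
                fh.write(json.dumps(s, separators=(",", ":")) + "\n")
    else:
        with path.open("w") as fh:
            json.dump(list(sessions), fh, separators=(",", ":"))


def write_metadata(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)
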