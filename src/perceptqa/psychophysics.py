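"""Simulated-observer 2AFC noise-detection experiment.

The measurement logic follows standard adaptive psychophysics: on each trial
two different images are shown, one with added white noise (in denoising
conditions both then pass through the denoiser); the observer reports which
interval contained the noise.  A pair of randomly interleaved 3-down-1-up
staircases drives the noise contrast in 3 dB steps, converging near the
79.4%-correct point; a cumulative log-Gaussian psychometric function fitted
by maximum likelihood yields the 75%-correct threshold in dB.  The quality
measure is *threshold elevation*: the dB increase in detection threshold
caused by the denoiser, i.e. how much added noise the algorithm conceals.

The human observer is replaced by a pluggable :class:`ObserverModel`.  The
default model scores each image by its high-frequency contrast-energy
fraction — sensitive both to residual white noise and to high-frequency
denoising artefacts, and computable without the clean original — plus
zero-mean Gaussian internal noise, and picks the interval with the larger
noisy statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .config import derive_seed
from .denoise import FilterBank, FilterBankConfig, ThresholdPolicy, denoise, optimize_threshold
from .stimuli import ImageStim, NoiseCondition, add_white_noise, apply_window, synth_image_set

__all__ = [
    "ObserverModel",
    "TrialRecord",
    "Staircase",
    "PsychometricFit",
    "PsychometricFitError",
    "BlockConfig",
    "ExperimentConfig",
    "ExperimentResult",
    "observer_decide",
    "hf_energy_fraction",
    "peak_hf_response",
    "calibrate_observer",
    "calibrate_internal_noise",
    "build_threshold_table",
    "run_block",
    "fit_psychometric",
    "threshold_elevation",
    "run_experiment",
]

log = logging.getLogger("perceptqa.psychophysics")


# ---------------------------------------------------------------------------
# Observer
# ---------------------------------------------------------------------------

def _highpass_filter(size: int, cutoff: float) -> np.ndarray:
    """Raised-cosine highpass (0.5-octave ramp above ``cutoff``), FFT layout."""
    fr = np.fft.fftfreq(size) * size
    fx, fy = np.meshgrid(fr, fr)
    f = np.hypot(fx, fy)
    with np.errstate(divide="ignore"):
        t = np.clip((np.log2(np.where(f > 0, f, np.finfo(float).tiny))
                     - math.log2(cutoff)) / 0.5, 0.0, 1.0)
    hp = 0.5 - 0.5 * np.cos(np.pi * t)
    hp[f == 0] = 0.0
    return hp


_HP_CACHE: dict = {}


def hf_energy_fraction(pixels: np.ndarray, cutoff: float) -> float:
    """Fraction of (non-DC) Fourier energy above ``cutoff`` cycles/image."""
    arr = np.asarray(pixels, dtype=float)
    size = arr.shape[0]
    power = np.abs(np.fft.fft2(arr - arr.mean())) ** 2
    fr = np.fft.fftfreq(size) * size
    fx, fy = np.meshgrid(fr, fr)
    f = np.hypot(fx, fy)
    total = power[f > 0].sum()
    if total == 0:
        return 0.0
    return float(power[f > cutoff].sum() / total)


def peak_hf_response(pixels: np.ndarray, cutoff: float) -> float:
    """Peak magnitude of the highpass band of the D.C.-balanced image.

    Isolated denoising artefacts are copies of fine-scale filter kernels whose
    amplitude grows with the threshold, so this local statistic increases
    monotonically with added-noise contrast both for raw noisy images and for
    images passed through a threshold denoiser.
    """
    arr = np.asarray(pixels, dtype=float)
    key = (arr.shape[0], round(float(cutoff), 6))
    hp = _HP_CACHE.get(key)
    if hp is None:
        hp = _HP_CACHE[key] = _highpass_filter(arr.shape[0], cutoff)
    band = np.fft.ifft2(hp * np.fft.fft2(arr - arr.mean()))
    return float(np.abs(band).max())


@dataclass
class ObserverModel:
    """Decision statistic + internal noise + tie-break rule.

    The default statistic is the rectified peak high-frequency response,
    ``max(peak_hf_response - floor, 0)``: the observer flags high-frequency
    content (residual noise or ringing artefacts) only where it exceeds the
    ``floor`` typical of clean natural images — an absolute visibility
    threshold.  ``statistic_name="energy_fraction"`` selects the global
    high-frequency contrast-energy fraction instead.  ``cutoff`` is in
    cycles/image; with ``cutoff`` at or above the grid's maximum frequency the
    observer is blind.  Internal noise is Gaussian on the statistic scale.
    Ties are broken in favour of interval 1 (reachable only with zero
    internal noise).
    """

    cutoff: float = 45.0
    internal_noise_sd: float = 0.01
    floor: float = 0.0
    statistic_name: str = "peak_hf"
    seed: int = 0
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.statistic_name not in ("peak_hf", "energy_fraction"):
            raise ValueError(f"unknown statistic {self.statistic_name!r}")
        self.rng = np.random.default_rng(self.seed)

    def raw_statistic(self, stim) -> float:
        pixels = stim.pixels if isinstance(stim, ImageStim) else stim
        if self.statistic_name == "peak_hf":
            return peak_hf_response(pixels, self.cutoff)
        return hf_energy_fraction(pixels, self.cutoff)

    def statistic(self, stim) -> float:
        return max(self.raw_statistic(stim) - self.floor, 0.0)

    def decide_from_stats(self, stat1: float, stat2: float) -> int:
        s1 = stat1 + self.rng.normal(0.0, self.internal_noise_sd)
        s2 = stat2 + self.rng.normal(0.0, self.internal_noise_sd)
        return 1 if s1 >= s2 else 2


def observer_decide(stim1, stim2, observer: ObserverModel) -> int:
    """Return the interval (1 or 2) with the larger noisy decision statistic."""
    p1 = stim1.pixels if isinstance(stim1, ImageStim) else np.asarray(stim1)
    p2 = stim2.pixels if isinstance(stim2, ImageStim) else np.asarray(stim2)
    if p1.shape != p2.shape:
        raise ValueError("stimuli must have the same size")
    return observer.decide_from_stats(observer.statistic(p1), observer.statistic(p2))


def calibrate_observer(pool, target_level_db: float, observer: ObserverModel,
                       seed: int = 0, criterion: float = 0.75) -> ObserverModel:
    """Set the observer's visibility floor and internal noise from a clean pool.

    The floor becomes the mean raw statistic of the clean images (the
    natural-image norm).  The internal-noise SD is then chosen so the baseline
    noise-detection threshold lands near ``target_level_db``: with statistic
    means/variances measured with and without noise at the target level,
    ``Phi(delta / sqrt(v_clean + v_noisy + 2*sd**2)) = criterion``.
    """
    raw_clean = np.array([observer.raw_statistic(im) for im in pool])
    floor = float(raw_clean.mean())
    probe = replace(observer, floor=floor)
    clean = np.array([probe.statistic(im) for im in pool])
    noisy = np.array([
        probe.statistic(add_white_noise(im, NoiseCondition(
            target_level_db, derive_seed(seed, "calib", i))))
        for i, im in enumerate(pool)
    ])
    delta = float(noisy.mean() - clean.mean())
    if delta <= 0:
        raise ValueError("statistic does not increase with noise at the target level")
    z = norm.ppf(criterion)
    need = (delta / z) ** 2 - clean.var() - noisy.var()
    if need <= 0:
        log.warning(
            "image variability alone puts threshold below %.1f dB; "
            "using minimal internal noise", target_level_db)
        need = (0.05 * delta) ** 2
    return replace(probe, internal_noise_sd=math.sqrt(need / 2.0))


def calibrate_internal_noise(pool, target_level_db: float, cutoff: float,
                             seed: int = 0, criterion: float = 0.75) -> float:
    """Internal-noise SD for a default observer at a baseline target level.

    Convenience wrapper around :func:`calibrate_observer`.
    """
    obs = calibrate_observer(pool, target_level_db,
                             ObserverModel(cutoff=cutoff), seed=seed,
                             criterion=criterion)
    return obs.internal_noise_sd


# ---------------------------------------------------------------------------
# Staircase
# ---------------------------------------------------------------------------

@dataclass
class Staircase:
    """3-down-1-up transformed staircase in fixed dB steps.

    The level drops one step after three consecutive correct responses and
    rises one step after any error, converging near the 79.4%-correct point
    (0.5 ** (1/3)).
    """

    level_db: float
    step_db: float = 3.0
    floor_db: float = -30.0
    ceiling_db: float = 45.0
    consecutive_correct: int = 0
    reversals: list = field(default_factory=list)
    trials_done: int = 0
    _last_direction: int = 0

    def update(self, correct: bool) -> None:
        self.trials_done += 1
        direction = 0
        if correct:
            self.consecutive_correct += 1
            if self.consecutive_correct >= 3:
                self.consecutive_correct = 0
                direction = -1
        else:
            self.consecutive_correct = 0
            direction = +1
        if direction != 0:
            if self._last_direction and direction != self._last_direction:
                self.reversals.append(self.level_db)
            self._last_direction = direction
            self.level_db = float(np.clip(self.level_db + direction * self.step_db,
                                          self.floor_db, self.ceiling_db))


# ---------------------------------------------------------------------------
# Trials and blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialRecord:
    condition: str
    trial: int
    staircase_id: int
    level_db: float
    image_noise: int
    image_clean: int
    interval_with_noise: int
    response: int
    correct: bool


@dataclass(frozen=True)
class BlockConfig:
    """One measurement block: staircase geometry and trial count."""

    n_trials: int = 100
    start_level_db: float = 18.0
    step_db: float = 3.0
    floor_db: float = -30.0
    ceiling_db: float = 45.0
    window_fwhh_frac: float | None = 0.9375  # 240/256; None disables windowing
    pair_same_image: bool = False


def _lattice_levels(cfg: BlockConfig) -> np.ndarray:
    """All levels reachable by the staircases (start ± k steps, clamped)."""
    down = np.arange(cfg.start_level_db, cfg.floor_db - 1e-9, -cfg.step_db)
    up = np.arange(cfg.start_level_db, cfg.ceiling_db + 1e-9, cfg.step_db)
    return np.unique(np.concatenate([down, up]))


def build_threshold_table(bank: FilterBank, levels_db, cal_images,
                          mode: str = "hard", seed: int = 0) -> dict:
    """Per-level PSNR-optimal noise-scaled thresholds for denoised conditions."""
    table = {}
    for level in levels_db:
        opt = optimize_threshold(cal_images, float(level), bank, mode=mode,
                                 seed=derive_seed(seed, "ttable", round(level, 3)))
        table[round(float(level), 3)] = opt.t_star
    return table


def run_block(pool, observer: ObserverModel, condition: str = "baseline",
              bank: FilterBank | None = None, threshold_table: dict | None = None,
              config: BlockConfig | None = None, seed: int = 0) -> list[TrialRecord]:
    """Run one block of 2AFC trials driven by two interleaved staircases.

    Each image from ``pool`` is used at most once; the pool must hold at least
    ``2 * n_trials`` images (one noisy, one clean per trial, different images
    unless ``pair_same_image``).  In denoised conditions both stimuli pass
    through the denoiser with the per-level threshold from ``threshold_table``.
    """
    cfg = config or BlockConfig()
    needed = cfg.n_trials * (1 if cfg.pair_same_image else 2)
    if len(pool) < needed:
        raise ValueError(
            f"image pool of {len(pool)} too small: a {cfg.n_trials}-trial block "
            f"needs at least {needed} distinct images"
        )
    if bank is not None and threshold_table is None:
        raise ValueError("denoised conditions need a per-level threshold table")
    rng = np.random.default_rng(derive_seed(seed, "block", condition))
    order = rng.permutation(len(pool))
    next_image = iter(order.tolist())

    stairs = [
        Staircase(level_db=cfg.start_level_db, step_db=cfg.step_db,
                  floor_db=cfg.floor_db, ceiling_db=cfg.ceiling_db)
        for _ in range(2)
    ]
    window_fwhh = (cfg.window_fwhh_frac * pool[0].size
                   if cfg.window_fwhh_frac else None)
    records: list[TrialRecord] = []
    for t in range(cfg.n_trials):
        sc_id = int(rng.integers(0, 2))
        stair = stairs[sc_id]
        level = stair.level_db
        idx_noise = next(next_image)
        idx_clean = idx_noise if cfg.pair_same_image else next(next_image)
        noisy_stim = add_white_noise(
            pool[idx_noise],
            NoiseCondition(level, derive_seed(seed, "trialnoise", condition, t)),
        )
        clean_stim = pool[idx_clean]
        if bank is not None:
            t_star = threshold_table[round(float(level), 3)]
            policy = ThresholdPolicy.noise_scaled(t_star, level)
            noisy_stim = ImageStim(pixels=denoise(noisy_stim.pixels, bank, policy))
            clean_stim = ImageStim(pixels=denoise(clean_stim.pixels, bank, policy))
        if window_fwhh:
            noisy_stim = apply_window(noisy_stim, window_fwhh)
            clean_stim = apply_window(clean_stim, window_fwhh)
        interval_with_noise = int(rng.integers(1, 3))
        if interval_with_noise == 1:
            response = observer_decide(noisy_stim, clean_stim, observer)
        else:
            response = observer_decide(clean_stim, noisy_stim, observer)
        correct = response == interval_with_noise
        records.append(TrialRecord(
            condition=condition, trial=t, staircase_id=sc_id, level_db=level,
            image_noise=int(idx_noise), image_clean=int(idx_clean),
            interval_with_noise=interval_with_noise, response=response,
            correct=bool(correct),
        ))
        stair.update(correct)
    return records


# ---------------------------------------------------------------------------
# Psychometric fitting
# ---------------------------------------------------------------------------

class PsychometricFitError(RuntimeError):
    """Fit did not converge (degenerate or insufficient data)."""


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative log-Gaussian fit: p = gamma + (1-gamma-lambda)*Phi((x-mu)/s).

    ``x`` is the noise level in dB (a log-contrast axis, so the function is a
    cumulative log-Gaussian in linear contrast).  ``threshold_db`` solves
    p = 0.75 exactly under the fitted parameters.
    """

    mu: float
    s: float
    gamma: float
    lam: float
    threshold_db: float
    n_trials: int
    nll: float


def _aggregate(records):
    if isinstance(records, tuple) and len(records) == 3:
        levels, k, n = (np.asarray(a, dtype=float) for a in records)
    else:
        df = pd.DataFrame([{"level_db": r.level_db, "correct": r.correct}
                           for r in records])
        grouped = df.groupby("level_db")["correct"].agg(["sum", "count"])
        levels = grouped.index.to_numpy(dtype=float)
        k = grouped["sum"].to_numpy(dtype=float)
        n = grouped["count"].to_numpy(dtype=float)
    return levels, k, n


def fit_psychometric(records, gamma: float = 0.5, lam: float = 0.01,
                     criterion: float = 0.75) -> PsychometricFit:
    """Maximum-likelihood cumulative log-Gaussian fit to 2AFC data.

    ``records`` is a list of :class:`TrialRecord` or a ``(levels_db,
    n_correct, n_total)`` triple.  The guess rate is fixed at ``gamma`` and
    the lapse rate at ``lam``.  Raises :class:`PsychometricFitError` for
    degenerate data (fewer than two levels, or responses all correct /
    all incorrect).
    """
    levels, k, n = _aggregate(records)
    if levels.size < 2:
        raise PsychometricFitError("need data at two or more distinct levels")
    if k.sum() == 0 or k.sum() == n.sum():
        raise PsychometricFitError(
            "all responses identical: psychometric function unconstrained")
    span = 1.0 - gamma - lam

    def nll(params):
        mu, log_s = params
        s = math.exp(log_s)
        p = gamma + span * norm.cdf((levels - mu) / s)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    # moment-based start: level closest to the midpoint performance
    frac = (k + 0.5) / (n + 1.0)
    mu0 = float(np.interp(gamma + span / 2, np.sort(frac),
                          levels[np.argsort(frac)]))
    best = None
    for s0 in (1.0, 3.0, 9.0):
        res = minimize(nll, x0=[mu0, math.log(s0)], method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise PsychometricFitError("maximum-likelihood fit did not converge")
    mu, log_s = best.x
    s = math.exp(log_s)
    p_target = (criterion - gamma) / span
    if not (0 < p_target < 1):
        raise PsychometricFitError(
            f"criterion {criterion} unreachable with gamma={gamma}, lambda={lam}")
    threshold = mu + s * norm.ppf(p_target)
    return PsychometricFit(mu=float(mu), s=float(s), gamma=gamma, lam=lam,
                           threshold_db=float(threshold),
                           n_trials=int(n.sum()), nll=float(best.fun))


def threshold_elevation(baseline: PsychometricFit, treated: PsychometricFit) -> float:
    """dB of added noise the treatment conceals (treated - baseline threshold)."""
    return treated.threshold_db - baseline.threshold_db


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """One baseline plus families × orientation-bandwidth denoising conditions."""

    image_size: int = 256
    n_pool: int = 220
    alpha: float = -1.45
    contrast_db: float = 21.0
    families: tuple = ("cartesian", "polar")
    orient_fwhhs: tuple = (11.25, 22.5, 45.0)
    omega: float = 1.43
    n_scales: int = 6
    reps: int = 4
    n_cal_images: int = 4
    observer_cutoff_frac: float = 0.25   # cutoff = frac * size (cycles/image)
    baseline_target_db: float = 9.0
    block: BlockConfig = field(default_factory=BlockConfig)
    seed: int = 0


@dataclass(frozen=True)
class ExperimentResult:
    trials: pd.DataFrame
    thresholds: pd.DataFrame
    summary: pd.DataFrame


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the simulated 2AFC experiment across all conditions and reps.

    Returns trial-level records, per-(condition, rep) thresholds, and a
    per-condition summary with mean threshold, SE over reps and elevation
    relative to the baseline mean.
    """
    cfg = config
    pool = synth_image_set(cfg.n_pool, cfg.image_size, cfg.alpha,
                           cfg.contrast_db, seed=derive_seed(cfg.seed, "pool"))
    cutoff = cfg.observer_cutoff_frac * cfg.image_size
    calibrated = calibrate_observer(
        pool[: min(len(pool), 60)], cfg.baseline_target_db,
        ObserverModel(cutoff=cutoff), seed=derive_seed(cfg.seed, "calib"))
    log.info("observer cutoff %.1f c/img, floor %.4g, internal noise sd %.3g",
             cutoff, calibrated.floor, calibrated.internal_noise_sd)

    conditions: list[tuple[str, FilterBank | None, dict | None]] = [("baseline", None, None)]
    lattice = _lattice_levels(cfg.block)
    cal_images = pool[: cfg.n_cal_images]
    for family in cfg.families:
        for fwhh in cfg.orient_fwhhs:
            bank = FilterBank(FilterBankConfig(
                size=cfg.image_size, n_scales=cfg.n_scales, omega=cfg.omega,
                orient_fwhh=fwhh, family=family))
            table = build_threshold_table(
                bank, lattice, cal_images,
                seed=derive_seed(cfg.seed, "ttable", family, fwhh))
            conditions.append((f"{family}-{fwhh:g}", bank, table))

    all_records: list[TrialRecord] = []
    rows = []
    for name, bank, table in conditions:
        for rep in range(cfg.reps):
            observer = replace(calibrated,
                               seed=derive_seed(cfg.seed, "observer", name, rep))
            records = run_block(pool, observer, condition=name, bank=bank,
                                threshold_table=table, config=cfg.block,
                                seed=derive_seed(cfg.seed, "blockseed", name, rep))
            all_records.extend(records)
            try:
                fit = fit_psychometric(records)
                rows.append({"condition": name, "rep": rep,
                             "threshold_db": fit.threshold_db,
                             "mu": fit.mu, "s": fit.s, "converged": True})
            except PsychometricFitError as exc:
                log.warning("fit failed for %s rep %d: %s", name, rep, exc)
                rows.append({"condition": name, "rep": rep,
                             "threshold_db": np.nan, "mu": np.nan,
                             "s": np.nan, "converged": False})

    thresholds = pd.DataFrame(rows)
    grouped = thresholds.groupby("condition")["threshold_db"]
    summary = grouped.agg(mean_threshold_db="mean",
                          se_threshold_db=lambda v: v.std(ddof=1) / math.sqrt(len(v)),
                          n_reps="count").reset_index()
    baseline_mean = float(
        summary.loc[summary["condition"] == "baseline", "mean_threshold_db"].iloc[0])
    summary["elevation_db"] = summary["mean_threshold_db"] - baseline_mean
    trials_df = pd.DataFrame([r.__dict__ for r in all_records])
    return ExperimentResult(trials=trials_df, thresholds=thresholds, summary=summary)
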