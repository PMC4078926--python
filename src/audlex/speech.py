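"""Speech-in-noise threshold estimators.

Two estimators are implemented:

* words in noise (CASPA-style): three 10-word CVC lists, each containing one
  occurrence of the same 30 phonemes (20 consonants + 10 vowels), presented
  at fixed SNRs of -5, -10 and -13 dB; the percentage of correctly repeated
  phonemes per SNR is fitted with a two-parameter logistic and the speech
  reception threshold (SRT) is the fitted 50% midpoint;

* sentences in noise (HINT-style): an adaptive 1-down/1-up track on whole
  sentence correctness starting at a 58 dB presentation level against a
  70 dB SPL masker, moving in 2 dB steps, with the threshold taken as the
  mean of the last 6 presented SNRs.  The 1-down/1-up rule targets the 50%
  intelligibility point.

Thresholds (lower = better) are inverted by multiplying by -1 before entering
the z-score pipeline so that higher always means better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, FitConvergenceError

__all__ = [
    "CASPA_SNRS",
    "N_PHONEMES_PER_LIST",
    "WordsInNoiseResult",
    "SRTFit",
    "SentenceObserver",
    "HintConfig",
    "SentenceTrack",
    "phoneme_percent",
    "fit_caspa_srt",
    "simulate_caspa",
    "run_hint_track",
    "invert_scores",
]

CASPA_SNRS = (-5.0, -10.0, -13.0)
N_PHONEMES_PER_LIST = 30  # 20 consonants + 10 vowels


def phoneme_percent(correct_phonemes: int, total: int) -> float:
    """Percent of phonemes repeated correctly in one list."""
    if total <= 0:
        raise ValueError("total phoneme count must be positive")
    if not (0 <= correct_phonemes <= total):
        raise ValueError("correct count must lie in [0, total]")
    return 100.0 * correct_phonemes / total


@dataclass(frozen=True)
class WordsInNoiseResult:
    """Per-subject fixed-SNR word scores: percent phonemes correct per SNR."""

    snr_levels: tuple[float, ...]
    phoneme_pct: tuple[float, ...]
    n_phonemes_per_list: int = N_PHONEMES_PER_LIST

    def __post_init__(self):
        if len(self.snr_levels) != len(self.phoneme_pct):
            raise ConfigurationError("snr_levels and phoneme_pct must align")
        if len(set(self.snr_levels)) != len(self.snr_levels):
            raise ConfigurationError("snr_levels must be distinct")
        if any(not (0.0 <= p <= 100.0) for p in self.phoneme_pct):
            raise ConfigurationError("percentages must lie in [0, 100]")


@dataclass(frozen=True)
class SRTFit:
    srt: float
    slope: float
    converged: bool
    sse: float


def _logistic(snr: np.ndarray, mid: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-slope * (snr - mid)))


def fit_caspa_srt(result: WordsInNoiseResult) -> SRTFit:
    """Least-squares two-parameter logistic fit of proportion correct vs SNR.

    Asymptotes are fixed at 0 and 1 (phoneme scoring has no meaningful
    chance floor); the SRT is the fitted midpoint, i.e. the SNR of 50%
    phonemes correct.  Slope sign is unconstrained and reported in the fit
    diagnostics.
    """
    snr = np.asarray(result.snr_levels, dtype=float)
    prop = np.asarray(result.phoneme_pct, dtype=float) / 100.0
    if len(snr) < 3:
        raise ConfigurationError("need at least 3 SNR points to fit an SRT")
    if np.allclose(prop, prop[0]):
        raise FitConvergenceError(
            f"degenerate word scores (all {prop[0]*100:.1f}%): logistic midpoint "
            "is unidentifiable"
        )

    # midpoint initialized by linear interpolation to 50%, slope at 0.5/dB
    order = np.argsort(snr)
    mid0 = float(np.interp(0.5, prop[order], snr[order]))
    mid0 = float(np.clip(mid0, snr.min() - 10, snr.max() + 10))

    def resid(theta):
        return _logistic(snr, theta[0], theta[1]) - prop

    sol = least_squares(resid, x0=[mid0, 0.5], method="lm", max_nfev=10_000)
    sse = float(np.sum(sol.fun**2))
    if not sol.success:
        raise FitConvergenceError(f"logistic fit did not converge: {sol.message}")
    return SRTFit(srt=float(sol.x[0]), slope=float(sol.x[1]), converged=True, sse=sse)


def simulate_caspa(
    true_srt: float,
    slope: float,
    rng: np.random.Generator,
    snrs: tuple[float, ...] = CASPA_SNRS,
    n_phonemes: int = N_PHONEMES_PER_LIST,
) -> WordsInNoiseResult:
    """Simulate one subject's word-in-noise session at the outcome level:
    phonemes correct per list are binomial with the logistic success rate."""
    pct = []
    for s in snrs:
        p = float(_logistic(np.asarray([s]), true_srt, slope)[0])
        k = int(rng.binomial(n_phonemes, p))
        pct.append(phoneme_percent(k, n_phonemes))
    return WordsInNoiseResult(snr_levels=tuple(snrs), phoneme_pct=tuple(pct),
                              n_phonemes_per_list=n_phonemes)


# --------------------------------------------------------------------------
# Sentences in noise
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SentenceObserver:
    """Whole-sentence intelligibility model: P(correct) is logistic in SNR
    with the 50% point at ``srt50`` and steepness ``slope`` per dB."""

    srt50: float
    slope: float = 0.5

    def p_correct(self, snr: float) -> float:
        return 1.0 / (1.0 + math.exp(-self.slope * (snr - self.srt50)))

    def respond(self, snr: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(snr))


@dataclass(frozen=True)
class HintConfig:
    start_level: float = 58.0  # dB presentation level of the first sentence
    step: float = 2.0          # dB per move
    noise_level: float = 70.0  # dB SPL fixed masker
    threshold_last: int = 6    # trailing SNRs averaged for the threshold


@dataclass(frozen=True)
class SentenceTrack:
    config: HintConfig
    presented_levels: tuple[float, ...]
    presented_snrs: tuple[float, ...]
    outcomes: tuple[bool, ...]
    threshold: float


def run_hint_track(
    observer,
    config: HintConfig,
    n_sentences: int,
    rng: np.random.Generator | None = None,
) -> SentenceTrack:
    """Adaptive sentence track: level drops one step after a correct
    sentence and rises one step after an incorrect one (1-down/1-up, the
    canonical HINT rule targeting 50% intelligibility).  SNR is recorded as
    presentation level minus the fixed masker level; the threshold is the
    mean of the last ``threshold_last`` presented SNRs.

    ``observer`` may be any object with ``respond(snr, rng) -> bool``
    (a :class:`SentenceObserver` or a scripted stand-in).
    """
    if n_sentences < config.threshold_last + 1:
        raise ConfigurationError(
            f"need at least {config.threshold_last + 1} sentences for a threshold"
        )
    level = config.start_level
    levels, snrs, outcomes = [], [], []
    for _ in range(n_sentences):
        snr = level - config.noise_level
        correct = observer.respond(snr, rng)
        levels.append(level)
        snrs.append(snr)
        outcomes.append(correct)
        level = level - config.step if correct else level + config.step
    threshold = float(np.mean(snrs[-config.threshold_last:]))
    return SentenceTrack(
        config=config,
        presented_levels=tuple(levels),
        presented_snrs=tuple(snrs),
        outcomes=tuple(outcomes),
        threshold=threshold,
    )


def invert_scores(values):
    """Multiply by -1 so lower-is-better thresholds become higher-is-better
    scores (yields positively oriented correlation matrices and z-scores).
    An involution: applying it twice is the identity."""
    arr = np.asarray(values, dtype=float)
    out = -arr
    if np.isscalar(values) or arr.ndim == 0:
        return float(out)
    return out
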