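"""Synthetic case-control cohort generator.

Generates subject tables with the statistical structure the downstream
analysis assumes: two groups (normal readers, NR, and dyslexic readers,
DYS), per-measure group means and SDs on each measure's native scale,
correlated latent abilities (literacy, phonological awareness, verbal
short-term memory, rapid naming, slow-rate auditory, intensity, speech in
noise), and per-group "deficit" subpopulations that fatten the lower tail
of a latent ability without moving the group moments.

The generative model per measure is::

    base  = sqrt(1-u) * F_factor + sqrt(u) * unique          (unit variance)
    lat   = base                      with prob 1-p
          = -shift + width * base     with prob p            (deficit draw)
    x     = standardize(lat)          (exact mean 0, var 1 in expectation)
    raw   = group_mean + group_sd * (x if higher_is_better else -x)

so group sample moments converge to the configured means/SDs regardless of
the mixture, while the mixture controls how many subjects land below a
control-referenced deviance cut.  Deficit draws are shared across the
measures of a factor (one Bernoulli per subject per mixture key), so
composite scores inherit the deficit; measure-level keys override the
factor key where prevalences differ within a factor.

``tune_deficit_mix`` calibrates mixture parameters so that the full
two-step deviance pipeline reproduces target per-group deviance
prevalences as closely as the mixture family allows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from . import deviance as dev
from .errors import ConfigurationError, SchemaError
from .speech import SentenceObserver
from .staircase import VirtualObserver

__all__ = [
    "MeasureSpec",
    "MixComponent",
    "CohortSpec",
    "load_cohort_spec",
    "default_cohort_spec",
    "generate_cohort",
    "oriented_scores",
    "observer_from_subject",
    "run_deviance_pipeline",
    "implied_deviance_rates",
    "tune_deficit_mix",
    "write_subjects",
    "read_subjects",
    "SUBJECT_ID_COL",
]

SUBJECT_ID_COL = "subject_id"
GROUPS = ("NR", "DYS")


@dataclass(frozen=True)
class MeasureSpec:
    """Per-group raw-scale moments and latent wiring for one measure."""

    nr_mean: float
    nr_sd: float
    dys_mean: float
    dys_sd: float
    higher_is_better: bool = True
    factor: str | None = None
    uniqueness: float = 0.3
    clip_lo: float | None = None
    clip_hi: float | None = None

    def __post_init__(self):
        if self.nr_sd < 0 or self.dys_sd < 0:
            raise ConfigurationError("SDs must be non-negative")
        if not (0.0 <= self.uniqueness <= 1.0):
            raise ConfigurationError("uniqueness must be in [0, 1]")

    def moments(self, group: str) -> tuple[float, float]:
        return (self.nr_mean, self.nr_sd) if group == "NR" else (self.dys_mean, self.dys_sd)


@dataclass(frozen=True)
class MixComponent:
    """Deficit mixture component: probability, downward shift (in latent SD
    units, before re-standardization) and component width."""

    prob: float = 0.0
    shift: float = 2.0
    width: float = 0.7

    def __post_init__(self):
        if not (0.0 <= self.prob <= 1.0):
            raise ConfigurationError("mixture probability must be in [0, 1]")
        if self.shift < 0 or self.width <= 0:
            raise ConfigurationError("shift must be >= 0 and width > 0")


@dataclass(frozen=True)
class CohortSpec:
    n_nr: int
    n_dys: int
    measures: dict[str, MeasureSpec]
    factors: tuple[str, ...]
    latent_corr: np.ndarray
    deficit_mix: dict[str, dict[str, MixComponent]] = field(default_factory=dict)
    demographics: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    configured_deviance: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_nr < 0 or self.n_dys < 0:
            raise ConfigurationError("group sizes must be non-negative")
        C = np.asarray(self.latent_corr, dtype=float)
        if C.shape != (len(self.factors), len(self.factors)):
            raise ConfigurationError("latent_corr shape must match factor count")
        if not np.allclose(C, C.T):
            raise ConfigurationError("latent_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ConfigurationError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ConfigurationError("latent_corr must be positive semi-definite")
        for m, ms in self.measures.items():
            if ms.factor is not None and ms.factor not in self.factors:
                raise ConfigurationError(f"measure {m!r} names unknown factor {ms.factor!r}")
        for key in self.deficit_mix:
            if key not in self.factors and key not in self.measures:
                raise ConfigurationError(f"deficit_mix key {key!r} is neither factor nor measure")

    def mix_for(self, measure: str, group: str) -> tuple[str | None, MixComponent]:
        """Resolve the mixture key for a measure: measure-level key wins,
        then the measure's factor, else no mixture."""
        if measure in self.deficit_mix:
            key = measure
        else:
            f = self.measures[measure].factor
            key = f if f is not None and f in self.deficit_mix else None
        if key is None:
            return None, MixComponent(prob=0.0)
        return key, self.deficit_mix[key].get(group, MixComponent(prob=0.0))


# --------------------------------------------------------------------------
# Spec IO
# --------------------------------------------------------------------------

def _spec_from_dict(doc: dict) -> CohortSpec:
    measures = {}
    for name, m in doc["measures"].items():
        clip = m.get("clip") or [None, None]
        measures[name] = MeasureSpec(
            nr_mean=m["nr_mean"], nr_sd=m["nr_sd"],
            dys_mean=m["dys_mean"], dys_sd=m["dys_sd"],
            higher_is_better=m.get("higher_is_better", True),
            factor=m.get("factor"),
            uniqueness=m.get("uniqueness", 0.3),
            clip_lo=clip[0], clip_hi=clip[1],
        )
    mix = {
        key: {g: MixComponent(*vals) for g, vals in comps.items()}
        for key, comps in doc.get("deficit_mix", {}).items()
    }
    demo = {
        name: {g: tuple(v) for g, v in per.items()}
        for name, per in doc.get("demographics", {}).items()
    }
    return CohortSpec(
        n_nr=doc["n_nr"],
        n_dys=doc["n_dys"],
        measures=measures,
        factors=tuple(doc["factors"]),
        latent_corr=np.asarray(doc["latent_corr"], dtype=float),
        deficit_mix=mix,
        demographics=demo,
        configured_deviance=doc.get("configured_deviance", {}),
        seed=doc.get("seed", 0),
    )


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        return _spec_from_dict(json.load(fh))


def default_cohort_spec() -> CohortSpec:
    """Shipped default parameterized from the study's descriptive tables
    (54 NR / 36 DYS; group means and SDs of every measure), with the
    deficit mixture calibrated to the published deviance prevalences."""
    with resources.files("audlex.data").joinpath("default_cohort.json").open() as fh:
        return _spec_from_dict(json.load(fh))


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _standardized_mixture(base: np.ndarray, deficit: np.ndarray, comp: MixComponent) -> np.ndarray:
    """Apply the deficit component and re-standardize to mean 0, var 1."""
    p, d, w = comp.prob, comp.shift, comp.width
    if p == 0.0:
        return base
    lat = np.where(deficit, -d + w * base, base)
    mean = -p * d
    var = (1.0 - p) + p * (w**2 + d**2) - mean**2
    return (lat - mean) / np.sqrt(var)


def _generate_group(spec: CohortSpec, group: str, n: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    K = len(spec.factors)
    L = np.linalg.cholesky(spec.latent_corr + 1e-12 * np.eye(K))
    F = rng.standard_normal((n, K)) @ L.T
    fidx = {f: i for i, f in enumerate(spec.factors)}

    # one deficit draw per subject per mixture key (shared across a factor's
    # member measures so composites inherit the deficit)
    deficit = {}
    for key in sorted(spec.deficit_mix):
        comp = spec.deficit_mix[key].get(group, MixComponent(prob=0.0))
        deficit[key] = rng.random(n) < comp.prob

    cols = {}
    for name, dem in spec.demographics.items():
        mean, sd = dem[group]
        cols[name] = mean + sd * rng.standard_normal(n)
    for name in spec.measures:
        ms = spec.measures[name]
        e = rng.standard_normal(n)
        if ms.factor is None:
            base = e
        else:
            u = ms.uniqueness
            base = np.sqrt(1.0 - u) * F[:, fidx[ms.factor]] + np.sqrt(u) * e
        key, comp = spec.mix_for(name, group)
        x = _standardized_mixture(base, deficit.get(key, np.zeros(n, bool)), comp)
        mean, sd = ms.moments(group)
        raw = mean + sd * (x if ms.higher_is_better else -x)
        if ms.clip_lo is not None or ms.clip_hi is not None:
            raw = np.clip(raw, ms.clip_lo, ms.clip_hi)
        cols[name] = raw
    out = pd.DataFrame(cols)
    out.insert(0, "group", group)
    return out


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate a subject table: one row per subject with columns
    subject_id, group, demographics, and one column per raw measure.
    Identical (spec, seed) reproduces identical tables."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for group, n in (("NR", spec.n_nr), ("DYS", spec.n_dys)):
        if n > 0:
            frames.append(_generate_group(spec, group, n, rng))
        else:
            _generate_group(spec, group, 0, rng)  # keep the stream aligned
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["group", *spec.demographics, *spec.measures])
    df.insert(0, SUBJECT_ID_COL, [f"S{i + 1:04d}" for i in range(len(df))])
    return df


def oriented_scores(subjects: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Measure columns oriented so higher = better: lower-is-better
    thresholds/SRTs are inverted by multiplying by -1."""
    out = {}
    for name, ms in spec.measures.items():
        col = subjects[name].astype(float)
        out[name] = col if ms.higher_is_better else -col
    return pd.DataFrame(out, index=subjects.index)


def observer_from_subject(subject: pd.Series, task: str,
                          slope: float = 4.0, lapse: float = 0.0):
    """Build the virtual observer whose true threshold is the subject's
    latent task threshold.  The three auditory tasks are 3AFC odd-one-out,
    so the guess rate is fixed at 1/3; the sentence task returns a
    whole-sentence intelligibility observer."""
    t = task.lower()
    if t in ("fm", "rt", "id"):
        return VirtualObserver(threshold=float(subject[t]), slope=slope,
                               guess=1.0 / 3.0, lapse=lapse, task=t.upper())
    if t == "hint":
        return SentenceObserver(srt50=float(subject["hint"]))
    raise ConfigurationError(f"unknown task {task!r}")


# --------------------------------------------------------------------------
# Deviance plumbing over a generated cohort
# --------------------------------------------------------------------------

def run_deviance_pipeline(subjects: pd.DataFrame, spec: CohortSpec,
                          config: dev.DevianceConfig | None = None):
    """Orient measures, run the two-step z-scores, build composites and
    deviance flags.  Returns (ztable, zscores-with-composites, flags)."""
    config = config or dev.DevianceConfig()
    oriented = oriented_scores(subjects, spec)
    groups = subjects["group"]
    groups.index = oriented.index
    ztable = dev.two_step_z(oriented, groups, config)
    zc = dev.make_composites(ztable, config)
    flags = dev.flag_deviant(zc, config)
    return ztable, zc, flags


def observed_deviance_rates(subjects: pd.DataFrame, spec: CohortSpec,
                            observables: list[str] | None = None) -> pd.DataFrame:
    """Per-group deviance proportions for composites and single measures."""
    _, zc, flags = run_deviance_pipeline(subjects, spec)
    groups = subjects["group"]
    obs = observables or _default_observables(spec)
    rows = {}
    for name in obs:
        rows[name] = {
            g: float(flags.loc[groups.values == g, name].mean()) for g in GROUPS
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(GROUPS)]


def _default_observables(spec: CohortSpec) -> list[str]:
    comps = list(dev.DEFAULT_COMPOSITES)
    members = {m for mem in dev.DEFAULT_COMPOSITES.values() for m in mem}
    singles = [m for m in spec.measures if m not in members]
    return comps + singles


def implied_deviance_rates(spec: CohortSpec, n_per_group: int = 100_000,
                           seed: int = 0) -> pd.DataFrame:
    """Deviance prevalences implied by the spec's mixture, estimated by
    pushing a large cohort through the full two-step pipeline."""
    big = replace(spec, n_nr=n_per_group, n_dys=n_per_group)
    subjects = generate_cohort(big, seed=seed)
    return observed_deviance_rates(subjects, big)


# --------------------------------------------------------------------------
# Mixture calibration
# --------------------------------------------------------------------------

def _members_of(spec: CohortSpec, observable: str) -> list[str]:
    if observable in dev.DEFAULT_COMPOSITES:
        return list(dev.DEFAULT_COMPOSITES[observable])
    return [observable]


def _rate_for_key(spec: CohortSpec, observable: str, group: str,
                  nr_comp: MixComponent, comp: MixComponent,
                  draws: dict, cut: float = -1.65) -> float:
    """Deviance rate of one observable under candidate mixture components,
    simulated on frozen base draws (common random numbers).  Only the
    observable's member measures matter for its marginal rate."""
    members = _members_of(spec, observable)
    Fb, Eb = draws["F"], draws["E"]
    z_nr, z_g = [], []
    for j, m in enumerate(members):
        ms = spec.measures[m]
        u = ms.uniqueness
        base_nr = np.sqrt(1 - u) * Fb[:, 0] + np.sqrt(u) * Eb[:, j]
        base_g = np.sqrt(1 - u) * Fb[:, 1] + np.sqrt(u) * Eb[:, len(members) + j]
        x_nr = _standardized_mixture(base_nr, draws["U"][:, 0] < nr_comp.prob, nr_comp)
        cg = nr_comp if group == "NR" else comp
        x_g = _standardized_mixture(base_g, draws["U"][:, 1] < cg.prob, cg)
        # oriented raw scale: the group mean gap and any clipping both
        # contribute to the deviance rate
        s = 1.0 if ms.higher_is_better else -1.0
        for grp, x, acc in (("NR", x_nr, z_nr), (group, x_g, z_g)):
            mean, sd = ms.moments(grp)
            raw = mean + sd * (x if ms.higher_is_better else -x)
            if ms.clip_lo is not None or ms.clip_hi is not None:
                raw = np.clip(raw, ms.clip_lo, ms.clip_hi)
            acc.append(s * raw)
    out = []
    moment_dev = 0.0
    for j, (x_nr, x_g) in enumerate(zip(z_nr, z_g)):
        ms = spec.measures[members[j]]
        mean_g, sd_g = ms.moments(group)
        if sd_g > 0:
            s = 1.0 if ms.higher_is_better else -1.0
            moment_dev = max(
                moment_dev,
                abs(x_g.mean() - s * mean_g) / sd_g,       # clip-induced mean shift
                abs(x_g.std(ddof=1) - sd_g) / sd_g,
            )
        m1, s1 = x_nr.mean(), x_nr.std(ddof=1)
        keep = (x_nr - m1) / s1 >= cut
        m2, s2 = x_nr[keep].mean(), x_nr[keep].std(ddof=1)
        out.append((x_g - m2) / s2)
    zfinal = np.mean(out, axis=0)
    return float((zfinal < cut).mean()), float(moment_dev)


def tune_deficit_mix(
    spec: CohortSpec,
    targets: dict[str, dict[str, tuple[str, float]]],
    n: int = 120_000,
    seed: int = 12345,
    probs: np.ndarray | None = None,
    shifts: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0),
    widths: tuple[float, ...] = (0.5, 0.7, 1.0),
) -> CohortSpec:
    """Calibrate the deficit mixture to target deviance prevalences.

    ``targets`` maps a mixture key (factor or measure name) to, per group,
    ``(observable, target_rate)`` where the observable is the composite or
    measure whose deviance prevalence should match.  For each key the NR
    component is tuned first (it defines the control reference), then the
    DYS component; each is a grid search over mixture probability and shift
    at fixed component width, using common random numbers.  Targets outside
    the reach of the mixture family (given the fixed group moments) get the
    closest achievable rate.
    """
    probs = probs if probs is not None else np.linspace(0.0, 0.95, 39)
    rng = np.random.default_rng(seed)
    mix = {k: dict(v) for k, v in spec.deficit_mix.items()}
    for key, per_group in targets.items():
        obs_nr, t_nr = per_group["NR"]
        obs_dys, t_dys = per_group["DYS"]
        members = _members_of(spec, obs_nr)
        draws = {
            "F": rng.standard_normal((n, 2)),
            "E": rng.standard_normal((n, 2 * len(members))),
            "U": rng.random((n, 2)),
        }
        nr_near = _grid_candidates(spec, obs_nr, "NR", None, t_nr, draws,
                                   probs, shifts, widths)
        best_pair, best_score = None, None
        for nr_err, nr_comp in nr_near:
            dys_near = _grid_candidates(spec, obs_dys, "DYS", nr_comp, t_dys,
                                        draws, probs, shifts, widths)
            dys_err, dys_comp = dys_near[0]
            score = (round(dys_err, 3), round(nr_err, 3),
                     nr_comp.prob + dys_comp.prob, nr_comp.shift + dys_comp.shift)
            if best_score is None or score < best_score:
                best_pair, best_score = (nr_comp, dys_comp), score
        mix[key] = {"NR": best_pair[0], "DYS": best_pair[1]}
    return replace(spec, deficit_mix=mix)


def _grid_candidates(spec, observable, group, nr_comp, target, draws,
                     probs, shifts, widths, tol: float = 0.004,
                     moment_tol: float = 0.03, max_keep: int = 10):
    """Grid-search one group's mixture component.

    Candidates whose clipped raw moments drift more than ``moment_tol``
    (in SD units) from the configured group moments are rejected so that
    extreme mixtures cannot buy tail mass at the price of the means the
    cohort is supposed to reproduce.  Returns the near-optimal candidates
    (within ``tol`` of the best error), most parsimonious first.
    """
    cands, fallback = [], []
    for w in widths:
        for d in shifts:
            for p in probs:
                comp = MixComponent(prob=float(p), shift=float(d), width=float(w))
                ref = comp if group == "NR" else nr_comp
                r, mdev = _rate_for_key(spec, observable, group, ref, comp, draws)
                entry = (abs(r - target), comp)
                fallback.append(entry)
                if mdev <= moment_tol:
                    cands.append(entry)
    if not cands:
        cands = fallback
    best_err = min(e for e, _ in cands)
    near = sorted(
        (entry for entry in cands if entry[0] <= best_err + tol),
        key=lambda entry: (entry[1].prob, entry[1].shift),
    )
    return near[:max_keep]


# --------------------------------------------------------------------------
# Subject table IO
# --------------------------------------------------------------------------

def write_subjects(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, index=False)


def read_subjects(path, spec: CohortSpec | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = [SUBJECT_ID_COL, "group"]
    if spec is not None:
        required += list(spec.demographics) + list(spec.measures)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"subject table missing columns: {missing}")
    if len(df) == 0:
        raise SchemaError("subject table is empty")
    return df
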