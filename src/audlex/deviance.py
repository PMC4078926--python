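"""Control-referenced individual-deviance analysis.

Implements the two-step z-scoring used in case-control neuropsychology
(Ramus-style): z-scores are first computed against the full control (normal
reader) mean and SD; controls falling below the deviance cut on that first
pass are removed, the control mean and SD are recomputed from the retained
controls, and final z-scores for *all* subjects are referenced to those
trimmed statistics.  A subject is deviant on a measure when the final z
falls strictly below the cut (default -1.65, the bottom ~5% of a normal
population).  Composite scores are unweighted means of member z-scores.

Group differences in deviance prevalence are tested with the Pearson
chi-square on the 2x2 deviant-by-group table (df 1, no continuity
correction), and the dyslexic group is partitioned into isolated vs
overlapping phonological-awareness (PA) and rise-time (RT) deficits, with a
variant controlling for intensity-discrimination (ID) deviance.

All measures entering the pipeline must be oriented so that higher means
better (thresholds and SRTs pre-inverted with ``speech.invert_scores``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateMeasureError, SchemaError

__all__ = [
    "DEFAULT_COMPOSITES",
    "DevianceConfig",
    "ZTable",
    "ContingencyTable",
    "OverlapPartition",
    "two_step_z",
    "make_composites",
    "flag_deviant",
    "deviance_table",
    "pearson_chi2",
    "overlap_partition",
]

DEFAULT_COMPOSITES: dict[str, tuple[str, ...]] = {
    "Literacy": ("reading", "spelling"),
    "PA": ("spoonerism",),
    "RAN": ("ran_color", "ran_object"),
    "VSTM": ("digit_span", "nonword_recall"),
}


@dataclass(frozen=True)
class DevianceConfig:
    cut: float = -1.65
    control_group: str = "NR"
    composites: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITES)
    )

    def __post_init__(self):
        if self.cut >= 0:
            raise ConfigurationError("deviance cut must be negative")


@dataclass(frozen=True)
class ZTable:
    """Per-subject, per-measure z-scores from the two-step standardization.

    ``z1``/``z2`` are subjects x measures frames of step-1 and final
    z-scores; ``control_stats`` holds the mean/SD used at each step;
    ``excluded`` flags controls removed between the steps (per measure).
    """

    z1: pd.DataFrame
    z2: pd.DataFrame
    control_stats: pd.DataFrame  # index: measure; cols: mean1, sd1, mean2, sd2, n_excluded
    excluded: pd.DataFrame      # control subjects x measures, bool
    groups: pd.Series
    control_group: str


def two_step_z(
    values: pd.DataFrame,
    groups: pd.Series,
    config: DevianceConfig | None = None,
) -> ZTable:
    """Two-step control-referenced z-scores, exclusion applied independently
    per measure.  Raises :class:`DegenerateMeasureError` when the control
    spread is zero at either step (the error names the measure)."""
    config = config or DevianceConfig()
    groups = groups.reindex(values.index)
    ctrl_mask = groups == config.control_group
    if int(ctrl_mask.sum()) < 2:
        raise SchemaError(
            f"need at least 2 subjects in control group {config.control_group!r}"
        )

    z1 = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    z2 = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    excluded = pd.DataFrame(
        False, index=values.index[ctrl_mask], columns=values.columns
    )
    stats_rows = {}
    for m in values.columns:
        col = values[m].astype(float)
        ctrl = col[ctrl_mask]
        mean1, sd1 = float(ctrl.mean()), float(ctrl.std(ddof=1))
        if not np.isfinite(sd1) or sd1 == 0.0:
            raise DegenerateMeasureError(m, step=1)
        z1[m] = (col - mean1) / sd1
        drop = z1.loc[ctrl.index, m] < config.cut
        excluded[m] = drop
        kept = ctrl[~drop]
        if len(kept) < 2:
            raise DegenerateMeasureError(m, step=2)
        mean2, sd2 = float(kept.mean()), float(kept.std(ddof=1))
        if not np.isfinite(sd2) or sd2 == 0.0:
            raise DegenerateMeasureError(m, step=2)
        z2[m] = (col - mean2) / sd2
        stats_rows[m] = {
            "mean1": mean1,
            "sd1": sd1,
            "mean2": mean2,
            "sd2": sd2,
            "n_excluded": int(drop.sum()),
        }
    return ZTable(
        z1=z1,
        z2=z2,
        control_stats=pd.DataFrame.from_dict(stats_rows, orient="index"),
        excluded=excluded,
        groups=groups,
        control_group=config.control_group,
    )


def make_composites(ztable: ZTable, config: DevianceConfig | None = None) -> pd.DataFrame:
    """Final z-scores extended with composite columns (unweighted means of
    member final z-scores; a single-member composite equals its member)."""
    config = config or DevianceConfig()
    out = ztable.z2.copy()
    for name, members in config.composites.items():
        missing = [m for m in members if m not in out.columns]
        if missing:
            raise SchemaError(f"composite {name!r} missing members: {missing}")
        out[name] = out[list(members)].mean(axis=1)
    return out


def flag_deviant(zscores: pd.DataFrame, config: DevianceConfig | None = None) -> pd.DataFrame:
    """Boolean deviance flags: strictly below the cut (z == cut is not
    deviant; the definition is "falling below" the threshold)."""
    config = config or DevianceConfig()
    return zscores < config.cut


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 deviant-by-group counts: row 1 = cases (DYS), row 2 = controls."""

    measure: str
    a: int  # DYS deviant
    b: int  # DYS non-deviant
    c: int  # NR deviant
    d: int  # NR non-deviant
    chi2: float
    p: float

    @property
    def pct_dys(self) -> float:
        return 100.0 * self.a / (self.a + self.b)

    @property
    def pct_nr(self) -> float:
        return 100.0 * self.c / (self.c + self.d)


def pearson_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df 1, no continuity correction:
    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p is the upper tail."""
    margins = {
        "row 1 (a+b)": a + b,
        "row 2 (c+d)": c + d,
        "column 1 (a+c)": a + c,
        "column 2 (b+d)": b + d,
    }
    for name, total in margins.items():
        if total <= 0:
            raise ConfigurationError(f"zero margin in contingency table: {name}")
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def deviance_table(
    flags: pd.DataFrame,
    groups: pd.Series,
    case_group: str = "DYS",
    control_group: str = "NR",
) -> list[ContingencyTable]:
    """Per-measure deviant counts, within-group percentages and chi-square."""
    groups = groups.reindex(flags.index)
    present = set(groups.unique())
    if not {case_group, control_group} <= present:
        raise SchemaError(
            f"need both groups {case_group!r} and {control_group!r}; found {sorted(present)}"
        )
    cases = flags[groups == case_group]
    ctrls = flags[groups == control_group]
    out = []
    for m in flags.columns:
        a = int(cases[m].sum())
        b = len(cases) - a
        c = int(ctrls[m].sum())
        d = len(ctrls) - c
        try:
            chi2, p = pearson_chi2(a, b, c, d)
        except ConfigurationError:
            chi2, p = float("nan"), float("nan")
        out.append(ContingencyTable(measure=m, a=a, b=b, c=c, d=d, chi2=chi2, p=p))
    return out


@dataclass(frozen=True)
class OverlapPartition:
    """Partition of the case group by PA / RT deficit overlap.

    Without ID control the four cells sum to ``n_cases``.  With ID control
    on, ID-deviant subjects are excluded before partitioning, the cells sum
    to ``n_id_clean``, and percentages are reported both over all cases and
    over the ID-clean subset.
    """

    n_cases: int
    pa_only: int
    rt_only: int
    both: int
    neither: int
    id_control: bool
    n_id_clean: int | None = None

    def pct(self, denominator: str = "cases") -> dict[str, float]:
        n = self.n_cases if denominator == "cases" else (self.n_id_clean or self.n_cases)
        return {
            "pa_only": 100.0 * self.pa_only / n,
            "rt_only": 100.0 * self.rt_only / n,
            "both": 100.0 * self.both / n,
            "neither": 100.0 * self.neither / n,
        }


def overlap_partition(
    flags: pd.DataFrame,
    groups: pd.Series,
    id_control: bool = False,
    case_group: str = "DYS",
    pa: str = "PA",
    rt: str = "rt",
    id_: str = "id",
) -> OverlapPartition:
    """Partition case subjects into PA-only / RT-only / both / neither
    deficit cells (the Figure-1-style overlap analysis)."""
    for col in (pa, rt) + ((id_,) if id_control else ()):
        if col not in flags.columns:
            raise SchemaError(f"deviance flags missing column {col!r}")
    groups = groups.reindex(flags.index)
    sub = flags[groups == case_group]
    n_cases = len(sub)
    n_id_clean = None
    if id_control:
        sub = sub[~sub[id_].astype(bool)]
        n_id_clean = len(sub)
    pa_f = sub[pa].astype(bool)
    rt_f = sub[rt].astype(bool)
    both = int((pa_f & rt_f).sum())
    pa_only = int((pa_f & ~rt_f).sum())
    rt_only = int((rt_f & ~pa_f).sum())
    neither = len(sub) - both - pa_only - rt_only
    return OverlapPartition(
        n_cases=n_cases,
        pa_only=pa_only,
        rt_only=rt_only,
        both=both,
        neither=neither,
        id_control=id_control,
        n_id_clean=n_id_clean,
    )
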