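"""Group-comparison statistics and dose arithmetic.

The comparison family mirrors common practice for multi-group assays:
D'Agostino-Pearson normality per group decides, for the whole dataset,
between one-way ANOVA with Tukey's HSD and Kruskal-Wallis with Dunn's
multiple-comparison test; pairwise results versus the control carry
figure-legend significance tiers (*, **, ***, ****).

Dose arithmetic converts a body-surface-area dose (mg/m^2) into the blood
plasma concentration dose * S / V (µg/mL) and rescales it to a washed-cell
suspension by the ratio of suspension to whole-blood cell concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError

_MIN_GROUP_SIZE = 5
_MIN_NORMALITY_SIZE = 8  # D'Agostino-Pearson is undefined below this

TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_tier(p: float) -> str:
    for threshold, stars in TIERS:
        if p <= threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    normality_p: float | None  # None when the test is not applicable


@dataclass(frozen=True)
class PairwiseComparison:
    group: str
    versus: str
    statistic: float
    p_adjusted: float
    tier: str


@dataclass
class GroupComparison:
    groups: list[GroupSummary]
    control: str
    all_normal: bool
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    posthoc_test: str
    comparisons: list[PairwiseComparison]

    def to_dict(self) -> dict:
        return {
            "control": self.control,
            "all_normal": self.all_normal,
            "omnibus": {
                "test": self.omnibus_test,
                "statistic": self.omnibus_statistic,
                "p": self.omnibus_p,
            },
            "posthoc": self.posthoc_test,
            "groups": [vars(g) for g in self.groups],
            "comparisons": [vars(c) for c in self.comparisons],
        }


def dunn_vs_control(samples: list[np.ndarray], labels: list[str], control_idx: int):
    """Dunn's rank-based z tests of every group against the control.

    Uses pooled average ranks with tie correction; two-sided p-values are
    Bonferroni-adjusted by the number of comparisons performed.
    """
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + len(s)].mean())
        sizes.append(len(s))
        start += len(s)

    n_comp = len(samples) - 1
    out = []
    for j in range(len(samples)):
        if j == control_idx:
            continue
        se = np.sqrt(base_var * (1.0 / sizes[control_idx] + 1.0 / sizes[j]))
        z = (mean_ranks[j] - mean_ranks[control_idx]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_comp)
        out.append(
            PairwiseComparison(
                group=labels[j],
                versus=labels[control_idx],
                statistic=float(z),
                p_adjusted=float(p),
                tier=significance_tier(p),
            )
        )
    return out


def compare_groups(data: dict, control: str | None = None, alpha: float = 0.05) -> GroupComparison:
    """Omnibus test plus pairwise comparisons of every group versus the control.

    If every group passes normality at ``alpha`` the parametric branch
    (one-way ANOVA + Tukey HSD) is used; a single failing group switches the
    whole dataset to Kruskal-Wallis + Dunn.  Groups smaller than 8 values
    cannot be normality-tested and send the dataset down the nonparametric
    branch as well.
    """
    labels = list(data)
    if len(labels) < 3:
        raise ConfigurationError("group comparison needs at least 3 groups")
    samples = [np.asarray(data[k], dtype=float) for k in labels]
    for lab, s in zip(labels, samples):
        if len(s) < _MIN_GROUP_SIZE:
            raise ConfigurationError(
                f"group {lab!r} has {len(s)} values; at least {_MIN_GROUP_SIZE} required"
            )
    if control is None:
        control = "Control" if "Control" in labels else labels[0]
    if control not in labels:
        raise ConfigurationError(f"control group {control!r} not among {labels}")
    control_idx = labels.index(control)

    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0.0:  # degenerate: every value identical
        groups = [
            GroupSummary(lab, len(s), float(s.mean()), 0.0, None)
            for lab, s in zip(labels, samples)
        ]
        comparisons = [
            PairwiseComparison(lab, control, 0.0, 1.0, "ns")
            for lab in labels
            if lab != control
        ]
        return GroupComparison(
            groups, control, True, "one-way ANOVA", 0.0, 1.0, "Tukey HSD", comparisons
        )

    normality_ps: list[float | None] = []
    all_normal = True
    for s in samples:
        if len(s) < _MIN_NORMALITY_SIZE or np.ptp(s) == 0.0:
            normality_ps.append(None)
            all_normal = False
            continue
        p = float(sps.normaltest(s).pvalue)
        normality_ps.append(p)
        if p <= alpha:
            all_normal = False

    groups = [
        GroupSummary(lab, len(s), float(s.mean()), float(s.std(ddof=1)), p)
        for lab, s, p in zip(labels, samples, normality_ps)
    ]

    if all_normal:
        stat, p = sps.f_oneway(*samples)
        res = sps.tukey_hsd(*samples)
        comparisons = []
        for j, lab in enumerate(labels):
            if j == control_idx:
                continue
            p_adj = float(res.pvalue[control_idx, j])
            comparisons.append(
                PairwiseComparison(
                    group=lab,
                    versus=control,
                    statistic=float(res.statistic[control_idx, j]),
                    p_adjusted=p_adj,
                    tier=significance_tier(p_adj),
                )
            )
        return GroupComparison(
            groups, control, True, "one-way ANOVA", float(stat), float(p),
            "Tukey HSD", comparisons,
        )

    stat, p = sps.kruskal(*samples)
    comparisons = dunn_vs_control(samples, labels, control_idx)
    return GroupComparison(
        groups, control, False, "Kruskal-Wallis", float(stat), float(p),
        "Dunn (Bonferroni)", comparisons,
    )


@dataclass(frozen=True)
class DoseSpec:
    """Body-surface-area dose and the population constants that convert it."""

    dose_per_bsa: float  # mg/m^2
    body_surface_area: float = 1.81  # m^2
    blood_volume_l: float = 4.5
    suspension_cell_conc_per_ml: float = 5e8
    whole_blood_cell_conc_per_ml: float = 5e9

    def __post_init__(self):
        for name in (
            "body_surface_area",
            "blood_volume_l",
            "suspension_cell_conc_per_ml",
            "whole_blood_cell_conc_per_ml",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.dose_per_bsa < 0:
            raise ConfigurationError("dose_per_bsa must be nonnegative")


@dataclass(frozen=True)
class DoseResult:
    blood_conc_ug_per_ml: float
    suspension_conc_ug_per_ml: float


def dose_to_concentration(spec: DoseSpec) -> DoseResult:
    """Blood and washed-suspension drug concentrations implied by a dose.

    Blood concentration = dose * S / V in µg/mL (mg/L); the suspension value
    rescales it by the ratio of suspension to whole-blood cell concentration,
    so the drug-per-cell load matches circulation.
    """
    blood = spec.dose_per_bsa * spec.body_surface_area / spec.blood_volume_l
    suspension = blood * spec.suspension_cell_conc_per_ml / spec.whole_blood_cell_conc_per_ml
    return DoseResult(blood_conc_ug_per_ml=blood, suspension_conc_ug_per_ml=suspension)


def suspension_hematocrit_percent(
    cell_conc_per_ml: float = 5e8, mcv_fl: float = 84.6
) -> float:
    """Hematocrit (%) of a suspension: cell concentration times cell volume."""
    if cell_conc_per_ml < 0 or mcv_fl <= 0:
        raise ConfigurationError("cell concentration and MCV must be positive")
    return 100.0 * cell_conc_per_ml * mcv_fl * 1e-12  # fL per mL -> volume fraction
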