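"""Method-agreement statistics: relative error with t-based CIs, Bland–Altman.

Conventions (stated in every output):

* relative error = (method − reference) / reference, dimensionless;
* differences are method − reference;
* standard deviations are sample SDs (n − 1), the convention for both the
  one-sample t-test and Bland–Altman limits of agreement;
* 95 % CIs use the t distribution with df = n − 1 (not normal z).

The packaged validation fixture is a published 10-participant comparison of
cumulative VO₂ (ml/kg) over a 5 km mixed-terrain course: breath-by-breath
reference measurements (K5 metabolic system) against three GPS-based
estimates (the METs/slope-cost model ``hypac`` and the two ACSM variants),
with participants A–E running throughout and F–J alternating running and
walking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .energy_models import Method
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedMeasurements",
    "RelativeErrorResult",
    "BlandAltmanResult",
    "relative_errors",
    "bland_altman",
    "bland_altman_plot",
    "table2_fixture",
    "REFERENCE_LABEL",
]

REFERENCE_LABEL = "K5"


@dataclass
class PairedMeasurements:
    """Paired method-vs-reference values (same subjects, same order)."""

    ids: list[str]
    reference: np.ndarray
    method: np.ndarray
    method_name: str = "method"

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.method = np.asarray(self.method, dtype=float)
        if not (len(self.ids) == len(self.reference) == len(self.method)):
            raise ParameterError("ids, reference and method must have equal length")
        if len(self.reference) < 2:
            raise ParameterError("need at least 2 pairs")
        if np.any(self.reference <= 0):
            raise ParameterError("reference values must be strictly positive")

    def __len__(self) -> int:
        return len(self.reference)

    def subset(self, ids: Sequence[str]) -> "PairedMeasurements":
        """Pairs restricted to the given subject ids, in fixture order."""
        keep = [i for i, s in enumerate(self.ids) if s in set(ids)]
        return PairedMeasurements(
            [self.ids[i] for i in keep], self.reference[keep], self.method[keep],
            self.method_name,
        )


@dataclass(frozen=True)
class RelativeErrorResult:
    """One-sample t summary of per-subject relative errors against zero."""

    per_subject: np.ndarray
    mean: float
    sd: float
    abs_mean: float
    ci_low: float
    ci_high: float
    t_stat: float
    p_two_sided: float
    n: int

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["per_subject"] = [float(x) for x in self.per_subject]
        return d


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95 % limits of agreement of method − reference differences."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray
    all_within_loa: bool
    n: int

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["means"] = [float(x) for x in self.means]
        d["diffs"] = [float(x) for x in self.diffs]
        return d


def relative_errors(pairs: PairedMeasurements) -> RelativeErrorResult:
    """Per-subject relative errors with mean, sample SD, t test and 95 % CI.

    With zero variance (method ≡ reference up to a constant factor applied to
    both columns can still vary; identical columns cannot) the CI collapses to
    the mean and a degenerate-variance warning is logged.
    """
    errs = (pairs.method - pairs.reference) / pairs.reference
    n = len(errs)
    mean = float(np.mean(errs))
    sd = float(np.std(errs, ddof=1))
    if sd == 0.0:
        logger.warning("degenerate variance: all relative errors identical; CI collapses")
        return RelativeErrorResult(errs, mean, 0.0, abs(mean), mean, mean,
                                   t_stat=float("inf") if mean else 0.0,
                                   p_two_sided=0.0 if mean else 1.0, n=n)
    se = sd / np.sqrt(n)
    t_stat = mean / se
    tcrit = float(stats.t.ppf(0.975, df=n - 1))
    p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    return RelativeErrorResult(errs, mean, sd, abs(mean),
                               mean - tcrit * se, mean + tcrit * se,
                               float(t_stat), p, n)


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bias = mean(method − reference); LoA = bias ± 1.96 · SD of differences."""
    diffs = pairs.method - pairs.reference
    means = (pairs.method + pairs.reference) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = bool(np.all((diffs >= lo) & (diffs <= hi)))
    return BlandAltmanResult(bias, sd, lo, hi, means, diffs, within, len(diffs))


def bland_altman_plot(result: BlandAltmanResult, path: str, title: str = "") -> None:
    """Write a Bland–Altman scatter (means vs differences) with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, color="k", zorder=3)
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias = {result.bias:.1f}")
    for y, lbl in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="k", ls="--", lw=1.0)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("method − reference")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# Published 10-participant validation table: cumulative VO2 (ml/kg) over the
# 5 km course per method, plus mean speed (km/h). A–E ran throughout ("running"
# group); F–J alternated running and walking ("running_walking" group).
_TABLE2_IDS = list("ABCDEFGHIJ")
_TABLE2_VO2 = {
    "k5":       [1214.9, 1173.4, 1102.0, 975.0, 842.9, 1280.8, 1275.4, 893.2, 1067.5, 1285.2],
    "hypac":    [1099.6, 1026.5, 1058.8, 1052.1, 1071.6, 1047.3, 1020.7, 990.4, 1152.1, 1079.4],
    "acsm_run": [1143.3, 1106.6, 1123.8, 1155.8, 1024.1, 1189.9, 1172.1, 1044.6, 1267.7, 1161.4],
    "acsm_rw":  [1135.7, 1099.0, 1123.2, 1152.8, 1021.5, 914.4, 780.6, 939.8, 1106.7, 877.7],
}
_TABLE2_SPEED_KMH = [11.4, 11.2, 10.9, 14.6, 17.4, 7.2, 5.8, 9.0, 7.7, 6.3]
TABLE2_GROUPS = {"running": list("ABCDE"), "running_walking": list("FGHIJ")}


@dataclass(frozen=True)
class MethodComparisonTable:
    """The packaged validation fixture: per-subject VO₂ per method."""

    ids: list[str]
    k5: np.ndarray
    columns: dict[str, np.ndarray]
    mean_speed_kmh: np.ndarray
    groups: dict[str, list[str]]

    def pairs(self, method: Method, group: Optional[str] = None) -> PairedMeasurements:
        """Reference-vs-method pairs, optionally restricted to one group."""
        if method not in self.columns:
            raise ParameterError(f"unknown method {method!r}; have {sorted(self.columns)}")
        p = PairedMeasurements(list(self.ids), self.k5.copy(), self.columns[method].copy(),
                               method_name=str(method))
        if group is None:
            return p
        if group not in self.groups:
            raise ParameterError(f"unknown group {group!r}; have {sorted(self.groups)}")
        return p.subset(self.groups[group])


def table2_fixture() -> MethodComparisonTable:
    """The 10×4 published VO₂ comparison table, exactly as printed."""
    return MethodComparisonTable(
        ids=list(_TABLE2_IDS),
        k5=np.array(_TABLE2_VO2["k5"]),
        columns={m: np.array(v) for m, v in _TABLE2_VO2.items() if m != "k5"},
        mean_speed_kmh=np.array(_TABLE2_SPEED_KMH),
        groups={k: list(v) for k, v in TABLE2_GROUPS.items()},
    )
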