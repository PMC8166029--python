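"""Hit-calling statistics for the zebrafish inflammation screen.

Two readouts decide whether a candidate is effective:

- the neutrophil recovery rate
  ``R = (N_model - N_drug) / (N_model - N_control)`` over group-mean
  intestinal neutrophil counts, with ``R > 0.6`` called effective
  (R = 1 means full rescue to the control level, R = 0 no effect);
- the ROS ratio ``rho = I_drug / I_model`` over group-mean DCFH-DA
  intensities, with ``rho < 0.7`` called effective.

Both inequalities are strict; a candidate satisfying both is a dual hit.
The module also provides mean +/- SEM group summaries, two-group t-tests /
one-way ANOVA, and comparative-Ct (2^-ddCt) expression fold changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "HitCall",
    "recovery_rate",
    "ros_ratio",
    "call_hits",
    "hitcalls_to_frame",
    "heatmap_matrix",
    "summarize_group",
    "compare_groups",
    "relative_expression",
]

THETA_RECOVERY = 0.6  # effective iff R > 0.6
THETA_ROS = 0.7       # effective iff rho < 0.7
MIN_EMBRYOS = 5


class DegenerateAssayError(ValueError):
    """Model arm failed to differ from control; recovery rate is undefined."""


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class HitCall:
    candidate: str
    recovery_rate: float
    ros_ratio: float
    neutrophil_effective: bool
    ros_effective: bool

    @property
    def dual_hit(self) -> bool:
        return self.neutrophil_effective and self.ros_effective


def recovery_rate(mean_model: float, mean_drug: float, mean_control: float) -> float:
    """(N_model - N_drug) / (N_model - N_control), unclipped.

    Values above 1 (drug below control) or below 0 (drug above model) are
    passed through so harmful or super-effective candidates stay visible.
    """
    if mean_model == mean_control:
        raise DegenerateAssayError(
            f"model mean ({mean_model}) equals control mean ({mean_control}); "
            "the disease model did not differ from control"
        )
    return (mean_model - mean_drug) / (mean_model - mean_control)


def ros_ratio(mean_drug_ros: float, mean_model_ros: float) -> float:
    """Drug-group mean ROS intensity divided by the model-group mean."""
    if mean_model_ros <= 0:
        raise ValueError(f"model ROS mean must be > 0, got {mean_model_ros}")
    return mean_drug_ros / mean_model_ros


def call_hits(
    plate: pd.DataFrame,
    theta_recovery: float = THETA_RECOVERY,
    theta_ros: float = THETA_ROS,
) -> list[HitCall]:
    """Classify every non-control, non-model arm of a plate table.

    ``plate`` needs columns group, neutrophil_count, ros_intensity. Both
    thresholds are strict: R exactly at ``theta_recovery`` or rho exactly at
    ``theta_ros`` is NOT effective.
    """
    groups = set(plate["group"])
    for required in ("control", "model"):
        if required not in groups:
            raise ValueError(f"plate is missing the {required!r} group")
    by_group = plate.groupby("group")
    n_mean = by_group["neutrophil_count"].mean()
    r_mean = by_group["ros_intensity"].mean()

    calls = []
    for cand in sorted(groups - {"control", "model"}):
        r = recovery_rate(n_mean["model"], n_mean[cand], n_mean["control"])
        rho = ros_ratio(r_mean[cand], r_mean["model"])
        calls.append(
            HitCall(
                candidate=cand,
                recovery_rate=float(r),
                ros_ratio=float(rho),
                neutrophil_effective=bool(r > theta_recovery),
                ros_effective=bool(rho < theta_ros),
            )
        )
    return calls


def hitcalls_to_frame(calls: list[HitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "candidate": [c.candidate for c in calls],
            "recovery_rate": [c.recovery_rate for c in calls],
            "ros_ratio": [c.ros_ratio for c in calls],
            "neutrophil_effective": [c.neutrophil_effective for c in calls],
            "ros_effective": [c.ros_effective for c in calls],
            "dual_hit": [c.dual_hit for c in calls],
        }
    )


def heatmap_matrix(calls: list[HitCall]) -> pd.DataFrame:
    """Candidate x statistic matrix for heat-map export, one row per candidate."""
    frame = hitcalls_to_frame(calls)
    return frame.set_index("candidate")[["recovery_rate", "ros_ratio"]]


def summarize_group(values, group: str = "") -> GroupSummary:
    """Mean and SEM (sd with n-1 denominator over sqrt(n)) of one arm."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 values to summarize, got {x.size}")
    if x.size < MIN_EMBRYOS:
        warnings.warn(
            f"group {group!r} has {x.size} < {MIN_EMBRYOS} embryos", stacklevel=2
        )
    return GroupSummary(
        group=group,
        n=int(x.size),
        mean=float(x.mean()),
        sem=float(x.std(ddof=1) / math.sqrt(x.size)),
    )


def compare_groups(groups: dict[str, np.ndarray]) -> dict:
    """Two groups: two-tailed t-test; three or more: one-way ANOVA.

    Returns the statistic, p-value, test name and significance flags at the
    conventional 0.05 (*) and 0.01 (**) levels.
    """
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n={arr.size} < 2")
    if len(arrays) == 2:
        a, b = arrays.values()
        stat, p = stats.ttest_ind(a, b)
        test = "t-test"
    else:
        stat, p = stats.f_oneway(*arrays.values())
        test = "anova"
    return {
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "significant_05": bool(p < 0.05),
        "significant_01": bool(p < 0.01),
    }


def relative_expression(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_group: str = "control",
) -> pd.DataFrame:
    """Comparative-Ct fold changes, 2^-ddCt, per sample and gene.

    ``ct_table`` needs columns sample, group, gene, Ct, with one reference-
    gene row per sample. dCt = Ct_target - Ct_reference within a sample;
    ddCt subtracts the control-group mean dCt of the same gene.
    """
    for col in ("sample", "group", "gene", "Ct"):
        if col not in ct_table.columns:
            raise ValueError(f"ct_table is missing column {col!r}")
    if reference_gene not in set(ct_table["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} not in ct_table")
    if control_group not in set(ct_table["group"]):
        raise ValueError(f"control group {control_group!r} not in ct_table")

    ref = (
        ct_table[ct_table["gene"] == reference_gene]
        .set_index("sample")["Ct"]
    )
    targets = ct_table[ct_table["gene"] != reference_gene].copy()
    missing = sorted(set(targets["sample"]) - set(ref.index))
    if missing:
        raise ValueError(f"samples missing the reference gene: {missing}")

    targets["dCt"] = targets["Ct"].to_numpy() - ref.loc[targets["sample"]].to_numpy()
    control_dct = (
        targets[targets["group"] == control_group].groupby("gene")["dCt"].mean()
    )
    unseen = sorted(set(targets["gene"]) - set(control_dct.index))
    if unseen:
        raise ValueError(f"genes with no control-group samples: {unseen}")
    targets["ddCt"] = targets["dCt"] - control_dct.loc[targets["gene"]].to_numpy()
    targets["fold_change"] = 2.0 ** (-targets["ddCt"])
    return targets[["sample", "group", "gene", "dCt", "ddCt", "fold_change"]].reset_index(
        drop=True
    )
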