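"""Group-comparison statistics and the glaucoma staging rule.

The comparison logic routes between parametric and non-parametric tests:

* two groups: if both pass a Kolmogorov-Smirnov normality check at alpha
  and an F-ratio variance-homogeneity check passes, use Student's t test
  (equal variances); otherwise Kruskal-Wallis on the two groups.
* three or more groups: if every group passes normality, use the one-way
  F test of equal means (ANOVA); otherwise Kruskal-Wallis.

Every result records the decision path that led to the chosen test.
The staging rule maps a visual-field mean deviation (MD, dB) onto stages
0-5; boundary values go to the less severe stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from octaquant.errors import ValidationError

TEST_NAMES = ("KS_normality", "F_equal_means", "Student_t", "Kruskal_Wallis")


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    decision_path: str

    def __post_init__(self):
        if self.test_name not in TEST_NAMES:
            raise ValidationError(f"unknown test name {self.test_name!r}")
        if not (0 <= self.p_value <= 1):
            raise ValidationError("p_value must lie in [0, 1]")
        if not self.decision_path:
            raise ValidationError("decision_path must be non-empty")


@dataclass
class GlaucomaStage:
    stage: int
    md_db: float
    vf_performed: bool


def _check_sample(sample: Sequence[float], min_n: int = 5) -> np.ndarray:
    arr = np.asarray(list(sample), dtype=np.float64)
    if arr.size < min_n:
        raise ValidationError(f"need at least {min_n} observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("sample contains non-finite values")
    return arr


def ks_normality(sample: Sequence[float]) -> TestResult:
    """One-sample KS test against a normal with the sample's own mean and sd."""
    arr = _check_sample(sample)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValidationError("degenerate sample: zero variance")
    stat, p = stats.kstest(arr, "norm", args=(arr.mean(), sd))
    return TestResult(
        test_name="KS_normality",
        statistic=float(stat),
        p_value=float(p),
        decision_path=f"KS vs Normal(mean={arr.mean():.4g}, sd={sd:.4g}), n={arr.size}",
    )


def _variances_homogeneous(g1: np.ndarray, g2: np.ndarray, alpha: float) -> tuple[bool, str]:
    # two-sided F-ratio test on sample variances
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        return True, "both variances zero -> treated as homogeneous"
    if v1 == 0 or v2 == 0:
        return False, "one variance zero -> heterogeneous"
    big, small = (v1, v2) if v1 >= v2 else (v2, v1)
    dfn = (g1 if v1 >= v2 else g2).size - 1
    dfd = (g2 if v1 >= v2 else g1).size - 1
    f = big / small
    p = 2 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
    verdict = p >= alpha
    return verdict, f"F-ratio={f:.4g}, p={p:.4g} -> {'homogeneous' if verdict else 'heterogeneous'}"


def compare_two_groups(
    g1: Sequence[float],
    g2: Sequence[float],
    alpha: float = 0.05,
) -> TestResult:
    """Compare two groups, choosing Student's t or Kruskal-Wallis.

    Student's t (equal variances) requires both groups to pass KS
    normality at ``alpha`` and the variance-homogeneity check; otherwise
    the non-parametric Kruskal-Wallis test is used.
    """
    a1 = _check_sample(g1)
    a2 = _check_sample(g2)
    path: list[str] = []

    if np.array_equal(a1, a2) and a1.var() == 0:
        # degenerate but well-defined: identical constant groups
        return TestResult(
            test_name="Student_t",
            statistic=0.0,
            p_value=1.0,
            decision_path="identical constant groups -> t=0, p=1",
        )

    normal = True
    for name, arr in (("group1", a1), ("group2", a2)):
        ks = ks_normality(arr)
        ok = ks.p_value >= alpha
        path.append(f"{name} normality p={ks.p_value:.4g} -> {'pass' if ok else 'fail'}")
        normal = normal and ok

    if normal:
        homo, msg = _variances_homogeneous(a1, a2, alpha)
        path.append(msg)
        if homo:
            stat, p = stats.ttest_ind(a1, a2, equal_var=True)
            path.append("-> Student t (equal variances)")
            return TestResult("Student_t", float(stat), float(p), "; ".join(path))

    stat, p = stats.kruskal(a1, a2)
    path.append("-> Kruskal-Wallis (two groups)")
    return TestResult("Kruskal_Wallis", float(stat), float(p), "; ".join(path))


def compare_multi_groups(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> TestResult:
    """Compare >= 3 groups: one-way F test if all normal, else Kruskal-Wallis."""
    if len(groups) < 3:
        raise ValidationError("need at least 3 groups (use compare_two_groups otherwise)")
    arrays = [_check_sample(g) for g in groups]
    path: list[str] = []

    normal = True
    for i, arr in enumerate(arrays, start=1):
        if arr.var() == 0:
            path.append(f"group{i} zero variance -> normality fail")
            normal = False
            continue
        ks = ks_normality(arr)
        ok = ks.p_value >= alpha
        path.append(f"group{i} normality p={ks.p_value:.4g} -> {'pass' if ok else 'fail'}")
        normal = normal and ok

    if normal:
        stat, p = stats.f_oneway(*arrays)
        path.append("-> one-way F test of equal means")
        return TestResult("F_equal_means", float(stat), float(p), "; ".join(path))
    stat, p = stats.kruskal(*arrays)
    path.append("-> Kruskal-Wallis")
    return TestResult("Kruskal_Wallis", float(stat), float(p), "; ".join(path))


def classify_glaucoma_stage(
    md_db: float,
    vf_performed: bool,
    field_abnormal: bool = True,
) -> GlaucomaStage:
    """Stage 0-5 from the visual-field mean deviation (dB).

    * not ``vf_performed`` -> stage 5 (unable to perform the visual field)
    * normal field (``field_abnormal`` False) -> stage 0
    * MD >= -6.00 -> stage 1; (-12.01, -6.00) -> stage 2;
      [-20.00, -12.01] -> stage 3; < -20.00 -> stage 4.

    Boundary values are assigned to the less severe stage; the printed
    scale's gap between -12.00 and -12.01 is closed into stage 2.
    """
    if not vf_performed:
        return GlaucomaStage(stage=5, md_db=float("nan"), vf_performed=False)
    md = float(md_db)
    if not np.isfinite(md):
        raise ValidationError("md_db must be finite when the visual field was performed")
    if not field_abnormal:
        return GlaucomaStage(stage=0, md_db=md, vf_performed=True)
    if md >= -6.00:
        stage = 1
    elif md > -12.01:
        stage = 2
    elif md >= -20.00:
        stage = 3
    else:
        stage = 4
    return GlaucomaStage(stage=stage, md_db=md, vf_performed=True)
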