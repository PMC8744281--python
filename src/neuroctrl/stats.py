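"""Cohort statistics: diagnosis-by-age interaction GLMs, FDR, trajectories.

The primary analysis asks, for each brain system and each node, whether the
age slope of average controllability differs between drug-naive patients
(SCZ) and healthy controls (HC).  The model is an ordinary least-squares GLM

    y ~ 1 + diagnosis + age + diagnosis:age + sex + education

with diagnosis coded SCZ=1/HC=0 and sex M=1/F=0; the interaction test is the
1-df partial F (equal to the squared t of the interaction coefficient).
System-level and node-level p-values form two separate Benjamini-Hochberg
FDR families at q = 0.05.  Targets with a significant interaction get
within-group age trajectories (partial correlation of controllability with
age, controlling sex and education), an age-35 subgroup battery, and
clinical partial correlations in the patient group.

The module-level functions are the primitive operations; the
:class:`ControllabilityAgeModel` / :class:`ControllabilityAgeResults` pair
wraps them in a fit/results interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

DIAGNOSES = ("SCZ", "HC")
CLINICAL_MEASURES = (
    "dup",
    "gaf",
    "panss_total",
    "panss_pos",
    "panss_neg",
    "panss_general",
)
AGE_RANGE = (16.0, 60.0)


class CohortError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cohort table


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table and return it with canonical dtypes.

    Required columns: subject_id, diagnosis (SCZ/HC), age, sex (M/F),
    education.  Clinical columns (dup, gaf, panss_*) must be present for SCZ
    rows and missing (NaN) for HC rows when the columns exist.
    """
    required = {"subject_id", "diagnosis", "age", "sex", "education"}
    missing = required - set(cohort.columns)
    if missing:
        raise CohortError(f"cohort table missing columns {sorted(missing)}")
    bad_dx = ~cohort["diagnosis"].isin(DIAGNOSES)
    if bad_dx.any():
        raise CohortError(
            f"unknown diagnosis values: {sorted(cohort.loc[bad_dx, 'diagnosis'].unique())}"
        )
    bad_sex = ~cohort["sex"].isin(("M", "F"))
    if bad_sex.any():
        raise CohortError(
            f"unknown sex values: {sorted(cohort.loc[bad_sex, 'sex'].unique())}"
        )
    ages = cohort["age"].astype(float)
    if ((ages < AGE_RANGE[0]) | (ages > AGE_RANGE[1])).any():
        bad = cohort.loc[(ages < AGE_RANGE[0]) | (ages > AGE_RANGE[1]), "subject_id"]
        raise CohortError(f"ages outside [16, 60] for subjects {list(bad)}")
    out = cohort.copy()
    out["age"] = ages
    out["education"] = out["education"].astype(float)
    for col in CLINICAL_MEASURES:
        if col in out.columns:
            hc_has = out.loc[out["diagnosis"] == "HC", col].notna()
            if hc_has.any():
                raise CohortError(f"clinical column {col!r} populated for HC subjects")
    return out


def _design(cohort: pd.DataFrame, moderator: np.ndarray, names: tuple[str, ...]):
    dx = (cohort["diagnosis"] == "SCZ").to_numpy(float)
    sex = (cohort["sex"] == "M").to_numpy(float)
    edu = cohort["education"].to_numpy(float)
    x = np.column_stack(
        [np.ones(len(cohort)), dx, moderator, dx * moderator, sex, edu]
    )
    return x, ("const", "diagnosis") + names + ("sex", "education")


def _check_full_rank(x: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        for j in range(1, x.shape[1]):
            others = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise CohortError(f"design is rank deficient: column {names[j]!r} is collinear")
        raise CohortError("design is rank deficient")


@dataclass(frozen=True)
class InteractionResult:
    """One GLM fit: interaction and diagnosis tests plus coefficients."""

    target: str
    F_interaction: float
    p_interaction: float
    F_diagnosis: float
    p_diagnosis: float
    coefficients: dict[str, float]
    n: int


def _interaction_fit(
    y: np.ndarray, cohort: pd.DataFrame, moderator: np.ndarray,
    names: tuple[str, ...], target: str,
) -> InteractionResult:
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise CohortError(f"missing outcome values for target {target!r}")
    n = len(y)
    if n < 10:
        raise CohortError(f"need at least 10 subjects, got {n}")
    x, colnames = _design(cohort, moderator, names)
    _check_full_rank(x, colnames)
    fit = sm.OLS(y, x).fit()
    # 1-df partial F for a single coefficient equals its squared t; the
    # two-sided coefficient p equals the upper-tail F(1, n-6) p.
    t_int, t_dx = fit.tvalues[3], fit.tvalues[1]
    df_resid = n - x.shape[1]
    return InteractionResult(
        target=target,
        F_interaction=float(t_int**2),
        p_interaction=float(scipy.stats.f.sf(t_int**2, 1, df_resid)),
        F_diagnosis=float(t_dx**2),
        p_diagnosis=float(scipy.stats.f.sf(t_dx**2, 1, df_resid)),
        coefficients=dict(zip(("intercept",) + colnames[1:], map(float, fit.params))),
        n=n,
    )


def fit_interaction_glm(y, cohort: pd.DataFrame, target: str = "y") -> InteractionResult:
    """OLS fit of y ~ diagnosis + age + diagnosis:age + sex + education."""
    age = cohort["age"].to_numpy(float)
    return _interaction_fit(y, cohort, age, ("age", "diagnosis_x_age"), target)


# ---------------------------------------------------------------------------
# multiple testing


@dataclass(frozen=True)
class FdrFamily:
    """One Benjamini-Hochberg family of tests."""

    family: str
    targets: tuple[str, ...]
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    significant: np.ndarray  # boolean, at level q
    q: float

    @property
    def significant_targets(self) -> tuple[str, ...]:
        return tuple(t for t, s in zip(self.targets, self.significant) if s)


def fdr_correct(
    pvals, q: float = 0.05, family: str = "family", targets=None
) -> FdrFamily:
    """Benjamini-Hochberg step-up correction over one family of p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise CohortError("empty p-value family")
    if ((p <= 0) | (p > 1) | np.isnan(p)).any():
        raise CohortError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    if targets is None:
        targets = tuple(f"t{i}" for i in range(p.size))
    return FdrFamily(family, tuple(targets), p, p_adj, reject, q)


# ---------------------------------------------------------------------------
# partial correlation


@dataclass(frozen=True)
class TrajectoryResult:
    target: str
    group: str
    partial_r: float
    p: float
    n: int
    covariates: tuple[str, ...]


def partial_correlation(x, y, covariates=None) -> tuple[float, float, int]:
    """Pearson correlation of OLS residuals of x and y on the covariates.

    With k covariates the two-tailed p comes from
    t = r * sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k degrees of freedom;
    with no covariates this reduces to the plain Pearson correlation.
    Returns (nan, nan, n) when a residual variance is zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        z = np.ones((n, 1))
        k = 0
    else:
        c = np.asarray(covariates, float)
        if c.ndim == 1:
            c = c[:, None]
        z = np.column_stack([np.ones(n), c])
        k = c.shape[1]
    if n <= k + 2:
        raise CohortError(f"need n > k + 2 (n={n}, k={k})")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if np.abs(rx).max() <= tol_x or np.abs(ry).max() <= tol_y:
        return float("nan"), float("nan"), n
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = min(1.0, max(-1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r**2))
    return r, float(2.0 * scipy.stats.t.sf(abs(t), df)), n


def _group_trajectory(
    cohort: pd.DataFrame, ctrl: pd.DataFrame, target: str, group: str
) -> TrajectoryResult:
    mask = (cohort["diagnosis"] == group).to_numpy()
    sub = cohort.loc[mask]
    covars = np.column_stack(
        [(sub["sex"] == "M").to_numpy(float), sub["education"].to_numpy(float)]
    )
    r, p, n = partial_correlation(
        sub["age"].to_numpy(float), ctrl.loc[mask, target].to_numpy(float), covars
    )
    return TrajectoryResult(target, group, r, p, n, ("sex", "education"))


# ---------------------------------------------------------------------------
# primary analysis


@dataclass
class PrimaryAnalysisResult:
    systems: list[InteractionResult]
    nodes: list[InteractionResult]
    fdr_systems: FdrFamily
    fdr_nodes: FdrFamily
    trajectories: list[TrajectoryResult]

    def interactions_frame(self) -> pd.DataFrame:
        rows = []
        for fam, results in (("systems", self.systems), ("nodes", self.nodes)):
            fdr = self.fdr_systems if fam == "systems" else self.fdr_nodes
            for res, p_adj, sig in zip(results, fdr.adjusted_p, fdr.significant):
                rows.append(
                    {
                        "family": fam,
                        "target": res.target,
                        "F_interaction": res.F_interaction,
                        "p_interaction": res.p_interaction,
                        "p_interaction_fdr": p_adj,
                        "sig_raw": res.p_interaction < 0.05,
                        "sig_fdr": bool(sig),
                        "F_diagnosis": res.F_diagnosis,
                        "p_diagnosis": res.p_diagnosis,
                        "n": res.n,
                        **{f"beta_{k}": v for k, v in res.coefficients.items()},
                    }
                )
        return pd.DataFrame(rows)

    def trajectories_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": t.target,
                "group": t.group,
                "partial_r": t.partial_r,
                "p": t.p,
                "n": t.n,
            }
            for t in self.trajectories
        )

    @property
    def followup_targets(self) -> list[str]:
        """Targets whose interaction is raw- or FDR-significant."""
        seen: list[str] = []
        for fam, results in (
            (self.fdr_systems, self.systems),
            (self.fdr_nodes, self.nodes),
        ):
            for res, sig in zip(results, fam.significant):
                if sig or res.p_interaction < 0.05:
                    seen.append(res.target)
        return seen


def _target_columns(ctrl: pd.DataFrame) -> tuple[list[str], list[str]]:
    systems = [c for c in ctrl.columns if c.startswith("ac_system_")]
    nodes = [c for c in ctrl.columns if c.startswith("ac_node_")]
    return systems, nodes


def _aligned(cohort: pd.DataFrame, ctrl: pd.DataFrame) -> pd.DataFrame:
    missing = set(cohort["subject_id"]) - set(ctrl["subject_id"])
    if missing:
        raise CohortError(
            f"subjects without controllability values: {sorted(missing)[:5]}"
        )
    ctrl = ctrl.set_index("subject_id").loc[cohort["subject_id"]].reset_index()
    return ctrl


def run_primary_analysis(
    cohort: pd.DataFrame, ctrl: pd.DataFrame, q: float = 0.05
) -> PrimaryAnalysisResult:
    """The full interaction battery: one GLM per system and per node, two
    FDR families, and within-group age trajectories for every target whose
    interaction is raw- or FDR-significant."""
    cohort = validate_cohort(cohort)
    ctrl = _aligned(cohort, ctrl)
    sys_cols, node_cols = _target_columns(ctrl)
    sys_cols = [c for c in sys_cols if ctrl[c].notna().all()]

    systems = [
        fit_interaction_glm(ctrl[c].to_numpy(float), cohort, target=c)
        for c in sys_cols
    ]
    nodes = [
        fit_interaction_glm(ctrl[c].to_numpy(float), cohort, target=c)
        for c in node_cols
    ]
    fdr_systems = fdr_correct(
        [r.p_interaction for r in systems], q, "systems", sys_cols
    )
    fdr_nodes = fdr_correct([r.p_interaction for r in nodes], q, "nodes", node_cols)

    result = PrimaryAnalysisResult(systems, nodes, fdr_systems, fdr_nodes, [])
    for target in result.followup_targets:
        for group in DIAGNOSES:
            result.trajectories.append(_group_trajectory(cohort, ctrl, target, group))
    return result


# ---------------------------------------------------------------------------
# age-35 subgroup battery


def subgroup_analysis(
    cohort: pd.DataFrame,
    ctrl: pd.DataFrame,
    targets,
    cutoff: float = 35.0,
) -> pd.DataFrame:
    """Stage-specific battery around an age cutoff (younger: age <= cutoff).

    For each supplied target: (i) a diagnosis x subgroup GLM on the whole
    cohort, and (ii) a diagnosis x age GLM within each subgroup, all with sex
    and education as covariates.  P-values are reported uncorrected — this
    battery is heuristic follow-up restricted to targets already significant
    in the primary analysis.
    """
    cohort = validate_cohort(cohort)
    ctrl = _aligned(cohort, ctrl)
    older = (cohort["age"] > cutoff).to_numpy(float)
    cells = pd.crosstab(cohort["diagnosis"], older)
    if cells.shape != (2, 2) or (cells.to_numpy() == 0).any():
        raise CohortError("empty cell in the diagnosis x age-subgroup design")
    rows = []
    for target in targets:
        y = ctrl[target].to_numpy(float)
        res = _interaction_fit(
            y, cohort, older, ("older", "diagnosis_x_older"), target
        )
        rows.append(
            {
                "target": target,
                "model": "diagnosis_x_subgroup",
                "subgroup": "all",
                "F_interaction": res.F_interaction,
                "p_interaction": res.p_interaction,
                "n": res.n,
            }
        )
        for name, mask in (("younger", older == 0), ("older", older == 1)):
            sub_res = fit_interaction_glm(
                y[mask], cohort.loc[mask].reset_index(drop=True), target=target
            )
            rows.append(
                {
                    "target": target,
                    "model": "diagnosis_x_age",
                    "subgroup": name,
                    "F_interaction": sub_res.F_interaction,
                    "p_interaction": sub_res.p_interaction,
                    "n": sub_res.n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinical correlations


def clinical_correlations(
    cohort: pd.DataFrame,
    ctrl: pd.DataFrame,
    targets,
    q: float = 0.05,
    log_dup: bool = False,
) -> tuple[pd.DataFrame, FdrFamily]:
    """Partial correlations of controllability with illness measures in SCZ.

    Controls age, sex and education; one FDR family over all target x measure
    pairs.  ``log_dup`` applies log(1 + DUP) before correlating.
    """
    cohort = validate_cohort(cohort)
    scz = cohort[cohort["diagnosis"] == "SCZ"].reset_index(drop=True)
    if scz.empty:
        raise CohortError("no SCZ subjects for clinical correlations")
    ctrl = _aligned(scz, ctrl)
    covars = np.column_stack(
        [
            scz["age"].to_numpy(float),
            (scz["sex"] == "M").to_numpy(float),
            scz["education"].to_numpy(float),
        ]
    )
    rows = []
    for target in targets:
        y = ctrl[target].to_numpy(float)
        for measure in CLINICAL_MEASURES:
            if measure not in scz.columns:
                continue
            x = scz[measure].to_numpy(float)
            if np.isnan(x).any():
                raise CohortError(f"missing clinical values in {measure!r}")
            if measure == "dup" and log_dup:
                x = np.log1p(x)
            r, p, n = partial_correlation(x, y, covars)
            rows.append(
                {"target": target, "measure": measure, "partial_r": r, "p": p, "n": n}
            )
    frame = pd.DataFrame(rows)
    fam = fdr_correct(
        frame["p"].to_numpy(),
        q,
        "clinical",
        tuple(frame["target"] + ":" + frame["measure"]),
    )
    frame["p_fdr"] = fam.adjusted_p
    frame["sig_fdr"] = fam.significant
    return frame, fam


# ---------------------------------------------------------------------------
# demographics


def two_sample_t(n1, mean1, sd1, n2, mean2, sd2) -> tuple[float, float, int]:
    """Pooled-variance two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise CohortError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise CohortError("standard deviations must be positive")
    res = scipy.stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(res.statistic), float(res.pvalue), n1 + n2 - 2


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise CohortError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise CohortError("zero margin in 2x2 table")
    chi2, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group summary table: means +/- SD, sex counts, t / chi2 and p.

    Clinical rows are SCZ-only with NA comparisons; all comparison cells are
    NA if either diagnostic group is absent.
    """
    cohort = validate_cohort(cohort)
    scz = cohort[cohort["diagnosis"] == "SCZ"]
    hc = cohort[cohort["diagnosis"] == "HC"]
    both = len(scz) >= 2 and len(hc) >= 2

    def _ms(frame, col):
        if col not in frame.columns or frame.empty or frame[col].isna().all():
            return None
        return float(frame[col].mean()), float(frame[col].std(ddof=1))

    rows = []
    for name, col in (("Age (years)", "age"), ("Education (years)", "education")):
        s, h = _ms(scz, col), _ms(hc, col)
        stat = p = float("nan")
        if both and s and h:
            stat, p, _ = two_sample_t(len(scz), *s, len(hc), *h)
        rows.append(
            {
                "row": name,
                "scz": f"{s[0]:.2f} ± {s[1]:.2f}" if s else "NA",
                "hc": f"{h[0]:.2f} ± {h[1]:.2f}" if h else "NA",
                "statistic": stat,
                "p": p,
            }
        )
    sm_, sf = (scz["sex"] == "M").sum(), (scz["sex"] == "F").sum()
    hm, hf = (hc["sex"] == "M").sum(), (hc["sex"] == "F").sum()
    stat = p = float("nan")
    if both:
        stat, p = chi2_2x2(sm_, sf, hm, hf)
    rows.append(
        {
            "row": "Sex (M/F)",
            "scz": f"{sm_}/{sf}" if len(scz) else "NA",
            "hc": f"{hm}/{hf}" if len(hc) else "NA",
            "statistic": stat,
            "p": p,
        }
    )
    clinical_rows = (
        ("DUP (months)", "dup"),
        ("GAF", "gaf"),
        ("PANSS total", "panss_total"),
        ("PANSS positive", "panss_pos"),
        ("PANSS negative", "panss_neg"),
        ("PANSS general", "panss_general"),
    )
    for name, col in clinical_rows:
        s = _ms(scz, col)
        rows.append(
            {
                "row": name,
                "scz": f"{s[0]:.2f} ± {s[1]:.2f}" if s else "NA",
                "hc": "NA",
                "statistic": float("nan"),
                "p": float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results interface


class ControllabilityAgeModel:
    """Diagnosis-by-age analysis of a controllability table.

    Parameters
    ----------
    ctrl_table : DataFrame with subject_id, ac_node_* and ac_system_* columns
        (one row per subject), as produced by
        :func:`neuroctrl.controllability.controllability_table`.
    cohort : DataFrame with demographics and clinical scores.
    q : FDR level for the two primary families and the clinical family.
    subgroup_cutoff : age separating the younger and older subgroups.
    rank_transform : replace each outcome column by its across-subject rank
        before fitting (off by default; the raw values are analyzed).
    log_dup : correlate log(1 + DUP) instead of raw DUP months.
    """

    def __init__(
        self,
        ctrl_table: pd.DataFrame,
        cohort: pd.DataFrame,
        q: float = 0.05,
        subgroup_cutoff: float = 35.0,
        rank_transform: bool = False,
        log_dup: bool = False,
    ) -> None:
        self.cohort = validate_cohort(cohort)
        ctrl = _aligned(self.cohort, ctrl_table)
        if rank_transform:
            ctrl = ctrl.copy()
            for c in ctrl.columns:
                if c.startswith("ac_"):
                    ctrl[c] = scipy.stats.rankdata(ctrl[c].to_numpy(float))
        self.ctrl = ctrl
        self.q = q
        self.subgroup_cutoff = subgroup_cutoff
        self.log_dup = log_dup

    @classmethod
    def from_files(cls, cohort_csv, ctrl_csv, **kwargs) -> "ControllabilityAgeModel":
        return cls(pd.read_csv(ctrl_csv), pd.read_csv(cohort_csv), **kwargs)

    def fit(self) -> "ControllabilityAgeResults":
        primary = run_primary_analysis(self.cohort, self.ctrl, self.q)
        targets = primary.followup_targets
        subgroups = (
            subgroup_analysis(self.cohort, self.ctrl, targets, self.subgroup_cutoff)
            if targets
            else pd.DataFrame(
                columns=["target", "model", "subgroup", "F_interaction", "p_interaction", "n"]
            )
        )
        has_clinical = any(c in self.cohort.columns for c in CLINICAL_MEASURES)
        if targets and has_clinical and (self.cohort["diagnosis"] == "SCZ").any():
            clinical, clinical_fdr = clinical_correlations(
                self.cohort, self.ctrl, targets, self.q, self.log_dup
            )
        else:
            clinical, clinical_fdr = (
                pd.DataFrame(columns=["target", "measure", "partial_r", "p", "n"]),
                None,
            )
        return ControllabilityAgeResults(self, primary, subgroups, clinical, clinical_fdr)


@dataclass
class ControllabilityAgeResults:
    """Fitted results: interaction tables, FDR families, follow-up batteries."""

    model: ControllabilityAgeModel
    primary: PrimaryAnalysisResult
    subgroups: pd.DataFrame
    clinical: pd.DataFrame
    clinical_fdr: FdrFamily | None = field(default=None)

    @property
    def interactions(self) -> pd.DataFrame:
        return self.primary.interactions_frame()

    @property
    def trajectories(self) -> pd.DataFrame:
        return self.primary.trajectories_frame()

    def summary(self) -> str:
        lines = []
        inter = self.interactions
        n = int(inter["n"].iloc[0]) if len(inter) else 0
        lines.append("Diagnosis-by-age controllability analysis")
        lines.append("=" * 41)
        lines.append(
            f"subjects: {n}   systems tested: {(inter['family'] == 'systems').sum()}"
            f"   nodes tested: {(inter['family'] == 'nodes').sum()}"
        )
        for fam in ("systems", "nodes"):
            sub = inter[inter["family"] == fam]
            sig = sub[sub["sig_fdr"] | sub["sig_raw"]]
            lines.append(f"\n{fam} with diagnosis x age interaction (raw p < .05):")
            if sig.empty:
                lines.append("  none")
            for _, r in sig.iterrows():
                tag = "FDR" if r["sig_fdr"] else "unc"
                lines.append(
                    f"  {r['target']:<32s} F = {r['F_interaction']:6.2f}  "
                    f"p = {r['p_interaction']:.4f} ({tag})"
                )
        traj = self.trajectories
        if len(traj):
            lines.append("\nwithin-group age trajectories (partial r | sex, education):")
            for _, r in traj.iterrows():
                lines.append(
                    f"  {r['target']:<32s} {r['group']:<4s} r = {r['partial_r']:+.2f}  "
                    f"p = {r['p']:.4f}  n = {int(r['n'])}"
                )
        if len(self.clinical):
            n_sig = int(self.clinical["sig_fdr"].sum())
            lines.append(
                f"\nclinical correlations (SCZ): {len(self.clinical)} pairs, "
                f"{n_sig} FDR-significant"
            )
        return "\n".join(lines)

    def plot_trajectory(self, target: str, ax=None):
        """Scatter of controllability vs age with per-group OLS lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        cohort, ctrl = self.model.cohort, self.model.ctrl
        for group, color in (("HC", "tab:blue"), ("SCZ", "tab:red")):
            mask = (cohort["diagnosis"] == group).to_numpy()
            age = cohort.loc[mask, "age"].to_numpy(float)
            y = ctrl.loc[mask, target].to_numpy(float)
            ax.scatter(age, y, s=12, alpha=0.5, color=color, label=group)
            if len(age) > 2:
                coef = np.polyfit(age, y, 1)
                grid = np.linspace(age.min(), age.max(), 50)
                ax.plot(grid, np.polyval(coef, grid), color=color)
        ax.set_xlabel("age (years)")
        ax.set_ylabel(target)
        ax.legend()
        return ax
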