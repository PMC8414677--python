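"""Group / side / NVC-stratified statistical comparisons of shape features.

The battery mirrors a standard bilateral-morphometry analysis plan:

* exact two-sided binomial test for laterality of the affected side;
* paired t-tests for within-subject side contrasts (affected vs unaffected,
  left vs right), both sides of each subject coming from the same head;
* ordinary least squares on a group indicator for between-group contrasts
  (numerically the pooled-variance two-sample t-test; a Welch option is
  available);
* Pearson chi-square (no continuity correction by default) for sex and a
  two-sample t-test for age in the demographics table;
* Kendall tau-b screen of flatness against the nine size features.

All tests are two-sided.  No multiple-testing correction is applied by
default — the ten features are tested marginally — but Holm adjustment can
be switched on.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .features import FEATURE_NAMES, TABLE_LABELS, ShapeFeatures
from .io import CohortManifest

__all__ = [
    "SubjectRecord",
    "ComparisonResult",
    "records_from_tables",
    "binomial_laterality_test",
    "paired_side_comparison",
    "group_comparison",
    "kendall_correlation_screen",
    "demographics_table",
    "nvc_crosstab",
    "no_nvc_subgroup_comparison",
    "run_full_analysis",
    "holm_adjust",
]


@dataclass
class SubjectRecord:
    """One subject: group, affected side, per-side NVC flags and features."""

    subject_id: str
    group: str
    affected_side: str
    nvc_left: str
    nvc_right: str
    features_left: ShapeFeatures
    features_right: ShapeFeatures
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.group == "HC" and self.affected_side != "none":
            raise ValueError(f"{self.subject_id}: HC subject with an affected side")
        if self.group == "PTN" and self.affected_side not in ("left", "right"):
            raise ValueError(f"{self.subject_id}: PTN subject without an affected side")

    def side(self, which: str) -> ShapeFeatures:
        if which == "affected":
            which = self.affected_side
        elif which == "unaffected":
            which = "left" if self.affected_side == "right" else "right"
        return {"left": self.features_left, "right": self.features_right}[which]

    def nvc(self, which: str) -> str:
        if which == "affected":
            which = self.affected_side
        elif which == "unaffected":
            which = "left" if self.affected_side == "right" else "right"
        return {"left": self.nvc_left, "right": self.nvc_right}[which]


@dataclass
class ComparisonResult:
    """One statistical contrast in a tabulated form."""

    contrast: str
    test: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p_value: float
    paired: bool
    note: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def as_row(self) -> dict:
        return {
            "contrast": self.contrast,
            "test": self.test,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "paired": self.paired,
            "note": self.note,
        }


def records_from_tables(
    manifest: pd.DataFrame | CohortManifest, features: pd.DataFrame
) -> list[SubjectRecord]:
    """Join a manifest with a per-mask feature table into SubjectRecords.

    ``features`` needs columns ``subject_id``, ``side`` and the ten feature
    columns (snake_case names).
    """
    if isinstance(manifest, CohortManifest):
        manifest = manifest.table
    feat = features.set_index(["subject_id", "side"])
    records = []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        per_side = {}
        for side in ("left", "right"):
            try:
                f = feat.loc[(sid, side)]
            except KeyError:
                raise KeyError(f"features missing for subject {sid} side {side}") from None
            per_side[side] = ShapeFeatures(**{k: float(f[k]) for k in FEATURE_NAMES})
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=row["group"],
                affected_side=row["affected_side"],
                nvc_left=row["nvc_left"],
                nvc_right=row["nvc_right"],
                features_left=per_side["left"],
                features_right=per_side["right"],
                age=float(row["age"]) if "age" in row and pd.notna(row["age"]) else None,
                sex=row["sex"] if "sex" in row and pd.notna(row["sex"]) else None,
            )
        )
    return records


def binomial_laterality_test(n_left: int, n_right: int) -> ComparisonResult:
    """Exact two-sided binomial test of affected-side counts against 0.5."""
    n = n_left + n_right
    if n < 1:
        raise ValueError("need at least one affected side")
    res = sps.binomtest(n_right, n, p=0.5, alternative="two-sided")
    return ComparisonResult(
        contrast="affected side left vs right",
        test="exact binomial vs 0.5",
        n_a=n_left,
        n_b=n_right,
        mean_a=100.0 * n_left / n,
        sd_a=float("nan"),
        mean_b=100.0 * n_right / n,
        sd_b=float("nan"),
        statistic=float(n_right),
        p_value=float(res.pvalue),
        paired=False,
        extra={"proportion_left_pct": 100.0 * n_left / n, "proportion_right_pct": 100.0 * n_right / n},
    )


def _feature_values(records, which_side: str, feature: str) -> np.ndarray:
    return np.array([getattr(r.side(which_side), feature) for r in records], dtype=float)


def paired_side_comparison(
    records: list[SubjectRecord], feature: str, pairing: str = "affected"
) -> ComparisonResult:
    """Two-sided paired t-test on within-subject side differences.

    ``pairing="affected"`` contrasts affected vs unaffected side (the
    records must then all be PTN); ``pairing="left_right"`` contrasts left
    vs right side of whatever records are passed.
    """
    if pairing == "affected":
        recs = [r for r in records if r.group == "PTN"]
        side_a, side_b = "affected", "unaffected"
    elif pairing == "left_right":
        recs = list(records)
        side_a, side_b = "left", "right"
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    name = f"{feature}: {side_a} vs {side_b}"
    if len(recs) < 3:
        return _flagged(name, "paired t-test", len(recs), len(recs), "stratum too small")
    a = _feature_values(recs, side_a, feature)
    b = _feature_values(recs, side_b, feature)
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        res = _flagged(name, "paired t-test", len(a), len(b), "zero-variance differences")
        res.mean_a, res.sd_a = float(a.mean()), float(a.std(ddof=1))
        res.mean_b, res.sd_b = float(b.mean()), float(b.std(ddof=1))
        return res
    t, p = sps.ttest_rel(a, b)
    return ComparisonResult(
        contrast=name,
        test="paired t-test",
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        statistic=float(t),
        p_value=float(p),
        paired=True,
        extra={"mean_difference": float(diff.mean())},
    )


def _flagged(name, test, n_a, n_b, note) -> ComparisonResult:
    return ComparisonResult(
        contrast=name,
        test=test,
        n_a=n_a,
        n_b=n_b,
        mean_a=float("nan"),
        sd_a=float("nan"),
        mean_b=float("nan"),
        sd_b=float("nan"),
        statistic=float("nan"),
        p_value=float("nan"),
        paired=False,
        note=note,
    )


def select_masks(records, group=None, side="both") -> np.ndarray:
    """Selector helper: per-mask feature extraction for group comparisons.

    ``side`` is one of ``left``, ``right``, ``affected``, ``unaffected`` or
    ``both`` (both sides contribute one mask each).
    """

    def _select(feature):
        recs = [r for r in records if group is None or r.group == group]
        if side == "both":
            vals = [getattr(r.features_left, feature) for r in recs]
            vals += [getattr(r.features_right, feature) for r in recs]
        else:
            vals = [getattr(r.side(side), feature) for r in recs]
        return np.asarray(vals, dtype=float)

    return _select


def group_comparison(
    records: list[SubjectRecord],
    feature: str,
    arm_a,
    arm_b,
    welch: bool = False,
    label: str = "",
) -> ComparisonResult:
    """Between-arm comparison of one feature via OLS on an arm indicator.

    The indicator's coefficient t-test is reported; with equal variances it
    is numerically the pooled two-sample t-test.  ``arm_a`` / ``arm_b`` are
    selectors built by :func:`select_masks` (or any callable mapping a
    feature name to a value array).  ``welch=True`` switches to the Welch
    unequal-variance t-test instead.
    """
    a = np.asarray(arm_a(feature), dtype=float)
    b = np.asarray(arm_b(feature), dtype=float)
    name = label or f"{feature}: arm A vs arm B"
    if len(a) < 3 or len(b) < 3:
        return _flagged(name, "OLS group indicator", len(a), len(b), "arm too small")
    if welch:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        test = "Welch t-test"
        stat = float(t)
    else:
        y = np.concatenate([a, b])
        x = sm.add_constant(np.concatenate([np.zeros(len(a)), np.ones(len(b))]))
        fit = sm.OLS(y, x).fit()
        stat, p = float(fit.tvalues[1]), float(fit.pvalues[1])
        test = "OLS group indicator"
    return ComparisonResult(
        contrast=name,
        test=test,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        statistic=stat,
        p_value=float(p),
        paired=False,
        extra={"mean_difference": float(b.mean() - a.mean())},
    )


def kendall_correlation_screen(
    records: list[SubjectRecord], group: str
) -> list[ComparisonResult]:
    """Kendall tau-b of flatness against each other feature over all masks
    of one group, ranked by |tau|.  Tau-b is tie-corrected, which matters
    because rounded feature values can tie."""
    sel = select_masks(records, group=group, side="both")
    flat = sel("flatness")
    if len(flat) < 5:
        raise ValueError(f"need >= 5 masks in group {group}, got {len(flat)}")
    out = []
    for feature in FEATURE_NAMES:
        if feature == "flatness":
            continue
        other = sel(feature)
        name = f"{group}: flatness vs {feature}"
        if np.allclose(other, other[0]) or np.allclose(flat, flat[0]):
            out.append(_flagged(name, "Kendall tau-b", len(flat), len(flat), "constant feature"))
            continue
        tau, p = sps.kendalltau(flat, other, variant="b")
        out.append(
            ComparisonResult(
                contrast=name,
                test="Kendall tau-b",
                n_a=len(flat),
                n_b=len(flat),
                mean_a=float(np.mean(flat)),
                sd_a=float(np.std(flat, ddof=1)),
                mean_b=float(np.mean(other)),
                sd_b=float(np.std(other, ddof=1)),
                statistic=float(tau),
                p_value=float(p),
                paired=False,
                extra={"tau": float(tau)},
            )
        )
    out.sort(key=lambda r: (np.isnan(r.statistic), -abs(r.statistic)))
    return out


def demographics_table(
    manifest: pd.DataFrame | CohortManifest,
    ages=None,
    sexes=None,
    yates: bool = False,
) -> pd.DataFrame:
    """Demographics summary: counts, percentages, chi-square on sex,
    t-test on age, binomial test on affected-side laterality.

    Ages and sexes default to the manifest's ``age`` / ``sex`` columns.
    """
    df = manifest.table if isinstance(manifest, CohortManifest) else manifest
    if ages is None and "age" in df.columns:
        ages = pd.to_numeric(df["age"])
    if sexes is None and "sex" in df.columns:
        sexes = df["sex"]
    is_ptn = (df["group"] == "PTN").to_numpy()
    n_ptn, n_hc = int(is_ptn.sum()), int((~is_ptn).sum())
    n = n_ptn + n_hc
    rows = [
        {
            "variable": "Case number (n, %)",
            "PTN": f"{n_ptn} ({100 * n_ptn / n:.1f})",
            "HC": f"{n_hc} ({100 * n_hc / n:.1f})",
            "total": n,
            "p_value": np.nan,
        },
        {
            "variable": "MC number (n, %)",
            "PTN": f"{2 * n_ptn} ({100 * n_ptn / n:.1f})",
            "HC": f"{2 * n_hc} ({100 * n_hc / n:.1f})",
            "total": 2 * n,
            "p_value": np.nan,
        },
    ]

    if sexes is not None and n_ptn > 0 and n_hc > 0:
        sexes = np.asarray(sexes)
        tab = np.array(
            [
                [(sexes[is_ptn] == "male").sum(), (sexes[~is_ptn] == "male").sum()],
                [(sexes[is_ptn] == "female").sum(), (sexes[~is_ptn] == "female").sum()],
            ],
            dtype=float,
        )
        if tab.min() == 0 or tab.sum(axis=0).min() == 0:
            chi_p = np.nan
        else:
            chi2, chi_p, _, _ = sps.chi2_contingency(tab, correction=yates)
        for k, label in enumerate(["Male (n, %)", "Female (n, %)"]):
            rows.append(
                {
                    "variable": label,
                    "PTN": f"{int(tab[k, 0])} ({100 * tab[k, 0] / n_ptn:.2f})",
                    "HC": f"{int(tab[k, 1])} ({100 * tab[k, 1] / n_hc:.2f})",
                    "total": int(tab[k].sum()),
                    "p_value": chi_p if k == 0 else np.nan,
                }
            )
    else:
        rows.append({"variable": "Sex", "PTN": "missing", "HC": "missing", "total": np.nan, "p_value": np.nan})

    if ages is not None and n_ptn >= 2 and n_hc >= 2:
        ages = np.asarray(ages, dtype=float)
        t, age_p = sps.ttest_ind(ages[is_ptn], ages[~is_ptn])
        rows.append(
            {
                "variable": "Age (year)",
                "PTN": f"{ages[is_ptn].mean():.2f} +/- {ages[is_ptn].std(ddof=1):.2f}",
                "HC": f"{ages[~is_ptn].mean():.2f} +/- {ages[~is_ptn].std(ddof=1):.2f}",
                "total": np.nan,
                "p_value": float(age_p),
            }
        )
    else:
        rows.append({"variable": "Age (year)", "PTN": "missing", "HC": "missing", "total": np.nan, "p_value": np.nan})

    n_left = int((df.loc[is_ptn, "affected_side"] == "left").sum())
    n_right = int((df.loc[is_ptn, "affected_side"] == "right").sum())
    if n_left + n_right:
        lat = binomial_laterality_test(n_left, n_right)
        rows.append(
            {
                "variable": "Affected side left (n, %)",
                "PTN": f"{n_left} ({lat.mean_a:.2f})",
                "HC": "",
                "total": n_left,
                "p_value": lat.p_value,
            }
        )
        rows.append(
            {
                "variable": "Affected side right (n, %)",
                "PTN": f"{n_right} ({lat.mean_b:.2f})",
                "HC": "",
                "total": n_right,
                "p_value": np.nan,
            }
        )
    return pd.DataFrame(rows)


def nvc_crosstab(records: list[SubjectRecord]) -> pd.DataFrame:
    """Per affected-side counts and percentages of the four
    (affected-side NVC, unaffected-side NVC) patterns among PTN subjects.
    Percentages are relative to that affected side's subject count."""
    patterns = [("yes", "no"), ("no", "yes"), ("yes", "yes"), ("no", "no")]
    rows = []
    for side in ("left", "right"):
        recs = [r for r in records if r.group == "PTN" and r.affected_side == side]
        n = len(recs)
        for aff, unaff in patterns:
            count = sum(1 for r in recs if r.nvc("affected") == aff and r.nvc("unaffected") == unaff)
            rows.append(
                {
                    "affected_side_group": f"{side} PTN (n={n})",
                    "nvc_affected": aff,
                    "nvc_unaffected": unaff,
                    "count": count,
                    "percent": 100.0 * count / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def no_nvc_subgroup_comparison(records: list[SubjectRecord]) -> pd.DataFrame:
    """Affected vs unaffected paired comparison of all ten features within
    the PTN subjects free of NVC on both sides, separately for left- and
    right-affected subjects."""
    rows = []
    for side in ("left", "right"):
        recs = [
            r
            for r in records
            if r.group == "PTN"
            and r.affected_side == side
            and r.nvc_left == "no"
            and r.nvc_right == "no"
        ]
        for feature in FEATURE_NAMES:
            res = paired_side_comparison(recs, feature, pairing="affected")
            row = res.as_row()
            row["subgroup"] = f"{side} PTN without bilateral NVC (n={len(recs)})"
            row["feature"] = TABLE_LABELS[feature]
            rows.append(row)
    cols = ["subgroup", "feature"] + [c for c in rows[0] if c not in ("subgroup", "feature")]
    return pd.DataFrame(rows)[cols]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    mask = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if mask.any():
        adj[mask] = sm.stats.multipletests(p[mask], method="holm")[1]
    return adj


def run_full_analysis(
    manifest: pd.DataFrame | CohortManifest,
    features: pd.DataFrame,
    out_dir,
    config: dict | None = None,
) -> dict:
    """Run the complete battery and emit table1..table4 CSVs plus a run log.

    Returns a dict with the four tables, the per-contrast results, and the
    Kendall screens.  ``config`` keys: ``holm`` (bool), ``welch`` (bool),
    ``yates`` (bool), ``seed`` (recorded in the log).
    """
    config = dict(config or {})
    holm = bool(config.get("holm", False))
    welch = bool(config.get("welch", False))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    stage = "record assembly"
    try:
        records = records_from_tables(manifest, features)
        ptn = [r for r in records if r.group == "PTN"]
        hc = [r for r in records if r.group == "HC"]

        stage = "table 1 (demographics)"
        table1 = demographics_table(manifest, yates=bool(config.get("yates", False)))
        table1.to_csv(out_dir / "table1.csv", index=False)

        stage = "table 2 (feature comparisons)"
        rows = []
        for feature in FEATURE_NAMES:
            contrasts = {
                "HC both sides vs PTN affected": group_comparison(
                    records,
                    feature,
                    select_masks(records, group="HC", side="both"),
                    select_masks(records, group="PTN", side="affected"),
                    welch=welch,
                    label=f"{feature}: HC both vs PTN affected",
                ),
                "PTN affected vs unaffected": paired_side_comparison(ptn, feature, "affected"),
                "PTN left vs right": paired_side_comparison(ptn, feature, "left_right"),
                "HC left vs right": paired_side_comparison(hc, feature, "left_right"),
            }
            for cname, res in contrasts.items():
                row = res.as_row()
                row["feature"] = TABLE_LABELS[feature]
                row["comparison"] = cname
                rows.append(row)
        table2 = pd.DataFrame(rows)[
            ["feature", "comparison", "test", "n_a", "n_b", "mean_a", "sd_a", "mean_b", "sd_b", "statistic", "p_value", "paired", "note"]
        ]
        if holm:
            for cname in table2["comparison"].unique():
                sel = table2["comparison"] == cname
                table2.loc[sel, "p_holm"] = holm_adjust(table2.loc[sel, "p_value"])
        table2.to_csv(out_dir / "table2.csv", index=False)

        stage = "table 3 (NVC cross-tab)"
        table3 = nvc_crosstab(records)
        table3.to_csv(out_dir / "table3.csv", index=False)

        stage = "table 4 (no-NVC subgroup)"
        table4 = no_nvc_subgroup_comparison(records)
        if holm:
            for sub in table4["subgroup"].unique():
                sel = table4["subgroup"] == sub
                table4.loc[sel, "p_holm"] = holm_adjust(table4.loc[sel, "p_value"])
        table4.to_csv(out_dir / "table4.csv", index=False)

        stage = "Kendall screen"
        screens = {}
        for grp, recs in (("PTN", records), ("HC", records)):
            try:
                screen = kendall_correlation_screen(recs, grp)
            except ValueError as exc:
                warnings.warn(f"Kendall screen skipped for {grp}: {exc}", stacklevel=2)
                screen = []
            screens[grp] = screen
        pd.DataFrame([r.as_row() for g in screens.values() for r in g]).to_csv(
            out_dir / "kendall_screen.csv", index=False
        )
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage: {stage}") from exc

    from . import __version__

    cfg_hash = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    with open(out_dir / "run.log", "w") as fh:
        fh.write(f"mcshape version: {__version__}\n")
        fh.write(f"seed: {config.get('seed', 'unset')}\n")
        fh.write(f"config hash: {cfg_hash}\n")
        fh.write(f"config: {json.dumps(config, sort_keys=True)}\n")
        fh.write(f"subjects: {len(records)} (PTN {len(ptn)}, HC {len(hc)})\n")
        fh.write(f"wall time s: {time.time() - t0:.2f}\n")

    return {
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "table4": table4,
        "kendall": screens,
        "records": records,
    }
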