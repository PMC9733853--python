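"""Statistical comparison of feature sets and classifiers.

Inter-subject evaluation yields five replicate accuracies (one per subject
fold) for every feature-set x classifier cell.  Per window length, a
classical fixed-effects two-way ANOVA with interaction tests the main and
interactive effects of feature set and classifier on overall accuracy; for
significant main effects, Tukey's honestly-significant-difference test
compares the factor levels pairwise using the ANOVA residual mean square and
the studentized range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .classification import EvaluationReport

FACTORS = ("feature", "classifier")


def accuracy_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Long-format table of replicate accuracies from inter-subject reports:
    one row per (window_s, feature domain, classifier, replicate)."""
    rows = []
    for rep in reports:
        if rep.protocol != "inter":
            raise ValueError("accuracy_table expects inter-subject reports")
        for i, acc in enumerate(rep.unit_accuracies):
            rows.append(
                {
                    "window_s": rep.window_s,
                    "feature": rep.domain,
                    "classifier": rep.model_kind,
                    "replicate": i + 1,
                    "accuracy": acc,
                }
            )
    return pd.DataFrame(rows)


def _select_window(tbl: pd.DataFrame, window_s: float | None) -> pd.DataFrame:
    if window_s is not None:
        tbl = tbl[tbl["window_s"] == window_s]
    if tbl.empty:
        raise ValueError(f"no rows for window_s={window_s}")
    return tbl.reset_index(drop=True)


def _check_balanced(tbl: pd.DataFrame) -> int:
    """Validate a balanced complete feature x classifier design; returns the
    per-cell replicate count."""
    feats = sorted(tbl["feature"].unique())
    clfs = sorted(tbl["classifier"].unique())
    counts = tbl.groupby(["feature", "classifier"]).size()
    missing = [
        (f, c) for f in feats for c in clfs if (f, c) not in counts.index
    ]
    if missing:
        raise ValueError(f"incomplete design; missing cells: {missing}")
    if counts.nunique() != 1:
        raise ValueError(
            f"unbalanced design; cell counts vary: {counts.to_dict()}"
        )
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need at least 2 replicates per cell")
    if not tbl["accuracy"].between(0, 1).all():
        raise ValueError("accuracies must lie in [0, 1]")
    return n


@dataclass
class AnovaResult:
    """Two-way ANOVA with interaction for one window length."""

    window_s: float | None
    effects: dict[str, tuple[float, float]]  # factor -> (F, p)
    ss: dict[str, float]  # feature, classifier, interaction, residual, total
    df: dict[str, float]
    ms_residual: float
    df_residual: int
    n_per_cell: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": k, "F": F, "p": p, "ss": self.ss[k], "df": self.df[k]}
            for k, (F, p) in self.effects.items()
        ]
        rows.append(
            {
                "effect": "residual",
                "F": np.nan,
                "p": np.nan,
                "ss": self.ss["residual"],
                "df": self.df["residual"],
            }
        )
        return pd.DataFrame(rows)


def two_way_anova(tbl: pd.DataFrame, window_s: float | None = None) -> AnovaResult:
    """Fixed-effects two-way ANOVA (feature, classifier, interaction) on the
    replicate accuracies of one window length.

    The design must be balanced and complete, so type I/II/III sums of
    squares coincide; F ratios are taken against the residual mean square.
    """
    tbl = _select_window(tbl, window_s)
    n_per_cell = _check_balanced(tbl)
    model = smf.ols("accuracy ~ C(feature) * C(classifier)", data=tbl).fit()
    table = sm.stats.anova_lm(model, typ=2)
    key = {
        "C(feature)": "feature",
        "C(classifier)": "classifier",
        "C(feature):C(classifier)": "interaction",
        "Residual": "residual",
    }
    ss, df, effects = {}, {}, {}
    for row_name, row in table.iterrows():
        name = key[row_name]
        ss[name] = float(row["sum_sq"])
        df[name] = float(row["df"])
        if name != "residual":
            effects[name] = (float(row["F"]), float(row["PR(>F)"]))
    ss["total"] = float(((tbl["accuracy"] - tbl["accuracy"].mean()) ** 2).sum())
    df["total"] = len(tbl) - 1
    return AnovaResult(
        window_s=window_s,
        effects=effects,
        ss=ss,
        df=df,
        ms_residual=ss["residual"] / df["residual"],
        df_residual=int(df["residual"]),
        n_per_cell=n_per_cell,
    )


def tukey_hsd(
    tbl: pd.DataFrame, factor: str, window_s: float | None = None
) -> dict[tuple[str, str], float]:
    """Tukey HSD p-values for all level pairs of ``factor``.

    Level means are compared with the studentized range statistic
    ``q = |mean_a - mean_b| / sqrt(MS_resid / n)`` where ``MS_resid`` and its
    degrees of freedom come from the two-way ANOVA with interaction and ``n``
    is the per-level replicate count.  The returned mapping contains both
    orientations of each pair.
    """
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")
    tbl = _select_window(tbl, window_s)
    anova = two_way_anova(tbl)
    levels = sorted(tbl[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    means = tbl.groupby(factor)["accuracy"].mean()
    n_per_level = len(tbl) // len(levels)
    se = np.sqrt(anova.ms_residual / n_per_level)
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            q = abs(means[a] - means[b]) / se
            p = float(
                studentized_range.sf(q, k=len(levels), df=anova.df_residual)
            )
            p = min(max(p, 0.0), 1.0)
            out[(a, b)] = p
            out[(b, a)] = p
    return out
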