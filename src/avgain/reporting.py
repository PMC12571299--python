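"""Psychometric aggregation and group-level frequentist checks.

Aggregates trial tables into per-rat proportion-of-High-choice tables under
the two groupings used in the analysis (audiovisual congruency, or the five
sound-intensity levels), applies the arcsine-square-root variance-stabilising
transform, verifies the ANOVA assumptions (Shapiro-Wilk normality per cell,
Levene homoscedasticity across conditions) and runs the two-way
repeated-measures ANOVA (visual temporal frequency x experimental condition)
with Tukey post-hoc contrasts.  These are off-the-shelf statistical routines
applied to cohort summaries; the Bayesian machinery lives elsewhere.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acoustics import AM_FREQUENCIES
from .observer import StimulusSet

__all__ = [
    "psychometric_table",
    "arcsine_transform",
    "congruency_of",
    "group_anova",
    "UnbalancedDesignError",
]


class UnbalancedDesignError(ValueError):
    """Raised when the rat x condition x TF design has missing cells."""


def congruency_of(visual_tf: float, sound_tf: float) -> str:
    """Label an audiovisual AM pairing as congruent/incongruent/anti-congruent.

    Congruent cells are the diagonal of the 9x9 pairing matrix (equal TFs);
    anti-congruent cells are the anti-diagonal (the i-th visual TF paired
    with the (9-i)-th auditory TF); everything else is incongruent.
    """
    tfs = list(AM_FREQUENCIES)
    vi = int(np.argmin([abs(visual_tf - t) for t in tfs]))
    ai = int(np.argmin([abs(sound_tf - t) for t in tfs]))
    if vi == ai:
        return "am_congruent"
    if vi + ai == len(tfs) - 1:
        return "am_anticongruent"
    return "am_incongruent"


def _condition_group(row: pd.Series, grouping: str) -> str:
    kind = row["sound_kind"]
    if grouping == "by_intensity_level":
        return f"level{int(row['intensity_level'])}"
    if kind == "fixed":
        return "v_fixed"
    if kind == "silence":
        return "v_only"
    return congruency_of(row["visual_tf_hz"], row["sound_tf_hz"])


def psychometric_table(trials: pd.DataFrame, grouping: str = "by_congruency") -> pd.DataFrame:
    """Per-rat, per-group, per-TF proportion of High-TF choices.

    ``grouping="by_congruency"`` splits AM trials into congruent,
    incongruent and anti-congruent pools alongside the fixed-sound and
    visual-only conditions; ``"by_intensity_level"`` groups by the five
    sound-intensity levels.  Auditory-only trials are excluded.
    """
    if grouping not in ("by_congruency", "by_intensity_level"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if trials.empty:
        raise ValueError("trial table is empty")
    v = trials[trials["visual_tf_hz"].notna()].copy()
    v["condition_group"] = v.apply(_condition_group, axis=1, grouping=grouping)
    out = (
        v.groupby(["rat_id", "condition_group", "visual_tf_hz"])
        .agg(
            n_trials=("choice", "size"),
            prop_high=("choice", lambda c: float((c == "H").mean())),
        )
        .reset_index()
    )
    return out


def arcsine_transform(p):
    """Variance-stabilising arcsine-square-root transform of a proportion."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def _check_balanced(table: pd.DataFrame, conditions: Sequence[str]) -> None:
    rats = sorted(table["rat_id"].unique())
    tfs = sorted(table["visual_tf_hz"].unique())
    have = set(
        zip(table["rat_id"], table["condition_group"], table["visual_tf_hz"])
    )
    missing = [
        (r, c, tf)
        for r in rats
        for c in conditions
        for tf in tfs
        if (r, c, tf) not in have
    ]
    if missing:
        raise UnbalancedDesignError(
            f"{len(missing)} missing design cells, e.g. {missing[:5]}"
        )


def group_anova(table: pd.DataFrame, conditions: Sequence[str]) -> dict:
    """Two-way repeated-measures ANOVA with assumption checks and post-hocs.

    Input is a psychometric table restricted to the named condition groups.
    Proportions are arcsine-transformed; normality is checked per
    (condition, TF) cell across rats (Shapiro-Wilk) and homoscedasticity
    across conditions (Levene); the ANOVA has within factors visual TF and
    condition; Tukey pairwise contrasts between conditions are reported on
    both the raw and the transformed scale.
    """
    import pingouin as pg
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = table[table["condition_group"].isin(conditions)].copy()
    if sub.empty:
        raise ValueError("no rows for the requested conditions")
    # The boundary pairing (TFv = TFa = s0) lies on both the diagonal and the
    # anti-diagonal; the table assigns it to the congruent pool, so the
    # anti-congruent pool borrows that cell to complete its 9-TF design.
    if "am_anticongruent" in conditions and "am_congruent" in set(
        table["condition_group"]
    ):
        s0 = StimulusSet().s0
        have_anti = set(
            sub.loc[sub["condition_group"] == "am_anticongruent", "rat_id"][
                np.isclose(
                    sub.loc[sub["condition_group"] == "am_anticongruent",
                            "visual_tf_hz"], s0)
            ]
        )
        centre = table[
            (table["condition_group"] == "am_congruent")
            & np.isclose(table["visual_tf_hz"], s0)
            & ~table["rat_id"].isin(have_anti)
        ].copy()
        centre["condition_group"] = "am_anticongruent"
        sub = pd.concat([sub, centre], ignore_index=True)
    _check_balanced(sub, conditions)
    sub["asin_prop"] = arcsine_transform(sub["prop_high"].to_numpy())

    shapiro_rows = []
    for (cond, tf), cell in sub.groupby(["condition_group", "visual_tf_hz"]):
        vals = cell["asin_prop"].to_numpy()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            w, p = stats.shapiro(vals)
        else:
            w, p = math.nan, math.nan
        shapiro_rows.append(
            {"condition": cond, "visual_tf_hz": tf, "W": w, "p": p}
        )
    shapiro = pd.DataFrame(shapiro_rows)

    groups = [g["asin_prop"].to_numpy() for _, g in sub.groupby("condition_group")]
    lev_stat, lev_p = stats.levene(*groups)

    anova = pg.rm_anova(
        data=sub,
        dv="asin_prop",
        within=["visual_tf_hz", "condition_group"],
        subject="rat_id",
    )
    # Layout: factor, df, SS, MS, F, p (uncorrected; GG-corrected appended
    # when pingouin provides it for this design).
    rename = {"Source": "factor", "DF1": "df", "ddof1": "df", "SS": "SS",
              "MS": "MS", "F": "F", "p-unc": "p", "p_unc": "p",
              "p-GG-corr": "p_gg", "p_GG_corr": "p_gg"}
    anova = anova.rename(columns={k: v for k, v in rename.items() if k in anova})

    per_rat = (
        sub.groupby(["rat_id", "condition_group"])[["prop_high", "asin_prop"]]
        .mean()
        .reset_index()
    )
    tukey_raw = pairwise_tukeyhsd(
        per_rat["prop_high"], per_rat["condition_group"]
    )
    tukey_tr = pairwise_tukeyhsd(
        per_rat["asin_prop"], per_rat["condition_group"]
    )

    def tukey_frame(t):
        return pd.DataFrame(
            t.summary().data[1:], columns=t.summary().data[0]
        )

    return {
        "shapiro": shapiro,
        "levene": {"stat": float(lev_stat), "p": float(lev_p)},
        "anova": anova,
        "tukey_raw": tukey_frame(tukey_raw),
        "tukey_transformed": tukey_frame(tukey_tr),
    }
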