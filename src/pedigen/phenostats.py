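"""Multi-environment randomized-complete-block ANOVA and trait summaries.

Model: ``y_ijk = mu + t_i + b_j(i) + g_k + (gt)_ik + e_ijk`` with
environments and blocks fixed, genotype and genotype-x-environment random.
Sums of squares are Type-I on the ordered model (environment, block within
environment, genotype, interaction), computed directly from cell means —
exact for the balanced or proportional designs in scope (every genotype in
every block, block counts may differ between environments).  Variance
components are solved from the expected mean squares; the genetic
coefficient of variation is ``GCV = 100 * sigma_g / mu``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["AnovaResult", "rcbd_anova_gcv", "subpopulation_summary"]

TRIAL_COLUMNS = ("genotype", "environment", "block", "trait", "value")


@dataclass(frozen=True)
class AnovaResult:
    """ANOVA table, variance components and GCV for one trait."""

    trait: str
    anova_table: pd.DataFrame  # index: source; columns df, sum_sq, mean_sq
    mu: float
    sigma2_g: float  # raw EMS estimates (can be negative)
    sigma2_ge: float
    sigma2_e: float
    gcv_percent: float  # from the clamped genotypic component

    @property
    def components_clamped(self) -> dict[str, float]:
        return {
            "sigma2_g": max(self.sigma2_g, 0.0),
            "sigma2_ge": max(self.sigma2_ge, 0.0),
            "sigma2_e": max(self.sigma2_e, 0.0),
        }

    def summary(self) -> str:
        lines = [
            f"RCBD multi-environment ANOVA: {self.trait}",
            self.anova_table.to_string(float_format=lambda v: f"{v:.6g}"),
            "",
            f"mu        = {self.mu:.6g}",
            f"sigma2_g  = {self.sigma2_g:.6g}"
            + ("  (negative, clamped to 0 in GCV)" if self.sigma2_g < 0 else ""),
            f"sigma2_ge = {self.sigma2_ge:.6g}",
            f"sigma2_e  = {self.sigma2_e:.6g}",
            f"GCV       = {self.gcv_percent:.4g} %",
        ]
        return "\n".join(lines)


def _check_trial(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    sub = df[df["trait"] == trait].copy()
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    dup = sub.duplicated(subset=["genotype", "environment", "block"])
    if dup.any():
        raise ValueError("at most one value per (genotype, environment, block)")
    return sub


def rcbd_anova_gcv(trial: pd.DataFrame, trait: str) -> AnovaResult:
    """Fit the RCBD multi-environment ANOVA for ``trait`` and derive GCV.

    ``trial`` is long-format with columns genotype, environment, block,
    trait, value.  Requires >= 2 genotypes, >= 2 environments and at least
    one error degree of freedom.
    """
    sub = _check_trial(trial, trait)
    y = sub["value"].to_numpy(dtype=float)
    n_total = y.size
    envs = sorted(sub["environment"].unique())
    genos = sorted(sub["genotype"].unique())
    t, g = len(envs), len(genos)
    if t < 2 or g < 2:
        raise ValueError("need at least two genotypes and two environments")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    env_groups = sub.groupby("environment")["value"]
    ss_env = float((env_groups.count() * (env_groups.mean() - grand) ** 2).sum())

    blk = sub.groupby(["environment", "block"])["value"]
    env_means = env_groups.mean()
    blk_mean = blk.mean()
    blk_n = blk.count()
    ss_block = float(
        (blk_n * (blk_mean - env_means.reindex(blk_mean.index.get_level_values(0)).to_numpy()) ** 2).sum()
    )
    df_block = int(sum(sub.groupby("environment")["block"].nunique() - 1))

    gen_groups = sub.groupby("genotype")["value"]
    ss_geno = float((gen_groups.count() * (gen_groups.mean() - grand) ** 2).sum())

    cell = sub.groupby(["environment", "genotype"])["value"]
    cell_mean = cell.mean()
    cell_n = cell.count()
    e_of_cell = env_means.reindex(cell_mean.index.get_level_values(0)).to_numpy()
    g_of_cell = gen_groups.mean().reindex(cell_mean.index.get_level_values(1)).to_numpy()
    ss_ge = float(
        (cell_n * (cell_mean - e_of_cell - g_of_cell + grand) ** 2).sum()
    )

    ss_err = ss_total - ss_env - ss_block - ss_geno - ss_ge
    df_env, df_geno, df_ge = t - 1, g - 1, (t - 1) * (g - 1)
    df_err = n_total - 1 - df_env - df_block - df_geno - df_ge
    if df_err <= 0:
        raise ValueError("no error degrees of freedom: replicate the trial")

    rows = {
        "environment": (df_env, ss_env),
        "block(environment)": (df_block, ss_block),
        "genotype": (df_geno, ss_geno),
        "genotype:environment": (df_ge, ss_ge),
        "error": (df_err, max(ss_err, 0.0)),
    }
    table = pd.DataFrame(
        {
            "df": [v[0] for v in rows.values()],
            "sum_sq": [v[1] for v in rows.values()],
        },
        index=list(rows),
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]

    # expected mean squares (genotype and GxE random):
    #   E[MS_g]  = s2_e + rbar*s2_ge + R*s2_g    with R = obs per genotype
    #   E[MS_ge] = s2_e + rbar*s2_ge             rbar = mean blocks per env
    ms = table["mean_sq"]
    r_per_geno = n_total / g
    rbar = n_total / (g * t)
    sigma2_e = float(ms["error"])
    sigma2_ge = float((ms["genotype:environment"] - ms["error"]) / rbar)
    sigma2_g = float((ms["genotype"] - ms["genotype:environment"]) / r_per_geno)
    gcv = 100.0 * np.sqrt(max(sigma2_g, 0.0)) / grand
    return AnovaResult(
        trait=trait,
        anova_table=table,
        mu=float(grand),
        sigma2_g=sigma2_g,
        sigma2_ge=sigma2_ge,
        sigma2_e=sigma2_e,
        gcv_percent=float(gcv),
    )


def subpopulation_summary(
    values: Mapping[str, float], partition: Mapping[str, str]
) -> pd.DataFrame:
    """Per-region and pooled descriptive statistics of a trait.

    Returns mean, min, max, and a CV-style dispersion (100 * sd / mean) per
    region plus a pooled row labelled 'ALL'.
    """
    if not values:
        raise ValueError("no values supplied")
    ids = sorted(values)
    df = pd.DataFrame(
        {
            "region": [partition.get(i, "UNKNOWN") for i in ids],
            "value": [values[i] for i in ids],
        }
    )

    def stats(s: pd.Series) -> pd.Series:
        mean = s.mean()
        cv = 100.0 * s.std(ddof=1) / mean if len(s) > 1 and mean != 0 else 0.0
        return pd.Series(
            {"n": len(s), "mean": mean, "min": s.min(), "max": s.max(), "cv_percent": cv}
        )

    per_region = df.groupby("region")["value"].apply(stats).unstack()
    pooled = stats(df["value"]).rename("ALL")
    out = pd.concat([per_region, pooled.to_frame().T])
    out["n"] = out["n"].astype(int)
    return out
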