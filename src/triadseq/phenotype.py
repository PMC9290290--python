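"""Trait-level heterosis indices and significance tests.

For a trait measured on a test hybrid and a standard (check) hybrid across
environments the package reports:

* over-standard heterosis = 100 * (hybrid - check) / check  per environment,
* the across-environment average of those percentages,
* Welch's t test (from per-environment mean/SD/n) with star annotations,

and, for a hybrid with its two parents, the degree of dominance

    d = F1 - (P1 + P2) / 2,    a = |P1 - P2| / 2,    d/a

with |d/a| >= 1 read as over-dominance.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import ValidationError, round_half_up
from .stats import significance_stars, welch_t

TRAIT_COLUMNS = ["trait", "environment", "genotype", "mean", "sd", "n"]


@dataclass
class EnvAverage:
    mean: float
    sd: float | None


@dataclass
class DominanceDegree:
    d: float
    a: float
    d_over_a: float | None
    over_dominant: bool
    mode: str
    a_is_zero: bool = False


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"trait": str, "genotype": str})
    if list(df.columns[: len(TRAIT_COLUMNS)]) != TRAIT_COLUMNS:
        raise ValidationError(f"trait TSV must start with columns {TRAIT_COLUMNS}")
    if (df["sd"] < 0).any() or (df["n"] < 1).any():
        raise ValidationError("trait rows need sd >= 0 and n >= 1")
    return df


def over_check_heterosis(hybrid_mean: float, check_mean: float) -> float:
    """Percentage advantage of the test hybrid over the check, 2 dp."""
    if check_mean <= 0:
        raise ValidationError("check mean must be positive")
    return round_half_up(100.0 * (hybrid_mean - check_mean) / check_mean, 2)


def env_average(values: Sequence[float]) -> EnvAverage:
    """Arithmetic mean (2 dp) and sample SD of per-environment values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("need at least one environment")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return EnvAverage(round_half_up(float(arr.mean()), 2), sd)


def average_difference(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Difference of the two across-environment averages (a minus b), 2 dp."""
    return round_half_up(
        float(np.mean(list(values_a))) - float(np.mean(list(values_b))), 2
    )


def dominance_degree(f1_mean: float, p1_mean: float, p2_mean: float) -> DominanceDegree:
    """Degree of dominance of a hybrid relative to its parents.

    d is the F1 deviation from the mid-parent value and a is half the
    (absolute) parental difference, so the measure is invariant under parent
    relabelling.  When the parents coincide (a = 0) the ratio is undefined and
    the mode falls back to the sign of d.
    """
    d = f1_mean - (p1_mean + p2_mean) / 2.0
    a = abs(p1_mean - p2_mean) / 2.0
    if a == 0:
        mode = "over_dominance" if d > 0 else "under_dominance" if d < 0 else "additive"
        return DominanceDegree(d, a, None, d != 0, mode, a_is_zero=True)
    ratio = d / a
    mag = abs(ratio)
    if mag > 1:
        mode = "over_dominance"
    elif mag == 1:
        mode = "complete_dominance"
    elif mag > 0:
        mode = "partial_dominance"
    else:
        mode = "additive"
    return DominanceDegree(d, a, ratio, mag >= 1, mode)


class HeterosisResults:
    """Per-trait, per-environment heterosis table plus Average rows.

    ``table`` columns: trait, environment, check_mean, check_sd, hybrid_mean,
    hybrid_sd, over_check_pct, t, p, stars.  Average rows (environment
    "Average") average the per-environment means and percentages.
    """

    def __init__(self, table: pd.DataFrame, hybrid: str, check: str) -> None:
        self.table = table
        self.hybrid = hybrid
        self.check = check

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [f"Trait heterosis: {self.hybrid} over check {self.check}"]
        for _, row in self.table.iterrows():
            p_txt = "" if pd.isna(row["p"]) else f"  p={row['p']:.2e}{row['stars']}"
            lines.append(
                f"  {row['trait']:<14} {row['environment']:<8} "
                f"check={row['check_mean']:.2f} hybrid={row['hybrid_mean']:.2f} "
                f"over-standard={row['over_check_pct']:+.2f}%{p_txt}"
            )
        return "\n".join(lines)


class HeterosisModel:
    """Over-standard heterosis of one hybrid against a check hybrid.

    Expects a long-format trait table (columns ``TRAIT_COLUMNS``) containing
    per-environment summary rows for both genotypes.  The check genotype is a
    parameter, never an assumption baked into the data.
    """

    def __init__(
        self,
        traits: pd.DataFrame,
        hybrid: str,
        check: str,
        *,
        equal_var: bool = False,
    ) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
        if missing:
            raise ValidationError(f"trait table missing columns {missing}")
        for g in (hybrid, check):
            if g not in set(traits["genotype"]):
                raise ValidationError(f"genotype {g!r} absent from trait table")
        self.traits = traits
        self.hybrid = hybrid
        self.check = check
        self.equal_var = equal_var

    def fit(self) -> HeterosisResults:
        rows = []
        for trait, sub in self.traits.groupby("trait", sort=False):
            hyb = sub[sub["genotype"] == self.hybrid].set_index("environment")
            chk = sub[sub["genotype"] == self.check].set_index("environment")
            envs = [e for e in chk.index if e in hyb.index]
            if not envs:
                raise ValidationError(
                    f"trait {trait!r} has no shared environments for the two hybrids"
                )
            pcts, hyb_means, chk_means = [], [], []
            for env in envs:
                h, c = hyb.loc[env], chk.loc[env]
                pct = over_check_heterosis(h["mean"], c["mean"])
                if h["n"] >= 2 and c["n"] >= 2:
                    t, _, p = welch_t(
                        h["mean"], h["sd"], int(h["n"]),
                        c["mean"], c["sd"], int(c["n"]),
                        equal_var=self.equal_var,
                    )
                else:
                    t, p = np.nan, np.nan
                rows.append(
                    {
                        "trait": trait,
                        "environment": env,
                        "check_mean": c["mean"],
                        "check_sd": c["sd"],
                        "hybrid_mean": h["mean"],
                        "hybrid_sd": h["sd"],
                        "over_check_pct": pct,
                        "t": t,
                        "p": p,
                        "stars": significance_stars(p) if not np.isnan(p) else "",
                    }
                )
                pcts.append(pct)
                hyb_means.append(h["mean"])
                chk_means.append(c["mean"])
            rows.append(
                {
                    "trait": trait,
                    "environment": "Average",
                    "check_mean": env_average(chk_means).mean,
                    "check_sd": np.nan,
                    "hybrid_mean": env_average(hyb_means).mean,
                    "hybrid_sd": np.nan,
                    "over_check_pct": env_average(pcts).mean,
                    "t": np.nan,
                    "p": np.nan,
                    "stars": "",
                }
            )
        return HeterosisResults(pd.DataFrame(rows), self.hybrid, self.check)
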