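"""Chemostat arithmetic and biomass-yield comparison statistics.

A chemostat at dilution rate D (h^-1) holds the culture at growth rate
mu = D, i.e. a doubling time of ln2/D.  The biomass yield of a steady-state
sample is measured as CDW concentration (g l^-1) divided by the formate
consumed (mol l^-1), in g CDW per mol formate.  Two strains are compared with
a two-sample t-test on per-sample yields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatsError, ValidationError

#: plate-reader OD600 -> cuvette OD600 conversion factor
PLATE_TO_CUVETTE_FACTOR = 4.35

SAMPLE_COLUMNS = ["strain", "sample_id", "cdw_g_per_l", "formate_mol_per_l", "day"]


def doubling_time_from_dilution(d: float) -> float:
    """Doubling time (h) at dilution rate d (h^-1): ln2/d.

    0.05 h^-1 gives 13.86 h (the '14 h' chemostat condition); 0.087 h^-1
    gives 7.97 h ('8 h').
    """
    if d <= 0:
        raise ValueError("dilution rate must be positive")
    return math.log(2.0) / d


def doubling_time_hours_rounded(d: float) -> int:
    """Nearest-integer-hour display companion of the conversion above."""
    return round(doubling_time_from_dilution(d))


def dilution_from_doubling_time(td: float) -> float:
    """Inverse conversion: D = ln2/Td (h^-1)."""
    if td <= 0:
        raise ValueError("doubling time must be positive")
    return math.log(2.0) / td


def time_for_turnovers(n: float, d: float) -> float:
    """Hours for n reactor volume turnovers at dilution rate d: n/d."""
    if n < 0:
        raise ValueError("turnover count must be >= 0")
    if d <= 0:
        raise ValueError("dilution rate must be positive")
    return n / d


def measured_yield(cdw: float, formate_consumed: float) -> float:
    """Biomass yield (g CDW mol^-1): CDW (g/l) over formate consumed (mol/l)."""
    if formate_consumed <= 0:
        raise ValueError("formate consumed must be positive")
    return cdw / formate_consumed


def percent_increase(difference: float, baseline_mean: float) -> float:
    """Percent increase of a difference over a baseline mean (one decimal)."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return round(100.0 * difference / baseline_mean, 1)


def od_plate_to_cuvette(od_plate: float) -> float:
    """Convert plate-reader OD600 to cuvette OD600 (factor 4.35)."""
    if od_plate < 0:
        raise ValueError("optical density must be >= 0")
    return PLATE_TO_CUVETTE_FACTOR * od_plate


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

class ChemostatSampleTable:
    """Per-sample CDW and formate-consumption records with strain labels."""

    def __init__(self, df: pd.DataFrame):
        missing = set(SAMPLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"sample table missing columns {sorted(missing)}")
        if (df["cdw_g_per_l"] < 0).any():
            raise ValidationError("CDW concentrations must be >= 0")
        if (df["formate_mol_per_l"] <= 0).any():
            raise ValidationError("formate consumption must be positive")
        bad = set(df["strain"].str.lower()) - {"cbb", "rglyp"}
        if bad:
            raise ValidationError(f"unknown strain labels {sorted(bad)}")
        self.df = df.assign(strain=df["strain"].str.lower()).reset_index(drop=True)

    @classmethod
    def read(cls, path: str | Path) -> "ChemostatSampleTable":
        # round_trip parsing keeps file -> table -> statistics bit-identical
        # with the in-memory pipeline
        return cls(pd.read_csv(path, sep="\t", comment="#",
                               float_precision="round_trip"))

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def yields(self) -> pd.Series:
        """Per-sample measured yields (g CDW mol^-1), indexed like the table."""
        return self.df["cdw_g_per_l"] / self.df["formate_mol_per_l"]

    def yields_by_strain(self) -> dict[str, np.ndarray]:
        y = self.yields()
        return {
            strain: y[self.df["strain"] == strain].to_numpy()
            for strain in sorted(self.df["strain"].unique())
        }

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class YieldComparison:
    """Two-sample comparison of strain yields (rGlyP minus CBB)."""

    mean_yield: dict[str, float]
    sd_yield: dict[str, float]
    n: dict[str, int]
    difference_of_means: float
    sem_of_difference: float
    t_statistic: float
    degrees_of_freedom: float
    df_pooled: float
    df_welch: float
    p_two_tailed: float
    ci95: tuple[float, float]
    percent_increase: float
    flavor: str = "pooled"
    paired: bool = False
    flags: list[str] = field(default_factory=list)


def _comparison_from_groups(
    cbb: np.ndarray, rglyp: np.ndarray, flavor: str, paired: bool
) -> YieldComparison:
    n1, n2 = len(cbb), len(rglyp)
    mean = {"cbb": float(np.mean(cbb)), "rglyp": float(np.mean(rglyp))}
    sd = {"cbb": float(np.std(cbb, ddof=1)), "rglyp": float(np.std(rglyp, ddof=1))}
    diff = mean["rglyp"] - mean["cbb"]
    df_pooled = n1 + n2 - 2
    v1, v2 = sd["cbb"] ** 2 / n1, sd["rglyp"] ** 2 / n2
    df_welch = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))

    if paired:
        if n1 != n2:
            raise StatsError("paired test requires equal sample counts")
        d = rglyp - cbb
        sem = float(np.std(d, ddof=1) / math.sqrt(n1))
        dof = n1 - 1
        t = diff / sem if sem > 0 else 0.0
    elif flavor == "pooled":
        sp2 = ((n1 - 1) * sd["cbb"] ** 2 + (n2 - 1) * sd["rglyp"] ** 2) / df_pooled
        sem = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        dof = df_pooled
        t = diff / sem if sem > 0 else 0.0
    elif flavor == "welch":
        sem = math.sqrt(v1 + v2)
        dof = df_welch
        t = diff / sem if sem > 0 else 0.0
    else:
        raise StatsError(f"unknown t-test flavor {flavor!r}")

    p = 1.0 if sem == 0 else 2.0 * stats.t.sf(abs(t), dof)
    t_crit = stats.t.ppf(0.975, dof)
    ci = (diff - t_crit * sem, diff + t_crit * sem)
    flags = []
    if not paired and n1 != n2:
        flags.append(f"unequal group sizes ({n1} vs {n2})")
    return YieldComparison(
        mean_yield=mean,
        sd_yield=sd,
        n={"cbb": n1, "rglyp": n2},
        difference_of_means=diff,
        sem_of_difference=sem,
        t_statistic=t,
        degrees_of_freedom=dof,
        df_pooled=df_pooled,
        df_welch=df_welch,
        p_two_tailed=float(min(p, 1.0)),
        ci95=ci,
        percent_increase=percent_increase(diff, mean["cbb"]) if mean["cbb"] > 0
        else float("nan"),
        flavor="paired" if paired else flavor,
        paired=paired,
        flags=flags,
    )


def two_sample_t(
    table: ChemostatSampleTable, flavor: str = "pooled", paired: bool = False
) -> YieldComparison:
    """Compare per-sample yields of the rGlyP strain against the CBB strain.

    ``flavor`` selects the pooled-variance or Welch unpaired t-test; the
    paired variant pairs samples in row order.  Both the pooled and Welch
    degrees of freedom are always reported.  Two-tailed p from the t
    distribution's survival function; 95 % CI on the difference of means.
    """
    groups = table.yields_by_strain()
    for strain in ("cbb", "rglyp"):
        if len(groups.get(strain, ())) < 2:
            raise StatsError(f"need >= 2 samples per strain, strain {strain!r} short")
    return _comparison_from_groups(groups["cbb"], groups["rglyp"], flavor, paired)


def two_sample_t_from_summary(
    mean_cbb: float, sd_cbb: float, n_cbb: int,
    mean_rglyp: float, sd_rglyp: float, n_rglyp: int,
    flavor: str = "pooled",
) -> YieldComparison:
    """Unpaired t-test from printed summary statistics (means, SDs, n).

    Useful for reproducing a published comparison when only the summary is
    available; uses the same machinery as the sample-level test via
    ``scipy.stats.ttest_ind_from_stats``-equivalent formulas.
    """
    if n_cbb < 2 or n_rglyp < 2:
        raise StatsError("need >= 2 samples per strain")
    diff = mean_rglyp - mean_cbb
    df_pooled = n_cbb + n_rglyp - 2
    v1, v2 = sd_cbb ** 2 / n_cbb, sd_rglyp ** 2 / n_rglyp
    df_welch = (v1 + v2) ** 2 / (
        v1 ** 2 / (n_cbb - 1) + v2 ** 2 / (n_rglyp - 1)
    )
    if flavor == "pooled":
        sp2 = ((n_cbb - 1) * sd_cbb ** 2 + (n_rglyp - 1) * sd_rglyp ** 2) / df_pooled
        sem = math.sqrt(sp2 * (1 / n_cbb + 1 / n_rglyp))
        dof = df_pooled
    elif flavor == "welch":
        sem = math.sqrt(v1 + v2)
        dof = df_welch
    else:
        raise StatsError(f"unknown t-test flavor {flavor!r}")
    t = diff / sem if sem > 0 else 0.0
    p = 1.0 if sem == 0 else 2.0 * stats.t.sf(abs(t), dof)
    t_crit = stats.t.ppf(0.975, dof)
    return YieldComparison(
        mean_yield={"cbb": mean_cbb, "rglyp": mean_rglyp},
        sd_yield={"cbb": sd_cbb, "rglyp": sd_rglyp},
        n={"cbb": n_cbb, "rglyp": n_rglyp},
        difference_of_means=diff,
        sem_of_difference=sem,
        t_statistic=t,
        degrees_of_freedom=dof,
        df_pooled=df_pooled,
        df_welch=df_welch,
        p_two_tailed=float(min(p, 1.0)),
        ci95=(diff - t_crit * sem, diff + t_crit * sem),
        percent_increase=percent_increase(diff, mean_cbb),
        flavor=flavor,
    )
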