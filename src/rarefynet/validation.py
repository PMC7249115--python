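"""Statistical validation of NDVI map refinement.

One-way fixed-effects ANOVA of map pixels grouped by vigor class (the
textbook SS decomposition, with p-values from the F survival function),
Pearson correlation of maps, and a combined raw/refined/reference report
mirroring the usual agreement tables and class boxplots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .raster_io import NDVIMap
from .vigor import NODATA_CLASS, VigorMap


@dataclass
class AnovaTable:
    """DF/SS/MS/F/p decomposition for one grouping of pixels.

    Invariants: DF and SS are additive across Classes + Error = Total;
    MS = SS/DF; F = MS_classes / MS_error.
    """

    df_classes: int
    df_error: int
    ss_classes: float
    ss_error: float
    f_value: float
    p_value: float

    @property
    def df_total(self) -> int:
        return self.df_classes + self.df_error

    @property
    def ss_total(self) -> float:
        return self.ss_classes + self.ss_error

    @property
    def ms_classes(self) -> float:
        return self.ss_classes / self.df_classes

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    def to_frame(self) -> pd.DataFrame:
        """Classic ANOVA table layout, p in 3-significant-digit scientific form."""
        return pd.DataFrame(
            {
                "DF": [self.df_classes, self.df_error, self.df_total],
                "SS": [self.ss_classes, self.ss_error, self.ss_total],
                "MS": [self.ms_classes, self.ms_error, np.nan],
                "F-Value": [self.f_value, np.nan, np.nan],
                "p-Value": [f"{self.p_value:.3g}", "", ""],
            },
            index=["Classes", "Error", "Total"],
        )


def one_way_anova(groups: list[np.ndarray]) -> AnovaTable:
    """One-way fixed-effects ANOVA of >= 2 non-empty value groups.

    SS_classes = sum_j n_j (mean_j - grand_mean)^2, SS_error = within-group
    squared deviations; F = MS_classes / MS_error with (g-1, n-g) degrees of
    freedom.  A zero error mean square yields F = +inf, p = 0.
    """
    groups = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(g.size < 1 for g in groups):
        raise ValueError("every group needs at least 1 observation")
    n = sum(g.size for g in groups)
    g = len(groups)
    if n < g + 1:
        raise ValueError("need at least one more observation than groups")
    grand = np.concatenate(groups).mean()
    ss_classes = float(sum(grp.size * (grp.mean() - grand) ** 2 for grp in groups))
    ss_error = float(sum(((grp - grp.mean()) ** 2).sum() for grp in groups))
    df_classes, df_error = g - 1, n - g
    ms_error = ss_error / df_error
    if ms_error == 0.0:
        f_value, p_value = np.inf, 0.0
    else:
        f_value = (ss_classes / df_classes) / ms_error
        p_value = f_pvalue(f_value, df_classes, df_error)
    return AnovaTable(df_classes, df_error, ss_classes, ss_error,
                      float(f_value), float(p_value))


def f_pvalue(f_value: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution."""
    if f_value < 0 or df1 < 1 or df2 < 1:
        raise ValueError("f_pvalue needs F >= 0 and df1, df2 >= 1")
    return float(stats.f.sf(f_value, df1, df2))


def pearson(a, b) -> float:
    """Product-moment correlation of two equal-length value lists."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("pearson needs two equal-length lists of >= 2 values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation is undefined for zero-variance input")
    return float(stats.pearsonr(a, b).statistic)


def _group_pixels(ndvi_map: NDVIMap, classes: VigorMap) -> list[np.ndarray]:
    """Pixels valid in both the NDVI map and the class map, split by class."""
    joint = ndvi_map.mask & classes.mask & (classes.classes != NODATA_CLASS)
    labels = np.unique(classes.classes[joint])
    return [ndvi_map.values[joint & (classes.classes == lab)] for lab in labels]


def anova_by_vigor(ndvi_map: NDVIMap, classes: VigorMap) -> AnovaTable:
    """ANOVA of one NDVI map grouped by a vigor-class map."""
    return one_way_anova(_group_pixels(ndvi_map, classes))


@dataclass
class RefinementReport:
    """Agreement of raw and refined maps with the reference, plus ANOVA tables."""

    rmse_raw: float
    rmse_refined: float
    pearson_raw: float
    pearson_refined: float
    anova: dict[str, AnovaTable]
    n_cells: int
    group_values: dict[str, list[np.ndarray]] = field(default_factory=dict)

    @property
    def rmse_improvement(self) -> float:
        """Relative RMSE reduction of the refined map (1 = perfect)."""
        return 1.0 - self.rmse_refined / self.rmse_raw

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, table in self.anova.items():
            rows.append({
                "map": name,
                "DF_classes": table.df_classes, "DF_error": table.df_error,
                "SS_classes": table.ss_classes, "SS_error": table.ss_error,
                "MS_classes": table.ms_classes, "MS_error": table.ms_error,
                "F": table.f_value, "p": table.p_value,
            })
        return pd.DataFrame(rows)

    def boxplot_frame(self) -> pd.DataFrame:
        """Long-form (map, class, ndvi) table for class boxplots."""
        records = []
        for name, groups in self.group_values.items():
            for label, values in enumerate(groups):
                for v in values:
                    records.append({"map": name, "class": "LMH"[label], "ndvi": v})
        return pd.DataFrame(records)


def evaluate_refinement(raw: NDVIMap, refined: NDVIMap, reference: NDVIMap,
                        groups: VigorMap) -> RefinementReport:
    """Score a refinement run against the reference map.

    RMSE and Pearson r are computed on cells valid in all three maps; ANOVA
    tables group each map's pixels by the supplied vigor classes.
    Deterministic: identical inputs give an identical report.
    """
    for other in (refined, reference):
        if not raw.same_geometry(other):
            raise ValueError("raw / refined / reference rasters must share geometry")
    joint = raw.mask & refined.mask & reference.mask
    if not joint.any():
        raise ValueError("no jointly valid cells")
    ref_v = reference.values[joint]
    report = RefinementReport(
        rmse_raw=float(np.sqrt(np.mean((raw.values[joint] - ref_v) ** 2))),
        rmse_refined=float(np.sqrt(np.mean((refined.values[joint] - ref_v) ** 2))),
        pearson_raw=pearson(raw.values[joint], ref_v),
        pearson_refined=pearson(refined.values[joint], ref_v),
        anova={
            "raw": anova_by_vigor(raw, groups),
            "refined": anova_by_vigor(refined, groups),
            "reference": anova_by_vigor(reference, groups),
        },
        n_cells=int(joint.sum()),
        group_values={
            "raw": _group_pixels(raw, groups),
            "refined": _group_pixels(refined, groups),
            "reference": _group_pixels(reference, groups),
        },
    )
    return report
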