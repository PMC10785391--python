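"""Pre-adjustment of phenotypes for fixed effects and covariates.

Each trait is adjusted by an ordinary fixed-effects linear model: the
trait is regressed on its contemporary-group factors (e.g. birth
year x month x line x sex for weaning traits; test year x month x
installation x sex for feedlot traits) and covariates such as dam age
(linear and quadratic) or age at the start of the test.  The adjusted
phenotype is the OLS residual, so adjusted values average zero within a
fitted group; the grand mean can optionally be re-added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdjustmentSpec",
    "DesignInfo",
    "build_design",
    "adjust_phenotypes",
    "DEFAULT_TRAIT_SPECS",
]


@dataclass(frozen=True)
class AdjustmentSpec:
    """Fixed-effect structure for one trait.

    ``categorical`` lists factor column names; ``covariates`` lists
    (column, degree) pairs — degree 2 adds both the linear and quadratic
    terms.
    """

    trait: str
    categorical: tuple[str, ...] = ()
    covariates: tuple[tuple[str, int], ...] = ()

    @classmethod
    def from_dict(cls, d: dict) -> "AdjustmentSpec":
        covs = []
        for c in d.get("covariates", []):
            if isinstance(c, str):
                covs.append((c, 1))
            else:
                covs.append((str(c[0]), int(c[1])))
        return cls(
            trait=d["trait"],
            categorical=tuple(d.get("categorical", [])),
            covariates=tuple(covs),
        )


#: Default per-trait adjustment structure for the Nellore herd layout:
#: CGw = birth year x month x line x sex; CGr = test year x month x
#: installation x sex; BM = birth month; CA = dam age; AW/ASW/AST = ages.
DEFAULT_TRAIT_SPECS: dict[str, AdjustmentSpec] = {
    "W210": AdjustmentSpec("W210", ("CGw",), (("CA", 2), ("AW", 1))),
    "WSel": AdjustmentSpec("WSel", ("CGw",), (("CA", 2), ("ASW", 1))),
    "ADG": AdjustmentSpec("ADG", ("CGr", "BM"), (("AST", 1),)),
    "DMI": AdjustmentSpec("DMI", ("CGr", "BM"), (("AST", 1),)),
    "RFI": AdjustmentSpec("RFI", ("CGr", "BM"), (("AST", 1),)),
    "TF": AdjustmentSpec("TF", ("CGr", "BM"), (("AST", 1),)),
    "FF": AdjustmentSpec("FF", ("CGr", "BM"), (("AST", 1),)),
}


@dataclass
class DesignInfo:
    matrix: np.ndarray
    columns: list[str]
    reference_levels: dict[str, str]
    singleton_levels: dict[str, list[str]] = field(default_factory=dict)
    level_counts: dict[str, int] = field(default_factory=dict)


def build_design(records: pd.DataFrame, spec: AdjustmentSpec) -> DesignInfo:
    """Full-rank fixed-effects design matrix (intercept + contrasts).

    Categorical factors are dummy-coded against a reference level (the
    first level in sorted order); covariates enter as powers up to their
    degree.  Levels carried by a single record are flagged.  A
    rank-deficient design (e.g. duplicated covariate) raises.
    """
    if len(records) == 0:
        raise ValueError("no records to build a design from")
    if not spec.categorical and not spec.covariates:
        raise ValueError("spec must name at least one factor or covariate")

    cols: list[np.ndarray] = [np.ones(len(records))]
    names = ["Intercept"]
    refs: dict[str, str] = {}
    singletons: dict[str, list[str]] = {}
    level_counts: dict[str, int] = {}
    for factor in spec.categorical:
        if factor not in records.columns:
            raise ValueError(f"missing factor column {factor!r}")
        levels = sorted(records[factor].astype(str).unique())
        level_counts[factor] = len(levels)
        refs[factor] = levels[0]
        counts = records[factor].astype(str).value_counts()
        single = [lv for lv in levels if counts[lv] == 1]
        if single:
            singletons[factor] = single
        for lv in levels[1:]:
            cols.append((records[factor].astype(str) == lv).to_numpy(dtype=float))
            names.append(f"{factor}[{lv}]")
    for cov, degree in spec.covariates:
        if cov not in records.columns:
            raise ValueError(f"missing covariate column {cov!r}")
        x = records[cov].to_numpy(dtype=float)
        for power in range(1, degree + 1):
            cols.append(x ** power)
            names.append(cov if power == 1 else f"{cov}^{power}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear columns)")
    return DesignInfo(
        matrix=X, columns=names, reference_levels=refs,
        singleton_levels=singletons, level_counts=level_counts,
    )


def adjust_phenotypes(
    records: pd.DataFrame,
    spec: AdjustmentSpec,
    *,
    value_column: str | None = None,
    id_column: str = "animal_id",
    add_grand_mean: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """OLS-residual adjustment of one trait.

    Returns a table (animal_id, trait, raw, adjusted) over the records
    with a non-missing trait value, plus a fit summary (R^2, n, level
    counts, flagged singleton levels).
    """
    value_column = value_column or spec.trait
    if value_column not in records.columns:
        raise ValueError(f"missing trait column {value_column!r}")
    sub = records.loc[records[value_column].notna()].reset_index(drop=True)
    design = build_design(sub, spec)
    y = sub[value_column].to_numpy(dtype=float)
    coef, _, _, _ = np.linalg.lstsq(design.matrix, y, rcond=None)
    fitted = design.matrix @ coef
    resid = y - fitted
    if add_grand_mean:
        resid = resid + y.mean()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    summary = {
        "trait": spec.trait,
        "n": int(len(sub)),
        "r2": 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0,
        "level_counts": design.level_counts,
        "singleton_levels": design.singleton_levels,
    }
    out = pd.DataFrame(
        {
            "animal_id": sub[id_column].astype(str),
            "trait": spec.trait,
            "raw": y,
            "adjusted": resid,
        }
    )
    return out, summary
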