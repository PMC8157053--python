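"""Multi-trait phenotype records: loading, yearling-weight derivation and
descriptive statistics.

Records are one row per animal with trait columns (missing entries allowed),
categorical fixed-effect factor columns and numeric covariate columns.
Missingness is carried as an explicit boolean mask; no sentinel values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraitDefinition",
    "PhenotypeTable",
    "derive_yearling_weight",
    "descriptive_stats",
    "cv_percent",
    "standard_error",
    "load_phenotypes",
    "write_phenotypes",
]

DEFAULT_MISSING_TOKENS = ("", "NA")


class PhenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class TraitDefinition:
    """A trait and its trait-specific fixed-effect structure.

    ``factors`` are categorical columns (e.g. a pre-combined batch-sex or
    slaughter-date contemporary group); ``covariates`` enter linearly (e.g.
    scan age or slaughter age in days).
    """

    name: str
    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self):
        overlap = set(self.factors) & set(self.covariates)
        if overlap:
            raise PhenotypeError(
                f"trait {self.name!r}: columns {sorted(overlap)} listed as both "
                "factor and covariate"
            )


@dataclass
class PhenotypeTable:
    """Validated multi-trait records.

    Attributes
    ----------
    animal_ids : list of str
        One entry per row; every id must exist in the pedigree used for
        model building.
    values : (n, k) ndarray
        Trait values; entries where ``observed`` is False are meaningless.
    observed : (n, k) bool ndarray
        Missingness mask (True = recorded).
    traits : tuple of TraitDefinition
    factors : dict name -> (n,) int ndarray of level codes
    factor_levels : dict name -> list of original level labels
    covariates : dict name -> (n,) float ndarray (raw, uncentred)
    """

    animal_ids: list[str]
    values: np.ndarray
    observed: np.ndarray
    traits: tuple[TraitDefinition, ...]
    factors: dict[str, np.ndarray] = field(default_factory=dict)
    factor_levels: dict[str, list] = field(default_factory=dict)
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        n, k = self.values.shape
        if self.observed.shape != (n, k) or len(self.animal_ids) != n:
            raise PhenotypeError("inconsistent phenotype table shapes")
        if k != len(self.traits):
            raise PhenotypeError("trait count does not match value columns")
        empty = [t.name for j, t in enumerate(self.traits) if not self.observed[:, j].any()]
        if empty:
            raise PhenotypeError(f"traits with no records: {empty}")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def trait_index(self, name: str) -> int:
        for j, t in enumerate(self.traits):
            if t.name == name:
                return j
        raise PhenotypeError(f"unknown trait {name!r}")


def derive_yearling_weight(w_t: float, w_prev: float, t: float, t_prev: float) -> float:
    """Project body weight linearly to day 365 from two weighings.

    YW = ((w_t - w_prev)/(t - t_prev)) * (365 - t_prev) + w_prev, i.e. the
    growth line through the ~6-month and ~12-month weights evaluated at one
    year of age.
    """
    if t == t_prev:
        raise PhenotypeError("weighing dates coincide; growth rate undefined")
    if not (t > t_prev > 0):
        raise PhenotypeError(f"need t > t_prev > 0, got t={t}, t_prev={t_prev}")
    return ((w_t - w_prev) / (t - t_prev)) * (365.0 - t_prev) + w_prev


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100*sd/mean."""
    return 100.0 * sd / mean


def standard_error(sd: float, n: int) -> float:
    """Standard error of the mean, sd/sqrt(n)."""
    return sd / math.sqrt(n)


def descriptive_stats(table: PhenotypeTable, trait: str) -> dict:
    """n, mean, se, min, max, sd (n-1 denominator) and CV% for one trait."""
    j = table.trait_index(trait)
    x = table.values[table.observed[:, j], j]
    if x.size == 0:
        raise PhenotypeError(f"trait {trait!r} has no records")
    n = int(x.size)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    return {
        "n": n,
        "mean": mean,
        "se": standard_error(sd, n),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "sd": sd,
        "cv": cv_percent(mean, sd) if mean != 0 else float("nan"),
    }


def descriptive_table(table: PhenotypeTable) -> pd.DataFrame:
    """Descriptive statistics for every trait, 2-decimal report style."""
    rows = []
    for t in table.traits:
        s = descriptive_stats(table, t.name)
        rows.append(
            {
                "trait": t.name,
                "n": s["n"],
                "mean": round(s["mean"], 2),
                "se": round(s["se"], 2),
                "min": round(s["min"], 2),
                "max": round(s["max"], 2),
                "sd": round(s["sd"], 2),
                "cv_pct": round(s["cv"], 2),
            }
        )
    return pd.DataFrame(rows)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header and header.count("\t") >= header.count(",") else ","


def load_phenotypes(
    path,
    trait_defs,
    pedigree=None,
    animal_col: str = "animal",
    sep: str | None = None,
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> PhenotypeTable:
    """Read a delimited phenotype file into a :class:`PhenotypeTable`.

    Factor levels are coded deterministically (lexicographic order of their
    string labels).  If ``pedigree`` is given, every animal id must be in it.
    A trait cell that is neither numeric nor a missing token is a hard error.
    """
    path = Path(path)
    trait_defs = tuple(trait_defs)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if animal_col not in df.columns:
        raise PhenotypeError(f"phenotype file lacks animal column {animal_col!r}")
    needed = set()
    for t in trait_defs:
        needed.add(t.name)
        needed.update(t.factors)
        needed.update(t.covariates)
    missing_cols = sorted(needed - set(df.columns))
    if missing_cols:
        raise PhenotypeError(f"phenotype file lacks columns: {missing_cols}")

    ids = [str(a).strip() for a in df[animal_col]]
    if pedigree is not None:
        absent = [a for a in ids if a not in pedigree.order_index]
        if absent:
            raise PhenotypeError(
                f"{len(absent)} animals absent from the pedigree, e.g. {absent[:5]}"
            )

    n, k = len(df), len(trait_defs)
    values = np.zeros((n, k))
    observed = np.zeros((n, k), dtype=bool)
    for j, t in enumerate(trait_defs):
        col = df[t.name].astype(str).str.strip()
        miss = col.isin(missing_tokens)
        try:
            vals = pd.to_numeric(col.where(~miss, other="0"))
        except (ValueError, TypeError) as exc:
            raise PhenotypeError(
                f"non-numeric value in trait column {t.name!r}: {exc}"
            ) from None
        values[:, j] = np.where(miss, 0.0, vals.to_numpy(dtype=float))
        observed[:, j] = ~miss.to_numpy()

    factors: dict[str, np.ndarray] = {}
    factor_levels: dict[str, list] = {}
    covariates: dict[str, np.ndarray] = {}
    for t in trait_defs:
        for f in t.factors:
            if f in factors:
                continue
            labels = df[f].astype(str).str.strip()
            levels = sorted(labels.unique())
            lut = {lev: c for c, lev in enumerate(levels)}
            factors[f] = labels.map(lut).to_numpy(dtype=np.int64)
            factor_levels[f] = levels
        for c in t.covariates:
            if c in covariates:
                continue
            try:
                covariates[c] = pd.to_numeric(df[c]).to_numpy(dtype=float)
            except (ValueError, TypeError) as exc:
                raise PhenotypeError(
                    f"non-numeric covariate column {c!r}: {exc}"
                ) from None

    return PhenotypeTable(
        animal_ids=ids,
        values=values,
        observed=observed,
        traits=trait_defs,
        factors=factors,
        factor_levels=factor_levels,
        covariates=covariates,
    )


def write_phenotypes(table: PhenotypeTable, path, sep: str = ",", missing: str = "NA") -> None:
    """Write a table back in the dialect :func:`load_phenotypes` reads."""
    df = pd.DataFrame({"animal": table.animal_ids})
    for j, t in enumerate(table.traits):
        col = np.array([repr(float(v)) for v in table.values[:, j]], dtype=object)
        col[~table.observed[:, j]] = missing
        df[t.name] = col
    for f, codes in table.factors.items():
        levels = table.factor_levels[f]
        df[f] = [levels[c] for c in codes]
    for c, vals in table.covariates.items():
        df[c] = vals
    df.to_csv(path, sep=sep, index=False)
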