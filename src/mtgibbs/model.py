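"""Design structures for the multi-trait animal model y = Xb + Zu + e.

Each trait owns its own fixed-effect columns (factors are trait-specific
contemporary groups, covariates enter linearly and are centred).  The design
is stored in a compressed per-coefficient layout: for every fixed-effect
coefficient we keep the list of record rows it touches and the covariate
value there (1 for factor incidences).  Only observed (animal, trait) cells
enter X; breeding values u exist for every pedigree animal regardless of
records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pedigree import Pedigree
from .phenotypes import PhenotypeTable, TraitDefinition

__all__ = ["ModelSpec", "MissingPattern", "build_design", "partition_missing"]

log = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class MissingPattern:
    """Rows of the record table sharing one observed-trait mask."""

    pattern_id: int
    observed_mask: np.ndarray  # (k,) bool
    member_rows: np.ndarray  # indices into the model's record rows


@dataclass
class ModelSpec:
    """Assembled design for the Gibbs sampler.

    Record rows are the phenotype-table rows with at least one observed
    trait, in table order.  Coefficients are indexed 0..p-1 across all
    traits; ``coef_labels[j]`` identifies coefficient j as
    (trait, column, level-label-or-"<cov>").
    """

    traits: tuple[TraitDefinition, ...]
    rec_table_rows: np.ndarray  # (n_rec,) indices into the source table
    rec_animal: np.ndarray  # (n_rec,) pedigree codes
    y: np.ndarray  # (n_rec, k) observed values (0 where missing)
    observed: np.ndarray  # (n_rec, k) bool
    coef_trait: np.ndarray  # (p,) trait index of each coefficient
    coef_ptr: np.ndarray  # (p+1,) CSC-style pointers
    coef_rec: np.ndarray  # (nnz,) record-row index per entry
    coef_x: np.ndarray  # (nnz,) design value per entry
    coef_labels: list[tuple[str, str, str]]
    centring: dict[tuple[str, str], float]  # (trait, covariate) -> mean used
    patterns: list[MissingPattern]
    n_ped: int
    excluded_animals: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return self.rec_animal.shape[0]

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_coefficients(self) -> int:
        return self.coef_trait.shape[0]

    def coef_sum_x2(self) -> np.ndarray:
        """Per-coefficient sum of squared design values (MME diagonal part)."""
        p = self.n_coefficients
        out = np.zeros(p)
        for j in range(p):
            sl = slice(self.coef_ptr[j], self.coef_ptr[j + 1])
            out[j] = np.sum(self.coef_x[sl] ** 2)
        return out


def partition_missing(observed: np.ndarray) -> list[MissingPattern]:
    """Partition record rows by their observed-trait mask.

    Rows with no observed trait must have been removed already.  Patterns
    are ordered by member count (descending), ties broken by the mask read
    as a binary number (descending), so the ordering is deterministic.
    """
    n, k = observed.shape
    weights = 1 << np.arange(k - 1, -1, -1)
    keys = observed.astype(np.int64) @ weights
    groups: dict[int, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(int(key), []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), -kv[0]))
    patterns = []
    for pid, (key, rows) in enumerate(ordered):
        mask = np.array([(key >> (k - 1 - j)) & 1 == 1 for j in range(k)])
        patterns.append(
            MissingPattern(
                pattern_id=pid,
                observed_mask=mask,
                member_rows=np.asarray(rows, dtype=np.int64),
            )
        )
    return patterns


def build_design(
    table: PhenotypeTable, ped: Pedigree, trait_defs=None
) -> ModelSpec:
    """Assemble the sparse design and missing patterns from validated inputs.

    Covariates are centred at their mean over the rows where the trait is
    observed (constants recorded in ``centring``).  Factor levels with no
    observed record for the trait are dropped; single-level factors are kept
    but flagged, since without an explicit intercept they simply absorb the
    trait mean.
    """
    traits = tuple(trait_defs) if trait_defs is not None else table.traits
    k = len(traits)
    animal_codes = ped.codes_of(table.animal_ids)

    any_obs = table.observed.any(axis=1)
    excluded = [table.animal_ids[i] for i in np.flatnonzero(~any_obs)]
    if excluded:
        log.info(
            "%d animals have no observed trait; kept in the pedigree, "
            "excluded from the residual likelihood", len(excluded),
        )
    rec_rows = np.flatnonzero(any_obs)
    rec_animal = animal_codes[rec_rows]
    if np.unique(rec_animal).size != rec_animal.size:
        raise ModelError(
            "repeated records per animal are not supported (one row per animal; "
            "a permanent-environment effect would be required)"
        )
    y = table.values[rec_rows][:, : k].astype(float)
    observed = table.observed[rec_rows][:, : k].copy()

    coef_trait: list[int] = []
    coef_labels: list[tuple[str, str, str]] = []
    ptr: list[int] = [0]
    rec_idx: list[np.ndarray] = []
    xval: list[np.ndarray] = []
    centring: dict[tuple[str, str], float] = {}

    for t_idx, t in enumerate(traits):
        obs_rows = np.flatnonzero(observed[:, t_idx])
        for f in t.factors:
            codes = table.factors[f][rec_rows]
            levels_here = np.unique(codes[obs_rows])
            if levels_here.size == 1:
                log.warning(
                    "trait %s: factor %s has a single observed level; it acts "
                    "as an intercept", t.name, f,
                )
            all_levels = len(table.factor_levels.get(f, [])) or int(codes.max()) + 1
            if levels_here.size < all_levels:
                log.info(
                    "trait %s: factor %s: %d of %d levels have no observed "
                    "record and were dropped", t.name, f,
                    all_levels - levels_here.size, all_levels,
                )
            for lev in levels_here:
                members = obs_rows[codes[obs_rows] == lev]
                coef_trait.append(t_idx)
                lev_label = (
                    str(table.factor_levels[f][lev])
                    if f in table.factor_levels
                    else str(lev)
                )
                coef_labels.append((t.name, f, lev_label))
                rec_idx.append(members.astype(np.int64))
                xval.append(np.ones(members.size))
                ptr.append(ptr[-1] + members.size)
        for c in t.covariates:
            vals = table.covariates[c][rec_rows].astype(float)
            mean = float(np.mean(vals[obs_rows]))
            centring[(t.name, c)] = mean
            coef_trait.append(t_idx)
            coef_labels.append((t.name, c, "<cov>"))
            rec_idx.append(obs_rows.astype(np.int64))
            xval.append(vals[obs_rows] - mean)
            ptr.append(ptr[-1] + obs_rows.size)

    patterns = partition_missing(observed)
    return ModelSpec(
        traits=traits,
        rec_table_rows=rec_rows,
        rec_animal=rec_animal,
        y=y,
        observed=observed,
        coef_trait=np.asarray(coef_trait, dtype=np.int64),
        coef_ptr=np.asarray(ptr, dtype=np.int64),
        coef_rec=(
            np.concatenate(rec_idx) if rec_idx else np.zeros(0, dtype=np.int64)
        ),
        coef_x=np.concatenate(xval) if xval else np.zeros(0),
        coef_labels=coef_labels,
        centring=centring,
        patterns=patterns,
        n_ped=len(ped),
        excluded_animals=excluded,
    )
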