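"""Synthetic pedigrees and multi-trait phenotypes with known truth.

The generator mirrors the structure of a Korean beef-cattle (Hanwoo)
performance/progeny-testing dataset: yearling weight recorded on bulls and
steers, live-animal ultrasound traits (intramuscular fat %, eye-muscle area,
backfat) on a scanned subset, and carcass traits (backfat, carcass weight,
eye-muscle area, marbling score) on steers only.  Breeding values follow the
pedigree exactly (u ~ N(0, G (x) A), generated by the Mendelian-sampling
recursion), residuals are i.i.d. MVN(0, R) per animal, and fixed effects are
contemporary-group draws plus a linear age covariate.

The default parameter set uses the published posterior means for the trait
(co)variances, so recovery tests run against realistic signal-to-noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .pedigree import UNKNOWN, Pedigree, compute_inbreeding, from_records
from .phenotypes import PhenotypeTable, TraitDefinition, derive_yearling_weight

__all__ = [
    "SimulationDesign",
    "TRAIT_ORDER",
    "reference_G",
    "reference_R",
    "hanwoo_design",
    "recovery_design",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
]

#: Canonical trait order used throughout (ultrasound, carcass, yearling weight).
TRAIT_ORDER = ("UIMF", "UEMA", "UBFT", "BFT", "CW", "EMA", "MS", "YW")

_UNITS = {
    "UIMF": "%", "UEMA": "cm^2", "UBFT": "mm", "BFT": "mm",
    "CW": "kg", "EMA": "cm^2", "MS": "score 1-9", "YW": "kg",
}

# Published posterior means: additive and residual variances per trait.
_SIGMA_A2 = {
    "UIMF": 0.23, "UEMA": 9.98, "UBFT": 0.21, "BFT": 7.15,
    "CW": 596.32, "EMA": 34.60, "MS": 1.43, "YW": 354.09,
}
_SIGMA_E2 = {
    "UIMF": 0.98, "UEMA": 20.72, "UBFT": 0.48, "BFT": 5.59,
    "CW": 828.31, "EMA": 34.40, "MS": 0.97, "YW": 792.65,
}

# Genetic (r_g) and phenotypic (r_p) correlations, upper triangle in
# TRAIT_ORDER.  Keys are unordered pairs.
_R_G = {
    ("UIMF", "UEMA"): 0.04, ("UIMF", "UBFT"): 0.46, ("UIMF", "BFT"): 0.11,
    ("UIMF", "CW"): 0.14, ("UIMF", "EMA"): 0.28, ("UIMF", "MS"): 0.78,
    ("UIMF", "YW"): -0.05,
    ("UEMA", "UBFT"): 0.16, ("UEMA", "BFT"): -0.09, ("UEMA", "CW"): 0.40,
    ("UEMA", "EMA"): 0.65, ("UEMA", "MS"): -0.07, ("UEMA", "YW"): 0.41,
    ("UBFT", "BFT"): 0.63, ("UBFT", "CW"): -0.01, ("UBFT", "EMA"): -0.12,
    ("UBFT", "MS"): 0.14, ("UBFT", "YW"): 0.15,
    ("BFT", "CW"): 0.07, ("BFT", "EMA"): -0.25, ("BFT", "MS"): 0.03,
    ("BFT", "YW"): -0.05,
    ("CW", "EMA"): 0.56, ("CW", "MS"): 0.17, ("CW", "YW"): 0.84,
    ("EMA", "MS"): 0.35, ("EMA", "YW"): 0.43,
    ("MS", "YW"): 0.03,
}
_R_P = {
    ("UIMF", "UEMA"): 0.05, ("UIMF", "UBFT"): 0.15, ("UIMF", "BFT"): 0.07,
    ("UIMF", "CW"): 0.04, ("UIMF", "EMA"): 0.09, ("UIMF", "MS"): 0.42,
    ("UIMF", "YW"): 0.05,
    ("UEMA", "UBFT"): 0.22, ("UEMA", "BFT"): 0.08, ("UEMA", "CW"): 0.42,
    ("UEMA", "EMA"): 0.48, ("UEMA", "MS"): 0.01, ("UEMA", "YW"): 0.51,
    ("UBFT", "BFT"): 0.40, ("UBFT", "CW"): 0.15, ("UBFT", "EMA"): 0.05,
    ("UBFT", "MS"): 0.08, ("UBFT", "YW"): 0.23,
    ("BFT", "CW"): 0.27, ("BFT", "EMA"): 0.01, ("BFT", "MS"): 0.08,
    ("BFT", "YW"): 0.18,
    ("CW", "EMA"): 0.57, ("CW", "MS"): 0.12, ("CW", "YW"): 0.78,
    ("EMA", "MS"): 0.24, ("EMA", "YW"): 0.40,
    ("MS", "YW"): 0.06,
}

#: Record-class proportions of the recorded population (from the published
#: record counts: 15,796 yearling weights; 8,945 scanned; 5,622 steers with
#: carcass data, 3,627 of them scanned).
HANWOO_CLASSES = (
    ("steer_scanned", 3627 / 15796, ("UIMF", "UEMA", "UBFT", "BFT", "CW", "EMA", "MS", "YW")),
    ("steer_unscanned", 1995 / 15796, ("BFT", "CW", "EMA", "MS", "YW")),
    ("bull_scanned", 5318 / 15796, ("UIMF", "UEMA", "UBFT", "YW")),
    ("bull_unscanned", 4856 / 15796, ("YW",)),
)

#: Fraction of records (steers with any carcass data) in the full dataset.
STEER_FRACTION = 5622 / 15796


def _corr_to_cov(names, diag, corr) -> np.ndarray:
    k = len(names)
    M = np.diag([diag[n] for n in names]).astype(float)
    sd = np.sqrt(np.diag(M))
    for i in range(k):
        for j in range(i + 1, k):
            key = (names[i], names[j]) if (names[i], names[j]) in corr else (names[j], names[i])
            M[i, j] = M[j, i] = corr[key] * sd[i] * sd[j]
    return M


def _clip_psd(M: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Eigenvalue-clip a nearly-PD matrix (2-dp rounding artefacts)."""
    w, V = np.linalg.eigh(M)
    if w.min() > 0:
        return M
    scale = np.abs(w).max()
    w = np.maximum(w, floor * scale)
    return (V * w) @ V.T


def reference_G(traits=TRAIT_ORDER) -> np.ndarray:
    """Additive-genetic covariance among ``traits`` at the published values."""
    return _clip_psd(_corr_to_cov(tuple(traits), _SIGMA_A2, _R_G))


def reference_R(traits=TRAIT_ORDER) -> np.ndarray:
    """Residual covariance among ``traits``: off-diagonals derive from the
    published phenotypic correlations, R_ij = r_p sqrt(sp2_i sp2_j) - G_ij."""
    names = tuple(traits)
    G = _corr_to_cov(names, _SIGMA_A2, _R_G)
    sp2 = {n: _SIGMA_A2[n] + _SIGMA_E2[n] for n in names}
    P = _corr_to_cov(names, sp2, _R_P)
    return _clip_psd(P - G)


@dataclass(frozen=True)
class SimulationDesign:
    """Everything the generator needs, with known true parameters.

    ``classes`` assigns each recorded animal a missingness class: a name, a
    proportion (must sum to 1) and the tuple of observed traits.  Founders
    are never recorded.  ``fixed_fraction`` is the share of phenotypic
    variance contributed by the fixed effects (split equally over a trait's
    factors and covariates).
    """

    traits: tuple[str, ...]
    true_G: np.ndarray
    true_R: np.ndarray
    n_founders: int = 100
    n_generations: int = 4
    matings_per_generation: int = 60
    offspring_per_mating: int = 8
    classes: tuple = ()
    trait_factors: dict = field(default_factory=dict)
    trait_covariates: dict = field(default_factory=dict)
    factor_levels: dict = field(default_factory=dict)
    covariate_ranges: dict = field(default_factory=dict)
    fixed_fraction: float = 0.20
    emit_weights_for_yw: bool = True

    def __post_init__(self):
        k = len(self.traits)
        for M, nm in ((self.true_G, "true_G"), (self.true_R, "true_R")):
            if M.shape != (k, k):
                raise ValueError(f"{nm} must be {k}x{k}")
            if not np.allclose(M, M.T):
                raise ValueError(f"{nm} must be symmetric")
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{nm} must be positive definite")
        if self.classes:
            total = sum(p for _, p, _ in self.classes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class proportions sum to {total}, not 1")
            for _, _, obs in self.classes:
                unknown = set(obs) - set(self.traits)
                if unknown:
                    raise ValueError(f"class observes undefined traits {unknown}")

    @property
    def n_animals(self) -> int:
        return self.n_founders + (
            self.n_generations * self.matings_per_generation * self.offspring_per_mating
        )

    def trait_definitions(self) -> tuple[TraitDefinition, ...]:
        return tuple(
            TraitDefinition(
                name=t,
                factors=tuple(self.trait_factors.get(t, ())),
                covariates=tuple(self.trait_covariates.get(t, ())),
                units=_UNITS.get(t, ""),
            )
            for t in self.traits
        )

    def true_h2(self) -> np.ndarray:
        return np.diag(self.true_G) / (np.diag(self.true_G) + np.diag(self.true_R))

    def true_rg(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.true_G))
        return self.true_G / np.outer(sd, sd)

    def true_rp(self) -> np.ndarray:
        P = self.true_G + self.true_R
        sd = np.sqrt(np.diag(P))
        return P / np.outer(sd, sd)


def hanwoo_design(scale: float = 1.0) -> SimulationDesign:
    """Default 8-trait design emulating the full study structure.

    At ``scale=1`` the pedigree has ~2,020 animals (test scale: recovery
    runs finish in minutes).  ``scale=8`` approaches the study's record
    count; it is correspondingly slow to fit.
    """
    traits = TRAIT_ORDER
    factors = {
        "UIMF": ("batch_sex_tech", "place"),
        "UEMA": ("batch_sex_tech", "place"),
        "UBFT": ("batch_sex_tech", "place"),
        "BFT": ("slaughter_date",),
        "CW": ("slaughter_date",),
        "EMA": ("slaughter_date",),
        "MS": ("slaughter_date",),
        "YW": ("batch_sex", "place_yw"),
    }
    covariates = {
        "UIMF": ("scan_age",), "UEMA": ("scan_age",), "UBFT": ("scan_age",),
        "BFT": ("slaughter_age",), "CW": ("slaughter_age",),
        "EMA": ("slaughter_age",), "MS": ("slaughter_age",),
        "YW": (),
    }
    m = max(int(round(40 * scale)), 4)
    return SimulationDesign(
        traits=traits,
        true_G=reference_G(traits),
        true_R=reference_R(traits),
        n_founders=max(int(round(100 * scale)), 10),
        n_generations=4,
        matings_per_generation=m,
        offspring_per_mating=12,
        classes=HANWOO_CLASSES,
        trait_factors=factors,
        trait_covariates=covariates,
        # level counts loosely proportional to the study's (108, 103, 87,
        # 109, 274 levels over ~16k records), scaled to the pedigree size
        factor_levels={
            "batch_sex_tech": max(int(12 * scale), 3),
            "place": max(int(12 * scale), 3),
            "batch_sex": max(int(10 * scale), 3),
            "place_yw": max(int(12 * scale), 3),
            "slaughter_date": max(int(30 * scale), 3),
        },
        covariate_ranges={"scan_age": (330.0, 420.0), "slaughter_age": (680.0, 780.0)},
    )


def recovery_design(n_target: int = 2000) -> SimulationDesign:
    """3-trait carcass design (CW, EMA, MS) used for parameter recovery.

    Carcass traits are recorded on steers only; the steer fraction matches
    the study (5,622 of 15,796 recorded animals), so bulls enter through
    the pedigree alone.  Truth comes from the published posterior means.
    """
    traits = ("CW", "EMA", "MS")
    founders = max(n_target // 17, 4)
    matings = max((n_target - founders) // (4 * 8), 1)
    return SimulationDesign(
        traits=traits,
        true_G=reference_G(traits),
        true_R=reference_R(traits),
        n_founders=founders,
        n_generations=4,
        matings_per_generation=matings,
        offspring_per_mating=8,
        classes=(
            ("steer", STEER_FRACTION, traits),
            ("bull", 1.0 - STEER_FRACTION, ()),
        ),
        trait_factors={t: ("slaughter_date",) for t in traits},
        trait_covariates={t: ("slaughter_age",) for t in traits},
        factor_levels={"slaughter_date": 25},
        covariate_ranges={"slaughter_age": (680.0, 780.0)},
        emit_weights_for_yw=False,
    )


def simulate_pedigree(design: SimulationDesign, rng: np.random.Generator) -> Pedigree:
    """Discrete generations, random mating without selfing.

    Parents of generation g are drawn from generation g-1; every non-founder
    has two known parents.  Labels encode generation and index (F0001,
    G1_0001, ...), and the output passes pedigree validation by construction.
    """
    records: list[tuple[str, str | None, str | None]] = []
    prev = [f"F{i+1:04d}" for i in range(design.n_founders)]
    if design.n_generations > 0 and design.n_founders < 2:
        raise ValueError("need at least two founders to mate")
    records.extend((lab, None, None) for lab in prev)
    for g in range(1, design.n_generations + 1):
        newgen = []
        for mtg in range(design.matings_per_generation):
            s, d = rng.choice(len(prev), size=2, replace=False)
            for o in range(design.offspring_per_mating):
                lab = f"G{g}_{mtg+1:03d}_{o+1:02d}"
                records.append((lab, prev[s], prev[d]))
                newgen.append(lab)
        prev = newgen
    return from_records(records)


def simulate_breeding_values(
    ped: Pedigree, true_G: np.ndarray, rng: np.random.Generator,
    F: np.ndarray | None = None,
) -> np.ndarray:
    """Breeding values with covariance G (x) A via the pedigree recursion.

    Founders are MVN(0, G); an offspring is the parent average plus a
    Mendelian-sampling deviation m ~ MVN(0, (0.5 - 0.25(F_s + F_d)) G),
    with an unknown parent contributing 0 and enlarging the deviation.
    """
    n = len(ped)
    k = true_G.shape[0]
    if F is None:
        F = compute_inbreeding(ped)
    L = np.linalg.cholesky(true_G)
    z = rng.standard_normal((n, k))
    u = np.zeros((n, k))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            u[i] = L @ z[i]
            continue
        mean = np.zeros(k)
        if s != UNKNOWN and d != UNKNOWN:
            mean = 0.5 * (u[s] + u[d])
            v = 0.5 - 0.25 * (F[s] + F[d])
        else:
            p = s if s != UNKNOWN else d
            mean = 0.5 * u[p]
            v = 0.75 - 0.25 * F[p]
        u[i] = mean + np.sqrt(v) * (L @ z[i])
    return u


def simulate_phenotypes(
    ped: Pedigree,
    u: np.ndarray,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> tuple[PhenotypeTable, dict]:
    """Phenotypes y = fixed effects + u + e with class-based missingness.

    Factor-level effects are N(0, tau^2) draws with tau^2 chosen so that all
    fixed terms of a trait jointly contribute ``fixed_fraction`` of its
    phenotypic variance; covariates are uniform ages with a slope on the
    same budget.  Founders carry no records; each non-founder is assigned a
    missingness class by the design's proportions.  When the design includes
    a YW trait and ``emit_weights_for_yw``, two raw weights and weighing days
    consistent with the simulated YW are emitted as extra covariate columns.
    """
    n = len(ped)
    traits = design.traits
    k = len(traits)
    vp = np.diag(design.true_G) + np.diag(design.true_R)

    # residuals and raw phenotypes
    Lr = np.linalg.cholesky(design.true_R)
    e = rng.standard_normal((n, k)) @ Lr.T
    y = u + e

    # factor assignments and effects
    factor_codes: dict[str, np.ndarray] = {}
    factor_effects: dict[str, np.ndarray] = {}
    truth_fixed: dict[str, dict] = {}
    all_factors = sorted({f for fs in design.trait_factors.values() for f in fs})
    for f in all_factors:
        nlev = design.factor_levels.get(f, 10)
        factor_codes[f] = rng.integers(0, nlev, size=n)
    covariate_values: dict[str, np.ndarray] = {}
    all_covs = sorted({c for cs in design.trait_covariates.values() for c in cs})
    for c in all_covs:
        lo, hi = design.covariate_ranges.get(c, (0.0, 1.0))
        covariate_values[c] = rng.uniform(lo, hi, size=n)

    for j, t in enumerate(traits):
        fs = design.trait_factors.get(t, ())
        cs = design.trait_covariates.get(t, ())
        n_terms = len(fs) + len(cs)
        share = design.fixed_fraction * vp[j] / n_terms if n_terms else 0.0
        for f in fs:
            nlev = design.factor_levels.get(f, 10)
            eff = rng.normal(0.0, np.sqrt(share), size=nlev)
            factor_effects[(t, f)] = eff
            y[:, j] += eff[factor_codes[f]]
            truth_fixed.setdefault(t, {})[f] = eff.tolist()
        for c in cs:
            lo, hi = design.covariate_ranges.get(c, (0.0, 1.0))
            var_c = (hi - lo) ** 2 / 12.0
            slope = np.sqrt(share / var_c) if var_c > 0 else 0.0
            xc = covariate_values[c] - 0.5 * (lo + hi)
            y[:, j] += slope * xc
            truth_fixed.setdefault(t, {})[c] = slope

    # missingness classes: founders unrecorded, non-founders by proportion
    observed = np.zeros((n, k), dtype=bool)
    founder = ped.founder_mask
    nonf = np.flatnonzero(~founder)
    class_of = np.full(n, -1, dtype=np.int64)
    if design.classes:
        props = np.array([p for _, p, _ in design.classes])
        assign = rng.choice(len(design.classes), size=nonf.size, p=props)
        class_of[nonf] = assign
        for ci, (_, _, obs_traits) in enumerate(design.classes):
            cols = [traits.index(t) for t in obs_traits]
            rows = nonf[assign == ci]
            for col in cols:
                observed[rows, col] = True
    else:
        observed[nonf] = True

    extra_covs = dict(covariate_values)
    if design.emit_weights_for_yw and "YW" in traits:
        jw = traits.index("YW")
        t_prev = rng.uniform(150.0, 250.0, size=n)
        t_term = rng.uniform(330.0, 420.0, size=n)
        w_prev = 0.55 * y[:, jw] + rng.normal(0.0, 5.0, size=n)
        slope = (y[:, jw] - w_prev) / (365.0 - t_prev)
        w_term = w_prev + slope * (t_term - t_prev)
        extra_covs.update(
            {"weight_prev": w_prev, "weight_term": w_term,
             "day_prev": t_prev, "day_term": t_term}
        )

    table = PhenotypeTable(
        animal_ids=list(ped.labels),
        values=y,
        observed=observed,
        traits=design.trait_definitions(),
        factors=factor_codes,
        factor_levels={
            f: [f"{f}_{i+1}" for i in range(design.factor_levels.get(f, 10))]
            for f in all_factors
        },
        covariates=extra_covs,
    )
    truth = {
        "traits": list(traits),
        "true_G": design.true_G.tolist(),
        "true_R": design.true_R.tolist(),
        "h2": design.true_h2().tolist(),
        "r_g": design.true_rg().tolist(),
        "r_p": design.true_rp().tolist(),
        "fixed_effects": truth_fixed,
        "class_of": class_of.tolist(),
        "class_names": [c[0] for c in design.classes],
    }
    return table, truth


def simulate_dataset(
    design: SimulationDesign, seed: int
) -> tuple[Pedigree, PhenotypeTable, np.ndarray, dict]:
    """Pedigree + phenotypes + true breeding values for one seeded replicate."""
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(design, rng)
    u = simulate_breeding_values(ped, design.true_G, rng)
    table, truth = simulate_phenotypes(ped, u, design, rng)
    return ped, table, u, truth


def write_dataset(design: SimulationDesign, seed: int, out_dir) -> dict:
    """Emit pedigree/phenotype files in the loaders' dialect plus truth JSON."""
    from .pedigree import write_pedigree
    from .phenotypes import write_phenotypes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped, table, u, truth = simulate_dataset(design, seed)
    write_pedigree(ped, out / "pedigree.csv", mapping_path=out / "pedigree_codes.csv")
    write_phenotypes(table, out / "phenotypes.csv")
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return {
        "pedigree": out / "pedigree.csv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
        "n_animals": len(ped),
    }
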