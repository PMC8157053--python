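"""Gibbs sampler for the multi-trait pedigree animal model.

Model: y = Xb + Zu + e with u ~ N(0, G (x) A) and e ~ N(0, R (x) I).
Flat priors on b; (conditionally) flat inverse-Wishart priors on G and R
with configurable degrees of freedom nu0 and scale S0 (default nu0 = 0,
S0 = 0, giving posterior df q and n respectively).

One iteration scans: location effects (single-site fixed effects, per-animal
trait blocks), missing-trait residual augmentation, then G and R from their
inverse-Wishart full conditionals.  Missing (animal, trait) cells are
modelled with mean u alone, so marginalising them leaves the observed-data
posterior untouched while keeping every conditional conjugate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import invwishart

from ._sweep import location_sweep
from .model import ModelSpec

__all__ = [
    "ChainConfig",
    "CovarianceState",
    "ChainResult",
    "sample_G",
    "sample_R",
    "sample_missing",
    "run_chain",
    "write_samples",
]

log = logging.getLogger(__name__)


class GibbsError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChainConfig:
    """MCMC schedule and prior convention.

    The default schedule (550,000 cycles, 50,000 burn-in, thinning 50)
    retains 10,000 samples.  ``nu0``/``S0`` select the flat-prior
    convention: 0/None is the default; nu0 = -(k+1) gives the alternative
    Jeffreys-style convention some programs use.
    """

    total_iterations: int = 550_000
    burn_in: int = 50_000
    thin: int = 50
    seed: int = 0
    store_location_effects: bool = False
    nu0_G: float = 0.0
    nu0_R: float = 0.0
    S0_G: np.ndarray | None = None
    S0_R: np.ndarray | None = None

    def __post_init__(self):
        if not (0 <= self.burn_in < self.total_iterations):
            raise ValueError("need 0 <= burn_in < total_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.total_iterations - self.burn_in) // self.thin


@dataclass
class CovarianceState:
    """Mutable chain state: covariances, location effects and residuals."""

    G: np.ndarray
    R: np.ndarray
    b: np.ndarray
    u: np.ndarray
    e: np.ndarray  # record residuals; augmented cells hold imputed residuals


@dataclass
class ChainResult:
    """Retained post-burn-in samples (thinned)."""

    iterations: np.ndarray  # (S,)
    G: np.ndarray  # (S, k, k)
    R: np.ndarray  # (S, k, k)
    trait_names: tuple[str, ...]
    b: np.ndarray | None = None  # (S, p) if stored
    u_mean: np.ndarray | None = None  # (n_ped, k) running mean if stored
    config: ChainConfig | None = None
    final_state: CovarianceState | None = None
    coef_labels: list = field(default_factory=list)


def _psd_scale(S: np.ndarray, what: str) -> np.ndarray:
    """Return S, jittered once if its Cholesky fails; raise if still bad."""
    try:
        np.linalg.cholesky(S)
        return S
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(S) if np.trace(S) > 0 else 1e-8
        log.warning("%s scale matrix not PD; adding jitter %.3e", what, jitter)
        S2 = S + jitter * np.eye(S.shape[0])
        try:
            np.linalg.cholesky(S2)
            return S2
        except np.linalg.LinAlgError:
            raise GibbsError(f"{what} scale matrix indefinite even after jitter")


def _iw_draw(S: np.ndarray, df: float, rng: np.random.Generator, size):
    """Inverse-Wishart draw(s) with shape normalised to (k,k) or (size,k,k)."""
    k = S.shape[0]
    if df <= k - 1:
        raise GibbsError(f"inverse-Wishart df {df} <= k-1 = {k - 1}")
    if size is None:
        d = invwishart.rvs(df=df, scale=S, random_state=rng)
        return np.asarray(d, dtype=float).reshape(k, k)
    d = invwishart.rvs(df=df, scale=S, size=size, random_state=rng)
    return np.asarray(d, dtype=float).reshape(size, k, k)


def sample_G(
    u: np.ndarray,
    A_inverse: sparse.spmatrix,
    rng: np.random.Generator,
    nu0: float = 0.0,
    S0: np.ndarray | None = None,
    size=None,
):
    """Draw G from its inverse-Wishart full conditional.

    Scale is U' A^-1 U (+ S0), degrees of freedom q + nu0 with q the number
    of animals.  ``size`` vectorises repeated draws for a fixed u (used by
    the conjugacy checks).
    """
    q, k = u.shape
    S = u.T @ (A_inverse @ u)
    if S0 is not None:
        S = S + S0
    S = _psd_scale(S, "genetic")
    df = q + nu0
    return _iw_draw(S, df, rng, size)


def sample_R(
    e: np.ndarray,
    rng: np.random.Generator,
    nu0: float = 0.0,
    S0: np.ndarray | None = None,
    size=None,
):
    """Draw R from its inverse-Wishart full conditional (scale E'E, df n + nu0)."""
    n, k = e.shape
    S = e.T @ e
    if S0 is not None:
        S = S + S0
    S = _psd_scale(S, "residual")
    df = n + nu0
    return _iw_draw(S, df, rng, size)


def stabilizing_scale(design: ModelSpec, factor: float = 1e-3) -> np.ndarray:
    """Weakly-informative prior scale: ``factor`` x diag(phenotypic variance).

    With the exactly-flat convention (S0 = 0) the posterior of sparse-record
    multi-trait models can place mass arbitrarily close to a singular R,
    where breeding values absorb residuals exactly and the chain is drawn
    into a degenerate boundary state.  A tiny positive-definite scale puts
    an exponential barrier at that boundary while being negligible against
    the data scale (it adds ``factor`` records' worth of variance).  Use it
    as ``S0_G``/``S0_R`` with ``nu0 = 0`` whenever records are much fewer
    than pedigree animals.
    """
    k = design.n_traits
    v = np.empty(k)
    for j in range(k):
        x = design.y[design.observed[:, j], j]
        v[j] = np.var(x, ddof=1) if x.size > 1 else 1.0
    return factor * np.diag(v)


def missing_conditionals(R: np.ndarray, patterns):
    """Per-pattern regression of missing on observed residuals under R.

    Returns list of (rows, obs_idx, mis_idx, B, L) with B the coefficient
    matrix of e_mis | e_obs and L the Cholesky factor of the conditional
    covariance; fully observed patterns yield None entries.
    """
    out = []
    for pat in patterns:
        m = np.flatnonzero(~pat.observed_mask)
        if m.size == 0:
            out.append(None)
            continue
        o = np.flatnonzero(pat.observed_mask)
        Roo = R[np.ix_(o, o)]
        B = R[np.ix_(m, o)] @ np.linalg.inv(Roo)
        C = R[np.ix_(m, m)] - B @ R[np.ix_(o, m)]
        C = 0.5 * (C + C.T)
        L = np.linalg.cholesky(C)
        out.append((pat.member_rows, o, m, B, L))
    return out


def sample_missing(e: np.ndarray, R: np.ndarray, patterns, rng: np.random.Generator):
    """Redraw augmented residuals from e_mis | e_obs ~ N(B e_obs, Schur(R)).

    Mutates ``e`` in place; rows with nothing missing are untouched.
    """
    for item in missing_conditionals(R, patterns):
        if item is None:
            continue
        rows, o, m, B, L = item
        z = rng.standard_normal((rows.size, m.size))
        e[np.ix_(rows, m)] = e[np.ix_(rows, o)] @ B.T + z @ L.T
    return e


def _initial_state(design: ModelSpec, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Starting G, R: half/half split of the observed per-trait variance."""
    v = np.empty(k)
    for j in range(k):
        x = design.y[design.observed[:, j], j]
        v[j] = np.var(x, ddof=1) if x.size > 1 else 1.0
        if v[j] <= 0:
            v[j] = 1.0
    return np.diag(v / 2), np.diag(v / 2)


def run_chain(
    config: ChainConfig,
    design: ModelSpec,
    A_inverse: sparse.spmatrix,
    G_init: np.ndarray | None = None,
    R_init: np.ndarray | None = None,
    update_G: bool = True,
    update_R: bool = True,
    progress_every: int = 0,
) -> ChainResult:
    """Run the Gibbs chain and return the retained (G, R) stream.

    Fully reproducible: all randomness derives from ``config.seed`` through
    independent per-operation streams (location, augmentation, G, R), so
    e.g. toggling ``store_location_effects`` cannot perturb the (G, R)
    stream.  ``update_G=False``/``update_R=False`` freeze the covariances
    (used by the generalized-least-squares oracle tests).
    """
    k = design.n_traits
    n_rec = design.n_records
    n_ped = design.n_ped
    p = design.n_coefficients

    ss = np.random.SeedSequence(config.seed)
    rng_loc, rng_mis, rng_G, rng_R = (np.random.default_rng(c) for c in ss.spawn(4))

    G0, R0 = _initial_state(design, k)
    G = np.array(G_init, dtype=float) if G_init is not None else G0
    R = np.array(R_init, dtype=float) if R_init is not None else R0
    Ginv = np.linalg.inv(G)
    Rinv = np.linalg.inv(R)

    b = np.zeros(p)
    u = np.zeros((n_ped, k))
    e = np.where(design.observed, design.y, 0.0).astype(float)

    rec_of_animal = np.full(n_ped, -1, dtype=np.int64)
    rec_of_animal[design.rec_animal] = np.arange(n_rec)
    Ainv = A_inverse.tocsr()
    sum_x2 = design.coef_sum_x2()
    any_missing = any((~pat.observed_mask).any() for pat in design.patterns)

    S = config.n_retained
    G_out = np.empty((S, k, k))
    R_out = np.empty((S, k, k))
    it_out = np.empty(S, dtype=np.int64)
    b_out = np.empty((S, p)) if config.store_location_effects else None
    u_sum = np.zeros((n_ped, k)) if config.store_location_effects else None

    s_idx = 0
    for it in range(1, config.total_iterations + 1):
        z_b = rng_loc.standard_normal(p)
        z_u = rng_loc.standard_normal((n_ped, k))
        code, where = location_sweep(
            b, u, e, Rinv, Ginv,
            design.coef_trait, design.coef_ptr, design.coef_rec, design.coef_x,
            sum_x2, rec_of_animal,
            Ainv.indptr, Ainv.indices, Ainv.data,
            z_b, z_u,
        )
        if code == 1:
            raise GibbsError(
                f"non-finite conditional variance for fixed effect "
                f"{design.coef_labels[where]} at iteration {it}"
            )
        if code == 2:
            raise GibbsError(
                f"breeding-value precision block not PD for animal code {where} "
                f"at iteration {it}"
            )
        if any_missing:
            sample_missing(e, R, design.patterns, rng_mis)
        if update_G:
            G = sample_G(u, Ainv, rng_G, nu0=config.nu0_G, S0=config.S0_G)
            Ginv = np.linalg.inv(G)
        if update_R:
            R = sample_R(e, rng_R, nu0=config.nu0_R, S0=config.S0_R)
            Rinv = np.linalg.inv(R)

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            it_out[s_idx] = it
            G_out[s_idx] = G
            R_out[s_idx] = R
            if config.store_location_effects:
                b_out[s_idx] = b
                u_sum += u
            s_idx += 1
        if progress_every and it % progress_every == 0:
            log.info(
                "iter %d: diag(G)=%s diag(R)=%s", it,
                np.array_str(np.diag(G), precision=3),
                np.array_str(np.diag(R), precision=3),
            )

    return ChainResult(
        iterations=it_out[:s_idx],
        G=G_out[:s_idx],
        R=R_out[:s_idx],
        trait_names=tuple(t.name for t in design.traits),
        b=b_out[:s_idx] if b_out is not None else None,
        u_mean=(u_sum / max(s_idx, 1)) if u_sum is not None else None,
        config=config,
        final_state=CovarianceState(G=G, R=R, b=b, u=u, e=e),
        coef_labels=design.coef_labels,
    )


def _upper_names(prefix: str, names) -> list[str]:
    k = len(names)
    return [f"{prefix}_{names[i]}_{names[j]}" for i in range(k) for j in range(i, k)]


def write_samples(result: ChainResult, path, sep: str = "\t") -> None:
    """Flat samples file: iteration, then upper triangles of G and R."""
    import pandas as pd

    k = len(result.trait_names)
    iu = np.triu_indices(k)
    cols = {"iteration": result.iterations}
    for name, arr in (("G", result.G), ("R", result.R)):
        tri = arr[:, iu[0], iu[1]]
        for c, label in enumerate(_upper_names(name, result.trait_names)):
            cols[label] = tri[:, c]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_samples(path, sep: str = "\t") -> ChainResult:
    """Read a samples file written by :func:`write_samples`."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep)
    g_cols = [c for c in df.columns if c.startswith("G_")]
    names: list[str] = []
    for c in g_cols:
        first = c[2:].split("_")[0]
        if first not in names:
            names.append(first)
    k = len(names)
    if len(g_cols) != k * (k + 1) // 2:
        # trait names containing underscores: fall back to counting
        m = len(g_cols)
        k = int((np.sqrt(8 * m + 1) - 1) / 2)
        names = [f"t{i+1}" for i in range(k)]
    iu = np.triu_indices(k)
    S = len(df)
    G = np.zeros((S, k, k))
    R = np.zeros((S, k, k))
    for arr, prefix in ((G, "G"), (R, "R")):
        tri = df[[c for c in df.columns if c.startswith(prefix + "_")]].to_numpy()
        arr[:, iu[0], iu[1]] = tri
        arr[:, iu[1], iu[0]] = tri
    return ChainResult(
        iterations=df["iteration"].to_numpy(dtype=np.int64),
        G=G,
        R=R,
        trait_names=tuple(names),
    )
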