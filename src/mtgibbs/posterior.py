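"""Posterior summaries: variance components, heritabilities, genetic and
phenotypic correlations, plus convergence diagnostics.

All derived quantities are computed per retained sample and then averaged
(ratio-then-average), which is how Bayesian posterior means of ratios are
reported; averaging the components first and then taking the ratio can
differ in the second decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "heritability",
    "genetic_correlation",
    "phenotypic_correlation",
    "PosteriorSummary",
    "summarize",
    "diagnostics",
    "write_report",
    "plot_traces",
]

log = logging.getLogger(__name__)


def heritability(G: np.ndarray, R: np.ndarray, i: int) -> np.ndarray:
    """h2 = G_ii / (G_ii + R_ii), elementwise over samples (or one sample)."""
    return G[..., i, i] / (G[..., i, i] + R[..., i, i])


def genetic_correlation(G: np.ndarray, i: int, j: int) -> np.ndarray:
    """r_g = G_ij / sqrt(G_ii G_jj)."""
    return G[..., i, j] / np.sqrt(G[..., i, i] * G[..., j, j])


def phenotypic_correlation(G: np.ndarray, R: np.ndarray, i: int, j: int) -> np.ndarray:
    """r_p = (G_ij + R_ij) / sqrt(sp2_i sp2_j) with sp2 = G_ii + R_ii."""
    P = G + R
    return P[..., i, j] / np.sqrt(P[..., i, i] * P[..., j, j])


@dataclass
class PosteriorSummary:
    """Posterior means/SDs of the reported genetic parameters.

    ``components``: one row per trait with sigma_a2, sigma_e2, sigma_p2 and
    h2 (mean and SD each).  ``correlations``: one row per trait pair with
    r_g and r_p.  ``correlation_matrix``: genetic above the diagonal,
    phenotypic below, ones on it.
    """

    trait_names: tuple[str, ...]
    components: pd.DataFrame
    correlations: pd.DataFrame
    correlation_matrix: pd.DataFrame
    hdi_95: pd.DataFrame


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1))


def _hdi(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    xs = np.sort(x)
    n = len(xs)
    m = max(int(np.floor(prob * n)), 1)
    widths = xs[m:] - xs[: n - m]
    lo = int(np.argmin(widths))
    return float(xs[lo]), float(xs[lo + m])


def summarize(G: np.ndarray, R: np.ndarray, trait_names=None) -> PosteriorSummary:
    """Reduce retained (G, R) samples to the reported parameter table.

    Order-invariant in the samples; every quantity is derived per sample
    first.  95% highest-density intervals are included for machine use.
    """
    S, k, _ = G.shape
    names = tuple(trait_names) if trait_names else tuple(f"t{i+1}" for i in range(k))
    comp_rows, hdi_rows = [], []
    for i in range(k):
        sa2 = G[:, i, i]
        se2 = R[:, i, i]
        sp2 = sa2 + se2
        h2 = heritability(G, R, i)
        row = {"trait": names[i]}
        for label, x in (("sigma_a2", sa2), ("sigma_e2", se2),
                         ("sigma_p2", sp2), ("h2", h2)):
            m, s = _mean_sd(x)
            row[label] = m
            row[label + "_sd"] = s
            lo, hi = _hdi(x)
            hdi_rows.append({"quantity": f"{label}[{names[i]}]",
                             "hdi_2.5": lo, "hdi_97.5": hi})
        comp_rows.append(row)
    corr_rows = []
    M = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rg = genetic_correlation(G, i, j)
            rp = phenotypic_correlation(G, R, i, j)
            (mg, sg), (mp, sp) = _mean_sd(rg), _mean_sd(rp)
            corr_rows.append({
                "trait_i": names[i], "trait_j": names[j],
                "r_g": mg, "r_g_sd": sg, "r_p": mp, "r_p_sd": sp,
            })
            for label, x in ((f"r_g[{names[i]},{names[j]}]", rg),
                             (f"r_p[{names[i]},{names[j]}]", rp)):
                lo, hi = _hdi(x)
                hdi_rows.append({"quantity": label, "hdi_2.5": lo, "hdi_97.5": hi})
            M[i, j] = mg  # genetic above the diagonal
            M[j, i] = mp  # phenotypic below
    return PosteriorSummary(
        trait_names=names,
        components=pd.DataFrame(comp_rows),
        correlations=pd.DataFrame(corr_rows),
        correlation_matrix=pd.DataFrame(M, index=list(names), columns=list(names)),
        hdi_95=pd.DataFrame(hdi_rows),
    )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the autocorrelation time (arviz bulk estimator)."""
    import arviz as az

    return float(az.ess(np.asarray(x, dtype=float)))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early vs late chain windows.

    Means of the first ``first`` and last ``last`` fractions are compared
    with variances estimated as spectral density at frequency zero (simple
    batch-free autocovariance-sum estimator, lags up to sqrt(window)).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: int(first * n)]
    b = x[int((1 - last) * n):]

    def s0(y):
        y = y - y.mean()
        m = len(y)
        lags = int(np.sqrt(m))
        acov = [y @ y / m]
        for lag in range(1, lags + 1):
            acov.append(y[:-lag] @ y[lag:] / m)
        return acov[0] + 2 * sum(
            (1 - lag / (lags + 1)) * acov[lag] for lag in range(1, lags + 1)
        )

    va, vb = s0(a) / len(a), s0(b) / len(b)
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def diagnostics(result, min_samples: int = 50) -> pd.DataFrame | None:
    """Per-quantity ESS and Geweke z for the chain's derived parameters.

    Returns None (with a warning) when fewer than ``min_samples`` retained
    samples are available.  Degenerate (constant) streams are flagged with
    NaN diagnostics rather than crashing.
    """
    G, R = result.G, result.R
    S, k, _ = G.shape
    if S < min_samples:
        log.warning("only %d retained samples; diagnostics skipped", S)
        return None
    names = result.trait_names
    streams: dict[str, np.ndarray] = {}
    for i in range(k):
        streams[f"sigma_a2[{names[i]}]"] = G[:, i, i]
        streams[f"sigma_e2[{names[i]}]"] = R[:, i, i]
        streams[f"h2[{names[i]}]"] = heritability(G, R, i)
    for i in range(k):
        for j in range(i + 1, k):
            streams[f"r_g[{names[i]},{names[j]}]"] = genetic_correlation(G, i, j)
    rows = []
    for label, x in streams.items():
        if np.ptp(x) == 0.0:
            rows.append({"quantity": label, "ess": np.nan, "geweke_z": np.nan,
                         "flag": "degenerate"})
            continue
        ess = effective_sample_size(x)
        z = geweke_z(x)
        rows.append({
            "quantity": label, "ess": ess, "geweke_z": z,
            "flag": "drift?" if abs(z) > 2 else "",
        })
    return pd.DataFrame(rows)


def _fmt2(v: float) -> str:
    return f"{v:.2f}"


def write_report(summary: PosteriorSummary, out_dir, prefix: str = "posterior") -> None:
    """Write the variance-component and correlation tables.

    Emits machine-readable TSVs plus human-readable 2-decimal text in the
    usual layout: components with h2 per trait, and one square matrix with
    genetic correlations above the diagonal, phenotypic below.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.components.to_csv(out / f"{prefix}_components.tsv", sep="\t", index=False)
    summary.correlations.to_csv(out / f"{prefix}_correlations.tsv", sep="\t", index=False)
    summary.hdi_95.to_csv(out / f"{prefix}_hdi95.tsv", sep="\t", index=False)

    lines = ["Trait\tsigma_a2\tsigma_e2\tsigma_p2\th2"]
    for _, r in summary.components.iterrows():
        lines.append(
            f"{r['trait']}\t{_fmt2(r['sigma_a2'])} ({_fmt2(r['sigma_a2_sd'])})\t"
            f"{_fmt2(r['sigma_e2'])} ({_fmt2(r['sigma_e2_sd'])})\t"
            f"{_fmt2(r['sigma_p2'])} ({_fmt2(r['sigma_p2_sd'])})\t"
            f"{_fmt2(r['h2'])} ({_fmt2(r['h2_sd'])})"
        )
    names = summary.trait_names
    lines.append("")
    lines.append("Correlations (genetic above diagonal, phenotypic below)")
    lines.append("\t" + "\t".join(names))
    Mat = summary.correlation_matrix.to_numpy()
    for i, nm in enumerate(names):
        cells = ["" if i == j else _fmt2(Mat[i, j]) for j in range(len(names))]
        lines.append(nm + "\t" + "\t".join(cells))
    (out / f"{prefix}_report.txt").write_text("\n".join(lines) + "\n")


def plot_traces(result, out_dir, prefix: str = "trace") -> list:
    """Trace plots of sigma_a2, sigma_e2 and h2 per trait (PNG files)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = result.trait_names
    k = len(names)
    paths = []
    for i in range(k):
        fig, axes = plt.subplots(3, 1, figsize=(7, 6), sharex=True)
        for ax, (label, x) in zip(
            axes,
            (
                ("sigma_a2", result.G[:, i, i]),
                ("sigma_e2", result.R[:, i, i]),
                ("h2", heritability(result.G, result.R, i)),
            ),
        ):
            ax.plot(result.iterations, x, lw=0.4)
            ax.set_ylabel(label)
        axes[-1].set_xlabel("iteration")
        fig.suptitle(names[i])
        path = out / f"{prefix}_{names[i]}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
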